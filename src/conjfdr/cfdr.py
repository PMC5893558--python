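"""Stratified conditional FDR and conjunction FDR.

The conditional FDR of trait 1 given trait 2, FDR(p1 | p2), is the
empirical-Bayes estimate of the posterior probability that a SNP is null
for trait 1 given that both traits' p-values are at least as small as
observed. With the null proportion conservatively set to 1 it reduces to

    cFDR(p1 | p2) = p1 / F_hat(p1 | p2 <= t2),

where F_hat is the empirical CDF of trait-1 p-values among SNPs whose
trait-2 p-value falls below the conditioning threshold t2 (cumulative
strata, default p2 <= 1, 0.1, 0.01, 0.001). The conjunction FDR — the
posterior probability that a SNP is null for either trait or both — is
conservatively estimated as the maximum of the two conditional FDRs, and
discoveries are flagged at conjunction FDR < 0.05.

The counting kernel here (``joint_exceedance_counts``) is the single
source of truth shared with the fold-enrichment module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_STRATA = (1.0, 0.1, 0.01, 0.001)

#: Sentinel returned by conditional_cdf when the conditioning stratum is empty.
EMPTY_STRATUM = float("nan")


@dataclass
class CfdrConfig:
    strata: tuple = DEFAULT_STRATA
    grid_size: int = 101
    fdr_threshold: float = 0.05
    min_stratum_size: int = 100
    pruning_r: int = 0            # 0 disables LD-aware count averaging
    pruning_seed: int = 0

    def sorted_strata(self) -> np.ndarray:
        s = np.sort(np.asarray(self.strata, dtype=float))[::-1]
        if s[0] != 1.0:
            s = np.concatenate([[1.0], s])  # base stratum is always present
        return s


def joint_exceedance_counts(p1, p2, t1_list, t2_list) -> np.ndarray:
    """counts[s, g] = #{i : p1_i <= t1[g] and p2_i <= t2[s]} (ties use <=)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    t1 = np.asarray(t1_list, dtype=float)
    out = np.empty((len(t2_list), len(t1)), dtype=np.int64)
    for s, t2 in enumerate(t2_list):
        sorted_p1 = np.sort(p1[p2 <= t2])
        out[s] = np.searchsorted(sorted_p1, t1, side="right")
    return out


def conditional_cdf(p1, p2, p1_threshold: float, p2_threshold: float) -> float:
    """Empirical F(p1 <= t1 | p2 <= t2); NaN sentinel on an empty stratum."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    in_stratum = p2 <= p2_threshold
    denom = int(in_stratum.sum())
    if denom == 0:
        return EMPTY_STRATUM
    return float(np.count_nonzero(p1[in_stratum] <= p1_threshold) / denom)


def assign_strata(p2, strata: np.ndarray, min_stratum_size: int) -> np.ndarray:
    """Index (into decreasing ``strata``) of each SNP's conditioning stratum.

    A SNP belongs to the smallest configured threshold >= its p2; strata
    holding fewer than ``min_stratum_size`` SNPs fall back to the next
    larger one (logged). The base stratum must satisfy the minimum size.
    """
    p2 = np.asarray(p2, dtype=float)
    denoms = np.array([(p2 <= t).sum() for t in strata])
    if denoms[0] < min_stratum_size:
        raise ValueError(
            f"base stratum has {denoms[0]} SNPs < min_stratum_size={min_stratum_size}")
    usable = denoms >= min_stratum_size
    # deepest usable stratum index for each SNP
    idx = np.zeros(len(p2), dtype=np.int64)
    for s in range(1, len(strata)):
        if usable[s]:
            idx[p2 <= strata[s]] = s
        else:
            logger.warning("stratum p2 <= %g has %d SNPs (< %d); falling back",
                           strata[s], denoms[s], min_stratum_size)
    return idx


def _raw_cfdr(p1, p2, strata, stratum_idx, prune_masks=None) -> np.ndarray:
    """min(1, p1 / F_hat(p1 | stratum)) per SNP, before monotonicity.

    When ``prune_masks`` is given (list of boolean keep-masks from random
    LD prunings), the conditional CDF is the average of the pruned
    empirical CDFs; per-SNP evaluation still covers all SNPs.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    cdf = np.empty(len(p1), dtype=float)
    for s, t2 in enumerate(strata):
        snps = stratum_idx == s
        if not snps.any():
            continue
        if prune_masks is None:
            sorted_p1 = np.sort(p1[p2 <= t2])
            cdf[snps] = np.searchsorted(sorted_p1, p1[snps], side="right") / len(sorted_p1)
        else:
            acc = np.zeros(int(snps.sum()))
            n_ok = 0
            for keep in prune_masks:
                sel = keep & (p2 <= t2)
                m = int(sel.sum())
                if m == 0:
                    continue
                sorted_p1 = np.sort(p1[sel])
                acc += np.searchsorted(sorted_p1, p1[snps], side="right") / m
                n_ok += 1
            cdf[snps] = acc / n_ok if n_ok else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(cdf > 0, p1 / cdf, 1.0)
    return np.minimum(raw, 1.0)


def enforce_monotone(raw, p1, stratum_idx) -> np.ndarray:
    """Running minimum scanning from p1 = 1 downward, within each stratum.

    Guarantees a smaller observed p1 never receives a larger cFDR; raw
    count ratios are noisy in the extreme tail.
    """
    out = np.asarray(raw, dtype=float).copy()
    p1 = np.asarray(p1, dtype=float)
    for s in np.unique(stratum_idx):
        snps = np.flatnonzero(stratum_idx == s)
        order = snps[np.argsort(-p1[snps], kind="mergesort")]
        out[order] = np.minimum.accumulate(out[order])
    return out


def cfdr_values(p1, p2, config: CfdrConfig | None = None, prune_masks=None) -> np.ndarray:
    """Per-SNP conditional FDR of trait 1 given trait 2."""
    config = config or CfdrConfig()
    strata = config.sorted_strata()
    idx = assign_strata(p2, strata, config.min_stratum_size)
    raw = _raw_cfdr(p1, p2, strata, idx, prune_masks)
    return enforce_monotone(raw, p1, idx)


def conjunction_fdr(cfdr_1_given_2, cfdr_2_given_1):
    """Conservative conjunction FDR: the maximum of the two conditionals."""
    return np.maximum(cfdr_1_given_2, cfdr_2_given_1)


@dataclass
class LookupGrid:
    """cFDR lookup table over a log-spaced p1 grid, for export/re-plotting."""

    p1_grid: np.ndarray
    p2_strata: np.ndarray
    counts: np.ndarray
    cfdr_table: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, t2 in enumerate(self.p2_strata):
            rows.append(pd.DataFrame({
                "p2_stratum": t2, "p1": self.p1_grid,
                "count": self.counts[s], "cfdr": self.cfdr_table[s]}))
        return pd.concat(rows, ignore_index=True)


def build_lookup_grid(p1, p2, config: CfdrConfig | None = None) -> LookupGrid:
    from .sumstats import P_FLOOR

    config = config or CfdrConfig()
    strata = config.sorted_strata()
    grid = np.logspace(0.0, np.log10(P_FLOOR), config.grid_size)  # 1 .. floor, decreasing
    counts = joint_exceedance_counts(p1, p2, grid, strata)
    denoms = np.array([(np.asarray(p2) <= t).sum() for t in strata], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cdf = counts / denoms[:, None]
        table = np.where(cdf > 0, grid[None, :] / cdf, 1.0)
    table = np.minimum(table, 1.0)
    # running min from p1 = 1 (index 0) downward along the grid
    table = np.minimum.accumulate(table, axis=1)
    return LookupGrid(p1_grid=grid, p2_strata=strata, counts=counts, cfdr_table=table)


def run_conjunction(panel, trait_a: str, trait_b: str,
                    config: CfdrConfig | None = None, blocks=None) -> pd.DataFrame:
    """Full conjunction-FDR analysis for one trait pair on a panel.

    Returns one row per SNP with both conditional FDRs, the conjunction
    FDR (their maximum) and the significance flag at the configured
    threshold. ``blocks`` (snp -> block id) enables LD-aware count
    averaging over ``config.pruning_r`` random prunings.
    """
    config = config or CfdrConfig()
    ia, ib = panel.trait_index(trait_a), panel.trait_index(trait_b)
    pa, pb = panel.p[:, ia], panel.p[:, ib]

    prune_masks = None
    if config.pruning_r > 0:
        if blocks is None:
            raise ValueError("pruning_r > 0 requires a block assignment")
        rng = np.random.default_rng(config.pruning_seed)
        block_ids = np.asarray([blocks[s] for s in panel.snp_ids])
        prune_masks = []
        for _ in range(config.pruning_r):
            perm = rng.permutation(len(block_ids))
            _, first = np.unique(block_ids[perm], return_index=True)
            keep = np.zeros(len(block_ids), dtype=bool)
            keep[perm[first]] = True
            prune_masks.append(keep)

    c_a_b = cfdr_values(pa, pb, config, prune_masks)
    c_b_a = cfdr_values(pb, pa, config, prune_masks)
    conj = conjunction_fdr(c_a_b, c_b_a)
    return pd.DataFrame({
        "snp": panel.snp_ids, "chrom": panel.chrom, "pos": panel.pos,
        f"p_{trait_a}": pa, f"p_{trait_b}": pb,
        "cfdr_1g2": c_a_b, "cfdr_2g1": c_b_a, "conjfdr": conj,
        "significant": conj < config.fdr_threshold,
    })
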