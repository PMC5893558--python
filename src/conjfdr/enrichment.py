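"""Stratified fold-enrichment curves, TDR interpretation, and figures.

Pleiotropic enrichment of trait A with trait B shows up as an excess of
small trait-A p-values among SNPs already nominally associated with trait
B. The curve computed here is the ratio of conditional to unconditional
tail proportions of trait-A p-values,

    fold[s, g] = [#{pA <= 10^-g, pB <= 10^-s} / #{pB <= 10^-s}]
                 / [#{pA <= 10^-g} / n],

evaluated on a -log10 grid capped at 7.3 (i.e. above the genome-wide
threshold p = 5e-8, to probe the polygenic sub-threshold signal), for
conditioning strata -log10(pB) >= 0, 1, 2 by default. Enrichment is
interpretable on the true-discovery-rate scale as TDR ~ 1 - 1/fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cfdr import joint_exceedance_counts

logger = logging.getLogger(__name__)

DEFAULT_STRATA_NEGLOG = (0.0, 1.0, 2.0)
DEFAULT_GRID = np.round(np.arange(0.0, 7.3 + 1e-9, 0.1), 10)

#: Joint exceedance count below which a fold cell is considered unreliable
#: (keeps the Poisson coefficient of variation of the ratio under ~7.5%).
RELIABLE_MIN_COUNT = 200


@dataclass
class EnrichmentCurve:
    grid: np.ndarray                 # increasing -log10(pA) evaluation points
    strata_neglog: np.ndarray        # -log10(pB) conditioning levels, 0 = all SNPs
    strata_labels: list[str]
    fold: np.ndarray                 # [strata x grid]; NaN where the cell is empty
    counts: np.ndarray               # joint exceedance counts, same shape
    stratum_sizes: np.ndarray
    n_snps: int

    def log2_fold(self, min_count: int = RELIABLE_MIN_COUNT) -> np.ma.MaskedArray:
        """log2 fold with unreliable (low-count) cells masked."""
        mask = (self.counts < min_count) | ~np.isfinite(self.fold) | (self.fold <= 0)
        return np.ma.masked_array(np.log2(np.where(self.fold > 0, self.fold, np.nan)),
                                  mask=mask)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, lab in enumerate(self.strata_labels):
            rows.append(pd.DataFrame({
                "stratum": lab, "neglog10_pA": self.grid,
                "fold": self.fold[s], "count": self.counts[s]}))
        return pd.concat(rows, ignore_index=True)


def fold_enrichment(pA, pB, strata=DEFAULT_STRATA_NEGLOG, grid=None) -> EnrichmentCurve:
    """Fold-enrichment of trait-A p-values across trait-B conditioning strata.

    The base stratum (-log10(pB) >= 0, all SNPs) is identically 1 wherever
    defined. Cells whose conditioning stratum or joint count is empty are
    NaN-flagged; summaries should additionally mask low-count cells via
    :meth:`EnrichmentCurve.log2_fold`.
    """
    pA = np.asarray(pA, dtype=float)
    pB = np.asarray(pB, dtype=float)
    if len(pA) == 0:
        raise ValueError("empty base SNP set")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    strata = np.asarray(strata, dtype=float)
    t1 = 10.0 ** (-grid)
    t2 = 10.0 ** (-strata)
    counts = joint_exceedance_counts(pA, pB, t1, t2)
    denoms = np.array([(pB <= t).sum() for t in t2], dtype=float)
    base = counts[strata == 0.0][0] if (strata == 0.0).any() else \
        joint_exceedance_counts(pA, pB, t1, [1.0])[0]
    n = float(len(pA))
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = counts / denoms[:, None]
        uncond = base / n
        fold = cond / uncond[None, :]
    fold[:, base == 0] = np.nan
    fold[denoms == 0, :] = np.nan
    labels = [f"-log10(pB) >= {s:g}" if s > 0 else "All SNPs" for s in strata]
    return EnrichmentCurve(grid=grid, strata_neglog=strata, strata_labels=labels,
                           fold=fold, counts=counts,
                           stratum_sizes=denoms.astype(np.int64), n_snps=len(pA))


def tdr_from_enrichment(fold: float, base_rate: float = 1.0) -> float:
    """Interpretive true-discovery-rate overlay, TDR = 1 - 1/fold, in [0, 1].

    Under a uniform null tail the unconditional tail is almost all null, so
    a fold-x enrichment of the conditional tail implies at most 1/x of it is
    null. This is an interpretation aid, not an inferential statistic.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if not (0 < base_rate <= 1):
        raise ValueError("base_rate must be in (0, 1]")
    return float(np.clip(1.0 - 1.0 / fold, 0.0, 1.0))


def plot_enrichment(curve: EnrichmentCurve, out, log_y: bool = True,
                    min_count: int = 1, style_seed: int = 0):
    """Render one line per conditioning stratum; empty strata are omitted
    (with a legend note). Writes PNG or SVG depending on the extension."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with _deterministic_style():
        fig, ax = plt.subplots(figsize=(5, 4))
        for s, lab in enumerate(curve.strata_labels):
            y = np.where(curve.counts[s] >= min_count, curve.fold[s], np.nan)
            if not np.isfinite(y).any():
                ax.plot([], [], label=f"{lab} (empty)")
                continue
            ax.plot(curve.grid, y, label=lab)
        if log_y:
            ax.set_yscale("log")
        ax.set_xlabel(r"nominal $-\log_{10}(p)$, trait A")
        ax.set_ylabel("fold enrichment")
        ax.legend(fontsize=8)
        fig.tight_layout()
        _savefig(fig, out)
        plt.close(fig)
    return out


def plot_conjunction_manhattan(results: pd.DataFrame, leads=None, annotations=None,
                               out=None, fdr_threshold: float = 0.05):
    """Conjunction Manhattan plot: y = -log10(conjunction FDR) by genomic
    position; significant SNPs enlarged, lead SNPs outlined and labeled
    with their closest gene."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = results.copy()
    leads = np.zeros(len(res), dtype=bool) if leads is None else np.asarray(leads, dtype=bool)
    chroms = sorted(pd.unique(res["chrom"]), key=_chrom_key)
    offset, offsets = 0, {}
    for c in chroms:
        offsets[c] = offset
        offset += int(res.loc[res["chrom"] == c, "pos"].max()) + 1
    x = res["pos"].to_numpy(float) + np.array([offsets[c] for c in res["chrom"]])
    y = -np.log10(np.maximum(res["conjfdr"].to_numpy(float), 1e-300))
    sig = res["significant"].to_numpy(bool)

    with _deterministic_style():
        fig, ax = plt.subplots(figsize=(7, 3.2))
        for i, c in enumerate(chroms):
            m = (res["chrom"] == c).to_numpy() & ~sig
            ax.scatter(x[m], y[m], s=4, color=("0.55", "0.75")[i % 2], linewidths=0)
        ax.scatter(x[sig & ~leads], y[sig & ~leads], s=22, color="tab:orange", linewidths=0)
        ax.scatter(x[leads], y[leads], s=34, color="tab:orange",
                   edgecolors="black", linewidths=0.8)
        if annotations is not None:
            for i in np.flatnonzero(leads):
                gene = annotations[i] if not isinstance(annotations, dict) \
                    else annotations.get(res["snp"].iloc[i], "NA")
                ax.annotate(str(gene), (x[i], y[i]), textcoords="offset points",
                            xytext=(0, 4), ha="center", fontsize=7, fontstyle="italic")
        ax.axhline(-np.log10(fdr_threshold), color="tab:red", lw=0.6, ls="--")
        ax.set_xlabel("chromosome")
        ax.set_ylabel(r"$-\log_{10}$(conjunction FDR)")
        ax.set_xticks([offsets[c] + res.loc[res["chrom"] == c, "pos"].max() / 2 for c in chroms])
        ax.set_xticklabels([str(c) for c in chroms], fontsize=7)
        fig.tight_layout()
        _savefig(fig, out)
        plt.close(fig)
    return out


def _chrom_key(c):
    c = str(c)
    return (0, int(c)) if c.isdigit() else (1, c)


def _deterministic_style():
    import matplotlib

    return matplotlib.rc_context({
        "svg.hashsalt": "conjfdr", "svg.fonttype": "none",
        "figure.dpi": 100, "savefig.dpi": 100,
    })


def _savefig(fig, out):
    out = str(out)
    kw = {"metadata": ({"Date": None} if out.endswith(".svg") else None)}
    if out.endswith(".png"):
        kw["metadata"] = {"Software": None}
    fig.savefig(out, **kw)
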