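"""Reading, validation and harmonization of GWAS summary statistics.

A summary-statistics table carries one row per SNP with an effect allele
(a1), other allele (a2) and some subset of {beta, se, z, p}. On load the
Wald Z-score and two-sided p-value are both populated and made mutually
consistent, rows failing validation are dropped (and counted), and tables
from several traits can be intersected into an allele-aligned
:class:`HarmonizedPanel` whose Z signs all refer to the first trait's
effect-allele orientation.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: p-values below this are floored so that -log10(p) survives text round-trips.
P_FLOOR = 1e-300

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: A/T and C/G pairs cannot be strand-resolved from summary data alone.
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

#: Default header synonyms, case-insensitive (consortium files vary widely).
DEFAULT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "snp": ("snp", "rsid", "rs_id", "markername", "marker", "snpid", "id"),
    "chrom": ("chrom", "chr", "chromosome", "#chrom"),
    "pos": ("pos", "bp", "position", "base_pair_location", "pos_b37", "pos_b38"),
    "a1": ("a1", "effect_allele", "alt", "allele1", "ea"),
    "a2": ("a2", "other_allele", "ref", "allele2", "oa", "nea"),
    "beta": ("beta", "effect", "b", "log_odds", "logor"),
    "se": ("se", "stderr", "standard_error", "sebeta"),
    "z": ("z", "zscore", "z_score", "zstat"),
    "p": ("p", "pval", "p_value", "pvalue", "p_val", "p.value"),
    "n": ("n", "nobs", "samplesize", "n_total", "neff"),
}

MANDATORY = ("snp", "chrom", "pos", "a1", "a2")


@dataclass
class SummaryStatTable:
    """One trait's per-SNP association results, validated and sorted."""

    trait_name: str
    records: pd.DataFrame
    genome_build_label: str = ""
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class HarmonizedPanel:
    """SNP-intersected, allele-aligned multi-trait Z/p matrices.

    ``z[:, k]`` is trait k's Z-score with sign referring to trait 1's
    effect allele at each SNP; ``p`` has the same shape.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    z: np.ndarray
    p: np.ndarray
    trait_names: list[str]
    log: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def trait_index(self, name: str) -> int:
        try:
            return self.trait_names.index(name)
        except ValueError:
            raise KeyError(f"trait {name!r} not in panel {self.trait_names}") from None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"snp": self.snp_ids, "chrom": self.chrom, "pos": self.pos,
             "a1": self.a1, "a2": self.a2}
        )
        for k, name in enumerate(self.trait_names):
            out[f"z_{name}"] = self.z[:, k]
            out[f"p_{name}"] = self.p[:, k]
        return out

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def wald_z(beta, se):
    """Wald Z-score, beta / se. ``se`` must be strictly positive."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be > 0")
    return beta / se


def p_from_z(z):
    """Two-sided normal p-value for a Wald Z, floored at ``P_FLOOR``."""
    p = 2.0 * stats.norm.sf(np.abs(np.asarray(z, dtype=float)))
    return np.maximum(p, P_FLOOR)


def z_from_p(p, sign=1.0):
    """|Z| implied by a two-sided p-value, with the given sign."""
    p = np.asarray(p, dtype=float)
    return np.asarray(sign, dtype=float) * stats.norm.isf(p / 2.0)


def normalize_chrom(c) -> str:
    c = str(c).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "23":
        c = "X"
    return c.upper() if c.upper() in {"X", "Y", "MT", "M"} else c


def _resolve_columns(header: list[str], column_map: dict | None) -> dict[str, str]:
    """Map canonical field names to actual header names."""
    resolved: dict[str, str] = {}
    lower = {h.lower(): h for h in header}
    column_map = column_map or {}
    for canon, synonyms in DEFAULT_SYNONYMS.items():
        if canon in column_map:
            if column_map[canon] in header:
                resolved[canon] = column_map[canon]
            continue
        for s in synonyms:
            if s in lower:
                resolved[canon] = lower[s]
                break
    return resolved


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sumstats(path, column_map: dict | None = None, trait_name: str = "",
                  sep: str | None = None, genome_build_label: str = "") -> SummaryStatTable:
    """Read a delimited summary-statistics file into a validated table.

    Rows failing validation (bad alleles, se <= 0, p outside (0, 1],
    non-positive position) are dropped and counted; duplicate SNP ids keep
    the record with the smallest p. Z and p are populated from whichever of
    {beta+se, z, p} is present and made consistent (p recomputed from z when
    they disagree by more than 1e-8 relative).
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep=sep if sep is not None else r"\s+",
                         engine="python" if sep is None else "c")
    cols = _resolve_columns(list(df.columns), column_map)
    missing = [c for c in MANDATORY if c not in cols]
    if missing:
        raise ValueError(f"{path}: mandatory columns not found: {missing}")
    has_beta_se = "beta" in cols and "se" in cols
    if not (has_beta_se or "z" in cols or "p" in cols):
        raise ValueError(f"{path}: need beta+se, z, or p to derive Z-scores")

    out = pd.DataFrame({
        "snp": df[cols["snp"]].astype(str),
        "chrom": df[cols["chrom"]].map(normalize_chrom),
        "pos": pd.to_numeric(df[cols["pos"]], errors="coerce"),
        "a1": df[cols["a1"]].astype(str).str.upper().str.strip(),
        "a2": df[cols["a2"]].astype(str).str.upper().str.strip(),
    })
    for f in ("beta", "se", "z", "p", "n"):
        out[f] = pd.to_numeric(df[cols[f]], errors="coerce") if f in cols else np.nan

    n0 = len(out)
    ok = (
        out["pos"].notna() & (out["pos"] > 0)
        & out["a1"].isin(VALID_ALLELES) & out["a2"].isin(VALID_ALLELES)
        & (out["a1"] != out["a2"])
    )
    # at least one usable statistic per row
    usable = (out["beta"].notna() & out["se"].notna() & (out["se"] > 0))
    usable |= out["z"].notna()
    usable |= out["p"].notna() & (out["p"] > 0) & (out["p"] <= 1)
    ok &= usable
    # explicit bad values even when another field could rescue the row:
    ok &= ~(out["se"].notna() & (out["se"] <= 0))
    ok &= ~(out["p"].notna() & ((out["p"] <= 0) | (out["p"] > 1)))
    dropped = int(n0 - ok.sum())
    if dropped:
        logger.warning("%s: dropped %d/%d rows failing validation", path, dropped, n0)
    out = out[ok].copy()
    if out.empty:
        raise ValueError(f"{path}: no valid rows after validation")

    # populate z
    out["unsigned"] = False
    from_beta = out["beta"].notna() & out["se"].notna()
    out.loc[from_beta, "z"] = out.loc[from_beta, "beta"] / out.loc[from_beta, "se"]
    need_z = out["z"].isna()
    if need_z.any():
        out.loc[need_z, "z"] = z_from_p(out.loc[need_z, "p"].to_numpy())
        out.loc[need_z, "unsigned"] = True
        logger.warning("%s: %d rows have p only; |z| imputed with sign +1 "
                       "(flagged unsigned)", path, int(need_z.sum()))
    # populate / reconcile p
    p_implied = p_from_z(out["z"].to_numpy())
    have_p = out["p"].notna().to_numpy()
    rel = np.abs(out["p"].to_numpy() - p_implied) / np.maximum(p_implied, P_FLOOR)
    inconsistent = have_p & (rel > 1e-8)
    out["p"] = np.where(have_p & ~inconsistent, out["p"].to_numpy(), p_implied)
    out["p"] = np.maximum(out["p"], P_FLOOR)
    if inconsistent.any():
        logger.warning("%s: %d p-values recomputed from z (relative mismatch > 1e-8)",
                       path, int(inconsistent.sum()))

    # duplicates: keep smallest p
    n_dup = int(out["snp"].duplicated().sum())
    if n_dup:
        logger.warning("%s: %d duplicate snp ids; keeping smallest p", path, n_dup)
        out = out.sort_values("p", kind="mergesort").drop_duplicates("snp", keep="first")
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return SummaryStatTable(trait_name=trait_name or str(path), records=out,
                            genome_build_label=genome_build_label,
                            n_dropped=dropped + n_dup)


def is_ambiguous(a1, a2) -> np.ndarray:
    a1 = np.asarray(a1, dtype=object)
    a2 = np.asarray(a2, dtype=object)
    return np.fromiter(((x, y) in AMBIGUOUS_PAIRS for x, y in zip(a1, a2)),
                       dtype=bool, count=len(a1))


def harmonize(tables: list[SummaryStatTable], autosomes_only: bool = True) -> HarmonizedPanel:
    """Intersect >= 2 trait tables on SNP id and align allele orientations.

    Trait 1 defines the reference (a1, a2) per SNP. For every other trait:
    exact allele match keeps z; swapped alleles negate z; a strand flip of
    either case behaves the same after complementing. Strand-ambiguous
    (A/T, C/G) SNPs and irreconcilable allele pairs are dropped.
    """
    if len(tables) < 2:
        raise ValueError("harmonize requires at least 2 tables")
    ref = tables[0].records
    common = ref["snp"]
    for t in tables[1:]:
        common = common[common.isin(set(t.records["snp"]))]
    if common.empty:
        raise ValueError("empty SNP intersection across traits")
    ref = ref.set_index("snp").loc[common].reset_index()

    amb = is_ambiguous(ref["a1"], ref["a2"])
    keep = ~amb
    counts = {"intersection": len(ref), "ambiguous_dropped": int(amb.sum())}
    if autosomes_only:
        sex = ref["chrom"].isin(["X", "Y", "MT", "M"]).to_numpy()
        counts["non_autosomal_dropped"] = int((sex & keep).sum())
        keep &= ~sex
    ref = ref[keep].reset_index(drop=True)

    z_cols = [ref["z"].to_numpy(dtype=float)]
    p_cols = [ref["p"].to_numpy(dtype=float)]
    match_keep = np.ones(len(ref), dtype=bool)
    n_flipped = 0
    ra1, ra2 = ref["a1"].to_numpy(object), ref["a2"].to_numpy(object)
    for t in tables[1:]:
        rec = t.records.set_index("snp").loc[ref["snp"]]
        ta1 = rec["a1"].to_numpy(object)
        ta2 = rec["a2"].to_numpy(object)
        ca1 = np.array([COMPLEMENT[a] for a in ta1], dtype=object)
        ca2 = np.array([COMPLEMENT[a] for a in ta2], dtype=object)
        same = ((ta1 == ra1) & (ta2 == ra2)) | ((ca1 == ra1) & (ca2 == ra2))
        swap = ((ta1 == ra2) & (ta2 == ra1)) | ((ca1 == ra2) & (ca2 == ra1))
        z = rec["z"].to_numpy(dtype=float).copy()
        z[swap] = -z[swap]
        n_flipped += int(swap.sum())
        match_keep &= same | swap
        z_cols.append(z)
        p_cols.append(rec["p"].to_numpy(dtype=float))
    counts["allele_mismatch_dropped"] = int((~match_keep).sum())
    counts["swapped_negated"] = n_flipped
    if not match_keep.any():
        raise ValueError("no SNPs with reconcilable alleles across traits")
    ref = ref[match_keep].reset_index(drop=True)
    z = np.column_stack([c[match_keep] for c in z_cols])
    p = np.column_stack([c[match_keep] for c in p_cols])
    counts["final"] = len(ref)
    logger.info("harmonize: %s", counts)
    return HarmonizedPanel(
        snp_ids=ref["snp"].to_numpy(object), chrom=ref["chrom"].to_numpy(object),
        pos=ref["pos"].to_numpy(dtype=np.int64), a1=ra1[match_keep], a2=ra2[match_keep],
        z=z, p=p, trait_names=[t.trait_name for t in tables], log=counts,
    )
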