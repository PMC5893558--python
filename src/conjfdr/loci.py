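"""LD-block clumping of significant SNPs and closest-gene annotation.

Association signals within an LD block are reported through a single lead
SNP (the one with the smallest conjunction FDR). Blocks come either from a
positional window merge (default 250 kb, no external data needed) or from
connected components of a user-supplied pairwise r^2 table thresholded at
r^2 >= 0.2. Leads are annotated with the closest gene by gene-body
distance, from BED or GFF3 annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 250_000
DEFAULT_R2_THRESHOLD = 0.2


@dataclass
class LdBlockAssignment:
    block_of: dict            # snp_id -> block_id
    method: str               # "window" | "r2_graph"
    parameters: dict = field(default_factory=dict)

    def __getitem__(self, snp_id):
        return self.block_of[snp_id]


@dataclass
class GeneAnnotation:
    gene_name: str
    chrom: str
    start: int               # 1-based inclusive
    end: int
    source: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_name}: start > end")


def assign_blocks(snp_ids, chrom, pos, ld_table: pd.DataFrame | None = None,
                  method: str = "window", window_bp: int = DEFAULT_WINDOW_BP,
                  r2_threshold: float = DEFAULT_R2_THRESHOLD) -> LdBlockAssignment:
    """Partition SNPs into LD blocks.

    window: SNPs sorted by position are greedily merged while the next SNP
    lies within ``window_bp`` of the current block's span; blocks are
    contiguous intervals on one chromosome. r2_graph: connected components
    of the graph with an edge wherever r^2 >= threshold (``ld_table`` needs
    columns snp_a, snp_b, r2; pairs naming unknown SNPs are ignored).
    """
    snp_ids = np.asarray(snp_ids, dtype=object)
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    if method == "window":
        order = np.lexsort((pos, chrom.astype(str)))
        block_of, bid = {}, -1
        cur_chrom, cur_end = None, None
        for i in order:
            if chrom[i] != cur_chrom or pos[i] - cur_end > window_bp:
                bid += 1
            cur_chrom, cur_end = chrom[i], pos[i]
            block_of[snp_ids[i]] = bid
        return LdBlockAssignment(block_of, "window", {"window_bp": window_bp})
    if method == "r2_graph":
        if ld_table is None:
            raise ValueError("r2_graph method requires an ld_table")
        index = {s: i for i, s in enumerate(snp_ids)}
        parent = np.arange(len(snp_ids))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        n_unknown = 0
        for a, b, r2 in ld_table[["snp_a", "snp_b", "r2"]].itertuples(index=False):
            if a not in index or b not in index:
                n_unknown += 1
                continue
            if r2 >= r2_threshold:
                ra, rb = find(index[a]), find(index[b])
                parent[ra] = rb
        if n_unknown:
            logger.warning("ld_table: %d pairs referenced unknown SNPs; ignored", n_unknown)
        roots = np.array([find(i) for i in range(len(snp_ids))])
        _, bids = np.unique(roots, return_inverse=True)
        return LdBlockAssignment(dict(zip(snp_ids, bids.tolist())), "r2_graph",
                                 {"r2_threshold": r2_threshold})
    raise ValueError(f"unknown block method {method!r}")


def lead_snps(results: pd.DataFrame, blocks: LdBlockAssignment) -> np.ndarray:
    """Flag, per block with >= 1 significant SNP, the SNP with the smallest
    conjunction FDR (ties: smaller p1, then lexicographic snp id)."""
    leads = np.zeros(len(results), dtype=bool)
    sig = results["significant"].to_numpy(bool)
    if not sig.any():
        return leads
    p1_col = next(c for c in results.columns if c.startswith("p_"))
    block_ids = np.array([blocks[s] for s in results["snp"]])
    sub = results.loc[sig, ["snp", "conjfdr", p1_col]].copy()
    sub["block"] = block_ids[sig]
    sub["_i"] = np.flatnonzero(sig)
    sub = sub.sort_values(["conjfdr", p1_col, "snp"], kind="mergesort")
    winners = sub.drop_duplicates("block", keep="first")["_i"].to_numpy()
    leads[winners] = True
    return leads


def read_gene_annotation(path) -> list[GeneAnnotation]:
    """Load genes from BED (0-based half-open) or GFF3 (1-based inclusive),
    normalized internally to 1-based inclusive coordinates."""
    import pyranges as pr

    from .sumstats import normalize_chrom

    path = str(path)
    if path.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
        df = pr.read_gff3(path).df
        df = df[df["Feature"] == "gene"] if "Feature" in df and (df["Feature"] == "gene").any() else df
        names = df["Name"] if "Name" in df else df.get("ID", df["Chromosome"].astype(str))
        tag = "gff3"
    else:
        df = pr.read_bed(path).df
        names = df["Name"] if "Name" in df else df.index.astype(str)
        tag = "bed"
    # pyranges holds 0-based half-open starts for both formats
    return [
        GeneAnnotation(gene_name=str(n), chrom=normalize_chrom(c),
                       start=int(s) + 1, end=int(e), source=tag)
        for n, c, s, e in zip(names, df["Chromosome"], df["Start"], df["End"])
    ]


def closest_gene(chrom, pos: int, genes: list[GeneAnnotation]):
    """Closest gene by gene-body distance (0 when inside the gene).

    Returns (gene_name, signed distance in bp; negative = gene upstream of
    the position, 0 = inside). Ties go to the smaller start coordinate.
    Returns ("NA", None) when the chromosome has no genes.
    """
    from .sumstats import normalize_chrom

    chrom = normalize_chrom(chrom)
    best = None
    for g in sorted(genes, key=lambda g: (g.start, g.end, g.gene_name)):
        if g.chrom != chrom:
            continue
        if g.start <= pos <= g.end:
            d = 0
        elif pos < g.start:
            d = g.start - pos
        else:
            d = -(pos - g.end)
        if best is None or abs(d) < abs(best[1]):
            best = (g.gene_name, d)
    if best is None:
        return "NA", None
    return best


def lead_report(results: pd.DataFrame, leads: np.ndarray,
                genes: list[GeneAnnotation] | None,
                panel=None) -> pd.DataFrame:
    """One row per lead SNP: rsID, closest gene, chromosome, alleles,
    conjunction FDR and the per-trait raw p-values."""
    p_cols = [c for c in results.columns if c.startswith("p_")]
    rows = []
    allele = {}
    if panel is not None:
        allele = {s: (a1, a2) for s, a1, a2 in zip(panel.snp_ids, panel.a1, panel.a2)}
    for i in np.flatnonzero(np.asarray(leads, dtype=bool)):
        r = results.iloc[i]
        gene, dist = closest_gene(r["chrom"], int(r["pos"]), genes) if genes else ("NA", None)
        a1, a2 = allele.get(r["snp"], ("NA", "NA"))
        row = {"rsid": r["snp"], "gene": gene, "chrom": r["chrom"], "pos": int(r["pos"]),
               "ref_allele": a2, "alt_allele": a1, "conjfdr": r["conjfdr"],
               "distance_bp": dist if dist is not None else "NA",
               "intergenic": (dist != 0) if dist is not None else "NA"}
        row.update({c: r[c] for c in p_cols})
        rows.append(row)
    return pd.DataFrame(rows)
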