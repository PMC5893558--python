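"""Two-trait GWAS summary-statistic simulator with known pleiotropy.

Each SNP is drawn from a four-component mixture: null for both traits,
non-null for trait 1 only, trait 2 only, or both (pleiotropic). Non-null
SNPs receive a latent mean effect on the Z scale, N(0, sigma^2) per
affected trait; pleiotropic effects are correlated across traits (default
0.8) so shared SNPs tend to be jointly extreme — the architecture that
produces conditional enrichment. Observed Z = (latent + noise) * sqrt(lambda),
where the noise is block-equicorrelated (shared Gaussian factor per LD
block) and lambda injects optional genomic inflation. Ground-truth
component labels are returned alongside, so FDR calibration is testable
without any real cohort data.

Effects are simulated directly on the Z scale — the downstream analysis
consumes only Z and p — and beta/se columns are emitted as z and 1 for
format compatibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import SummaryStatTable, p_from_z

logger = logging.getLogger(__name__)

COMPONENTS = ("null", "trait1_only", "trait2_only", "pleiotropic")
_NONAMBIGUOUS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                 ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
N_CHROM = 22
SNP_SPACING_BP = 5_000


@dataclass
class SimConfig:
    """Study conditions for the two-trait simulation.

    Defaults mirror the calibration regime exercised throughout the test
    suite: 1e5 SNPs, 0.5% of SNPs non-null per class, effect SD 4 on the
    Z scale, no LD, no inflation.
    """

    n_snps: int = 100_000
    n_traits: int = 2
    pi: tuple = (0.985, 0.005, 0.005, 0.005)   # null, trait1, trait2, pleiotropic
    sigma: tuple = (4.0, 4.0, 4.0)             # effect SD: trait1, trait2, shared
    shared_effect_corr: float = 0.8
    ld_block_size: int = 1
    rho: float = 0.0                           # within-block noise correlation
    inflation: tuple = (1.0, 1.0)
    n_samples: tuple = (10_000, 10_000)        # metadata only
    seed: int = 0

    def validate(self):
        pi = np.asarray(self.pi, dtype=float)
        if len(pi) != 4 or (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("mixture proportions must be 4 non-negative values summing to 1")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if any(s < 0 for s in self.sigma):
            raise ValueError("sigma must be >= 0")
        if self.n_traits != 2:
            raise ValueError("only the two-trait simulator is implemented")
        return self


@dataclass
class TruthTable:
    labels: pd.Series          # snp_id -> component label

    def mask(self, *components) -> np.ndarray:
        return self.labels.isin(components).to_numpy()


def simulate_panel(config: SimConfig) -> tuple[list[SummaryStatTable], TruthTable]:
    """Draw per-trait summary statistics plus truth labels; deterministic
    given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_snps

    comp = rng.choice(4, size=n, p=np.asarray(config.pi, dtype=float))
    s1, s2, s12 = config.sigma
    mu = np.zeros((n, 2))
    m = comp == 1
    mu[m, 0] = rng.normal(0.0, s1, m.sum())
    m = comp == 2
    mu[m, 1] = rng.normal(0.0, s2, m.sum())
    m = comp == 3
    if m.any():
        c = config.shared_effect_corr
        cov = s12**2 * np.array([[1.0, c], [c, 1.0]])
        mu[m] = rng.multivariate_normal([0.0, 0.0], cov, size=m.sum())

    # block-equicorrelated unit noise, independently per trait
    bs = max(int(config.ld_block_size), 1)
    block_id = np.arange(n) // bs
    n_blocks = block_id[-1] + 1
    noise = np.empty((n, 2))
    for t in range(2):
        e = rng.normal(size=n)
        b = rng.normal(size=n_blocks)[block_id]
        noise[:, t] = np.sqrt(1.0 - config.rho) * e + np.sqrt(config.rho) * b
    lam = np.asarray(config.inflation, dtype=float)
    z = (mu + noise) * np.sqrt(lam)[None, :]
    p = p_from_z(z)

    snp = np.array([f"rs{i + 1:07d}" for i in range(n)], dtype=object)
    # contiguous runs of whole blocks per chromosome (blocks never straddle)
    chrom_of_block = (np.arange(n_blocks) * N_CHROM // n_blocks) + 1
    chrom = chrom_of_block[block_id].astype(str)
    pos = np.empty(n, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = (np.arange(len(idx)) + 1) * SNP_SPACING_BP
    alleles = np.array(_NONAMBIGUOUS, dtype=object)[rng.integers(0, len(_NONAMBIGUOUS), n)]

    tables = []
    for t in range(2):
        df = pd.DataFrame({
            "snp": snp, "chrom": chrom, "pos": pos,
            "a1": alleles[:, 0], "a2": alleles[:, 1],
            "beta": z[:, t], "se": 1.0, "z": z[:, t], "p": p[:, t],
            "n": config.n_samples[t], "unsigned": False,
        })
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        tables.append(SummaryStatTable(trait_name=f"trait{t + 1}", records=df,
                                       genome_build_label="synthetic"))
    truth = TruthTable(labels=pd.Series(
        np.array(COMPONENTS, dtype=object)[comp], index=snp, name="component"))
    return tables, truth


def write_fixture(tables: list[SummaryStatTable], truth: TruthTable, out_dir,
                  config: SimConfig | None = None) -> dict:
    """Write per-trait TSVs (sumstats dialect), a truth TSV and the config
    JSON; ``read_sumstats`` round-trips the tables losslessly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for t in tables:
        p = out / f"{t.trait_name}.sumstats.tsv"
        t.records.drop(columns=["unsigned"]).to_csv(p, sep="\t", index=False,
                                                    float_format="%.17g")
        paths[t.trait_name] = str(p)
    tp = out / "truth.tsv"
    truth.labels.rename_axis("snp").to_frame().to_csv(tp, sep="\t")
    paths["truth"] = str(tp)
    if config is not None:
        cp = out / "sim_config.json"
        cp.write_text(json.dumps(asdict(config), indent=1) + "\n")
        paths["config"] = str(cp)
    return paths


def read_truth(path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)  # "null" is a label
    return TruthTable(labels=pd.Series(df["component"].to_numpy(object),
                                       index=pd.Index(df["snp"].astype(str).to_numpy(object)),
                                       name="component"))
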