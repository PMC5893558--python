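import numpy as np
import pytest

from conjfdr.sumstats import HarmonizedPanel, p_from_z


def panel_from_p(p1, p2, chrom=None, pos=None, names=("trait1", "trait2")):
    """Build a HarmonizedPanel directly from two p-vectors (for unit tests
    that do not care about alleles)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n = len(p1)
    from scipy import stats

    z = np.column_stack([stats.norm.isf(p1 / 2), stats.norm.isf(p2 / 2)])
    return HarmonizedPanel(
        snp_ids=np.array([f"rs{i:06d}" for i in range(n)], dtype=object),
        chrom=np.array(["1"] * n, dtype=object) if chrom is None else np.asarray(chrom, dtype=object),
        pos=np.arange(1, n + 1) * 1000 if pos is None else np.asarray(pos, dtype=np.int64),
        a1=np.array(["A"] * n, dtype=object), a2=np.array(["G"] * n, dtype=object),
        z=z, p=np.column_stack([p1, p2]), trait_names=list(names),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 20k-SNP simulated two-trait panel with truth labels (session-cached)."""
    from conjfdr.simulate import SimConfig, simulate_panel
    from conjfdr.sumstats import harmonize

    tables, truth = simulate_panel(SimConfig(n_snps=20_000, seed=11))
    return harmonize(tables), truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
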