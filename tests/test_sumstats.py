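import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from conjfdr.sumstats import (P_FLOOR, HarmonizedPanel, harmonize, p_from_z,
                              read_sumstats, wald_z, z_from_p)


def write_tsv(path, rows, header="snp chrom pos a1 a2 beta se p"):
    lines = [header.replace(" ", "\t")]
    lines += ["\t".join(str(x) for x in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestWaldZ:
    @pytest.mark.parametrize("beta,se,expected", [(1.0, 0.5, 2.0), (0.0, 1.0, 0.0),
                                                  (-0.3, 0.1, -3.0)])
    def test_ratio(self, beta, se, expected):
        assert wald_z(beta, se) == pytest.approx(expected)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_z(1.0, 0.0)


class TestPFromZ:
    def test_zero_gives_one(self):
        assert p_from_z(0.0) == 1.0

    def test_quantile(self):
        assert p_from_z(1.959964) == pytest.approx(0.05, abs=1e-6)

    def test_underflow_floored(self):
        assert p_from_z(40.0) == P_FLOOR

    @given(st.floats(0.01, 30), st.floats(0.01, 30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_abs_z(self, a, b):
        lo, hi = sorted([a, b])
        assert p_from_z(hi) <= p_from_z(lo)


def test_unsigned_z_matches_quadrature_oracle():
    """|z| recovered from p only must satisfy: integral of the standard
    normal density over [-|z|, |z|] equals 1 - p."""
    for p in (0.3, 0.04, 1e-6):
        z = float(z_from_p(p))
        mass, _ = integrate.quad(stats.norm.pdf, -z, z)
        assert mass == pytest.approx(1 - p, abs=1e-9)
        assert z > 0  # sign convention +1


class TestReadSumstats:
    def test_well_formed_roundtrip(self, tmp_path):
        f = write_tsv(tmp_path / "a.tsv", [
            ("rs1", 1, 100, "A", "G", 0.1, 0.1, p_from_z(1.0)),
            ("rs2", 1, 200, "C", "A", -0.2, 0.1, p_from_z(2.0)),
            ("rs3", 2, 50, "G", "T", 0.0, 0.1, 1.0),
        ])
        t = read_sumstats(f, trait_name="a")
        assert len(t) == 3
        assert list(t.records["z"].round(6)) == [1.0, -2.0, 0.0]
        np.testing.assert_allclose(t.records["p"], p_from_z(t.records["z"]), rtol=1e-8)

    def test_bad_se_row_dropped(self, tmp_path):
        f = write_tsv(tmp_path / "a.tsv", [
            ("rs1", 1, 100, "A", "G", 0.1, 0.0, 0.5),
            ("rs2", 1, 200, "C", "A", 0.1, 0.1, p_from_z(1.0)),
        ])
        t = read_sumstats(f)
        assert len(t) == 1 and t.n_dropped == 1

    def test_p_only_flagged_unsigned(self, tmp_path):
        f = write_tsv(tmp_path / "a.tsv", [("rs1", 1, 100, "A", "G", 0.05)],
                      header="snp chrom pos a1 a2 p")
        t = read_sumstats(f)
        assert t.records["unsigned"].all()
        assert t.records["z"].iloc[0] == pytest.approx(float(z_from_p(0.05)))

    def test_duplicate_keeps_smallest_p(self, tmp_path):
        f = write_tsv(tmp_path / "a.tsv", [
            ("rs1", 1, 100, "A", "G", 0.1, 0.1, p_from_z(1.0)),
            ("rs1", 1, 100, "A", "G", 0.3, 0.1, p_from_z(3.0)),
        ])
        t = read_sumstats(f)
        assert len(t) == 1
        assert t.records["z"].iloc[0] == pytest.approx(3.0)

    def test_missing_mandatory_column_errors(self, tmp_path):
        f = write_tsv(tmp_path / "a.tsv", [("rs1", 1, 100, "A", 0.1, 0.1, 0.5)],
                      header="snp chrom pos a1 beta se p")
        with pytest.raises(ValueError, match="mandatory"):
            read_sumstats(f)

    def test_zero_valid_rows_errors(self, tmp_path):
        f = write_tsv(tmp_path / "a.tsv", [("rs1", 1, 100, "A", "A", 0.1, 0.1, 0.5)])
        with pytest.raises(ValueError, match="no valid rows"):
            read_sumstats(f)

    def test_synonym_headers_and_gzip(self, tmp_path):
        import gzip

        content = "MarkerName\tCHR\tBP\tEffect_allele\tOther_allele\tBETA\tStdErr\tP\n" \
                  "rs9\tchr2\t500\ta\tc\t0.2\t0.1\t%.6g\n" % p_from_z(2.0)
        f = tmp_path / "b.tsv.gz"
        with gzip.open(f, "wt") as fh:
            fh.write(content)
        t = read_sumstats(f)
        assert len(t) == 1 and t.records["chrom"].iloc[0] == "2"


def _table(rows, trait):
    from conjfdr.sumstats import SummaryStatTable

    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "a1", "a2", "z"])
    df["p"] = p_from_z(df["z"])
    df["beta"] = df["z"]
    df["se"] = 1.0
    df["n"] = 1000
    df["unsigned"] = False
    return SummaryStatTable(trait_name=trait, records=df)


class TestHarmonize:
    def test_swap_negates_z(self):
        t1 = _table([("rs1", "1", 100, "A", "G", 2.0)], "a")
        t2 = _table([("rs1", "1", 100, "G", "A", -2.0)], "b")
        panel = harmonize([t1, t2])
        np.testing.assert_allclose(panel.z[0], [2.0, 2.0])

    def test_strand_flip_of_swap_negates_z(self):
        t1 = _table([("rs1", "1", 100, "A", "G", 2.0)], "a")
        t2 = _table([("rs1", "1", 100, "C", "T", -2.0)], "b")  # complement of G/A
        panel = harmonize([t1, t2])
        np.testing.assert_allclose(panel.z[0], [2.0, 2.0])

    def test_ambiguous_snp_dropped(self):
        t1 = _table([("rs1", "1", 100, "A", "T", 2.0), ("rs2", "1", 200, "A", "G", 1.0)], "a")
        t2 = _table([("rs1", "1", 100, "A", "T", 2.0), ("rs2", "1", 200, "A", "G", 1.0)], "b")
        panel = harmonize([t1, t2])
        assert list(panel.snp_ids) == ["rs2"]

    def test_disjoint_sets_error(self):
        t1 = _table([("rs1", "1", 100, "A", "G", 2.0)], "a")
        t2 = _table([("rs2", "1", 200, "A", "G", 2.0)], "b")
        with pytest.raises(ValueError, match="intersection"):
            harmonize([t1, t2])

    def test_flip_roundtrip_identity(self):
        """harmonize(t, flip_alleles(t)) restores equal z columns."""
        rows = [("rs1", "1", 100, "A", "G", 2.0), ("rs2", "1", 200, "C", "A", -1.5),
                ("rs3", "2", 300, "G", "T", 0.7)]
        t1 = _table(rows, "a")
        flipped = [(s, c, p, a2, a1, -z) for s, c, p, a1, a2, z in rows]
        t2 = _table(flipped, "b")
        panel = harmonize([t1, t2])
        np.testing.assert_allclose(panel.z[:, 0], panel.z[:, 1])

    def test_abs_z_invariant(self):
        t1 = _table([("rs1", "1", 100, "A", "G", 2.0), ("rs2", "1", 200, "C", "T", -3.0)], "a")
        t2 = _table([("rs1", "1", 100, "G", "A", 2.0), ("rs2", "1", 200, "T", "C", -3.0)], "b")
        panel = harmonize([t1, t2])
        np.testing.assert_allclose(np.abs(panel.z[:, 1]), [2.0, 3.0])

    def test_sex_chromosomes_excluded_by_default(self):
        t1 = _table([("rs1", "X", 100, "A", "G", 2.0), ("rs2", "1", 200, "A", "G", 1.0)], "a")
        t2 = _table([("rs1", "X", 100, "A", "G", 2.0), ("rs2", "1", 200, "A", "G", 1.0)], "b")
        assert list(harmonize([t1, t2]).snp_ids) == ["rs2"]
        assert len(harmonize([t1, t2], autosomes_only=False).snp_ids) == 2
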