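import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mapit import (
    load_genotypes,
    load_phenotype,
    quantile_normalize,
    standardize,
    write_plink,
)
from mapit.genotypes_io import EmptyPanelError, FormatError


class TestStandardize:
    def test_column_moments(self, rng):
        counts = rng.integers(0, 3, size=(50, 10))
        while (counts.std(axis=0) == 0).any():
            counts = rng.integers(0, 3, size=(50, 10))
        Z = standardize(counts)
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        assert np.abs(Z.std(axis=0) - 1).max() < 1e-10

    def test_symmetric_column_uses_population_sd(self):
        Z = standardize(np.array([[0.0], [1.0], [2.0]]))
        assert np.allclose(Z[:, 0], [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_idempotent(self, rng):
        counts = rng.integers(0, 3, size=(40, 5)).astype(float)
        Z = standardize(counts)
        assert np.allclose(standardize(Z), Z, atol=1e-8)

    def test_constant_column_raises(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(np.array([[1, 0], [1, 1], [1, 2]]))


class TestQuantileNormalize:
    def test_rank_quantiles(self):
        out = quantile_normalize(np.array([10.0, 20.0, 30.0]))
        expected = stats.norm.ppf([0.25, 0.5, 0.75])
        assert np.allclose(out, expected, atol=1e-12)

    def test_ties_share_a_quantile(self):
        out = quantile_normalize(np.array([1.0, 2.0, 2.0, 5.0]))
        # average-rank oracle: tied entries get rank 2.5 -> same quantile
        expected = stats.norm.ppf(np.array([1.0, 2.5, 2.5, 4.0]) / 5)
        assert np.allclose(out, expected)
        assert out[1] == out[2]

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=30, unique=True))
    def test_monotone_transform_invariance(self, values):
        v = np.asarray(values, dtype=float)
        assert np.allclose(quantile_normalize(v), quantile_normalize(np.exp(v / 100)))

    def test_output_centered(self, rng):
        out = quantile_normalize(rng.standard_normal(101))
        assert abs(out.mean()) < 1e-2


class TestLoadTsv:
    def write(self, tmp_path, body):
        f = tmp_path / "geno.tsv"
        f.write_text(body)
        return f

    def test_standardizes_columns(self, tmp_path):
        f = self.write(tmp_path, "v1\tv2\n0\t2\n1\t1\n2\t0\n")
        g = load_genotypes(f, format="tsv", maf_floor=0.0)
        assert g.standardized.shape == (3, 2)
        assert np.abs(g.standardized.mean(axis=0)).max() < 1e-10
        assert np.abs(g.standardized.std(axis=0) - 1).max() < 1e-10

    def test_constant_column_dropped(self, tmp_path):
        f = self.write(tmp_path, "v1\tv2\tv3\n0\t1\t2\n1\t1\t1\n2\t1\t0\n")
        g = load_genotypes(f, format="tsv", maf_floor=0.0)
        assert list(g.variant_ids) == ["v1", "v3"]

    def test_maf_floor(self, tmp_path):
        # v2 has one alt allele in 8 -> freq 1/16 < 0.25; v1, v3 are common
        rows = ["v1\tv2\tv3"] + ["1\t0\t2"] * 4 + ["0\t0\t1"] * 3 + ["2\t1\t0"]
        f = self.write(tmp_path, "\n".join(rows) + "\n")
        g = load_genotypes(f, format="tsv", maf_floor=0.25)
        assert list(g.variant_ids) == ["v1", "v3"]

    def test_bad_count_named_in_error(self, tmp_path):
        f = self.write(tmp_path, "v1\tv2\n0\t5\n1\t1\n2\t0\n")
        with pytest.raises(FormatError, match="v2"):
            load_genotypes(f, format="tsv")

    def test_all_dropped_raises(self, tmp_path):
        f = self.write(tmp_path, "v1\tv2\n1\t1\n1\t1\n1\t1\n")
        with pytest.raises(EmptyPanelError):
            load_genotypes(f, format="tsv", maf_floor=0.0)


class TestPlinkRoundTrip:
    @pytest.mark.parametrize("n,p", [(7, 5), (8, 3), (33, 12)])
    def test_counts_recovered_exactly(self, tmp_path, rng, n, p):
        counts = rng.integers(0, 3, size=(n, p)).astype(np.int8)
        counts[:, 0] = [0, 1, 2] * (n // 3) + [1] * (n % 3)  # keep polymorphic
        prefix = tmp_path / "panel"
        write_plink(counts, prefix)
        g = load_genotypes(prefix, format="plink", maf_floor=0.0)
        kept = [int(v[3:]) for v in g.variant_ids]
        assert np.array_equal(g.counts, counts[:, kept])
        # every polymorphic column must have survived
        poly = [j for j in range(p) if counts[:, j].std() > 0]
        assert kept == poly

    def test_missing_triplet_member(self, tmp_path, rng):
        counts = rng.integers(0, 3, size=(6, 4)).astype(np.int8)
        prefix = tmp_path / "panel"
        write_plink(counts, prefix)
        prefix.with_suffix(".bim").unlink()
        with pytest.raises(FormatError, match="bim"):
            load_genotypes(prefix, format="plink")

    def test_bad_magic(self, tmp_path, rng):
        counts = rng.integers(0, 3, size=(6, 4)).astype(np.int8)
        prefix = tmp_path / "panel"
        write_plink(counts, prefix)
        bed = prefix.with_suffix(".bed")
        bed.write_bytes(b"\x00\x00\x00" + bed.read_bytes()[3:])
        with pytest.raises(FormatError, match="magic"):
            load_genotypes(prefix, format="plink")


class TestPhenotype:
    def test_single_column(self, tmp_path):
        f = tmp_path / "pheno.txt"
        f.write_text("1.5\n-0.25\n3\n")
        ph = load_phenotype(f)
        assert np.allclose(ph.y, [1.5, -0.25, 3.0])

    def test_fid_iid_value_aligned(self, tmp_path):
        f = tmp_path / "pheno.txt"
        f.write_text("f1 s1 1.0\nf2 s2 2.0\nf3 s3 3.0\n")
        ph = load_phenotype(f, sample_ids=["s3", "s1", "s2"])
        assert np.allclose(ph.y, [3.0, 1.0, 2.0])

    def test_missing_sample_raises(self, tmp_path):
        f = tmp_path / "pheno.txt"
        f.write_text("f1 s1 1.0\n")
        with pytest.raises(FormatError, match="s9"):
            load_phenotype(f, sample_ids=["s9"])
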