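"""VCF reading, per-variant statistics and QC filter behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathkat.errors import ConfigError, VcfParseError
from pathkat.geno_io import (
    filter_variants,
    hwe_exact_p,
    read_vcf,
    variant_stats,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=A,Type=Float,Description="Dosage">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def write_vcf(tmp_path, body, name="t.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestReadVcf:
    def test_hard_call_dosages_and_missing(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1\n"
        )
        gm = read_vcf(write_vcf(tmp_path, body))
        assert gm.samples == ["S1", "S2", "S3"]
        np.testing.assert_array_equal(gm.dosage[:, 0], [0.0, 1.0, 2.0])
        assert np.isnan(gm.dosage[0, 1])
        np.testing.assert_array_equal(gm.dosage[1:, 1], [0.0, 1.0])

    def test_ds_preferred_over_gt(self, tmp_path):
        body = "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DS\t0/0:0.13\t0/1:1.02\t1/1:1.9\n"
        gm = read_vcf(write_vcf(tmp_path, body))
        np.testing.assert_allclose(gm.dosage[:, 0], [0.13, 1.02, 1.9])

    def test_multiallelic_decomposed_per_alt(self, tmp_path):
        body = "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t1/2\t2/2\n"
        gm = read_vcf(write_vcf(tmp_path, body))
        assert gm.n_variants == 2
        assert list(gm.variants["alt"]) == ["G", "T"]
        # focal-alt counting: other alts count as 0
        np.testing.assert_array_equal(gm.dosage[:, 0], [1.0, 1.0, 0.0])
        np.testing.assert_array_equal(gm.dosage[:, 1], [0.0, 1.0, 2.0])

    def test_info_score_read_with_fallback(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tG\t.\tPASS\tINFO=0.87\tGT\t0/0\t0/0\t0/0\n"
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\n"
        )
        gm = read_vcf(write_vcf(tmp_path, body))
        assert gm.variants["info"].iloc[0] == pytest.approx(0.87)
        assert np.isnan(gm.variants["info"].iloc[1])

    def test_unknown_sample_subset_rejected(self, tmp_path):
        body = "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        path = write_vcf(tmp_path, body)
        with pytest.raises(VcfParseError, match="SX"):
            read_vcf(path, sample_subset=["S1", "SX"])
        gm = read_vcf(path, sample_subset=["S3", "S1"])
        assert set(gm.samples) == {"S1", "S3"}

    def test_roundtrip_matches_generator_truth(self, bundle_missing):
        gm = read_vcf(bundle_missing.vcf)
        assert gm.samples == bundle_missing.samples
        truth = bundle_missing.dosage
        assert np.array_equal(np.isnan(gm.dosage), np.isnan(truth))
        np.testing.assert_array_equal(
            np.nan_to_num(gm.dosage), np.nan_to_num(truth)
        )


class TestVariantStats:
    def test_hand_computed_mafs(self):
        from pathkat.geno_io import GenotypeMatrix

        cols = {
            "monomorphic": np.zeros(10),
            "het_two_of_ten": np.array([1, 1] + [0] * 8, dtype=float),
            "dosage": np.array([0.5, 1.5, 0, 2] + [np.nan] * 6),
        }
        gm = GenotypeMatrix(
            samples=[f"s{i}" for i in range(10)],
            variants=pd.DataFrame(
                {"chrom": "1", "pos": [1, 2, 3], "ref": "A", "alt": "G",
                 "info": np.nan}
            ),
            dosage=np.column_stack(list(cols.values())),
        )
        st_ = variant_stats(gm)
        assert st_["maf"].iloc[0] == 0.0
        assert st_["maf"].iloc[1] == pytest.approx(0.1)
        # (0.5+1.5+0+2) / (2*4) = 0.5 by hand
        assert st_["maf"].iloc[2] == pytest.approx(0.5)
        assert st_["call_rate"].iloc[2] == pytest.approx(0.4)
        # exact HWE test only for integral genotypes
        assert np.isfinite(st_["hwe_p"].iloc[1])
        assert np.isnan(st_["hwe_p"].iloc[2])

    def test_maf_invariant_under_allele_flip(self, rng):
        from pathkat.geno_io import GenotypeMatrix

        d = rng.binomial(2, 0.2, size=(50, 4)).astype(float)
        meta = pd.DataFrame(
            {"chrom": "1", "pos": range(1, 5), "ref": "A", "alt": "G",
             "info": np.nan}
        )
        a = variant_stats(GenotypeMatrix([f"s{i}" for i in range(50)], meta, d))
        b = variant_stats(
            GenotypeMatrix([f"s{i}" for i in range(50)], meta, 2.0 - d)
        )
        np.testing.assert_allclose(a["maf"], b["maf"])


def hwe_oracle(n0, n1, n2):
    """Exhaustive-enumeration oracle with exact integer arithmetic."""
    n = n0 + n1 + n2
    n_alt = 2 * n2 + n1
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        rare_hom = (n_minor - h) // 2
        com_hom = n - h - rare_hom
        if com_hom < 0:
            continue
        weights[h] = (
            math.factorial(n)
            * 2**h
            // (math.factorial(h) * math.factorial(rare_hom) * math.factorial(com_hom))
        )
    total = sum(weights.values())
    obs = weights[n1]
    return sum(w for w in weights.values() if w <= obs) / total


class TestHweExact:
    @pytest.mark.parametrize(
        "counts,expected",
        [((10, 0, 0), 1.0), ((0, 0, 7), 1.0)],
    )
    def test_monomorphic_returns_one(self, counts, expected):
        assert hwe_exact_p(*counts) == expected

    def test_symmetry_under_allele_swap(self):
        assert hwe_exact_p(21, 57, 22) == pytest.approx(hwe_exact_p(22, 57, 21))

    def test_against_enumeration_oracle(self):
        assert hwe_exact_p(21, 57, 22) == pytest.approx(
            hwe_oracle(21, 57, 22), rel=1e-9
        )

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        n0=st.integers(0, 60), n1=st.integers(0, 60), n2=st.integers(0, 60)
    )
    def test_matches_oracle_for_all_small_configurations(self, n0, n1, n2):
        if n0 + n1 + n2 == 0:
            return
        assert hwe_exact_p(n0, n1, n2) == pytest.approx(
            hwe_oracle(n0, n1, n2), rel=1e-9, abs=1e-12
        )

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)


def _matrix_from(dosage, info=None):
    from pathkat.geno_io import GenotypeMatrix

    n, m = dosage.shape
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        variants=pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, m + 1), "ref": "A", "alt": "G",
             "info": info if info is not None else np.nan}
        ),
        dosage=dosage,
    )


class TestFilterVariants:
    def test_maf_boundary_inclusive(self, rng):
        # 10 variants all at maf exactly 0.005 -> all retained at max 0.01
        d = np.zeros((100, 10))
        d[0, :] = 1.0  # one het in 100 samples: maf 0.005
        gm = _matrix_from(d)
        out, report = filter_variants(gm, variant_stats(gm), max_maf=0.01)
        assert out.n_variants == 10
        # boundary equality: maf == max_maf retained
        d2 = np.zeros((100, 1))
        d2[:2, 0] = 1.0  # maf = 2/200 = 0.01
        gm2 = _matrix_from(d2)
        out2, _ = filter_variants(gm2, variant_stats(gm2), max_maf=0.01)
        assert out2.n_variants == 1

    def test_info_boundary_inclusive_and_absent_dropped(self):
        d = np.tile(np.array([0.0, 1.0, 0, 0]), (3, 1)).T
        gm = _matrix_from(d, info=[0.39, 0.40, np.nan])
        out, report = filter_variants(
            gm, variant_stats(gm), max_maf=0.5, min_info=0.4
        )
        assert list(out.variants["pos"]) == [2]
        row = report[report["criterion"] == "info"].iloc[0]
        assert row["n_removed"] == 2

    def test_hwe_strictly_greater(self):
        # all-het column: strong HWE violation
        d = np.column_stack([np.ones(40), np.r_[np.ones(8), np.zeros(32)]])
        gm = _matrix_from(d)
        stats = variant_stats(gm)
        p_violating = stats["hwe_p"].iloc[0]
        out, _ = filter_variants(
            gm, stats, max_maf=0.5, min_hwe_p=p_violating
        )  # strict: P > threshold, so the boundary variant is dropped
        assert list(out.variants["pos"]) == [2]

    def test_hand_filtered_fixture_and_idempotence(self, rng):
        d = rng.binomial(2, rng.uniform(0.001, 0.2, 30), size=(200, 30)).astype(float)
        info = rng.uniform(0.0, 1.0, 30)
        gm = _matrix_from(d, info=info)
        stats = variant_stats(gm)
        out, _ = filter_variants(gm, stats, 0.05, min_info=0.4, min_hwe_p=1e-6)
        maf = stats["maf"].to_numpy()
        hwe = stats["hwe_p"].to_numpy()
        expect = np.flatnonzero((maf <= 0.05) & (info >= 0.4) & (hwe > 1e-6)) + 1
        assert list(out.variants["pos"]) == list(expect)
        again, _ = filter_variants(
            out, variant_stats(out), 0.05, min_info=0.4, min_hwe_p=1e-6
        )
        assert list(again.variants["pos"]) == list(out.variants["pos"])

    def test_zero_call_variant_excluded(self):
        d = np.column_stack([np.full(5, np.nan), np.zeros(5)])
        gm = _matrix_from(d)
        out, report = filter_variants(gm, variant_stats(gm), 0.5)
        assert list(out.variants["pos"]) == [2]
        assert report[report["criterion"] == "defined_maf"]["n_removed"].iloc[0] == 1

    def test_invalid_max_maf_rejected(self):
        gm = _matrix_from(np.zeros((4, 1)))
        with pytest.raises(ConfigError):
            filter_variants(gm, variant_stats(gm), 0.7)
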