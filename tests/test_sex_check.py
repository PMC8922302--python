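"""PAR classification, X-inbreeding estimation, and sex inference."""

import numpy as np
import pytest

from arrayqc.dataset import MISSING, SEX_FEMALE, SEX_MALE
from arrayqc.regions import (
    REGION_AUTOSOME,
    REGION_PAR,
    REGION_X_NONPAR,
    classify_par,
    par_table,
)
from arrayqc.sexcheck import (
    FLAG_MISMATCH,
    FLAG_OK,
    FLAG_OUT_OF_RANGE,
    FLAG_RECOVERED,
    SexThresholds,
    infer_sex,
    sex_check,
    x_inbreeding,
)
from arrayqc.simulate import SimSpec, simulate_cohort

from conftest import make_dataset


class TestClassifyPar:
    def test_chrom_xy_is_par_regardless_of_position(self):
        ds = make_dataset(np.zeros((1, 1), dtype=np.int8), chroms=["XY"], bps=[1])
        assert classify_par(ds, par_table())[0] == REGION_PAR

    def test_x_position_inside_par1(self):
        par = par_table("grch37")
        ds = make_dataset(
            np.zeros((1, 3), dtype=np.int8),
            chroms=["X", "X", "7"],
            bps=[1_000_000, 50_000_000, 500],
        )
        assert classify_par(ds, par).tolist() == [
            REGION_PAR,
            REGION_X_NONPAR,
            REGION_AUTOSOME,
        ]

    def test_unrecognized_chrom_is_other_not_error(self):
        ds = make_dataset(np.zeros((1, 1), dtype=np.int8), chroms=["contig5"])
        assert classify_par(ds, par_table())[0] == "other"

    def test_par3_toggle(self):
        par_on = par_table("grch37", include_par3=True)
        par_off = par_table("grch37", include_par3=False)
        bp = 90_000_000  # inside the debated Xq21.3 block
        ds = make_dataset(np.zeros((1, 1), dtype=np.int8), chroms=["X"], bps=[bp])
        assert classify_par(ds, par_on)[0] == REGION_PAR
        assert classify_par(ds, par_off)[0] == REGION_X_NONPAR


class TestXInbreeding:
    def _regions(self, m):
        return np.array([REGION_X_NONPAR] * m, dtype=object)

    def test_all_homozygous_gives_exactly_one(self):
        G = np.array([[0, 2, 0, 2], [0, 1, 1, 2], [1, 1, 0, 2]], dtype=np.int8)
        f, _ = x_inbreeding(make_dataset(G, chroms=["X"] * 4, bps=[10] * 4), self._regions(4))
        assert f[0] == pytest.approx(1.0)

    def test_matches_literal_formula_on_hand_built_matrix(self):
        G = np.array(
            [[0, 1, 2], [1, 1, 0], [2, 0, 1], [2, 2, MISSING]], dtype=np.int8
        )
        ds = make_dataset(G, chroms=["X"] * 3, bps=[10, 20, 30])
        f, n_used = x_inbreeding(ds, self._regions(3))
        # independent transcription of the method-of-moments estimator
        for i in range(4):
            O = N = E = 0.0
            for j in range(3):
                col = G[:, j]
                called = col[col != MISSING]
                n_alleles = 2 * len(called)
                p = called.sum() / n_alleles
                if p in (0.0, 1.0) or n_alleles < 2:
                    continue
                e_j = 1 - 2 * p * (1 - p) * n_alleles / (n_alleles - 1)
                if G[i, j] == MISSING:
                    continue
                N += 1
                O += G[i, j] != 1
                E += e_j
            expected = (O - E) / (N - E)
            assert f[i] == pytest.approx(expected, abs=1e-12)

    def test_hwe_females_center_on_zero(self):
        spec = SimSpec(
            n_samples=200, n_variants=1, seed=5, n_x=2000,
            sex_fractions=(0.0, 1.0, 0.0),
        )
        ds = simulate_cohort(spec)
        labels = classify_par(ds, par_table())
        f, _ = x_inbreeding(ds, labels)
        se = np.std(f, ddof=1) / np.sqrt(len(f))
        assert abs(np.mean(f)) <= 3 * se + 1e-3

    def test_allele_label_swap_invariance(self, rng):
        G = rng.choice([0, 1, 2, MISSING], size=(20, 50)).astype(np.int8)
        ds = make_dataset(G, chroms=["X"] * 50, bps=list(range(10_000_000, 10_000_050)))
        swapped = G.copy()
        called = swapped != MISSING
        swapped[called] = 2 - swapped[called]
        ds_swap = make_dataset(swapped, chroms=["X"] * 50, bps=list(range(10_000_000, 10_000_050)))
        labels = classify_par(ds, par_table())
        f1, _ = x_inbreeding(ds, labels)
        f2, _ = x_inbreeding(ds_swap, labels)
        np.testing.assert_allclose(f1, f2, atol=1e-10)

    def test_par_calls_never_contribute(self):
        """Injecting heterozygous PAR calls into males leaves F unchanged."""
        spec = SimSpec(n_samples=60, n_variants=1, seed=9, n_x=500, n_par=100)
        ds = simulate_cohort(spec)
        labels = classify_par(ds, par_table())
        f1, _ = x_inbreeding(ds, labels)
        G = ds.G.copy()
        G[:, labels == REGION_PAR] = 1  # everyone het on PAR
        ds2 = make_dataset(G, chroms=[v.chrom for v in ds.variants], bps=[v.bp for v in ds.variants])
        f2, _ = x_inbreeding(ds2.with_samples(ds.samples), labels)
        np.testing.assert_allclose(f1, f2, atol=0)


class TestInferSex:
    def _ds(self, sexes):
        return make_dataset(np.zeros((len(sexes), 1), dtype=np.int8), sexes=sexes)

    @pytest.mark.parametrize(
        "reported,f,inferred,flag",
        [
            ("male", -0.02, "female", FLAG_MISMATCH),
            ("unknown", 0.999, "male", FLAG_RECOVERED),
            ("female", 0.5, "undetermined", FLAG_OUT_OF_RANGE),
            ("female", -0.5, "undetermined", FLAG_OUT_OF_RANGE),
            ("male", 0.985, "male", FLAG_OK),
            ("female", 0.15, "female", FLAG_OK),
        ],
    )
    def test_threshold_logic(self, reported, f, inferred, flag):
        tbl = infer_sex(self._ds([reported]), np.array([f]), np.array([100]))
        assert tbl["inferred_sex"].iloc[0] == inferred
        assert tbl["mismatch_flag"].iloc[0] == flag

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(Exception):
            SexThresholds(male_low=0.1, female_high=0.2)

    def test_end_to_end_recovery_rate(self):
        """>=99% of simulated samples recover their genetic sex at m=1000."""
        spec = SimSpec(n_samples=300, n_variants=1, seed=17, n_x=1000)
        ds = simulate_cohort(spec)
        labels = classify_par(ds, par_table())
        tbl = sex_check(ds, labels)
        correct = (tbl["inferred_sex"] == tbl["reported_sex"]).mean()
        assert correct >= 0.99
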