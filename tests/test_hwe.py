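"""Exact Hardy-Weinberg test against a rational-arithmetic enumeration
oracle, plus scan-level stratification behaviour."""

from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arrayqc.dataset import MISSING
from arrayqc.exceptions import ParameterError
from arrayqc.hwe import genotype_counts, hwe_exact_pvalue, hwe_scan, _het_log_probs
from arrayqc.simulate import SimSpec, simulate_cohort

from conftest import make_dataset


def oracle_pvalue(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Brute-force exact test in rational arithmetic (independent oracle)."""
    n_total = n_het + n_hom_rare + n_hom_common
    n_rare = 2 * n_hom_rare + n_het
    if n_rare > n_total:
        n_rare = 2 * n_total - n_rare
    if n_rare == 0:
        return 1.0
    n_common = 2 * n_total - n_rare

    def prob(h: int) -> Fraction:
        n_aa = (n_rare - h) // 2
        n_bb = n_total - h - n_aa
        return (
            Fraction(factorial(n_total), factorial(n_aa) * factorial(h) * factorial(n_bb))
            * Fraction(2) ** h
            * Fraction(factorial(n_rare) * factorial(n_common), factorial(2 * n_total))
        )

    hs = range(n_rare % 2, n_rare + 1, 2)
    probs = {h: prob(h) for h in hs}
    assert sum(probs.values()) == 1
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


class TestExactPvalue:
    def test_monomorphic_is_one(self):
        assert hwe_exact_pvalue(0, 0, 100) == 1.0

    def test_two_hets_tiny_case_matches_enumeration(self):
        # n_rare=2, N=2: only h in {0, 2} feasible
        assert hwe_exact_pvalue(2, 0, 0) == pytest.approx(oracle_pvalue(2, 0, 0))

    @settings(max_examples=200, deadline=None)
    @given(
        n_hom_rare=st.integers(0, 15),
        n_het=st.integers(0, 30),
        n_hom_common=st.integers(0, 120),
    )
    def test_matches_rational_oracle_up_to_minor_count_40(
        self, n_hom_rare, n_het, n_hom_common
    ):
        if n_het + n_hom_rare + n_hom_common == 0:
            return
        p = hwe_exact_pvalue(n_het, n_hom_rare, n_hom_common)
        assert p == pytest.approx(oracle_pvalue(n_het, n_hom_rare, n_hom_common), rel=1e-9)

    def test_homozygote_swap_invariance(self):
        assert hwe_exact_pvalue(10, 3, 40) == pytest.approx(
            hwe_exact_pvalue(10, 40, 3), rel=1e-12
        )

    def test_probabilities_sum_to_one_up_to_200_rare_alleles(self):
        for n_total, n_rare in [(100, 1), (100, 57), (150, 200), (500, 123)]:
            _, logp = _het_log_probs(n_total, min(n_rare, n_total))
            assert np.exp(logp).sum() == pytest.approx(1.0, rel=1e-10)

    def test_midp_is_smaller_and_negative_counts_raise(self):
        assert hwe_exact_pvalue(5, 5, 40, midp=True) < hwe_exact_pvalue(5, 5, 40)
        with pytest.raises(ParameterError):
            hwe_exact_pvalue(-1, 0, 0)

    def test_null_type_one_error_is_conservative(self, rng):
        """Exact-test rejection rate at nominal 0.05 stays <= 0.06 under HWE."""
        n, reps, q = 100, 2000, 0.25
        hits = 0
        for _ in range(reps):
            g = rng.binomial(1, q, (n, 2)).sum(axis=1)
            p = hwe_exact_pvalue(int((g == 1).sum()), int((g == 2).sum()), int((g == 0).sum()))
            hits += p < 0.05
        assert hits / reps <= 0.06


class TestGenotypeCounts:
    def test_direct_tally(self, rng):
        ds = make_dataset([[0], [1], [2], [MISSING]])
        tbl = genotype_counts(ds)
        assert tbl.loc[0, ["n_hom1", "n_het", "n_hom2"]].tolist() == [1, 1, 1]
        G = rng.choice([MISSING, 0, 1, 2], size=(40, 5)).astype(np.int8)
        tbl = genotype_counts(make_dataset(G))
        for j in range(5):
            assert tbl.loc[j, "n_het"] == int((G[:, j] == 1).sum())
            assert tbl.loc[j, "n_hom1"] == int((G[:, j] == 0).sum())

    def test_all_missing(self):
        tbl = genotype_counts(make_dataset([[MISSING], [MISSING]]))
        assert tbl.loc[0, ["n_hom1", "n_het", "n_hom2"]].tolist() == [0, 0, 0]


class TestScan:
    def test_null_simulation_flags_almost_nothing_after_bonferroni(self):
        spec = SimSpec(n_samples=500, n_variants=1000, seed=23)
        ds = simulate_cohort(spec)
        tbl = hwe_scan(ds, strata={"all": np.ones(ds.n_samples, dtype=bool)})
        assert tbl["violation"].mean() <= 0.01
        # adjusted p never below raw p, never above 1
        assert (tbl["p_adj"] >= tbl["p_exact"] - 1e-12).all()
        assert (tbl["p_adj"] <= 1.0).all()

    def test_power_against_planted_inbreeding(self):
        f = np.zeros(1050)
        f[:50] = 0.6
        spec = SimSpec(n_samples=500, n_variants=1050, seed=29, inbreeding_f=f)
        ds = simulate_cohort(spec)
        tbl = hwe_scan(ds, strata={"all": np.ones(ds.n_samples, dtype=bool)})
        planted = tbl["vid"].isin([f"var{i + 1}" for i in range(50)])
        assert tbl.loc[planted, "violation"].mean() >= 0.90

    def test_wahlund_effect_needs_stratification(self):
        """Two HWE populations with divergent frequencies: the pooled test
        flags variants that race-by-race testing does not."""
        q = np.full(300, 0.5)
        spec = SimSpec(
            n_samples=600,
            n_variants=300,
            seed=31,
            populations={"popA": 0.5, "popB": 0.5},
            pop_freqs={"popA": np.full(300, 0.1), "popB": np.full(300, 0.9)},
        )
        ds = simulate_cohort(spec)
        pooled = hwe_scan(ds, strata={"all": np.ones(ds.n_samples, dtype=bool)})
        stratified = hwe_scan(ds)  # race labels from the simulated populations
        assert pooled["violation"].mean() > 0.5
        assert stratified["violation"].mean() <= 0.01

    def test_controls_only_and_empty_stratum_warning(self):
        spec = SimSpec(n_samples=100, n_variants=50, seed=37, case_fraction=0.5)
        ds = simulate_cohort(spec)
        tbl = hwe_scan(
            ds,
            strata={"all": np.ones(ds.n_samples, dtype=bool)},
            controls_only=True,
        )
        n_controls = sum(s.is_control for s in ds.samples)
        assert (tbl[["n_hom1", "n_het", "n_hom2"]].sum(axis=1) <= n_controls).all()
        with pytest.warns(UserWarning, match="skipped"):
            with pytest.raises(Exception):
                hwe_scan(ds, strata={"none": np.zeros(ds.n_samples, dtype=bool)})
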