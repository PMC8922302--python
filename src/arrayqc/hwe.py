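"""Hardy-Weinberg equilibrium exact testing.

The exact test conditions on the observed allele counts: given N genotyped
individuals carrying n_rare copies of the minor allele, the heterozygote
count h follows

    P(h | N, n_rare) = N! / (n_aa! h! n_bb!) * 2**h * n_rare! n_common! / (2N)!

over all h of the same parity as n_rare. The two-sided p-value sums the
probabilities of every outcome no more likely than the observed one.
Deviation from equilibrium within a randomly-mating stratum is a standard
warning sign of genotyping error, which is why the scan runs race by race
(allele frequencies differ across ancestries, so a pooled test confounds
structure with error) and, in case-control designs, on controls only.

Enumeration is done in log-space so alleles counts in the thousands do not
overflow.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .dataset import MISSING, RACE_UNKNOWN, GenotypeDataset
from .exceptions import DegenerateInputError, ParameterError
from .regions import diploid_mask

# relative slack when comparing outcome probabilities for the two-sided sum;
# outcomes exactly tied with the observed one must be included despite
# floating-point rounding
_TIE_EPS = 1e-12


def genotype_counts(ds: GenotypeDataset, sample_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-variant genotype counts (hom-a1, het, hom-a2) over non-missing calls."""
    G = ds.G if sample_mask is None else ds.G[np.asarray(sample_mask, dtype=bool)]
    return pd.DataFrame(
        {
            "vid": ds.variant_ids,
            "n_hom1": (G == 0).sum(axis=0).astype(int),
            "n_het": (G == 1).sum(axis=0).astype(int),
            "n_hom2": (G == 2).sum(axis=0).astype(int),
        }
    )


def _het_log_probs(n_total: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities of each feasible heterozygote count.

    Returns (h_values, normalized log-probabilities).
    """
    h = np.arange(n_rare % 2, n_rare + 1, 2)
    n_aa = (n_rare - h) // 2
    n_bb = n_total - h - n_aa
    logp = (
        gammaln(n_total + 1)
        - gammaln(n_aa + 1)
        - gammaln(h + 1)
        - gammaln(n_bb + 1)
        + h * np.log(2.0)
    )
    return h, logp - logsumexp(logp)


def hwe_exact_pvalue(
    n_het: int, n_hom_rare: int, n_hom_common: int, midp: bool = False
) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one variant's counts.

    The rare/common roles are recomputed internally, so the result is
    invariant under swapping the homozygote arguments. A monomorphic variant
    returns p = 1. ``midp`` subtracts half the observed outcome's
    probability (the mid-p variant, less conservative for discrete data).
    """
    if min(n_het, n_hom_rare, n_hom_common) < 0:
        raise ParameterError("genotype counts must be non-negative")
    n_total = n_het + n_hom_rare + n_hom_common
    if n_total < 1:
        raise ParameterError("at least one genotyped sample is required")
    n_rare = 2 * n_hom_rare + n_het
    if n_rare > n_total:  # caller's "rare" was actually the common allele
        n_rare = 2 * n_total - n_rare
    if n_rare == 0:
        return 1.0

    h, logp = _het_log_probs(n_total, n_rare)
    probs = np.exp(logp)
    obs = probs[np.searchsorted(h, n_het)]
    p = float(probs[probs <= obs * (1.0 + _TIE_EPS)].sum())
    if midp:
        p -= 0.5 * float(obs)
    return min(p, 1.0)


def hwe_scan(
    ds: GenotypeDataset,
    region_labels: np.ndarray | None = None,
    strata: dict[str, np.ndarray] | None = None,
    controls_only: bool = False,
    alpha: float = 0.05,
    midp: bool = False,
    include_unknown: bool = False,
) -> pd.DataFrame:
    """Race-stratified exact HWE scan over diploid variants.

    Parameters
    ----------
    region_labels
        Output of :func:`arrayqc.regions.classify_par`; only autosome + PAR
        variants are tested. ``None`` tests every variant.
    strata
        Mapping stratum label -> sample boolean mask. Defaults to the
        reported-race groups; unknown-race samples are excluded unless
        ``include_unknown`` makes them their own stratum.
    controls_only
        Restrict to samples with control status (case-control designs break
        equilibrium at trait-associated loci).

    Within each stratum p-values are Bonferroni-adjusted by the number of
    variants actually tested there (recorded in ``m_tests``); a variant is
    flagged when the adjusted p falls below ``alpha``. Empty strata are
    skipped with a warning, never a crash.
    """
    if region_labels is not None:
        vmask = diploid_mask(region_labels)
    else:
        vmask = np.ones(ds.n_variants, dtype=bool)
    sub = ds.subset(variant_sel=vmask)

    if strata is None:
        races = np.array([s.reported_race for s in ds.samples], dtype=object)
        labels = [r for r in pd.unique(races) if include_unknown or r != RACE_UNKNOWN]
        strata = {str(r): races == r for r in labels}
    if not strata:
        raise DegenerateInputError("no strata available for HWE testing")

    frames = []
    for label, mask in strata.items():
        mask = np.asarray(mask, dtype=bool).copy()
        if controls_only:
            ctrl = np.array([s.is_control is True for s in ds.samples])
            mask &= ctrl
        if not mask.any():
            warnings.warn(f"HWE stratum {label!r} has no eligible samples; skipped")
            continue
        counts = genotype_counts(sub, sample_mask=mask)
        total = counts[["n_hom1", "n_het", "n_hom2"]].sum(axis=1)
        tested = total > 0
        m_tests = int(tested.sum())
        pvals = np.full(len(counts), np.nan)
        for i in np.flatnonzero(tested.to_numpy()):
            pvals[i] = hwe_exact_pvalue(
                int(counts.at[i, "n_het"]),
                int(counts.at[i, "n_hom1"]),
                int(counts.at[i, "n_hom2"]),
                midp=midp,
            )
        frame = counts.copy()
        frame.insert(1, "stratum", label)
        frame["p_exact"] = pvals
        frame["m_tests"] = m_tests
        frame["p_adj"] = np.minimum(pvals * m_tests, 1.0)
        frame["violation"] = frame["p_adj"] < alpha
        frames.append(frame[tested.to_numpy()])

    if not frames:
        raise DegenerateInputError("every HWE stratum was empty")
    return pd.concat(frames, ignore_index=True)
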