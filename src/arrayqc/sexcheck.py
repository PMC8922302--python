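"""Genetic-sex inference from chromosome-X homozygosity.

Males carry one X, so their non-PAR X genotypes are effectively hemizygous
and read as homozygous on an array: their X inbreeding coefficient F sits
near 1 (expected range 0.98-1). Females are diploid on X and, under random
mating, near 0 (expected range -0.3-0.2). F is the method-of-moments excess
homozygosity

    F_i = (O_i - E_i) / (N_i - E_i)

over sample i's called non-PAR X variants, where O_i counts observed
homozygotes, N_i the called variants, and E_i the homozygosity expected
under Hardy-Weinberg with the small-sample correction
``1 - 2 p q * n/(n-1)`` (n = allele count used to estimate p). This is the
estimator behind the conventional sex-check statistic, which is what the
published expected ranges were calibrated on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, SEX_FEMALE, SEX_MALE, SEX_UNKNOWN, GenotypeDataset
from .exceptions import DegenerateInputError
from .regions import REGION_X_NONPAR

FLAG_OK = "ok"
FLAG_MISMATCH = "mismatch"
FLAG_RECOVERED = "recovered"
FLAG_OUT_OF_RANGE = "out_of_range"

SEX_UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class SexThresholds:
    """Decision bounds on the X inbreeding estimate.

    male_low .. 1 calls male; female_low .. female_high calls female; the gap
    and anything below female_low are undetermined/out-of-range.
    """

    male_low: float = 0.98
    female_low: float = -0.3
    female_high: float = 0.2

    def __post_init__(self):
        if not self.female_high < self.male_low:
            raise DegenerateInputError("female_high must be below male_low")


def x_inbreeding(
    ds: GenotypeDataset,
    region_labels: np.ndarray,
    freq_sample_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample X inbreeding estimate over non-PAR X variants.

    Allele frequencies default to all samples' non-missing calls treated as
    diploid (a single deterministic pass); ``freq_sample_mask`` restricts
    frequency estimation, e.g. to inferred females for a second pass.
    Variants that are monomorphic in the frequency pool, or rest on fewer
    than 2 alleles, are uninformative and excluded from both O and E.

    Returns ``(f_x, n_used)``; ``f_x`` is NaN where no informative variant
    was called or the denominator degenerates.
    """
    xmask = np.asarray(region_labels, dtype=object) == REGION_X_NONPAR
    if not xmask.any():
        raise DegenerateInputError("no non-PAR X variants available for sex check")
    X = ds.G[:, xmask]

    F = X if freq_sample_mask is None else X[np.asarray(freq_sample_mask, dtype=bool)]
    called_f = F != MISSING
    n_alleles = 2.0 * called_f.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_alleles > 0, np.where(called_f, F, 0).sum(axis=0) / n_alleles, np.nan)
    informative = (n_alleles >= 2) & (p > 0) & (p < 1)

    q = 1.0 - p
    with np.errstate(invalid="ignore", divide="ignore"):
        # expected homozygosity per variant with the n/(n-1) correction
        e_hom = 1.0 - 2.0 * p * q * (n_alleles / np.maximum(n_alleles - 1.0, 1e-12))

    X = X[:, informative]
    e_hom = e_hom[informative]
    called = X != MISSING
    n_used = called.sum(axis=1)
    obs_hom = (called & (X != 1)).sum(axis=1)
    exp_hom = (called * e_hom).sum(axis=1)

    denom = n_used - exp_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f_x = np.where(
            (n_used > 0) & (np.abs(denom) > 1e-12),
            (obs_hom - exp_hom) / np.where(np.abs(denom) > 1e-12, denom, 1.0),
            np.nan,
        )
    return f_x, n_used.astype(int)


def infer_sex(
    ds: GenotypeDataset,
    f_x: np.ndarray,
    n_used: np.ndarray,
    thresholds: SexThresholds = SexThresholds(),
) -> pd.DataFrame:
    """Classify samples and flag disagreements with reported sex.

    Flags: ``ok`` (reported and inferred agree, or both indeterminate),
    ``mismatch`` (both determined, different), ``recovered`` (reported
    unknown, inference determined), ``out_of_range`` (estimate in the gap
    zone, below the female floor, or undefined). Reported sex is never
    rewritten, only flagged.
    """
    t = thresholds
    rows = []
    for s, f, n in zip(ds.samples, f_x, n_used):
        if np.isnan(f):
            inferred = SEX_UNDETERMINED
        elif f >= t.male_low:
            inferred = SEX_MALE
        elif t.female_low <= f <= t.female_high:
            inferred = SEX_FEMALE
        else:
            inferred = SEX_UNDETERMINED

        if inferred == SEX_UNDETERMINED:
            flag = FLAG_OUT_OF_RANGE
        elif s.reported_sex == SEX_UNKNOWN:
            flag = FLAG_RECOVERED
        elif s.reported_sex != inferred:
            flag = FLAG_MISMATCH
        else:
            flag = FLAG_OK
        rows.append((s.iid, s.reported_sex, float(f), int(n), inferred, flag))
    return pd.DataFrame(
        rows,
        columns=["iid", "reported_sex", "f_x", "n_x_used", "inferred_sex", "mismatch_flag"],
    )


def sex_check(
    ds: GenotypeDataset,
    region_labels: np.ndarray,
    thresholds: SexThresholds = SexThresholds(),
    two_pass: bool = False,
) -> pd.DataFrame:
    """Full sex check: X inbreeding, inference, mismatch flags.

    With ``two_pass=True`` allele frequencies are re-estimated from the
    samples inferred female in a first pass, then F is recomputed.
    """
    f_x, n_used = x_inbreeding(ds, region_labels)
    if two_pass:
        result = infer_sex(ds, f_x, n_used, thresholds)
        females = (result["inferred_sex"] == SEX_FEMALE).to_numpy()
        if females.sum() >= 2:
            f_x, n_used = x_inbreeding(ds, region_labels, freq_sample_mask=females)
    return infer_sex(ds, f_x, n_used, thresholds)
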