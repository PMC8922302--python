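"""Per-sample Heterozygosity Ratio.

The ratio of heterozygous calls to non-reference homozygous calls has a
theoretical expectation of two in an equilibrium population (at allele
frequency q the per-variant expectation is 2pq / q^2 = 2p/q, which is 2 at
q = 1/2), but is strongly ancestry-dependent in practice, so outlier flags
are relative to the sample's race stratum. Exceedingly high values point at
sample contamination (mixed DNA reads as heterozygous); exceedingly low
values point at inbreeding. Only diploid calls (autosomes + PAR) enter the
counts, because hemizygous X/Y calls cannot be heterozygous.

The fileset does not say which allele is "reference", so orientation is
explicit: by default a1 is reference (dosage 2 = non-reference homozygote),
switchable globally or per variant via a reference-allele table. The ratio
is deliberately *not* invariant under allele relabelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import MISSING, RACE_UNKNOWN, GenotypeDataset
from .exceptions import DegenerateInputError
from .regions import diploid_mask

FLAG_OK = "ok"
FLAG_HIGH = "high"
FLAG_LOW = "low"
FLAG_UNDEFINED = "undefined"


def het_ratio(
    ds: GenotypeDataset,
    region_labels: np.ndarray,
    ref_is_a1: bool = True,
    ref_alleles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Heterozygote and non-reference-homozygote counts and their ratio.

    ``ref_alleles`` maps variant id -> reference allele label and overrides
    the global orientation where it applies. A sample with zero
    non-reference homozygotes gets ratio NaN and flag ``undefined`` (never an
    exception). Flags relative to stratum medians are added separately by
    :func:`flag_het_ratio`.
    """
    dmask = diploid_mask(region_labels)
    if not dmask.any():
        raise DegenerateInputError("no diploid variants available for heterozygosity ratio")
    G = ds.G[:, dmask]
    variants = [v for v, keep in zip(ds.variants, dmask) if keep]

    # per-variant dosage that means "non-reference homozygote"
    nonref_dose = np.full(len(variants), 2 if ref_is_a1 else 0, dtype=np.int8)
    if ref_alleles:
        for j, v in enumerate(variants):
            ref = ref_alleles.get(v.vid)
            if ref == v.a1:
                nonref_dose[j] = 2
            elif ref == v.a2:
                nonref_dose[j] = 0

    n_het = (G == 1).sum(axis=1)
    n_nonref_hom = (G == nonref_dose[np.newaxis, :]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_nonref_hom > 0, n_het / np.maximum(n_nonref_hom, 1), np.nan)
    return pd.DataFrame(
        {
            "iid": ds.sample_ids,
            "n_het": n_het.astype(int),
            "n_nonref_hom": n_nonref_hom.astype(int),
            "ratio": ratio,
        }
    )


def flag_het_ratio(
    result: pd.DataFrame,
    race_labels: np.ndarray,
    hi_mult: float = 1.5,
    lo_mult: float = 0.5,
) -> pd.DataFrame:
    """Flag samples whose ratio strays from their race stratum's median.

    ``high`` when ratio > hi_mult x stratum median, ``low`` when
    < lo_mult x stratum median; unknown-race samples are judged against the
    overall median. Relative bounds are used because the ratio's typical
    value is ancestry-dependent.
    """
    races = np.asarray(race_labels, dtype=object)
    ratio = result["ratio"].to_numpy()
    overall_med = np.nanmedian(ratio) if np.isfinite(ratio).any() else np.nan

    medians = {}
    for r in pd.unique(races):
        vals = ratio[races == r]
        medians[r] = np.nanmedian(vals) if np.isfinite(vals).any() else np.nan
    medians[RACE_UNKNOWN] = overall_med

    flags = []
    for r, x in zip(races, ratio):
        med = medians.get(r, overall_med)
        if not np.isfinite(x):
            flags.append(FLAG_UNDEFINED)
        elif np.isfinite(med) and x > hi_mult * med:
            flags.append(FLAG_HIGH)
        elif np.isfinite(med) and x < lo_mult * med:
            flags.append(FLAG_LOW)
        else:
            flags.append(FLAG_OK)
    out = result.copy()
    out["stratum_median"] = [medians.get(r, overall_med) for r in races]
    out["flag"] = flags
    return out


def stratified_summary(
    result: pd.DataFrame, race_labels: np.ndarray, min_size: int = 3
) -> pd.DataFrame:
    """Per-race summary statistics of the ratio.

    Strata smaller than ``min_size`` are kept in the table but marked
    ``plotted=False`` so downstream figures can drop them; unknown-race
    samples are excluded from the stratified view.
    """
    races = np.asarray(race_labels, dtype=object)
    ratio = result["ratio"].to_numpy()
    rows = []
    for r in sorted({x for x in races if x != RACE_UNKNOWN}):
        vals = ratio[(races == r) & np.isfinite(ratio)]
        if vals.size == 0:
            continue
        rows.append(
            (
                r,
                int(vals.size),
                float(np.median(vals)),
                float(np.percentile(vals, 25)),
                float(np.percentile(vals, 75)),
                float(np.mean(vals)),
                vals.size >= min_size,
            )
        )
    return pd.DataFrame(
        rows, columns=["stratum", "n", "median", "q1", "q3", "mean", "plotted"]
    )
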