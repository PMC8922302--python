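"""Per-sample and per-variant call rates, allele frequencies, and
concordance of cohort MAF against a reference panel."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset
from .exceptions import DegenerateInputError

#: Default threshold ladder for call-rate summaries.
DEFAULT_LADDER = (0.90, 0.95, 0.98, 0.99)


def sample_call_rate(ds: GenotypeDataset) -> np.ndarray:
    """Fraction of the fileset's variants called in each sample.

    The denominator is the full variant list (the union set across samples);
    variants called in no sample still count.
    """
    if ds.n_variants == 0:
        raise DegenerateInputError("sample call rate undefined with zero variants")
    return (ds.G != MISSING).mean(axis=1)


def variant_call_rate(ds: GenotypeDataset) -> np.ndarray:
    """Fraction of samples with a non-missing call at each variant."""
    if ds.n_samples == 0:
        raise DegenerateInputError("variant call rate undefined with zero samples")
    return (ds.G != MISSING).mean(axis=0)


def call_rate_summary(rates: np.ndarray, ladder: Sequence[float] = DEFAULT_LADDER) -> pd.DataFrame:
    """Count how many rates meet each threshold of an ascending ladder.

    A rate exactly at a threshold counts as passing (>=). Counts are
    necessarily non-increasing along the ladder.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise DegenerateInputError("call-rate summary undefined on empty rates")
    ladder = list(ladder)
    if any(b < a for a, b in zip(ladder, ladder[1:])):
        raise DegenerateInputError("threshold ladder must be ascending")
    counts = [int(np.sum(rates >= t)) for t in ladder]
    return pd.DataFrame(
        {
            "threshold": ladder,
            "count": counts,
            "fraction": [c / rates.size for c in counts],
        }
    )


def allele_frequency(
    ds: GenotypeDataset,
    sample_mask: np.ndarray | None = None,
    variant_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Alt-allele (a2) frequency and MAF per variant over non-missing calls.

    Every call is counted as diploid (two alleles); restrict to diploid
    regions and/or one sex via the masks before mixing ploidies. Variants
    with zero calls are flagged ``defined=False`` rather than dropped, and a
    monomorphic variant reports maf 0 with the absent allele as minor.

    Returns a frame with columns vid, a2_freq, maf, n_called, minor_allele,
    defined.
    """
    G = ds.G
    if sample_mask is not None:
        G = G[np.asarray(sample_mask, dtype=bool)]
    variants = ds.variants
    if variant_mask is not None:
        vm = np.asarray(variant_mask, dtype=bool)
        G = G[:, vm]
        variants = [v for v, keep in zip(variants, vm) if keep]

    called = G != MISSING
    n_called = called.sum(axis=0)
    dos_sum = np.where(called, G, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        a2_freq = np.where(n_called > 0, dos_sum / (2.0 * np.maximum(n_called, 1)), np.nan)
    maf = np.where(n_called > 0, np.minimum(a2_freq, 1.0 - a2_freq), np.nan)
    minor = [
        (v.a1 if f > 0.5 else v.a2) if n > 0 else "NA"
        for v, f, n in zip(variants, a2_freq, n_called)
    ]
    return pd.DataFrame(
        {
            "vid": [v.vid for v in variants],
            "a2_freq": a2_freq,
            "maf": maf,
            "n_called": n_called.astype(int),
            "minor_allele": minor,
            "defined": n_called > 0,
        }
    )


def read_reference_maf(path) -> pd.Series:
    """Read a tab-delimited reference MAF table with header ``vid  maf``."""
    df = pd.read_csv(path, sep="\t", dtype={"vid": str})
    return pd.Series(df["maf"].astype(float).values, index=df["vid"], name="maf")


def maf_concordance(
    local: pd.DataFrame, reference: Mapping[str, float] | pd.Series
) -> tuple[int, float, pd.DataFrame]:
    """Pearson correlation of cohort MAF against a reference panel's MAF.

    Variants are intersected on id; undefined local MAFs are dropped.
    Returns ``(n_shared, r, paired)`` where ``r`` is NaN when fewer than 3
    variants are shared and ``paired`` keeps the matched MAF pairs for
    plotting.
    """
    ref = pd.Series(reference, dtype=float) if not isinstance(reference, pd.Series) else reference
    ok = local[local["defined"]].set_index("vid")["maf"]
    shared = ok.index.intersection(ref.index)
    paired = pd.DataFrame(
        {"vid": shared, "maf_local": ok.loc[shared].values, "maf_ref": ref.loc[shared].values}
    )
    n_shared = len(paired)
    if n_shared < 3:
        return n_shared, float("nan"), paired
    r = float(np.corrcoef(paired["maf_local"], paired["maf_ref"])[0, 1])
    return n_shared, r, paired
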