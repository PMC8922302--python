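"""Genotype consistency between duplicated samples and duplicated variants.

Duplicate pairs (technical replicates, external control samples run twice,
or the same locus probed by two array designs) should genotype identically;
their concordance rate is a direct readout of assay quality. Matching is
defined on dosage after allele reconciliation: if two variant records carry
the same alleles in swapped order, dosage d on one equals 2-d on the other.
Pairs whose allele sets cannot be reconciled even by swapping (e.g. a
probable strand flip) are flagged incomparable and excluded from rates —
strand correction is out of scope here.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset
from .regions import diploid_mask

FLAG_OK = "ok"
FLAG_LOW = "low"
FLAG_UNDEFINED = "undefined"
FLAG_INCOMPARABLE = "incomparable"

_SAMPLE_COLUMNS = ["id_a", "id_b", "group", "n_overlap", "n_match", "rate", "flag"]
_VARIANT_COLUMNS = ["vid_a", "vid_b", "swapped", "n_overlap", "n_match", "rate", "flag"]


def _rate_row(a: np.ndarray, b: np.ndarray, threshold: float):
    both = (a != MISSING) & (b != MISSING)
    n_overlap = int(both.sum())
    n_match = int(np.sum(a[both] == b[both]))
    if n_overlap == 0:
        return n_overlap, n_match, float("nan"), FLAG_UNDEFINED
    rate = n_match / n_overlap
    return n_overlap, n_match, rate, (FLAG_OK if rate >= threshold else FLAG_LOW)


def sample_pair_concordance(
    ds: GenotypeDataset,
    region_labels: np.ndarray | None = None,
    threshold: float = 0.99,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Concordance over all within-dup_group sample pairs.

    Comparison runs over diploid variants (when region labels are supplied)
    where both calls are non-missing. With no duplicate groups and no
    explicit pairs the result is an empty table — the stage is "not
    assessed", mirroring cohorts that simply contain no duplicates.
    """
    vmask = diploid_mask(region_labels) if region_labels is not None else None
    G = ds.G if vmask is None else ds.G[:, vmask]
    index = {iid: i for i, iid in enumerate(ds.sample_ids)}

    rows = []
    if pairs is None:
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(ds.samples):
            if s.dup_group is not None:
                groups.setdefault(s.dup_group, []).append(i)
        pair_list = [
            (g, i, j)
            for g, members in sorted(groups.items())
            if len(members) >= 2
            for i, j in combinations(members, 2)
        ]
    else:
        pair_list = [("user", index[a], index[b]) for a, b in pairs]

    for group, i, j in pair_list:
        n_overlap, n_match, rate, flag = _rate_row(G[i], G[j], threshold)
        rows.append(
            (ds.samples[i].iid, ds.samples[j].iid, group, n_overlap, n_match, rate, flag)
        )
    return pd.DataFrame(rows, columns=_SAMPLE_COLUMNS)


def _reconcile(va, vb) -> str | None:
    """Return 'direct', 'swapped', or None when alleles are irreconcilable."""
    if (va.a1, va.a2) == (vb.a1, vb.a2):
        return "direct"
    if (va.a1, va.a2) == (vb.a2, vb.a1):
        return "swapped"
    return None


def variant_pair_concordance(
    ds: GenotypeDataset,
    pairs: list[tuple[str, str]] | None = None,
    threshold: float = 0.99,
) -> pd.DataFrame:
    """Concordance between duplicated variants (same locus, two probes).

    Pairs default to variants sharing (chrom, bp). When the two records'
    alleles are swapped, dosages are compared as d vs 2-d; irreconcilable
    allele sets flag the pair incomparable with no rate.
    """
    vindex = {v: i for i, v in enumerate(ds.variant_ids)}
    if pairs is None:
        by_pos: dict[tuple[str, int], list[int]] = {}
        for i, v in enumerate(ds.variants):
            by_pos.setdefault((v.chrom, v.bp), []).append(i)
        pair_list = [
            (i, j)
            for members in by_pos.values()
            if len(members) >= 2
            for i, j in combinations(members, 2)
        ]
    else:
        pair_list = [(vindex[a], vindex[b]) for a, b in pairs]

    rows = []
    for i, j in pair_list:
        va, vb = ds.variants[i], ds.variants[j]
        mode = _reconcile(va, vb)
        if mode is None:
            rows.append((va.vid, vb.vid, False, 0, 0, float("nan"), FLAG_INCOMPARABLE))
            continue
        a = ds.G[:, i]
        b = ds.G[:, j].copy()
        if mode == "swapped":
            called = b != MISSING
            b = np.where(called, 2 - b, MISSING).astype(np.int8)
        n_overlap, n_match, rate, flag = _rate_row(a, b, threshold)
        rows.append((va.vid, vb.vid, mode == "swapped", n_overlap, n_match, rate, flag))
    return pd.DataFrame(rows, columns=_VARIANT_COLUMNS)
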