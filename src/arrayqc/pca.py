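"""Ancestry PCA on the genotype matrix.

Principal components of variance-standardized genotypes recover the main
axes of ancestry; distinct populations form separated clusters on the
PC1-vs-PC2 plane, which lets reported race be cross-checked genetically.
Without a user-supplied list of ancestry-informative markers, a standard
surrogate is used: autosomal variants filtered on MAF and call rate and
thinned by sliding-window LD pruning on squared genotype correlation.

Standardization follows the population-genetics convention: dosages are
centered at 2p and scaled by sqrt(2p(1-p)); missing entries are imputed to
the column mean and therefore contribute exactly zero after centering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, RACE_UNKNOWN, GenotypeDataset
from .exceptions import DegenerateInputError, ParameterError
from .regions import REGION_AUTOSOME

FLAG_OK = "ok"
FLAG_MISMATCH = "mismatch"
FLAG_OUTLIER = "hybrid/outlier"
FLAG_UNLABELLED = "unlabelled"


@dataclass
class PcaResult:
    """Scores, explained variance, and race-consistency flags."""

    scores: np.ndarray                  # (n_samples, k)
    explained_variance: np.ndarray      # fraction per component, non-increasing
    variant_ids: list[str]
    table: pd.DataFrame = field(default=None)  # per-sample output table


def select_pca_variants(
    ds: GenotypeDataset,
    region_labels: np.ndarray,
    maf_table: pd.DataFrame | None = None,
    maf_min: float = 0.05,
    callrate_min: float = 0.95,
    ld_window: int = 50,
    ld_step: int = 5,
    ld_r2: float = 0.2,
    aim_list: list[str] | None = None,
) -> list[str]:
    """Pick the variant panel for PCA.

    A user AIM list wins outright (intersected with the dataset, dataset
    order). Otherwise autosomal variants are filtered on MAF and call rate
    and greedily LD-pruned: windows of ``ld_window`` variants advanced by
    ``ld_step``; within a window, of any pair with squared correlation above
    ``ld_r2`` the later variant is dropped.
    """
    if aim_list is not None:
        keep = set(aim_list)
        chosen = [v for v in ds.variant_ids if v in keep]
        if len(chosen) < 2:
            raise DegenerateInputError("fewer than 2 AIM-list variants present in dataset")
        return chosen

    from .cohort import allele_frequency, variant_call_rate

    if maf_table is None:
        maf_table = allele_frequency(ds)
    maf = maf_table.set_index("vid")["maf"].reindex(ds.variant_ids).to_numpy()
    cr = variant_call_rate(ds)
    auto = np.asarray(region_labels, dtype=object) == REGION_AUTOSOME
    candidate = auto & (cr >= callrate_min) & (np.nan_to_num(maf, nan=-1.0) >= maf_min)
    idx = np.flatnonzero(candidate)
    if idx.size < 2:
        raise DegenerateInputError("fewer than 2 variants survive MAF/call-rate filtering")

    # mean-imputed dosage matrix over candidates for correlation pruning
    G = ds.G[:, idx].astype(float)
    G[G == MISSING] = np.nan
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean, G)

    kept = np.ones(idx.size, dtype=bool)
    start = 0
    while start < idx.size:
        window = np.flatnonzero(kept[start : start + ld_window]) + start
        if window.size > 1:
            W = G[:, window]
            W = W - W.mean(axis=0)
            sd = W.std(axis=0)
            sd[sd == 0] = np.inf  # constant columns correlate with nothing
            C = (W / sd).T @ (W / sd) / W.shape[0]
            r2 = C**2
            for a in range(window.size):
                if not kept[window[a]]:
                    continue
                for b in range(a + 1, window.size):
                    if kept[window[b]] and r2[a, b] > ld_r2:
                        kept[window[b]] = False
        start += ld_step
    chosen = idx[kept]
    if chosen.size < 2:
        raise DegenerateInputError("fewer than 2 variants survive LD pruning")
    return [ds.variant_ids[j] for j in chosen]


def standardize_genotypes(ds: GenotypeDataset) -> np.ndarray:
    """Center columns at 2p and scale by sqrt(2p(1-p)); impute missing to mean.

    Monomorphic columns must have been removed upstream (their scale is 0).
    """
    G = ds.G.astype(float)
    G[G == MISSING] = np.nan
    p = np.nanmean(G, axis=0) / 2.0
    if np.any(~np.isfinite(p)) or np.any((p <= 0) | (p >= 1)):
        raise DegenerateInputError(
            "standardization requires every column polymorphic with >=1 call"
        )
    X = np.where(np.isnan(G), 2.0 * p, G)
    return (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def top_pcs(X: np.ndarray, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal-component scores and explained-variance fractions.

    Scores are projections onto the top right-singular directions of the
    sample-by-variant matrix. Sign convention: the largest-magnitude variant
    loading of each component is positive, so results are reproducible
    across SVD implementations.
    """
    n, m = X.shape
    if n < 2:
        raise DegenerateInputError("PCA needs at least 2 samples")
    if k > min(n, m):
        raise ParameterError(f"k={k} exceeds min(n_samples, n_variants)={min(n, m)}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    for comp in range(k):
        j = np.argmax(np.abs(Vt[comp]))
        if Vt[comp, j] < 0:
            Vt[comp] *= -1
            U[:, comp] *= -1
    scores = U[:, :k] * s[:k]
    ev = (s**2) / np.sum(s**2)
    return scores, ev[:k]


def flag_race_outliers(
    scores: np.ndarray,
    reported_race: np.ndarray,
    k_used: int = 2,
    z_max: float = 3.0,
) -> pd.DataFrame:
    """Nearest-centroid race consistency check in PC space.

    Per reported race (>=3 samples, known label) a centroid (componentwise
    median) and a robust scale (1.4826 x MAD) are estimated over the first
    ``k_used`` components. A sample farther than ``z_max`` robust-z units
    from every centroid is a hybrid/outlier; otherwise, a nearest centroid
    differing from the reported race is a mismatch. Unknown-race samples are
    ``unlabelled`` with the nearest centroid reported as a suggestion. With
    fewer than 2 usable strata everything is unlabelled and a warning is
    issued.
    """
    races = np.asarray(reported_race, dtype=object)
    S = np.asarray(scores)[:, :k_used]
    usable = [
        r
        for r in pd.unique(races)
        if r != RACE_UNKNOWN and np.sum(races == r) >= 3
    ]
    if len(usable) < 2:
        warnings.warn("fewer than 2 labelled race strata; race check not performed")
        return pd.DataFrame(
            {
                "nearest_race": ["NA"] * len(races),
                "z_distance": np.nan,
                "flag": [FLAG_UNLABELLED] * len(races),
            }
        )

    centroids, scales = {}, {}
    for r in usable:
        pts = S[races == r]
        med = np.median(pts, axis=0)
        mad = np.median(np.abs(pts - med), axis=0)
        centroids[r] = med
        scales[r] = np.maximum(1.4826 * mad, 1e-8)

    nearest, zdist, flags = [], [], []
    for i in range(len(races)):
        d = {
            r: float(np.sqrt(np.sum(((S[i] - centroids[r]) / scales[r]) ** 2)))
            for r in usable
        }
        best = min(d, key=d.get)
        nearest.append(best)
        zdist.append(d[best])
        if races[i] == RACE_UNKNOWN or races[i] not in usable:
            flags.append(FLAG_UNLABELLED)
        elif min(d.values()) > z_max:
            flags.append(FLAG_OUTLIER)
        elif best != races[i]:
            flags.append(FLAG_MISMATCH)
        else:
            flags.append(FLAG_OK)
    return pd.DataFrame({"nearest_race": nearest, "z_distance": zdist, "flag": flags})


def run_pca(
    ds: GenotypeDataset,
    region_labels: np.ndarray,
    k: int = 10,
    maf_min: float = 0.05,
    callrate_min: float = 0.95,
    ld_window: int = 50,
    ld_step: int = 5,
    ld_r2: float = 0.2,
    aim_list: list[str] | None = None,
    k_used: int = 2,
    z_max: float = 3.0,
) -> PcaResult:
    """Variant selection + standardization + SVD + race flags in one call."""
    vids = select_pca_variants(
        ds,
        region_labels,
        maf_min=maf_min,
        callrate_min=callrate_min,
        ld_window=ld_window,
        ld_step=ld_step,
        ld_r2=ld_r2,
        aim_list=aim_list,
    )
    sub = ds.subset(variant_sel=vids)
    X = standardize_genotypes(sub)
    k_eff = min(k, min(X.shape))
    scores, ev = top_pcs(X, k_eff)
    races = np.array([s.reported_race for s in ds.samples], dtype=object)
    flags = flag_race_outliers(scores, races, k_used=min(k_used, k_eff), z_max=z_max)
    table = pd.DataFrame({"iid": ds.sample_ids})
    for c in range(k_eff):
        table[f"PC{c + 1}"] = scores[:, c]
    table["reported_race"] = races
    table = pd.concat([table, flags], axis=1)
    return PcaResult(scores=scores, explained_variance=ev, variant_ids=vids, table=table)
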