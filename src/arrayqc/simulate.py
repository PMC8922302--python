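"""Synthetic PLINK cohorts with controlled statistical structure.

Cohorts are drawn under the explicit population-genetics model each QC
stage assumes, so every generator parameter is recoverable downstream:
autosomal genotypes follow Hardy-Weinberg with optional per-variant
inbreeding f, i.e. genotype probabilities (p^2 + fpq, 2pq(1-f), q^2 + fpq);
females are diploid on X while males are hemizygous (coded as the
corresponding homozygote, never heterozygous); PAR variants are diploid in
both sexes; Y variants are missing in females. Variants are independent
except where duplicated by construction — no linkage is simulated.

Randomness is fully deterministic: one root seed feeds a named substream
per generation stage, so adding a stage never perturbs earlier stages'
draws and equal specs produce byte-identical filesets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
import yaml

from .dataset import (
    MISSING,
    SEX_FEMALE,
    SEX_MALE,
    SEX_UNKNOWN,
    GenotypeDataset,
    SampleRecord,
    VariantRecord,
)
from .exceptions import ParameterError

# stable substream ids; append-only so draws never shift between versions
_STREAMS = {
    "pop_assign": 0,
    "frequencies": 1,
    "autosomes": 2,
    "sex_assign": 3,
    "x_chrom": 4,
    "y_chrom": 5,
    "par": 6,
    "missingness": 7,
    "duplicates": 8,
    "contamination": 9,
    "case_status": 10,
}

# non-PAR X positions are drawn from this window, clear of PAR1/2/3 on both
# supported builds
_X_NONPAR_LO, _X_NONPAR_HI = 5_000_000, 88_000_000
_Y_NONPAR_LO, _Y_NONPAR_HI = 6_500_000, 28_000_000
_PAR1_LO, _PAR1_HI = 100_000, 2_600_000


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stage],)))


@dataclass
class SimSpec:
    """Recipe for one synthetic cohort; the seed is mandatory.

    ``maf`` / ``x_maf`` accept a float, a ``("uniform", lo, hi)`` triple, or
    an explicit per-variant vector of alt-allele frequencies.
    ``populations`` maps label -> sample fraction; ``pop_freqs`` optionally
    pins each population's autosomal alt-frequency vector (default:
    independent drift of +/- ``pop_shift`` around the base frequencies).
    ``duplicates`` lists (sample_index, error_rate); ``contamination`` lists
    (target_index, donor_index, mixing_fraction).
    """

    n_samples: int
    n_variants: int
    seed: int
    maf: object = ("uniform", 0.1, 0.5)
    inbreeding_f: object = 0.0
    sex_fractions: tuple[float, float, float] = (0.5, 0.5, 0.0)
    n_x: int = 0
    n_y: int = 0
    n_par: int = 0
    x_maf: object = ("uniform", 0.1, 0.9)
    sample_missing: object = 0.0
    variant_missing: object = 0.0
    populations: dict[str, float] | None = None
    pop_freqs: dict[str, np.ndarray] | None = None
    pop_shift: float = 0.2
    case_fraction: float = 0.0
    duplicates: list[tuple[int, float]] = field(default_factory=list)
    contamination: list[tuple[int, int, float]] = field(default_factory=list)
    sex_mislabels: list[int] = field(default_factory=list)
    genetic_sexes: object = None  # optional explicit per-sample "male"/"female"

    def __post_init__(self):
        if self.seed is None:
            raise ParameterError("SimSpec.seed is mandatory")
        if abs(sum(self.sex_fractions) - 1.0) > 1e-9:
            raise ParameterError("sex_fractions must sum to 1")
        if self.populations is not None and abs(sum(self.populations.values()) - 1.0) > 1e-9:
            raise ParameterError("population fractions must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "SimSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("duplicates", "contamination"):
            if key in data:
                data[key] = [tuple(x) for x in data[key]]
        if "sex_fractions" in data:
            data["sex_fractions"] = tuple(data["sex_fractions"])
        for key in ("maf", "x_maf"):
            val = data.get(key)
            if isinstance(val, list):
                # ["uniform", lo, hi] is a distribution; a bare list is an
                # explicit per-variant frequency vector
                data[key] = tuple(val) if val and val[0] == "uniform" else np.asarray(val, dtype=float)
        return cls(**data)


def _freq_vector(spec_value, m: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec_value, (int, float)):
        q = np.full(m, float(spec_value))
    elif isinstance(spec_value, (tuple, list)) and len(spec_value) == 3 and spec_value[0] == "uniform":
        q = rng.uniform(float(spec_value[1]), float(spec_value[2]), size=m)
    else:
        q = np.asarray(spec_value, dtype=float)
        if q.shape != (m,):
            raise ParameterError(f"frequency vector has shape {q.shape}, expected ({m},)")
    if np.any((q < 0) | (q > 1)):
        raise ParameterError("allele frequencies must lie in [0, 1]")
    return q


def _draw_hwe(q: np.ndarray, f: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an (n, m) diploid genotype block with per-variant inbreeding."""
    p = 1.0 - q
    p0 = p * p + f * p * q
    p1 = 2.0 * p * q * (1.0 - f)
    if np.any(p0 < -1e-12) or np.any(p1 < -1e-12):
        raise ParameterError("inbreeding_f yields negative genotype probabilities")
    p0, p1 = np.clip(p0, 0, 1), np.clip(p1, 0, 1)
    u = rng.random((n, q.size))
    return ((u > p0).astype(np.int8) + (u > p0 + p1)).astype(np.int8)


def simulate_cohort(spec: SimSpec) -> GenotypeDataset:
    """Generate a full cohort: autosomes, sex chromosomes, missingness,
    duplicates and contamination, with metadata-laden sample records."""
    n, m = spec.n_samples, spec.n_variants

    # population assignment and per-population autosomal frequencies
    if spec.populations:
        labels = list(spec.populations)
        pr = np.array([spec.populations[k] for k in labels])
        pop_of = _rng(spec.seed, "pop_assign").choice(len(labels), size=n, p=pr)
    else:
        labels = ["pop1"]
        pop_of = np.zeros(n, dtype=int)

    frng = _rng(spec.seed, "frequencies")
    base_q = _freq_vector(spec.maf, m, frng)
    if spec.pop_freqs is not None:
        pop_q = {k: _freq_vector(v, m, frng) for k, v in spec.pop_freqs.items()}
    elif len(labels) > 1:
        pop_q = {
            k: np.clip(base_q + frng.uniform(-spec.pop_shift, spec.pop_shift, size=m), 0.01, 0.99)
            for k in labels
        }
    else:
        pop_q = {labels[0]: base_q}

    f = np.asarray(spec.inbreeding_f, dtype=float)
    f = np.full(m, float(f)) if f.ndim == 0 else f
    if f.shape != (m,):
        raise ParameterError("inbreeding_f must be scalar or length n_variants")

    arng = _rng(spec.seed, "autosomes")
    G_auto = np.empty((n, m), dtype=np.int8)
    for k, label in enumerate(labels):
        rows = pop_of == k
        if rows.any():
            G_auto[rows] = _draw_hwe(pop_q[label], f, int(rows.sum()), arng)

    # genetic and reported sex
    srng = _rng(spec.seed, "sex_assign")
    if spec.genetic_sexes is not None:
        sexes = list(spec.genetic_sexes)
        if len(sexes) != n:
            raise ParameterError("genetic_sexes must have one entry per sample")
        genetic_male = np.array([s == SEX_MALE for s in sexes])
        reported = np.where(genetic_male, SEX_MALE, SEX_FEMALE).astype(object)
    else:
        male_frac, female_frac, unk_frac = spec.sex_fractions
        denom = male_frac + female_frac
        if denom <= 0:
            raise ParameterError("male + female fractions must be positive")
        genetic_male = srng.random(n) < (male_frac / denom)
        reported_unknown = srng.random(n) < unk_frac
        reported = np.where(genetic_male, SEX_MALE, SEX_FEMALE).astype(object)
        reported[reported_unknown] = SEX_UNKNOWN
    for i in spec.sex_mislabels:
        reported[i] = SEX_FEMALE if genetic_male[i] else SEX_MALE

    blocks = [G_auto]
    variants = [
        VariantRecord(chrom="1", vid=f"var{j + 1}", cm=0.0, bp=10_000 + 100 * j, a1="A", a2="B")
        for j in range(m)
    ]

    xq = None
    if spec.n_x:
        xrng = _rng(spec.seed, "x_chrom")
        xq = _freq_vector(spec.x_maf, spec.n_x, xrng)
        GX = np.empty((n, spec.n_x), dtype=np.int8)
        fem = ~genetic_male
        if fem.any():
            GX[fem] = _draw_hwe(xq, np.zeros(spec.n_x), int(fem.sum()), xrng)
        if genetic_male.any():
            # hemizygous: one allele, coded as the matching homozygote
            GX[genetic_male] = 2 * (
                xrng.random((int(genetic_male.sum()), spec.n_x)) < xq
            ).astype(np.int8)
        blocks.append(GX)
        bp = np.linspace(_X_NONPAR_LO, _X_NONPAR_HI, spec.n_x).astype(int)
        variants += [
            VariantRecord(chrom="X", vid=f"xvar{j + 1}", cm=0.0, bp=int(bp[j]), a1="A", a2="B")
            for j in range(spec.n_x)
        ]

    if spec.n_par:
        prng = _rng(spec.seed, "par")
        pq = _freq_vector(spec.x_maf, spec.n_par, prng)
        blocks.append(_draw_hwe(pq, np.zeros(spec.n_par), n, prng))
        bp = np.linspace(_PAR1_LO, _PAR1_HI, spec.n_par).astype(int)
        variants += [
            VariantRecord(chrom="X", vid=f"pvar{j + 1}", cm=0.0, bp=int(bp[j]), a1="A", a2="B")
            for j in range(spec.n_par)
        ]

    if spec.n_y:
        yrng = _rng(spec.seed, "y_chrom")
        yq = _freq_vector(spec.x_maf, spec.n_y, yrng)
        GY = np.full((n, spec.n_y), MISSING, dtype=np.int8)
        if genetic_male.any():
            GY[genetic_male] = 2 * (
                yrng.random((int(genetic_male.sum()), spec.n_y)) < yq
            ).astype(np.int8)
        blocks.append(GY)
        bp = np.linspace(_Y_NONPAR_LO, _Y_NONPAR_HI, spec.n_y).astype(int)
        variants += [
            VariantRecord(chrom="Y", vid=f"yvar{j + 1}", cm=0.0, bp=int(bp[j]), a1="A", a2="B")
            for j in range(spec.n_y)
        ]

    G = np.concatenate(blocks, axis=1) if len(blocks) > 1 else blocks[0]

    # control/case status
    crng = _rng(spec.seed, "case_status")
    is_case = crng.random(n) < spec.case_fraction
    samples = [
        SampleRecord(
            fid=f"F{i + 1}",
            iid=f"S{i + 1}",
            reported_sex=str(reported[i]),
            reported_race=labels[pop_of[i]] if spec.populations else "unknown",
            is_control=(not is_case[i]) if spec.case_fraction > 0 else True,
        )
        for i in range(n)
    ]
    ds = GenotypeDataset(samples, variants, G)

    ds = inject_missingness(
        ds, spec.sample_missing, spec.variant_missing, _rng(spec.seed, "missingness")
    )
    ds = add_duplicates_and_contamination(
        ds,
        spec.duplicates,
        spec.contamination,
        dup_rng=_rng(spec.seed, "duplicates"),
        contam_rng=_rng(spec.seed, "contamination"),
    )
    return ds


def inject_missingness(
    ds: GenotypeDataset,
    sample_rates,
    variant_rates,
    rng: np.random.Generator,
) -> GenotypeDataset:
    """Mask each call independently with probability 1-(1-r_sample)(1-r_variant)."""
    n, m = ds.n_samples, ds.n_variants
    rs = np.asarray(sample_rates, dtype=float)
    rs = np.full(n, float(rs)) if rs.ndim == 0 else rs
    rv = np.asarray(variant_rates, dtype=float)
    rv = np.full(m, float(rv)) if rv.ndim == 0 else rv
    if np.any((rs < 0) | (rs > 1)) or np.any((rv < 0) | (rv > 1)):
        raise ParameterError("missingness rates must lie in [0, 1]")
    prob = 1.0 - np.outer(1.0 - rs, 1.0 - rv)
    if not prob.any():
        return ds
    G = ds.G.copy()
    G[rng.random((n, m)) < prob] = MISSING
    return GenotypeDataset(ds.samples, ds.variants, G)


def add_duplicates_and_contamination(
    ds: GenotypeDataset,
    duplicates: Sequence[tuple[int, float]],
    contamination: Sequence[tuple[int, int, float]],
    dup_rng: np.random.Generator,
    contam_rng: np.random.Generator,
    diploid_cols: np.ndarray | None = None,
) -> GenotypeDataset:
    """Append duplicate copies and apply DNA contamination.

    Duplicates are copies with an independent per-genotype error at the
    stated rate (an erroneous call becomes one of the other two genotypes,
    uniformly), labelled with a shared dup_group. Contamination models
    pooled DNA: the target's dosage becomes the mixing-weighted average of
    target and donor re-called to a genotype, with the middle band called
    heterozygous — which is exactly why contaminated samples show inflated
    heterozygosity. It applies to diploid columns (``diploid_cols`` mask,
    default: all autosomal-coded chromosomes "1".."22" plus chromosome-X PAR
    window positions are left to the caller; with ``None`` every non-sex
    chromosome column is eligible).
    """
    G = ds.G.copy()
    samples = list(ds.samples)

    if diploid_cols is None:
        diploid_cols = np.array(
            [v.chrom not in ("X", "Y", "XY", "MT") for v in ds.variants], dtype=bool
        )

    # contamination first, so a duplicate of a contaminated sample would
    # copy the contaminated calls (duplicates are taken downstream of wet-lab
    # handling)
    for target, donor, frac in contamination:
        if not 0.0 <= frac <= 1.0:
            raise ParameterError("contamination fraction must lie in [0, 1]")
        cols = np.flatnonzero(diploid_cols)
        t, d = G[target, cols].astype(float), G[donor, cols].astype(float)
        both = (t != MISSING) & (d != MISSING)
        pooled = (1.0 - frac) * t[both] + frac * d[both]
        called = np.where(pooled < 0.5, 0, np.where(pooled > 1.5, 2, 1)).astype(np.int8)
        out = G[target, cols]
        out[both] = called
        G[target, cols] = out

    dup_blocks = []
    for k, (idx, err) in enumerate(duplicates, start=1):
        if not 0.0 <= err <= 1.0:
            raise ParameterError("duplicate error rate must lie in [0, 1]")
        src = samples[idx]
        row = G[idx].copy()
        called = row != MISSING
        flip = called & (dup_rng.random(row.size) < err)
        # replace with one of the other two genotypes, uniformly
        shift = dup_rng.integers(1, 3, size=row.size)
        row[flip] = ((row[flip] + shift[flip]) % 3).astype(np.int8)
        group = src.dup_group or f"dup{k}"
        samples[idx] = dc_replace(src, dup_group=group)
        samples.append(
            SampleRecord(
                fid=src.fid,
                iid=f"{src.iid}_dup",
                reported_sex=src.reported_sex,
                reported_race=src.reported_race,
                is_control=src.is_control,
                dup_group=group,
            )
        )
        dup_blocks.append(row)

    if dup_blocks:
        G = np.vstack([G, np.array(dup_blocks, dtype=np.int8)])
    return GenotypeDataset(samples, ds.variants, G)
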