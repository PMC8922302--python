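"""Chromosomal region classification, notably the pseudo-autosomal regions.

PAR1 and PAR2 are the canonical recombining X/Y homology blocks and carry
well-established coordinates on both supported builds. A third region
(the Xq21.3 / Yp11.2 homology block, sometimes called PAR3) has been
proposed but remains debated; it ships here with approximate bounds and can
be toggled off. Variants on the synthetic "XY" chromosome are PAR by
definition regardless of position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset, VariantRecord
from .exceptions import ParameterError, ParseError

REGION_AUTOSOME = "autosome"
REGION_X_NONPAR = "x_nonpar"
REGION_Y_NONPAR = "y_nonpar"
REGION_PAR = "par"
REGION_MITO = "mito"
REGION_OTHER = "other"

#: Regions treated as diploid in both sexes.
DIPLOID_REGIONS = (REGION_AUTOSOME, REGION_PAR)

_AUTOSOMES = frozenset(str(i) for i in range(1, 23))


@dataclass(frozen=True)
class ParInterval:
    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self):
        if self.start >= self.end:
            raise ParameterError(f"{self.name}: start must be < end")


@dataclass(frozen=True)
class ParTable:
    """Pseudo-autosomal intervals for one genome build."""

    build: str
    intervals: tuple[ParInterval, ...] = field(default_factory=tuple)

    def contains(self, chrom: str, bp: int) -> bool:
        return any(iv.chrom == chrom and iv.start <= bp <= iv.end for iv in self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "build": self.build,
                "name": [iv.name for iv in self.intervals],
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
            }
        )


# Canonical PAR1/PAR2 coordinates; PAR3 bounds are the approximate Xq21.3 /
# Yp11.2 homology block and are marked debated.
_PAR_DATA = {
    "grch37": [
        ("PAR1", "X", 60_001, 2_699_520),
        ("PAR1", "Y", 10_001, 2_649_520),
        ("PAR2", "X", 154_931_044, 155_260_560),
        ("PAR2", "Y", 59_034_050, 59_363_566),
        ("PAR3", "X", 88_456_802, 92_375_509),
        ("PAR3", "Y", 3_447_000, 5_821_000),
    ],
    "grch38": [
        ("PAR1", "X", 10_001, 2_781_479),
        ("PAR1", "Y", 10_001, 2_781_479),
        ("PAR2", "X", 155_701_383, 156_030_895),
        ("PAR2", "Y", 56_887_903, 57_217_415),
        ("PAR3", "X", 89_201_802, 93_120_510),
        ("PAR3", "Y", 3_511_000, 5_885_000),
    ],
}


def par_table(build: str = "grch37", include_par3: bool = True) -> ParTable:
    """Built-in PAR intervals for GRCh37 or GRCh38.

    ``include_par3=False`` drops the debated third region.
    """
    key = build.lower()
    if key not in _PAR_DATA:
        raise ParameterError(f"unknown build {build!r}; expected grch37 or grch38")
    rows = [
        ParInterval(name, chrom, start, end)
        for name, chrom, start, end in _PAR_DATA[key]
        if include_par3 or name != "PAR3"
    ]
    return ParTable(build=key, intervals=tuple(rows))


def read_par_table(path, build: str) -> ParTable:
    """Read a user PAR table (columns build, name, chrom, start, end; 1-based
    inclusive) and keep the rows for ``build``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"build", "name", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: PAR table needs columns {sorted(required)}")
    rows = df[df["build"].str.lower() == build.lower()]
    return ParTable(
        build=build.lower(),
        intervals=tuple(
            ParInterval(r.name, str(r.chrom), int(r.start), int(r.end))
            for r in rows.itertuples()
        ),
    )


def classify_par(
    variants: Sequence[VariantRecord] | GenotypeDataset, par: ParTable
) -> np.ndarray:
    """Label each variant autosome / x_nonpar / y_nonpar / par / mito / other.

    Chromosome "XY" is PAR by convention; X and Y positions inside a PAR
    interval are PAR; unrecognized chromosome labels map to "other" rather
    than raising.
    """
    if isinstance(variants, GenotypeDataset):
        variants = variants.variants
    labels = np.empty(len(variants), dtype=object)
    for i, v in enumerate(variants):
        if v.chrom in _AUTOSOMES:
            labels[i] = REGION_AUTOSOME
        elif v.chrom == "XY":
            labels[i] = REGION_PAR
        elif v.chrom == "X":
            labels[i] = REGION_PAR if par.contains("X", v.bp) else REGION_X_NONPAR
        elif v.chrom == "Y":
            labels[i] = REGION_PAR if par.contains("Y", v.bp) else REGION_Y_NONPAR
        elif v.chrom == "MT":
            labels[i] = REGION_MITO
        else:
            labels[i] = REGION_OTHER
    return labels


def diploid_mask(region_labels: Iterable[str]) -> np.ndarray:
    """Boolean mask of variants in diploid regions (autosomes + PAR)."""
    return np.isin(np.asarray(list(region_labels), dtype=object), DIPLOID_REGIONS)
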