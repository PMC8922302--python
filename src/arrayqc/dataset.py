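"""In-memory genotype container shared by every QC stage.

Genotypes are stored as an ``int8`` sample x variant matrix of alt-allele
(a2) dosages: 0, 1, 2, or :data:`MISSING` (-1). Variant and sample
annotations travel alongside the matrix and are sliced in lockstep by
:meth:`GenotypeDataset.subset`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ArrayQcError, ParseError

#: Sentinel for a missing (uncalled) genotype.
MISSING = -1

_LEGAL_CODES = frozenset({-1, 0, 1, 2})

_CHROM_ALIASES = {"23": "X", "24": "Y", "25": "XY", "26": "MT", "M": "MT"}

SEX_MALE = "male"
SEX_FEMALE = "female"
SEX_UNKNOWN = "unknown"

_SEX_FROM_CODE = {"1": SEX_MALE, "2": SEX_FEMALE, "0": SEX_UNKNOWN}
_SEX_TO_CODE = {SEX_MALE: "1", SEX_FEMALE: "2", SEX_UNKNOWN: "0"}

RACE_UNKNOWN = "unknown"


def normalize_chrom(chrom: str) -> str:
    """Map numeric PLINK chromosome codes onto the string dialect.

    ``"23"/"24"/"25"/"26"`` become ``"X"/"Y"/"XY"/"MT"``; a leading ``chr``
    prefix is stripped; autosome labels pass through unchanged.
    """
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper() if not c.isdigit() else c
    return _CHROM_ALIASES.get(c, c)


def normalize_sex(value) -> str:
    """Coerce a reported-sex value to the closed {male, female, unknown} set."""
    if value is None:
        return SEX_UNKNOWN
    s = str(value).strip().lower()
    if s in ("male", "m", "1"):
        return SEX_MALE
    if s in ("female", "f", "2"):
        return SEX_FEMALE
    return SEX_UNKNOWN


@dataclass(frozen=True)
class VariantRecord:
    """One array marker: map position and the two allele labels.

    ``a1``/``a2`` follow the .bim convention; genotype dosage counts copies
    of ``a2``.
    """

    chrom: str
    vid: str
    cm: float
    bp: int
    a1: str
    a2: str

    def __post_init__(self):
        if not self.vid:
            raise ArrayQcError("variant id must be non-empty")
        if self.bp < 0:
            raise ArrayQcError(f"variant {self.vid}: bp must be >= 0")


@dataclass(frozen=True)
class SampleRecord:
    """One study subject with its self-reported phenotypic labels."""

    fid: str
    iid: str
    reported_sex: str = SEX_UNKNOWN
    reported_race: str = RACE_UNKNOWN
    is_control: bool | None = None
    dup_group: str | None = None

    def __post_init__(self):
        if not self.iid:
            raise ArrayQcError("sample iid must be non-empty")
        if self.reported_sex not in (SEX_MALE, SEX_FEMALE, SEX_UNKNOWN):
            raise ArrayQcError(f"illegal reported_sex {self.reported_sex!r}")


class GenotypeDataset:
    """Sample x variant dosage matrix plus annotations.

    Parameters
    ----------
    samples, variants
        Ordered annotation lists; ids must be unique within each list.
    G
        ``(n_samples, n_variants)`` integer matrix with entries in
        {0, 1, 2, MISSING}.
    """

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        variants: Sequence[VariantRecord],
        G: np.ndarray,
    ):
        G = np.asarray(G, dtype=np.int8)
        if G.ndim != 2 or G.shape != (len(samples), len(variants)):
            raise ArrayQcError(
                f"genotype matrix shape {G.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        bad = set(np.unique(G)) - _LEGAL_CODES
        if bad:
            raise ArrayQcError(f"illegal genotype codes in matrix: {sorted(bad)}")
        iids = [s.iid for s in samples]
        if len(set(iids)) != len(iids):
            raise ArrayQcError("duplicate sample iids")
        vids = [v.vid for v in variants]
        if len(set(vids)) != len(vids):
            raise ArrayQcError("duplicate variant ids")
        self.samples = list(samples)
        self.variants = list(variants)
        self.G = G

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return [s.iid for s in self.samples]

    @property
    def variant_ids(self) -> list[str]:
        return [v.vid for v in self.variants]

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fid": [s.fid for s in self.samples],
                "iid": [s.iid for s in self.samples],
                "reported_sex": [s.reported_sex for s in self.samples],
                "reported_race": [s.reported_race for s in self.samples],
                "is_control": [s.is_control for s in self.samples],
                "dup_group": [s.dup_group for s in self.samples],
            }
        )

    def variants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "vid": [v.vid for v in self.variants],
                "cm": [v.cm for v in self.variants],
                "bp": [v.bp for v in self.variants],
                "a1": [v.a1 for v in self.variants],
                "a2": [v.a2 for v in self.variants],
            }
        )

    # -- slicing -------------------------------------------------------------

    def _resolve(self, sel, ids: list[str], what: str) -> np.ndarray:
        if sel is None:
            return np.arange(len(ids))
        sel = np.asarray(sel)
        if sel.dtype == bool:
            if sel.shape != (len(ids),):
                raise ArrayQcError(f"{what} mask has wrong length {sel.shape}")
            return np.flatnonzero(sel)
        index = {x: i for i, x in enumerate(ids)}
        out = []
        for x in sel:
            key = str(x)
            if key not in index:
                raise KeyError(f"unknown {what} id: {key!r}")
            out.append(index[key])
        return np.asarray(out, dtype=int)

    def subset(self, sample_sel=None, variant_sel=None) -> "GenotypeDataset":
        """Slice samples and/or variants by id list or boolean mask.

        ``None`` keeps everything; order of retained rows/columns follows the
        selection (dataset order for masks).
        """
        si = self._resolve(sample_sel, self.sample_ids, "sample")
        vi = self._resolve(variant_sel, self.variant_ids, "variant")
        return GenotypeDataset(
            [self.samples[i] for i in si],
            [self.variants[j] for j in vi],
            self.G[np.ix_(si, vi)],
        )

    def with_samples(self, samples: Iterable[SampleRecord]) -> "GenotypeDataset":
        return GenotypeDataset(list(samples), self.variants, self.G)

    # -- metadata sidecar ----------------------------------------------------

    def with_metadata(self, meta: pd.DataFrame) -> "GenotypeDataset":
        """Overlay a metadata table (columns iid, sex, race, status, dup_group).

        Samples absent from the table keep their current annotations; unknown
        iids in the table are ignored.
        """
        meta = meta.set_index(meta["iid"].astype(str))
        new = []
        for s in self.samples:
            if s.iid in meta.index:
                row = meta.loc[s.iid]
                s = replace(
                    s,
                    reported_sex=normalize_sex(row.get("sex")),
                    reported_race=_norm_race(row.get("race")),
                    is_control=_norm_status(row.get("status")),
                    dup_group=_norm_dup(row.get("dup_group")),
                )
            new.append(s)
        return self.with_samples(new)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.variants == other.variants
            and np.array_equal(self.G, other.G)
        )

    def __repr__(self) -> str:
        return f"GenotypeDataset(n_samples={self.n_samples}, n_variants={self.n_variants})"


def _norm_race(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return RACE_UNKNOWN
    s = str(value).strip()
    return s if s and s.upper() not in ("NA", ".", "-9") else RACE_UNKNOWN


def _norm_status(value) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().lower()
    if s in ("control", "1"):
        return True
    if s in ("case", "2"):
        return False
    return None


def _norm_dup(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s if s and s.upper() not in ("NA", ".", "-9") else None


def read_metadata(path) -> pd.DataFrame:
    """Read the tab-delimited sample-metadata sidecar.

    Expected header: ``iid  sex  race  status  dup_group`` (extra columns are
    carried through untouched; missing optional columns are tolerated).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "iid" not in df.columns:
        raise ParseError(f"{path}: metadata file must have an 'iid' column")
    for col in ("sex", "race", "status", "dup_group"):
        if col not in df.columns:
            df[col] = None
    return df


def write_metadata(ds: GenotypeDataset, path) -> None:
    """Write the sample annotations as a metadata sidecar."""
    df = ds.samples_frame()
    out = pd.DataFrame(
        {
            "iid": df["iid"],
            "sex": df["reported_sex"],
            "race": df["reported_race"],
            "status": [
                "control" if v is True else ("case" if v is False else "NA")
                for v in df["is_control"]
            ],
            "dup_group": [v if v is not None else "NA" for v in df["dup_group"]],
        }
    )
    out.to_csv(path, sep="\t", index=False)
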