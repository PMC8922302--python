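"""Readers and writers for the PLINK genotype filesets.

The binary dialect (.bed/.bim/.fam) packs four genotypes per byte, two bits
each, variant-major: byte value ``0b00`` is two copies of a1 (a2 dosage 0),
``0b01`` a missing call, ``0b10`` a heterozygote, ``0b11`` two copies of a2.
The text dialect (.ped/.map) spells genotypes as whitespace-delimited allele
pairs with ``0`` as the missing-allele code.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (
    MISSING,
    GenotypeDataset,
    SampleRecord,
    VariantRecord,
    normalize_chrom,
    normalize_sex,
    _SEX_TO_CODE,
)
from .exceptions import CorruptFilesetError, ParseError, UnsupportedFormatError

_MAGIC = b"\x6c\x1b"
_VARIANT_MAJOR = 0x01
_SAMPLE_MAJOR = 0x00

# 2-bit code -> dosage; index by code value
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
# dosage+1 -> 2-bit code (index 0 is MISSING=-1)
_DOSAGE_TO_CODE = np.array([1, 0, 2, 3], dtype=np.uint8)

# byte -> 4 dosages (sample order within the byte runs from the low bit pair up)
_BYTE_DECODE = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _BYTE_DECODE[_b, _k] = _CODE_TO_DOSAGE[(_b >> (2 * _k)) & 0b11]


def _fam_to_samples(fam: pd.DataFrame) -> list[SampleRecord]:
    samples = []
    for _, row in fam.iterrows():
        pheno = str(row["pheno"]).strip()
        if pheno == "1":
            is_control = True
        elif pheno == "2":
            is_control = False
        else:  # -9, 0 and anything else mean missing
            is_control = None
        samples.append(
            SampleRecord(
                fid=str(row["fid"]),
                iid=str(row["iid"]),
                reported_sex=normalize_sex(row["sex"]),
                is_control=is_control,
            )
        )
    return samples


def _read_bim(path) -> list[VariantRecord]:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "vid", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "vid": str, "a1": str, "a2": str},
    )
    return [
        VariantRecord(
            chrom=normalize_chrom(r.chrom),
            vid=r.vid,
            cm=float(r.cm),
            bp=int(r.bp),
            a1=r.a1,
            a2=r.a2,
        )
        for r in bim.itertuples()
    ]


def _read_fam(path) -> list[SampleRecord]:
    fam = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    return _fam_to_samples(fam)


def read_bed(prefix) -> GenotypeDataset:
    """Read a binary PLINK fileset ``prefix{.bed,.bim,.fam}``.

    Raises
    ------
    UnsupportedFormatError
        Bad magic bytes, or a sample-major .bed (rejected, never transposed).
    CorruptFilesetError
        Payload size inconsistent with the .bim/.fam line counts.
    """
    prefix = os.fspath(prefix)
    variants = _read_bim(prefix + ".bim")
    samples = _read_fam(prefix + ".fam")
    n, m = len(samples), len(variants)

    raw = Path(prefix + ".bed").read_bytes()
    if len(raw) < 3 or raw[:2] != _MAGIC:
        offender = raw[:2].hex() if len(raw) >= 2 else raw.hex()
        raise UnsupportedFormatError(
            f"{prefix}.bed: bad magic bytes 0x{offender} (expected 0x6c1b)"
        )
    if raw[2] == _SAMPLE_MAJOR:
        raise UnsupportedFormatError(
            f"{prefix}.bed: sample-major layout is not supported; "
            "re-export the fileset variant-major"
        )
    if raw[2] != _VARIANT_MAJOR:
        raise UnsupportedFormatError(
            f"{prefix}.bed: unknown layout byte 0x{raw[2]:02x}"
        )

    bytes_per_variant = (n + 3) // 4
    expected = 3 + m * bytes_per_variant
    if len(raw) != expected:
        raise CorruptFilesetError(
            f"{prefix}.bed: payload is {len(raw) - 3} bytes but "
            f"{m} variants x {len(samples)} samples require {expected - 3}"
        )

    if m == 0 or n == 0:
        return GenotypeDataset(samples, variants, np.empty((n, m), dtype=np.int8))

    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_variant)
    decoded = _BYTE_DECODE[payload].reshape(m, 4 * bytes_per_variant)[:, :n]
    return GenotypeDataset(samples, variants, np.ascontiguousarray(decoded.T))


def write_bed(ds: GenotypeDataset, prefix) -> None:
    """Write ``ds`` as a variant-major binary fileset; pad bits are zero.

    ``read_bed(write_bed(ds, p), p)`` round-trips exactly (annotation string
    fields permitting).
    """
    prefix = os.fspath(prefix)
    n, m = ds.n_samples, ds.n_variants
    bytes_per_variant = (n + 3) // 4

    codes = np.zeros((m, 4 * bytes_per_variant), dtype=np.uint8)
    codes[:, :n] = _DOSAGE_TO_CODE[ds.G.T.astype(np.int16) + 1]
    codes = codes.reshape(m, bytes_per_variant, 4)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)

    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC + bytes([_VARIANT_MAJOR]))
        fh.write(packed.tobytes())

    with open(prefix + ".bim", "w") as fh:
        for v in ds.variants:
            cm = int(v.cm) if float(v.cm).is_integer() else v.cm
            fh.write(f"{v.chrom}\t{v.vid}\t{cm}\t{v.bp}\t{v.a1}\t{v.a2}\n")

    with open(prefix + ".fam", "w") as fh:
        for s in ds.samples:
            if s.is_control is True:
                pheno = "1"
            elif s.is_control is False:
                pheno = "2"
            else:
                pheno = "-9"
            fh.write(f"{s.fid}\t{s.iid}\t0\t0\t{_SEX_TO_CODE[s.reported_sex]}\t{pheno}\n")


def read_ped_map(prefix) -> GenotypeDataset:
    """Read a text PLINK fileset ``prefix{.ped,.map}``.

    The text dialect carries no allele-order metadata, so alleles are
    assigned provisionally in order of first appearance and reconciled at the
    end so that a1 is the minor and a2 the major allele (ties keep first
    appearance as a1). A pair containing a ``0`` allele is a missing call.
    """
    prefix = os.fspath(prefix)
    map_df = pd.read_csv(prefix + ".map", sep=r"\s+", header=None, dtype=str)
    if map_df.shape[1] == 3:  # cm column omitted
        map_df.columns = ["chrom", "vid", "bp"]
        map_df["cm"] = 0.0
    elif map_df.shape[1] == 4:
        map_df.columns = ["chrom", "vid", "cm", "bp"]
    else:
        raise ParseError(f"{prefix}.map: expected 3 or 4 columns, got {map_df.shape[1]}")
    m = len(map_df)

    samples: list[SampleRecord] = []
    allele_rows: list[list[str]] = []
    with open(prefix + ".ped") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 6 + 2 * m:
                raise ParseError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * m} fields "
                    f"(6 + 2x{m} alleles), got {len(tokens)}"
                )
            fid, iid, _father, _mother, sex, pheno = tokens[:6]
            if pheno == "1":
                is_control = True
            elif pheno == "2":
                is_control = False
            else:
                is_control = None
            samples.append(
                SampleRecord(
                    fid=fid, iid=iid, reported_sex=normalize_sex(sex), is_control=is_control
                )
            )
            allele_rows.append(tokens[6:])

    n = len(samples)
    alleles = np.array(allele_rows, dtype=object).reshape(n, m, 2) if n else np.empty(
        (0, m, 2), dtype=object
    )

    G = np.full((n, m), MISSING, dtype=np.int8)
    variants: list[VariantRecord] = []
    for j, row in enumerate(map_df.itertuples()):
        pair = alleles[:, j, :] if n else np.empty((0, 2), dtype=object)
        called = ~np.any(pair == "0", axis=1)
        seen: list[str] = []
        for a in pair[called].ravel():
            if a not in seen:
                seen.append(a)
            if len(seen) > 2:
                raise ParseError(
                    f"{prefix}.ped: variant {row.vid} is tri-allelic "
                    f"(alleles {sorted(set(pair[called].ravel()))})"
                )
        # provisional a1 = first seen; reconcile to minor/major by count
        if len(seen) == 0:
            a1, a2 = "0", "0"
        elif len(seen) == 1:
            a1, a2 = "0", seen[0]
        else:
            counts = {a: int(np.sum(pair[called] == a)) for a in seen}
            a1, a2 = seen
            if counts[a1] > counts[a2]:
                a1, a2 = a2, a1
        if n:
            G[called, j] = np.sum(pair[called] == a2, axis=1)
        variants.append(
            VariantRecord(
                chrom=normalize_chrom(row.chrom),
                vid=row.vid,
                cm=float(row.cm),
                bp=int(row.bp),
                a1=a1,
                a2=a2,
            )
        )

    return GenotypeDataset(samples, variants, G)
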