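"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from arrayqc.dataset import MISSING, GenotypeDataset, SampleRecord, VariantRecord


def pack_bed_bytes(G: np.ndarray) -> bytes:
    """Independent, deliberately naive PLINK .bed packer (oracle).

    Packs a sample x variant dosage matrix variant-major, two bits per
    genotype, zero pad bits, using the published code table directly.
    """
    code = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}
    n, m = G.shape
    out = bytearray(b"\x6c\x1b\x01")
    for j in range(m):
        for start in range(0, n, 4):
            byte = 0
            for k, i in enumerate(range(start, min(start + 4, n))):
                byte |= code[int(G[i, j])] << (2 * k)
            out.append(byte)
    return bytes(out)


def make_dataset(G, chroms=None, bps=None, sexes=None, races=None, dup_groups=None):
    """Build a GenotypeDataset around a literal genotype matrix."""
    G = np.asarray(G, dtype=np.int8)
    n, m = G.shape
    samples = [
        SampleRecord(
            fid=f"F{i}",
            iid=f"S{i}",
            reported_sex=(sexes[i] if sexes else "unknown"),
            reported_race=(races[i] if races else "unknown"),
            dup_group=(dup_groups[i] if dup_groups else None),
        )
        for i in range(n)
    ]
    variants = [
        VariantRecord(
            chrom=(chroms[j] if chroms else "1"),
            vid=f"v{j}",
            cm=0.0,
            bp=(bps[j] if bps else 1000 + j),
            a1="A",
            a2="B",
        )
        for j in range(m)
    ]
    return GenotypeDataset(samples, variants, G)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def build_planted_cohort(seed=20240601):
    """Cohort with exactly five kinds of planted defects.

    One low-call-rate sample, one sample with flipped reported sex, five
    variants generated far out of Hardy-Weinberg (f=0.6), one contaminated
    sample (50/50 pooled with an unrelated cohort member), and one duplicate
    pair at 2% per-genotype error. Returns (dataset, expected) where
    ``expected`` is the set of (item_type, id, stage) rows a correct QC run
    must flag -- each defect once, nothing else.
    """
    from arrayqc.simulate import SimSpec, simulate_cohort

    n, m = 300, 3000
    maf = np.random.default_rng(seed).uniform(0.15, 0.45, m)
    maf[:5] = 0.3
    f = np.zeros(m)
    f[:5] = 0.6

    # probe run: sex assignment depends only on the seed, so we can pick a
    # genetically female sample to duplicate (a male duplicate's X errors
    # would shift its inbreeding estimate, which is not the planted defect)
    probe = simulate_cohort(SimSpec(n_samples=n, n_variants=1, seed=seed, n_x=1))
    female_idx = [i for i, s in enumerate(probe.samples) if s.reported_sex == "female"]
    male_idx = [i for i, s in enumerate(probe.samples) if s.reported_sex == "male"]
    dup_i = female_idx[3]
    mislabel_i = male_idx[0]
    contam_i, donor_i = female_idx[5], female_idx[6]

    sample_missing = np.zeros(n)
    low_cr_i = female_idx[7]
    sample_missing[low_cr_i] = 0.15

    spec = SimSpec(
        n_samples=n,
        n_variants=m,
        seed=seed,
        maf=maf,
        inbreeding_f=f,
        n_x=1000,
        n_y=50,
        n_par=30,
        sample_missing=sample_missing,
        duplicates=[(dup_i, 0.02)],
        contamination=[(contam_i, donor_i, 0.5)],
        sex_mislabels=[mislabel_i],
    )
    ds = simulate_cohort(spec)
    iid = lambda i: ds.samples[i].iid
    expected = {
        ("sample", iid(low_cr_i), "call_rate"),
        ("sample", iid(mislabel_i), "sex_check"),
        ("sample", iid(contam_i), "het_ratio"),
        ("pair", f"{iid(dup_i)}|{iid(dup_i)}_dup", "concordance"),
    } | {("variant", f"var{j + 1}", "hwe") for j in range(5)}
    return ds, expected


@pytest.fixture(scope="session")
def planted_report(tmp_path_factory):
    """Planted-defect cohort run through the full pipeline once per session."""
    from arrayqc.dataset import read_metadata, write_metadata
    from arrayqc.pipeline import QcConfig, run_pipeline
    from arrayqc.plink import write_bed

    ds, expected = build_planted_cohort()
    d = tmp_path_factory.mktemp("planted")
    prefix = str(d / "cohort")
    write_bed(ds, prefix)
    write_metadata(ds, prefix + ".meta.tsv")
    cfg = QcConfig(bfile=prefix, meta=prefix + ".meta.tsv", out_dir=str(d / "out"), seed=1)
    report = run_pipeline(cfg)
    return report, expected, d


@pytest.fixture
def small_dataset(rng):
    """5 samples x 7 variants with a couple of missing calls."""
    G = rng.integers(0, 3, size=(5, 7)).astype(np.int8)
    G[0, 1] = MISSING
    G[3, 4] = MISSING
    return make_dataset(G)
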