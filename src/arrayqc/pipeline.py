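"""Pipeline orchestration: run every QC stage in dependency order, collect
tab-delimited tables, assemble the flagged-item summary, render the report.

QC findings never fail the run — a QC tool's job is to finish on bad data
and report it. Only operational errors (unreadable input, invalid config)
raise; a stage that errors at runtime is logged and marked failed while the
remaining independent stages still run.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import concordance as conc_mod
from . import hetratio as het_mod
from . import hwe as hwe_mod
from . import pca as pca_mod
from . import sexcheck as sex_mod
from .dataset import GenotypeDataset, read_metadata
from .exceptions import ArrayQcError, ParameterError
from .plink import read_bed, read_ped_map
from .regions import classify_par, par_table

log = logging.getLogger("arrayqc")

STAGE_ORDER = (
    "call_rate",
    "maf",
    "sex_check",
    "hwe",
    "het_ratio",
    "pca",
    "concordance",
)

STATUS_OK = "ok"
STATUS_NOT_ASSESSED = "not_assessed"
STATUS_DISABLED = "disabled"
STATUS_FAILED = "failed"


@dataclass
class QcConfig:
    """Everything the pipeline needs; validated before any stage runs."""

    bfile: str | None = None
    ped: str | None = None
    meta: str | None = None
    ref_maf: str | None = None
    build: str = "grch37"
    include_par3: bool = True
    out_dir: str = "qc_out"
    seed: int = 0
    stages: dict = field(default_factory=dict)  # stage name -> bool
    # stage parameters
    ladder: tuple = cohort_mod.DEFAULT_LADDER
    sample_cr_min: float = 0.98
    variant_cr_min: float = 0.95
    sex_thresholds: sex_mod.SexThresholds = field(default_factory=sex_mod.SexThresholds)
    hwe_alpha: float = 0.05
    hwe_controls_only: bool = False
    hwe_midp: bool = False
    het_hi_mult: float = 1.5
    het_lo_mult: float = 0.5
    het_min_stratum: int = 3
    het_ref_is_a1: bool = True
    pca_k: int = 10
    pca_maf_min: float = 0.05
    pca_callrate_min: float = 0.95
    pca_ld: tuple = (50, 5, 0.2)
    pca_z_max: float = 3.0
    aim_list: str | None = None
    concordance_threshold: float = 0.99

    def validate(self) -> None:
        if self.bfile is None and self.ped is None:
            raise ParameterError("one of bfile/ped input prefixes is required")
        if not 0 < self.hwe_alpha < 1:
            raise ParameterError("hwe_alpha must lie in (0, 1)")
        if self.het_lo_mult >= self.het_hi_mult:
            raise ParameterError("het_lo_mult must be below het_hi_mult")
        if any(b < a for a, b in zip(self.ladder, list(self.ladder)[1:])):
            raise ParameterError("call-rate ladder must be ascending")
        if self.build.lower() not in ("grch37", "grch38"):
            raise ParameterError(f"unknown build {self.build!r}")
        if not 0 < self.concordance_threshold <= 1:
            raise ParameterError("concordance threshold must lie in (0, 1]")

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


@dataclass
class StageResult:
    name: str
    status: str
    tables: dict = field(default_factory=dict)  # label -> DataFrame
    message: str = ""


@dataclass
class QcReport:
    """Aggregation of all stage outputs; feeds the HTML renderer."""

    config: QcConfig
    n_samples: int
    n_variants: int
    stages: dict = field(default_factory=dict)  # name -> StageResult
    flags: pd.DataFrame = None

    def stage(self, name: str) -> StageResult:
        return self.stages[name]


def _run_stage(report: QcReport, name: str, fn) -> None:
    t0 = time.time()
    try:
        result = fn()
    except ArrayQcError as exc:
        log.warning("stage %s failed: %s", name, exc)
        result = StageResult(name, STATUS_FAILED, message=str(exc))
    report.stages[name] = result
    dims = {k: tuple(v.shape) for k, v in result.tables.items()}
    log.info("stage %-12s %-12s %.2fs %s", name, result.status, time.time() - t0, dims)


def load_input(config: QcConfig) -> GenotypeDataset:
    """Read the fileset (+ optional metadata sidecar) per config."""
    ds = read_bed(config.bfile) if config.bfile else read_ped_map(config.ped)
    if config.meta:
        ds = ds.with_metadata(read_metadata(config.meta))
    return ds


def run_pipeline(config: QcConfig, ds: GenotypeDataset | None = None) -> QcReport:
    """Execute the configured stages and write tables + HTML under out_dir.

    Returns the in-memory :class:`QcReport`; per-stage tab-delimited tables
    land in ``out_dir/tables`` and the single-file HTML report at
    ``out_dir/qc_report.html``.
    """
    config.validate()
    if ds is None:
        ds = load_input(config)
    log.info("input: %d samples x %d variants", ds.n_samples, ds.n_variants)

    par = par_table(config.build, include_par3=config.include_par3)
    regions = classify_par(ds, par)
    report = QcReport(config=config, n_samples=ds.n_samples, n_variants=ds.n_variants)

    races = np.array([s.reported_race for s in ds.samples], dtype=object)
    have_race = bool((races != "unknown").any())
    have_sex = any(s.reported_sex != "unknown" for s in ds.samples)

    # --- call rates ---------------------------------------------------------
    def call_rate_stage():
        sr = cohort_mod.sample_call_rate(ds)
        vr = cohort_mod.variant_call_rate(ds)
        # sex-chromosome QC runs within a homogeneous sex subpopulation:
        # Y variants are uncalled in females by biology, so their call rate
        # is assessed over reported males only
        from .dataset import SEX_MALE
        from .regions import REGION_Y_NONPAR

        ymask = np.asarray(regions, dtype=object) == REGION_Y_NONPAR
        males = np.array([s.reported_sex == SEX_MALE for s in ds.samples])
        if ymask.any() and males.any():
            from .dataset import MISSING

            vr = vr.copy()
            vr[ymask] = (ds.G[np.ix_(males, ymask)] != MISSING).mean(axis=0)
        sample_tbl = pd.DataFrame({"iid": ds.sample_ids, "call_rate": sr})
        sample_tbl["flag"] = np.where(sr < config.sample_cr_min, "low", "ok")
        variant_tbl = pd.DataFrame({"vid": ds.variant_ids, "call_rate": vr})
        variant_tbl["flag"] = np.where(vr < config.variant_cr_min, "low", "ok")
        return StageResult(
            "call_rate",
            STATUS_OK,
            tables={
                "sample_call_rate": sample_tbl,
                "variant_call_rate": variant_tbl,
                "sample_summary": cohort_mod.call_rate_summary(sr, config.ladder),
                "variant_summary": cohort_mod.call_rate_summary(vr, config.ladder),
            },
        )

    # --- MAF ----------------------------------------------------------------
    def maf_stage():
        from .regions import diploid_mask

        maf = cohort_mod.allele_frequency(ds, variant_mask=diploid_mask(regions))
        tables = {"maf": maf}
        msg = ""
        if config.ref_maf:
            ref = cohort_mod.read_reference_maf(config.ref_maf)
            n_shared, r, paired = cohort_mod.maf_concordance(maf, ref)
            tables["maf_concordance"] = paired
            tables["maf_concordance_summary"] = pd.DataFrame(
                {"n_shared": [n_shared], "pearson_r": [r]}
            )
        else:
            msg = "no reference MAF table supplied; concordance not assessed"
        return StageResult("maf", STATUS_OK, tables=tables, message=msg)

    # --- sex check ----------------------------------------------------------
    def sex_stage():
        tbl = sex_mod.sex_check(ds, regions, thresholds=config.sex_thresholds)
        msg = "" if have_sex else "reported sex unavailable; genetic inference only"
        return StageResult("sex_check", STATUS_OK, tables={"sex_check": tbl}, message=msg)

    # --- HWE ----------------------------------------------------------------
    def hwe_stage():
        strata = None
        if not have_race:
            strata = {"all": np.ones(ds.n_samples, dtype=bool)}
        tbl = hwe_mod.hwe_scan(
            ds,
            region_labels=regions,
            strata=strata,
            controls_only=config.hwe_controls_only,
            alpha=config.hwe_alpha,
            midp=config.hwe_midp,
        )
        return StageResult("hwe", STATUS_OK, tables={"hwe": tbl})

    # --- heterozygosity ratio -----------------------------------------------
    def het_stage():
        tbl = het_mod.het_ratio(ds, regions, ref_is_a1=config.het_ref_is_a1)
        tbl = het_mod.flag_het_ratio(
            tbl, races, hi_mult=config.het_hi_mult, lo_mult=config.het_lo_mult
        )
        tbl.insert(1, "reported_race", races)
        summary = het_mod.stratified_summary(tbl, races, min_size=config.het_min_stratum)
        return StageResult(
            "het_ratio", STATUS_OK, tables={"het_ratio": tbl, "het_ratio_by_race": summary}
        )

    # --- ancestry PCA ---------------------------------------------------------
    def pca_stage():
        aim = None
        if config.aim_list:
            aim = [line.strip() for line in open(config.aim_list) if line.strip()]
        w, s, r2 = config.pca_ld
        res = pca_mod.run_pca(
            ds,
            regions,
            k=config.pca_k,
            maf_min=config.pca_maf_min,
            callrate_min=config.pca_callrate_min,
            ld_window=w,
            ld_step=s,
            ld_r2=r2,
            aim_list=aim,
            z_max=config.pca_z_max,
        )
        ev = pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(res.explained_variance))],
                "explained_variance_fraction": res.explained_variance,
            }
        )
        return StageResult(
            "pca",
            STATUS_OK,
            tables={"pca_scores": res.table, "pca_explained_variance": ev},
            message=f"{len(res.variant_ids)} variants used",
        )

    # --- concordance ----------------------------------------------------------
    def concordance_stage():
        sample_tbl = conc_mod.sample_pair_concordance(
            ds, region_labels=regions, threshold=config.concordance_threshold
        )
        variant_tbl = conc_mod.variant_pair_concordance(
            ds, threshold=config.concordance_threshold
        )
        if sample_tbl.empty and variant_tbl.empty:
            return StageResult(
                "concordance",
                STATUS_NOT_ASSESSED,
                message="no duplicated samples or variants designated",
            )
        return StageResult(
            "concordance",
            STATUS_OK,
            tables={"sample_concordance": sample_tbl, "variant_concordance": variant_tbl},
        )

    stage_fns = {
        "call_rate": call_rate_stage,
        "maf": maf_stage,
        "sex_check": sex_stage,
        "hwe": hwe_stage,
        "het_ratio": het_stage,
        "pca": pca_stage,
        "concordance": concordance_stage,
    }
    for name in STAGE_ORDER:
        if config.enabled(name):
            _run_stage(report, name, stage_fns[name])
        else:
            report.stages[name] = StageResult(name, STATUS_DISABLED)

    report.flags = flag_summary(report)

    out = Path(config.out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    write_tables(report, out / "tables")
    from .report import render_html

    render_html(report, out / "qc_report.html")
    return report


def flag_summary(report: QcReport) -> pd.DataFrame:
    """Union of every stage's flags: one row per flagged item per stage.

    Columns: item_type (sample/variant/pair), id, stage, reason. A variant
    flagged in several HWE strata appears once, with the strata listed in
    the reason.
    """
    rows: list[tuple[str, str, str, str]] = []

    def stage_tbl(name, label):
        st = report.stages.get(name)
        if st is None or st.status != STATUS_OK:
            return None
        return st.tables.get(label)

    tbl = stage_tbl("call_rate", "sample_call_rate")
    if tbl is not None:
        for r in tbl[tbl["flag"] == "low"].itertuples():
            rows.append(("sample", r.iid, "call_rate", f"sample call rate {r.call_rate:.4f} below threshold"))
    tbl = stage_tbl("call_rate", "variant_call_rate")
    if tbl is not None:
        for r in tbl[tbl["flag"] == "low"].itertuples():
            rows.append(("variant", r.vid, "call_rate", f"variant call rate {r.call_rate:.4f} below threshold"))

    tbl = stage_tbl("sex_check", "sex_check")
    if tbl is not None:
        bad = tbl[tbl["mismatch_flag"].isin([sex_mod.FLAG_MISMATCH, sex_mod.FLAG_OUT_OF_RANGE])]
        for r in bad.itertuples():
            reason = (
                f"reported {r.reported_sex}, inferred {r.inferred_sex} (F={r.f_x:.3f})"
                if r.mismatch_flag == sex_mod.FLAG_MISMATCH
                else f"X inbreeding F={r.f_x:.3f} outside expected ranges"
            )
            rows.append(("sample", r.iid, "sex_check", reason))

    tbl = stage_tbl("hwe", "hwe")
    if tbl is not None:
        viol = tbl[tbl["violation"]]
        for vid, grp in viol.groupby("vid", sort=False):
            strata = ",".join(grp["stratum"])
            pmin = grp["p_adj"].min()
            rows.append(("variant", vid, "hwe", f"HWE violated (p_adj={pmin:.2e}; strata {strata})"))

    tbl = stage_tbl("het_ratio", "het_ratio")
    if tbl is not None:
        for r in tbl[tbl["flag"].isin([het_mod.FLAG_HIGH, het_mod.FLAG_LOW])].itertuples():
            rows.append(
                ("sample", r.iid, "het_ratio", f"heterozygosity ratio {r.ratio:.3f} {r.flag} vs stratum median {r.stratum_median:.3f}")
            )

    tbl = stage_tbl("pca", "pca_scores")
    if tbl is not None:
        for r in tbl[tbl["flag"].isin([pca_mod.FLAG_MISMATCH, pca_mod.FLAG_OUTLIER])].itertuples():
            rows.append(
                ("sample", r.iid, "pca", f"reported {r.reported_race}, nearest cluster {r.nearest_race} ({r.flag})")
            )

    tbl = stage_tbl("concordance", "sample_concordance")
    if tbl is not None:
        for r in tbl[tbl["flag"] == conc_mod.FLAG_LOW].itertuples():
            rows.append(("pair", f"{r.id_a}|{r.id_b}", "concordance", f"duplicate-sample concordance {r.rate:.4f} below threshold"))
    tbl = stage_tbl("concordance", "variant_concordance")
    if tbl is not None:
        for r in tbl[tbl["flag"] == conc_mod.FLAG_LOW].itertuples():
            rows.append(("pair", f"{r.vid_a}|{r.vid_b}", "concordance", f"duplicate-variant concordance {r.rate:.4f} below threshold"))

    df = pd.DataFrame(rows, columns=["item_type", "id", "stage", "reason"])
    return df.drop_duplicates(subset=["item_type", "id", "stage"], ignore_index=True)


def write_tables(report: QcReport, out_dir: Path) -> dict[str, str]:
    """Write every stage table (and the flag summary) as TSV; returns the
    exact serialized text per table so the HTML can embed it bit-for-bit."""
    out_dir = Path(out_dir)
    serialized: dict[str, str] = {}
    for st in report.stages.values():
        for label, tbl in st.tables.items():
            text = tbl.to_csv(sep="\t", index=False)
            (out_dir / f"{label}.tsv").write_text(text)
            serialized[label] = text
    if report.flags is not None:
        text = report.flags.to_csv(sep="\t", index=False)
        (out_dir / "flag_summary.tsv").write_text(text)
        serialized["flag_summary"] = text
    return serialized
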