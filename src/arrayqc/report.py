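"""Single-file HTML report renderer.

Every figure is embedded as a base64 PNG and every table both shown as HTML
and embedded verbatim as the tab-delimited text written to disk, so the
report is one portable file whose numbers equal the TSV outputs
bit-for-bit. Section inventory mirrors the stage list: call-rate summary,
MAF histogram, MAF-vs-reference scatter, X-inbreeding histogram with the
male/female decision ranges shaded, PC1-vs-PC2 scatter coloured by reported
race, adjusted-HWE-p histogram with the significance line, heterozygosity
ratio by race, concordance tables, and the flagged-item summary.
"""

from __future__ import annotations

import base64
import html
import io
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pipeline import STATUS_OK, QcReport

_CSS = """
body { font-family: sans-serif; margin: 2em auto; max-width: 70em; color: #222; }
h1 { border-bottom: 2px solid #444; }
h2 { border-bottom: 1px solid #bbb; margin-top: 2em; }
table { border-collapse: collapse; margin: 0.5em 0; }
th, td { border: 1px solid #ccc; padding: 0.25em 0.6em; font-size: 0.9em; }
th { background: #f0f0f0; }
.na { color: #888; font-style: italic; }
details { margin: 0.4em 0; }
pre { background: #f8f8f8; padding: 0.5em; overflow-x: auto; font-size: 0.8em; }
img { max-width: 100%; }
"""


def _fig_to_b64(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, metadata={"Software": "arrayqc"})
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _img(fig) -> str:
    return f'<img src="data:image/png;base64,{_fig_to_b64(fig)}" alt="figure"/>'


def _table_block(label: str, tbl: pd.DataFrame, tsv: str, max_rows: int = 25) -> str:
    shown = tbl.head(max_rows)
    note = (
        f"<p class='na'>showing first {max_rows} of {len(tbl)} rows; full table embedded below</p>"
        if len(tbl) > max_rows
        else ""
    )
    return (
        f"{shown.to_html(index=False)}\n{note}"
        f"<details><summary>machine-readable table: {html.escape(label)}.tsv</summary>"
        f"<pre>{html.escape(tsv)}</pre></details>"
    )


def _not_assessed(msg: str = "not assessed") -> str:
    return f"<p class='na'>{html.escape(msg)}</p>"


def render_html(report: QcReport, path) -> None:
    """Render the report to a single self-contained HTML file."""
    # same serialization as write_tables, so HTML and TSV agree bit-for-bit
    tsv = {}
    for st in report.stages.values():
        for label, tbl in st.tables.items():
            tsv[label] = tbl.to_csv(sep="\t", index=False)
    if report.flags is not None:
        tsv["flag_summary"] = report.flags.to_csv(sep="\t", index=False)

    cfg = report.config
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>Genotyping-array QC report</title>",
        f"<style>{_CSS}</style></head><body>",
        "<h1>Genotyping-array QC report</h1>",
        f"<p>Input: {report.n_samples} samples &times; {report.n_variants} variants; "
        f"build {html.escape(cfg.build)}; seed {cfg.seed}.</p>",
    ]

    def stage(name):
        return report.stages.get(name)

    # A. call rates
    parts.append("<h2>Sample and variant call rates</h2>")
    st = stage("call_rate")
    if st and st.status == STATUS_OK:
        parts.append("<h3>Sample call rate at varied thresholds</h3>")
        parts.append(_table_block("sample_summary", st.tables["sample_summary"], tsv["sample_summary"]))
        parts.append("<h3>Variant call rate at varied thresholds</h3>")
        parts.append(_table_block("variant_summary", st.tables["variant_summary"], tsv["variant_summary"]))
        for label in ("sample_call_rate", "variant_call_rate"):
            parts.append(
                f"<details><summary>machine-readable table: {label}.tsv</summary>"
                f"<pre>{html.escape(tsv[label])}</pre></details>"
            )
    else:
        parts.append(_not_assessed(st.message if st else "disabled"))

    # B/C. MAF
    parts.append("<h2>Minor allele frequency</h2>")
    st = stage("maf")
    if st and st.status == STATUS_OK:
        maf = st.tables["maf"]
        vals = maf.loc[maf["defined"], "maf"].to_numpy()
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.hist(vals, bins=50, color="#4878a8")
        ax.set_xlabel("MAF")
        ax.set_ylabel("variants")
        ax.set_title("MAF distribution (diploid regions)")
        parts.append(_img(fig))
        parts.append(_table_block("maf", maf, tsv["maf"]))
        if "maf_concordance" in st.tables:
            paired = st.tables["maf_concordance"]
            summ = st.tables["maf_concordance_summary"]
            n_shared = int(summ["n_shared"].iloc[0])
            r = float(summ["pearson_r"].iloc[0])
            fig, ax = plt.subplots(figsize=(4.5, 4.5))
            ax.scatter(paired["maf_ref"], paired["maf_local"], s=6, alpha=0.5)
            ax.plot([0, 0.5], [0, 0.5], "k--", lw=0.8)
            ax.set_xlabel("reference MAF")
            ax.set_ylabel("cohort MAF")
            ax.set_title(f"MAF concordance: n={n_shared}, Pearson r={r:.3f}")
            parts.append(_img(fig))
            parts.append(_table_block("maf_concordance", paired, tsv["maf_concordance"]))
        else:
            parts.append(_not_assessed("reference MAF comparison not assessed"))
    else:
        parts.append(_not_assessed(st.message if st else "disabled"))

    # D. sex check
    parts.append("<h2>Sex check (chromosome-X inbreeding)</h2>")
    st = stage("sex_check")
    if st and st.status == STATUS_OK:
        t = report.config.sex_thresholds
        fx = st.tables["sex_check"]["f_x"].to_numpy()
        fx = fx[np.isfinite(fx)]
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.hist(fx, bins=50, color="#4878a8")
        ax.axvspan(t.female_low, t.female_high, color="#88c888", alpha=0.3, label="female range")
        ax.axvspan(t.male_low, 1.0, color="#8888d8", alpha=0.3, label="male range")
        ax.set_xlabel("X inbreeding estimate F")
        ax.set_ylabel("samples")
        ax.legend()
        parts.append(_img(fig))
        if st.message:
            parts.append(_not_assessed(st.message))
        parts.append(_table_block("sex_check", st.tables["sex_check"], tsv["sex_check"]))
    else:
        parts.append(_not_assessed(st.message if st else "disabled"))

    # E. ancestry PCA
    parts.append("<h2>Ancestry PCA</h2>")
    st = stage("pca")
    if st and st.status == STATUS_OK:
        scores = st.tables["pca_scores"]
        fig, ax = plt.subplots(figsize=(5, 4.5))
        for race, grp in scores.groupby("reported_race"):
            ax.scatter(grp["PC1"], grp["PC2"], s=10, alpha=0.7, label=str(race))
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend(fontsize=7)
        ax.set_title("PC1 vs PC2 by reported race")
        parts.append(_img(fig))
        parts.append(_table_block("pca_scores", scores, tsv["pca_scores"]))
        parts.append(
            _table_block(
                "pca_explained_variance",
                st.tables["pca_explained_variance"],
                tsv["pca_explained_variance"],
            )
        )
    else:
        parts.append(_not_assessed(st.message if st else "disabled"))

    # F. HWE
    parts.append("<h2>Hardy-Weinberg equilibrium</h2>")
    st = stage("hwe")
    if st and st.status == STATUS_OK:
        padj = st.tables["hwe"]["p_adj"].to_numpy()
        padj = padj[np.isfinite(padj)]
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.hist(padj, bins=50, color="#4878a8")
        ax.axvline(report.config.hwe_alpha, color="red", ls=":", label=f"alpha={report.config.hwe_alpha}")
        ax.set_xlabel("Bonferroni-adjusted HWE p-value")
        ax.set_ylabel("variant tests")
        ax.legend()
        parts.append(_img(fig))
        parts.append(_table_block("hwe", st.tables["hwe"], tsv["hwe"]))
    else:
        parts.append(_not_assessed(st.message if st else "disabled"))

    # G. heterozygosity ratio
    parts.append("<h2>Heterozygosity ratio</h2>")
    st = stage("het_ratio")
    if st and st.status == STATUS_OK:
        summary = st.tables["het_ratio_by_race"]
        het = st.tables["het_ratio"]
        plot_strata = summary.loc[summary["plotted"], "stratum"].tolist()
        fig, ax = plt.subplots(figsize=(6, 3.5))
        data, labels = [], []
        if "reported_race" in het.columns:
            for s_name in plot_strata:  # under-sized strata are not plotted
                vals = het.loc[het["reported_race"] == s_name, "ratio"].dropna()
                if len(vals):
                    data.append(vals.to_numpy())
                    labels.append(s_name)
        if data:
            ax.violinplot(data, showmedians=True)
            ax.set_xticks(range(1, len(labels) + 1), labels)
        else:
            ax.boxplot([het["ratio"].dropna().to_numpy()], tick_labels=["all samples"])
        ax.set_ylabel("heterozygosity ratio")
        parts.append(_img(fig))
        parts.append(_table_block("het_ratio_by_race", summary, tsv["het_ratio_by_race"]))
        parts.append(_table_block("het_ratio", het, tsv["het_ratio"]))
    else:
        parts.append(_not_assessed(st.message if st else "disabled"))

    # concordance
    parts.append("<h2>Duplicate concordance</h2>")
    st = stage("concordance")
    if st and st.status == STATUS_OK:
        for label in ("sample_concordance", "variant_concordance"):
            tbl = st.tables[label]
            parts.append(f"<h3>{label.replace('_', ' ')}</h3>")
            if tbl.empty:
                parts.append(_not_assessed())
            else:
                parts.append(_table_block(label, tbl, tsv[label]))
    else:
        parts.append(_not_assessed(st.message if st else "disabled"))

    # summary
    parts.append("<h2>Flagged items</h2>")
    if report.flags is None or report.flags.empty:
        parts.append("<p>No samples or variants were flagged.</p>")
    else:
        parts.append(_table_block("flag_summary", report.flags, tsv["flag_summary"], max_rows=100))

    parts.append("</body></html>")
    Path(path).write_text("\n".join(parts))
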