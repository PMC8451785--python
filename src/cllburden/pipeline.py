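"""End-to-end study orchestration.

Runs the full analysis on either a synthetic cohort or user-supplied
clinical + variant tables: variant filtering -> TMB and estimator
status -> marker informativeness table -> panel search -> stratified
Kaplan-Meier / logrank -> contingency tables -> Cox univariate and
stepwise multivariate models. All outputs are plain-text tables plus a
JSON run log and a checksummed manifest; runs are deterministic given
the configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (clinical_to_frame, default_spec, generate_cohort,
                     generate_variant_calls, read_clinical_csv)
from .panel import PanelSelector, per_gene_cindex_table
from .stepwise import StepwiseCoxPH
from .survival import (SurvivalData, association_test, cox_fit, kaplan_meier,
                       logrank_test)
from .tmb import EIGHT_GENE_ESTIMATOR, TMB_THRESHOLD, estimator_status, tmb_profile
from .variants import (FilterConfig, MutationMatrix, decisions_to_frame,
                       read_variant_tsv, run_filter_pipeline)

log = logging.getLogger("cllburden")

#: Named cohort subset rules usable in configuration.
SUBSET_RULES = ("untreated", "binet_a", "binet_ab", "tfs_gt_6mo",
                "good_karyotype")


@dataclass
class AnalysisConfig:
    """Configuration of a full study run."""

    clinical_path: str | None = None
    variants_path: str | None = None           # annotated TSV
    synthetic: bool = True
    seed: int = 0
    min_depth: int = 100
    min_alt_reads: int = 5
    min_vaf: float = 0.02
    maf_cutoff: float = 0.01
    cadd_cutoff: float = 20.0
    review_policy: str = "exclude"
    tmb_threshold: int = TMB_THRESHOLD
    estimator_panel: tuple = tuple(sorted(EIGHT_GENE_ESTIMATOR))
    survival_subsets: tuple = ("untreated", "binet_ab", "tfs_gt_6mo")
    short_long_cut_years: float = 2.0
    panel_max_size: int = 8
    panel_mode: str = "auto"
    n_bootstrap: int = 1000
    out_dir: str = "study_out"

    def validate(self) -> None:
        if self.tmb_threshold < 1:
            raise ValueError("tmb_threshold must be >= 1")
        if self.short_long_cut_years <= 0:
            raise ValueError("short_long_cut_years must be positive")
        for rule in self.survival_subsets:
            if rule not in SUBSET_RULES:
                raise ValueError(f"unknown subset rule {rule!r}")
        if not self.synthetic and (self.clinical_path is None
                                   or self.variants_path is None):
            raise ValueError("non-synthetic runs need clinical_path and variants_path")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def subset_cohort(clinical: pd.DataFrame, rule: str) -> pd.DataFrame:
    """Apply a named subset rule; logs counts before/after.

    ``tfs_gt_6mo`` keeps patients whose TFS exceeds half a year whether
    the time is an event or a censoring time (either way the patient is
    known untreated for at least 6 months).
    """
    n0 = len(clinical)
    if rule == "untreated":
        out = clinical[~clinical["previously_treated"]]
    elif rule == "binet_a":
        out = clinical[clinical["binet_stage"] == "A"]
    elif rule == "binet_ab":
        out = clinical[clinical["binet_stage"].isin(["A", "B"])]
    elif rule == "tfs_gt_6mo":
        out = clinical[clinical["tfs_years"] > 0.5]
    elif rule == "good_karyotype":
        out = clinical[clinical["cytogenetic_class"].isin(
            ["normal", "isolated_del13q"])]
    else:
        raise ValueError(f"unknown subset rule {rule!r}")
    log.info("subset %s: %d -> %d patients", rule, n0, len(out))
    return out.reset_index(drop=True)


def short_long_tfs_split(clinical: pd.DataFrame, cut_years: float = 2.0
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split untreated patients into short (event before the cut) and
    long (follow-up reaching the cut) TFS groups.

    Patients censored before the cut are indeterminate and excluded;
    the excluded count is logged.
    """
    df = clinical[~clinical["previously_treated"]].dropna(subset=["tfs_years"])
    short = df[(df["event"]) & (df["tfs_years"] < cut_years)]
    long = df[df["tfs_years"] >= cut_years]
    n_excl = len(df) - len(short) - len(long)
    log.info("short/long TFS split at %.1f y: %d short, %d long, %d excluded "
             "(censored before cut)", cut_years, len(short), len(long), n_excl)
    return short.reset_index(drop=True), long.reset_index(drop=True)


@dataclass
class StudyReport:
    """All study outputs, as DataFrames/dicts keyed by stage."""

    tmb_table: pd.DataFrame
    contingency: dict
    km_tables: dict
    logrank: dict
    marker_table: pd.DataFrame
    panel_result: object
    cox_univariate: pd.DataFrame
    cox_multivariate: object
    provenance: dict
    audit: pd.DataFrame = None


def _surv_from(df: pd.DataFrame) -> SurvivalData:
    return SurvivalData.from_frame(df)


def _binary_covariates(clinical: pd.DataFrame, matrix: MutationMatrix,
                       estimator_panel) -> pd.DataFrame:
    """Patient-aligned 0/1 covariates for Cox and marker tables."""
    idx = clinical["patient_id"]
    bin_mat = matrix.binary.loc[idx]
    cov = pd.DataFrame(index=clinical.index)
    cov["eight_gene_estimator"] = estimator_status(
        MutationMatrix(matrix.counts.loc[idx]), set(estimator_panel)).to_numpy(int)
    prof = tmb_profile(MutationMatrix(matrix.counts.loc[idx]))
    cov["tmb_high"] = prof["tmb_high"].to_numpy(int)
    cov["ighv_unmutated"] = (clinical["ighv_status"] == "unmutated").astype(int).to_numpy()
    cov["binet_b"] = (clinical["binet_stage"] == "B").astype(int).to_numpy()
    for cls in ("isolated_del13q", "trisomy12", "del11q", "del17p", "complex",
                "normal"):
        cov[cls] = (clinical["cytogenetic_class"] == cls).astype(int).to_numpy()
    return cov


def run_study(config: AnalysisConfig) -> StudyReport:
    """Execute the full study and write report files under config.out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- ingest ----------------------------------------------------------
    if config.synthetic:
        spec = default_spec(seed=config.seed)
        clin_records, true_matrix = generate_cohort(spec)
        clinical = clinical_to_frame(clin_records)
        records = generate_variant_calls(true_matrix, spec,
                                         noise_seed=config.seed + 1)
    else:
        clinical = read_clinical_csv(config.clinical_path)
        records = read_variant_tsv(config.variants_path)
        true_matrix = None

    unknown = {r.patient_id for r in records} - set(clinical["patient_id"])
    if unknown:
        raise ValueError(
            f"variant records for patients absent from the clinical table: "
            f"{sorted(unknown)}")

    # ---- filtering -> mutation matrix ------------------------------------
    fcfg = FilterConfig(min_depth=config.min_depth,
                        min_alt_reads=config.min_alt_reads,
                        min_vaf=config.min_vaf, maf_cutoff=config.maf_cutoff,
                        cadd_cutoff=config.cadd_cutoff,
                        review_policy=config.review_policy)
    genes = true_matrix.genes if true_matrix is not None else None
    matrix, decisions = run_filter_pipeline(
        records, fcfg, patients=list(clinical["patient_id"]), genes=genes)
    audit = decisions_to_frame(decisions)
    for rule in ("exonic", "min_depth", "min_alt_reads", "min_vaf",
                 "polymorphism_maf", "pathogenicity", "manual_review"):
        n_fail = audit["failed_rules"].str.contains(rule, regex=False).sum()
        log.info("filter rule %s: %d records failed", rule, n_fail)

    # ---- TMB --------------------------------------------------------------
    profile = tmb_profile(matrix, threshold=config.tmb_threshold,
                          panel=set(config.estimator_panel))
    tmb_table = clinical.merge(profile.reset_index(), on="patient_id")

    # ---- subsets -----------------------------------------------------------
    untreated = subset_cohort(tmb_table, "untreated").dropna(subset=["tfs_years"])
    surv_base = untreated
    for rule in config.survival_subsets:
        if rule != "untreated":
            surv_base = subset_cohort(surv_base, rule)

    report_sections_skipped = []

    # ---- contingency tables ------------------------------------------------
    contingency = {}
    short, long_ = short_long_tfs_split(tmb_table, config.short_long_cut_years)
    treated = tmb_table[tmb_table["previously_treated"]]
    for name, flag in (("tmb_high", "tmb_high"),
                       ("estimator", "estimator_mutated")):
        groups = {"treated": treated, "short_tfs": short, "long_tfs": long_}
        tab = pd.DataFrame({g: [int(df[flag].sum()), int((~df[flag]).sum())]
                            for g, df in groups.items()},
                           index=["positive", "negative"])
        if tab.to_numpy().sum() > 0 and (tab.sum(0) > 0).all():
            test, stat, p = association_test(tab.to_numpy())
            contingency[f"{name}_vs_tfs_category"] = {
                "table": tab, "test": test, "statistic": stat, "p": p}
        # cytogenetic risk: high = del11q/del17p/complex
        udf = untreated
        high_risk = udf["cytogenetic_class"].isin(["del11q", "del17p", "complex"])
        low_risk = udf["cytogenetic_class"].isin(["normal", "isolated_del13q"])
        sel = udf[high_risk | low_risk]
        tab2 = pd.crosstab(sel[flag],
                           np.where(high_risk[high_risk | low_risk], "high_risk",
                                    "low_risk"))
        if tab2.shape == (2, 2):
            test, stat, p = association_test(tab2.to_numpy())
            contingency[f"{name}_vs_cytogenetic_risk"] = {
                "table": tab2, "test": test, "statistic": stat, "p": p}
        tab3 = pd.crosstab(udf[flag], udf["ighv_status"])
        if tab3.shape == (2, 2):
            test, stat, p = association_test(tab3.to_numpy())
            contingency[f"{name}_vs_ighv"] = {
                "table": tab3, "test": test, "statistic": stat, "p": p}

    # ---- marker informativeness table (C-index, logrank) -------------------
    surv_m = _surv_from(surv_base)
    sub_matrix = MutationMatrix(matrix.counts.loc[surv_base["patient_id"]])
    cov = _binary_covariates(surv_base, matrix, config.estimator_panel)
    extra = cov[["eight_gene_estimator", "ighv_unmutated", "binet_b",
                 "isolated_del13q", "trisomy12", "del11q", "del17p",
                 "complex", "normal"]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        marker_table = per_gene_cindex_table(sub_matrix, surv_m,
                                             extra_markers=extra)

    # ---- panel search ------------------------------------------------------
    selector = PanelSelector(max_size=config.panel_max_size,
                             mode=config.panel_mode)
    selector.fit(sub_matrix, surv_m)
    panel_result = selector.result_

    # ---- stratified KM / logrank -------------------------------------------
    km_tables, logrank_out = {}, {}
    strata = {
        "untreated_binet_ab": subset_cohort(untreated, "binet_ab"),
        "binet_a": subset_cohort(untreated, "binet_a"),
        "good_karyotype": subset_cohort(untreated, "good_karyotype"),
    }
    for stratum, df in strata.items():
        if len(df) == 0:
            report_sections_skipped.append(stratum)
            log.warning("stratum %s empty; section skipped", stratum)
            continue
        sv = _surv_from(df)
        for flag in ("estimator_mutated", "tmb_high"):
            g = df[flag].to_numpy(bool)
            for label, mask in (("positive", g), ("negative", ~g)):
                if mask.sum() == 0:
                    continue
                km = kaplan_meier(sv.subset(mask))
                km_tables[f"{stratum}.{flag}.{label}"] = km
            if 0 < g.sum() < len(g):
                stat, p = logrank_test(g, sv)
                logrank_out[f"{stratum}.{flag}"] = {"chi2": stat, "p": p}

    # ---- Cox univariate and multivariate ----------------------------------
    binet_a = subset_cohort(untreated, "binet_a")
    sv_a = _surv_from(binet_a)
    cov_a = _binary_covariates(binet_a, matrix, config.estimator_panel)
    candidates = ["eight_gene_estimator", "tmb_high", "ighv_unmutated",
                  "isolated_del13q", "trisomy12", "del11q"]
    uni_rows = []
    for c in candidates:
        if cov_a[c].nunique() <= 1:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = cox_fit(cov_a[[c]], sv_a)
            uni_rows.append(res.summary.assign(covariate=c))
        except ValueError as err:
            log.warning("univariate Cox failed for %s: %s", c, err)
    cox_uni = (pd.concat(uni_rows).reset_index(drop=True)
               if uni_rows else pd.DataFrame())

    multi_candidates = [c for c in candidates
                        if c != "tmb_high" and cov_a[c].nunique() > 1]
    if multi_candidates and sv_a.event.sum() >= 2:
        model = StepwiseCoxPH(n_bootstrap=config.n_bootstrap,
                              random_state=config.seed + 17)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(cov_a[multi_candidates], sv_a)
        cox_multi = model.result_
    else:
        cox_multi = None
        report_sections_skipped.append("cox_multivariate")

    provenance = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_patients": int(len(clinical)),
        "n_variant_records": int(len(records)),
        "n_retained": int(matrix.counts.to_numpy().sum()),
        "sections_skipped": report_sections_skipped,
    }
    report = StudyReport(tmb_table=tmb_table, contingency=contingency,
                         km_tables=km_tables, logrank=logrank_out,
                         marker_table=marker_table, panel_result=panel_result,
                         cox_univariate=cox_uni, cox_multivariate=cox_multi,
                         provenance=provenance, audit=audit)
    write_report(report, out)
    return report


def write_report(report: StudyReport, out_dir: Path) -> None:
    """Persist all report tables as CSV/JSON plus a checksummed manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def save_frame(df: pd.DataFrame, name: str):
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    save_frame(report.tmb_table, "tmb_table.csv")
    save_frame(report.marker_table, "marker_table.csv")
    save_frame(report.audit, "filter_audit.tsv")
    ptab = report.panel_result.table.copy()
    ptab["genes"] = ptab["genes"].map(lambda g: ";".join(g))
    save_frame(ptab, "panel_search.csv")
    if len(report.cox_univariate):
        save_frame(report.cox_univariate, "cox_univariate.csv")
    if report.cox_multivariate is not None:
        s = report.cox_multivariate.summary.reset_index()
        save_frame(s, "cox_multivariate.csv")
        freqs = report.cox_multivariate.selection_frequencies or {}
        path = out_dir / "bootstrap_selection.json"
        path.write_text(json.dumps(freqs, indent=2, sort_keys=True))
        written.append(path)
    for key, km in report.km_tables.items():
        save_frame(km.to_frame(), f"km_{key}.csv")
    cont = {k: {"table": v["table"].to_dict(), "test": v["test"],
                "statistic": v["statistic"], "p": v["p"]}
            for k, v in report.contingency.items()}
    for name, payload in (("contingency.json", cont),
                          ("logrank.json", report.logrank),
                          ("provenance.json", report.provenance)):
        path = out_dir / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
        written.append(path)

    manifest = {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(written)}
    (out_dir / "MANIFEST.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
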