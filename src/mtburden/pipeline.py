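"""End-to-end orchestration: simulate/ingest -> call -> burden -> outcomes.

``run_pipeline`` executes the stages in a fixed order, writes every
intermediate table under the output directory and returns a
:class:`CohortReport`. All outputs are deterministic given the config seed
(logging goes to stderr and carries no timestamps into artifacts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import calling, io, simulate, stats
from .burden import GLEASON_CATEGORIES
from .errors import ConfigError, MtBurdenError, ValidationError

logger = logging.getLogger(__name__)

#: expected European-ancestry haplogroup frequencies used for the
#: observed-vs-expected contingency test (remainder pooled as "other")
DEFAULT_EXPECTED_HAPLOGROUP_FREQS = {
    "H": 0.43, "U": 0.14, "J": 0.11, "T": 0.09, "K": 0.08, "other": 0.15,
}

GLEASON_ORDINAL = {"<7": 1, "=7": 2, ">7": 3}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (either file inputs or a simulation)."""

    variants_path: str | None = None
    clinical_path: str | None = None
    catalog_path: str | None = None
    simulation: simulate.SimulationConfig | None = None
    somatic_threshold: float = calling.DEFAULT_SOMATIC_THRESHOLD
    min_depth: int = calling.DEFAULT_MIN_DEPTH
    cvf_on_raw: bool = False
    functional_threshold: float = burden_mod.DEFAULT_FUNCTIONAL_THRESHOLD
    burden_cutoffs: tuple[int, ...] = (1, 2)
    alpha: float = 0.05
    bonferroni_m: int = 7
    expected_haplogroup_freqs: dict = field(
        default_factory=lambda: dict(DEFAULT_EXPECTED_HAPLOGROUP_FREQS)
    )
    output_dir: str = "mtburden_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        has_files = self.variants_path is not None and self.clinical_path is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ConfigError(
                "config must carry exactly one of {variants+clinical paths, simulation block}"
            )
        if not 0 <= self.somatic_threshold < 1:
            raise ConfigError(f"somatic_threshold {self.somatic_threshold} outside [0,1)")
        if not 0 < self.functional_threshold:
            raise ConfigError("functional_threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0,1)")
        if self.bonferroni_m < 1:
            raise ConfigError("bonferroni_m must be >= 1")
        if any(c < 1 for c in self.burden_cutoffs):
            raise ConfigError("burden cutoffs must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", None)
        cfg = cls(**{k: tuple(v) if k == "burden_cutoffs" else v for k, v in data.items()})
        if sim is not None:
            sim = dict(sim)
            sim.setdefault("seed", cfg.seed)
            cfg.simulation = simulate.SimulationConfig.from_dict(sim)
        cfg.validate()
        return cfg


@dataclass
class CohortReport:
    summary: pd.DataFrame
    spectrum: dict
    densities: pd.DataFrame
    enrichment: dict
    haplogroup_test: dict
    anova: list[dict]
    survival: list[dict]
    roc: dict
    warnings: list[str]
    n_somatic_calls: int
    n_unique_variants: int
    bonferroni_threshold: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_somatic_calls": self.n_somatic_calls,
            "n_unique_variants": self.n_unique_variants,
            "bonferroni_threshold": round(self.bonferroni_threshold, 4),
            "summary": json.loads(self.summary.to_json()),
            "spectrum": self.spectrum,
            "enrichment": self.enrichment,
            "haplogroup_test": self.haplogroup_test,
            "anova": self.anova,
            "survival": self.survival,
            "roc": self.roc,
            "warnings": self.warnings,
        }


def validate_inputs(variants_path: str, clinical_path: str, catalog_path: str | None = None) -> list[dict]:
    """Schema/domain validation; returns a machine-readable issue list."""
    issues: list[dict] = []
    try:
        variants = io.read_tsv(variants_path)
    except ValidationError as exc:
        return [{"stage": "io", "issue": str(exc)}]
    try:
        clinical = io.read_tsv(clinical_path)
    except ValidationError as exc:
        return [{"stage": "io", "issue": str(exc)}]

    required_v = {"patient_id", "position", "ref_base", "alt_base", "tumor_af", "normal_af"}
    missing = required_v - set(variants.columns)
    if missing:
        issues.append({"stage": "variants", "issue": f"missing columns {sorted(missing)}"})
    required_c = {"patient_id", "gleason_category", "purity", "follow_up_months", "relapse"}
    missing = required_c - set(clinical.columns)
    if missing:
        issues.append({"stage": "clinical", "issue": f"missing columns {sorted(missing)}"})
    if issues:
        return issues

    for row in clinical.itertuples(index=False):
        if not 0 < float(row.purity) <= 1:
            issues.append(
                {"stage": "clinical", "issue": f"purity {row.purity} outside (0,1]",
                 "patient_id": row.patient_id}
            )
        if float(row.follow_up_months) <= 0:
            issues.append(
                {"stage": "clinical", "issue": "non-positive follow-up",
                 "patient_id": row.patient_id}
            )
        if str(row.gleason_category) not in GLEASON_CATEGORIES:
            issues.append(
                {"stage": "clinical", "issue": f"bad gleason category {row.gleason_category}",
                 "patient_id": row.patient_id}
            )
    for af_col in ("tumor_af", "normal_af"):
        bad = variants[(variants[af_col] < 0) | (variants[af_col] > 1)]
        for row in bad.itertuples(index=False):
            issues.append(
                {"stage": "variants", "issue": f"{af_col} outside [0,1]",
                 "patient_id": row.patient_id}
            )
    unmatched = set(variants["patient_id"]) - set(clinical["patient_id"])
    for pid in sorted(unmatched):
        issues.append({"stage": "join", "issue": "variant rows without clinical record",
                       "patient_id": pid})
    issues.extend(
        {"stage": "reference", "issue": msg} for msg in io.check_reference_consistency(variants)
    )
    if catalog_path is not None:
        try:
            catalog = io.read_tsv(catalog_path)
            required_k = {"position", "ref_base", "alt_base", "context"}
            missing = required_k - set(catalog.columns)
            if missing:
                issues.append({"stage": "catalog", "issue": f"missing columns {sorted(missing)}"})
        except ValidationError as exc:
            issues.append({"stage": "catalog", "issue": str(exc)})
    return issues


def _haplogroup_table(clinical: pd.DataFrame, expected_freqs: dict) -> dict:
    """Observed-vs-expected haplogroup counts compared by Fisher r x c.

    Expected counts are the cohort size multiplied by the published frequency
    vector and rounded to integers; labels outside the vector pool as "other".
    """
    n = len(clinical)
    labels = list(expected_freqs)
    observed = clinical["haplogroup"].map(
        lambda h: h if h in expected_freqs else "other"
    ).value_counts()
    obs = [int(observed.get(lab, 0)) for lab in labels]
    exp = [int(round(expected_freqs[lab] * n)) for lab in labels]
    table = np.array([obs, exp])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    result = stats.fisher_exact_rxc(table, mc_iterations=20_000, seed=0)
    if isinstance(result, stats.MonteCarloP):
        return {"p_value": result.p, "mc_se": result.se, "observed": obs, "expected": exp,
                "labels": labels, "method": "fisher_rxc_monte_carlo"}
    return {"p_value": result, "observed": obs, "expected": exp, "labels": labels,
            "method": "fisher_exact_2x2"}


def _anova_entry(name, y, x, threshold, warnings_list, diagnostic=False) -> dict | None:
    try:
        res = stats.anova_linear(y, x)
    except MtBurdenError as exc:
        warnings_list.append(f"anova {name}: {exc}")
        return None
    return {
        "test": name,
        "diagnostic": diagnostic,
        "slope": res.slope,
        "f_statistic": res.f_statistic,
        "df": [1, res.df_resid],
        "p_value": res.p_value,
        "significant_bonferroni": bool(res.p_value < threshold),
    }


def run_pipeline(config: PipelineConfig) -> CohortReport:
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_list: list[str] = []
    meta = {"seed": config.seed, "somatic_threshold": config.somatic_threshold,
            "functional_threshold": config.functional_threshold,
            "cvf_on_raw": config.cvf_on_raw}

    # stage: simulate or ingest -------------------------------------------------
    if config.simulation is not None:
        logger.info("stage=simulate n=%d", config.simulation.n_patients)
        clinical, pair_table, truths = simulate.simulate_cohort(config.simulation)
        io.write_tsv(pair_table, outdir / "calls.tsv", meta)
        (outdir / "truth.json").write_text(simulate.truth_to_json(truths, config.simulation))
    else:
        logger.info("stage=ingest variants=%s", config.variants_path)
        issues = validate_inputs(config.variants_path, config.clinical_path, config.catalog_path)
        if issues:
            raise ValidationError(f"{len(issues)} validation issues; first: {issues[0]}")
        pair_table = io.read_tsv(config.variants_path)
        clinical = io.read_tsv(config.clinical_path)
    io.write_tsv(clinical, outdir / "clinical.tsv", meta)

    # stage: call ---------------------------------------------------------------
    logger.info("stage=call threshold=%.3f", config.somatic_threshold)
    calls = io.calls_from_frame(pair_table)
    somatic, diagnostics = calling.call_cohort(calls, config.somatic_threshold)
    somatic_df = calling.variants_to_frame(somatic)
    io.write_tsv(somatic_df, outdir / "somatic.tsv", meta)
    io.write_tsv(diagnostics, outdir / "diagnostics.tsv", meta)

    # stage: annotate / deduplicate --------------------------------------------
    unique_df = calling.deduplicate(somatic)
    catalog = io.read_tsv(config.catalog_path) if config.catalog_path else None
    if len(unique_df):
        novelty, n_skipped = calling.annotate_novelty(unique_df, catalog)
        unique_df = unique_df.assign(novelty=novelty)
        if n_skipped:
            warnings_list.append(f"catalog: skipped {n_skipped} malformed rows")
    io.write_tsv(unique_df, outdir / "unique_variants.tsv", meta)

    try:
        spectrum = calling.spectrum_summary(somatic)
    except MtBurdenError:
        spectrum = {}
        warnings_list.append("spectrum: no somatic variants")

    # stage: burden -------------------------------------------------------------
    logger.info("stage=burden")
    profiles = burden_mod.build_profiles(
        somatic_df, clinical, config.functional_threshold, config.cvf_on_raw
    )
    profile_df = burden_mod.profiles_to_frame(profiles)
    io.write_tsv(profile_df, outdir / "burden.tsv", meta)
    summary = burden_mod.cohort_summary(profiles, clinical)
    io.write_tsv(summary.reset_index(names="metric"), outdir / "summary.tsv", meta)

    densities, aggregates = burden_mod.region_densities(unique_df)
    dens_df = burden_mod.densities_to_frame(densities, aggregates)
    io.write_tsv(dens_df, outdir / "densities.tsv", meta)
    enrichment = {}
    pc = aggregates["protein_coding"]
    for name, other in (
        ("noncoding_vs_coding", aggregates["noncoding_total"]),
        ("dloop_trna_vs_coding", None),
    ):
        if other is None:
            n_v = aggregates["control_region"].n_variants + aggregates["tRNA"].n_variants
            n_l = aggregates["control_region"].length_bp + aggregates["tRNA"].length_bp
        else:
            n_v, n_l = other.n_variants, other.length_bp
        enrichment[name] = {
            "p_value": burden_mod.region_enrichment_test(n_v, n_l, pc.n_variants, pc.length_bp),
            "variants": [n_v, pc.n_variants],
            "lengths": [n_l, pc.length_bp],
        }

    # stage: associate (ANOVA linear models) ------------------------------------
    logger.info("stage=associate")
    bonf = stats.bonferroni_threshold(config.alpha, config.bonferroni_m)
    merged = clinical.merge(profile_df, on="patient_id", validate="one_to_one")
    y_rp = merged["gleason_category"].map(GLEASON_ORDINAL).to_numpy(float)
    y_bx = (
        merged["gleason_biopsy_category"].map(GLEASON_ORDINAL).to_numpy(float)
        if "gleason_biopsy_category" in merged
        else None
    )
    n_syn_nc = merged["n_snv"] - merged["n_nonsynonymous"]
    anova_results = []
    tests = [
        ("gleason_rp ~ n_snv", y_rp, merged["n_snv"]),
        ("gleason_rp ~ cvf", y_rp, merged["cvf"]),
        ("gleason_rp ~ n_nonsynonymous", y_rp, merged["n_nonsynonymous"]),
        ("gleason_rp ~ n_synonymous_noncoding", y_rp, n_syn_nc),
        ("gleason_rp ~ purity", y_rp, merged["purity"]),
    ]
    if y_bx is not None:
        tests[2:2] = [
            ("gleason_biopsy ~ n_snv", y_bx, merged["n_snv"]),
            ("gleason_biopsy ~ cvf", y_bx, merged["cvf"]),
        ]
    for name, y, x in tests:
        entry = _anova_entry(name, y, np.asarray(x, float), bonf, warnings_list)
        if entry:
            anova_results.append(entry)
    # diagnostics: swapped-direction models
    for name, y, x in (("n_snv ~ gleason_rp", merged["n_snv"], y_rp),
                       ("n_snv ~ purity", merged["n_snv"], merged["purity"])):
        entry = _anova_entry(name, np.asarray(y, float), np.asarray(x, float),
                             bonf, warnings_list, diagnostic=True)
        if entry:
            anova_results.append(entry)

    # stage: survival -----------------------------------------------------------
    logger.info("stage=survive")
    times = merged["follow_up_months"].to_numpy(float)
    events = merged["relapse"].to_numpy(int)
    survival_results = []
    for cutoff in config.burden_cutoffs:
        groups = np.array([stats.dichotomize_burden(k, cutoff) for k in merged["n_snv"]])
        entry = {"cutoff": int(cutoff)}
        try:
            res = stats.logrank_hr(times, events, groups, exposed="high")
            entry.update(
                chi_square=res.chi_square, p_value=res.p_value,
                hazard_ratio=res.hazard_ratio, ci_low=res.ci_low, ci_high=res.ci_high,
                observed=res.observed, expected=res.expected,
                significant_bonferroni=bool(res.p_value < bonf),
            )
            for label in ("low", "high"):
                mask = groups == label
                curve = stats.km_estimate(times[mask], events[mask])
                io.write_tsv(
                    pd.DataFrame({"time": curve.times, "survival": curve.survival,
                                  "at_risk": curve.at_risk}),
                    outdir / f"km_cutoff{cutoff}_{label}.tsv", meta,
                )
        except MtBurdenError as exc:
            entry["warning"] = str(exc)
            warnings_list.append(f"survival cutoff {cutoff}: {exc}")
        survival_results.append(entry)

    # stage: roc ----------------------------------------------------------------
    logger.info("stage=roc")
    roc_report: dict = {}
    try:
        gleason_scores = y_rp
        burden_scores = merged["n_snv"].to_numpy(float)
        roc_g = stats.roc_auc(gleason_scores, events)
        roc_b = stats.roc_auc(burden_scores, events)
        combined = stats.combine_predictors(gleason_scores, burden_scores, events)
        roc_c = stats.roc_auc(combined.scores, events)
        _, _, delong_p = stats.delong_test(combined.scores, gleason_scores, events)
        roc_report = {
            "auc_gleason": roc_g.auc,
            "auc_burden": roc_b.auc,
            "auc_combined": roc_c.auc,
            "delong_p_combined_vs_gleason": delong_p,
            "combined_separation_fallback": combined.separation_fallback,
        }
        for tag, r in (("gleason", roc_g), ("burden", roc_b), ("combined", roc_c)):
            io.write_tsv(
                pd.DataFrame({"threshold": r.thresholds, "sensitivity": r.sensitivities,
                              "specificity": r.specificities}),
                outdir / f"roc_{tag}.tsv", meta,
            )
    except MtBurdenError as exc:
        roc_report = {"warning": str(exc)}
        warnings_list.append(f"roc: {exc}")

    report = CohortReport(
        summary=summary,
        spectrum=spectrum,
        densities=dens_df,
        enrichment=enrichment,
        haplogroup_test=_haplogroup_table(clinical, config.expected_haplogroup_freqs),
        anova=anova_results,
        survival=survival_results,
        roc=roc_report,
        warnings=warnings_list,
        n_somatic_calls=len(somatic_df),
        n_unique_variants=len(unique_df),
        bonferroni_threshold=bonf,
        seed=config.seed,
    )
    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True, default=float) + "\n"
    )
    (outdir / "report.txt").write_text(render_report_text(report))
    return report


def render_report_text(report: CohortReport) -> str:
    """Human-readable cohort summary mirroring the tabular report layout."""
    lines = ["mtburden cohort report", "=" * 60, ""]
    lines.append(f"somatic calls: {report.n_somatic_calls}   "
                 f"unique variants: {report.n_unique_variants}")
    lines.append(f"bonferroni per-test threshold: {report.bonferroni_threshold:.4f}")
    lines.append("")
    lines.append("cohort summary (per Gleason category)")
    lines.append(report.summary.to_string(float_format=lambda v: f"{v:.4g}"))
    lines.append("")
    if report.spectrum:
        lines.append("substitution spectrum: " + "  ".join(
            f"{k}={v:.1%}" for k, v in report.spectrum.items()))
    for name, ent in report.enrichment.items():
        lines.append(f"enrichment {name}: p={ent['p_value']:.4g}")
    lines.append(f"haplogroup observed-vs-expected: p={report.haplogroup_test['p_value']:.4g}")
    lines.append("")
    for ent in report.anova:
        tag = " [diagnostic]" if ent["diagnostic"] else ""
        star = "*" if ent["significant_bonferroni"] else ""
        lines.append(
            f"ANOVA {ent['test']}{tag}: F={ent['f_statistic']:.4g} "
            f"df={ent['df']} p={ent['p_value']:.4g}{star}"
        )
    lines.append("")
    for ent in report.survival:
        if "warning" in ent:
            lines.append(f"log-rank cutoff {ent['cutoff']}: {ent['warning']}")
        else:
            star = "*" if ent["significant_bonferroni"] else ""
            lines.append(
                f"log-rank cutoff {ent['cutoff']}: chi2={ent['chi_square']:.4g} "
                f"p={ent['p_value']:.4g}{star} HR={ent['hazard_ratio']:.3g} "
                f"[{ent['ci_low']:.3g}, {ent['ci_high']:.3g}]"
            )
    lines.append("")
    if "warning" in report.roc:
        lines.append(f"ROC: {report.roc['warning']}")
    elif report.roc:
        lines.append(
            f"ROC AUC gleason={report.roc['auc_gleason']:.3f} "
            f"burden={report.roc['auc_burden']:.3f} "
            f"combined={report.roc['auc_combined']:.3f} "
            f"(DeLong p={report.roc['delong_p_combined_vs_gleason']:.4g})"
        )
    if report.warnings:
        lines.append("")
        lines.append("warnings:")
        lines.extend(f"  - {w}" for w in report.warnings)
    return "\n".join(lines) + "\n"
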