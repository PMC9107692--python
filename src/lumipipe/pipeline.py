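"""End-to-end orchestration: QC -> scores -> surrogate calls -> statistics.

Each stage is a pure function of (inputs, config, seed); ``run_all`` chains
them and writes the per-stage CSV outputs plus a machine-readable JSON summary
with the headline quantities (subtype counts, risk-class distribution, kappa
values, concordance fractions).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import cohort_analysis, config, ihc_subtyping, molecular_scoring, synthetic_cohort
from .expression_qc import ExpressionPanel, normalize, qc_filter_samples, read_counts


@dataclass
class RunConfig:
    """Paths, constants and the single seed every stage draws from."""

    outdir: str = "lumipipe_out"
    counts_path: str | None = None
    clinical_path: str | None = None
    seed: int = 0
    n_patients: int = config.REFERENCE_COHORT_SIZE
    expression_separation: float = 2.0
    immune_coupling: float = 0.9
    censoring_rate: float = 0.3
    immune_cutoff: float = config.IMMUNE_CUTOFF_PRESET
    tils_cutoff: float = config.TILS_CUTOFF_PRESET
    label_column: str = "true_subtype"
    centroid_model_path: str | None = None
    constants: config.ModelConstants = field(default_factory=config.ModelConstants)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__) - {"constants"}
        kwargs = {k: v for k, v in payload.items() if k in known}
        unknown = set(payload) - known - {"constants"}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**kwargs)


def _round_tree(obj, ndigits=6):
    if isinstance(obj, dict):
        return {k: _round_tree(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_tree(v, ndigits) for v in obj]
    if isinstance(obj, float):
        return round(obj, ndigits)
    return obj


def stage_simulate(cfg: RunConfig) -> synthetic_cohort.SyntheticCohort:
    spec = synthetic_cohort.CohortSpec(
        n_patients=cfg.n_patients,
        expression_separation=cfg.expression_separation,
        immune_coupling=cfg.immune_coupling,
        censoring_rate=cfg.censoring_rate,
        seed=cfg.seed,
    )
    return synthetic_cohort.generate_cohort(spec)


def stage_qc(panel: ExpressionPanel, outdir: str | None = None):
    filtered, report = qc_filter_samples(panel)
    nm = normalize(filtered)
    if outdir:
        report.to_csv(os.path.join(outdir, "qc_report.csv"), index_label="sample")
        nm.values.to_csv(os.path.join(outdir, "normalized.csv"), index_label="sample")
    return filtered, nm, report


def stage_score(nm, labels: pd.Series, cfg: RunConfig, outdir: str | None = None) -> pd.DataFrame:
    c = cfg.constants
    if cfg.centroid_model_path:
        model = molecular_scoring.load_centroid_model(cfg.centroid_model_path)
    else:
        # subtypes with fewer than two labeled samples cannot contribute a centroid;
        # train on the represented ones and still score every sample
        counts = labels.value_counts()
        thin = counts.index[counts < 2].tolist()
        train_nm, train_labels = nm, labels
        if thin:
            import warnings as _w

            _w.warn(f"subtype(s) with <2 training samples dropped from centroids: {thin}",
                    stacklevel=2)
            keep = labels.index[labels.isin(counts.index[counts >= 2])]
            from .expression_qc import NormalizedMatrix

            train_nm = NormalizedMatrix(
                values=nm.values.loc[keep], log2=nm.log2.loc[keep],
                centering=nm.centering, standardized=nm.standardized,
                zero_variance_genes=nm.zero_variance_genes,
            )
            train_labels = labels.loc[keep]
        model = molecular_scoring.train_centroids(
            train_nm, train_labels, correlation_method=c.correlation_method,
            ror_coefficients=dict(c.ror_coefficients),
            proliferation_weight=c.ror_proliferation_weight,
            proliferation_genes=c.proliferation_genes,
            ror_rescale=c.ror_rescale, ror_thresholds=c.ror_thresholds,
        )
    rs_model = molecular_scoring.RSModel(
        groups={k: dict(v) for k, v in c.rs_groups.items()},
        coefficients=dict(c.rs_coefficients), floors=dict(c.rs_group_floors),
        reference_offset=c.rs_reference_offset, unscaled_map=c.rs_unscaled_map,
        class_thresholds=c.rs_thresholds,
    )
    scores = molecular_scoring.score_cohort(
        nm, model, rs_model=rs_model, immune_cutoff=cfg.immune_cutoff
    )
    if outdir:
        scores.to_csv(os.path.join(outdir, "scores.csv"), index_label="sample")
        molecular_scoring.save_centroid_model(model, os.path.join(outdir, "centroid_model.yaml"))
    return scores


def stage_surrogate(clinical: pd.DataFrame, cfg: RunConfig, outdir: str | None = None) -> pd.DataFrame:
    calls = ihc_subtyping.surrogate_table(clinical, tils_cutoff=cfg.tils_cutoff)
    if outdir:
        calls.to_csv(os.path.join(outdir, "surrogate.csv"), index_label="sample")
    return calls


def stage_analyze(
    clinical: pd.DataFrame,
    scores: pd.DataFrame | None,
    surrogate: pd.DataFrame,
    cfg: RunConfig,
    outdir: str | None = None,
) -> dict:
    merged = clinical.join(surrogate, how="inner")
    summary: dict = {"n": int(len(merged))}
    summary["modified_ihc_counts"] = surrogate["modified"].value_counts().to_dict()
    if scores is not None:
        merged = merged.join(scores, how="inner")
        summary["subtype_counts"] = scores["subtype"].value_counts().to_dict()
        summary["ror_class_counts"] = scores["ror_class"].value_counts().to_dict()
        summary["rs_class_counts"] = scores["rs_class"].value_counts().to_dict()

        risk = cohort_analysis.cohens_kappa(
            scores["ror_class"], scores["rs_class"], categories=["low", "medium", "high"]
        )
        modified = surrogate["modified"].reindex(scores.index)
        sub = cohort_analysis.cohens_kappa(
            scores["subtype"], modified, categories=["LumA", "LumB", "HER2E", "Basal"]
        )
        summary["kappa_ror_vs_rs"] = risk.kappa
        summary["concordance_ror_vs_rs"] = risk.observed_agreement
        summary["kappa_modified_ihc_vs_molecular"] = sub.kappa
        summary["concordance_modified_ihc_vs_molecular"] = sub.observed_agreement
        if outdir:
            risk.crosstab.to_csv(os.path.join(outdir, "agreement_ror_vs_rs.csv"))
            sub.crosstab.to_csv(os.path.join(outdir, "agreement_subtype.csv"))

        if {"dfs_months", "dfs_event"}.issubset(merged.columns):
            factors = cohort_analysis.build_factor_table(merged)
            groups = [g for g in cohort_analysis.FACTOR_GROUPS
                      if all(c in factors.columns for c in g)]
            multivariate = [c for c in ("size_gt_1cm", "basal_marker", "istrong", "tils_high")
                            if c in factors.columns and factors[c].nunique() > 1]
            for endpoint in ("dfs", "dmfs"):
                res = cohort_analysis.cox_analysis(
                    factors, merged[f"{endpoint}_months"], merged[f"{endpoint}_event"],
                    univariate=groups, multivariate=multivariate,
                )
                km = cohort_analysis.km_logrank(
                    merged[f"{endpoint}_months"], merged[f"{endpoint}_event"],
                    merged["ror_class"],
                )
                summary[f"logrank_ror_{endpoint}_p"] = km.logrank_p
                if outdir:
                    if res.cox_univariate is not None:
                        res.cox_univariate.to_csv(
                            os.path.join(outdir, f"cox_univariate_{endpoint}.csv"), index=False)
                    if res.cox_multivariate is not None:
                        res.cox_multivariate.to_csv(
                            os.path.join(outdir, f"cox_multivariate_{endpoint}.csv"), index=False)
                    for gname, curve in km.km_curves.items():
                        curve.to_csv(os.path.join(
                            outdir, f"km_{endpoint}_ror_{gname}.csv"), index=False)
    if outdir:
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(_round_tree(summary), fh, sort_keys=True, indent=2)
            fh.write("\n")
    return summary


def run_all(cfg: RunConfig) -> dict:
    """Full pipeline; simulates a cohort when no counts path is configured."""
    os.makedirs(cfg.outdir, exist_ok=True)
    if cfg.counts_path is None:
        cohort = stage_simulate(cfg)
        synthetic_cohort.write_cohort(cohort, cfg.outdir)
        panel, clinical = cohort.panel, cohort.clinical
    else:
        panel = read_counts(cfg.counts_path)
        if cfg.clinical_path is None:
            raise ValueError("clinical_path is required when counts are supplied")
        clinical = pd.read_csv(cfg.clinical_path, index_col=0)

    scores = None
    if panel is not None and len(panel.samples):
        filtered, nm, _ = stage_qc(panel, cfg.outdir)
        labels = clinical[cfg.label_column].reindex(nm.values.index) \
            if cfg.label_column in clinical.columns else None
        if labels is not None or cfg.centroid_model_path:
            scores = stage_score(nm, labels, cfg, cfg.outdir)
            clinical = clinical.loc[clinical.index.intersection(nm.values.index)]
    surrogate = stage_surrogate(clinical, cfg, cfg.outdir)
    return stage_analyze(clinical, scores, surrogate, cfg, cfg.outdir)
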