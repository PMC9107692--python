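"""Intrinsic subtyping and molecular risk scores.

Four outputs per sample:

* an intrinsic-subtype call (LumA / LumB / HER2E / Basal) by nearest-centroid
  correlation over the 50 subtype genes, on median-centered, standardized log2
  expression (Spearman by default);
* the proliferation-weighted risk-of-recurrence score ROR-P, a weighted sum of
  the four centroid correlations plus a proliferation term (mean centered
  expression of an 11-gene proliferation subset), affinely rescaled to 0-100
  and cut into low / medium / high classes;
* the 21-gene recurrence score RS from housekeeping-referenced log2 expression:
  weighted group scores (HER2, ER, proliferation, invasion, plus CD68, GSTM1
  and BAG1 singletons) with the published floor rules, combined linearly and
  affinely mapped with clipping to 0-100, cut at 18 / 31;
* a 17-gene immune score: mean housekeeping-referenced log2 immune expression,
  min-max rescaled to 0-100 across the cohort, dichotomized istrong/iweak at an
  inclusive cutoff (ROC-derived; 45.5 preset).

No published centroid values ship with the package; centroids are trained from
labeled expression (``train_centroids``), and ROR weights can alternatively be
refit by Cox regression (``fit_ror_coefficients``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import config
from .expression_qc import NormalizedMatrix

SUBTYPES = config.SUBTYPES


@dataclass
class CentroidModel:
    """Per-subtype mean expression profiles plus ROR scoring constants."""

    centroids: pd.DataFrame  # subtypes x subtype-genes
    correlation_method: str = "spearman"
    ror_coefficients: dict[str, float] = field(default_factory=lambda: dict(config.ROR_COEFFICIENTS))
    proliferation_weight: float = config.ROR_PROLIFERATION_WEIGHT
    proliferation_genes: tuple[str, ...] = config.PROLIFERATION_GENES
    ror_rescale: tuple[float, float] = config.ROR_RESCALE
    ror_thresholds: tuple[float, float] = config.ROR_THRESHOLDS

    def __post_init__(self) -> None:
        if self.correlation_method not in ("spearman", "pearson"):
            raise ValueError(f"unknown correlation method {self.correlation_method!r}")
        if not self.ror_thresholds[0] < self.ror_thresholds[1]:
            raise ValueError("ROR thresholds must be ordered")
        const = self.centroids.std(axis=1, ddof=0) == 0
        if const.any():
            raise ValueError(
                f"constant centroid row(s) {self.centroids.index[const].tolist()}: "
                "correlation undefined"
            )


@dataclass
class RSModel:
    """Gene groups, weights, floors and scaling of the 21-gene recurrence score."""

    groups: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in config.RS_GROUPS.items()}
    )
    coefficients: dict[str, float] = field(default_factory=lambda: dict(config.RS_COEFFICIENTS))
    floors: dict[str, float] = field(default_factory=lambda: dict(config.RS_GROUP_FLOORS))
    reference_genes: tuple[str, ...] = config.HOUSEKEEPING_GENES
    reference_offset: float = config.RS_REFERENCE_OFFSET
    unscaled_map: tuple[float, float] = config.RS_UNSCALED_MAP
    class_thresholds: tuple[float, float] = config.RS_THRESHOLDS

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for group, genes in self.groups.items():
            for g in genes:
                if g in seen:
                    raise ValueError(f"gene {g!r} appears in groups {seen[g]!r} and {group!r}")
                seen[g] = group
        if not self.class_thresholds[0] < self.class_thresholds[1]:
            raise ValueError("RS class thresholds must be ordered")

    @property
    def informative_genes(self) -> list[str]:
        return [g for genes in self.groups.values() for g in genes]


@dataclass
class SubtypeCall:
    subtype: str
    correlations: pd.Series  # indexed by subtype, values in [-1, 1]
    tie: bool = False


def train_centroids(
    normalized: NormalizedMatrix,
    labels: pd.Series,
    correlation_method: str = "spearman",
    subtype_genes: list[str] | None = None,
    **model_kwargs,
) -> CentroidModel:
    """Fit per-subtype centroids as gene-wise means of centered expression.

    Requires at least two labeled samples per represented subtype.
    """
    values = normalized.values
    genes = subtype_genes if subtype_genes is not None else [
        g for g in values.columns if g in set(config.SUBTYPE_GENES)
    ]
    if not genes:
        raise ValueError("no subtype genes present in the normalized matrix")
    labels = labels.reindex(values.index)
    if labels.isna().any():
        raise ValueError("every sample needs a subtype label for training")
    counts = labels.value_counts()
    thin = [k for k, n in counts.items() if n < 2]
    if thin:
        raise ValueError(f"subtype(s) with fewer than 2 training samples: {sorted(thin)}")
    centroids = values[genes].groupby(labels, observed=True).mean()
    centroids = centroids.reindex([s for s in SUBTYPES if s in centroids.index])
    centroids.index.name = None
    return CentroidModel(centroids=centroids, correlation_method=correlation_method, **model_kwargs)


def _correlation(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


def classify_subtype(sample_profile: pd.Series, model: CentroidModel) -> SubtypeCall:
    """Nearest-centroid call: argmax correlation, ties broken in fixed subtype order."""
    genes = model.centroids.columns
    profile = sample_profile.reindex(genes)
    if profile.isna().any():
        missing = profile.index[profile.isna()].tolist()
        raise ValueError(f"sample profile missing subtype gene(s): {missing}")
    x = profile.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant sample profile: correlation undefined")
    corrs = pd.Series(
        {k: _correlation(x, model.centroids.loc[k].to_numpy(dtype=float), model.correlation_method)
         for k in model.centroids.index},
        name="correlation",
    )
    best = corrs.max()
    winners = [k for k in model.centroids.index if corrs[k] == best]
    ordered = [s for s in SUBTYPES if s in winners]
    return SubtypeCall(subtype=ordered[0], correlations=corrs, tie=len(winners) > 1)


def classify_subtype_knn(
    sample_profile: pd.Series,
    training_values: pd.DataFrame,
    training_labels: pd.Series,
    k: int = 5,
) -> str:
    """K-nearest-neighbor subtype assignment against the training samples.

    Alternative assignment variant (nearest-centroid is the default and the
    documented pipeline behavior): majority vote among the k training samples
    closest in Euclidean distance on centered, standardized expression.
    """
    from sklearn.neighbors import KNeighborsClassifier

    genes = training_values.columns
    x = sample_profile.reindex(genes)
    if x.isna().any():
        raise ValueError("sample profile missing genes required by the training matrix")
    clf = KNeighborsClassifier(n_neighbors=min(k, len(training_values)))
    clf.fit(training_values.to_numpy(), training_labels.reindex(training_values.index))
    return str(clf.predict(x.to_numpy()[None, :])[0])


def proliferation_score(sample_profile: pd.Series, model: CentroidModel) -> float:
    """Mean centered expression over the proliferation gene subset."""
    genes = [g for g in model.proliferation_genes if g in sample_profile.index]
    if not genes:
        raise ValueError("no proliferation genes present in the sample profile")
    return float(sample_profile[genes].mean())


def ror_p(sample_profile: pd.Series, model: CentroidModel) -> tuple[float, str, SubtypeCall]:
    """Proliferation-weighted ROR: score in [0, 100], class, and the subtype call."""
    call = classify_subtype(sample_profile, model)
    raw = sum(model.ror_coefficients[k] * call.correlations[k] for k in call.correlations.index)
    raw += model.proliferation_weight * proliferation_score(sample_profile, model)
    offset, scale = model.ror_rescale
    score = float(np.clip(offset + scale * raw, 0.0, 100.0))
    return score, _three_class(score, model.ror_thresholds), call


def _three_class(score: float, thresholds: tuple[float, float]) -> str:
    lo, hi = thresholds
    if score < lo:
        return "low"
    if score < hi:
        return "medium"
    return "high"


def reference_normalize(log2_profile: pd.Series, model: RSModel) -> pd.Series:
    """Subtract the housekeeping log2 mean and shift by the reference offset."""
    missing = [g for g in model.reference_genes if g not in log2_profile.index]
    if missing:
        raise ValueError(f"missing reference gene(s): {missing}")
    hk_mean = float(log2_profile[list(model.reference_genes)].mean())
    return log2_profile - hk_mean + model.reference_offset


def oncotype_rs(log2_profile: pd.Series, model: RSModel | None = None) -> tuple[float, str, dict[str, float]]:
    """21-gene recurrence score from an uncentered log2 expression profile.

    Returns the clipped 0-100 score, its class, and the per-group scores (after
    floor rules) for inspection.
    """
    model = model or RSModel()
    missing = [g for g in model.informative_genes if g not in log2_profile.index]
    if missing:
        raise ValueError(f"missing informative gene(s): {missing}")
    norm = reference_normalize(log2_profile, model)
    group_scores: dict[str, float] = {}
    for name, genes in model.groups.items():
        score = sum(w * float(norm[g]) for g, w in genes.items())
        if name in model.floors:
            score = max(score, model.floors[name])
        group_scores[name] = score
    rs_unscaled = sum(model.coefficients[g] * group_scores[g] for g in model.coefficients)
    a, b = model.unscaled_map
    rs = float(np.clip(a + b * rs_unscaled, 0.0, 100.0))
    return rs, _three_class(rs, model.class_thresholds), group_scores


def immune_scores(
    log2: pd.DataFrame,
    immune_genes: list[str] | None = None,
    reference_genes: tuple[str, ...] = config.HOUSEKEEPING_GENES,
    cutoff: float = config.IMMUNE_CUTOFF_PRESET,
) -> pd.DataFrame:
    """Cohort immune scores: housekeeping-referenced immune mean, min-max 0-100.

    ``log2`` is the uncentered samples x genes log2 matrix. Group is "istrong"
    iff score >= cutoff (inclusive). The min-max rescaling needs a
    non-degenerate cohort (at least two distinct raw means).
    """
    genes = immune_genes if immune_genes is not None else [
        g for g in log2.columns if g in set(config.IMMUNE_GENES)
    ]
    if not genes:
        raise ValueError("no immune genes present")
    ref = [g for g in reference_genes if g in log2.columns]
    if not ref:
        raise ValueError("no reference genes present")
    hk_mean = log2[ref].mean(axis=1)
    raw = log2[genes].sub(hk_mean, axis=0).mean(axis=1)
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        raise ValueError("degenerate cohort: all immune means identical, cannot rescale")
    score = (raw - lo) / (hi - lo) * 100.0
    group = np.where(score >= cutoff, "istrong", "iweak")
    return pd.DataFrame({"immune_score": score, "immune_group": group}, index=log2.index)


def fit_ror_coefficients(
    correlations: pd.DataFrame,
    proliferation: pd.Series,
    times: pd.Series,
    events: pd.Series,
    penalizer: float = 0.1,
) -> tuple[dict[str, float], float]:
    """Self-trained mode: Cox regression of survival on correlations + proliferation.

    Mirrors how correlation-weighted recurrence scores are built when no
    published weights are available. Returns (subtype weight map, proliferation
    weight), i.e. the fitted log-hazard coefficients. A small ridge penalty
    stabilizes the fit: the four centroid correlations are strongly mutually
    collinear by construction.
    """
    from lifelines import CoxPHFitter

    df = correlations.copy()
    df["proliferation"] = proliferation
    df["time"] = times
    df["event"] = events
    cph = CoxPHFitter(penalizer=penalizer)
    cph.fit(df, duration_col="time", event_col="event")
    coefs = cph.params_
    weights = {k: float(coefs[k]) for k in correlations.columns}
    return weights, float(coefs["proliferation"])


def save_centroid_model(model: CentroidModel, path) -> None:
    """Serialize a centroid model (centroids + every scoring constant) to YAML."""
    import yaml

    payload = {
        "correlation_method": model.correlation_method,
        "genes": model.centroids.columns.tolist(),
        "centroids": {k: model.centroids.loc[k].tolist() for k in model.centroids.index},
        "ror_coefficients": model.ror_coefficients,
        "proliferation_weight": model.proliferation_weight,
        "proliferation_genes": list(model.proliferation_genes),
        "ror_rescale": list(model.ror_rescale),
        "ror_thresholds": list(model.ror_thresholds),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_centroid_model(path) -> CentroidModel:
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    centroids = pd.DataFrame.from_dict(payload["centroids"], orient="index",
                                       columns=payload["genes"])
    centroids = centroids.reindex([s for s in SUBTYPES if s in centroids.index])
    return CentroidModel(
        centroids=centroids,
        correlation_method=payload["correlation_method"],
        ror_coefficients={k: float(v) for k, v in payload["ror_coefficients"].items()},
        proliferation_weight=float(payload["proliferation_weight"]),
        proliferation_genes=tuple(payload["proliferation_genes"]),
        ror_rescale=tuple(payload["ror_rescale"]),
        ror_thresholds=tuple(payload["ror_thresholds"]),
    )


def score_cohort(
    normalized: NormalizedMatrix,
    centroid_model: CentroidModel,
    rs_model: RSModel | None = None,
    immune_cutoff: float = config.IMMUNE_CUTOFF_PRESET,
    immune_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Full per-sample score set: subtype + correlations, ROR-P, RS, immune score."""
    rs_model = rs_model or RSModel()
    centered = normalized.values
    missing_genes = [g for g in centroid_model.centroids.columns if g not in centered.columns]
    if missing_genes:
        warnings.warn(
            f"subtype gene(s) absent from the matrix, mean-imputed at 0: {missing_genes}",
            stacklevel=2,
        )
        centered = centered.copy()
        for g in missing_genes:
            centered[g] = 0.0
    rows = {}
    for s in centered.index:
        score, ror_class, call = ror_p(centered.loc[s], centroid_model)
        rs, rs_class, _ = oncotype_rs(normalized.log2.loc[s], rs_model)
        row = {
            "subtype": call.subtype,
            "subtype_tie": call.tie,
            "ror_p": score,
            "ror_class": ror_class,
            "rs": rs,
            "rs_class": rs_class,
        }
        for k in call.correlations.index:
            row[f"corr_{k}"] = call.correlations[k]
        rows[s] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    imm = immune_scores(normalized.log2, immune_genes=immune_genes, cutoff=immune_cutoff)
    return out.join(imm)
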