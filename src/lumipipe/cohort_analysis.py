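"""Downstream cohort statistics.

ROC/Youden cutpoint selection, agreement between classification systems
(cross-tabulation + Cohen's kappa), Kaplan-Meier / log-rank survival, uni- and
multivariate Cox proportional-hazards models, and Benjamini-Hochberg FDR
adjustment within test families. Survival machinery delegates to lifelines;
kappa and the cutpoint search are implemented here because their exact
conventions (midpoint thresholds, unweighted kappa) are part of the pipeline's
contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests


@dataclass
class CutpointResult:
    cutoff: float
    youden: float
    roc: pd.DataFrame  # threshold, sensitivity, specificity, youden
    n_ties: int = 0  # number of thresholds attaining the maximal Youden index


@dataclass
class AgreementResult:
    crosstab: pd.DataFrame
    observed_agreement: float
    kappa: float
    n: int
    undefined: bool = False  # both raters constant: chance agreement is 1

    def __post_init__(self) -> None:
        if not self.undefined and not (-1.0 - 1e-12 <= self.kappa <= 1.0 + 1e-12):
            raise ValueError(f"kappa {self.kappa} outside [-1, 1]")


@dataclass
class SurvivalResult:
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    logrank_defined: bool = True
    cox_univariate: pd.DataFrame | None = None
    cox_multivariate: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)


def youden_cutpoint(values, events) -> CutpointResult:
    """Threshold maximizing sensitivity + specificity - 1 (higher value = event).

    Candidate thresholds are the midpoints of consecutive sorted unique values;
    a sample is called positive when its value exceeds the threshold. Ties on
    the maximal Youden index resolve to the smallest threshold, with the tie
    count reported.
    """
    v = np.asarray(values, dtype=float)
    e = np.asarray(events, dtype=int)
    if v.shape != e.shape:
        raise ValueError("values and outcome must have equal length")
    if set(np.unique(e)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    n_pos = int(e.sum())
    n_neg = int(len(e) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    uniq = np.unique(v)
    if len(uniq) < 2:
        raise ValueError("values are constant; no cutpoint exists")
    thresholds = (uniq[:-1] + uniq[1:]) / 2.0
    rows = []
    for t in thresholds:
        pred = v > t
        sens = float((pred & (e == 1)).sum() / n_pos)
        spec = float((~pred & (e == 0)).sum() / n_neg)
        rows.append((t, sens, spec, sens + spec - 1.0))
    roc = pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity", "youden"])
    best = roc["youden"].max()
    winners = roc.loc[roc["youden"] == best, "threshold"]
    return CutpointResult(
        cutoff=float(winners.min()), youden=float(best), roc=roc, n_ties=len(winners)
    )


def cohens_kappa(labels_a, labels_b, categories=None) -> AgreementResult:
    """Unweighted Cohen's kappa with the full cross-tabulation.

    kappa = (p_o - p_e) / (1 - p_e), with p_e from the product of marginals.
    When both raters are constant on the same category, p_e = 1 and kappa is
    undefined; the result is flagged (kappa set to NaN) rather than raised.
    """
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length ({len(a)} vs {len(b)})")
    if len(a) == 0:
        raise ValueError("empty label vectors")
    cats = list(categories) if categories is not None else sorted(set(a) | set(b))
    ct = pd.crosstab(a, b).reindex(index=cats, columns=cats, fill_value=0)
    n = int(ct.to_numpy().sum())
    p_o = float(np.trace(ct.to_numpy()) / n)
    row_marg = ct.sum(axis=1).to_numpy() / n
    col_marg = ct.sum(axis=0).to_numpy() / n
    p_e = float((row_marg * col_marg).sum())
    if p_e == 1.0:
        return AgreementResult(crosstab=ct, observed_agreement=p_o, kappa=float("nan"),
                               n=n, undefined=True)
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(crosstab=ct, observed_agreement=p_o, kappa=float(kappa), n=n)


def km_logrank(times, events, groups) -> SurvivalResult:
    """Product-limit curves per group plus the (2+ group) log-rank test.

    Ties are handled by the standard aggregated-risk-set formulation (lifelines'
    default). With a single group, or with no events anywhere, the test is
    flagged undefined rather than computed.
    """
    df = pd.DataFrame({"time": np.asarray(times, dtype=float),
                       "event": np.asarray(events, dtype=int),
                       "group": list(groups)})
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    result = SurvivalResult()
    for g, sub in df.groupby("group", observed=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        surv = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        result.km_curves[str(g)] = pd.DataFrame(
            {"time": surv.index.to_numpy(), "survival": surv.iloc[:, 0].to_numpy(),
             "at_risk": at_risk.to_numpy()}
        )
    n_groups = df["group"].nunique()
    if n_groups < 2 or df["event"].sum() == 0:
        result.logrank_defined = False
        if df["event"].sum() == 0:
            result.warnings.append("log-rank undefined: all observations censored")
        return result
    lr = multivariate_logrank_test(df["time"], df["group"], df["event"])
    result.logrank_chi2 = float(lr.test_statistic)
    result.logrank_p = float(lr.p_value)
    return result


def _fit_cox(df: pd.DataFrame, covariates: list[str], time_col: str, event_col: str):
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df[covariates + [time_col, event_col]], duration_col=time_col,
                event_col=event_col)
    notes = sorted({str(w.message).splitlines()[0] for w in caught})
    return cph, notes


def _cox_rows(cph: CoxPHFitter, covariates: list[str], notes: list[str]) -> list[dict]:
    summ = cph.summary
    rows = []
    for cov in covariates:
        rows.append({
            "factor": cov,
            "hr": float(summ.loc[cov, "exp(coef)"]),
            "ci_lower": float(summ.loc[cov, "exp(coef) lower 95%"]),
            "ci_upper": float(summ.loc[cov, "exp(coef) upper 95%"]),
            "p": float(summ.loc[cov, "p"]),
            "note": "; ".join(notes),
        })
    return rows


def cox_analysis(
    covariates: pd.DataFrame,
    times,
    events,
    univariate: list[str] | list[list[str]] | None = None,
    multivariate: list[str] | None = None,
) -> SurvivalResult:
    """Univariate (per factor) and joint multivariate Cox fits.

    ``univariate`` entries may be single column names or lists of columns that
    together encode one multi-level factor against its reference. Degenerate
    strata (zero events on one side, monotone likelihood) are reported per
    factor with a note instead of crashing; the univariate p-values get a
    BH-adjusted column as one family.
    """
    df = covariates.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=int)
    result = SurvivalResult()

    if univariate:
        rows = []
        for factor in univariate:
            cols = [factor] if isinstance(factor, str) else list(factor)
            if any(df[c].nunique() < 2 for c in cols):
                rows.extend({"factor": c, "hr": np.nan, "ci_lower": np.nan,
                             "ci_upper": np.nan, "p": np.nan,
                             "note": "constant covariate"} for c in cols)
                continue
            try:
                cph, notes = _fit_cox(df, cols, "_time", "_event")
            except Exception as exc:  # convergence failure stays a report, not a crash
                rows.extend({"factor": c, "hr": np.nan, "ci_lower": np.nan,
                             "ci_upper": np.nan, "p": np.nan,
                             "note": f"fit failed: {exc}"} for c in cols)
                continue
            for c in cols:
                zero_events = df.loc[df[c] != 0, "_event"].sum() == 0 if df[c].isin((0, 1)).all() else False
                extra = ["monotone likelihood: zero events in a stratum"] if zero_events else []
                rows.extend(_cox_rows(cph, [c], notes + extra))
        uni = pd.DataFrame(rows)
        mask = uni["p"].notna()
        uni["fdr_p"] = np.nan
        if mask.any():
            uni.loc[mask, "fdr_p"] = fdr_adjust(uni.loc[mask, "p"].to_numpy())
        result.cox_univariate = uni

    if multivariate:
        cols = list(multivariate)
        const = [c for c in cols if df[c].nunique() < 2]
        if const:
            raise ValueError(f"constant covariate(s) in the multivariate set: {const}")
        if df["_event"].sum() < len(cols):
            result.warnings.append(
                f"joint model unstable: {int(df['_event'].sum())} events for {len(cols)} covariates"
            )
        try:
            cph, notes = _fit_cox(df, cols, "_time", "_event")
            result.cox_multivariate = pd.DataFrame(_cox_rows(cph, cols, notes))
        except Exception as exc:
            result.warnings.append(f"multivariate fit failed: {exc}")
    return result


# Declarative prognostic-factor menu: name -> (builder over the merged
# clinical + surrogate + score table). Multi-level factors are dummy-encoded
# against an explicit reference (listed in _FACTOR_GROUPS).
FACTOR_MENU: dict[str, callable] = {
    "age_gt_50": lambda d: (d["age_years"] > 50).astype(float),
    "size_gt_1cm": lambda d: (d["tumor_size_cm"] > 1.0).astype(float),
    "grade_3": lambda d: (d["grade"] == 3).astype(float),
    "ki67_gt_30": lambda d: (d["ki67_pct"] > 30).astype(float),
    "basal_marker": lambda d: d["basal_marker_any"].astype(float),
    "mod_ihc_luma": lambda d: (d["modified"] == "LumA").astype(float),  # ref: Basal
    "mod_ihc_lumb": lambda d: (d["modified"] == "LumB").astype(float),
    "mol_luma": lambda d: (d["subtype"] == "LumA").astype(float),  # ref: Basal
    "mol_lumb": lambda d: (d["subtype"] == "LumB").astype(float),
    "mol_her2e": lambda d: (d["subtype"] == "HER2E").astype(float),
    "ror_medium": lambda d: (d["ror_class"] == "medium").astype(float),  # ref: high
    "ror_low": lambda d: (d["ror_class"] == "low").astype(float),
    "rs_medium": lambda d: (d["rs_class"] == "medium").astype(float),  # ref: high
    "rs_low": lambda d: (d["rs_class"] == "low").astype(float),
    "istrong": lambda d: (d["immune_group"] == "istrong").astype(float),
    "tils_high": lambda d: (d["tils_level"] == "high").astype(float),
    "p53_pos": lambda d: d["p53_pos"].astype(float),
    "chemo": lambda d: d["chemo"].astype(float),
    "radio": lambda d: d["radio"].astype(float),
}

# Columns that jointly encode one multi-level factor (fit together univariately).
FACTOR_GROUPS: list[list[str]] = [
    ["age_gt_50"], ["size_gt_1cm"], ["grade_3"], ["ki67_gt_30"], ["basal_marker"],
    ["mod_ihc_luma", "mod_ihc_lumb"], ["mol_luma", "mol_lumb", "mol_her2e"],
    ["ror_medium", "ror_low"], ["rs_medium", "rs_low"],
    ["istrong"], ["tils_high"], ["p53_pos"], ["chemo"], ["radio"],
]


def build_factor_table(merged: pd.DataFrame) -> pd.DataFrame:
    """Dummy-encode every available factor of the menu from a merged cohort table."""
    out = {}
    for name, builder in FACTOR_MENU.items():
        try:
            out[name] = builder(merged)
        except KeyError:
            continue
    return pd.DataFrame(out, index=merged.index)


def fdr_adjust(p_values, family_labels=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, applied within each family."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if family_labels is None:
        return multipletests(p, method="fdr_bh")[1]
    fams = pd.Series(list(family_labels))
    if len(fams) != len(p):
        raise ValueError("family labels must match p-values in length")
    out = np.empty_like(p)
    for fam in fams.unique():
        idx = (fams == fam).to_numpy()
        out[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return out
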