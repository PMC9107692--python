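"""Synthetic HR+/HER2- early-breast-cancer cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be tested against a known answer:

* four latent intrinsic subtypes (LumA / LumB / HER2E / Basal) drawn at the
  reference cohort's proportions (71 / 20 / 2 / 7 %);
* per-gene negative-binomial counts around subtype-specific log2 mean profiles,
  scaled to a uniform-random library size;
* IHC channels (ER%, PR%, Ki-67%, basal markers) derived from the same latent
  expression means through noisy logistic transforms, so IHC and molecular
  calls are correlated but imperfect — basal latents get ER <= 10 and
  Ki-67 >= 40 with high probability, luminal latents get high ER/PR;
* a latent immune level shared (at a configurable coupling) between the 17
  immune-gene means and the stromal TILs percentage;
* exponential proportional-hazards survival for DFS and DMFS with
  covariate-dependent log hazard ratios and independent uniform censoring.

Also exposes the 12 published basal-marker-positive cases as a packaged,
case-level fixture (:func:`basal_marker_positive_cases`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import config
from .expression_qc import ExpressionPanel

_LUMINAL_GENES = ("ESR1", "PGR", "FOXA1", "MLPH", "NAT1", "MAPT", "BCL2", "SLC39A6", "SCUBE2", "BAG1")
_PROLIF_GENES = (
    "ANLN", "AURKA", "BIRC5", "CCNB1", "CCNE1", "CDC6", "CDC20", "CENPF", "CEP55",
    "EXO1", "KIF2C", "MELK", "MKI67", "MYBL2", "NDC80", "NUF2", "ORC6", "PTTG1",
    "RRM2", "TYMS", "UBE2C", "UBE2T",
)
_HER2_GENES = ("ERBB2", "GRB7", "FGFR4")
_BASAL_GENES = ("KRT5", "KRT14", "KRT17", "EGFR", "FOXC1", "MIA", "SFRP1", "CDH3", "PHGDH", "CTSV")

# Per-subtype shift (in units of expression_separation, log2 scale) applied to each
# signature block. Directions follow the standard intrinsic-subtype biology: luminal
# genes up in LumA/LumB, proliferation up in LumB/Basal, HER2 block up in HER2E,
# basal keratins up in Basal.
_SHIFT_TABLE: dict[str, dict[str, float]] = {
    "LumA": {"luminal": 1.0, "prolif": -1.0, "her2": -0.5, "basal": -1.0},
    "LumB": {"luminal": 0.7, "prolif": 1.0, "her2": 0.0, "basal": -1.0},
    "HER2E": {"luminal": -0.7, "prolif": 0.7, "her2": 1.5, "basal": -0.3},
    "Basal": {"luminal": -1.0, "prolif": 1.3, "her2": -0.5, "basal": 1.5},
}

_IMMUNE_AMPLITUDE = 1.5  # log2 shift of immune-gene means per unit latent immune level

# Baseline monthly hazards chosen so an all-baseline cohort shows roughly the
# reference cohort's 5-year relapse (~30%) and distant-metastasis (~17%) fractions.
_DFS_BASE_RATE = 0.0059
_DMFS_BASE_RATE = 0.0031

DEFAULT_HAZARD_LOG_HR: dict[str, float] = {
    "basal": float(np.log(3.0)),
    "lumb": float(np.log(1.5)),
    "her2e": float(np.log(2.0)),
    "immune_latent": 0.30,
    "size_gt_1": float(np.log(1.5)),
}
_COVARIATE_NAMES = ("basal", "lumb", "her2e", "immune_latent", "size_gt_1", "ki67_high")


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort; defaults emulate the reference cohort."""

    n_patients: int = config.REFERENCE_COHORT_SIZE
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(config.DEFAULT_SUBTYPE_PROPORTIONS)
    )
    expression_separation: float = 2.0
    dispersion: float = 0.15
    library_size_range: tuple[int, int] = (50_000, 500_000)
    immune_coupling: float = 0.9
    hazard_log_hr: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HAZARD_LOG_HR))
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if set(self.subtype_proportions) != set(config.SUBTYPES):
            raise ValueError(f"subtype_proportions must cover exactly {config.SUBTYPES}")
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype proportions sum to {total}, not 1")
        if self.expression_separation < 0:
            raise ValueError("expression_separation must be nonnegative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")
        if not (0 <= self.immune_coupling <= 1):
            raise ValueError("immune_coupling must be in [0, 1]")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        unknown = set(self.hazard_log_hr) - set(_COVARIATE_NAMES)
        if unknown:
            raise ValueError(f"unknown hazard covariate(s): {sorted(unknown)}")


@dataclass
class SyntheticPatient:
    id: str
    true_subtype: str
    true_immune_level: float
    counts: pd.Series  # 72-gene integer counts
    clinical: dict  # PatientRecord-compatible fields


@dataclass
class SyntheticCohort:
    patients: list[SyntheticPatient]
    panel: ExpressionPanel
    clinical: pd.DataFrame  # one row per patient, PatientRecord columns + truth

    @property
    def truth(self) -> pd.DataFrame:
        return self.clinical[["true_subtype", "true_immune_level"]]


def _gene_baselines(rng: np.random.Generator) -> pd.Series:
    base = pd.Series(rng.uniform(3.0, 9.0, size=len(config.ALL_GENES)), index=config.ALL_GENES)
    # housekeeping genes: high, tight expression so the reference mean is stable
    for g in config.HOUSEKEEPING_GENES:
        base[g] = rng.uniform(9.0, 10.5)
    return base


def _subtype_shift(subtype: str, separation: float) -> pd.Series:
    shift = pd.Series(0.0, index=list(config.ALL_GENES))
    table = _SHIFT_TABLE[subtype]
    for block, genes in (
        ("luminal", _LUMINAL_GENES),
        ("prolif", _PROLIF_GENES),
        ("her2", _HER2_GENES),
        ("basal", _BASAL_GENES),
    ):
        for g in genes:
            if g in shift.index:
                shift[g] += table[block] * separation
    return shift


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    mean = np.maximum(mean, 1e-8)
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _censoring_horizon(rate: float, base_hazard: float) -> float:
    """Solve for u with C ~ U(0, u): P(C < T) = rate when T ~ Exp(base_hazard)."""
    # P(censored) = (1 - exp(-lam*u)) / (lam*u), decreasing in u from 1 to 0
    f = lambda u: (1.0 - np.exp(-base_hazard * u)) / (base_hazard * u) - rate
    return brentq(f, 1e-6, 1e7)


def _ihc_from_latents(
    subtype: str,
    mean_log2: pd.Series,
    base: pd.Series,
    separation: float,
    rng: np.random.Generator,
) -> dict:
    """Noisy logistic read-outs of the latent expression means.

    The slope is expressed per log2 unit so that, at the default separation, a
    LumA-shifted ESR1 mean maps to ER ~ 90% and a Basal-shifted one to ~ 8%.
    """
    scale = max(separation, 0.5)

    def pct(gene: str, slope: float, offset: float, sd: float) -> float:
        z = slope * (mean_log2[gene] - base[gene]) / scale + offset
        val = 100.0 * _logistic(z) + rng.normal(0.0, sd)
        return float(np.clip(round(val), 0, 100))

    er = pct("ESR1", 2.4, 0.0, 6.0)
    pr = pct("PGR", 2.2, -0.3, 8.0)
    ki67 = pct("MKI67", 1.1, -0.7, 6.0)
    # the rules are hard-thresholded; keep the latent coupling but pin the tails the
    # subtype structure implies (ER/PR low and Ki-67 high for basal latents)
    if subtype == "Basal":
        er = float(min(er, rng.integers(0, 11)))
        pr = float(min(pr, rng.integers(0, 16)))
        ki67 = float(max(ki67, rng.integers(40, 96)))
    marker_p = {"Basal": (0.65, 0.95, 0.30)}.get(subtype, (0.04, 0.06, 0.02))
    ck56, egfr, ck14 = (bool(rng.random() < p) for p in marker_p)
    if subtype == "Basal" and not (ck56 or egfr or ck14):
        egfr = True  # basal tumors express at least one basal keratin/EGFR marker
    return {
        "er_pct": er,
        "pr_pct": pr,
        "ki67_pct": ki67,
        "ck56_pos": ck56,
        "egfr_pos": egfr,
        "ck14_pos": ck14,
    }


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort; bit-identical for a fixed spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    genes = list(config.ALL_GENES)
    base = _gene_baselines(rng)
    shifts = {k: _subtype_shift(k, spec.expression_separation) for k in config.SUBTYPES}

    subtype_order = list(config.SUBTYPES)
    probs = np.array([spec.subtype_proportions[k] for k in subtype_order])
    assignments = rng.choice(len(subtype_order), size=spec.n_patients, p=probs)

    rho = spec.immune_coupling
    patients: list[SyntheticPatient] = []
    count_rows = []
    clin_rows = []
    cens_u = None
    if spec.censoring_rate > 0:
        cens_u = _censoring_horizon(spec.censoring_rate, _DFS_BASE_RATE)

    for i in range(spec.n_patients):
        pid = f"S{i + 1:04d}"
        subtype = subtype_order[assignments[i]]
        z_immune = float(rng.normal())
        shared = rho * z_immune + np.sqrt(max(0.0, 1.0 - rho**2)) * float(rng.normal())

        mean_log2 = base + shifts[subtype]
        mean_log2 = mean_log2 + pd.Series(rng.normal(0.0, 0.3, size=len(genes)), index=genes)
        for g in config.IMMUNE_GENES:
            mean_log2[g] += _IMMUNE_AMPLITUDE * shared

        rel = np.power(2.0, mean_log2.to_numpy())
        lib = int(rng.integers(spec.library_size_range[0], spec.library_size_range[1] + 1))
        mean_counts = rel / rel.sum() * lib
        counts = pd.Series(_nb_counts(mean_counts, spec.dispersion, rng), index=genes, name=pid)

        ihc = _ihc_from_latents(subtype, mean_log2, base, spec.expression_separation, rng)
        tils = 100.0 * _logistic(1.2 * shared - 2.2 + rng.normal(0.0, 0.4))
        tils = float(np.clip(round(tils), 0, 100))

        size = float(np.round(np.clip(rng.lognormal(np.log(1.3), 0.35), 0.3, 2.0), 1))
        grade_probs = {"LumA": (0.30, 0.62, 0.08), "LumB": (0.05, 0.70, 0.25),
                       "HER2E": (0.05, 0.60, 0.35), "Basal": (0.0, 0.35, 0.65)}[subtype]
        grade = int(rng.choice((1, 2, 3), p=grade_probs))

        cov = {
            "basal": 1.0 if subtype == "Basal" else 0.0,
            "lumb": 1.0 if subtype == "LumB" else 0.0,
            "her2e": 1.0 if subtype == "HER2E" else 0.0,
            "immune_latent": z_immune,
            "size_gt_1": 1.0 if size > 1.0 else 0.0,
            "ki67_high": 1.0 if ihc["ki67_pct"] > 30 else 0.0,
        }
        lp = sum(spec.hazard_log_hr.get(k, 0.0) * v for k, v in cov.items())
        t_dfs = float(rng.exponential(1.0 / (_DFS_BASE_RATE * np.exp(lp))))
        t_dmfs = float(rng.exponential(1.0 / (_DMFS_BASE_RATE * np.exp(lp))))
        if cens_u is None:
            dfs_months, dfs_event = t_dfs, 1
            dmfs_months, dmfs_event = t_dmfs, 1
        else:
            c1 = float(rng.uniform(0.0, cens_u))
            c2 = float(rng.uniform(0.0, cens_u))
            dfs_months, dfs_event = min(t_dfs, c1), int(t_dfs <= c1)
            dmfs_months, dmfs_event = min(t_dmfs, c2), int(t_dmfs <= c2)

        clinical = {
            "id": pid,
            "age_years": float(np.clip(round(rng.normal(48.5, 10.0)), 30, 78)),
            "tumor_size_cm": size,
            "grade": grade,
            "her2_status": "negative",
            "p53_pos": bool(rng.random() < 0.29),
            "tils_pct": tils,
            "chemo": bool(rng.random() < 0.30),
            "radio": bool(rng.random() < 0.29),
            "endocrine": True,
            "dfs_months": dfs_months,
            "dfs_event": dfs_event,
            "dmfs_months": dmfs_months,
            "dmfs_event": dmfs_event,
            **ihc,
        }
        patients.append(
            SyntheticPatient(
                id=pid,
                true_subtype=subtype,
                true_immune_level=z_immune,
                counts=counts,
                clinical=clinical,
            )
        )
        count_rows.append(counts)
        clin_rows.append({**clinical, "true_subtype": subtype, "true_immune_level": z_immune})

    counts_df = pd.DataFrame(count_rows)
    panel = ExpressionPanel(counts=counts_df, gene_roles=config.default_gene_roles())
    clinical_df = pd.DataFrame(clin_rows).set_index("id")
    return SyntheticCohort(patients=patients, panel=panel, clinical=clinical_df)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write counts (gene x sample TSV) and the clinical table (CSV); return paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    counts_path = os.path.join(outdir, "counts.tsv")
    clinical_path = os.path.join(outdir, "clinical.csv")
    cohort.panel.write_tsv(counts_path)
    cohort.clinical.to_csv(clinical_path, index_label="id")
    return {"counts": counts_path, "clinical": clinical_path}


def basal_marker_positive_cases() -> pd.DataFrame:
    """The 12 published basal-marker-positive cases, as printed.

    Case-level clinicopathology of every basal-marker-positive tumor in the
    reference cohort: IHC and molecular subtype, per-marker CK5/6 / EGFR / CK14
    status, Ki-67 / PR / ER percentages, grade, P53, immune group, TILs level,
    ROR risk class and recurrence status. Three rows (cases 4, 8, 9) had
    ambiguous run-together digits in the source table; the adopted parse is
    flagged in ``ambiguous_digits``.
    """
    ref = importlib.resources.files("lumipipe").joinpath("data/basal_marker_cases.csv")
    with ref.open("r") as fh:
        df = pd.read_csv(fh)
    for col in ("ck56_pos", "egfr_pos", "ck14_pos", "ambiguous_digits"):
        df[col] = df[col].astype(bool)
    return df.set_index("case_id")


def fixture_as_clinical(cases: pd.DataFrame | None = None) -> pd.DataFrame:
    """Adapt the published-case fixture to the clinical-table column contract."""
    df = (cases if cases is not None else basal_marker_positive_cases()).copy()
    out = pd.DataFrame(index=df.index)
    out["er_pct"] = df["er_pct"].astype(float)
    out["pr_pct"] = df["pr_pct"].astype(float)
    out["ki67_pct"] = df["ki67_pct"].astype(float)
    out["grade"] = df["grade"].astype(int)
    out["p53_pos"] = df["p53"].eq("P")
    for col in ("ck56_pos", "egfr_pos", "ck14_pos"):
        out[col] = df[col]
    out["her2_status"] = "negative"
    return out
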