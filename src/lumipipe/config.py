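"""Gene-panel definitions, model constants and their YAML (de)serialization.

Every numeric constant the pipeline uses — centroid-correlation weights for the
risk-of-recurrence score, the 21-gene recurrence-score group weights and floors,
risk-class boundaries, the immune and TILs cutoffs — lives here as inspectable
data with a documented provenance, and can be overridden from a YAML file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

SUBTYPES = ("LumA", "LumB", "HER2E", "Basal")

ROLE_SUBTYPE = "subtype"
ROLE_IMMUNE = "immune"
ROLE_HOUSEKEEPING = "housekeeping"


def _load_default_panel() -> dict:
    ref = importlib.resources.files("lumipipe").joinpath("data/gene_panel.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


_PANEL = _load_default_panel()

SUBTYPE_GENES: tuple[str, ...] = tuple(_PANEL["subtype_genes"])
IMMUNE_GENES: tuple[str, ...] = tuple(_PANEL["immune_genes"])
HOUSEKEEPING_GENES: tuple[str, ...] = tuple(_PANEL["housekeeping_genes"])
PROLIFERATION_GENES: tuple[str, ...] = tuple(_PANEL["proliferation_genes"])
ALL_GENES: tuple[str, ...] = SUBTYPE_GENES + IMMUNE_GENES + HOUSEKEEPING_GENES


def default_gene_roles() -> dict[str, str]:
    """Gene -> role mapping for the default 50/17/5 panel."""
    roles: dict[str, str] = {}
    for g in SUBTYPE_GENES:
        roles[g] = ROLE_SUBTYPE
    for g in IMMUNE_GENES:
        roles[g] = ROLE_IMMUNE
    for g in HOUSEKEEPING_GENES:
        roles[g] = ROLE_HOUSEKEEPING
    return roles


def load_gene_roles(path) -> dict[str, str]:
    """Read a gene-role panel from a YAML file with subtype/immune/housekeeping lists."""
    with open(path) as fh:
        panel = yaml.safe_load(fh)
    roles: dict[str, str] = {}
    for key, role in (
        ("subtype_genes", ROLE_SUBTYPE),
        ("immune_genes", ROLE_IMMUNE),
        ("housekeeping_genes", ROLE_HOUSEKEEPING),
    ):
        for g in panel.get(key, []):
            if g in roles:
                raise ValueError(f"gene {g!r} listed under more than one role")
            roles[g] = role
    return roles


# --- Risk-of-recurrence (proliferation-weighted) constants -------------------------
# Centroid-correlation weights in the style of the published subtype-correlation ROR
# model, with the node-negative low/medium/high class boundaries of that method; the
# 0-100 rescaling is the package's own affine convention for the housekeeping-free
# correlation + proliferation raw score.
ROR_COEFFICIENTS: dict[str, float] = {
    "LumA": -0.34,
    "LumB": 0.23,
    "HER2E": 0.12,
    "Basal": 0.05,
}
ROR_PROLIFERATION_WEIGHT: float = 0.32
ROR_RESCALE: tuple[float, float] = (50.0, 55.0)  # score = offset + scale * raw
ROR_THRESHOLDS: tuple[float, float] = (29.0, 53.0)  # low < 29 <= medium < 53 <= high

# --- 21-gene recurrence-score constants --------------------------------------------
# Group structure, weights, floors and the affine 0-100 map follow the published
# 21-gene method; expression enters on a housekeeping-referenced log2 scale shifted
# by +10 so that the published floors (8, 6.5) and neutral ranges are meaningful.
RS_REFERENCE_OFFSET: float = 10.0
RS_GROUPS: dict[str, dict[str, float]] = {
    # weighted means; weights sum to the divisor used in the published group scores
    "her2": {"GRB7": 0.9, "ERBB2": 0.1},
    "er": {"ESR1": 0.2, "PGR": 0.3, "BCL2": 0.25, "SCUBE2": 0.25},
    "proliferation": {"AURKA": 0.2, "BIRC5": 0.2, "CCNB1": 0.2, "MKI67": 0.2, "MYBL2": 0.2},
    "invasion": {"CTSV": 0.5, "MMP11": 0.5},
    "cd68": {"CD68": 1.0},
    "gstm1": {"GSTM1": 1.0},
    "bag1": {"BAG1": 1.0},
}
RS_GROUP_FLOORS: dict[str, float] = {"her2": 8.0, "proliferation": 6.5}
RS_COEFFICIENTS: dict[str, float] = {
    "her2": 0.47,
    "er": -0.34,
    "proliferation": 1.04,
    "invasion": 0.10,
    "cd68": 0.05,
    "gstm1": -0.08,
    "bag1": -0.07,
}
RS_UNSCALED_MAP: tuple[float, float] = (-134.0, 20.0)  # RS = clip(a + b*RSu, 0, 100)
RS_THRESHOLDS: tuple[float, float] = (18.0, 31.0)  # low < 18 <= medium < 31 <= high

# --- Immune / TILs cutoff presets --------------------------------------------------
IMMUNE_CUTOFF_PRESET: float = 45.5  # inclusive: score >= cutoff is "istrong"
TILS_CUTOFF_PRESET: float = 13.5  # strict: TILs% > cutoff is "high"

# --- IHC surrogate thresholds ------------------------------------------------------
MARKER_POSITIVE_PCT: float = 1.0  # strictly greater than 1% stained cells
KI67_LOW_MAX: float = 30.0  # St. Gallen "low" is <= 30%
PR_LOW_MAX: float = 20.0  # St. Gallen luminal-B branch: PR < 20%
BASAL_KI67_MIN: float = 40.0  # modified rule: Ki-67 >= 40%
BASAL_ER_MAX: float = 10.0  # modified rule: ER <= 10%

# --- Reference cohort marginals ----------------------------------------------------
# Case-level composition of the published 87-patient HR+/HER2- stage 1 cohort that the
# generator defaults emulate: intrinsic-subtype counts and basal-marker prevalence.
REFERENCE_COHORT_SIZE: int = 87
REFERENCE_SUBTYPE_COUNTS: dict[str, int] = {"LumA": 62, "LumB": 17, "HER2E": 2, "Basal": 6}
REFERENCE_BASAL_MARKER_POSITIVE: int = 12
DEFAULT_SUBTYPE_PROPORTIONS: dict[str, float] = {
    "LumA": 0.71,
    "LumB": 0.20,
    "HER2E": 0.02,
    "Basal": 0.07,
}


@dataclass
class ModelConstants:
    """Bundle of every overridable scoring constant, YAML round-trippable."""

    ror_coefficients: dict[str, float] = field(default_factory=lambda: dict(ROR_COEFFICIENTS))
    ror_proliferation_weight: float = ROR_PROLIFERATION_WEIGHT
    ror_rescale: tuple[float, float] = ROR_RESCALE
    ror_thresholds: tuple[float, float] = ROR_THRESHOLDS
    rs_groups: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in RS_GROUPS.items()}
    )
    rs_group_floors: dict[str, float] = field(default_factory=lambda: dict(RS_GROUP_FLOORS))
    rs_coefficients: dict[str, float] = field(default_factory=lambda: dict(RS_COEFFICIENTS))
    rs_unscaled_map: tuple[float, float] = RS_UNSCALED_MAP
    rs_thresholds: tuple[float, float] = RS_THRESHOLDS
    rs_reference_offset: float = RS_REFERENCE_OFFSET
    immune_cutoff: float = IMMUNE_CUTOFF_PRESET
    tils_cutoff: float = TILS_CUTOFF_PRESET
    correlation_method: str = "spearman"
    proliferation_genes: tuple[str, ...] = PROLIFERATION_GENES

    def to_yaml(self, path) -> None:
        payload = {
            "ror_coefficients": self.ror_coefficients,
            "ror_proliferation_weight": self.ror_proliferation_weight,
            "ror_rescale": list(self.ror_rescale),
            "ror_thresholds": list(self.ror_thresholds),
            "rs_groups": self.rs_groups,
            "rs_group_floors": self.rs_group_floors,
            "rs_coefficients": self.rs_coefficients,
            "rs_unscaled_map": list(self.rs_unscaled_map),
            "rs_thresholds": list(self.rs_thresholds),
            "rs_reference_offset": self.rs_reference_offset,
            "immune_cutoff": self.immune_cutoff,
            "tils_cutoff": self.tils_cutoff,
            "correlation_method": self.correlation_method,
            "proliferation_genes": list(self.proliferation_genes),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ModelConstants":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        kwargs = dict(payload)
        for key in ("ror_rescale", "ror_thresholds", "rs_unscaled_map", "rs_thresholds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "proliferation_genes" in kwargs:
            kwargs["proliferation_genes"] = tuple(kwargs["proliferation_genes"])
        return cls(**kwargs)
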