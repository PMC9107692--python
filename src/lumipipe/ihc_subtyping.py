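"""IHC marker conventions, St. Gallen surrogate and the modified basal-like rule.

Positivity for ER/PR and the basal markers (CK5/6, EGFR, CK14) means staining in
strictly more than 1% of tumor cells. The St. Gallen surrogate splits
ER-positive / HER2-negative tumors into luminal A (PR-positive at >= 20% and
Ki-67 <= 30%) and luminal B (PR < 20% or Ki-67 > 30%). The modified surrogate
first tests a basal-like rule — any basal marker positive AND Ki-67 >= 40% AND
ER <= 10% — and only on failure falls through to the St. Gallen split, so a
basal call always carries a positive basal marker. Stromal TILs are
dichotomized at a ROC-derived cutoff (default 13.5%, strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config


@dataclass
class PatientRecord:
    """Clinical, IHC and follow-up fields for one ER+/HER2- patient."""

    id: str
    er_pct: float
    pr_pct: float
    ki67_pct: float
    ck56_pos: bool = False
    egfr_pos: bool = False
    ck14_pos: bool = False
    age_years: float | None = None
    tumor_size_cm: float | None = None
    grade: int | None = None
    her2_status: str = "negative"
    p53_pos: bool | None = None
    tils_pct: float | None = None
    chemo: bool | None = None
    radio: bool | None = None
    endocrine: bool | None = None
    dfs_months: float | None = None
    dfs_event: int | None = None
    dmfs_months: float | None = None
    dmfs_event: int | None = None

    def __post_init__(self) -> None:
        for name in ("er_pct", "pr_pct", "ki67_pct", "tils_pct"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 100):
                raise ValueError(f"{name}={v} outside [0, 100] for patient {self.id!r}")
        if self.grade is not None and self.grade not in (1, 2, 3):
            raise ValueError(f"grade must be 1, 2 or 3, got {self.grade!r}")
        if self.her2_status != "negative":
            raise ValueError("cohort definition requires HER2-negative records")
        for name in ("dfs_months", "dmfs_months"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"negative {name} for patient {self.id!r}")
        for name in ("dfs_event", "dmfs_event"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")

    @classmethod
    def from_series(cls, row: pd.Series, id=None) -> "PatientRecord":
        known = {f for f in cls.__dataclass_fields__}
        kw = {k: row[k] for k in row.index if k in known and pd.notna(row[k])}
        for flag in ("ck56_pos", "egfr_pos", "ck14_pos", "p53_pos", "chemo", "radio", "endocrine"):
            if flag in kw:
                kw[flag] = bool(kw[flag])
        if "grade" in kw:
            kw["grade"] = int(kw["grade"])
        kw.setdefault("id", str(id) if id is not None else str(row.name))
        return cls(**kw)


@dataclass
class SurrogateCall:
    st_gallen: str | None  # LumA or LumB (None when ER-negative blocks the split)
    modified: str  # LumA, LumB or Basal
    basal_marker_any: bool
    tils_level: str | None  # low / high, None when TILs not recorded

    def __post_init__(self) -> None:
        if self.modified == "Basal" and not self.basal_marker_any:
            raise ValueError("a Basal surrogate call requires a positive basal marker")


def marker_positive(value, threshold_pct: float = config.MARKER_POSITIVE_PCT) -> bool:
    """Staining positivity: strictly more than ``threshold_pct`` % of cells.

    Booleans pass through unchanged (pre-dichotomized marker columns).
    """
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if not (0 <= value <= 100):
        raise ValueError(f"staining percentage {value} outside [0, 100]")
    return value > threshold_pct


def basal_marker_any(record: PatientRecord) -> bool:
    return bool(record.ck56_pos or record.egfr_pos or record.ck14_pos)


def st_gallen_subtype(record: PatientRecord) -> str:
    """St. Gallen ER+/HER2- split: LumB iff PR < 20% or Ki-67 > 30%, else LumA."""
    if not marker_positive(record.er_pct):
        raise ValueError(
            f"patient {record.id!r} is ER-negative ({record.er_pct}%); "
            "the St. Gallen luminal split applies only to ER-positive tumors"
        )
    if record.pr_pct < config.PR_LOW_MAX or record.ki67_pct > config.KI67_LOW_MAX:
        return "LumB"
    return "LumA"


def modified_ihc_subtype(record: PatientRecord) -> str:
    """Basal-first surrogate: marker+ AND Ki-67 >= 40 AND ER <= 10, else St. Gallen."""
    if (
        basal_marker_any(record)
        and record.ki67_pct >= config.BASAL_KI67_MIN
        and record.er_pct <= config.BASAL_ER_MAX
    ):
        return "Basal"
    return st_gallen_subtype(record)


def tils_level(record_or_pct, cutoff: float = config.TILS_CUTOFF_PRESET) -> str:
    """Dichotomize stromal TILs: high iff TILs% strictly exceeds the cutoff."""
    if not (0 < cutoff < 100):
        raise ValueError(f"TILs cutoff {cutoff} outside (0, 100)")
    pct = record_or_pct.tils_pct if isinstance(record_or_pct, PatientRecord) else record_or_pct
    if pct is None:
        raise ValueError("TILs percentage not recorded")
    if not (0 <= pct <= 100):
        raise ValueError(f"TILs percentage {pct} outside [0, 100]")
    return "high" if pct > cutoff else "low"


def surrogate_call(record: PatientRecord, tils_cutoff: float = config.TILS_CUTOFF_PRESET) -> SurrogateCall:
    """All surrogate outputs for one record; tolerates ER-negative basal cases."""
    modified = modified_ihc_subtype(record)
    try:
        sg = st_gallen_subtype(record)
    except ValueError:
        # ER-negative records are outside the St. Gallen cohort definition but can
        # still fire the basal rule (which itself demands ER <= 10%).
        if modified != "Basal":
            raise
        sg = None
    tl = None if record.tils_pct is None else tils_level(record, tils_cutoff)
    return SurrogateCall(
        st_gallen=sg,
        modified=modified,
        basal_marker_any=basal_marker_any(record),
        tils_level=tl,
    )


def surrogate_table(clinical: pd.DataFrame, tils_cutoff: float = config.TILS_CUTOFF_PRESET) -> pd.DataFrame:
    """Vectorize :func:`surrogate_call` over a clinical table (one row per patient)."""
    rows = {}
    for idx, row in clinical.iterrows():
        rec = PatientRecord.from_series(row, id=idx)
        call = surrogate_call(rec, tils_cutoff=tils_cutoff)
        rows[idx] = {
            "st_gallen": call.st_gallen,
            "modified": call.modified,
            "basal_marker_any": call.basal_marker_any,
            "tils_level": call.tils_level,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
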