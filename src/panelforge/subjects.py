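"""Subject metadata, CSF biomarker values and A/T biological classification.

Subjects carry an amyloid (A) and phosphorylated-tau (T) status derived
from CSF biomarker ratios compared against study-specific thresholds —
e.g. p-Tau/Abeta42 > 0.023 for the ADNI cohort, t-Tau/Abeta42 > 0.226 for
the Bangs cohort — plus a clinical status (CU / MCI / dementia / PD) and
basic covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "CLINICAL_STATES",
    "SubjectRecord",
    "ATRule",
    "ADNI_AT_RULE",
    "BANGS_AT_RULE",
    "classify_at_status",
    "read_metadata",
    "read_visits",
]

CLINICAL_STATES = ("CU", "MCI", "dementia", "PD", "unknown")


@dataclass
class SubjectRecord:
    subject_id: str
    cohort_id: str
    amyloid_status: str = "unknown"  # pos | neg | unknown
    tau_status: str = "unknown"
    clinical_status: str = "unknown"
    age: Optional[float] = None
    sex: str = "unknown"  # F | M | unknown
    csf: Optional[dict] = None  # {abeta42, abeta40, ttau, ptau} -> pg/mL
    visits: Optional[List[Tuple[float, str]]] = None  # (years since baseline, clinical_status)

    def __post_init__(self) -> None:
        if self.age is not None and not self.age > 0:
            raise ValueError(f"subject {self.subject_id}: age must be > 0")
        if self.csf:
            bad = {k: v for k, v in self.csf.items() if v is not None and v <= 0}
            if bad:
                raise ValueError(f"subject {self.subject_id}: non-positive CSF values {bad}")
        if self.visits:
            times = [t for t, _ in self.visits]
            if any(b < a for a, b in zip(times, times[1:])):
                raise ValueError(f"subject {self.subject_id}: visit times must be non-decreasing")

    @property
    def is_at_positive(self) -> bool:
        return self.amyloid_status == "pos" and self.tau_status == "pos"

    @property
    def is_at_negative(self) -> bool:
        return self.amyloid_status == "neg" and self.tau_status == "neg"


@dataclass(frozen=True)
class ATRule:
    """Threshold rule turning CSF biomarkers into A/T status.

    ``numerator``/``denominator`` name biomarkers in the subject's ``csf``
    map; ``denominator=None`` compares a single biomarker.  Comparison is
    strict in the stated ``direction``; ``assigns`` says whether a positive
    call sets both A and T (the ratio rules) or the amyloid axis only.
    """

    numerator: str
    denominator: Optional[str]
    threshold: float
    direction: str = "greater_is_positive"  # or less_is_positive
    assigns: str = "AT_joint"  # or A_only

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")
        if self.direction not in ("greater_is_positive", "less_is_positive"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.assigns not in ("AT_joint", "A_only"):
            raise ValueError(f"unknown assigns {self.assigns!r}")


#: ADNI: biological classification by p-Tau181/Abeta42 ratio > 0.023.
ADNI_AT_RULE = ATRule(numerator="ptau", denominator="abeta42", threshold=0.023)
#: Bangs: t-Tau/Abeta42 ratio threshold 0.226.
BANGS_AT_RULE = ATRule(numerator="ttau", denominator="abeta42", threshold=0.226)


def classify_at_status(subjects: Sequence[SubjectRecord], rule: ATRule) -> List[SubjectRecord]:
    """Assign A/T status from CSF biomarkers by a strict threshold rule.

    Deterministic and total on subjects with complete biomarkers; subjects
    lacking an input stay ``unknown``.  Values exactly at the threshold
    fall on the negative side (strict inequality).
    """
    out = []
    for s in subjects:
        csf = s.csf or {}
        num = csf.get(rule.numerator)
        if rule.denominator is not None:
            den = csf.get(rule.denominator)
            if num is None or den is None:
                out.append(s)
                continue
            if den == 0:
                raise ZeroDivisionError(
                    f"subject {s.subject_id}: denominator {rule.denominator} is 0")
            value = num / den
        else:
            if num is None:
                out.append(s)
                continue
            value = num
        if rule.direction == "greater_is_positive":
            positive = value > rule.threshold
        else:
            positive = value < rule.threshold
        status = "pos" if positive else "neg"
        if rule.assigns == "AT_joint":
            out.append(replace(s, amyloid_status=status, tau_status=status))
        else:
            out.append(replace(s, amyloid_status=status))
    return out


def _norm(x) -> str:
    return "unknown" if x is None or (isinstance(x, float) and pd.isna(x)) or x == "" else str(x)


def read_metadata(path, format: Optional[str] = None) -> List[SubjectRecord]:
    """Read subject metadata from a TSV/CSV table.

    Expected columns: subject_id, cohort_id, amyloid_status, tau_status,
    clinical_status, age, sex, abeta42, abeta40, ttau, ptau (biomarker
    columns optional).
    """
    sep = "," if (format == "csv" or str(path).endswith(".csv")) else "\t"
    df = pd.read_csv(path, sep=sep)
    records = []
    csf_cols = [c for c in ("abeta42", "abeta40", "ttau", "ptau") if c in df.columns]
    for _, row in df.iterrows():
        csf = {c: float(row[c]) for c in csf_cols if pd.notna(row[c])} or None
        age = float(row["age"]) if "age" in df.columns and pd.notna(row.get("age")) else None
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            cohort_id=str(row.get("cohort_id", "unknown")),
            amyloid_status=_norm(row.get("amyloid_status")),
            tau_status=_norm(row.get("tau_status")),
            clinical_status=_norm(row.get("clinical_status")),
            age=age,
            sex=_norm(row.get("sex")),
            csf=csf,
        ))
    return records


def read_visits(path, subjects: Optional[Sequence[SubjectRecord]] = None,
                format: Optional[str] = None) -> pd.DataFrame:
    """Read a long-format visits table (subject_id, time_years,
    clinical_status[, amyloid_status, tau_status]).

    If ``subjects`` is given, their ``visits`` lists are populated in
    place (sorted by time).
    """
    sep = "," if (format == "csv" or str(path).endswith(".csv")) else "\t"
    df = pd.read_csv(path, sep=sep)
    df = df.sort_values(["subject_id", "time_years"]).reset_index(drop=True)
    if subjects is not None:
        by_id = {s.subject_id: s for s in subjects}
        for sid, grp in df.groupby("subject_id"):
            s = by_id.get(str(sid))
            if s is not None:
                s.visits = list(zip(grp["time_years"].astype(float), grp["clinical_status"]))
    return df
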