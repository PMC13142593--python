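"""Prognostic evaluation: median-split stratification, Cox proportional
hazards and Kaplan-Meier curves for clinical progression.

Subjects are split into high/low panel-score groups at the sample median
and the relative hazard of progressing (CU -> A+T+ MCI, or A+T+ MCI ->
A+T+ dementia) is estimated by a Cox model adjusted for age and sex, with
Wald inference on the group coefficient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from statsmodels.duration.hazard_regression import PHReg

logger = logging.getLogger(__name__)

__all__ = [
    "MAX_FOLLOWUP_YEARS",
    "MIN_FOLLOWUP_YEARS",
    "SurvivalRecord",
    "HazardResult",
    "median_stratify",
    "cox_fit",
    "kaplan_meier",
    "build_transition_dataset",
    "TRANSITIONS",
]

#: Follow-up window for inclusion: six months to 12.5 years.
MIN_FOLLOWUP_YEARS = 0.5
MAX_FOLLOWUP_YEARS = 12.5


@dataclass
class SurvivalRecord:
    """One subject's right-censored time to clinical progression."""

    subject_id: str
    time: float  # years to event or censoring
    event: int  # 1 = progressed, 0 = censored
    group: str  # high | low panel score
    age: Optional[float] = None
    sex: Optional[str] = None  # F | M

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"subject {self.subject_id}: time must be > 0")
        if self.event not in (0, 1):
            raise ValueError(f"subject {self.subject_id}: event must be 0 or 1")
        if self.group not in ("high", "low"):
            raise ValueError(f"subject {self.subject_id}: group must be high/low")


@dataclass
class HazardResult:
    """Cox fit summary for the high- vs low-score contrast."""

    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    coef: float
    se: float
    n_high: int
    n_low: int
    n_events: int
    transition: str = ""
    covariates: tuple = ()
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "transition": self.transition, "hr": self.hr, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "wald_p": self.wald_p, "coef": self.coef,
            "se": self.se, "n_high": self.n_high, "n_low": self.n_low,
            "n_events": self.n_events, "covariates": list(self.covariates),
            "warnings": self.warnings,
        }


def median_stratify(scores: Dict[str, float]) -> Dict[str, str]:
    """Split subjects at the sample median of their panel scores.

    Scores strictly above the mid-rank median go to ``high``; scores at or
    below (including ties at the median) go to ``low``.
    """
    if len(scores) < 2:
        raise ValueError("median stratification needs >= 2 subjects")
    values = np.asarray(list(scores.values()), dtype=float)
    med = float(np.median(values))
    if np.all(values == values[0]):
        raise ValueError("all scores identical; no stratification possible")
    return {sid: ("high" if v > med else "low") for sid, v in scores.items()}


def _records_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "time": [r.time for r in records],
        "event": [r.event for r in records],
        "group": [r.group for r in records],
        "age": [r.age for r in records],
        "sex": [r.sex for r in records],
    })


def cox_fit(records: Sequence[SurvivalRecord], covariates: Sequence[str] = ("age", "sex"),
            ties: str = "breslow", transition: str = "") -> HazardResult:
    """Cox proportional-hazards fit of the high/low group contrast.

    Partial-likelihood estimation with Breslow tie handling by default
    (Efron by flag); HR = exp(group coefficient); 95% CI from the Wald
    normal approximation; two-sided Wald p.  If all events fall in one
    group the partial likelihood is monotone, so the fit falls back to a
    lightly ridge-penalized estimate with a warning.
    """
    records = list(records)
    df = _records_frame(records)
    n_events = int(df["event"].sum())
    if n_events < 1:
        raise ValueError("no events in data; cannot fit Cox model")
    n_high = int((df["group"] == "high").sum())
    n_low = int((df["group"] == "low").sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("both groups must be present")
    if len(records) <= 2:
        raise ValueError("degenerate fit: need more than 2 records")

    cols = ["group_high"]
    X = [(df["group"] == "high").astype(float).to_numpy()]
    notes: List[str] = []
    for cov in covariates:
        if cov == "age":
            if df["age"].isna().any():
                notes.append("age missing for some subjects; covariate dropped")
                continue
            age = df["age"].astype(float)
            if age.nunique() < 2:
                notes.append("age constant; covariate dropped")
                continue
            X.append((age - age.mean()).to_numpy())
            cols.append("age")
        elif cov == "sex":
            if df["sex"].isna().any():
                notes.append("sex missing for some subjects; covariate dropped")
                continue
            if df["sex"].nunique() < 2:
                notes.append("sex constant; covariate dropped")
                continue
            X.append((df["sex"] == "F").astype(float).to_numpy())
            cols.append("sex_F")
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    exog = np.column_stack(X)

    events_by_group = df.groupby("group")["event"].sum()
    monotone = (events_by_group.get("high", 0) == 0) or (events_by_group.get("low", 0) == 0)

    model = PHReg(df["time"].to_numpy(), exog, status=df["event"].to_numpy(), ties=ties)
    if monotone:
        notes.append("all events in one group: monotone likelihood; ridge-penalized fallback")
        logger.warning("cox_fit: %s", notes[-1])
        res = model.fit_regularized(alpha=1e-2, L1_wt=0.0)
        # fit_regularized gives no covariance; use observed information at
        # the penalized estimate for an approximate Wald SE
        hess = -model.hessian(res.params)
        cov = np.linalg.pinv(hess + 1e-2 * np.eye(hess.shape[0]))
        bse = np.sqrt(np.diag(cov))
        params = res.params
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=False)
        params = res.params
        bse = res.bse

    coef = float(params[0])
    se = float(bse[0])
    from scipy.stats import norm
    z = coef / se if se > 0 else np.inf
    p = float(2 * norm.sf(abs(z)))
    return HazardResult(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        wald_p=p, coef=coef, se=se,
        n_high=n_high, n_low=n_low, n_events=n_events,
        transition=transition, covariates=tuple(cols[1:]), warnings=notes,
    )


def kaplan_meier(records: Sequence[SurvivalRecord]) -> Dict[str, pd.DataFrame]:
    """Product-limit survival curves per group.

    Returns, per group, a step function table (time, survival, at_risk,
    censored) with S(0)=1 and steps at event times only.
    """
    df = _records_frame(list(records))
    out: Dict[str, pd.DataFrame] = {}
    for grp, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        tab = kmf.survival_function_.rename(columns={"KM_estimate": "survival"})
        tab = tab.reset_index().rename(columns={"timeline": "time", "index": "time"})
        ev = kmf.event_table
        tab["at_risk"] = ev["at_risk"].to_numpy()
        tab["censored"] = ev["censored"].to_numpy()
        out[str(grp)] = tab
    return out


TRANSITIONS = {
    # origin state at baseline -> (is_event_state predicate description)
    "CU_to_ATMCI": ("CU", "MCI"),
    "ATMCI_to_ATdementia": ("MCI", "dementia"),
}


def build_transition_dataset(subjects, transition: str, scores: Dict[str, float],
                             groups: Optional[Dict[str, str]] = None) -> List[SurvivalRecord]:
    """Assemble right-censored records for one clinical transition.

    Eligible subjects start at the transition's origin state, have at
    least two visits and follow-up inside the 0.5-12.5 year window.  The
    event is the first visit at the destination state; otherwise the
    subject is censored at the last visit.  ``scores`` are baseline panel
    scores; ``groups`` (high/low) defaults to a median split of the
    eligible subjects' scores.
    """
    if transition not in TRANSITIONS:
        raise ValueError(f"unknown transition {transition!r}; expected {sorted(TRANSITIONS)}")
    origin, destination = TRANSITIONS[transition]
    eligible = []
    for s in subjects:
        if not s.visits or len(s.visits) < 2:
            continue
        baseline_state = s.visits[0][1]
        if baseline_state != origin:
            continue
        follow = s.visits[-1][0] - s.visits[0][0]
        if not (MIN_FOLLOWUP_YEARS <= follow <= MAX_FOLLOWUP_YEARS):
            continue
        if s.subject_id not in scores:
            continue
        states = [st for _, st in s.visits]
        if any(states[i] == destination and states[i + 1] == origin for i in range(len(states) - 1)):
            logger.warning("subject %s: non-monotone state sequence; first qualifying "
                           "event used", s.subject_id)
        event_time = None
        t0 = s.visits[0][0]
        for t, state in s.visits[1:]:
            if state == destination:
                event_time = t - t0
                break
        eligible.append((s, event_time, follow))
    if not eligible:
        return []
    if groups is None:
        groups = median_stratify({s.subject_id: scores[s.subject_id] for s, _, _ in eligible})
    records = []
    for s, event_time, follow in eligible:
        if event_time is not None and event_time > 0:
            records.append(SurvivalRecord(s.subject_id, event_time, 1,
                                          groups[s.subject_id], s.age, s.sex))
        else:
            records.append(SurvivalRecord(s.subject_id, follow, 0,
                                          groups[s.subject_id], s.age, s.sex))
    return records
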