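"""Packaged cohort registry: demographics of the discovery, training,
validation and differential-diagnosis cohorts, with roll-up arithmetic.

The registry records, per study: total n, the A/T strata (A-T-, A+T+,
A-T- CU, A+T+ CI, A+T+ MCI, A+T+ dementia), sex counts and platform.
``summarize_registry`` reproduces the per-role totals (e.g. 759 discovery
subjects, 1,198 validation subjects) from the per-study rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, List, Optional

logger = logging.getLogger(__name__)

__all__ = ["CohortRegistryEntry", "load_cohort_registry", "summarize_registry"]

ROLES = ("discovery", "training", "validation", "differential")

_COUNT_FIELDS = (
    "n_total", "n_aneg_tneg", "n_apos_tpos", "n_aneg_tneg_cu",
    "n_apos_tpos_ci", "n_apos_tpos_mci", "n_apos_tpos_dementia",
    "n_female", "n_male",
)


@dataclass(frozen=True)
class CohortRegistryEntry:
    study: str
    role: str
    platform: str
    n_total: int
    n_aneg_tneg: Optional[int] = None
    n_apos_tpos: Optional[int] = None
    n_aneg_tneg_cu: Optional[int] = None
    n_apos_tpos_ci: Optional[int] = None
    n_apos_tpos_mci: Optional[int] = None
    n_apos_tpos_dementia: Optional[int] = None
    n_female: Optional[int] = None
    n_male: Optional[int] = None
    at_rule: Optional[str] = None
    notes: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        for f in _COUNT_FIELDS[1:]:
            v = getattr(self, f)
            if v is not None and v > self.n_total:
                raise ValueError(f"{self.study}: {f}={v} exceeds n_total={self.n_total}")


def load_cohort_registry(path=None) -> List[CohortRegistryEntry]:
    """Load the packaged registry (or a user-supplied JSON in the same
    schema)."""
    if path is None:
        text = resources.files("panelforge.data").joinpath("cohort_registry.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    blob = json.loads(text)
    return [CohortRegistryEntry(**entry) for entry in blob["entries"]]


def summarize_registry(registry: Iterable[CohortRegistryEntry], roles, field: str) -> int:
    """Sum ``field`` over registry entries whose role is in ``roles``.

    Missing (NA) entries contribute 0 and are logged, matching how the
    source table's totals treat studies that did not report a stratum.
    """
    if field not in _COUNT_FIELDS:
        raise KeyError(f"unknown field {field!r}; expected one of {_COUNT_FIELDS}")
    roles = {roles} if isinstance(roles, str) else set(roles)
    unknown = roles - set(ROLES)
    if unknown:
        raise ValueError(f"unknown roles {sorted(unknown)}")
    total = 0
    for e in registry:
        if e.role not in roles:
            continue
        v = getattr(e, field)
        if v is None:
            logger.info("registry: %s has no %s; contributing 0", e.study, field)
            continue
        total += v
    return total
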