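"""Synthetic multi-cohort generator.

Emulates the statistical structure the analysis assumes: several cohorts
measured on distinct platforms, a shared set of truly dysregulated
proteins with per-study effect sizes and directions, study-specific noise
hits, platform gain/offset, per-protein missingness, binary disease labels
with A/T substructure, and right-censored progression times whose hazard
depends on group membership.  Protein abundances are Gaussian on the log2
scale; event times are exponential so the hazard ratio is controlled in
closed form.  All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import CohortMatrix
from .prognosis import MAX_FOLLOWUP_YEARS, MIN_FOLLOWUP_YEARS, SurvivalRecord
from .subjects import SubjectRecord

__all__ = [
    "DETECTABILITY_FLOOR",
    "SimStudyConfig",
    "SimProgressionConfig",
    "simulate_cohort",
    "simulate_multi_study",
    "simulate_progression_cohort",
]

#: Planted effects must clear the differential-abundance filter boundary
#: (|log2 FC| >= 0.6) to count as detectable truth.
DETECTABILITY_FLOOR = 0.6


@dataclass
class SimStudyConfig:
    """Parameters for one simulated cohort.

    ``planted_markers`` is a list of (gene_symbol, effect) pairs; the
    effect is the case-minus-control shift in log2 units and its sign is
    the direction of dysregulation.
    """

    cohort_id: str = "sim"
    platform: str = "mass_spec"
    n_case: int = 30
    n_control: int = 30
    n_proteins: int = 300
    seed: int = 0
    planted_markers: List[Tuple[str, float]] = field(default_factory=list)
    noise_sd: float = 0.4
    study_specific_hits: int = 0
    study_specific_effect: float = 1.0
    missing_beta: Tuple[float, float] = (1.0, 19.0)  # Beta params; mean 5% missing
    platform_offset: float = 0.0
    platform_gain: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    background_prefix: str = "BG"

    def __post_init__(self) -> None:
        if self.n_case < 3 or self.n_control < 3:
            raise ValueError("at least three subjects per group are required")
        low = [g for g, eff in self.planted_markers if abs(eff) < DETECTABILITY_FLOOR]
        if low:
            raise ValueError(
                f"planted effects below the {DETECTABILITY_FLOOR} log2-unit "
                f"detectability floor: {low}")
        if len(self.planted_markers) + self.study_specific_hits > self.n_proteins:
            raise ValueError("planted marker count exceeds n_proteins")
        if self.platform_gain <= 0:
            raise ValueError("platform_gain must be > 0")


@dataclass
class SimProgressionConfig:
    """Parameters for a simulated progression cohort."""

    n_subjects: int = 300
    group_fraction_high: float = 0.5
    hazard_ratio_true: float = 3.0
    baseline_hazard: float = 0.1  # events/year in the low group
    censor_min_years: float = MIN_FOLLOWUP_YEARS
    censor_max_years: float = MAX_FOLLOWUP_YEARS
    age_effect: float = 0.0  # log-hazard per year of age (centered)
    sex_effect: float = 0.0  # log-hazard for female vs male
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_ratio_true <= 0:
            raise ValueError("hazard_ratio_true must be > 0")
        if not 0 < self.group_fraction_high < 1:
            raise ValueError("group_fraction_high must be in (0,1)")
        if not 0 < self.censor_min_years < self.censor_max_years:
            raise ValueError("censoring window must satisfy 0 < min < max")


def _universe(cfg: SimStudyConfig) -> List[str]:
    planted = [g for g, _ in cfg.planted_markers]
    n_bg = cfg.n_proteins - len(planted) - cfg.study_specific_hits
    specific = [f"{cfg.cohort_id}_SP{i:03d}" for i in range(cfg.study_specific_hits)]
    background = [f"{cfg.background_prefix}{i:04d}" for i in range(n_bg)]
    return planted + specific + background


def simulate_cohort(cfg: SimStudyConfig):
    """Generate one cohort: (CohortMatrix, subjects, truth table).

    Values are Normal(baseline + group*effect, noise_sd) on the log2
    scale, then platform gain/offset are applied and missingness masked.
    Cases are labelled A+T+ (clinically impaired), controls A-T- CU.  The
    truth table lists every planted marker with its effect and sign.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _universe(cfg)
    effects = dict(cfg.planted_markers)
    for g in genes:
        if g.startswith(f"{cfg.cohort_id}_SP"):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effects[g] = sign * cfg.study_specific_effect
    n = cfg.n_case + cfg.n_control
    case = np.array([1.0] * cfg.n_case + [0.0] * cfg.n_control)
    subjects_ids = [f"{cfg.cohort_id}_case{i:03d}" for i in range(cfg.n_case)] + \
                   [f"{cfg.cohort_id}_ctrl{i:03d}" for i in range(cfg.n_control)]
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    eff = np.array([effects.get(g, 0.0) for g in genes])
    values = baseline[:, None] + eff[:, None] * case[None, :] \
        + rng.normal(0.0, cfg.noise_sd, size=(len(genes), n))
    values = values * cfg.platform_gain + cfg.platform_offset
    a, b = cfg.missing_beta
    if a > 0 and b > 0:
        rates = rng.beta(a, b, size=len(genes))
        mask = rng.random(size=values.shape) < rates[:, None]
        values = np.where(mask, np.nan, values)
    data = pd.DataFrame(values, index=genes, columns=subjects_ids)
    m = CohortMatrix(cohort_id=cfg.cohort_id, platform=cfg.platform, data=data, scale="log2")
    m.log.append(f"simulated with seed {cfg.seed}")

    subjects = []
    for sid, is_case in zip(subjects_ids, case):
        age = float(np.round(rng.normal(72.0, 7.0), 1))
        age = max(age, 40.0)
        sex = "F" if rng.random() < 0.5 else "M"
        if is_case:
            clinical = "MCI" if rng.random() < 0.5 else "dementia"
            subjects.append(SubjectRecord(sid, cfg.cohort_id, "pos", "pos", clinical, age, sex))
        else:
            subjects.append(SubjectRecord(sid, cfg.cohort_id, "neg", "neg", "CU", age, sex))

    truth = pd.DataFrame({
        "gene_symbol": [g for g in genes if effects.get(g, 0.0) != 0.0],
    })
    truth["effect"] = [effects[g] for g in truth["gene_symbol"]]
    truth["sign"] = np.sign(truth["effect"]).astype(int)
    truth["kind"] = ["study_specific" if g.startswith(f"{cfg.cohort_id}_SP") else "shared"
                     for g in truth["gene_symbol"]]
    truth["study"] = cfg.cohort_id
    return m, subjects, truth


def simulate_multi_study(configs: Sequence[SimStudyConfig],
                         shared_markers: Sequence[Tuple[str, float]],
                         concordance: float = 1.0,
                         seed: Optional[int] = None):
    """Generate several cohorts sharing a planted marker set.

    Shared markers are planted in every study; a (1 - concordance)
    fraction of them have their sign flipped in exactly one randomly
    chosen study, to exercise the directional-concordance filter.
    Study-specific hits are disjoint across studies by construction.
    Returns (bundles, truth) where each bundle is the simulate_cohort
    triple.
    """
    if not 0 <= concordance <= 1:
        raise ValueError("concordance must be in [0, 1]")
    rng = np.random.default_rng(configs[0].seed if seed is None else seed)
    shared = list(shared_markers)
    n_flip = int(round((1 - concordance) * len(shared)))
    flip_idx = rng.choice(len(shared), size=n_flip, replace=False) if n_flip else []
    flips = {}  # marker index -> study index whose sign is flipped
    for i in flip_idx:
        flips[int(i)] = int(rng.integers(len(configs)))

    bundles = []
    truths = []
    for j, cfg in enumerate(configs):
        markers = []
        for i, (gene, eff) in enumerate(shared):
            markers.append((gene, -eff if flips.get(i) == j else eff))
        cfg_j = replace(cfg, planted_markers=markers)
        bundle = simulate_cohort(cfg_j)
        bundles.append(bundle)
        truths.append(bundle[2])
    truth = pd.concat(truths, ignore_index=True)
    truth.attrs["flipped"] = {shared[i][0]: configs[j].cohort_id for i, j in flips.items()}
    return bundles, truth


def simulate_progression_cohort(cfg: SimProgressionConfig) -> List[SurvivalRecord]:
    """Generate right-censored progression records with a known hazard ratio.

    Event times are exponential with hazard baseline * HR^group *
    exp(covariate effects); administrative censoring is uniform on the
    follow-up window, so every observed time lies in (0, max window].
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    high = rng.random(n) < cfg.group_fraction_high
    age = rng.normal(72.0, 7.0, size=n)
    female = rng.random(n) < 0.5
    log_h = (np.log(cfg.baseline_hazard)
             + np.log(cfg.hazard_ratio_true) * high
             + cfg.age_effect * (age - age.mean())
             + cfg.sex_effect * female)
    event_t = rng.exponential(1.0 / np.exp(log_h))
    censor_t = rng.uniform(cfg.censor_min_years, cfg.censor_max_years, size=n)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    time = np.maximum(time, 1e-6)
    return [
        SurvivalRecord(
            subject_id=f"sim{i:04d}", time=float(time[i]), event=int(event[i]),
            group="high" if high[i] else "low", age=float(age[i]),
            sex="F" if female[i] else "M")
        for i in range(n)
    ]
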