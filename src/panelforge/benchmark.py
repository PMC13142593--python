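"""Head-to-head signature benchmarking under one uniform harness.

Every signature in the registry is evaluated on every cohort and
comparison with identical preprocessing, fold assignments, ridge and
seeds, so differences in the resulting AUCs / hazard ratios reflect the
panels, not the harness.  Coverage (which panel proteins a cohort
actually measures) is accounted per cell; zero-coverage cells are
explicit NAs, never silent skips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .diagnostics import external_validation, fit_panel_model, repeated_cv_auc, score_subjects
from .matrix import CohortMatrix
from .prognosis import build_transition_dataset, cox_fit, median_stratify
from .signatures import Signature

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageReport",
    "EvalSpec",
    "BenchmarkTable",
    "signature_coverage",
    "signature_overlap",
    "mean_z_score",
    "run_benchmark",
]


@dataclass
class CoverageReport:
    signature_name: str
    cohort_id: str
    n_total: int
    n_covered: int
    missing: List[str]

    def __post_init__(self) -> None:
        assert self.n_covered + len(self.missing) == self.n_total


@dataclass
class EvalSpec:
    """What to run for one cohort: regime and comparisons.

    ``regime`` is ``cv`` (repeated stratified CV within the cohort) or
    ``external`` (fit on ``train`` bundles, validate frozen).
    ``comparisons`` maps a free-text label (e.g. "A+T+ vs A-T-") to a
    subject -> case/control map.  ``transitions`` maps a transition label
    to a list of subjects-with-visits for prognostic cells.
    """

    cohort_id: str
    regime: str  # cv | external
    comparisons: Dict[str, Dict[str, str]]
    train: Optional[list] = None  # list of (CohortMatrix, labels) for external
    k: int = 5
    repeats: int = 10
    transitions: Dict[str, list] = field(default_factory=dict)


@dataclass
class BenchmarkTable:
    diagnostics: pd.DataFrame
    prognostics: pd.DataFrame
    coverage: List[CoverageReport]


def signature_coverage(sig: Signature, m: CohortMatrix) -> CoverageReport:
    """Which of the signature's proteins the cohort measures; missing
    symbols reported in signature order."""
    present = set(m.proteins)
    missing = [g for g in sig.gene_symbols if g not in present]
    return CoverageReport(
        signature_name=sig.name, cohort_id=m.cohort_id,
        n_total=len(sig.gene_symbols),
        n_covered=len(sig.gene_symbols) - len(missing), missing=missing)


def signature_overlap(sigs: Sequence[Signature]) -> Dict[str, int]:
    """How many signatures contain each gene symbol (shared-protein
    accounting across panels)."""
    if len(sigs) < 2:
        raise ValueError("signature_overlap needs >= 2 signatures")
    counts: Dict[str, int] = {}
    for sig in sigs:
        for g in set(sig.gene_symbols):
            counts[g] = counts.get(g, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def mean_z_score(m: CohortMatrix, sig: Signature,
                 signs: Optional[Dict[str, int]] = None) -> pd.Series:
    """Unweighted panel score: mean of member-protein z-values per
    subject, each direction-aligned by its discovery sign (default +1)."""
    covered = [g for g in sig.gene_symbols if g in m.data.index]
    if not covered:
        raise ValueError(f"signature {sig.name!r} has zero coverage in {m.cohort_id!r}")
    signs = signs or {}
    aligned = m.data.loc[covered].mul(
        pd.Series({g: float(signs.get(g, 1)) for g in covered}), axis=0)
    s = aligned.mean(axis=0, skipna=True)
    s.name = "score"
    s.attrs["coverage_fraction"] = len(covered) / len(sig.gene_symbols)
    return s


def run_benchmark(registry: Sequence[Signature],
                  cohorts: Dict[str, Tuple[CohortMatrix, dict]],
                  eval_specs: Sequence[EvalSpec], seed: int = 0,
                  ridge: float = 1e-3, score_mode: str = "meanz") -> BenchmarkTable:
    """Evaluate every signature on every (cohort, comparison) cell.

    ``cohorts`` maps cohort_id -> (preprocessed CohortMatrix, metadata).
    Determinism: the same master seed feeds every cell, and fold
    assignments within a (cohort, comparison) are identical across
    signatures (they depend only on seed and labels).
    """
    diag_rows, prog_rows, reports = [], [], []
    for spec in eval_specs:
        m, _meta = cohorts[spec.cohort_id]
        for sig in registry:
            cov = signature_coverage(sig, m)
            reports.append(cov)
            for label, labels in spec.comparisons.items():
                row = {"signature": sig.name, "cohort": spec.cohort_id,
                       "comparison": label, "coverage": cov.n_covered,
                       "coverage_fraction": cov.n_covered / cov.n_total}
                if cov.n_covered == 0:
                    row.update({"auc": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                                "youden_j": np.nan, "status": "not_evaluable (coverage 0)"})
                    diag_rows.append(row)
                    continue
                if spec.regime == "cv":
                    res = repeated_cv_auc(m, labels, sig, k=spec.k,
                                          repeats=spec.repeats, ridge=ridge,
                                          seed=seed, comparison=label)
                elif spec.regime == "external":
                    if not spec.train:
                        raise ValueError(f"{spec.cohort_id}: external regime needs train bundles")
                    model = fit_panel_model(spec.train, sig, ridge=ridge, seed=seed)
                    res = external_validation(model, (m, labels), comparison=label, seed=seed)
                else:
                    raise ValueError(f"unknown regime {spec.regime!r}")
                row.update({"auc": res.auc, "ci_low": res.ci_low, "ci_high": res.ci_high,
                            "sensitivity": res.sensitivity, "specificity": res.specificity,
                            "youden_j": res.youden_j, "status": "ok"})
                diag_rows.append(row)

            for trans_label, subjects in spec.transitions.items():
                row = {"signature": sig.name, "cohort": spec.cohort_id,
                       "transition": trans_label, "coverage": cov.n_covered}
                if cov.n_covered == 0:
                    row.update({"hr": np.nan, "wald_p": np.nan,
                                "status": "not_evaluable (coverage 0)"})
                    prog_rows.append(row)
                    continue
                if score_mode == "model" and spec.train:
                    model = fit_panel_model(spec.train, sig, ridge=ridge, seed=seed)
                    scores = score_subjects(model, m)
                else:
                    scores = mean_z_score(m, sig)
                records = build_transition_dataset(subjects, trans_label,
                                                   scores.to_dict())
                try:
                    hz = cox_fit(records, transition=trans_label)
                    row.update({"hr": hz.hr, "ci_low": hz.ci_low, "ci_high": hz.ci_high,
                                "wald_p": hz.wald_p, "n_events": hz.n_events,
                                "status": "ok"})
                except ValueError as exc:
                    row.update({"hr": np.nan, "wald_p": np.nan,
                                "status": f"not_evaluable ({exc})"})
                prog_rows.append(row)

    return BenchmarkTable(
        diagnostics=pd.DataFrame(diag_rows),
        prognostics=pd.DataFrame(prog_rows),
        coverage=reports)
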