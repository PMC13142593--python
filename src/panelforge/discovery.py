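"""Reproducibility-centered biomarker discovery funnel.

Per-study differential abundance -> effect-size and significance
thresholds (|log2 FC| >= 0.6, p < 0.05) -> cross-study vote counting
(shared in at least two studies) -> directional concordance -> coverage
in every validation cohort -> AUC-driven down-selection to the final
panel.  Error control comes from reproducibility across independent
studies rather than per-study multiplicity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import CohortMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DAPRecord",
    "DiscoveryConfig",
    "VoteTally",
    "differential_abundance",
    "filter_daps",
    "vote_count",
    "concordant_direction",
    "coverage_filter",
    "down_select_panel",
    "read_dap_table",
    "run_funnel",
    "membership_matrix",
]


@dataclass(frozen=True)
class DAPRecord:
    """One protein's differential result in one study."""

    gene_symbol: str
    study_id: str
    log2fc: float  # case - control, log2 units
    p_value: float
    passes_filter: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"{self.gene_symbol}: p_value must be in (0, 1]")


@dataclass(frozen=True)
class DiscoveryConfig:
    lfc_threshold: float = 0.6
    p_threshold: float = 0.05
    min_studies: int = 2
    require_concordance: bool = True
    lfc_strict: bool = False  # False: |lfc| >= threshold kept (the default reading)
    epsilon: float = 0.002  # down-selection AUC tolerance

    def __post_init__(self) -> None:
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0,1)")
        if self.min_studies < 2:
            raise ValueError("min_studies must be >= 2")


@dataclass
class VoteTally:
    """Cross-study tally for one gene symbol."""

    gene_symbol: str
    signs: List[int]  # +1 / -1 per contributing study
    studies: List[str]
    concordant: bool = False

    @property
    def n_studies_present(self) -> int:
        return len(self.signs)


def differential_abundance(m: CohortMatrix, labels: Dict[str, str],
                           config: Optional[DiscoveryConfig] = None) -> List[DAPRecord]:
    """Per-protein case/control differential abundance on log2 data.

    log2 FC is mean(case) - mean(control); the p-value comes from a
    two-sided Welch t-test on observed values.  Proteins with fewer than
    three observed values in either group are skipped with a warning
    (mirrors the inclusion criterion of at least three subjects per
    group).
    """
    if m.scale not in ("log2", "zscore"):
        raise ValueError(f"differential_abundance expects log2-scale data, got {m.scale!r}")
    config = config or DiscoveryConfig()
    case_ids = [s for s in m.subjects if labels.get(s) == "case"]
    ctrl_ids = [s for s in m.subjects if labels.get(s) == "control"]
    if len(case_ids) < 3 or len(ctrl_ids) < 3:
        raise ValueError("at least three subjects per group are required")
    case = m.data[case_ids].to_numpy(dtype=float)
    ctrl = m.data[ctrl_ids].to_numpy(dtype=float)
    n_case_obs = (~np.isnan(case)).sum(axis=1)
    n_ctrl_obs = (~np.isnan(ctrl)).sum(axis=1)
    ok = (n_case_obs >= 3) & (n_ctrl_obs >= 3)
    skipped = int((~ok).sum())
    if skipped:
        logger.warning("differential_abundance: skipped %d proteins with < 3 "
                       "observed values per group", skipped)
    import warnings as _warnings
    with _warnings.catch_warnings(), np.errstate(invalid="ignore"):
        _warnings.simplefilter("ignore")
        fc = np.nanmean(case, axis=1) - np.nanmean(ctrl, axis=1)
        t = stats.ttest_ind(case, ctrl, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(t.pvalue, dtype=float)
    records = []
    for i, gene in enumerate(m.proteins):
        if not ok[i] or not np.isfinite(p[i]):
            continue
        pv = min(max(float(p[i]), np.nextafter(0, 1)), 1.0)
        lfc = float(fc[i])
        records.append(DAPRecord(
            gene_symbol=str(gene), study_id=m.cohort_id, log2fc=lfc, p_value=pv,
            passes_filter=_passes(lfc, pv, config)))
    return records


def _passes(lfc: float, p: float, cfg: DiscoveryConfig) -> bool:
    big = abs(lfc) > cfg.lfc_threshold if cfg.lfc_strict else abs(lfc) >= cfg.lfc_threshold
    return big and p < cfg.p_threshold


def filter_daps(records: Sequence[DAPRecord],
                config: Optional[DiscoveryConfig] = None) -> List[DAPRecord]:
    """Keep records with |log2 FC| >= 0.6 (inclusive) and p < 0.05
    (strict); order preserved; idempotent."""
    config = config or DiscoveryConfig()
    out = []
    for r in records:
        if _passes(r.log2fc, r.p_value, config):
            out.append(r if r.passes_filter else
                       DAPRecord(r.gene_symbol, r.study_id, r.log2fc, r.p_value, True))
    return out


def vote_count(per_study: Dict[str, Sequence[DAPRecord]],
               config: Optional[DiscoveryConfig] = None) -> List[VoteTally]:
    """Tally genes appearing in the filtered lists of >= min_studies
    studies.

    Signs come from sign(log2 FC) per study; if a study contributes a
    gene more than once (multiple analytes) the record with the highest
    |log2 FC| supplies the single sign for that study.  Output sorted by
    gene symbol for determinism.
    """
    config = config or DiscoveryConfig()
    if len(per_study) < 2:
        raise ValueError("vote counting needs >= 2 studies")
    votes: Dict[str, Dict[str, float]] = {}
    for study, records in per_study.items():
        best: Dict[str, float] = {}
        for r in records:
            if r.gene_symbol not in best or abs(r.log2fc) > abs(best[r.gene_symbol]):
                best[r.gene_symbol] = r.log2fc
        for gene, lfc in best.items():
            votes.setdefault(gene, {})[study] = lfc
    tallies = []
    for gene in sorted(votes):
        contrib = votes[gene]
        if len(contrib) < config.min_studies:
            continue
        studies = sorted(contrib)
        signs = [1 if contrib[s] > 0 else -1 for s in studies]
        tallies.append(VoteTally(gene_symbol=gene, signs=signs, studies=studies,
                                 concordant=len(set(signs)) == 1))
    return tallies


def concordant_direction(tallies: Sequence[VoteTally]) -> List[VoteTally]:
    """Retain tallies whose per-study signs all agree."""
    out = []
    for t in tallies:
        if len(set(t.signs)) == 1:
            t.concordant = True
            out.append(t)
    return out


def coverage_filter(candidates: Sequence, validation_matrices: Sequence[CohortMatrix]) -> List:
    """Keep candidates measured in EVERY validation matrix
    (post-missingness-filter)."""
    if not validation_matrices:
        raise ValueError("at least one validation matrix is required")
    present = [set(m.proteins) for m in validation_matrices]
    out = []
    for c in candidates:
        gene = c.gene_symbol if hasattr(c, "gene_symbol") else c
        if all(gene in p for p in present):
            out.append(c)
    return out


def down_select_panel(candidates: Sequence[str], train_bundles,
                      config: Optional[DiscoveryConfig] = None,
                      k: int = 5, repeats: int = 3, ridge: float = 1e-3,
                      seed: int = 0, name: str = "panel"):
    """Greedy forward down-selection by cross-validated AUC.

    Candidates are ranked by univariate cross-validated AUC on the
    pooled training data, added in rank order, and the smallest prefix
    whose mean CV AUC is within ``epsilon`` of the best prefix is kept.
    Ties in the univariate ranking break alphabetically.  Returns a
    :class:`~panelforge.signatures.Signature` with the selection trace in
    its notes.
    """
    from .diagnostics import _cv_auc_matrix  # local import to avoid cycle
    from .signatures import Signature

    config = config or DiscoveryConfig()
    candidates = [c.gene_symbol if hasattr(c, "gene_symbol") else c for c in candidates]
    if not candidates:
        raise ValueError("no candidates to select from")
    if len(candidates) == 1:
        return Signature(name=name, gene_symbols=list(candidates),
                         source="down_select_panel", objective="diagnosis",
                         notes="single candidate; returned as-is")

    X, y = _stack_training(train_bundles, candidates)
    uni = {}
    for gene in candidates:
        auc = _cv_auc_matrix(X[[gene]], y, k=k, repeats=repeats, ridge=ridge, seed=seed)
        uni[gene] = auc
    order = sorted(candidates, key=lambda g: (-uni[g], g))

    prefix_auc = []
    for j in range(1, len(order) + 1):
        auc = _cv_auc_matrix(X[order[:j]], y, k=k, repeats=repeats, ridge=ridge, seed=seed)
        prefix_auc.append(auc)
    best = max(prefix_auc)
    if best <= 0.5:
        logger.warning("down_select_panel: no prefix beats AUC 0.5; returning best single protein")
        chosen = [order[0]]
    else:
        size = next(j + 1 for j, a in enumerate(prefix_auc) if a >= best - config.epsilon)
        chosen = order[:size]
    trace = "; ".join(f"{g}:{uni[g]:.3f}" for g in order)
    prefix_trace = ", ".join(f"{j + 1}:{a:.4f}" for j, a in enumerate(prefix_auc))
    return Signature(
        name=name, gene_symbols=chosen, source="down_select_panel",
        objective="diagnosis",
        notes=f"univariate ranking [{trace}]; prefix CV AUC [{prefix_trace}]; "
              f"epsilon {config.epsilon}")


def _stack_training(train_bundles, genes: Sequence[str]):
    """Pool (matrix, labels) bundles into a subjects x genes frame + labels."""
    frames, labels = [], []
    for m, lab in train_bundles:
        cols = [g for g in genes if g in m.data.index]
        sub = m.data.loc[cols].T.reindex(columns=list(genes))
        frames.append(sub)
        labels.extend(1 if lab[s] == "case" else 0 for s in m.subjects)
    X = pd.concat(frames, axis=0).fillna(0.0)
    y = np.asarray(labels)
    return X, y


def read_dap_table(path, study_id: Optional[str] = None) -> List[DAPRecord]:
    """Read a per-study differential table (gene_symbol, log2fc, p_value)
    from TSV/CSV, e.g. a pre-extracted published DAP list."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    need = {"gene_symbol", "log2fc", "p_value"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"DAP table {path} lacks columns {sorted(missing)}")
    sid = study_id or str(df["study_id"].iloc[0]) if "study_id" in df.columns else (study_id or str(path))
    return [DAPRecord(str(r.gene_symbol), str(r.study_id) if "study_id" in df.columns else sid,
                      float(r.log2fc), float(r.p_value))
            for r in df.itertuples()]


def run_funnel(per_study: Dict[str, Sequence[DAPRecord]],
               validation_matrices: Sequence[CohortMatrix] = (),
               config: Optional[DiscoveryConfig] = None) -> dict:
    """Run thresholds -> vote count -> concordance -> coverage and return
    every stage (counts shrink monotonically)."""
    config = config or DiscoveryConfig()
    filtered = {s: filter_daps(r, config) for s, r in per_study.items()}
    n_daps = len({(r.gene_symbol) for recs in filtered.values() for r in recs})
    tallies = vote_count(filtered, config)
    concordant = concordant_direction(tallies) if config.require_concordance else tallies
    if validation_matrices:
        covered = coverage_filter(concordant, validation_matrices)
    else:
        covered = list(concordant)
    return {
        "filtered": filtered,
        "n_daps": n_daps,
        "shared": tallies,
        "concordant": concordant,
        "candidates": covered,
    }


def membership_matrix(per_study: Dict[str, Sequence[DAPRecord]]) -> pd.DataFrame:
    """Gene x study boolean membership table (UpSet-compatible)."""
    studies = sorted(per_study)
    genes = sorted({r.gene_symbol for recs in per_study.values() for r in recs})
    out = pd.DataFrame(False, index=genes, columns=studies)
    for s, recs in per_study.items():
        for r in recs:
            out.loc[r.gene_symbol, s] = True
    return out
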