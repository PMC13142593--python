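"""Panel scoring and diagnostic evaluation.

A panel is scored by a ridge-stabilized logistic regression on z-scored
abundances; performance is summarized by the ROC curve, the
Mann-Whitney AUC with a DeLong (or bootstrap) confidence interval, and
the Youden operating point.  Two validation regimes mirror common
practice: repeated stratified cross-validation within a cohort, and
train-on-some / validate-externally across cohorts.  A PCA + MANOVA
(Pillai's trace) exploratory test checks multivariate group separation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.multivariate.manova import MANOVA

from .matrix import CohortMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PanelModel",
    "DiagnosticResult",
    "ManovaResult",
    "fit_panel_model",
    "score_subjects",
    "roc_auc",
    "auc_confidence",
    "youden_threshold",
    "repeated_cv_auc",
    "external_validation",
    "pca_manova",
]


@dataclass
class PanelModel:
    """Fitted logistic panel scorer on standardized inputs."""

    signature_name: str
    proteins: List[str]
    coef: np.ndarray
    intercept: float
    ridge: float
    training_cohorts: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if not np.all(np.isfinite(self.coef)) or not np.isfinite(self.intercept):
            raise ValueError("panel coefficients must be finite")


@dataclass
class DiagnosticResult:
    """AUC with CI and Youden operating point for one evaluation cell."""

    cohort_id: str
    comparison: str
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    n_case: int
    n_control: int
    coverage_fraction: float = 1.0
    details: dict = field(default_factory=dict)

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def to_dict(self) -> dict:
        return {
            "cohort_id": self.cohort_id, "comparison": self.comparison,
            "auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "threshold": self.threshold, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "youden_j": self.youden_j,
            "n_case": self.n_case, "n_control": self.n_control,
            "coverage_fraction": self.coverage_fraction,
        }


@dataclass
class ManovaResult:
    pillai_trace: float
    approx_f: float
    df1: float
    df2: float
    p_value: float
    n_components: int


# ---------------------------------------------------------------------------
# model fitting and scoring

def _design(m: CohortMatrix, proteins: Sequence[str]) -> pd.DataFrame:
    """Subjects x proteins frame; absent proteins / missing values -> 0
    (the mean on the z scale)."""
    cols = [p for p in proteins if p in m.data.index]
    X = m.data.loc[cols].T.reindex(columns=list(proteins)).fillna(0.0)
    return X


def fit_panel_model(train, signature, ridge: float = 1e-3, seed: int = 0) -> PanelModel:
    """Fit the panel's logistic scorer on one or more z-scored training
    cohorts.

    ``train`` is a (matrix, labels) pair or a list of them; labels map
    subject id -> 'case'/'control'.  The small ridge keeps the
    maximum-penalized-likelihood fit finite under perfect separation and
    makes the fit deterministic.
    """
    if isinstance(train, tuple):
        train = [train]
    name = signature.name if hasattr(signature, "name") else "panel"
    genes = list(signature.gene_symbols) if hasattr(signature, "gene_symbols") else list(signature)
    covered = [g for g in genes if all(g in m.data.index for m, _ in train)]
    if not covered:
        raise ValueError(f"signature {name!r} has no coverage in the training data")
    frames, labels = [], []
    for m, lab in train:
        if m.scale != "zscore":
            logger.warning("fit_panel_model: training matrix %s is on scale %r, "
                           "expected zscore", m.cohort_id, m.scale)
        frames.append(_design(m, covered))
        labels.extend(1 if lab[s] == "case" else 0 for s in m.subjects)
    X = pd.concat(frames, axis=0).to_numpy()
    y = np.asarray(labels)
    if len(set(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs",
                             max_iter=5000, tol=1e-10)
    clf.fit(X, y)
    return PanelModel(
        signature_name=name, proteins=covered, coef=clf.coef_[0],
        intercept=float(clf.intercept_[0]), ridge=ridge,
        training_cohorts=tuple(m.cohort_id for m, _ in train), seed=seed)


def score_subjects(model: PanelModel, m: CohortMatrix) -> pd.Series:
    """Linear predictor per subject; unavailable proteins contribute 0."""
    available = [p for p in model.proteins if p in m.data.index]
    if not available:
        raise ValueError(f"no overlap between panel {model.signature_name!r} "
                         f"and cohort {m.cohort_id!r}")
    X = _design(m, model.proteins).to_numpy()
    scores = X @ model.coef + model.intercept
    s = pd.Series(scores, index=m.subjects, name="score")
    s.attrs["coverage_fraction"] = len(available) / len(model.proteins)
    return s


# ---------------------------------------------------------------------------
# ROC machinery

def _split(scores, labels) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(scores, pd.Series):
        s = np.asarray([scores[k] for k in scores.index], dtype=float)
        y = np.asarray([1 if labels[k] == "case" else 0 for k in scores.index])
    else:
        s = np.asarray(scores, dtype=float)
        y = np.asarray([1 if l in (1, "case", True) else 0 for l in labels])
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    return s, y


def roc_auc(scores, labels) -> Tuple[pd.DataFrame, float]:
    """ROC points at every unique threshold and the Mann-Whitney AUC.

    The AUC equals the probability a random case outscores a random
    control, ties counted one half.
    """
    s, y = _split(scores, labels)
    n1, n0 = int(y.sum()), int(len(y) - y.sum())
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    # ROC points: threshold rule "positive if score >= t" for each unique
    # score, plus the all-negative point
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    uniq = np.flatnonzero(np.r_[np.diff(s_sorted) != 0, True])
    tps = np.cumsum(y_sorted)[uniq]
    fps = np.cumsum(1 - y_sorted)[uniq]
    points = pd.DataFrame({
        "threshold": np.r_[np.inf, s_sorted[uniq]],
        "tpr": np.r_[0.0, tps / n1],
        "fpr": np.r_[0.0, fps / n0],
    })
    return points, float(auc)


def _delong_variance(s: np.ndarray, y: np.ndarray) -> float:
    """DeLong variance of the AUC via structural components (midranks)."""
    cases, controls = s[y == 1], s[y == 0]
    m_, n_ = len(cases), len(controls)
    all_r = stats.rankdata(np.r_[cases, controls])
    case_r = stats.rankdata(cases)
    ctrl_r = stats.rankdata(controls)
    v10 = (all_r[:m_] - case_r) / n_  # P(control < case_i) with ties/2
    v01 = 1.0 - (all_r[m_:] - ctrl_r) / m_
    s10 = np.var(v10, ddof=1) if m_ > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n_ > 1 else 0.0
    return s10 / m_ + s01 / n_


def auc_confidence(scores, labels, method: str = "delong", level: float = 0.95,
                   seed: int = 0, n_boot: int = 2000) -> Tuple[float, float]:
    """Confidence interval for the AUC, clipped to [0, 1].

    ``delong`` uses the asymptotic normal interval from the DeLong
    structural-component variance; ``bootstrap`` is a seeded percentile
    bootstrap resampling cases and controls independently.
    """
    s, y = _split(scores, labels)
    _, auc = roc_auc(s, y)
    alpha = 1 - level
    if method == "delong":
        var = _delong_variance(s, y)
        if var <= 0:
            logger.warning("auc_confidence: degenerate DeLong variance; CI collapses to the point")
            return float(auc), float(auc)
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var)
        return float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        cases, controls = s[y == 1], s[y == 0]
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            cs = rng.choice(cases, size=len(cases), replace=True)
            ct = rng.choice(controls, size=len(controls), replace=True)
            ranks = stats.rankdata(np.r_[cs, ct])
            aucs[b] = (ranks[:len(cs)].sum() - len(cs) * (len(cs) + 1) / 2) / (len(cs) * len(ct))
        lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
        return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))
    raise ValueError(f"unknown CI method {method!r}")


def youden_threshold(roc_points: pd.DataFrame) -> Tuple[float, float, float]:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Ties break toward higher specificity (lower false-positive rate).
    Returns (threshold, sensitivity, specificity).
    """
    if len(roc_points) < 2:
        raise ValueError("need >= 2 thresholds")
    j = roc_points["tpr"] - roc_points["fpr"]
    best = roc_points.assign(j=j).sort_values(["j", "fpr"], ascending=[False, True],
                                              kind="mergesort").iloc[0]
    return float(best["threshold"]), float(best["tpr"]), float(1.0 - best["fpr"])


# ---------------------------------------------------------------------------
# validation regimes

def _fold_seed(seed: int, repeat: int) -> int:
    # counter-based: stable across platforms, distinct per repeat
    return (seed * 1_000_003 + repeat * 7919 + 1) % (2**31 - 1)


def _cv_auc_matrix(X: pd.DataFrame, y: np.ndarray, k: int = 5, repeats: int = 10,
                   ridge: float = 1e-3, seed: int = 0) -> float:
    """Mean over repeats of the pooled out-of-fold AUC (internal helper)."""
    aucs = []
    Xv = X.to_numpy()
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=_fold_seed(seed, rep))
        oof = np.empty(len(y))
        for tr, te in skf.split(Xv, y):
            clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs",
                                     max_iter=5000, tol=1e-10)
            clf.fit(Xv[tr], y[tr])
            oof[te] = Xv[te] @ clf.coef_[0] + clf.intercept_[0]
        _, auc = roc_auc(oof, y)
        aucs.append(auc)
    return float(np.mean(aucs))


def repeated_cv_auc(m: CohortMatrix, labels: Dict[str, str], signature,
                    k: int = 5, repeats: int = 10, ridge: float = 1e-3,
                    seed: int = 0, comparison: str = "") -> DiagnosticResult:
    """Stratified k-fold cross-validation with re-randomized repeats.

    Out-of-fold scores are pooled within each repeat; the reported AUC is
    the mean over repeats.  Two CIs are logged: a normal interval from
    the across-repeat dispersion, and DeLong on the last repeat's pooled
    scores; the across-repeat interval is the headline one.
    """
    genes = list(signature.gene_symbols) if hasattr(signature, "gene_symbols") else list(signature)
    covered = [g for g in genes if g in m.data.index]
    if not covered:
        raise ValueError("signature has no coverage in this cohort")
    keep = [s for s in m.subjects if labels.get(s) in ("case", "control")]
    X = _design(m, covered).loc[keep]
    y = np.asarray([1 if labels[s] == "case" else 0 for s in keep])
    n1, n0 = int(y.sum()), int(len(y) - y.sum())
    if min(n1, n0) < k:
        raise ValueError(f"class count {min(n1, n0)} < k={k}; use a smaller k")
    Xv = X.to_numpy()
    rep_aucs = []
    oof = np.empty(len(y))
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=_fold_seed(seed, rep))
        for tr, te in skf.split(Xv, y):
            clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs",
                                     max_iter=5000, tol=1e-10)
            clf.fit(Xv[tr], y[tr])
            oof[te] = Xv[te] @ clf.coef_[0] + clf.intercept_[0]
        _, auc = roc_auc(oof, y)
        rep_aucs.append(auc)
    mean_auc = float(np.mean(rep_aucs))
    sd = float(np.std(rep_aucs, ddof=1)) if repeats > 1 else 0.0
    z = stats.norm.ppf(0.975)
    ci_rep = (max(0.0, mean_auc - z * sd), min(1.0, mean_auc + z * sd))
    ci_delong = auc_confidence(oof, ["case" if v else "control" for v in y], "delong")
    points, _ = roc_auc(oof, y)
    thr, sens, spec = youden_threshold(points)
    return DiagnosticResult(
        cohort_id=m.cohort_id, comparison=comparison, auc=mean_auc,
        ci_low=ci_rep[0], ci_high=ci_rep[1], threshold=thr,
        sensitivity=sens, specificity=spec, n_case=n1, n_control=n0,
        coverage_fraction=len(covered) / len(genes),
        details={"repeat_aucs": rep_aucs, "ci_delong_pooled": ci_delong,
                 "k": k, "repeats": repeats, "seed": seed})


def external_validation(model: PanelModel, test: Tuple[CohortMatrix, Dict[str, str]],
                        comparison: str = "", ci_method: str = "delong",
                        seed: int = 0) -> DiagnosticResult:
    """Score an external cohort with a frozen model, then ROC + Youden.

    Labels enter only at the metric stage — the model never sees them —
    so there is no test-set refitting by construction.
    """
    m, labels = test
    scores = score_subjects(model, m)
    keep = [s for s in scores.index if labels.get(s) in ("case", "control")]
    s = scores.loc[keep]
    y = {k: labels[k] for k in keep}
    points, auc = roc_auc(s, y)
    ci = auc_confidence(s, y, method=ci_method, seed=seed)
    thr, sens, spec = youden_threshold(points)
    n1 = sum(1 for v in y.values() if v == "case")
    return DiagnosticResult(
        cohort_id=m.cohort_id, comparison=comparison, auc=auc,
        ci_low=ci[0], ci_high=ci[1], threshold=thr, sensitivity=sens,
        specificity=spec, n_case=n1, n_control=len(keep) - n1,
        coverage_fraction=scores.attrs.get("coverage_fraction", 1.0),
        details={"ci_method": ci_method})


# ---------------------------------------------------------------------------
# exploratory multivariate separation

def pca_manova(m: CohortMatrix, groups: Dict[str, str], n_components: int = 2) -> ManovaResult:
    """PCA on protein z-scores, then one-way MANOVA (Pillai's trace) on
    the top components."""
    keep = [s for s in m.subjects if s in groups]
    g = pd.Series({s: groups[s] for s in keep})
    n_groups = g.nunique()
    if n_groups < 2:
        raise ValueError("need >= 2 groups")
    if n_components >= len(keep) - n_groups:
        raise ValueError("n_components must be < n_subjects - n_groups")
    X = m.data[keep].T.fillna(0.0).to_numpy()
    pcs = PCA(n_components=n_components, random_state=0).fit_transform(X)
    if n_components == 1:
        # univariate reduction: Pillai's trace is the between/total
        # sum-of-squares ratio and the F test is one-way ANOVA
        pc = pcs.ravel()
        grand = pc.mean()
        levels = g.unique()
        ssb = sum((g == lv).sum() * (pc[(g == lv).to_numpy()].mean() - grand) ** 2
                  for lv in levels)
        sst = ((pc - grand) ** 2).sum()
        ssw = sst - ssb
        df1, df2 = n_groups - 1, len(pc) - n_groups
        f = (ssb / df1) / (ssw / df2)
        return ManovaResult(
            pillai_trace=float(ssb / sst), approx_f=float(f), df1=float(df1),
            df2=float(df2), p_value=float(stats.f.sf(f, df1, df2)), n_components=1)
    df = pd.DataFrame(pcs, columns=[f"pc{i+1}" for i in range(n_components)])
    df["group"] = g.to_numpy()
    lhs = " + ".join(df.columns[:-1])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mv = MANOVA.from_formula(f"{lhs} ~ C(group)", data=df)
            tab = mv.mv_test().results["C(group)"]["stat"]
    except Exception as exc:  # singular within-group scatter
        raise ValueError(f"MANOVA failed (try fewer components): {exc}") from exc
    row = tab.loc["Pillai's trace"]
    return ManovaResult(
        pillai_trace=float(row["Value"]), approx_f=float(row["F Value"]),
        df1=float(row["Num DF"]), df2=float(row["Den DF"]),
        p_value=float(row["Pr > F"]), n_components=n_components)
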