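"""Covariate-adjusted association of protein abundance with clinical and
imaging variables.

Per (protein, variable) pair an ordinary least-squares model
``log2 abundance ~ variable + age + sex`` is fitted on complete cases;
the variable's beta is the change in log2 abundance per unit of the
variable.  P-values are Benjamini-Hochberg adjusted per clinical
variable across proteins.  Optional empirical-Bayes variance moderation
pools residual variances across proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import CohortMatrix

logger = logging.getLogger(__name__)

__all__ = ["AssociationResult", "clinical_association", "bh_adjust", "scale_effects"]


@dataclass
class AssociationResult:
    gene_symbol: str
    variable: str
    beta: float
    se: float
    p_value: float
    n: int
    adjusted_p: Optional[float] = None
    standardized_beta: Optional[float] = None
    flagged: bool = False  # collinear / degenerate design
    sd_variable: Optional[float] = None
    sd_protein: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "gene_symbol": self.gene_symbol, "variable": self.variable,
            "beta": self.beta, "se": self.se, "p_value": self.p_value,
            "adjusted_p": self.adjusted_p, "n": self.n,
            "standardized_beta": self.standardized_beta, "flagged": self.flagged,
        }


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def _ols(y: np.ndarray, X: np.ndarray):
    """Least squares with classical t-inference on the first non-intercept
    column; returns (beta, se, p, df_resid, sigma2)."""
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - k
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    t = beta[1] / se if se > 0 else np.inf
    p = 2 * stats.t.sf(abs(t), df)
    return float(beta[1]), float(se), float(min(max(p, np.nextafter(0, 1)), 1.0)), df, float(sigma2)


def _moderate(results_by_var: Dict[str, list]) -> None:
    """Empirical-Bayes variance moderation within each variable's family.

    Residual variances are shrunk toward a pooled prior via a scaled
    inverse-chi-square model with moments-matched prior df; t-statistics
    are recomputed with the moderated variance and df + prior df.
    """
    for var, rows in results_by_var.items():
        s2 = np.array([r["sigma2"] for r in rows])
        dfs = np.array([r["df"] for r in rows])
        if len(s2) < 3 or np.any(s2 <= 0):
            continue
        z = np.log(s2)
        # moments of log-variances under scaled inv-chi2 (Smyth-style)
        e_z = z - (np.log(dfs / 2) - _digamma(dfs / 2))
        mean_e, var_z = e_z.mean(), e_z.var(ddof=1)
        excess = var_z - np.mean(_trigamma(dfs / 2))
        if excess > 0:
            d0 = 2 * _trigamma_inverse(excess)
            s0_2 = np.exp(mean_e + _digamma(d0 / 2) - np.log(d0 / 2))
        else:
            d0, s0_2 = np.inf, np.exp(mean_e)
        for r in rows:
            df = r["df"]
            post = ((d0 * s0_2 + df * r["sigma2"]) / (d0 + df)) if np.isfinite(d0) else s0_2
            scale = np.sqrt(post / r["sigma2"])
            se = r["res"].se * scale
            df_tot = df + (d0 if np.isfinite(d0) else 1e6)
            t = r["res"].beta / se if se > 0 else np.inf
            r["res"].se = float(se)
            r["res"].p_value = float(min(max(2 * stats.t.sf(abs(t), df_tot),
                                             np.nextafter(0, 1)), 1.0))


def _digamma(x):
    from scipy.special import digamma
    return digamma(x)


def _trigamma(x):
    from scipy.special import polygamma
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(_trigamma(x))
        step = tri * (1.0 - tri / y) / float(_tetragamma(x))
        x_new = max(x + step, 1e-6)
        if abs(x_new - x) < 1e-8 * x:
            return float(x_new)
        x = x_new
    return float(x)


def _tetragamma(x):
    from scipy.special import polygamma
    return polygamma(2, x)


def clinical_association(m: CohortMatrix, clinical: pd.DataFrame,
                         covariates: Sequence[str] = ("age", "sex"),
                         moderate: bool = False) -> List[AssociationResult]:
    """Associate every protein with every clinical variable, adjusted for
    covariates.

    ``clinical`` has one row per subject (index or ``subject_id`` column)
    and one column per variable; ``age``/``sex`` columns supply the
    covariates.  Complete-case analysis per pair; constant (collinear)
    designs are flagged and excluded from the BH family.
    """
    if m.scale not in ("log2", "zscore"):
        raise ValueError("clinical_association expects log2-scale abundances")
    clin = clinical.set_index("subject_id") if "subject_id" in clinical.columns else clinical
    clin = clin.loc[[s for s in m.subjects if s in clin.index]]
    variables = [c for c in clin.columns if c not in covariates]
    cov_arrays = {}
    for cov in covariates:
        if cov not in clin.columns:
            raise ValueError(f"covariate {cov!r} not in clinical table")
        col = clin[cov]
        cov_arrays[cov] = ((col == "F").astype(float) if col.dtype == object else
                           col.astype(float))

    results: List[AssociationResult] = []
    by_var: Dict[str, list] = {}
    for var in variables:
        v = clin[var].astype(float)
        for gene in m.proteins:
            yv = m.data.loc[gene, clin.index]
            block = pd.DataFrame({"y": yv.to_numpy(dtype=float), "v": v.to_numpy()})
            for cov in covariates:
                block[cov] = cov_arrays[cov].to_numpy()
            block = block.dropna()
            n = len(block)
            p_params = 2 + len(covariates)
            if n < p_params + 1:
                continue
            X = np.column_stack([np.ones(n), block["v"].to_numpy()] +
                                [block[c].to_numpy() for c in covariates])
            res = AssociationResult(gene_symbol=str(gene), variable=str(var),
                                    beta=np.nan, se=np.nan, p_value=1.0, n=n,
                                    sd_variable=float(block["v"].std(ddof=1)),
                                    sd_protein=float(block["y"].std(ddof=1)))
            if np.linalg.matrix_rank(X) < X.shape[1]:
                res.flagged = True
                logger.warning("collinear design for (%s, %s); excluded from BH family",
                               gene, var)
                results.append(res)
                continue
            beta, se, p, df, sigma2 = _ols(block["y"].to_numpy(), X)
            res.beta, res.se, res.p_value = beta, se, p
            results.append(res)
            by_var.setdefault(var, []).append({"res": res, "df": df, "sigma2": sigma2})

    if moderate:
        _moderate(by_var)
    # BH family: per clinical variable, across proteins
    for var, rows in by_var.items():
        adj = bh_adjust([r["res"].p_value for r in rows])
        for r, a in zip(rows, adj):
            r["res"].adjusted_p = float(a)
    return results


def scale_effects(results: Sequence[AssociationResult]) -> List[AssociationResult]:
    """Standardize betas (beta * sd(variable)/sd(protein)) so effect sizes
    are comparable across variables; idempotent."""
    for r in results:
        if r.standardized_beta is not None:
            continue
        if not r.sd_variable or r.sd_variable == 0 or np.isnan(r.sd_variable):
            r.flagged = True
            continue
        if not r.sd_protein or r.sd_protein == 0:
            r.flagged = True
            continue
        r.standardized_beta = float(r.beta * r.sd_variable / r.sd_protein)
    return list(results)
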