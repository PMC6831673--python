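"""Survey-weighted logistic regression with sandwich variance.

The fit maximizes the weighted pseudo-log-likelihood
``sum_i w_i [y_i log p_i + (1 - y_i) log(1 - p_i)]`` by iteratively
reweighted least squares.  Variance is the weights-only sandwich (robust,
with-replacement approximation): it ignores strata/PSU structure, so
intervals are an approximation to full Taylor-linearized design-based ones.
Weights are normalized to mean 1 before fitting; point estimates are
invariant to rescaling the weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


class SeparationError(RuntimeError):
    """Quasi-complete separation: a coefficient diverges instead of
    converging (the classic rare-cell logistic pathology).

    ``term`` names the diverging coefficient when identifiable.
    """

    def __init__(self, message: str, term: str | None = None):
        super().__init__(message)
        self.term = term


@dataclass
class WeightedGLMFit:
    terms: list[str]
    beta: np.ndarray
    vcov: np.ndarray
    converged: bool
    n_iter: int
    weight_total: float
    n_obs: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se}, index=pd.Index(self.terms, name="term")
        )


def _design(X_design) -> tuple[np.ndarray, list[str]]:
    if isinstance(X_design, pd.DataFrame):
        return X_design.to_numpy(dtype=float), list(X_design.columns)
    arr = np.asarray(X_design, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def add_intercept(X: pd.DataFrame, name: str = "(Intercept)") -> pd.DataFrame:
    out = X.copy()
    out.insert(0, name, 1.0)
    return out


def fit_weighted_logistic(
    X_design, y, weights=None,
    max_iter: int = 100, tol: float = 1e-8,
    separation_bound: float = 15.0,
) -> WeightedGLMFit:
    """IRLS fit of the weighted logistic pseudo-likelihood.

    Converges when ``max |delta beta| < tol`` (default 1e-8) within
    ``max_iter`` iterations.  If the fit fails to converge while some
    coefficient exceeds ``separation_bound`` in magnitude, a
    :class:`SeparationError` naming the offending term is raised — diverging
    estimates from near-empty cells are an error, not a number.
    """
    X, terms = _design(X_design)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("y has a single class")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
    weight_total = float(w.sum())
    w = w / w.mean()  # normalize to mean 1 for numerical stability

    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(p, 1e-10, 1 - 1e-10)
        wls = w * mu * (1 - mu)
        score = X.T @ (w * (y - mu))
        H = (X * wls[:, None]).T @ X
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"singular working Hessian at iteration {it}"
            ) from exc
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged and np.max(np.abs(beta)) > separation_bound:
        worst = terms[int(np.argmax(np.abs(beta)))]
        raise SeparationError(
            f"coefficient for {worst!r} diverged (|beta| > {separation_bound}); "
            "likely quasi-complete separation — check for near-empty factor cells",
            term=worst,
        )

    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    mu = np.clip(p, 1e-10, 1 - 1e-10)
    A = (X * (w * mu * (1 - mu))[:, None]).T @ X
    U = X * (w * (y - mu))[:, None]  # weighted score contributions
    B = U.T @ U
    Ainv = np.linalg.inv(A)
    vcov = Ainv @ B @ Ainv
    vcov = (vcov + vcov.T) / 2.0
    return WeightedGLMFit(
        terms=terms, beta=beta, vcov=vcov, converged=converged,
        n_iter=it, weight_total=weight_total, n_obs=n,
    )


def odds_ratios(
    fit: WeightedGLMFit, level: float = 0.95,
    labels: dict[str, str] | None = None,
    include_intercept: bool = False,
) -> pd.DataFrame:
    """Odds ratios with Wald confidence limits, exp(beta +/- z * se).

    ``labels`` can attach "level vs reference" descriptions to terms (e.g.
    ``{"language=Spanish": "Spanish vs English"}``).
    """
    if not fit.converged:
        raise ValueError("odds ratios require a converged fit")
    z = norm.ppf(0.5 + level / 2.0)
    rows = []
    for term, b, s in zip(fit.terms, fit.beta, fit.se):
        if term == "(Intercept)" and not include_intercept:
            continue
        rows.append(
            {
                "term": term,
                "label": (labels or {}).get(term, term),
                "point": float(np.exp(b)),
                "lo95": float(np.exp(b - z * s)),
                "hi95": float(np.exp(b + z * s)),
            }
        )
    return pd.DataFrame(rows).set_index("term")


def predict_prob(fit: WeightedGLMFit, X_new) -> np.ndarray:
    """Predicted probabilities 1 / (1 + exp(-x' beta)) for new rows.

    ``X_new`` columns must match the fit's terms exactly (same reference
    coding); a mismatch is an error so respondents from unseen factor levels
    can never be silently scored.
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [t for t in fit.terms if t not in X_new.columns]
        extra = [c for c in X_new.columns if c not in fit.terms]
        if missing or extra:
            raise ValueError(
                f"design mismatch: missing terms {missing}, unexpected columns {extra}"
            )
        X = X_new[fit.terms].to_numpy(dtype=float)
    else:
        X = np.asarray(X_new, dtype=float)
        if X.shape[1] != len(fit.terms):
            raise ValueError(
                f"expected {len(fit.terms)} columns, got {X.shape[1]}"
            )
    eta = np.clip(X @ fit.beta, -500, 500)
    return 1.0 / (1.0 + np.exp(-eta))


def evaluate_predictions(probs, y_true, threshold: float = 0.5) -> dict:
    """Held-out classification metrics.

    accuracy
        Fraction with ``1{p >= threshold} == y``.
    auc
        Mann-Whitney form: P(p_case > p_control) + 0.5 P(tie) over all
        case-control pairs; ``None`` (flagged) when only one class is
        present.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(y_true, dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y_true must be binary 0/1")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    accuracy = float((tp + tn) / len(y))
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        auc = None
    else:
        ranks = rankdata(p)  # midranks implement the half-credit tie rule
        auc = float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    return {
        "accuracy": accuracy,
        "auc": auc,
        "auc_defined": auc is not None,
        "threshold": float(threshold),
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        "n": len(y),
    }
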