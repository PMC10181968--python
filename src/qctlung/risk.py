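"""Risk statistics: group comparisons, logistic modelling and ROC analysis.

This module carries the statistical chain that turns a cohort table into a
malignancy risk model:

1. descriptive group comparisons (Mann-Whitney U for continuous variables,
   Pearson chi-square for categorical ones);
2. univariate logistic screens and a multivariate backward elimination
   driven by likelihood-ratio tests (SPSS-style removal at p >= 0.10);
3. published clinical risk scores (Mayo Clinic model for incidental
   nodules; parsimonious Brock/PanCan model for screening-detected
   nodules), loaded from auditable JSON constants files;
4. extension of a clinical model with quantitative-CT covariates: the base
   model enters as its logit with a free recalibration slope, the QCT
   covariates are added, and the gain is a 2-df likelihood-ratio test;
5. ROC AUC with DeLong variance and confidence interval.

The logistic fitter is iteratively reweighted least squares with Wald
standard errors, explicit separation and rank-deficiency diagnostics.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "GroupComparison",
    "LogisticFit",
    "ModelComparison",
    "RocResult",
    "RiskModelSpec",
    "SelectionResult",
    "ExtensionResult",
    "compare_groups",
    "fit_logistic",
    "lr_test",
    "backward_select_lr",
    "load_model_spec",
    "mayo_probability",
    "brock_probability",
    "extend_with_qct",
    "roc_auc",
    "SeparationError",
    "RankDeficiencyError",
]


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation: the MLE does not exist."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


# ---------------------------------------------------------------- descriptive


@dataclasses.dataclass
class GroupComparison:
    variable: str
    kind: str  # "continuous" | "categorical"
    statistic: float
    p_value: float
    summary: dict


def _median_iqr(x: np.ndarray) -> dict:
    return {
        "n": int(x.size),
        "median": float(np.median(x)),
        "iqr": (float(np.percentile(x, 25)), float(np.percentile(x, 75))),
    }


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    *,
    outcome: str = "malignant",
    kind: str = "auto",
) -> GroupComparison:
    """Benign-vs-malignant comparison of one variable.

    Continuous variables use the two-sided Mann-Whitney U test (exact when
    both groups have n <= 8 and no ties, otherwise the normal approximation
    with tie and continuity correction) and are summarized as median [IQR]
    per group. Categorical variables use Pearson's chi-square without
    continuity correction and are summarized as counts (percentages).
    """
    y = cohort[outcome].to_numpy()
    col = cohort[variable]
    if kind == "auto":
        kind = "continuous" if pd.api.types.is_numeric_dtype(col) and col.nunique() > 4 else "categorical"
    if kind == "continuous":
        x0 = pd.to_numeric(col[y == 0], errors="coerce").dropna().to_numpy(dtype=float)
        x1 = pd.to_numeric(col[y == 1], errors="coerce").dropna().to_numpy(dtype=float)
        if x0.size == 0 or x1.size == 0:
            raise ValueError(f"empty group for variable {variable!r}")
        if np.ptp(np.concatenate([x0, x1])) == 0:
            raise ValueError(f"variable {variable!r} is constant")
        pooled = np.concatenate([x0, x1])
        exact_ok = x0.size <= 8 and x1.size <= 8 and np.unique(pooled).size == pooled.size
        res = stats.mannwhitneyu(
            x1, x0, alternative="two-sided",
            method="exact" if exact_ok else "asymptotic",
            use_continuity=True,
        )
        return GroupComparison(
            variable=variable,
            kind="continuous",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            summary={"benign": _median_iqr(x0), "malignant": _median_iqr(x1)},
        )
    tab = pd.crosstab(col, y)
    if tab.shape[1] < 2 or (tab.sum(axis=0) == 0).any():
        raise ValueError(f"empty group for variable {variable!r}")
    chi2, p, dof, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    pct = tab / tab.sum(axis=0)
    summary = {
        str(level): {
            "benign": (int(tab.loc[level, 0]), float(100 * pct.loc[level, 0])),
            "malignant": (int(tab.loc[level, 1]), float(100 * pct.loc[level, 1])),
        }
        for level in tab.index
    }
    return GroupComparison(
        variable=variable, kind="categorical", statistic=float(chi2),
        p_value=float(p), summary=summary,
    )


# ------------------------------------------------------------------ logistic


@dataclasses.dataclass
class LogisticFit:
    names: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    loglik: float
    n: int
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        if self.loglik > 1e-9:
            raise ValueError("log-likelihood of a Bernoulli model must be <= 0")

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.names.index(name)])

    @property
    def wald_z(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def wald_p(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.wald_z))

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """OR with Wald CI = exp(beta +/- z * SE), per covariate."""
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "or": np.exp(self.params),
                "or_ci_low": lo,
                "or_ci_high": hi,
                "p": self.wald_p,
            },
            index=list(self.names),
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, dtype=float) @ self.params)


def _as_design(
    X, names: Sequence[str] | None, add_intercept: bool
) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        names = tuple(map(str, X.columns))
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = tuple(names) if names else tuple(f"x{i}" for i in range(X.shape[1]))
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ("intercept",) + tuple(names)
    return X, names


def fit_logistic(
    X,
    y,
    *,
    names: Sequence[str] | None = None,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    Convergence is declared when the relative log-likelihood change drops
    below ``tol``. Raises :class:`SeparationError` on (quasi-)perfect
    separation and :class:`RankDeficiencyError` (naming the offending
    columns) on a singular design.
    """
    X, names_t = _as_design(X, names, add_intercept)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")

    # rank diagnostics with column names
    _, r, piv = _qr_pivot(X)
    diag = np.abs(np.diag(r))
    rank = int((diag > diag.max() * 1e-10).sum()) if diag.size else 0
    if rank < p:
        bad = [names_t[j] for j in piv[rank:]]
        raise RankDeficiencyError(f"collinear design columns: {bad}")

    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "IRLS normal equations singular (possible separation)"
            ) from exc
        beta = beta_new
        ll = _bernoulli_loglik(y, X @ beta)
        if np.abs(ll - ll_old) < tol * (np.abs(ll) + tol):
            converged = True
            break
        ll_old = ll
    eta = X @ beta
    ll = _bernoulli_loglik(y, eta)
    if np.max(np.abs(eta)) > 30.0 or np.max(np.abs(beta)) > 1e4:
        mu = expit(eta)
        if np.all((mu > 0.5) == (y > 0.5)) and ll > -1e-6 * n:
            raise SeparationError(
                "perfect separation detected: coefficients diverge, MLE does not exist"
            )
    cov = np.linalg.inv(X.T @ (X * np.clip(expit(eta) * (1 - expit(eta)), 1e-12, None)[:, None]))
    return LogisticFit(
        names=names_t,
        params=beta,
        bse=np.sqrt(np.diag(cov)),
        loglik=float(ll),
        n=n,
        converged=converged,
        n_iter=it,
    )


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    return qr(X, mode="economic", pivoting=True)


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically safe: log(1+e^eta) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclasses.dataclass
class ModelComparison:
    lr_statistic: float
    df: int
    p_value: float
    label_full: str
    label_reduced: str

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")


def lr_test(full: LogisticFit, reduced: LogisticFit, *, labels=("full", "reduced")) -> ModelComparison:
    """Likelihood-ratio test of nested fits; LR clipped at 0 for round-off."""
    df = len(full.names) - len(reduced.names)
    if df < 1:
        raise ValueError("full model must have more parameters than reduced")
    lr = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return ModelComparison(
        lr_statistic=lr,
        df=df,
        p_value=float(stats.chi2.sf(lr, df)),
        label_full=labels[0],
        label_reduced=labels[1],
    )


@dataclasses.dataclass
class SelectionResult:
    selected: tuple[str, ...]
    fit: LogisticFit | None
    path: tuple[tuple[str, float], ...]  # (dropped covariate, removal p)


def backward_select_lr(
    X: pd.DataFrame,
    y,
    *,
    candidates: Sequence[str] | None = None,
    p_remove: float = 0.10,
    add_intercept: bool = True,
) -> SelectionResult:
    """Backward elimination by likelihood-ratio tests.

    Starting from all ``candidates`` (default: every column of ``X``),
    repeatedly refit without each remaining covariate, compute the 1-df LR
    removal p-value, and drop the covariate with the largest p while that p
    is at least ``p_remove``; ties break on covariate name order. Returns
    the retained set, the final fit (``None`` when everything was dropped)
    and the elimination path.
    """
    current = list(candidates) if candidates is not None else list(map(str, X.columns))
    if not current:
        raise ValueError("no candidate covariates")
    y = np.asarray(y)
    path: list[tuple[str, float]] = []
    fit = fit_logistic(X[current], y, add_intercept=add_intercept)
    while current:
        drops = []
        for name in current:
            rest = [c for c in current if c != name]
            if rest or add_intercept:
                reduced = fit_logistic(
                    X[rest] if rest else np.empty((len(y), 0)),
                    y,
                    names=rest,
                    add_intercept=add_intercept,
                )
                p = lr_test(fit, reduced).p_value
            else:
                p = 1.0  # removing the last covariate of an intercept-free model
            drops.append((name, p))
        # largest removal p; ties by name order
        drops.sort(key=lambda t: (-t[1], t[0]))
        name, p = drops[0]
        if p < p_remove:
            break
        current.remove(name)
        path.append((name, p))
        if current or add_intercept:
            fit = fit_logistic(
                X[current] if current else np.empty((len(y), 0)),
                y,
                names=current,
                add_intercept=add_intercept,
            )
        else:
            fit = None
            break
    return SelectionResult(selected=tuple(current), fit=fit, path=tuple(path))


# ------------------------------------------------------------- risk models


@dataclasses.dataclass
class RiskModelSpec:
    """A published logistic risk model as auditable constants.

    Terms support the transforms used by the packaged models:
    ``linear`` (coef * x), ``center`` (coef * (x - center)), ``indicator``
    (coef if the categorical value equals ``level``) and ``brock_size``
    (coef * ((x/10)^-0.5 - 10^-0.5-normalized offset)), the PanCan nodule
    size transform.
    """

    name: str
    citation: str
    intercept: float
    terms: tuple[dict, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        for t in self.terms:
            if not np.isfinite(t["coefficient"]):
                raise ValueError(f"non-finite coefficient in term {t}")

    @property
    def required_covariates(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(t["covariate"] for t in self.terms))

    def linear_predictor(self, record: Mapping) -> float:
        lp = self.intercept
        for t in self.terms:
            cov = t["covariate"]
            if cov not in record or record[cov] is None or (
                isinstance(record[cov], float) and np.isnan(record[cov])
            ):
                raise ValueError(f"missing required covariate {cov!r}")
            x = record[cov]
            kind = t.get("transform", "linear")
            if kind == "linear":
                lp += t["coefficient"] * float(x)
            elif kind == "center":
                lp += t["coefficient"] * (float(x) - float(t["center"]))
            elif kind == "indicator":
                lp += t["coefficient"] * float(str(x) == str(t["level"]))
            elif kind == "brock_size":
                size = float(x)
                if size <= 0:
                    raise ValueError("nodule size must be positive")
                lp += t["coefficient"] * ((size / 10.0) ** -0.5 - 1.58113883)
            else:
                raise ValueError(f"unknown transform {kind!r}")
        return float(lp)

    def probability(self, record: Mapping) -> float:
        return float(expit(self.linear_predictor(record)))


def load_model_spec(which: str) -> RiskModelSpec:
    """Load a packaged model constants file: ``"mayo"`` or ``"brock"``."""
    fname = {"mayo": "mayo.json", "brock": "brock_parsimonious.json"}[which]
    with importlib.resources.files("qctlung.models").joinpath(fname).open() as fh:
        raw = json.load(fh)
    return RiskModelSpec(
        name=raw["name"],
        citation=raw["citation"],
        intercept=float(raw["intercept"]),
        terms=tuple(raw["terms"]),
    )


def mayo_probability(record: Mapping, spec: RiskModelSpec | None = None) -> float:
    """Mayo Clinic malignancy probability for one subject record."""
    return (spec or load_model_spec("mayo")).probability(record)


def brock_probability(record: Mapping, spec: RiskModelSpec | None = None) -> float:
    """Parsimonious Brock (PanCan) malignancy probability for one record."""
    return (spec or load_model_spec("brock")).probability(record)


# --------------------------------------------------------------- extension


@dataclasses.dataclass
class ExtensionResult:
    base_fit: LogisticFit
    extended_fit: LogisticFit
    comparison: ModelComparison
    auc_base: "RocResult"
    auc_extended: "RocResult"


def extend_with_qct(
    base_probs,
    qct: pd.DataFrame,
    y,
    *,
    mode: str = "logit-covariate",
) -> ExtensionResult:
    """Add QCT covariates to a clinical base model.

    The base model enters as its logit. In ``"logit-covariate"`` mode
    (default) the logit gets a free recalibration slope, so base and
    extended models are properly nested and the added value of the QCT
    covariates is the LR test with df = number of QCT columns. In
    ``"offset"`` mode the base logit is a fixed offset (slope 1).
    """
    base_probs = np.asarray(base_probs, dtype=float)
    if np.any((base_probs <= 0) | (base_probs >= 1)):
        raise ValueError("base probabilities must lie strictly in (0, 1)")
    if np.ptp(base_probs) == 0:
        raise ValueError("degenerate base model: all probabilities equal")
    y = np.asarray(y)
    base_logit = logit(base_probs)
    qct = qct.astype(float)
    if qct.isna().any().any():
        raise ValueError("QCT covariates contain missing values")
    if mode == "logit-covariate":
        Xb = pd.DataFrame({"base_logit": base_logit})
        Xe = pd.concat([Xb, qct.reset_index(drop=True)], axis=1)
        base_fit = fit_logistic(Xb, y)
        extended_fit = fit_logistic(Xe, y)
    elif mode == "offset":
        base_fit = _fit_offset_only(base_logit, y)
        extended_fit = _fit_with_offset(qct, base_logit, y)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    comp = lr_test(extended_fit, base_fit, labels=("base+QCT", "base"))
    auc_b = roc_auc(base_probs, y)
    auc_e = roc_auc(extended_fit_predict(extended_fit, base_logit, qct, mode), y)
    return ExtensionResult(
        base_fit=base_fit,
        extended_fit=extended_fit,
        comparison=comp,
        auc_base=auc_b,
        auc_extended=auc_e,
    )


def extended_fit_predict(fit: LogisticFit, base_logit, qct: pd.DataFrame, mode: str) -> np.ndarray:
    if mode == "logit-covariate":
        X = np.column_stack([np.ones(len(base_logit)), base_logit, qct.to_numpy(dtype=float)])
        return expit(X @ fit.params)
    X = np.column_stack([np.ones(len(base_logit)), qct.to_numpy(dtype=float)])
    return expit(X @ fit.params + base_logit)


def _fit_offset_only(offset: np.ndarray, y: np.ndarray) -> LogisticFit:
    # intercept-only fit with fixed offset; 1-parameter IRLS
    beta = 0.0
    ll_old = -np.inf
    for it in range(100):
        eta = offset + beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        beta += np.sum(y - mu) / np.sum(w)
        ll = _bernoulli_loglik(y, offset + beta)
        if abs(ll - ll_old) < 1e-10 * (abs(ll) + 1e-10):
            break
        ll_old = ll
    eta = offset + beta
    w = expit(eta) * (1 - expit(eta))
    return LogisticFit(
        names=("intercept",),
        params=np.array([beta]),
        bse=np.array([1.0 / np.sqrt(w.sum())]),
        loglik=_bernoulli_loglik(y, eta),
        n=len(y),
        converged=True,
        n_iter=it + 1,
    )


def _fit_with_offset(qct: pd.DataFrame, offset: np.ndarray, y: np.ndarray) -> LogisticFit:
    X = np.column_stack([np.ones(len(y)), qct.to_numpy(dtype=float)])
    names = ("intercept",) + tuple(map(str, qct.columns))
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    for it in range(100):
        eta = offset + X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        z = (eta - offset) + (y - mu) / w
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        ll = _bernoulli_loglik(y, offset + X @ beta)
        if abs(ll - ll_old) < 1e-10 * (abs(ll) + 1e-10):
            break
        ll_old = ll
    eta = offset + X @ beta
    w = np.clip(expit(eta) * (1 - expit(eta)), 1e-12, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return LogisticFit(
        names=names,
        params=beta,
        bse=np.sqrt(np.diag(cov)),
        loglik=_bernoulli_loglik(y, eta),
        n=len(y),
        converged=True,
        n_iter=it + 1,
    )


# --------------------------------------------------------------------- ROC


@dataclasses.dataclass
class RocResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0, 1]")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI must contain the AUC")


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores, labels, *, alpha: float = 0.05) -> RocResult:
    """AUC with DeLong variance and Wald CI (truncated to [0, 1]).

    The AUC is the Mann-Whitney statistic with half credit for ties; the
    variance uses DeLong's structural components (placement values).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    allv = np.concatenate([pos, neg])
    t_all = _midrank(allv)
    t_pos = _midrank(pos)
    t_neg = _midrank(neg)
    auc = (t_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v_pos = (t_all[:m] - t_pos) / n  # placement of each positive among negatives
    v_neg = 1.0 - (t_all[m:] - t_neg) / m
    s_pos = np.var(v_pos, ddof=1) if m > 1 else 0.0
    s_neg = np.var(v_neg, ddof=1) if n > 1 else 0.0
    var = s_pos / m + s_neg / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return RocResult(
        auc=float(auc),
        variance=float(var),
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_pos=m,
        n_neg=n,
    )
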