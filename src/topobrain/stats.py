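"""Statistical workflow for evaluating topological imaging biomarkers.

Implements the full inferential stage of the biomarker analysis as
self-contained primitives so the pipeline has no hidden statistical
dependencies: Wilcoxon rank-sum group comparison (exact enumeration for
small tie-free samples, tie- and continuity-corrected normal approximation
otherwise), Cohen's d with pooled SD, post-hoc power of the two-sample
t-test via the noncentral t, maximum-likelihood logistic regression
(Newton-Raphson) with Wald inference, Benjamini-Hochberg FDR adjustment,
subject-level percentile bootstrap for odds ratios, and the rank-based
(Mann-Whitney) ROC AUC.

Scipy supplies distribution functions only; the estimators and tests
themselves are authored here and cross-checked against scipy/statsmodels in
the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ModelFit",
    "SeparationError",
    "wilcoxon_rank_sum",
    "cohens_d",
    "posthoc_power",
    "logistic_fit",
    "bh_adjust",
    "bootstrap_or_ci",
    "roc_auc",
]

Z975 = 1.96  # Wald 95% normal quantile, matching standard software output


class SeparationError(RuntimeError):
    """Raised when the logistic MLE diverges (perfect separation)."""

    def __init__(self, covariate: str):
        self.covariate = covariate
        super().__init__(
            f"perfect separation: covariate {covariate!r} separates the outcome"
        )


# ---------------------------------------------------------------------------
# Group comparison


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (rank-sum statistic of ``x``, two-sided p).  Exact enumeration
    of all rank assignments when n1 + n2 <= 10 and there are no ties;
    otherwise the normal approximation with midranks, tie-corrected
    variance, and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())

    has_ties = len(np.unique(pooled)) < n
    if n <= 10 and not has_ties:
        # enumerate all C(n, n1) assignments of ranks to the x-sample
        all_ranks = np.arange(1, n + 1)
        sums = np.fromiter(
            (sum(c) for c in itertools.combinations(all_ranks, n1)),
            dtype=float,
        )
        p_low = np.mean(sums <= w)
        p_high = np.mean(sums >= w)
        return w, float(min(1.0, 2 * min(p_low, p_high)))

    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return w, 1.0
    z = (abs(w - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return w, float(min(1.0, 2 * sps.norm.sf(z)))


def cohens_d(x, y) -> float:
    """Standardized mean difference with pooled (n-1) variance."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / math.sqrt(s2))


def posthoc_power(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test at effect size ``d``.

    Noncentrality d * sqrt(n1 n2 / (n1 + n2)), df = n1 + n2 - 2, evaluated
    with the noncentral t distribution.
    """
    if not (n1 >= 2 and n2 >= 2 and 0 < alpha < 1 and np.isfinite(d)):
        raise ValueError("invalid power-analysis inputs")
    df = n1 + n2 - 2
    nc = d * math.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    power = sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
    return float(power)


# ---------------------------------------------------------------------------
# Logistic regression


@dataclass(frozen=True)
class ModelFit:
    """Logistic-regression fit with Wald inference.

    All per-covariate entries exclude the intercept (reported separately).
    """

    covariates: tuple[str, ...]
    coefficients: np.ndarray  # log-odds
    std_errors: np.ndarray
    odds_ratios: np.ndarray
    wald_ci: np.ndarray  # (p, 2) on the OR scale
    p_values: np.ndarray  # two-sided Wald
    intercept: float
    auc: float
    n_obs: int
    converged: bool = True
    fitted_probs: np.ndarray = dc_field(
        default_factory=lambda: np.empty(0), repr=False
    )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "odds_ratio": self.odds_ratios,
                "ci_low": self.wald_ci[:, 0],
                "ci_high": self.wald_ci[:, 1],
                "p_value": self.p_values,
            },
            index=list(self.covariates),
        )


def _check_separation(X: np.ndarray, y: np.ndarray, names) -> None:
    """Raise SeparationError naming a covariate that completely separates y.

    Only *complete* (strict) single-covariate separation is an error;
    quasi-complete separation (boundary overlap, e.g. a zero cell in a
    binary covariate) is fitted like standard GLM software does, returning
    a large coefficient with a correspondingly large Wald SE.
    """
    for j, name in enumerate(names):
        x0, x1 = X[y == 0, j], X[y == 1, j]
        if x0.max() < x1.min() or x1.max() < x0.min():
            raise SeparationError(name)


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -35, 35)
    return float(y @ eta - np.sum(np.log1p(np.exp(eta))))


def _newton_logistic(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, maxiter: int = 100
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson MLE.  Returns (beta, cov, converged).

    Stops on a small step or on a log-likelihood plateau; the plateau rule
    terminates quasi-separated fits the way IRLS software does.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    ll_old = _loglik(X, y, beta)
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        wt = mu * (1.0 - mu)
        H = (X * wt[:, None]).T @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        beta = beta + step
        ll = _loglik(X, y, beta)
        if np.max(np.abs(step)) < tol or abs(ll - ll_old) < 1e-9:
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    wt = mu * (1.0 - mu)
    H = (X * wt[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return beta, cov, converged


def logistic_fit(
    table: pd.DataFrame,
    outcome: str,
    covariates: list[str] | tuple[str, ...],
) -> ModelFit:
    """Maximum-likelihood logistic regression of a binary outcome.

    Wald CIs use exp(beta +/- 1.96 SE); AUC is the rank-based area under
    the ROC of the fitted probabilities.  Listwise deletion of rows with
    missing values.  Raises :class:`SeparationError` on perfect separation
    and ``ValueError`` on a rank-deficient design or single-class outcome.
    """
    covariates = list(covariates)
    cols = [outcome] + covariates
    data = table[cols].dropna()
    y = np.asarray(data[outcome], dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("outcome must be binary with both classes present")
    Xc = np.asarray(data[covariates], dtype=float)
    X = np.column_stack([np.ones(len(y)), Xc])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    _check_separation(Xc, y, covariates)

    beta, cov, converged = _newton_logistic(X, y)
    if not converged or np.max(np.abs(beta)) > 50:
        # MLE drifting to infinity: separation by some linear combination
        raise SeparationError("linear combination of covariates")

    se = np.sqrt(np.diag(cov))
    coef = beta[1:]
    se_c = se[1:]
    with np.errstate(over="ignore"):  # quasi-separated fits: CI bound -> inf
        or_ = np.exp(coef)
        ci = np.exp(
            np.column_stack([coef - Z975 * se_c, coef + Z975 * se_c])
        )
    z = np.divide(coef, se_c, out=np.zeros_like(coef), where=se_c > 0)
    pvals = 2 * sps.norm.sf(np.abs(z))
    probs = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -35, 35)))
    return ModelFit(
        covariates=tuple(covariates),
        coefficients=coef,
        std_errors=se_c,
        odds_ratios=or_,
        wald_ci=ci,
        p_values=pvals,
        intercept=float(beta[0]),
        auc=roc_auc(probs, y),
        n_obs=len(y),
        converged=converged,
        fitted_probs=probs,
    )


# ---------------------------------------------------------------------------
# Multiplicity, bootstrap, ROC


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def bootstrap_or_ci(
    table: pd.DataFrame,
    outcome: str,
    covariates: list[str] | tuple[str, ...],
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Subject-level percentile bootstrap of logistic odds ratios.

    Case resampling with replacement (unstratified).  Resamples on which
    the fit fails (separation, non-convergence, rank deficiency) are
    redrawn and counted; more than 50% failed draws aborts.
    Returns ``{covariate: (lo, hi), ..., "n_failed": count}`` with the
    2.5th/97.5th percentiles of the B odds-ratio estimates.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    covariates = list(covariates)
    logistic_fit(table, outcome, covariates)  # must succeed on the data
    n = len(table)
    ors = np.empty((B, len(covariates)))
    done = 0
    failed = 0
    while done < B:
        idx = rng.integers(0, n, size=n)
        resample = table.iloc[idx]
        try:
            fit = logistic_fit(resample, outcome, covariates)
        except (SeparationError, ValueError):
            failed += 1
            if failed > done and failed >= B:  # > 50% of draws failed
                raise RuntimeError(
                    f"bootstrap redraw exhaustion: {failed} failed resamples"
                )
            continue
        ors[done] = fit.odds_ratios
        done += 1
    lo = np.percentile(ors, 2.5, axis=0)
    hi = np.percentile(ors, 97.5, axis=0)
    out: dict = {c: (float(lo[j]), float(hi[j])) for j, c in enumerate(covariates)}
    out["n_failed"] = failed
    return out


def load_cohort_xlsx(
    path, column_map: dict[str, str] | None = None, sheet: int | str = 0
) -> pd.DataFrame:
    """Read a per-subject cohort spreadsheet into the analysis layout.

    ``column_map`` maps spreadsheet column names to the canonical names
    used by the pipeline (``group``, ``age``, ``cvd``, ``ch50``,
    ``duration``, ``pred_dose``, ``dim{0,1}_*``); unmapped columns pass
    through unchanged.
    """
    table = pd.read_excel(path, sheet_name=sheet)
    if column_map:
        table = table.rename(columns=dict(column_map))
    return table


def roc_auc(scores, labels) -> float:
    """Rank-based AUC: P(score_case > score_control), ties counted 1/2."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both label classes must be present")
    ranks = sps.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
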