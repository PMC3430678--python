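"""Model development: logistic regression, stepwise selection, diagnostics.

Re-derives MSI-style death-probability models from cohort data: maximum
likelihood logistic fits, forward-stepwise covariate selection with
likelihood-ratio tests (entry p < 0.05, removal p > 0.10), the
Hosmer-Lemeshow calibration test, Nagelkerke pseudo-R2, AUROC with DeLong
intervals, the random 80/20 development/testing split, and the
Hanley-McNeil AUROC-based sample-size computation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from .epi import IntervalEstimate
from .markers import CaseRecord
from .msi import MsiCoefficients, derive_covariates

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticFit",
    "FitDiagnostics",
    "fit_logistic",
    "stepwise_select",
    "hosmer_lemeshow",
    "nagelkerke_r2",
    "auroc",
    "split_cohort",
    "auroc_sample_size",
    "design_matrix",
]

#: |coefficient| on the standardized scale beyond which the fit is flagged
#: as likely separated.
_SEPARATION_BOUND = 15.0


@dataclass
class LogisticFit:
    """A fitted binary logistic regression."""

    params: pd.Series
    cov: pd.DataFrame
    llf: float
    llnull: float
    n: int
    converged: bool
    n_iter: int
    separation_suspected: bool = False

    @property
    def names(self) -> list[str]:
        return list(self.params.index)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = _with_intercept(pd.DataFrame(X))
        X = X[self.names]
        eta = X.to_numpy(dtype=float) @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def to_msi_coefficients(self, name: str = "refit") -> MsiCoefficients:
        """Interpret a model-II style fit (x1..x7) as an MSI coefficient set."""
        expected = ["const", "x1", "x2", "x3", "x4", "x5", "x6", "x7"]
        if list(self.params.index) != expected:
            raise ValueError(
                f"fit does not have the MSI covariate layout {expected}"
            )
        b = self.params.to_numpy()
        return MsiCoefficients(*[float(v) for v in b], name=name)


@dataclass
class FitDiagnostics:
    """Calibration, explained-variation and discrimination summaries."""

    hosmer_lemeshow: tuple[float, int, float]
    nagelkerke_r2: float
    auroc: IntervalEstimate
    pct_deaths_pred_gt_half: float


def _with_intercept(X: pd.DataFrame) -> pd.DataFrame:
    if "const" not in X.columns:
        X = sm.add_constant(X, has_constant="add")
    cols = ["const"] + [c for c in X.columns if c != "const"]
    return X[cols]


def fit_logistic(
    y: Sequence[int] | np.ndarray,
    X: pd.DataFrame | np.ndarray,
    add_intercept: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic regression (iteratively reweighted LS).

    Deterministic given the input.  Perfect separation is detected (via
    diverging standardized coefficients or solver warnings) and flagged on
    the returned fit rather than silently 'fixed'; non-convergence is
    reported with the iteration count.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).reset_index(drop=True)
    if add_intercept:
        X = _with_intercept(X)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")
    uniq = np.unique(y)
    if not np.isin(uniq, [0.0, 1.0]).all():
        raise ValueError("outcomes must be binary 0/1")
    if uniq.size < 2:
        raise ValueError("outcomes are all identical; model not estimable")

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception as exc:
            # Newton's singular Hessian under (quasi-)separation; retry with
            # a gradient method so the diverging fit can be inspected
            if "singular" not in str(exc).lower() and "separation" not in str(
                exc
            ).lower():
                raise RuntimeError(f"logistic fit failed: {exc}") from exc
            separation = True
            try:
                res = model.fit(disp=0, maxiter=500, method="bfgs")
            except Exception as exc2:  # pragma: no cover - defensive
                raise RuntimeError(f"logistic fit failed: {exc2}") from exc2
        for w in caught:
            if "separat" in str(w.message).lower():
                separation = True

    sds = X.to_numpy(dtype=float).std(axis=0)
    sds[sds == 0] = 1.0  # intercept / constant columns
    if np.any(np.abs(res.params.to_numpy() * sds) > _SEPARATION_BOUND):
        separation = True
    if separation:
        logger.warning("possible (quasi-)separation detected in logistic fit")
    if not res.mle_retvals.get("converged", True):
        logger.warning(
            "logistic fit did not converge after %s iterations",
            res.mle_retvals.get("iterations"),
        )
    try:
        cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    except Exception:  # singular information matrix under separation
        cov = pd.DataFrame(
            np.full((X.shape[1], X.shape[1]), np.nan),
            index=X.columns, columns=X.columns,
        )
    return LogisticFit(
        params=res.params,
        cov=cov,
        llf=float(res.llf),
        llnull=float(res.llnull),
        n=n,
        converged=bool(res.mle_retvals.get("converged", True)),
        n_iter=int(res.mle_retvals.get("iterations", -1)),
        separation_suspected=separation,
    )


def _lr_pvalue(ll_small: float, ll_big: float, df: int) -> float:
    lr = max(0.0, 2.0 * (ll_big - ll_small))
    return float(stats.chi2.sf(lr, df))


def stepwise_select(
    y: Sequence[int] | np.ndarray,
    candidates: pd.DataFrame,
    p_entry: float = 0.05,
    p_removal: float = 0.10,
    max_steps: int = 100,
) -> LogisticFit:
    """Forward stepwise logistic selection with likelihood-ratio tests.

    At each step the most significant remaining candidate with LR p-value
    below ``p_entry`` is added, then any retained term whose LR p-value
    (against the model without it) exceeds ``p_removal`` is removed.  A step
    cap guards against add/remove cycles.  Returns the fit of the selected
    model (intercept-only if nothing enters).
    """
    y = np.asarray(y, dtype=float)
    candidates = pd.DataFrame(candidates).reset_index(drop=True)
    if candidates.shape[1] == 0:
        raise ValueError("need at least one candidate covariate")
    if p_removal < p_entry:
        raise ValueError("p_removal must be >= p_entry to avoid cycling")
    selected: list[str] = []

    def _fit(cols: list[str]) -> LogisticFit:
        if cols:
            return fit_logistic(y, candidates[cols])
        X0 = pd.DataFrame({"const": np.ones(len(y))})
        return fit_logistic(y, X0, add_intercept=False)

    current = _fit(selected)
    for _ in range(max_steps):
        changed = False
        # entry: best LR p among remaining candidates
        remaining = [c for c in candidates.columns if c not in selected]
        best, best_p = None, 1.0
        for c in remaining:
            try:
                trial = _fit(selected + [c])
            except (ValueError, RuntimeError):
                continue
            p = _lr_pvalue(current.llf, trial.llf, 1)
            if p < best_p:
                best, best_p = c, p
        if best is not None and best_p < p_entry:
            selected.append(best)
            current = _fit(selected)
            changed = True
        # removal: worst LR p among retained terms
        while len(selected) > 0:
            worst, worst_p = None, -1.0
            for c in selected:
                reduced = _fit([s for s in selected if s != c])
                p = _lr_pvalue(reduced.llf, current.llf, 1)
                if p > worst_p:
                    worst, worst_p = c, p
            if worst is not None and worst_p > p_removal:
                selected.remove(worst)
                current = _fit(selected)
                changed = True
            else:
                break
        if not changed:
            break
    return current


def hosmer_lemeshow(
    y: Sequence[int] | np.ndarray,
    p_hat: Sequence[float] | np.ndarray,
    groups: int = 10,
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit test over risk deciles.

    Cases are sorted by predicted probability (stable sort, ties broken by
    case order) and split into ``groups`` near-equal groups; the statistic
    is sum (O - E)^2 / (E (1 - E/n_g)) with df = groups - 2.  Groups whose
    expected count is degenerate (E = 0 or E = n_g) are merged into their
    neighbour and the group count reduced, with a log message.
    """
    y = np.asarray(y, dtype=float)
    p_hat = np.asarray(p_hat, dtype=float)
    if y.shape != p_hat.shape:
        raise ValueError("y and p_hat must have equal length")
    n = y.size
    if n < groups:
        raise ValueError(f"need at least {groups} observations")
    order = np.argsort(p_hat, kind="stable")
    splits = [s for s in np.array_split(order, groups) if s.size > 0]
    obs = np.array([y[s].sum() for s in splits])
    exp = np.array([p_hat[s].sum() for s in splits])
    sizes = np.array([s.size for s in splits], dtype=float)
    ok = (exp > 0) & (exp < sizes)
    if not ok.all():
        logger.info(
            "hosmer_lemeshow: merging %d degenerate group(s)", (~ok).sum()
        )
        # pool degenerate groups into the adjacent kept group
        keep_obs, keep_exp, keep_sizes = [], [], []
        for o, e, s, k in zip(obs, exp, sizes, ok):
            if k or not keep_obs:
                keep_obs.append(o)
                keep_exp.append(e)
                keep_sizes.append(s)
            else:
                keep_obs[-1] += o
                keep_exp[-1] += e
                keep_sizes[-1] += s
        obs, exp, sizes = map(np.array, (keep_obs, keep_exp, keep_sizes))
    g = len(obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs - exp) ** 2 / (exp * (1 - exp / sizes))
    terms = terms[np.isfinite(terms)]
    chi2 = float(terms.sum())
    df = max(1, g - 2)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def nagelkerke_r2(fit: LogisticFit) -> float:
    """Nagelkerke pseudo-R2: Cox-Snell R2 rescaled by its maximum."""
    n = fit.n
    cox_snell = 1.0 - np.exp(2.0 * (fit.llnull - fit.llf) / n)
    max_cs = 1.0 - np.exp(2.0 * fit.llnull / n)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def _delong_variance(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """DeLong variance of the AUROC via placement values (midranks)."""
    m, n = pos_scores.size, neg_scores.size
    allv = np.concatenate([pos_scores, neg_scores])
    order = np.argsort(allv, kind="mergesort")
    ranks = stats.rankdata(allv)  # midranks
    pos_ranks = ranks[:m]
    neg_ranks = ranks[m:]
    pos_ranks_within = stats.rankdata(pos_scores)
    neg_ranks_within = stats.rankdata(neg_scores)
    del order
    # placement values: V10_i = fraction of negatives below positive i
    v10 = (pos_ranks - pos_ranks_within) / n
    v01 = 1.0 - (neg_ranks - neg_ranks_within) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auroc(
    y: Sequence[int] | np.ndarray,
    scores: Sequence[float] | np.ndarray,
    level: float = 0.95,
) -> IntervalEstimate:
    """Area under the ROC curve with a DeLong confidence interval.

    The point estimate is the Mann-Whitney concordance probability
    (ties counted half).  Requires both outcome classes present.
    """
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")
    point = float(roc_auc_score(y, scores))
    var = _delong_variance(scores[y == 1], scores[y == 0])
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    lo = max(0.0, point - half)
    hi = min(1.0, point + half)
    return IntervalEstimate(point, lo, hi, level, "delong")


def split_cohort(
    cohort: Sequence[CaseRecord], fraction_a: float = 0.80, seed: int = 0
) -> tuple[list[CaseRecord], list[CaseRecord]]:
    """Seeded simple random split into development (A) and testing (B) sets.

    |A| = round(fraction_a * n), without stratification by outcome.
    """
    if not 0.0 < fraction_a < 1.0:
        raise ValueError("fraction_a must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(cohort))
    n_a = int(round(fraction_a * len(cohort)))
    a_idx = set(idx[:n_a].tolist())
    a = [c for i, c in enumerate(cohort) if i in a_idx]
    b = [c for i, c in enumerate(cohort) if i not in a_idx]
    return a, b


def _hanley_mcneil_var(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)


def auroc_sample_size(
    neg_pos_ratio: float,
    alpha: float = 0.05,
    beta: float = 0.20,
    auc_null: float = 0.5,
    auc_alt: float = 0.8,
    max_pos: int = 1_000_000,
) -> int:
    """Required positives to test an AUROC against a null value.

    Hanley-McNeil variance-based computation: the smallest number of
    positive cases (with ``neg_pos_ratio`` negatives per positive) such that
    z_{alpha/2} * sqrt(V(auc_null)) + z_beta * sqrt(V(auc_alt))
    <= auc_alt - auc_null.  The negative:positive ratio is an explicit
    required argument -- there is no defensible universal default.
    """
    if not 0.5 <= auc_null < auc_alt < 1.0:
        raise ValueError("need 0.5 <= auc_null < auc_alt < 1")
    if neg_pos_ratio <= 0:
        raise ValueError("neg_pos_ratio must be positive")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(1 - beta)
    delta = auc_alt - auc_null
    for n_pos in range(2, max_pos + 1):
        n_neg = max(2, int(np.ceil(neg_pos_ratio * n_pos)))
        v0 = _hanley_mcneil_var(auc_null, n_pos, n_neg)
        v1 = _hanley_mcneil_var(auc_alt, n_pos, n_neg)
        if z_a * np.sqrt(v0) + z_b * np.sqrt(v1) <= delta:
            return n_pos
    raise RuntimeError("no feasible sample size below max_pos")


def design_matrix(cohort: Sequence[CaseRecord]) -> pd.DataFrame:
    """MSI covariate design matrix (columns x1..x7) for a cohort."""
    rows = [derive_covariates(c).as_vector() for c in cohort]
    return pd.DataFrame(rows, columns=[f"x{i}" for i in range(1, 8)])
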