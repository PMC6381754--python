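"""Shared statistical primitives for the methylation-signature pipeline.

Every pipeline stage funnels its inference through this module so that the
same conventions (two-sided tests, ties half-counted, seeded resampling)
hold everywhere:

* rank-sum (Wilcoxon / Mann-Whitney U) group comparison, exact by full
  enumeration for small untied samples, normal approximation with tie
  correction otherwise;
* Spearman rank correlation with midrank ties and a t-distribution p-value;
* empirical ROC curves with the pairwise-wins AUC, percentile bootstrap
  confidence intervals and the Youden-optimal operating cutoff;
* binomial logistic maximum likelihood with AIC;
* two-proportion sample-size design formulas.

All randomness is injected through explicit integer seeds.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as _sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "RankTestResult",
    "RocResult",
    "LogisticFit",
    "SampleSizePlan",
    "rank_sum_test",
    "spearman_correlation",
    "roc_with_bootstrap",
    "logistic_fit",
    "two_proportion_sample_size",
    "inflate_for_dropout",
    "auc_from_scores",
]

#: default combined-n ceiling for exact rank-test enumeration; discovery
#: cohorts here are small (10 vs 14), so the exact path is the common case
#: for per-gene comparisons while whole-cohort scores fall back to the
#: normal approximation.
DEFAULT_EXACT_LIMIT = 20


@dataclass(frozen=True)
class RankTestResult:
    """Two-sided rank-sum test outcome.

    ``u_statistic`` counts pairwise wins of group A over group B with ties
    half-counted, so it lies in [0, n_a * n_b].
    """

    u_statistic: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    n_a: int
    n_b: int
    degenerate: bool = False  # pooled values constant -> p = 1 by convention


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with bootstrap CI and Youden operating point.

    ``thresholds`` are candidate cutoffs in ascending order, starting at
    -inf; a sample is called positive when its score is strictly greater
    than the cutoff. ``auc`` is the pairwise-wins probability
    U / (n_pos * n_neg) with ties half-counted.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    youden_cutoff: float
    youden_j: float
    n_boot: int
    n_redraws: int  # single-class bootstrap resamples that were redrawn
    seed: int


@dataclass(frozen=True)
class LogisticFit:
    """Binomial logistic maximum-likelihood fit with intercept.

    ``aic = 2k - 2*log_likelihood`` where k counts every fitted parameter
    including the intercept. Under quasi-complete separation the likelihood
    has no finite maximiser; ``converged`` is False and the coefficients
    are those reached at the iteration cap.
    """

    coefficients: np.ndarray
    intercept: float
    log_likelihood: float
    aic: float
    converged: bool
    n_params: int
    feature_names: tuple[str, ...] = ()
    dropped_features: tuple[str, ...] = ()


@dataclass(frozen=True)
class SampleSizePlan:
    """Two-group design for comparing two response proportions."""

    p1: float
    p2: float
    alpha: float
    power: float
    n_per_group: int
    n_total: int
    n_with_dropout: int
    dropout: float = 0.0


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if np.isnan(arr).any():
        arr = arr[~np.isnan(arr)]
    return arr


def rank_sum_test(group_a, group_b, exact_limit: int = DEFAULT_EXACT_LIMIT) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney U comparison of two groups.

    The exact permutation distribution is enumerated when the combined
    sample size is at most ``exact_limit`` and the pooled values carry no
    ties; otherwise the normal approximation with tie correction and
    continuity correction is used. Constant pooled input is degenerate and
    returns p = 1 with the ``degenerate`` flag set.

    Parameters
    ----------
    group_a, group_b : array-like
        At least two values each; NaN entries are dropped.
    exact_limit : int
        Combined-n ceiling below which the exact distribution is used.
    """
    a = _as_1d_float(group_a, "group_a")
    b = _as_1d_float(group_b, "group_b")
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each group needs >= 2 values (got {a.size} and {b.size})"
        )
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        # all observations identical: every rank assignment is equivalent
        return RankTestResult(
            u_statistic=a.size * b.size / 2.0,
            p_two_sided=1.0,
            method="exact" if pooled.size <= exact_limit else "normal_approx",
            n_a=int(a.size),
            n_b=int(b.size),
            degenerate=True,
        )
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and pooled.size <= exact_limit:
        res = _sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = _sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal_approx"
    return RankTestResult(
        u_statistic=float(res.statistic),
        p_two_sided=float(min(res.pvalue, 1.0)),
        method=method,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    The p-value uses the t-distribution approximation
    t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom, which is
    accurate for n >= ~8 and conventional below that.

    Raises
    ------
    ValueError
        If fewer than 3 pairs remain or either margin is constant (rho is
        undefined when ranks carry no variation).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs (got {x.size})")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("Spearman rho is undefined for a constant margin")
    rho, p = _sps.spearmanr(x, y)
    return float(rho), float(min(p, 1.0))


def auc_from_scores(scores, labels) -> float:
    """Pairwise-wins AUC: P(score_pos > score_neg) with ties half-counted.

    Computed from midranks, which is exactly U / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = _sps.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _roc_curve(scores: np.ndarray, labels: np.ndarray):
    """Sensitivity/specificity at every cutoff, calling positive score > cutoff.

    Candidate cutoffs are -inf followed by the sorted unique scores; -inf
    calls everything positive and the largest score calls everything
    negative, so the curve spans (1,0) to (0,1) in (sens, 1-spec) space.
    """
    thresholds = np.concatenate([[-np.inf], np.unique(scores)])
    pos = scores[labels]
    neg = scores[~labels]
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    return thresholds, sens, spec


def roc_with_bootstrap(scores, labels, n_boot: int = 1000, seed: int = 0) -> RocResult:
    """Empirical ROC with percentile-bootstrap AUC CI and Youden cutoff.

    The confidence interval comes from unstratified case resampling: whole
    (score, label) cases are drawn with replacement ``n_boot`` times with
    the given seed, and the 2.5/97.5 percentiles of the resampled AUCs are
    reported. A resample that loses one class entirely is redrawn (the
    count of redraws is returned). The Youden cutoff is the smallest
    threshold attaining max(sensitivity + specificity - 1).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(bool).ravel()
    if scores.size != labels.size:
        raise ValueError("scores and labels must align")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    thresholds, sens, spec = _roc_curve(scores, labels)
    auc = auc_from_scores(scores, labels)
    j = sens + spec - 1.0
    j_max = float(j.max())
    # smallest cutoff attaining the max, up to float noise
    best = int(np.flatnonzero(j >= j_max - 1e-12)[0])
    youden_cutoff = float(thresholds[best])

    rng = np.random.default_rng(seed)
    n = scores.size
    boot = np.empty(n_boot)
    redraws = 0
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            lab = labels[idx]
            if lab.any() and not lab.all():
                break
            redraws += 1
            if redraws > 1000 * n_boot:
                raise RuntimeError("bootstrap cannot draw two-class resamples")
        boot[i] = auc_from_scores(scores[idx], lab)
    lo, hi = np.percentile(boot, [2.5, 97.5])

    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci_low=float(lo),
        auc_ci_high=float(hi),
        youden_cutoff=youden_cutoff,
        youden_j=j_max,
        n_boot=int(n_boot),
        n_redraws=int(redraws),
        seed=int(seed),
    )


def logistic_fit(features, labels, feature_names=None, maxiter: int = 200) -> LogisticFit:
    """Maximum-likelihood binomial logistic regression with intercept.

    ``features`` is an (n_samples, n_features) array; an empty feature set
    fits the intercept-only null model in closed form. Constant features
    are dropped with a warning. Quasi-complete separation leaves the
    likelihood without a finite maximiser: the fit is flagged
    ``converged=False`` and coefficients/AIC are reported at the iteration
    cap.
    """
    y = np.asarray(labels, dtype=float).ravel()
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        # degenerate outcome: p-hat at the boundary, MLE non-finite
        k = 1
        return LogisticFit(
            coefficients=np.empty(0),
            intercept=math.inf if y.sum() == y.size else -math.inf,
            log_likelihood=0.0,
            aic=2.0 * k,
            converged=False,
            n_params=k,
        )

    X = np.asarray(features, dtype=float)
    if X.size == 0:
        X = X.reshape(y.size, 0)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.size:
        raise ValueError("features and labels must have matching rows")
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(X.shape[1])
    )
    if len(names) != X.shape[1]:
        raise ValueError("feature_names length must match feature count")

    keep = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0.0]
    dropped = tuple(names[i] for i in range(X.shape[1]) if i not in keep)
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
    X = X[:, keep]
    names = tuple(names[i] for i in keep)

    if X.shape[1] == 0:
        # intercept-only model, closed form
        p_hat = y.mean()
        ll = float(y.sum() * math.log(p_hat) + (y.size - y.sum()) * math.log(1 - p_hat))
        return LogisticFit(
            coefficients=np.empty(0),
            intercept=float(math.log(p_hat / (1 - p_hat))),
            log_likelihood=ll,
            aic=2.0 - 2.0 * ll,
            converged=True,
            n_params=1,
            dropped_features=dropped,
        )

    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=maxiter, method="newton")
            converged = bool(res.mle_retvals["converged"])
        except (PerfectSeparationError, np.linalg.LinAlgError, RuntimeError):
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=maxiter, method="bfgs")
            converged = False
        fitted = np.asarray(res.predict(Xc))
    if np.abs(y - fitted).max() < 1e-6:
        converged = False  # perfect in-sample prediction: separation
    params = np.asarray(res.params, dtype=float)
    k = params.size
    return LogisticFit(
        coefficients=params[1:],
        intercept=float(params[0]),
        log_likelihood=float(res.llf),
        aic=float(2 * k - 2 * res.llf),
        converged=converged,
        n_params=k,
        feature_names=names,
        dropped_features=dropped,
    )


def two_proportion_sample_size(
    p1: float, p2: float, alpha: float = 0.05, power: float = 0.80, dropout: float = 0.0
) -> SampleSizePlan:
    """Per-group n to detect a difference between two proportions.

    Unpooled normal approximation without continuity correction:

        n = ceil[ (z_{1-alpha/2} + z_power)^2 * (p1 q1 + p2 q2) / (p1-p2)^2 ]

    With (0.45, 0.10, 0.05, 0.80) this gives 22 per group, 44 total, and
    51 after 15% drop-out inflation.
    """
    for name, v in (("p1", p1), ("p2", p2), ("alpha", alpha), ("power", power)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
    if p1 == p2:
        raise ValueError("p1 == p2 implies an infinite sample size")
    z_a = _sps.norm.ppf(1.0 - alpha / 2.0)
    z_b = _sps.norm.ppf(power)
    var = p1 * (1 - p1) + p2 * (1 - p2)
    n_per_group = math.ceil((z_a + z_b) ** 2 * var / (p1 - p2) ** 2)
    n_total = 2 * n_per_group
    return SampleSizePlan(
        p1=p1,
        p2=p2,
        alpha=alpha,
        power=power,
        n_per_group=n_per_group,
        n_total=n_total,
        n_with_dropout=inflate_for_dropout(n_total, dropout),
        dropout=dropout,
    )


def inflate_for_dropout(n_total: int, dropout: float) -> int:
    """Inflate a planned total multiplicatively for anticipated drop-out.

    ceil(n_total * (1 + dropout)); e.g. 44 patients at 15% drop-out -> 51.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must lie in [0, 1)")
    return math.ceil(n_total * (1.0 + dropout))
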