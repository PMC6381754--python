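"""Two-gene methylation score: AIC selection, scoring, ROC/Youden cutoff.

The classifier is a linear score over per-gene percent methylation,

    score = sum_g coefficient_g * methylation_g(%)

with the gene subset and coefficients chosen by exhaustive AIC comparison
of binomial logistic fits (all candidate subsets up to ``max_genes``,
against the intercept-only null). The published rule carries no intercept:
the logistic intercept is a monotone shift of the linear predictor, so it
is absorbed into the decision cutoff, which is derived afterwards as the
Youden-optimal threshold of the empirical ROC curve. Classification
performance is reported in "k out of n (p%)" form: the fraction of
score-positive samples that are true responders (RCB = 0) and likewise for
score-negative samples.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats

log = logging.getLogger(__name__)

__all__ = [
    "SignatureModel",
    "select_signature",
    "score_samples",
    "derive_cutoff_and_performance",
    "rate_pct",
    "format_rate",
]


@dataclass(frozen=True)
class SignatureModel:
    """Selected gene signature with score coefficients and decision rule.

    ``coefficients`` apply to percent methylation (0-100). A sample is
    called score-positive when score > ``cutoff`` (strict). ``rate_above``
    is the fraction of score-positive samples with RCB = 0 and
    ``rate_below`` the analogous fraction among score-negative samples.
    The cutoff, AUC, CI and rates are populated by
    :func:`derive_cutoff_and_performance`; a freshly selected model leaves
    them NaN.
    """

    genes: tuple[str, ...]
    coefficients: dict
    aic: float
    intercept: float
    null_aic: float
    n_samples: int
    n_dropped: int = 0
    converged: bool = True
    null_model: bool = False
    cutoff: float = float("nan")
    auc: float = float("nan")
    auc_ci_low: float = float("nan")
    auc_ci_high: float = float("nan")
    youden_j: float = float("nan")
    n_above: int = 0
    n_below: int = 0
    rcb0_above: int = 0
    rcb0_below: int = 0
    rate_above: float = float("nan")
    rate_below: float = float("nan")
    n_boot: int = 0
    seed: int = 0
    degenerate: bool = False

    def score(self, methylation: dict | pd.Series) -> float:
        """Linear score of one sample's per-gene percent methylation."""
        return float(sum(self.coefficients[g] * float(methylation[g]) for g in self.genes))


def rate_pct(k: int, n: int) -> float:
    """Percentage k/n rounded to one decimal, as reported clinically."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, 1)


def format_rate(k: int, n: int) -> str:
    """Render a count fraction as 'k out of n (p%)'."""
    return f"{k} out of {n} ({rate_pct(k, n):.1f}%)"


def select_signature(
    gene_meth: pd.DataFrame,
    samples: pd.DataFrame,
    candidates: list[str] | tuple[str, ...],
    max_genes: int = 2,
    aic_margin: float = 4.0,
) -> SignatureModel:
    """Choose the gene subset minimising AIC of a logistic response model.

    ``gene_meth`` is a samples x genes table of percent methylation.
    Samples missing any candidate measurement are excluded (count logged).
    Every subset of size 1..``max_genes`` is fit with an intercept and
    compared with the intercept-only null; the minimal-AIC subset wins. If
    no subset improves on the null by more than ``aic_margin``, a
    null-model sentinel (empty gene tuple, ``null_model=True``) is
    returned with a warning.
    """
    candidates = [c for c in candidates]
    if not candidates:
        raise ValueError("need at least one candidate gene")
    missing_cols = [c for c in candidates if c not in gene_meth.columns]
    if missing_cols:
        raise ValueError(f"candidates not measured: {missing_cols}")

    sheet = samples.set_index("sample_id")
    common = gene_meth.index.intersection(sheet.index)
    X_all = gene_meth.loc[common, candidates]
    keep = ~X_all.isna().any(axis=1)
    n_dropped = int((~keep).sum()) + (len(gene_meth) - len(common))
    if n_dropped:
        log.info("%d samples dropped for missing measurements", n_dropped)
    X_all = X_all[keep]
    y = (sheet.loc[X_all.index, "response"] == "R").to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both response classes must be present")

    null_fit = stats.logistic_fit(np.empty((y.size, 0)), y)
    best: tuple[float, tuple[str, ...], stats.LogisticFit] | None = None
    for size in range(1, max_genes + 1):
        for combo in itertools.combinations(candidates, size):
            fit = stats.logistic_fit(
                X_all[list(combo)].to_numpy(dtype=float), y, feature_names=combo
            )
            if best is None or fit.aic < best[0]:
                best = (fit.aic, combo, fit)

    if best is None or best[0] >= null_fit.aic - aic_margin:
        log.warning(
            "no gene subset beats the intercept-only null by AIC margin %.3g; "
            "returning null sentinel", aic_margin,
        )
        return SignatureModel(
            genes=(), coefficients={}, aic=null_fit.aic, intercept=null_fit.intercept,
            null_aic=null_fit.aic, n_samples=int(y.size), n_dropped=n_dropped,
            converged=null_fit.converged, null_model=True,
        )
    aic, combo, fit = best
    coefs = {g: float(c) for g, c in zip(fit.feature_names, fit.coefficients)}
    return SignatureModel(
        genes=tuple(fit.feature_names),
        coefficients=coefs,
        aic=float(aic),
        intercept=fit.intercept,
        null_aic=null_fit.aic,
        n_samples=int(y.size),
        n_dropped=n_dropped,
        converged=fit.converged,
    )


def score_samples(
    model: SignatureModel,
    gene_meth: pd.DataFrame,
    samples: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score every sample with the model's linear predictor.

    Samples missing any model gene are skipped (logged). When the model
    already carries a cutoff, ``predicted_positive`` is filled; when a
    sample sheet is given, ``true_response`` records whether RCB = 0.
    """
    if model.null_model or not model.genes:
        raise ValueError("cannot score with a null-model sentinel")
    missing_cols = [g for g in model.genes if g not in gene_meth.columns]
    if missing_cols:
        raise ValueError(f"model genes not measured: {missing_cols}")
    sub = gene_meth[list(model.genes)]
    complete = ~sub.isna().any(axis=1)
    n_skip = int((~complete).sum())
    if n_skip:
        log.info("%d samples skipped at scoring for missing genes", n_skip)
    sub = sub[complete]
    coef = np.array([model.coefficients[g] for g in model.genes])
    out = sub.copy()
    out["score"] = sub.to_numpy(dtype=float) @ coef
    if not np.isnan(model.cutoff):
        out["predicted_positive"] = out["score"] > model.cutoff
    if samples is not None:
        sheet = samples.set_index("sample_id")
        out["true_response"] = (
            sheet["response"].reindex(out.index) == "R"
        )
    out.index.name = "sample_id"
    return out.reset_index()


def derive_cutoff_and_performance(
    model: SignatureModel,
    scored: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[SignatureModel, pd.DataFrame, stats.RocResult]:
    """Complete the model: Youden cutoff, AUC with bootstrap CI, rates.

    ``scored`` must carry ``score`` and ``true_response`` columns (from
    :func:`score_samples` with a sample sheet). Returns the completed
    model, the scored table with ``predicted_positive`` filled, and the
    full ROC result.
    """
    if "true_response" not in scored:
        raise ValueError("scored table needs true_response (pass samples to score_samples)")
    scores = scored["score"].to_numpy(dtype=float)
    labels = scored["true_response"].to_numpy(dtype=bool)
    roc = stats.roc_with_bootstrap(scores, labels, n_boot=n_boot, seed=seed)

    positive = scores > roc.youden_cutoff
    n_above, n_below = int(positive.sum()), int((~positive).sum())
    rcb0_above = int((labels & positive).sum())
    rcb0_below = int((labels & ~positive).sum())
    degenerate = n_above == 0 or n_below == 0
    if degenerate:
        log.warning("degenerate cutoff: all samples on one side")
    completed = dataclasses.replace(
        model,
        cutoff=roc.youden_cutoff,
        auc=roc.auc,
        auc_ci_low=roc.auc_ci_low,
        auc_ci_high=roc.auc_ci_high,
        youden_j=roc.youden_j,
        n_above=n_above,
        n_below=n_below,
        rcb0_above=rcb0_above,
        rcb0_below=rcb0_below,
        rate_above=rate_pct(rcb0_above, n_above) if n_above else float("nan"),
        rate_below=rate_pct(rcb0_below, n_below) if n_below else float("nan"),
        n_boot=int(n_boot),
        seed=int(seed),
        degenerate=degenerate,
    )
    out = scored.copy()
    out["predicted_positive"] = positive
    return completed, out, roc
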