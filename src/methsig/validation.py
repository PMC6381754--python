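"""Replication of candidate genes by targeted per-gene methylation.

Candidate genes emerging from the array cascade are re-measured by
pyrosequencing-style assays (percent methylation over a handful of
consecutive CpGs) first in the discovery cohort (technical replication)
and then in an independent validation cohort (analytical replication).
A gene replicates when the responder / non-responder difference is
significant by a two-sided rank test AND its sign agrees with the
direction seen on the array; a non-significant but direction-concordant
p-value below 0.20 is annotated as a trend (the band the study used to
carry a borderline gene forward). Clinicopathological covariates are
checked for association with gene methylation so that a candidate can be
ruled out as a mere stage/age/proliferation surrogate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import stats

log = logging.getLogger(__name__)

__all__ = [
    "ReplicationResult",
    "CovariateResult",
    "aggregate_gene_methylation",
    "replicate_gene",
    "covariate_association",
]


@dataclass(frozen=True)
class ReplicationResult:
    """Outcome of one gene's replication test in one cohort."""

    gene: str
    cohort: str
    n_r: int
    n_nr: int
    mean_r: float
    mean_nr: float
    delta_pct: float  # mean_NR - mean_R, percentage points
    p_value: float
    expected_direction: str
    replicated: bool
    trend: bool


@dataclass(frozen=True)
class CovariateResult:
    """Association of gene methylation with one clinical covariate."""

    covariate: str
    levels: tuple
    test: str  # "rank_sum" | "kruskal_wallis"
    p_value: float
    skipped_levels: tuple = ()


def aggregate_gene_methylation(pyro: pd.DataFrame, gene: str) -> pd.Series:
    """Per-sample mean percent methylation over a gene's assayed CpGs.

    Unweighted mean across the assay's CpG positions; CpGs missing for a
    sample are dropped from that sample's mean. Returns a Series indexed
    by sample_id, values in [0, 100].
    """
    sub = pyro[pyro["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} absent from pyrosequencing table")
    gm = sub.groupby("sample_id")["pct_methylation"].mean()
    gm.name = gene
    return gm


def _direction_matches(delta_pct: float, expected_direction: str) -> bool:
    if expected_direction == "hyper_in_NR":
        return delta_pct > 0
    if expected_direction == "hyper_in_R":
        return delta_pct < 0
    raise ValueError(f"unknown direction {expected_direction!r}")


def replicate_gene(
    gene_methylation: pd.Series,
    samples: pd.DataFrame,
    cohort: str,
    expected_direction: str,
    alpha: float = 0.05,
    trend_p: float = 0.20,
    exact_limit: int = stats.DEFAULT_EXACT_LIMIT,
) -> ReplicationResult:
    """Test a candidate gene's R vs NR methylation difference in a cohort.

    ``replicated`` requires both p < alpha and a delta_pct sign consistent
    with the expected array direction; ``trend`` flags a
    direction-concordant p in [alpha, trend_p).
    """
    sel = samples[samples["cohort"] == cohort] if "cohort" in samples else samples
    sel = sel[sel["sample_id"].isin(gene_methylation.index)]
    vals_r = gene_methylation.reindex(sel.loc[sel["response"] == "R", "sample_id"]).dropna()
    vals_nr = gene_methylation.reindex(sel.loc[sel["response"] == "NR", "sample_id"]).dropna()
    if len(vals_r) < 2 or len(vals_nr) < 2:
        raise ValueError(
            f"cohort {cohort!r} needs both response groups measured "
            f"(got {len(vals_r)} R, {len(vals_nr)} NR)"
        )
    res = stats.rank_sum_test(vals_r, vals_nr, exact_limit=exact_limit)
    delta = float(vals_nr.mean() - vals_r.mean())
    sign_ok = _direction_matches(delta, expected_direction)
    replicated = bool(res.p_two_sided < alpha and sign_ok)
    trend = bool(sign_ok and alpha <= res.p_two_sided < trend_p)
    return ReplicationResult(
        gene=str(gene_methylation.name),
        cohort=cohort,
        n_r=len(vals_r),
        n_nr=len(vals_nr),
        mean_r=float(vals_r.mean()),
        mean_nr=float(vals_nr.mean()),
        delta_pct=delta,
        p_value=res.p_two_sided,
        expected_direction=expected_direction,
        replicated=replicated,
        trend=trend,
    )


def covariate_association(
    gene_methylation: pd.Series,
    samples: pd.DataFrame,
    covariate: str,
    age_cut: float | None = None,
    exact_limit: int = stats.DEFAULT_EXACT_LIMIT,
) -> CovariateResult:
    """Does gene methylation differ across levels of a clinical covariate?

    Numeric covariates with many distinct values (e.g. age) are
    dichotomized at ``age_cut`` (default: the observed median). Two-level
    covariates use the rank-sum test, three or more the Kruskal-Wallis
    test; levels with fewer than 2 measured samples are skipped (logged).
    """
    if covariate not in samples.columns:
        raise ValueError(f"covariate {covariate!r} not in sample sheet")
    df = samples[["sample_id", covariate]].copy()
    df["meth"] = gene_methylation.reindex(df["sample_id"]).to_numpy()
    df = df.dropna(subset=[covariate, "meth"])

    values = df[covariate]
    if pd.api.types.is_numeric_dtype(values) and values.nunique() > 6:
        cut = float(values.median()) if age_cut is None else float(age_cut)
        df["level"] = np.where(values <= cut, f"<={cut:g}", f">{cut:g}")
    else:
        df["level"] = values.astype(str)

    groups, skipped = [], []
    levels = []
    for lev, grp in df.groupby("level", sort=True):
        if len(grp) < 2:
            skipped.append(lev)
            log.info("covariate %s level %r skipped (<2 samples)", covariate, lev)
            continue
        levels.append(lev)
        groups.append(grp["meth"].to_numpy(dtype=float))
    if len(groups) < 2:
        raise ValueError(
            f"covariate {covariate!r} has {len(groups)} usable level(s); need >= 2"
        )
    if len(groups) == 2:
        res = stats.rank_sum_test(groups[0], groups[1], exact_limit=exact_limit)
        return CovariateResult(covariate, tuple(levels), "rank_sum",
                               res.p_two_sided, tuple(skipped))
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0.0:
        p = 1.0  # no variation anywhere: nothing to distinguish
    else:
        p = float(_sps.kruskal(*groups).pvalue)
    return CovariateResult(covariate, tuple(levels), "kruskal_wallis", p, tuple(skipped))
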