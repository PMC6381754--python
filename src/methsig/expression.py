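"""Relative gene expression by the delta-delta-Ct method and its coupling
to promoter methylation.

qPCR Ct triplicates are averaged on the Ct scale, normalised to an
endogenous control gene (delta-Ct), referenced to a calibrator sample
(delta-delta-Ct) and expressed as fold change 2^(-ddCt), assuming perfect
doubling per cycle. The module also compares expression between responder
groups, correlates methylation with expression (Spearman), and evaluates
the demethylating-treatment contrast (e.g. AZA-treated vs control cells)
on both endpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionComparison",
    "TreatmentContrast",
    "delta_delta_ct",
    "compare_expression_groups",
    "methylation_expression_correlation",
    "treatment_contrast",
]


@dataclass(frozen=True)
class ExpressionComparison:
    """Responder vs non-responder comparison of relative expression."""

    p_value: float
    direction: str  # "higher_in_NR" | "higher_in_R" | "none"
    median_r: float
    median_nr: float
    n_r: int
    n_nr: int


@dataclass(frozen=True)
class TreatmentContrast:
    """Demethylating-treatment effect on methylation and expression."""

    p_methylation: float
    p_expression: float
    median_meth_treated: float
    median_meth_control: float
    median_fold_treated: float
    median_fold_control: float
    n_treated: int
    n_control: int


def delta_delta_ct(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """Relative expression of ``target_gene`` by the delta-delta-Ct method.

    ``ct`` has columns sample_id, gene, replicate, ct. Replicates are
    averaged on the Ct scale; delta_ct = mean target Ct - mean reference
    Ct per sample; delta_delta_ct references the calibrator sample's
    delta_ct; fold_change = 2^(-delta_delta_ct), so the calibrator has
    fold 1 exactly. Samples lacking the reference gene are skipped with a
    log entry.
    """
    for col in ("sample_id", "gene", "replicate", "ct"):
        if col not in ct.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    summ = (
        ct[ct["gene"].isin((target_gene, reference_gene))]
        .groupby(["sample_id", "gene"])["ct"]
        .agg(["mean", "std", "count"])
        .unstack("gene")
    )
    if target_gene == reference_gene:
        raise ValueError("target and reference genes must differ")
    try:
        mean_t = summ[("mean", target_gene)]
        mean_r = summ[("mean", reference_gene)]
    except KeyError as exc:
        raise ValueError(f"gene missing from Ct table: {exc}") from exc

    usable = mean_t.notna() & mean_r.notna()
    skipped = summ.index[~usable].tolist()
    if skipped:
        log.info("samples skipped (missing target or reference Ct): %s", skipped)
    if calibrator_sample not in summ.index[usable]:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not measured")

    delta_ct = (mean_t - mean_r)[usable]
    ddct = delta_ct - delta_ct[calibrator_sample]
    out = pd.DataFrame(
        {
            "sample_id": delta_ct.index,
            "gene": target_gene,
            "mean_ct_target": mean_t[usable].to_numpy(),
            "sd_ct_target": summ[("std", target_gene)][usable].to_numpy(),
            "mean_ct_reference": mean_r[usable].to_numpy(),
            "sd_ct_reference": summ[("std", reference_gene)][usable].to_numpy(),
            "delta_ct": delta_ct.to_numpy(),
            "delta_delta_ct": ddct.to_numpy(),
            "fold_change": np.power(2.0, -ddct.to_numpy()),
        }
    ).reset_index(drop=True)
    return out


def compare_expression_groups(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    exact_limit: int = stats.DEFAULT_EXACT_LIMIT,
) -> ExpressionComparison:
    """Two-sided rank test of fold change between R and NR patients."""
    sheet = samples.set_index("sample_id")
    fold = expr.set_index("sample_id")["fold_change"]
    common = fold.index.intersection(sheet.index)
    resp = sheet.loc[common, "response"]
    vals_r = fold.loc[common[resp == "R"]].dropna()
    vals_nr = fold.loc[common[resp == "NR"]].dropna()
    if len(vals_r) < 2 or len(vals_nr) < 2:
        raise ValueError("both response groups need >= 2 expression values")
    res = stats.rank_sum_test(vals_r, vals_nr, exact_limit=exact_limit)
    med_r, med_nr = float(vals_r.median()), float(vals_nr.median())
    direction = (
        "higher_in_NR" if med_nr > med_r else "higher_in_R" if med_r > med_nr else "none"
    )
    return ExpressionComparison(
        p_value=res.p_two_sided,
        direction=direction,
        median_r=med_r,
        median_nr=med_nr,
        n_r=len(vals_r),
        n_nr=len(vals_nr),
    )


def methylation_expression_correlation(
    methylation: pd.Series, expression: pd.Series
) -> tuple[float, float]:
    """Spearman correlation of per-sample methylation with expression.

    Pairs are aligned on sample index; returns (rho, p). A negative rho
    with small p indicates the expected epigenetic silencing pattern.
    """
    joined = pd.concat([methylation, expression], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 paired samples")
    return stats.spearman_correlation(
        joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    )


def treatment_contrast(
    treated_methylation,
    control_methylation,
    treated_fold,
    control_fold,
    exact_limit: int = stats.DEFAULT_EXACT_LIMIT,
) -> TreatmentContrast:
    """Demethylating treatment vs control, on both endpoints independently.

    Each arm needs at least 3 replicates per endpoint (the triplicate
    design); methylation percentages and expression fold changes are each
    compared with a two-sided rank test.
    """
    arrays = {
        "treated_methylation": np.asarray(treated_methylation, dtype=float),
        "control_methylation": np.asarray(control_methylation, dtype=float),
        "treated_fold": np.asarray(treated_fold, dtype=float),
        "control_fold": np.asarray(control_fold, dtype=float),
    }
    for name, arr in arrays.items():
        if arr.size < 3:
            raise ValueError(f"{name} needs >= 3 replicates (got {arr.size})")
    p_meth = stats.rank_sum_test(
        arrays["treated_methylation"], arrays["control_methylation"],
        exact_limit=exact_limit,
    ).p_two_sided
    p_expr = stats.rank_sum_test(
        arrays["treated_fold"], arrays["control_fold"], exact_limit=exact_limit
    ).p_two_sided
    return TreatmentContrast(
        p_methylation=p_meth,
        p_expression=p_expr,
        median_meth_treated=float(np.median(arrays["treated_methylation"])),
        median_meth_control=float(np.median(arrays["control_methylation"])),
        median_fold_treated=float(np.median(arrays["treated_fold"])),
        median_fold_control=float(np.median(arrays["control_fold"])),
        n_treated=int(arrays["treated_methylation"].size),
        n_control=int(arrays["control_methylation"].size),
    )
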