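"""Five-filter differential-methylation discovery cascade.

For every probe, the beta values of responders (R, RCB = 0) and
non-responders (NR, RCB > 0) are compared with a two-sided rank-sum test,
then candidates are funnelled through five filters applied in a fixed
order:

1. p < 0.05 (unadjusted; an optional Benjamini-Hochberg flag exists but
   defaults off),
2. |delta-beta| >= 0.20 where delta-beta = mean_NR - mean_R,
3. promoter island/shore context: island relation in {Island, N_Shore,
   S_Shore} AND at least one gene-group annotation in {TSS1500, TSS200,
   5UTR, 1stExon},
4. intragroup SD <= 0.20 in both groups,
5. consistent methylation of consecutive CpGs: enough neighbouring probes
   of the same gene within a window share the probe's delta-beta sign at a
   minimum magnitude.

Each non-surviving probe records the first filter it failed, survivors are
grouped into candidate genes (multi-gene probes count for every annotated
gene), and per-step counts are reported, which are monotone non-increasing
by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats

log = logging.getLogger(__name__)

__all__ = [
    "CascadeParams",
    "CascadeResult",
    "test_all_probes",
    "apply_cascade",
    "consecutive_consistency",
    "FILTER_ORDER",
]

FILTER_ORDER = ("p", "delta", "region", "sd", "consistency")

RECORD_COLUMNS = [
    "probe_id", "n_r", "n_nr", "mean_r", "mean_nr", "delta_beta",
    "sd_r", "sd_nr", "p_value", "direction", "tested", "exclude_reason",
]


@dataclass(frozen=True)
class CascadeParams:
    """Thresholds of the selection cascade; defaults are the published ones."""

    p_alpha: float = 0.05
    delta_min: float = 0.20
    sd_max: float = 0.20
    promoter_groups: frozenset = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})
    island_relations: frozenset = frozenset({"Island", "N_Shore", "S_Shore"})
    window_bp: int = 1000
    min_concordant: int = 2
    concordance_delta: float = 0.10
    zero_neighbors_pass: bool = False
    max_missing_frac: float = 0.2
    exact_limit: int = stats.DEFAULT_EXACT_LIMIT
    bh_correct: bool = False

    def __post_init__(self):
        if not 0.0 < self.p_alpha <= 1.0:
            raise ValueError("p_alpha must lie in (0, 1]")
        if self.delta_min < 0 or self.sd_max < 0:
            raise ValueError("delta_min and sd_max must be >= 0")
        if self.window_bp < 0 or self.min_concordant < 0:
            raise ValueError("window_bp and min_concordant must be >= 0")


@dataclass
class CascadeResult:
    """Audit trail of one cascade run.

    ``records`` carries one row per probe with its statistics and the
    ``first_failed_filter`` tag ("none" for survivors); ``step_counts``
    maps step name to the number of probes surviving through that step;
    ``candidates`` is the per-gene summary of final survivors.
    """

    records: pd.DataFrame
    step_counts: dict
    candidates: pd.DataFrame
    params: CascadeParams


def test_all_probes(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    cohort: str = "discovery",
    params: CascadeParams | None = None,
) -> pd.DataFrame:
    """Per-probe group comparison between responders and non-responders.

    Returns one row per probe with group sizes, means, SDs,
    delta_beta = mean_NR - mean_R, the two-sided rank-sum p-value and the
    direction label. Probes with more than ``params.max_missing_frac``
    missing values, or missing in an entire group, are kept in the table
    with ``tested=False`` and an ``exclude_reason``.
    """
    params = params or CascadeParams()
    sel = samples[samples["cohort"] == cohort] if "cohort" in samples else samples
    r_ids = sel.loc[sel["response"] == "R", "sample_id"]
    nr_ids = sel.loc[sel["response"] == "NR", "sample_id"]
    if len(r_ids) < 2 or len(nr_ids) < 2:
        raise ValueError(
            f"cohort {cohort!r} needs >= 2 samples per response group "
            f"(got {len(r_ids)} R, {len(nr_ids)} NR)"
        )
    missing_r = r_ids[~r_ids.isin(beta.columns)].tolist()
    missing_nr = nr_ids[~nr_ids.isin(beta.columns)].tolist()
    if missing_r or missing_nr:
        raise ValueError(f"samples absent from beta matrix: {missing_r + missing_nr}")

    mat_r = beta[list(r_ids)].to_numpy(dtype=float)
    mat_nr = beta[list(nr_ids)].to_numpy(dtype=float)
    n_total = mat_r.shape[1] + mat_nr.shape[1]

    rows = []
    for i, probe in enumerate(beta.index):
        vr = mat_r[i][~np.isnan(mat_r[i])]
        vnr = mat_nr[i][~np.isnan(mat_nr[i])]
        n_missing = n_total - vr.size - vnr.size
        reason = None
        if vr.size == 0 or vnr.size == 0:
            reason = "missing_in_entire_group"
        elif n_missing / n_total > params.max_missing_frac:
            reason = "too_many_missing"
        elif vr.size < 2 or vnr.size < 2:
            reason = "group_too_small"
        if reason is not None:
            log.info("probe %s excluded: %s", probe, reason)
            rows.append(
                dict.fromkeys(RECORD_COLUMNS)
                | {"probe_id": probe, "n_r": vr.size, "n_nr": vnr.size,
                   "tested": False, "exclude_reason": reason}
            )
            continue
        res = stats.rank_sum_test(vr, vnr, exact_limit=params.exact_limit)
        mean_r, mean_nr = float(vr.mean()), float(vnr.mean())
        delta = mean_nr - mean_r
        rows.append(
            {
                "probe_id": probe,
                "n_r": vr.size,
                "n_nr": vnr.size,
                "mean_r": mean_r,
                "mean_nr": mean_nr,
                "delta_beta": delta,
                "sd_r": float(vr.std(ddof=1)),
                "sd_nr": float(vnr.std(ddof=1)),
                "p_value": res.p_two_sided,
                "direction": (
                    "hyper_in_NR" if delta > 0 else "hyper_in_R" if delta < 0 else "none"
                ),
                "tested": True,
                "exclude_reason": None,
            }
        )
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    n_excluded = int((~records["tested"]).sum())
    if n_excluded:
        log.info("%d of %d probes excluded before testing", n_excluded, len(records))
    return records


def _split_multi(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    return [v for v in str(value).split(";") if v]


def consecutive_consistency(
    probe_id: str,
    manifest: pd.DataFrame,
    records: pd.DataFrame,
    params: CascadeParams | None = None,
) -> tuple[bool, pd.DataFrame]:
    """Consistency of a probe's delta-beta with its consecutive CpGs.

    Neighbours are tested probes on the same chromosome sharing at least
    one gene annotation within ``window_bp`` of the probe (the probe
    itself excluded). A neighbour is concordant when its delta-beta has
    the probe's sign and |delta-beta| >= ``concordance_delta``. The probe
    passes when the number of concordant neighbours reaches
    ``min_concordant`` (or all of them, when fewer neighbours exist).
    Probes with no neighbours fail unless ``zero_neighbors_pass`` is set.

    Returns (pass flag, neighbour report with per-neighbour concordance).
    """
    params = params or CascadeParams()
    mrow = manifest.loc[manifest["probe_id"] == probe_id]
    if mrow.empty:
        raise ValueError(f"probe {probe_id!r} not in manifest")
    mrow = mrow.iloc[0]
    genes = set(_split_multi(mrow["gene"]))
    rec = records.set_index("probe_id")
    if probe_id not in rec.index or not rec.at[probe_id, "tested"]:
        raise ValueError(f"probe {probe_id!r} has no test record")
    own_delta = float(rec.at[probe_id, "delta_beta"])

    near = manifest[
        (manifest["chrom"] == mrow["chrom"])
        & ((manifest["pos"] - mrow["pos"]).abs() <= params.window_bp)
        & (manifest["probe_id"] != probe_id)
    ]
    if genes:
        overlap = near["gene"].map(
            lambda g: bool(genes & set(_split_multi(g)))
        ).astype(bool)
        near = near[overlap]
    near = near[near["probe_id"].isin(rec.index[rec["tested"].fillna(False)])]

    deltas = rec.loc[near["probe_id"], "delta_beta"].to_numpy(dtype=float)
    concordant = (np.sign(deltas) == np.sign(own_delta)) & (
        np.abs(deltas) >= params.concordance_delta
    )
    report = pd.DataFrame(
        {
            "probe_id": near["probe_id"].to_numpy(),
            "pos": near["pos"].to_numpy(),
            "delta_beta": deltas,
            "concordant": concordant,
        }
    )
    n_neighbors = len(report)
    if n_neighbors == 0:
        return bool(params.zero_neighbors_pass), report
    required = min(params.min_concordant, n_neighbors)
    return bool(concordant.sum() >= required), report


def _region_pass(manifest_row, params: CascadeParams) -> bool:
    relation = manifest_row["island_relation"]
    groups = set(_split_multi(manifest_row["gene_group"]))
    return relation in params.island_relations and bool(groups & params.promoter_groups)


def apply_cascade(
    records: pd.DataFrame,
    manifest: pd.DataFrame,
    params: CascadeParams | None = None,
) -> CascadeResult:
    """Run the five filters in order and group survivors into genes.

    ``records`` is the output of :func:`test_all_probes`; probes flagged
    untested there are outside the cascade (they keep
    ``first_failed_filter = "not_tested"``). Step counts are reported for
    the tested pool and each filter in order, and are monotone
    non-increasing.
    """
    params = params or CascadeParams()
    rec = records.reset_index(drop=True).copy()
    manifest_idx = manifest.set_index("probe_id")
    missing = rec.loc[rec["tested"].fillna(False), "probe_id"]
    missing = missing[~missing.isin(manifest_idx.index)]
    if len(missing):
        raise ValueError(f"tested probes missing from manifest: {list(missing[:5])}")

    tested = rec["tested"].fillna(False).to_numpy(dtype=bool)
    p_vals = rec["p_value"].to_numpy(dtype=float)
    if params.bh_correct:
        from statsmodels.stats.multitest import multipletests

        adj = np.full(len(rec), np.nan)
        adj[tested] = multipletests(p_vals[tested], method="fdr_bh")[1]
        p_for_filter = adj
    else:
        p_for_filter = p_vals

    delta = rec["delta_beta"].to_numpy(dtype=float)
    sd_r = rec["sd_r"].to_numpy(dtype=float)
    sd_nr = rec["sd_nr"].to_numpy(dtype=float)

    pass_p = tested & (p_for_filter < params.p_alpha)
    pass_delta = np.abs(delta) >= params.delta_min
    region = np.array(
        [
            _region_pass(manifest_idx.loc[p], params) if t else False
            for p, t in zip(rec["probe_id"], tested)
        ]
    )
    pass_sd = (sd_r <= params.sd_max) & (sd_nr <= params.sd_max)

    first_failed = np.full(len(rec), "none", dtype=object)
    first_failed[~tested] = "not_tested"
    alive = tested.copy()
    step_counts = {"tested": int(tested.sum())}
    checks = {"p": pass_p, "delta": pass_delta, "region": region, "sd": pass_sd}
    for step in ("p", "delta", "region", "sd"):
        fail_now = alive & ~checks[step]
        first_failed[fail_now] = step
        alive &= checks[step]
        step_counts[step] = int(alive.sum())

    # step 5 evaluated only for probes still alive (neighbour context uses
    # the full tested record table, not just survivors)
    for i in np.flatnonzero(alive):
        ok, _ = consecutive_consistency(rec.at[i, "probe_id"], manifest, records, params)
        if not ok:
            first_failed[i] = "consistency"
            alive[i] = False
    step_counts["consistency"] = int(alive.sum())

    rec["first_failed_filter"] = first_failed
    candidates = _group_candidates(rec[alive], manifest_idx)
    return CascadeResult(records=rec, step_counts=step_counts,
                         candidates=candidates, params=params)


def _group_candidates(survivors: pd.DataFrame, manifest_idx: pd.DataFrame) -> pd.DataFrame:
    """Group surviving probes into candidate genes, one row per gene.

    A probe annotated to several genes (semicolon-joined) supports each of
    them. If a gene somehow collects probes of both directions, the
    direction with the larger total |delta-beta| wins and only its probes
    are kept as support.
    """
    rows: dict[str, dict] = {}
    for _, r in survivors.iterrows():
        for gene in _split_multi(manifest_idx.at[r["probe_id"], "gene"]):
            d = rows.setdefault(gene, {"hyper_in_NR": [], "hyper_in_R": []})
            d[r["direction"]].append((r["probe_id"], float(r["delta_beta"])))
    out = []
    for gene, dirs in sorted(rows.items()):
        weight = {k: sum(abs(d) for _, d in v) for k, v in dirs.items()}
        direction = max(weight, key=lambda k: weight[k])
        support = sorted(dirs[direction])
        if dirs["hyper_in_NR"] and dirs["hyper_in_R"]:
            log.warning("gene %s has survivors in both directions; keeping %s",
                        gene, direction)
        out.append(
            {
                "gene": gene,
                "direction": direction,
                "supporting_probe_ids": ";".join(p for p, _ in support),
                "n_probes": len(support),
                "mean_delta_beta": float(np.mean([d for _, d in support])),
            }
        )
    return pd.DataFrame(
        out, columns=["gene", "direction", "supporting_probe_ids", "n_probes",
                      "mean_delta_beta"]
    )
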