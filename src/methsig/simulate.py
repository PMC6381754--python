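"""Synthetic 450K-style methylation data with planted ground truth.

The generator emulates the study design the pipeline assumes: two patient
groups (responders with residual cancer burden RCB = 0 vs non-responders
with RCB > 0), a probe manifest with promoter / CpG-island annotation, a
probe-by-sample matrix of beta values, pyrosequencing-style per-CpG
methylation percentages, and qPCR Ct triplicates whose expression is
inversely coupled to promoter methylation.

Planted genes carry a group mean beta difference on a run of consecutive
promoter-island CpGs, with configurable within-group SD; everything else is
drawn from a bimodal per-probe baseline shared by both groups. Per-sample
latent gene methylation is returned alongside the matrix so that
pyrosequencing can be simulated either as a technical replication of the
same truth (discovery cohort) or as a fresh biological draw (validation
cohort).

All outputs are deterministic functions of their seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "PlantedGene",
    "CohortData",
    "PROMOTER_GROUPS",
    "generate_manifest",
    "generate_cohort",
    "generate_pyro_table",
    "generate_expression",
]

#: manifest gene-group annotations that count as promoter context
PROMOTER_GROUPS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})

_PROMOTER_CYCLE = ("TSS1500", "TSS200", "5UTR", "1stExon")


@dataclass(frozen=True)
class PlantedGene:
    """Ground truth for one differentially methylated gene.

    ``delta`` is the planted group mean beta difference on the gene's run
    of consecutive promoter CpGs; ``direction`` says which group carries
    the higher methylation. ``sd_within`` is the per-group SD of the
    generated beta values (split ~80/20 variance-wise between a shared
    per-sample biological component and per-probe technical noise, so the
    same latent truth can feed both array and pyrosequencing emulation).
    ``expression_coupling`` is the slope of log2 relative expression per
    unit beta (negative: methylation silences). ``delta_validation``
    optionally overrides ``delta`` in the validation cohort, which lets a
    simulation emulate discovery hits that fail to replicate.
    """

    gene: str
    direction: str  # "hyper_in_NR" | "hyper_in_R"
    delta: float
    n_consecutive_cpgs: int = 4
    sd_within: float = 0.10
    expression_coupling: float = -4.0
    base_low: float = 0.25  # mean beta of the less methylated group
    delta_validation: float | None = None

    def __post_init__(self):
        if self.direction not in ("hyper_in_NR", "hyper_in_R"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must lie in [0, 1)")
        if self.n_consecutive_cpgs < 1:
            raise ValueError("n_consecutive_cpgs must be >= 1")

    def delta_for(self, cohort: str) -> float:
        if cohort == "validation" and self.delta_validation is not None:
            return self.delta_validation
        return self.delta


@dataclass
class CohortData:
    """One simulated cohort: beta matrix, sample sheet, latent gene truth.

    ``latent`` holds the per-sample true methylation fraction of each
    planted gene (rows = samples, columns = genes); it is what
    pyrosequencing and expression emulation measure.
    """

    beta: pd.DataFrame
    samples: pd.DataFrame
    latent: pd.DataFrame
    planted: tuple[PlantedGene, ...] = ()


def generate_manifest(
    n_genes: int,
    cpgs_per_gene: int,
    islands_fraction: float = 0.7,
    seed: int = 0,
    gene_names: list[str] | None = None,
) -> pd.DataFrame:
    """Lay out a 450K-like probe manifest on synthetic chromosomes.

    Each gene receives a promoter CpG run (ceil(c/2) probes within ~500 bp
    of each other, island core flanked by shores) plus body probes placed
    far enough downstream not to count as promoter neighbours. The island
    core spans the central ``ceil(k * islands_fraction)`` promoter probes,
    so every gene keeps at least one promoter-island probe whenever
    ``islands_fraction > 0``.

    Returns a DataFrame with columns probe_id, chrom, pos, gene,
    gene_group, island_relation (1-based positions).
    """
    if n_genes < 1 or cpgs_per_gene < 1:
        raise ValueError("n_genes and cpgs_per_gene must be >= 1")
    if not 0.0 <= islands_fraction <= 1.0:
        raise ValueError("islands_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    probe_no = 0
    for g in range(n_genes):
        gene = (
            gene_names[g]
            if gene_names is not None and g < len(gene_names)
            else f"GENE{g + 1:04d}"
        )
        chrom = f"chr{(g % 22) + 1}"
        start = 1_000_000 + (g // 22) * 1_000_000
        k_prom = max(1, math.ceil(cpgs_per_gene / 2)) if cpgs_per_gene > 1 else 1
        k_prom = min(k_prom, cpgs_per_gene)
        n_island = math.ceil(k_prom * islands_fraction) if islands_fraction > 0 else 0
        flank = k_prom - n_island
        left = flank // 2
        pos = start
        for i in range(k_prom):
            pos += int(100 + rng.integers(0, 60))
            if n_island and left <= i < left + n_island:
                relation = "Island"
            else:
                relation = "N_Shore" if i < left else "S_Shore"
            rows.append(
                {
                    "probe_id": f"cg{probe_no:08d}",
                    "chrom": chrom,
                    "pos": pos,
                    "gene": gene,
                    "gene_group": _PROMOTER_CYCLE[i % len(_PROMOTER_CYCLE)],
                    "island_relation": relation,
                }
            )
            probe_no += 1
        body_pos = pos + 5_000
        for i in range(cpgs_per_gene - k_prom):
            body_pos += int(1_500 + rng.integers(0, 300))
            rows.append(
                {
                    "probe_id": f"cg{probe_no:08d}",
                    "chrom": chrom,
                    "pos": body_pos,
                    "gene": gene,
                    "gene_group": "Body",
                    "island_relation": "OpenSea" if i % 2 == 0 else "S_Shelf",
                }
            )
            probe_no += 1
    return pd.DataFrame(rows)


def _rcb_for_nonresponders(n: int, rng: np.random.Generator) -> np.ndarray:
    # residual burden classes 1..3 in roughly the observed clinical mix
    return rng.choice([1, 2, 3], size=n, p=[0.2, 0.45, 0.35])


def _make_sample_sheet(cohort: str, n_r: int, n_nr: int, rng: np.random.Generator) -> pd.DataFrame:
    n = n_r + n_nr
    ids = [f"{cohort[:3].upper()}{i + 1:03d}" for i in range(n)]
    rcb = np.concatenate([np.zeros(n_r, dtype=int), _rcb_for_nonresponders(n_nr, rng)])
    response = np.where(rcb == 0, "R", "NR")
    age = np.clip(rng.normal(48.0, 12.0, n), 27.0, 79.0).round(2)
    ct_stage = rng.choice(["cTx", "cT1-2", "cT3-4"], size=n, p=[0.09, 0.74, 0.17])
    cn_stage = rng.choice(["cNx", "cN0", "cN+"], size=n, p=[0.07, 0.60, 0.33])
    ki67 = np.round(rng.uniform(5.0, 95.0, n), 1)
    ki67[rng.random(n) < 0.15] = np.nan  # biopsies without a Ki67 read
    return pd.DataFrame(
        {
            "sample_id": ids,
            "cohort": cohort,
            "rcb_class": rcb,
            "response": response,
            "age": age,
            "ct_stage": ct_stage,
            "cn_stage": cn_stage,
            "ki67": ki67,
        }
    )


def _promoter_run_probes(manifest: pd.DataFrame, gene: str, n: int) -> pd.DataFrame:
    sub = manifest[
        (manifest["gene"] == gene)
        & manifest["gene_group"].isin(PROMOTER_GROUPS)
        & manifest["island_relation"].isin(("Island", "N_Shore", "S_Shore"))
    ].sort_values("pos")
    return sub.head(n)


def generate_cohort(
    manifest: pd.DataFrame,
    n_r: int,
    n_nr: int,
    planted: list[PlantedGene] | tuple[PlantedGene, ...] = (),
    noise_sd: float = 0.10,
    seed: int = 0,
    cohort: str = "discovery",
) -> CohortData:
    """Simulate a patient cohort measured on the array.

    Unplanted probes share a bimodal per-probe baseline (Beta-mixture of
    hypo- and hypermethylated modes) in both groups with Gaussian noise of
    ``noise_sd`` on the beta scale. Each planted gene's first
    ``n_consecutive_cpgs`` promoter CpGs separate the group means by its
    ``delta`` (direction-dependent), with per-group SD ``sd_within``. All
    values are clamped to [0, 1]; a planted mean falling outside [0, 1]
    logs a warning before clamping.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    genes = set(manifest["gene"])
    for pg in planted:
        if pg.gene not in genes:
            raise ValueError(f"planted gene {pg.gene!r} not in manifest")
    rng = np.random.default_rng(seed)
    samples = _make_sample_sheet(cohort, n_r, n_nr, rng)
    is_r = (samples["response"] == "R").to_numpy()

    n_probes = len(manifest)
    n_samples = len(samples)
    # bimodal baseline typical of array beta distributions
    mode = rng.choice([0, 1, 2], size=n_probes, p=[0.4, 0.4, 0.2])
    baseline = np.where(
        mode == 0,
        rng.beta(2.0, 18.0, n_probes),
        np.where(mode == 1, rng.beta(18.0, 2.0, n_probes), rng.beta(4.0, 4.0, n_probes)),
    )
    beta = baseline[:, None] + rng.normal(0.0, noise_sd, (n_probes, n_samples))

    probe_index = pd.Index(manifest["probe_id"])
    latent = pd.DataFrame(index=pd.Index(samples["sample_id"], name="sample_id"))
    for pg in planted:
        delta = pg.delta_for(cohort)
        run = _promoter_run_probes(manifest, pg.gene, pg.n_consecutive_cpgs)
        if len(run) < pg.n_consecutive_cpgs:
            raise ValueError(
                f"gene {pg.gene!r} has only {len(run)} promoter island/shore CpGs,"
                f" cannot plant a run of {pg.n_consecutive_cpgs}"
            )
        low, high = pg.base_low, pg.base_low + delta
        if high > 1.0 or low < 0.0:
            log.warning(
                "planted mean for %s outside [0,1] (low=%.3f high=%.3f); clamping",
                pg.gene, low, high,
            )
        if pg.direction == "hyper_in_NR":
            group_mean = np.where(is_r, low, high)
        else:
            group_mean = np.where(is_r, high, low)
        sd_biol = 0.8 * pg.sd_within
        sd_tech = 0.6 * pg.sd_within
        lat = np.clip(group_mean + rng.normal(0.0, sd_biol, n_samples), 0.0, 1.0)
        latent[pg.gene] = lat
        rows = probe_index.get_indexer(run["probe_id"])
        offsets = rng.normal(0.0, 0.02, len(rows))  # small fixed per-probe shift
        beta[rows, :] = (
            lat[None, :]
            + offsets[:, None]
            + rng.normal(0.0, sd_tech, (len(rows), n_samples))
        )

    beta = np.clip(beta, 0.0, 1.0)
    beta_df = pd.DataFrame(
        beta, index=probe_index.rename("probe_id"), columns=samples["sample_id"].to_numpy()
    )
    return CohortData(
        beta=beta_df, samples=samples, latent=latent, planted=tuple(planted)
    )


def _fresh_latent(
    planted, samples: pd.DataFrame, rng: np.random.Generator, cohort: str
) -> pd.DataFrame:
    is_r = (samples["response"] == "R").to_numpy()
    latent = pd.DataFrame(index=pd.Index(samples["sample_id"], name="sample_id"))
    for pg in planted:
        delta = pg.delta_for(cohort)
        low, high = pg.base_low, pg.base_low + delta
        if pg.direction == "hyper_in_NR":
            mean = np.where(is_r, low, high)
        else:
            mean = np.where(is_r, high, low)
        latent[pg.gene] = np.clip(
            mean + rng.normal(0.0, 0.8 * pg.sd_within, len(samples)), 0.0, 1.0
        )
    return latent


def generate_pyro_table(
    planted,
    samples: pd.DataFrame,
    cpgs_per_assay: int = 4,
    assay_noise_sd: float = 3.0,
    seed: int = 0,
    latent: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pyrosequencing-style per-CpG methylation percentages.

    When ``latent`` (per-sample truth from :func:`generate_cohort`) is
    given, the assay technically re-measures the same underlying biology
    with independent ``assay_noise_sd`` (in percentage points); otherwise a
    fresh biological draw from the planted truth emulates an independent
    cohort. With ``assay_noise_sd=0`` the returned percentages are exactly
    100 x latent. Output columns: sample_id, gene, cpg_index,
    pct_methylation (clamped to [0, 100]).
    """
    if cpgs_per_assay < 1:
        raise ValueError("cpgs_per_assay must be >= 1")
    if assay_noise_sd < 0:
        raise ValueError("assay_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    cohort = samples["cohort"].iloc[0] if len(samples) else "discovery"
    if latent is None:
        latent = _fresh_latent(planted, samples, rng, cohort)
    rows = []
    for pg in planted:
        lat = latent[pg.gene].reindex(samples["sample_id"]).to_numpy()
        for ci in range(1, cpgs_per_assay + 1):
            noise = rng.normal(0.0, assay_noise_sd, len(samples)) if assay_noise_sd else 0.0
            pct = np.clip(100.0 * lat + noise, 0.0, 100.0)
            for sid, v in zip(samples["sample_id"], pct):
                rows.append(
                    {"sample_id": sid, "gene": pg.gene, "cpg_index": ci,
                     "pct_methylation": float(v)}
                )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "cpg_index", "pct_methylation"])


def generate_expression(
    planted,
    samples: pd.DataFrame,
    reference_ct: float = 20.0,
    coupling: float | None = None,
    seed: int = 0,
    latent: pd.DataFrame | None = None,
    reference_gene: str = "GAPDH",
    ct_noise_sd: float = 0.15,
    dct_base: float = 2.0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """qPCR Ct triplicates with expression inversely coupled to methylation.

    The target gene's Ct relative to the endogenous control follows
    ``delta_ct = dct_base - coupling * latent_methylation``; coupling is in
    log2-expression units per unit beta and must be negative (or ~0 for a
    null), so higher methylation raises delta-Ct and lowers relative
    expression by 2^(-delta-delta-Ct). ``coupling=None`` uses each planted
    gene's own ``expression_coupling``. Technical replicate noise
    ``ct_noise_sd`` is added per Ct read. Output columns: sample_id, gene,
    replicate, ct (the reference gene gets its own rows near
    ``reference_ct``).
    """
    if coupling is not None and coupling > 0:
        raise ValueError("coupling must be <= 0 (methylation silences expression)")
    rng = np.random.default_rng(seed)
    cohort = samples["cohort"].iloc[0] if len(samples) else "discovery"
    if latent is None:
        latent = _fresh_latent(planted, samples, rng, cohort)
    rows = []
    for sid in samples["sample_id"]:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {"sample_id": sid, "gene": reference_gene, "replicate": rep,
                 "ct": float(reference_ct + rng.normal(0.0, ct_noise_sd))}
            )
    for pg in planted:
        c = pg.expression_coupling if coupling is None else coupling
        lat = latent[pg.gene].reindex(samples["sample_id"]).to_numpy()
        dct = dct_base - c * lat
        for sid, d in zip(samples["sample_id"], dct):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {"sample_id": sid, "gene": pg.gene, "replicate": rep,
                     "ct": float(reference_ct + d + rng.normal(0.0, ct_noise_sd))}
                )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "replicate", "ct"])
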