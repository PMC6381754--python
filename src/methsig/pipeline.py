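"""End-to-end orchestration: simulate -> discover -> validate -> model
-> expression, with a machine-readable run report.

The stages mirror the study workflow: a discovery cohort measured on the
array feeds the five-filter cascade; candidate genes are re-measured by
pyrosequencing in both cohorts; genes replicating (or trending, when
allowed) in the independent cohort enter AIC model selection on the
pooled cohorts; the selected linear score gets a Youden cutoff, AUC with
bootstrap CI, and per-side RCB = 0 rates; finally relative expression of
the top gene is derived by delta-delta-Ct, compared between response
groups and correlated with methylation.

All stage seeds are derived deterministically from the config seed, so an
identical config + seed reproduces a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, discovery, expression, io, signature, simulate, validation

log = logging.getLogger(__name__)

__all__ = ["simulate_study", "run_pipeline"]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def simulate_study(config: io.PipelineConfig, outdir=None):
    """Generate manifest, both cohorts, pyro and Ct tables per the config.

    The discovery cohort's pyrosequencing re-measures the array's latent
    truth (technical replication); the validation cohort is a fresh
    biological draw. Returns a dict of all artefacts; writes them under
    ``outdir`` when given.
    """
    sim = config.simulation
    seeds = _child_seeds(config.seed, 6)
    gene_names = [pg.gene for pg in sim.planted]
    manifest = simulate.generate_manifest(
        sim.n_genes, sim.cpgs_per_gene, sim.islands_fraction,
        seed=seeds[0], gene_names=gene_names,
    )
    disc = simulate.generate_cohort(
        manifest, sim.n_r_discovery, sim.n_nr_discovery, sim.planted,
        noise_sd=sim.noise_sd, seed=seeds[1], cohort="discovery",
    )
    valc = simulate.generate_cohort(
        manifest, sim.n_r_validation, sim.n_nr_validation, sim.planted,
        noise_sd=sim.noise_sd, seed=seeds[2], cohort="validation",
    )
    pyro_disc = simulate.generate_pyro_table(
        sim.planted, disc.samples, sim.pyro_cpgs_per_assay, sim.pyro_noise_sd,
        seed=seeds[3], latent=disc.latent,
    )
    pyro_val = simulate.generate_pyro_table(
        sim.planted, valc.samples, sim.pyro_cpgs_per_assay, sim.pyro_noise_sd,
        seed=seeds[4], latent=valc.latent,
    )
    samples = pd.concat([disc.samples, valc.samples], ignore_index=True)
    latent = pd.concat([disc.latent, valc.latent])
    ct = simulate.generate_expression(
        sim.planted, samples, reference_ct=sim.reference_ct,
        seed=seeds[5], latent=latent,
    )
    data = {
        "manifest": manifest,
        "discovery": disc,
        "validation": valc,
        "samples": samples,
        "pyro": pd.concat([pyro_disc, pyro_val], ignore_index=True),
        "ct": ct,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_manifest(manifest, outdir / "manifest.csv")
        io.write_beta_matrix(disc.beta, outdir / "beta_discovery.tsv")
        io.write_beta_matrix(valc.beta, outdir / "beta_validation.tsv")
        io.write_sample_sheet(samples, outdir / "samples.csv")
        io.write_pyro(data["pyro"], outdir / "pyro.csv")
        io.write_ct(ct, outdir / "ct.csv")
    return data


def run_pipeline(config: io.PipelineConfig, outdir) -> dict:
    """Run the full analysis on simulated data and write the run report.

    Returns the report dict; every stage output lands under ``outdir``.
    Any stage failure raises after writing a FAILED marker naming the
    stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "versions": {
            "methsig": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
    }
    stage = "simulate"
    try:
        data = simulate_study(config, outdir / "inputs")

        stage = "discover"
        records = discovery.test_all_probes(
            data["discovery"].beta, data["samples"], cohort="discovery",
            params=config.cascade,
        )
        cascade = discovery.apply_cascade(records, data["manifest"], config.cascade)
        cascade.records.to_csv(outdir / "probe_records.tsv", sep="\t", index=False)
        cascade.candidates.to_csv(outdir / "candidate_genes.tsv", sep="\t", index=False)
        survivors = cascade.records[cascade.records["first_failed_filter"] == "none"]
        bed = io.manifest_to_bed(
            data["manifest"][data["manifest"]["probe_id"].isin(survivors["probe_id"])]
        )
        io.write_bed(bed, outdir / "surviving_cpgs.bed")
        report["cascade"] = {
            "step_counts": cascade.step_counts,
            "candidate_genes": cascade.candidates["gene"].tolist(),
        }

        stage = "validate"
        rep_rows = []
        for _, cand in cascade.candidates.iterrows():
            gene = cand["gene"]
            if gene not in set(data["pyro"]["gene"]):
                log.info("no pyrosequencing assay for candidate %s; skipped", gene)
                continue
            gm = validation.aggregate_gene_methylation(data["pyro"], gene)
            for cohort in ("discovery", "validation"):
                rep = validation.replicate_gene(
                    gm, data["samples"], cohort, cand["direction"],
                    alpha=config.validation.alpha, trend_p=config.validation.trend_p,
                    exact_limit=config.cascade.exact_limit,
                )
                rep_rows.append(dataclasses.asdict(rep))
        replication = pd.DataFrame(rep_rows)
        replication.to_csv(outdir / "replication.tsv", sep="\t", index=False)
        report["replication"] = rep_rows

        stage = "model"
        if replication.empty:
            selected = []
        else:
            val_rep = replication[replication["cohort"] == "validation"]
            selected = val_rep[
                val_rep["replicated"]
                | (config.model.allow_trend & val_rep["trend"])
            ]["gene"].tolist()
        report["model_input_genes"] = selected
        if not selected:
            report["model"] = None
            log.warning("no gene replicated in the validation cohort; no model fit")
        else:
            gene_meth = pd.DataFrame(
                {g: validation.aggregate_gene_methylation(data["pyro"], g)
                 for g in selected}
            )
            model = signature.select_signature(
                gene_meth, data["samples"], selected,
                max_genes=config.model.max_genes, aic_margin=config.model.aic_margin,
            )
            if model.null_model:
                report["model"] = {"null_model": True, "aic": model.aic}
            else:
                scored = signature.score_samples(model, gene_meth, data["samples"])
                seeds = _child_seeds(config.seed, 8)
                model, scored, roc = signature.derive_cutoff_and_performance(
                    model, scored, n_boot=config.model.n_boot, seed=seeds[6],
                )
                scored.to_csv(outdir / "scored_samples.tsv", sep="\t", index=False)
                pd.DataFrame(
                    {"threshold": roc.thresholds, "sensitivity": roc.sensitivity,
                     "specificity": roc.specificity}
                ).to_csv(outdir / "roc_coordinates.tsv", sep="\t", index=False)
                report["model"] = {
                    "genes": list(model.genes),
                    "coefficients": model.coefficients,
                    "aic": model.aic,
                    "cutoff": model.cutoff,
                    "auc": model.auc,
                    "auc_ci": [model.auc_ci_low, model.auc_ci_high],
                    "n_boot": model.n_boot,
                    "rate_above": model.rate_above,
                    "rate_below": model.rate_below,
                    "above": signature.format_rate(model.rcb0_above, model.n_above)
                    if model.n_above else None,
                    "below": signature.format_rate(model.rcb0_below, model.n_below)
                    if model.n_below else None,
                }
                with open(outdir / "model.json", "w") as fh:
                    json.dump(report["model"], fh, indent=2, sort_keys=True)

        stage = "expression"
        if report.get("model") and report["model"].get("genes"):
            target = report["model"]["genes"][0]
            calibrator = str(data["samples"]["sample_id"].iloc[0])
            expr = expression.delta_delta_ct(data["ct"], target, "GAPDH", calibrator)
            expr.to_csv(outdir / "relative_expression.tsv", sep="\t", index=False)
            comp = expression.compare_expression_groups(expr, data["samples"])
            meth = validation.aggregate_gene_methylation(data["pyro"], target)
            rho, p_rho = expression.methylation_expression_correlation(
                meth, expr.set_index("sample_id")["fold_change"]
            )
            report["expression"] = {
                "target": target,
                "group_comparison": dataclasses.asdict(comp),
                "methylation_expression_rho": rho,
                "methylation_expression_p": p_rho,
            }
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
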