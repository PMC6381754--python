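"""File formats, configuration and interval conversion.

On disk the pipeline speaks the field's plain-text conventions:

* beta matrix — TSV, probes in rows (index column ``probe_id``), samples
  in columns, values in [0, 1], missing as empty cells ("NA" accepted on
  read, never written);
* probe manifest — CSV with 450K-style headers (IlmnID, CHR, MAPINFO,
  UCSC_RefGene_Name, UCSC_RefGene_Group, Relation_to_UCSC_CpG_Island),
  1-based positions;
* sample sheet, pyrosequencing and Ct tables — CSV;
* CpG exports — BED (0-based half-open), converted from the manifest's
  1-based coordinates;
* model and run report — JSON.

Loading enforces the structural invariants (beta range, unique IDs,
sample cross-references) and raises naming the offending cell.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .discovery import CascadeParams
from .simulate import PlantedGene

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "SimulationParams",
    "ValidationParams",
    "ModelParams",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_manifest",
    "write_manifest",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_pyro",
    "write_pyro",
    "read_ct",
    "write_ct",
    "manifest_to_bed",
    "bed_to_positions",
]

_MANIFEST_HEADERS = {
    "probe_id": "IlmnID",
    "chrom": "CHR",
    "pos": "MAPINFO",
    "gene": "UCSC_RefGene_Name",
    "gene_group": "UCSC_RefGene_Group",
    "island_relation": "Relation_to_UCSC_CpG_Island",
}
_MANIFEST_HEADERS_INV = {v: k for k, v in _MANIFEST_HEADERS.items()}


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SimulationParams:
    """What the bundled demo simulation generates.

    Cohort sizes default to the study design (discovery 10 R vs 14 NR,
    validation 9 R vs 21 NR). Planted genes mirror the reported structure:
    several discovery hits of which only one fully replicates in the
    validation cohort and one shows a trend.
    """

    n_genes: int = 60
    cpgs_per_gene: int = 8
    islands_fraction: float = 0.7
    n_r_discovery: int = 10
    n_nr_discovery: int = 14
    n_r_validation: int = 9
    n_nr_validation: int = 21
    noise_sd: float = 0.10
    pyro_cpgs_per_assay: int = 4
    pyro_noise_sd: float = 3.0
    reference_ct: float = 20.0
    planted: tuple[PlantedGene, ...] = (
        PlantedGene("FERD3L", "hyper_in_R", 0.30, sd_within=0.15,
                    delta_validation=0.25, expression_coupling=-4.0),
        PlantedGene("TRIP10", "hyper_in_R", 0.30, sd_within=0.15,
                    delta_validation=0.12, expression_coupling=-4.0),
        PlantedGene("CHL1", "hyper_in_R", 0.25, sd_within=0.12,
                    delta_validation=0.03, expression_coupling=-3.0),
        PlantedGene("LEF1", "hyper_in_NR", 0.30, sd_within=0.10,
                    delta_validation=0.04, expression_coupling=-3.0),
        PlantedGene("HOXA5", "hyper_in_NR", 0.28, sd_within=0.12,
                    delta_validation=0.05, expression_coupling=-3.0),
        PlantedGene("CDKL2", "hyper_in_NR", 0.24, sd_within=0.15,
                    delta_validation=0.02, expression_coupling=-3.0),
    )


@dataclass(frozen=True)
class ValidationParams:
    alpha: float = 0.05
    trend_p: float = 0.20
    age_cut: float | None = None


@dataclass(frozen=True)
class ModelParams:
    max_genes: int = 2
    n_boot: int = 1000
    allow_trend: bool = True  # carry trend-level genes into AIC selection
    aic_margin: float = 4.0


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; defaults are the published thresholds."""

    seed: int = 0
    cascade: CascadeParams = field(default_factory=CascadeParams)
    validation: ValidationParams = field(default_factory=ValidationParams)
    model: ModelParams = field(default_factory=ModelParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build_dataclass(cls, data, "config")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, frozenset):
                return sorted(obj)
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            return obj

        return enc(self)


def _build_dataclass(cls, data: dict, where: str):
    """Recursively build a (frozen) dataclass, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"{where}: expected a mapping, got {type(data).__name__}")
    fields_by_name = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields_by_name)
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields_by_name[name]
        if name == "planted":
            kwargs[name] = tuple(
                v if isinstance(v, PlantedGene) else PlantedGene(**v) for v in value
            )
        elif f.type in ("CascadeParams",) or f.name == "cascade":
            kwargs[name] = (
                value if isinstance(value, CascadeParams)
                else _build_dataclass(CascadeParams, _setify(value), f"{where}.{name}")
            )
        elif f.name == "validation":
            kwargs[name] = (
                value if isinstance(value, ValidationParams)
                else _build_dataclass(ValidationParams, value, f"{where}.{name}")
            )
        elif f.name == "model":
            kwargs[name] = (
                value if isinstance(value, ModelParams)
                else _build_dataclass(ModelParams, value, f"{where}.{name}")
            )
        elif f.name == "simulation":
            kwargs[name] = (
                value if isinstance(value, SimulationParams)
                else _build_dataclass(SimulationParams, value, f"{where}.{name}")
            )
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _setify(value: dict) -> dict:
    out = dict(value)
    for key in ("promoter_groups", "island_relations"):
        if key in out and not isinstance(out[key], frozenset):
            out[key] = frozenset(out[key])
    return out


# ---------------------------------------------------------------------------
# readers / writers

def read_beta_matrix(
    path, manifest: pd.DataFrame | None = None, samples: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Load a probe x sample beta TSV, enforcing range and label invariants."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    df.index.name = "probe_id"
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate probe_id in beta matrix: {dup[0]!r}")
    values = df.to_numpy(dtype=float)
    bad = np.argwhere((values < 0.0) | (values > 1.0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"beta out of [0,1] at probe {df.index[i]!r}, sample "
            f"{df.columns[j]!r}: {values[i, j]}"
        )
    if manifest is not None:
        unknown = df.index.difference(manifest["probe_id"])
        if len(unknown):
            raise ValueError(f"beta probes absent from manifest: {list(unknown[:5])}")
    if samples is not None:
        unknown = df.columns.difference(samples["sample_id"])
        if len(unknown):
            raise ValueError(f"unknown samples in beta matrix: {list(unknown[:5])}")
    log.info("beta matrix: %d probes x %d samples", *df.shape)
    return df


def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", na_rep="", index_label="probe_id")


def read_manifest(path) -> pd.DataFrame:
    """Load a 450K-style manifest CSV into internal column names."""
    df = pd.read_csv(path, na_values=["NA", ""])
    missing = set(_MANIFEST_HEADERS.values()) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    df = df.rename(columns=_MANIFEST_HEADERS_INV)[list(_MANIFEST_HEADERS)]
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate probe_id in manifest: {dup.iloc[0]!r}")
    if (df["pos"] < 1).any():
        bad = df.loc[df["pos"] < 1, "probe_id"].iloc[0]
        raise ValueError(f"manifest position < 1 for probe {bad!r}")
    log.info("manifest: %d probes", len(df))
    return df


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.rename(columns=_MANIFEST_HEADERS).to_csv(path, index=False, na_rep="")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA", ""])
    for col in ("sample_id", "cohort", "rcb_class"):
        if col not in df.columns:
            raise ValueError(f"sample sheet missing column {col!r}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id: {dup.iloc[0]!r}")
    derived = np.where(df["rcb_class"] == 0, "R", "NR")
    if "response" in df.columns:
        bad = df.loc[df["response"] != derived, "sample_id"]
        if len(bad):
            raise ValueError(
                f"response inconsistent with rcb_class for sample {bad.iloc[0]!r}"
            )
    else:
        df["response"] = derived
    log.info("sample sheet: %d samples", len(df))
    return df


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False, na_rep="")


def read_pyro(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA", ""])
    for col in ("sample_id", "gene", "cpg_index", "pct_methylation"):
        if col not in df.columns:
            raise ValueError(f"pyro table missing column {col!r}")
    vals = df["pct_methylation"]
    bad = df[(vals < 0) | (vals > 100)]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(
            f"pct_methylation out of [0,100] for sample {r['sample_id']!r} "
            f"gene {r['gene']!r}: {r['pct_methylation']}"
        )
    return df


def write_pyro(pyro: pd.DataFrame, path) -> None:
    pyro.to_csv(path, index=False, na_rep="")


def read_ct(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA", ""])
    for col in ("sample_id", "gene", "replicate", "ct"):
        if col not in df.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    return df


def write_ct(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# interval conversion

def manifest_to_bed(manifest: pd.DataFrame) -> pd.DataFrame:
    """1-based manifest positions -> 0-based half-open single-base BED."""
    return pd.DataFrame(
        {
            "chrom": manifest["chrom"],
            "start": manifest["pos"] - 1,
            "end": manifest["pos"],
            "name": manifest["probe_id"],
        }
    )


def bed_to_positions(bed: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`manifest_to_bed` for single-base intervals."""
    if ((bed["end"] - bed["start"]) != 1).any():
        raise ValueError("expected single-base intervals")
    return pd.DataFrame(
        {"probe_id": bed["name"], "chrom": bed["chrom"], "pos": bed["start"] + 1}
    )


def write_bed(bed: pd.DataFrame, path) -> None:
    bed.to_csv(path, sep="\t", header=False, index=False)
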