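"""Tabular readers/writers, configuration loading and run manifests.

All tabular files are UTF-8, tab-delimited with a header row; units are
embedded in the column names.  The configuration schema (pydantic) drives
the CLI pipeline and enumerates violations with field paths.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError as PydanticValidationError

from . import __version__
from .exceptions import ValidationError
from .mbll import ConcentrationSeries, ExtinctionTable, PathlengthSpec, RawRecording
from .tissue_mc import OpticalLayer, ProbeGeometry, TissueModel


# ---------------------------------------------------------------- tissue

def load_tissue_model(path=None) -> TissueModel:
    """Load a layered tissue model from YAML (packaged calf model by default)."""
    if path is None:
        ref = resources.files("nirsox.data") / "tissue_calf.yaml"
        with resources.as_file(ref) as p:
            cfg = yaml.safe_load(p.read_text())
    else:
        cfg = yaml.safe_load(Path(path).read_text())
    layers = []
    for lay in cfg["layers"]:
        mu_a = lay["mu_a"]
        mu_s = lay["mu_s"]
        if isinstance(mu_a, dict):
            mu_a = {float(k): float(v) for k, v in mu_a.items()}
        if isinstance(mu_s, dict):
            mu_s = {float(k): float(v) for k, v in mu_s.items()}
        layers.append(OpticalLayer(
            mu_a=mu_a, mu_s=mu_s, g=float(lay["g"]), n=float(lay["n"]),
            thickness_mm=lay.get("thickness_mm"), name=lay.get("name", "")))
    return TissueModel(layers=tuple(layers),
                       n_ambient=float(cfg.get("n_ambient", 1.0)))


# ------------------------------------------------------------- recordings

def read_recording(path, baseline_window=(0.0, 600.0)) -> RawRecording:
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"time_s", "detector", "wavelength_nm", "intensity"}
    if not required.issubset(df.columns):
        raise ValidationError(f"recording file missing columns {required - set(df.columns)}")
    return RawRecording.from_frame(df, baseline_window=baseline_window)


def write_concentrations(conc: ConcentrationSeries, path) -> None:
    conc.to_frame().to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_concentrations(path) -> ConcentrationSeries:
    df = pd.read_csv(path, sep="\t")
    return ConcentrationSeries(
        time=df["time_s"].to_numpy(float),
        dc_hb=df["dc_hb_um"].to_numpy(float),
        dc_hbo2=df["dc_hbo2_um"].to_numpy(float),
        d_oxy=df["d_oxy_um"].to_numpy(float) if "d_oxy_um" in df else None,
        d_bv=df["d_bv_um"].to_numpy(float) if "d_bv_um" in df else None,
        residual=df["residual_od"].to_numpy(float) if "residual_od" in df else None)


# ------------------------------------------------------------------ config

class NoiseConfig(BaseModel):
    intensity_cv: float = Field(0.005, ge=0)
    amplitude_sigma: float = Field(0.10, ge=0)
    reference_sigma_pct: float = Field(0.2, ge=0)
    hr_sigma_bpm: float = Field(2.0, ge=0)


class MbllConfig(BaseModel):
    extinction_table: str | None = None  # None -> packaged table
    dpf: float = Field(4.0, gt=0)
    separation_cm: float = Field(2.0, gt=0)
    baseline_s: tuple[float, float] = (0.0, 600.0)
    detector: str = "mean"


class CohortConfig(BaseModel):
    n_per_group: int = Field(6, ge=2)
    sample_rate_hz: float = Field(1.0, gt=0)


class SimulationConfig(BaseModel):
    tissue_model: str | None = None  # None -> packaged calf model
    wavelength_nm: float = 805.0
    n_photons: int = Field(1_000_000, ge=1)
    separations_cm: tuple[float, ...] = (2.0,)
    detector_radius_mm: float = Field(1.5, gt=0)


class StudyConfig(BaseModel):
    """Single configuration object driving every pipeline stage."""

    seed: int = 42
    alpha: float = Field(0.01, gt=0, lt=1)
    cohort: CohortConfig = CohortConfig()
    noise: NoiseConfig = NoiseConfig()
    mbll: MbllConfig = MbllConfig()
    simulation: SimulationConfig = SimulationConfig()


def load_config(path=None) -> StudyConfig:
    """Load and validate a YAML/JSON study configuration.

    Schema violations are re-raised as ValidationError listing each
    offending field path.
    """
    if path is None:
        return StudyConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return StudyConfig.model_validate(raw)
    except PydanticValidationError as exc:
        fields = "; ".join(
            ".".join(str(loc) for loc in err["loc"]) + ": " + err["msg"]
            for err in exc.errors())
        raise ValidationError(f"invalid configuration: {fields}") from exc


def mbll_settings(cfg: StudyConfig) -> tuple[ExtinctionTable, PathlengthSpec]:
    eps = (ExtinctionTable.from_tsv(cfg.mbll.extinction_table)
           if cfg.mbll.extinction_table else ExtinctionTable.default())
    return eps, PathlengthSpec(separation_cm=cfg.mbll.separation_cm, dpf=cfg.mbll.dpf)


# ---------------------------------------------------------------- manifest

def sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir, command: str, config: dict, seeds: dict,
                   files: list[Path]) -> Path:
    """Record enough provenance to re-run a deterministic command
    bit-identically: command, config hash, seeds and output checksums."""
    out_dir = Path(out_dir)
    config_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "tool_version": __version__,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "config": json.loads(config_json),
        "seeds": seeds,
        "outputs": {Path(f).name: sha256_file(f) for f in files},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
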