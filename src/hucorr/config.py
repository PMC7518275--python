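"""Run configuration: one YAML file driving the command-line workflows."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .beam import BeamModelParams
from .correction import MaterialTable, ScannerCalibration
from .xsection import (
    RAYLEIGH_FIT_TABLE,
    CrossSectionTable,
    load_packaged_table,
    load_xsection_table,
)

__all__ = ["SimulationConfig", "FitConfig", "RunConfig"]


@dataclass(frozen=True)
class SimulationConfig:
    spacing: float = 0.1
    n_slices: int = 8
    noise_sd: float = 5.0
    seed: int = 0
    kvps: tuple[float, ...] = (80.0, 110.0, 130.0)
    shapes: tuple[str, ...] = ("head", "abdomen")

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.n_slices < 1 or self.noise_sd < 0:
            raise ValueError("invalid simulation block: spacing > 0, n_slices >= 1, noise_sd >= 0 required")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")


@dataclass(frozen=True)
class FitConfig:
    component: str = "rayleigh"
    e_min: float = 50.0
    e_max: float = 100.0


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for the CLI commands."""

    xsection: CrossSectionTable
    fit_table: CrossSectionTable
    calibration: ScannerCalibration = ScannerCalibration()
    beam: BeamModelParams = BeamModelParams()
    materials: MaterialTable = field(default_factory=MaterialTable)
    simulation: SimulationConfig = SimulationConfig()
    fit: FitConfig = FitConfig()
    config_hash: str = ""

    @classmethod
    def load(cls, path: str | Path | None = None) -> "RunConfig":
        """Load a YAML config; every block is optional and defaults apply."""
        raw: dict = {}
        digest = "defaults"
        if path is not None:
            text = Path(path).read_text()
            raw = yaml.safe_load(text) or {}
            digest = hashlib.sha256(text.encode()).hexdigest()[:12]

        paths = raw.get("paths", {}) or {}
        for key in ("xsection_table", "fit_table", "material_table"):
            p = paths.get(key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured {key} does not exist: {p}")

        xsec = (
            load_xsection_table(paths["xsection_table"])
            if paths.get("xsection_table")
            else load_packaged_table()
        )
        fit_table = (
            load_xsection_table(paths["fit_table"])
            if paths.get("fit_table")
            else load_packaged_table(RAYLEIGH_FIT_TABLE)
        )
        materials = (
            MaterialTable.from_csv(paths["material_table"], xsec)
            if paths.get("material_table")
            else MaterialTable()
        )

        calib_kw = dict(raw.get("calibration", {}) or {})
        if "effective_energy_map" in calib_kw:
            calib_kw["effective_energy_map"] = tuple(
                sorted((float(k), float(v)) for k, v in dict(calib_kw["effective_energy_map"]).items())
            )
        beam_kw = dict(raw.get("beam", {}) or {})
        sim_kw = dict(raw.get("simulation", {}) or {})
        for key in ("kvps", "shapes"):
            if key in sim_kw:
                sim_kw[key] = tuple(sim_kw[key])
        fit_kw = dict(raw.get("fit", {}) or {})

        return cls(
            xsection=xsec,
            fit_table=fit_table,
            calibration=ScannerCalibration(**calib_kw),
            beam=BeamModelParams(**beam_kw),
            materials=materials,
            simulation=SimulationConfig(**sim_kw),
            fit=FitConfig(**fit_kw),
            config_hash=digest,
        )
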