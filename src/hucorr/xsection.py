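"""Photon cross-section tables of water: loading, interpolation and power-law fits.

Water's attenuation components anchor two things downstream: the Rayleigh
(coherent) component drives the size/depth correction through its mean free
path, and the total attenuation provides the water reference of the
Hounsfield scale.  Tables store one row per photon energy (keV); component
values are in the units recorded by ``units_label`` (the packaged wide table
uses mass attenuation coefficients, cm^2/g).  All interpolation is
piecewise-linear in (log E, log sigma) and never extrapolates: attenuation
curves are locally close to power laws, and silent extrapolation of a fitted
power law outside the diagnostic energy window is exactly the failure mode
this module is meant to prevent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CrossSectionTable",
    "PowerLawFit",
    "load_xsection_table",
    "load_packaged_table",
    "fit_power_law",
    "rayleigh_mean_free_path",
    "interpolate_mu_water",
    "RAYLEIGH_FIT_TABLE",
    "WIDE_WATER_TABLE",
]

#: Names of the packaged fixture tables (under ``hucorr/data``).
RAYLEIGH_FIT_TABLE = "water_rayleigh_50_100keV_synthetic.csv"
WIDE_WATER_TABLE = "water_xsection_10_150keV_synthetic.csv"

_COMPONENTS = ("rayleigh", "compton", "photoelectric", "total")

# Tolerance of the row-wise sum consistency check: total must equal the sum of
# Rayleigh + Compton + photoelectric within 5% (minor processes ignored).
_SUM_RTOL = 0.05


@dataclass(frozen=True)
class CrossSectionTable:
    """Energy-gridded attenuation components of a medium (usually water).

    Parameters
    ----------
    energy_grid
        Photon energies in keV, strictly increasing, all positive.
    rayleigh, compton, photoelectric, total
        Component arrays aligned with ``energy_grid``; any may be ``None``
        except that at least one component must be present.  Units are
        whatever ``units_label`` says; conversion to linear attenuation
        (1/cm) multiplies by ``density``.
    density
        Mass density of the medium in g/cm^3 (water: 1.0).
    units_label
        Free-text record of the cross-section unit convention.
    """

    energy_grid: np.ndarray
    rayleigh: np.ndarray | None = None
    compton: np.ndarray | None = None
    photoelectric: np.ndarray | None = None
    total: np.ndarray | None = None
    density: float = 1.0
    units_label: str = "unspecified"
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_grid, dtype=float)
        object.__setattr__(self, "energy_grid", e)
        if e.ndim != 1 or e.size < 2:
            raise ValueError("energy_grid must be a 1-d array with >= 2 points")
        if np.any(e <= 0):
            raise ValueError("energy_grid values must be > 0")
        if np.any(np.diff(e) <= 0):
            raise ValueError("non-monotonic energy grid")
        present = []
        for name in _COMPONENTS:
            col = getattr(self, name)
            if col is None:
                continue
            col = np.asarray(col, dtype=float)
            if col.shape != e.shape:
                raise ValueError(f"component '{name}' length {col.size} != energy grid length {e.size}")
            if np.any(col < 0):
                raise ValueError(f"component '{name}' contains negative values")
            object.__setattr__(self, name, col)
            present.append(name)
        if not present or present == ["total"]:
            raise ValueError("at least one component column (rayleigh/compton/photoelectric) is required")
        self._check_sum_consistency()

    def _check_sum_consistency(self) -> None:
        if self.total is None:
            return
        if any(getattr(self, n) is None for n in ("rayleigh", "compton", "photoelectric")):
            return
        s = self.rayleigh + self.compton + self.photoelectric
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(self.total - s) / self.total
        bad = np.nonzero(rel > _SUM_RTOL)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                "sum-consistency failure: |total - (rayleigh+compton+photoelectric)|/total "
                f"= {rel[i]:.3f} > {_SUM_RTOL} at {self.energy_grid[i]:g} keV"
            )

    @property
    def n_rows(self) -> int:
        return int(self.energy_grid.size)

    def component(self, name: str) -> np.ndarray:
        """Return a component array by name, raising if absent."""
        if name not in _COMPONENTS:
            raise ValueError(f"unknown component '{name}'; expected one of {_COMPONENTS}")
        col = getattr(self, name)
        if col is None:
            raise ValueError(f"table has no '{name}' column")
        return col

    def energy_span(self) -> tuple[float, float]:
        return float(self.energy_grid[0]), float(self.energy_grid[-1])


@dataclass(frozen=True)
class PowerLawFit:
    """Result of fitting sigma(V) = amplitude * V**exponent over a restricted range."""

    amplitude: float
    exponent: float
    fit_range: tuple[float, float]
    rms_relative_residual: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.rms_relative_residual < 0:
            raise ValueError("rms_relative_residual must be >= 0")

    def __call__(self, energy_kev: float) -> float:
        return self.amplitude * float(energy_kev) ** self.exponent


def load_xsection_table(source: str | Path | io.TextIOBase, *, density: float = 1.0) -> CrossSectionTable:
    """Load a cross-section table from CSV text.

    The CSV must have a header naming ``energy_keV`` and at least one
    component column among ``rayleigh``, ``compton``, ``photoelectric``
    (``total`` optional), with ``#`` comment lines allowed; a comment line of
    the form ``# units_label: ...`` is picked up as the unit convention.
    Rows are validated (>= 4 of them), sorted order is required (duplicate or
    decreasing energies are a hard error, not silently fixed).
    """
    units_label = "unspecified"
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        origin = str(source)
    else:
        text = source.read()
        origin = getattr(source, "name", "<stream>")
    for line in text.splitlines():
        if line.startswith("#") and "units_label:" in line:
            units_label = line.split("units_label:", 1)[1].strip()
    df = pd.read_csv(io.StringIO(text), comment="#")
    df.columns = [c.strip() for c in df.columns]
    if "energy_keV" not in df.columns:
        raise ValueError("missing required column 'energy_keV'")
    component_cols = [c for c in _COMPONENTS if c in df.columns]
    if not [c for c in component_cols if c != "total"]:
        raise ValueError("missing component column: need at least one of 'rayleigh', 'compton', 'photoelectric'")
    if len(df) < 4:
        raise ValueError(f"table has {len(df)} rows; >= 4 required")
    kwargs = {name: df[name].to_numpy(dtype=float) for name in component_cols}
    return CrossSectionTable(
        energy_grid=df["energy_keV"].to_numpy(dtype=float),
        density=density,
        units_label=units_label,
        source=origin,
        **kwargs,
    )


def load_packaged_table(name: str = WIDE_WATER_TABLE) -> CrossSectionTable:
    """Load one of the water tables shipped with the package."""
    ref = resources.files("hucorr.data").joinpath(name)
    with resources.as_file(ref) as path:
        return load_xsection_table(path)


def fit_power_law(
    table: CrossSectionTable,
    component: str,
    e_min: float,
    e_max: float,
) -> PowerLawFit:
    """Ordinary least squares fit of log(sigma) = log(A) + b*log(V) on [e_min, e_max].

    Returns the amplitude A (table units), exponent b (dimensionless, unit
    independent) and the RMS relative residual of the fit.  Requires at least
    three grid points inside the range and strictly positive component values
    there.
    """
    sigma = table.component(component)
    e = table.energy_grid
    lo, hi = table.energy_span()
    if e_min >= e_max:
        raise ValueError("e_min must be < e_max")
    if e_min < lo or e_max > hi:
        raise ValueError(f"fit range [{e_min}, {e_max}] outside table span [{lo}, {hi}]")
    mask = (e >= e_min) & (e <= e_max)
    if int(mask.sum()) < 3:
        raise ValueError(f"only {int(mask.sum())} grid points inside [{e_min}, {e_max}]; >= 3 required")
    y = sigma[mask]
    if np.any(y <= 0):
        raise ValueError(f"component '{component}' has non-positive values inside the fit range")
    logv = np.log(e[mask])
    logy = np.log(y)
    design = np.column_stack([np.ones_like(logv), logv])
    coef, *_ = np.linalg.lstsq(design, logy, rcond=None)
    log_a, b = coef
    pred = design @ coef
    rms = float(np.sqrt(np.mean((np.exp(pred) / y - 1.0) ** 2)))
    return PowerLawFit(
        amplitude=float(np.exp(log_a)),
        exponent=float(b),
        fit_range=(float(e_min), float(e_max)),
        rms_relative_residual=rms,
    )


def _loglog_interp(table: CrossSectionTable, component: str, energy_kev: float) -> float:
    """Piecewise-linear interpolation in (log E, log sigma); hard error outside the grid."""
    e = table.energy_grid
    lo, hi = table.energy_span()
    v = float(energy_kev)
    if not (lo <= v <= hi):
        raise ValueError(f"energy {v:g} keV outside table span [{lo:g}, {hi:g}] (no extrapolation)")
    sigma = table.component(component)
    if np.any(sigma <= 0):
        raise ValueError(f"component '{component}' has non-positive values; log-log interpolation undefined")
    return float(np.exp(np.interp(np.log(v), np.log(e), np.log(sigma))))


def rayleigh_mean_free_path(table: CrossSectionTable, energy_kev: float) -> float:
    """Mean free path of Rayleigh scattering, x0 = 1/sigma_R (cm).

    The table's Rayleigh component is converted to a linear attenuation
    coefficient (1/cm) with the table density before taking the reciprocal;
    interpolation between grid points is log-log.
    """
    sigma_mass = _loglog_interp(table, "rayleigh", energy_kev)
    sigma_lin = sigma_mass * table.density
    if sigma_lin <= 0:
        raise ValueError("Rayleigh attenuation is zero at the requested energy; mean free path undefined")
    return 1.0 / sigma_lin


def interpolate_mu_water(table: CrossSectionTable, energy_kev: float) -> float:
    """Total linear attenuation of water at the given energy (1/cm), log-log interpolated."""
    mu_mass = _loglog_interp(table, "total", energy_kev)
    return mu_mass * table.density
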