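"""Hounsfield Unit computation and the size/voltage-dependent correction.

The CT number of a material with linear attenuation ``mu`` against the water
reference ``mu_w(V)`` is ``HU = 1000 * (mu - mu_w) / mu_w``.  In a body of
finite size the effective attenuation of bulk water is depressed by the
depth-dependent Rayleigh term, so the reported number at depth x inside a
body of radius r becomes

    HU(x, V) = 1000 * (mu - mu_w(V) + f_c(x, V)) / (mu_w(V) - f_c(r, V))

with the correction factor ``f_c`` of :mod:`hucorr.beam` (numerator at the
query depth, denominator at the body radius).  That form assumes the scanner
was calibrated on a zero-sized phantom.  Real scanners are calibrated on a
finite phantom, so when a non-zero calibration size is configured the
correction enters as a *difference* against the calibration geometry,

    Dfc(x, V) = f_c(x, V) - f_c(x_cal, V),   x_cal = cal_diameter / 2,

which makes the calibration point an exact fixed point: water measured at
the calibration size reads 0.000 HU at every mapped voltage.  Setting
``cal_diameter = 0`` recovers the zero-size-calibration form unchanged.

All scanner-facing operations take the tube voltage in kVp and map it to the
effective mono-energy in keV through :class:`ScannerCalibration`; the
scanner's own hardening exponent ``epsilon_system`` overrides the generic
``BeamModelParams.epsilon`` here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beam import BeamModelParams, DepthQuery
from .xsection import CrossSectionTable, interpolate_mu_water, rayleigh_mean_free_path

__all__ = [
    "ScannerCalibration",
    "MaterialTable",
    "DEFAULT_NOMINAL_HU",
    "effective_energy",
    "hu_from_mu",
    "corrected_hu",
    "corrected_hu_field",
    "correct_measured_hu",
    "predict_delta_hu_size",
    "predict_delta_hu_depth",
]


@dataclass(frozen=True)
class ScannerCalibration:
    """What "zero correction" means for a given scanner.

    Defaults model the studied system: calibrated on a 30 cm (averaged)
    phantom at 110 kVp, effective energies 58/64/72 keV for 80/110/130 kVp,
    and a system hardening exponent of 0.045.
    """

    cal_diameter: float = 30.0
    cal_kvp: float = 110.0
    effective_energy_map: tuple[tuple[float, float], ...] = ((80.0, 58.0), (110.0, 64.0), (130.0, 72.0))
    epsilon_system: float = 0.045

    def __post_init__(self) -> None:
        if self.cal_diameter < 0:
            raise ValueError("cal_diameter must be >= 0")
        m = tuple((float(k), float(v)) for k, v in self.effective_energy_map)
        object.__setattr__(self, "effective_energy_map", m)
        kvps = [k for k, _ in m]
        kevs = [v for _, v in m]
        if len(m) < 1:
            raise ValueError("effective_energy_map must not be empty")
        if any(b <= a for a, b in zip(kvps, kvps[1:])):
            raise ValueError("effective_energy_map kVp keys must be strictly increasing")
        if any(b <= a for a, b in zip(kevs, kevs[1:])):
            raise ValueError("effective_energy_map keV values must be strictly increasing")
        if self.cal_kvp not in kvps:
            raise ValueError(f"cal_kvp {self.cal_kvp:g} is not a key of the effective-energy map")
        if self.epsilon_system <= 0:
            raise ValueError("epsilon_system must be > 0")

    @property
    def cal_radius(self) -> float:
        return self.cal_diameter / 2.0

    @property
    def cal_energy_kev(self) -> float:
        return effective_energy(self.cal_kvp, self)


def effective_energy(kvp: float, calib: ScannerCalibration) -> float:
    """Map a tube voltage (kVp) to the effective mono-energy (keV).

    Exact on map keys, linear interpolation between keys, hard error outside
    the key range (beam filtration outside the calibrated range is unknown).
    """
    kvps = np.array([k for k, _ in calib.effective_energy_map])
    kevs = np.array([v for _, v in calib.effective_energy_map])
    v = float(kvp)
    if not (kvps[0] <= v <= kvps[-1]):
        raise ValueError(f"kVp {v:g} outside calibrated range [{kvps[0]:g}, {kvps[-1]:g}]")
    return float(np.interp(v, kvps, kevs))


def hu_from_mu(mu: float, mu_w: float) -> float:
    """Plain Hounsfield Unit: 1000 * (mu - mu_w) / mu_w."""
    if mu_w <= 0:
        raise ValueError("water attenuation mu_w must be > 0")
    return 1000.0 * (mu - mu_w) / mu_w


# --- material table -------------------------------------------------------

#: Nominal CT numbers of the insert materials at the calibration point.
#: Soft-tissue values are CIRS-typical literature numbers; the bone names
#: carry their nominal HU.  These are fixture defaults, not measured data.
DEFAULT_NOMINAL_HU: dict[str, float] = {
    "water": 0.0,
    "breast": -46.0,
    "adipose": -69.0,
    "liver": 49.0,
    "muscle": 44.0,
    "bone200": 200.0,
    "bone800": 800.0,
    "bone1250": 1250.0,
}


@dataclass(frozen=True)
class MaterialTable:
    """Linear attenuation of the insert materials as a function of energy.

    Two representations are supported: per-material nominal HU at the
    calibration point, back-converted to ``mu(V) = mu_w(V) * (1 + hu/1000)``
    at any energy (energy-independent contrast, a deliberate fixture
    simplification), or an explicit per-energy ``mu`` table interpolated
    log-linearly in energy.
    """

    nominal_hu: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOMINAL_HU))
    mu_table: pd.DataFrame | None = None  # columns: material, energy_keV, mu_per_cm

    def __post_init__(self) -> None:
        if self.mu_table is not None:
            if np.any(self.mu_table["mu_per_cm"].to_numpy() <= 0):
                raise ValueError("all mu values must be > 0")

    @property
    def materials(self) -> tuple[str, ...]:
        if self.mu_table is not None:
            return tuple(dict.fromkeys(self.mu_table["material"]))
        return tuple(self.nominal_hu)

    def __contains__(self, name: str) -> bool:
        return name in self.materials

    def _require(self, name: str) -> None:
        if name not in self:
            raise ValueError(f"unknown material '{name}'; known materials: {', '.join(self.materials)}")

    def mu(self, name: str, energy_kev: float, xsec: CrossSectionTable) -> float:
        """Linear attenuation (1/cm) of a material at an effective energy."""
        self._require(name)
        if self.mu_table is not None:
            rows = self.mu_table[self.mu_table["material"] == name]
            e = rows["energy_keV"].to_numpy(dtype=float)
            m = rows["mu_per_cm"].to_numpy(dtype=float)
            order = np.argsort(e)
            e, m = e[order], m[order]
            v = float(energy_kev)
            if not (e[0] <= v <= e[-1]):
                raise ValueError(f"energy {v:g} keV outside material table span for '{name}'")
            return float(np.exp(np.interp(v, e, np.log(m))))
        mu_w = interpolate_mu_water(xsec, energy_kev)
        return mu_w * (1.0 + self.nominal_hu[name] / 1000.0)

    def hu_at(self, name: str, energy_kev: float, xsec: CrossSectionTable) -> float:
        """Nominal (uncorrected) HU of a material at an effective energy."""
        return hu_from_mu(self.mu(name, energy_kev, xsec), interpolate_mu_water(xsec, energy_kev))

    @classmethod
    def from_csv(cls, source: str | Path | io.TextIOBase, xsec: CrossSectionTable | None = None) -> "MaterialTable":
        """Load from CSV, schema ``material,nominal_hu`` or ``material,energy_keV,mu_per_cm``.

        If a cross-section table is supplied and the mu-table contains a
        water row, the water attenuation is validated against the table's
        interpolated value (1% tolerance).
        """
        df = pd.read_csv(source, comment="#")
        df.columns = [c.strip() for c in df.columns]
        if {"material", "nominal_hu"}.issubset(df.columns):
            return cls(nominal_hu=dict(zip(df["material"], df["nominal_hu"].astype(float))))
        if {"material", "energy_keV", "mu_per_cm"}.issubset(df.columns):
            table = cls(nominal_hu={}, mu_table=df)
            if xsec is not None and "water" in table:
                rows = df[df["material"] == "water"]
                for _, row in rows.iterrows():
                    ref = interpolate_mu_water(xsec, float(row["energy_keV"]))
                    if abs(float(row["mu_per_cm"]) - ref) / ref > 0.01:
                        raise ValueError(
                            f"water mu at {row['energy_keV']:g} keV deviates from the "
                            f"cross-section table by more than 1%"
                        )
            return table
        raise ValueError("material CSV needs columns material,nominal_hu or material,energy_keV,mu_per_cm")


# --- corrected HU ---------------------------------------------------------

def _delta_fc(x: np.ndarray | float, V: float, calib: ScannerCalibration,
              params: BeamModelParams, xsec: CrossSectionTable) -> np.ndarray | float:
    """Calibration-referenced correction Dfc(x, V) = f_c(x, V) - f_c(x_cal, V).

    Vectorized over x.  Uses the scanner's epsilon and the Rayleigh mean
    free path from the cross-section table; reduces to plain f_c when the
    calibration diameter is zero.
    """
    p = params.with_epsilon(calib.epsilon_system)
    x0 = rayleigh_mean_free_path(xsec, V)
    amp = p.A * V ** (p.b + 1.0)
    c = p.denom_const

    def fc(depth):
        return amp / (p.epsilon * x0 + c) - amp / (p.epsilon * (x0 + np.asarray(depth, dtype=float)) + c)

    out = fc(x) - fc(calib.cal_radius)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def corrected_hu(
    mu: float,
    q: DepthQuery,
    calib: ScannerCalibration,
    params: BeamModelParams,
    xsec: CrossSectionTable,
) -> float:
    """Size/voltage-corrected CT number at depth ``q.x`` in a body of radius ``q.r``.

    ``q.V`` is the effective energy in keV.  The numerator applies the
    calibration-referenced correction at the query depth, the denominator at
    the body radius; at the calibration geometry both vanish and the plain
    HU definition is recovered exactly.
    """
    mu_w = interpolate_mu_water(xsec, q.V)
    dfc_x = _delta_fc(q.x, q.V, calib, params, xsec)
    dfc_r = _delta_fc(q.r, q.V, calib, params, xsec)
    denom = mu_w - dfc_r
    if denom <= 0:
        raise ValueError("correction exceeds water attenuation: mu_w - f_c(r, V) <= 0")
    return 1000.0 * (mu - mu_w + dfc_x) / denom


def corrected_hu_field(
    mu: np.ndarray | float,
    depth: np.ndarray,
    r: float,
    V: float,
    calib: ScannerCalibration,
    params: BeamModelParams,
    xsec: CrossSectionTable,
) -> np.ndarray:
    """Vectorized :func:`corrected_hu` over arrays of depths (and optionally mu).

    Used by the phantom rasterizer; identical arithmetic to the scalar form.
    """
    mu_w = interpolate_mu_water(xsec, V)
    dfc_x = _delta_fc(np.asarray(depth, dtype=float), V, calib, params, xsec)
    dfc_r = _delta_fc(float(r), V, calib, params, xsec)
    denom = mu_w - dfc_r
    if denom <= 0:
        raise ValueError("correction exceeds water attenuation: mu_w - f_c(r, V) <= 0")
    return 1000.0 * (np.asarray(mu, dtype=float) - mu_w + dfc_x) / denom


def correct_measured_hu(
    hu_meas: float,
    q: DepthQuery,
    calib: ScannerCalibration,
    params: BeamModelParams,
    xsec: CrossSectionTable,
) -> float:
    """Map a measured HU at (x, r, V) back to the calibration-condition HU.

    Inverts the corrected-HU relation for the material attenuation ``mu``
    and re-evaluates the plain HU definition; exact round-trip with
    :func:`corrected_hu`.
    """
    if hu_meas <= -1000.0:
        raise ValueError("measured HU must be > -1000")
    mu_w = interpolate_mu_water(xsec, q.V)
    dfc_x = _delta_fc(q.x, q.V, calib, params, xsec)
    dfc_r = _delta_fc(q.r, q.V, calib, params, xsec)
    denom = mu_w - dfc_r
    if denom <= 0:
        raise ValueError("correction exceeds water attenuation: mu_w - f_c(r, V) <= 0")
    mu = hu_meas / 1000.0 * denom + mu_w - dfc_x
    return hu_from_mu(mu, mu_w)


# --- change predictions ---------------------------------------------------

def predict_delta_hu_size(
    material: str,
    kvp: float,
    size1_diam: float,
    size2_diam: float,
    calib: ScannerCalibration,
    params: BeamModelParams,
    xsec: CrossSectionTable,
    materials: MaterialTable,
    *,
    depth1: float | None = None,
    depth2: float | None = None,
) -> float:
    """Predicted CT-number change when the body grows from size1 to size2.

    By default the insert is taken at the body centre (depth = radius) in
    each body.  ``depth1``/``depth2`` override the insert depth per size for
    off-centre inserts — the measured hole sits well off centre, so pattern
    comparisons against measurements should pass the true hole depths.
    Antisymmetric under swapping the two sizes.
    """
    if size1_diam <= 0 or size2_diam <= 0:
        raise ValueError("phantom diameters must be > 0")
    materials._require(material)
    V = effective_energy(kvp, calib)
    mu = materials.mu(material, V, xsec)
    r1, r2 = size1_diam / 2.0, size2_diam / 2.0
    x1 = r1 if depth1 is None else depth1
    x2 = r2 if depth2 is None else depth2
    hu1 = corrected_hu(mu, DepthQuery(x=x1, r=r1, V=V), calib, params, xsec)
    hu2 = corrected_hu(mu, DepthQuery(x=x2, r=r2, V=V), calib, params, xsec)
    return hu2 - hu1


def predict_delta_hu_depth(
    material: str,
    kvp: float,
    x1: float,
    x2: float,
    body_diam: float,
    calib: ScannerCalibration,
    params: BeamModelParams,
    xsec: CrossSectionTable,
    materials: MaterialTable,
) -> float:
    """Predicted CT-number change between two depths within one body.

    The body radius (hence the denominator correction) is held fixed at
    ``body_diam / 2``; only the numerator correction moves with depth.
    """
    if body_diam <= 0:
        raise ValueError("body diameter must be > 0")
    for x in (x1, x2):
        if not (0.0 <= x <= body_diam):
            raise ValueError(f"depth {x:g} cm outside the body (diameter {body_diam:g} cm)")
    materials._require(material)
    V = effective_energy(kvp, calib)
    mu = materials.mu(material, V, xsec)
    R = body_diam / 2.0
    hu1 = corrected_hu(mu, DepthQuery(x=x1, r=R, V=V), calib, params, xsec)
    hu2 = corrected_hu(mu, DepthQuery(x=x2, r=R, V=V), calib, params, xsec)
    return hu2 - hu1
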