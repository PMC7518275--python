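"""Bulk-water beam intensity model and the quantities derived from it.

The in-phantom X-ray intensity at depth x (cm) for an effective energy V
(keV) is modelled as

    I(x, V) = B * V**(eps*x + beta) * exp(-tau_b * x)

where the exponent ``eps = alpha + sigma_h`` combines body-size and depth
hardening and ``tau_b`` is the intensity attenuation constant.  Inserting
this closed form into the one-dimensional photon transport balance, with the
Rayleigh kernel approximated by the power law ``A * V**b``, yields a depth-
and energy-dependent effective attenuation of bulk water

    mu_eff(x, V) = tau_b - eps*ln(V) + f(x, V),
    f(x, V)      = A * V**(b+1) / (eps*x + beta + b + 1),

the "size factor" f being the Rayleigh gain term.  Shifting f by the
Rayleigh mean free path x0(V) and differencing gives the HU correction
factor f_c(x, V) = f(x0) - f(x0 + x), which vanishes at the surface and
saturates at f(x0) deep in the body.

The denominator constant is always computed as ``beta + b + 1`` (1.144 for
the default beta = 2, b = -1.856): the transport-balance algebra requires
this link, so refitted (A, b, beta) stay mutually consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BeamModelParams",
    "DepthQuery",
    "CorrectionResult",
    "intensity",
    "effective_attenuation",
    "size_factor",
    "transport_residual",
    "shifted_size_factor",
    "correction_factor",
    "correction_result",
    "fit_beam_params",
]

# Generic hardening exponents of the intensity model: alpha for body size,
# sigma_h for depth from the entrance surface.
DEFAULT_ALPHA = 0.034
DEFAULT_SIGMA_H = 0.023


@dataclass(frozen=True)
class BeamModelParams:
    """Constants of the intensity model and the Rayleigh power law.

    ``epsilon`` defaults to ``alpha + sigma_h`` (0.057); a scanner-specific
    override (e.g. 0.045 for the modelled Siemens system) may be supplied.
    ``A`` and ``b`` are the Rayleigh power-law amplitude and exponent; the
    denominator constant of the size factor is ``beta + b + 1`` and must be
    positive.
    """

    B: float = 1.0
    alpha: float = DEFAULT_ALPHA
    sigma_h: float = DEFAULT_SIGMA_H
    beta: float = 2.0
    epsilon: float | None = None
    tau_b: float = 0.5302
    A: float = 27.696
    b: float = -1.856

    def __post_init__(self) -> None:
        if self.epsilon is None:
            object.__setattr__(self, "epsilon", self.alpha + self.sigma_h)
        if self.B <= 0:
            raise ValueError("B must be > 0")
        if self.tau_b <= 0:
            raise ValueError("tau_b must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.denom_const <= 0:
            raise ValueError(
                f"beta + b + 1 = {self.denom_const:g} must be > 0 for the size-factor denominator"
            )

    @property
    def denom_const(self) -> float:
        """The constant beta + b + 1 (1.144 with defaults)."""
        return self.beta + self.b + 1.0

    def with_epsilon(self, epsilon: float) -> "BeamModelParams":
        return replace(self, epsilon=epsilon)


@dataclass(frozen=True)
class DepthQuery:
    """One (depth, body radius, effective energy) evaluation point.

    ``x`` is the depth from the entrance surface in cm; ``r = d/2`` the body
    radius in cm; ``V`` the effective photon energy in keV (not the kVp).
    """

    x: float
    r: float
    V: float

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError("depth x must be >= 0")
        if self.r < 0:
            raise ValueError("body radius r must be >= 0")
        if self.V <= 0:
            raise ValueError("effective energy V must be > 0")


@dataclass(frozen=True)
class CorrectionResult:
    """All correction-model quantities for one query: f, f_x, f_c, x0, mu_eff."""

    f: float
    f_x: float
    f_c: float
    x0: float
    mu_eff: float


def _check_xv(x: float, v: float) -> None:
    if x < 0:
        raise ValueError("depth x must be >= 0")
    if v <= 0:
        raise ValueError("energy V must be > 0")


def intensity(x: float, V: float, params: BeamModelParams) -> float:
    """In-phantom intensity I(x, V) = B * V**(eps*x + beta) * exp(-tau_b * x)."""
    _check_xv(x, V)
    return params.B * V ** (params.epsilon * x + params.beta) * math.exp(-params.tau_b * x)


def _denominator(x: float, params: BeamModelParams) -> float:
    d = params.epsilon * x + params.denom_const
    if d <= 0:
        raise ValueError(f"size-factor denominator eps*x + (beta+b+1) = {d:g} must be > 0")
    return d


def size_factor(q: DepthQuery, params: BeamModelParams) -> float:
    """Size factor f(x, V) = A * V**(b+1) / (eps*x + beta + b + 1).

    Strictly positive and strictly decreasing in both depth and energy
    (for V > 0 and the default b < -1).
    """
    return params.A * q.V ** (params.b + 1.0) / _denominator(q.x, params)


def effective_attenuation(q: DepthQuery, params: BeamModelParams) -> float:
    """Effective attenuation of bulk water, mu_eff = tau_b - eps*ln(V) + f(x, V) (1/cm)."""
    return params.tau_b - params.epsilon * math.log(q.V) + size_factor(q, params)


def transport_residual(q: DepthQuery, params: BeamModelParams) -> float:
    """Self-consistency diagnostic of the transport balance.

    The closed-form intensity satisfies
    ``(eps*ln V - tau_b) I = -mu_eff I + f I``; this returns
    ``(eps*ln V - tau_b) + mu_eff - f``, identically zero up to rounding.
    """
    return (
        params.epsilon * math.log(q.V)
        - params.tau_b
        + effective_attenuation(q, params)
        - size_factor(q, params)
    )


def shifted_size_factor(q: DepthQuery, params: BeamModelParams, x0: float) -> float:
    """Mean-free-path-shifted factor f_x(x, V) = f(x0 + x, V)."""
    if x0 < 0:
        raise ValueError("mean free path x0 must be >= 0")
    return size_factor(DepthQuery(x=q.x + x0, r=q.r, V=q.V), params)


def correction_factor(q: DepthQuery, params: BeamModelParams, x0: float) -> float:
    """HU correction factor f_c(x, V) = f(x0, V) - f(x0 + x, V) >= 0.

    Zero at the surface (x = 0), strictly increasing in depth, bounded above
    by f(x0, V).
    """
    if x0 < 0:
        raise ValueError("mean free path x0 must be >= 0")
    at_x0 = size_factor(DepthQuery(x=x0, r=q.r, V=q.V), params)
    return at_x0 - shifted_size_factor(q, params, x0)


def correction_result(q: DepthQuery, params: BeamModelParams, x0: float) -> CorrectionResult:
    """Bundle f, f_x, f_c, x0 and mu_eff for one query."""
    return CorrectionResult(
        f=size_factor(q, params),
        f_x=shifted_size_factor(q, params, x0),
        f_c=correction_factor(q, params, x0),
        x0=x0,
        mu_eff=effective_attenuation(q, params),
    )


def fit_beam_params(
    profiles: Iterable[Sequence[float]],
    *,
    template: BeamModelParams | None = None,
) -> BeamModelParams:
    """Recover (B, beta, eps, tau_b) from measured intensity profiles.

    ``profiles`` iterates over (x, V, intensity) triples.  The model is
    linear in log space,

        ln I = ln B + beta*ln V + eps*(x*ln V) - tau_b*x,

    and is solved by ordinary least squares.  At least six points spanning
    two or more distinct depths and two or more distinct energies are
    required; a single-depth or single-energy design cannot separate eps
    from tau_b (or beta) and is rejected.  The Rayleigh constants (A, b) are
    carried over from ``template`` (or defaults) untouched.
    """
    data = np.asarray(list(profiles), dtype=float)
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValueError("profiles must be (x, V, intensity) triples")
    x, v, i = data.T
    if data.shape[0] < 6:
        raise ValueError(f"{data.shape[0]} profile points given; >= 6 required")
    if np.any(i <= 0):
        raise ValueError("intensities must be > 0")
    if np.any(x < 0) or np.any(v <= 0):
        raise ValueError("depths must be >= 0 and energies > 0")
    if np.unique(x).size < 2 or np.unique(v).size < 2:
        raise ValueError("cannot identify eps and tau_b: need >= 2 distinct depths and >= 2 distinct energies")
    logv = np.log(v)
    design = np.column_stack([np.ones_like(x), logv, x * logv, -x])
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("cannot identify eps and tau_b: rank-deficient profile design")
    coef, *_ = np.linalg.lstsq(design, np.log(i), rcond=None)
    log_b, beta, eps, tau_b = (float(c) for c in coef)
    base = template if template is not None else BeamModelParams()
    return replace(base, B=math.exp(log_b), beta=beta, epsilon=eps, tau_b=tau_b)
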