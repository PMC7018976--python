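"""Energy densities of the augmented Helfrich model and derived scalars.

The membrane free energy per unit area is

    W = κ(s) [H − C(σ)]² + κ_G(s) K  −  α σ²  +  β (σ′)²   (+ entropic term)

with the protein-induced spontaneous curvature C(σ) = μ φ σ.  The
entropic contribution k_BT σ (log(σ/σ_s) − 1) is negligible in the dilute
regime (k_BT σ ≪ 1) and is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "EnergyBreakdown",
    "spontaneous_curvature",
    "protein_energy_density",
    "bending_energy_density",
    "entropic_energy_density",
    "total_energy",
    "induced_length_scales",
]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Surface-integrated energy components [pN·nm]."""

    bending: float
    gaussian: float
    aggregation: float
    gradient: float
    entropic: float = 0.0

    @property
    def total(self) -> float:
        return self.bending + self.gaussian + self.aggregation + self.gradient + self.entropic


def spontaneous_curvature(sigma, params: ModelParameters):
    """Protein-induced spontaneous curvature C = μ φ σ [nm⁻¹].

    Linear in the protein density; negative wherever σ > 0 for
    cone-shaped proteins (φ < 0).
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("protein density sigma must be non-negative")
    out = params.mu * params.phi * sigma
    return float(out) if out.ndim == 0 else out


def entropic_energy_density(sigma, params: ModelParameters):
    """k_BT σ (log(σ/σ_s) − 1) [pN/nm], with the σ→0 limit taken as 0."""
    sigma = np.asarray(sigma, dtype=float)
    out = np.zeros_like(sigma)
    pos = sigma > 0
    out[pos] = params.kBT * sigma[pos] * (np.log(sigma[pos] / params.sigma_s) - 1.0)
    return float(out) if out.ndim == 0 else out


def protein_energy_density(sigma, dsigma_ds, params: ModelParameters):
    """Protein contribution −α σ² + β (σ′)² [pN/nm].

    The entropic term is added only when ``params.include_entropy`` is
    set; it is evaluated as 0 at σ = 0 (the σ log σ limit).
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("protein density sigma must be non-negative")
    dsigma_ds = np.asarray(dsigma_ds, dtype=float)
    out = -params.alpha * sigma**2 + params.beta * dsigma_ds**2
    if params.include_entropy:
        out = out + entropic_energy_density(sigma, params)
    return float(out) if np.ndim(out) == 0 else out


def bending_energy_density(H, K, sigma, kappa_local, kappaG_local, params: ModelParameters):
    """Heterogeneous Helfrich density κ(s)[H − C(σ)]² + κ_G(s) K [pN/nm]."""
    kappa_local = np.asarray(kappa_local, dtype=float)
    if np.any(kappa_local <= 0):
        raise ValueError("kappa_local must be positive")
    C = spontaneous_curvature(sigma, params)
    out = kappa_local * (np.asarray(H, dtype=float) - C) ** 2 + np.asarray(
        kappaG_local, dtype=float
    ) * np.asarray(K, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


def total_energy(shape, fields, params: ModelParameters) -> EnergyBreakdown:
    """Integrate the energy densities over the surface of revolution.

    Each component is ∫ density · 2πr ds along the full tube, evaluated
    on the shape's arclength mesh with the trapezoidal rule; the fields
    are evaluated at the mesh positions through their analytic forms.

    Parameters
    ----------
    shape : MembraneShape
        A solved (or candidate) configuration providing ``s``, ``r``,
        ``H`` and ``K`` arrays.
    fields : ProfileSet
        Heterogeneity fields; must cover the shape's arclength span.
    """
    from scipy.integrate import trapezoid

    s = np.asarray(shape.s, dtype=float)
    # material coordinate on which the heterogeneity fields live
    m = np.asarray(getattr(shape, "m", s), dtype=float)
    # the field grid must cover the central material region of the shape
    # (tanh fields extend analytically past the grid ends, so margins at
    # the boundaries are fine; a disjoint or far smaller grid is not)
    mid = 0.5 * (m[0] + m[-1])
    half = 0.25 * (m[-1] - m[0])
    if fields.s_grid[0] > mid - half or fields.s_grid[-1] < mid + half:
        raise ValueError(
            f"field grid [{fields.s_grid[0]}, {fields.s_grid[-1]}] does not "
            f"overlap the shape's central material span "
            f"[{mid - half}, {mid + half}]"
        )
    r = np.asarray(shape.r, dtype=float)
    area_w = 2.0 * np.pi * r
    sigma = fields.sigma_fn(m)
    dsigma = fields.sigma_fn(m, 1) * r / params.Rc  # dσ/ds on the surface
    kappa = fields.kappa_fn(m)
    kappaG = fields.kappaG_fn(m)
    C = spontaneous_curvature(sigma, params)
    H = np.asarray(shape.H, dtype=float)
    K = np.asarray(shape.K, dtype=float)

    bending = trapezoid(kappa * (H - C) ** 2 * area_w, s)
    gaussian = trapezoid(kappaG * K * area_w, s)
    aggregation = trapezoid(-params.alpha * sigma**2 * area_w, s)
    gradient = trapezoid(params.beta * dsigma**2 * area_w, s)
    entropic = 0.0
    if params.include_entropy:
        entropic = trapezoid(entropic_energy_density(sigma, params) * area_w, s)
    return EnergyBreakdown(
        bending=float(bending),
        gaussian=float(gaussian),
        aggregation=float(aggregation),
        gradient=float(gradient),
        entropic=float(entropic),
    )


def induced_length_scales(
    sigma0: float,
    lambda_val: float,
    kappa_protein: float,
    params: ModelParameters,
) -> tuple[float, float, float]:
    """The two induced length scales and their log ratio.

    Returns ``(l_sigma, l_kappa, log_ratio)`` where

    * ``l_kappa = (1/2) sqrt(kappa_protein / lambda)`` is the tube
      length scale set by the rigid domain (the equilibrium tube radius
      at rigidity κ_protein),
    * ``l_sigma = 1 / |μ φ σ₀|`` is the curvature length scale induced
      by protein aggregation (absolute value: a length is positive even
      though C = μφσ < 0 for cone-shaped proteins),
    * ``log_ratio = log10(l_sigma / l_kappa)``.

    For σ₀ = 0, ``l_sigma`` and ``log_ratio`` are +inf (flagged, not an
    error): the protein length scale is absent.
    """
    if lambda_val <= 0:
        raise ValueError("lambda_val must be positive")
    if kappa_protein <= 0:
        raise ValueError("kappa_protein must be positive")
    if sigma0 < 0:
        raise ValueError("sigma0 must be non-negative")
    l_kappa = 0.5 * math.sqrt(kappa_protein / lambda_val)
    c = abs(params.mu * params.phi * sigma0)
    if c == 0.0:
        return math.inf, l_kappa, math.inf
    l_sigma = 1.0 / c
    return l_sigma, l_kappa, math.log10(l_sigma / l_kappa)
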