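"""Closed-form limit results for beads on a heterogeneous nanotube.

These expressions follow from matching the local free-energy density in
the protein-enriched domain to the bare-tube value W₀ = κ H₀²
(H₀ = 1/(2 R_c)), treating the bead as locally cylindrical.  They are
quantitative only for small deformations (r_b ≲ 200 nm) and serve as
independent oracles for the boundary-value-problem solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import ModelParameters

__all__ = [
    "AnalyticInput",
    "mean_curvature_center",
    "mean_curvature_center_linearized",
    "bead_radius_analytic",
    "bead_radius_linearized",
    "equilibrium_tube_radius",
]


@dataclass(frozen=True)
class AnalyticInput:
    """Inputs to the analytic bead formulas.

    ``grad_sigma`` is a representative protein-density gradient; the
    default 0 corresponds to the domain center, where the gradient
    vanishes by symmetry.
    """

    sigma: float
    params: ModelParameters
    kappa_ratio: float = 1.0
    grad_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa_ratio <= 0:
            raise ValueError("kappa_ratio must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def mean_curvature_center(inp: AnalyticInput) -> float:
    """Mean curvature at the center of the heterogeneous domain [nm⁻¹].

    H = μφσ + sqrt[ (1/(2R_c)² + ασ²/κ − β(∇σ)²/κ) / κ_ratio ].
    """
    p = inp.params
    radicand = (
        1.0 / (2.0 * p.Rc) ** 2
        + p.alpha * inp.sigma**2 / p.kappa
        - p.beta * inp.grad_sigma**2 / p.kappa
    ) / inp.kappa_ratio
    if radicand < 0:
        raise ValueError(
            "negative radicand: the gradient-penalty term β(∇σ)²/κ exceeds "
            "the curvature and aggregation terms; the analytic limit does "
            "not apply"
        )
    return p.mu * p.phi * inp.sigma + math.sqrt(radicand)


def mean_curvature_center_linearized(inp: AnalyticInput) -> float:
    """First-order (low-σ) expansion of :func:`mean_curvature_center`.

    H = μφσ + (1/√κ_ratio) [ 1/(2R_c) + (R_c/κ)(ασ² − β(∇σ)²) ].
    """
    p = inp.params
    return p.mu * p.phi * inp.sigma + (
        1.0 / (2.0 * p.Rc)
        + (p.Rc / p.kappa) * (p.alpha * inp.sigma**2 - p.beta * inp.grad_sigma**2)
    ) / math.sqrt(inp.kappa_ratio)


def bead_radius_analytic(inp: AnalyticInput) -> float:
    """Bead radius r_b = 1/(2 H) from the cylindrical-bead approximation [nm].

    Valid only while the analytic mean curvature is positive; at high
    protein density / rigidity ratio the predicted curvature changes
    sign and the cylindrical approximation breaks down.
    """
    H = mean_curvature_center(inp)
    if H <= 0:
        raise ValueError(
            f"analytic mean curvature is non-positive (H = {H:.4g} nm^-1): "
            "outside the validity regime of the cylindrical-bead "
            "approximation (the regime where the analytic curvature changes "
            "sign at large sigma and kappa_ratio)"
        )
    return 1.0 / (2.0 * H)


def bead_radius_linearized(inp: AnalyticInput) -> float:
    """Low-density expansion of the bead radius [nm].

    r_b = √κ_ratio R_c [ 1 − 2 R_c √κ_ratio μφσ − (2R_c²/κ)(ασ² − β(∇σ)²) ].
    """
    p = inp.params
    rk = math.sqrt(inp.kappa_ratio)
    return (
        rk
        * p.Rc
        * (
            1.0
            - 2.0 * p.Rc * rk * (p.mu * p.phi * inp.sigma)
            - (2.0 * p.Rc**2 / p.kappa)
            * (p.alpha * inp.sigma**2 - p.beta * inp.grad_sigma**2)
        )
    )


def equilibrium_tube_radius(kappa_val: float, lambda_val: float) -> float:
    """Radius of the uniform equilibrium cylinder, R = (1/2)√(κ/λ) [nm].

    This is the homogeneous, zero-pressure, protein-free specialization
    of the axisymmetric shape equation: a cylinder of radius R is an
    equilibrium iff λ = κ/(4R²).
    """
    if lambda_val <= 0:
        raise ValueError("lambda_val must be positive (λ = 0 gives an unbounded radius)")
    if kappa_val <= 0:
        raise ValueError("kappa_val must be positive")
    return 0.5 * math.sqrt(kappa_val / lambda_val)
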