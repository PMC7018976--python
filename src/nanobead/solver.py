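"""Axisymmetric equilibrium solver for heterogeneous membrane nanotubes.

The normal (shape) and tangential (tension) force balances of the
augmented Helfrich model reduce, on a surface of revolution
parameterized by deformed arclength s, to the first-order system

    r' = cos ψ
    z' = sin ψ
    ψ' = 2H − sin ψ / r
    H' = (L/r − κ'(H − C)) / κ + C'
    L' = r [ p + 2ΛH + 2κH(H − C)² − 2κ(H − C)(2H² − K) − G ]
    Λ' = 2κ(H − C)C' − κ'(H − C)² − κ_G' K
    m' = r / R_c

where C = μφσ is the protein-induced spontaneous curvature,
K = ψ' sinψ/r the Gaussian curvature, L = r d/ds[κ(H − C)] an auxiliary
moment flux, G = (1/r) d/ds[κ_G' sinψ] the heterogeneous-Gaussian-modulus
source, and Λ = λ − ασ² + β(σ')² the *net* membrane tension (λ is the
bare area-incompressibility Lagrange multiplier, recovered
algebraically).  A consequence of this exact reduction is that the
aggregation strength α and gradient penalty β do not influence
equilibrium shapes when the protein density vanishes at the boundary —
they shift only the tension field and the energy bookkeeping.

The heterogeneity fields are material fields of the areally
incompressible membrane: they are prescribed on the reference arclength
m of the undeformed tube (the last equation maps local membrane area
2πr ds onto reference area 2πR_c dm), anchored so that the material
midpoint sits at the tube midpoint.  On the undeformed cylinder m ≡ s.
All primed field quantities above (C', κ', κ_G') are derivatives along
the deformed arclength, obtained from the analytic reference-coordinate
derivatives by the chain rule dm/ds = r/R_c.

Internally the system is nondimensionalized (lengths by R_c, tensions by
κ/R_c², moment flux by κ/R_c) and solved with a fourth-order collocation
method (``scipy.integrate.solve_bvp``) under six mechanical boundary
conditions plus the material anchor; for mirror-symmetric inputs only
half of the tube is solved, with symmetry conditions
(z = 0, ψ = π/2, L = 0) at the midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_bvp

from .energy import EnergyBreakdown, total_energy
from .parameters import ModelParameters
from .profiles import ProfileSet

__all__ = [
    "SolverConfig",
    "MembraneShape",
    "ContinuationBranch",
    "ConvergenceError",
    "ode_rhs",
    "boundary_residuals",
    "solve_shape",
    "continuation",
    "verify_stationarity",
]

_RMIN = 1e-8  # dimensionless guard against r -> 0 during iterations


class ConvergenceError(RuntimeError):
    """Raised when the collocation solver fails to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings for the boundary-value solve.

    ``symmetry_mode``: "full" solves the whole tube, "half" solves
    [L_c/2, L_c] with symmetry conditions at the midpoint (valid only
    for mirror-symmetric profiles), "auto" picks "half" when the
    profiles are symmetric.
    """

    mesh_size: int = 601
    tolerance: float = 1e-6
    max_nodes: int = 60000
    max_continuation_step: float = math.inf
    step_halving_limit: int = 4
    symmetry_mode: str = "auto"
    clamp_edge_radius: bool = True

    def __post_init__(self) -> None:
        if self.mesh_size < 200:
            raise ValueError("mesh_size must be >= 200")
        if self.tolerance > 1e-6:
            raise ValueError("tolerance must be <= 1e-6")
        if self.symmetry_mode not in {"auto", "full", "half"}:
            raise ValueError(f"unknown symmetry_mode {self.symmetry_mode!r}")


@dataclass
class MembraneShape:
    """A solved equilibrium configuration in physical units.

    ``lam`` is the net membrane tension Λ(s) [pN/nm] (the mechanically
    measured tension entering the normal force balance); the bare
    area-incompressibility Lagrange multiplier is
    ``lagrange_tension = Λ + ασ² − β(σ')²``.  ``m`` is the material
    (reference-arclength) coordinate on which the heterogeneity fields
    live.
    """

    s: np.ndarray        # deformed arclength [nm]
    r: np.ndarray        # radius [nm]
    z: np.ndarray        # axial coordinate [nm]
    psi: np.ndarray      # tangent angle [rad]
    H: np.ndarray        # mean curvature [nm^-1]
    flux: np.ndarray     # moment flux r d/ds[kappa (H - C)] [pN]
    lam: np.ndarray      # net tension Lambda [pN/nm]
    m: np.ndarray        # material (reference) coordinate [nm]
    sigma: np.ndarray    # protein density [nm^-2]
    params: ModelParameters
    fields: ProfileSet
    residual: float = 0.0
    symmetry_mode: str = "full"
    _x: np.ndarray | None = field(default=None, repr=False)   # dimensionless mesh
    _y: np.ndarray | None = field(default=None, repr=False)   # dimensionless states
    _sol: object | None = field(default=None, repr=False)     # dense interpolant

    @property
    def K(self) -> np.ndarray:
        """Gaussian curvature ψ' sinψ / r [nm⁻²]."""
        sphi = np.sin(self.psi) / self.r
        return (2.0 * self.H - sphi) * sphi

    @property
    def dsigma_ds(self) -> np.ndarray:
        """dσ/ds along the deformed meridian [nm⁻³] (chain rule via m)."""
        return self.fields.sigma_fn(self.m, 1) * self.r / self.params.Rc

    @property
    def lagrange_tension(self) -> np.ndarray:
        """Bare Lagrange multiplier λ = Λ + ασ² − β(σ')² [pN/nm]."""
        p = self.params
        return self.lam + p.alpha * self.sigma**2 - p.beta * self.dsigma_ds**2

    @property
    def r_max(self) -> float:
        return float(np.max(self.r))

    def resample(self, n: int) -> "MembraneShape":
        """Evaluate the collocation interpolant on a uniform n-point mesh."""
        if self._sol is None:
            raise ValueError("shape carries no dense interpolant")
        x = np.linspace(self._x[0], self._x[-1], n)
        y = self._sol(x)
        return _shape_from_dimless(x, y, self.params, self.fields, self.residual,
                                   self.symmetry_mode, sol=self._sol)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "s_nm": self.s,
                "r_nm": self.r,
                "z_nm": self.z,
                "psi_rad": self.psi,
                "H_per_nm": self.H,
                "K_per_nm2": self.K,
                "lambda_pN_per_nm": self.lam,
                "sigma_nm2": self.sigma,
                "m_nm": self.m,
            }
        ).to_csv(path, index=False)

    def summary(self) -> dict:
        energies = total_energy(self, self.fields, self.params)
        return {
            "r_max_nm": self.r_max,
            "residual": self.residual,
            "symmetry_mode": self.symmetry_mode,
            "energy_pNnm": {
                "bending": energies.bending,
                "gaussian": energies.gaussian,
                "aggregation": energies.aggregation,
                "gradient": energies.gradient,
                "entropic": energies.entropic,
                "total": energies.total,
            },
            "parameters": self.params.to_dict(),
        }


@dataclass
class ContinuationBranch:
    """Family of equilibria along a swept parameter."""

    parameter: str
    values: list[float]
    shapes: list[MembraneShape]
    energies: list[EnergyBreakdown]
    converged: list[bool]
    direction: str = "forward"
    requested_values: list[float] = field(default_factory=list)
    failures: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.values)
        if not (len(self.shapes) == len(self.energies) == len(self.converged) == n):
            raise ValueError("branch columns must have equal length")

    @property
    def r_b(self) -> np.ndarray:
        return np.array([sh.r_max for sh in self.shapes])

    @property
    def totals(self) -> np.ndarray:
        return np.array([e.total for e in self.energies])

    def shape_jumps(self) -> np.ndarray:
        """RMS radius change between consecutive states (arclength-normalized)."""
        u = np.linspace(0.0, 1.0, 512)
        rs = [
            np.interp(u, (sh.s - sh.s[0]) / (sh.s[-1] - sh.s[0]), sh.r)
            for sh in self.shapes
        ]
        return np.array(
            [np.sqrt(np.mean((a - b) ** 2)) for a, b in zip(rs[:-1], rs[1:])]
        )

    @property
    def discontinuities(self) -> list[int]:
        """Indices i where the shape jump (i-1 -> i) exceeds 10x the median."""
        if len(self.shapes) < 3:
            return []
        jumps = self.shape_jumps()
        med = float(np.median(jumps))
        if med == 0.0:
            return [i + 1 for i, j in enumerate(jumps) if j > 0]
        return [i + 1 for i, j in enumerate(jumps) if j > 10.0 * med]


# ---------------------------------------------------------------------------
# dimensionless field evaluation (material coordinate, physical nm)
# ---------------------------------------------------------------------------


class _DimlessFields:
    """Heterogeneity fields vs material coordinate, in solver units."""

    def __init__(self, fields: ProfileSet, params: ModelParameters):
        self.fields = fields
        self.p = params

    def __call__(self, m_phys: np.ndarray) -> dict[str, np.ndarray]:
        """Evaluate at material positions [nm]; derivatives are d/dm̃ with
        m̃ = m/R_c, i.e. chain-rule factors r̃ are applied by the caller."""
        p = self.p
        f = self.fields
        mufi = p.mu * p.phi
        return {
            "C": mufi * f.sigma_fn(m_phys) * p.Rc,
            "dC": mufi * f.sigma_fn(m_phys, 1) * p.Rc**2,
            "kap": f.kappa_fn(m_phys) / p.kappa,
            "dkap": f.kappa_fn(m_phys, 1) * p.Rc / p.kappa,
            "dkG": f.kappaG_fn(m_phys, 1) * p.Rc / p.kappa,
            "d2kG": f.kappaG_fn(m_phys, 2) * p.Rc**2 / p.kappa,
        }


def _rhs_dimless(x, y, fl: _DimlessFields, p_dimless: float, Rc: float):
    """Vectorized dimensionless right-hand side; y has shape (7, m)."""
    r = np.maximum(y[0], _RMIN)
    psi, H, L, tau, mcoord = y[2], y[3], y[4], y[5], y[6]
    f = fl(mcoord * Rc)
    kap, dkap_m = f["kap"], f["dkap"]
    # chain rule: d/ds̃ = r̃ d/dm̃ for material fields
    C = f["C"]
    dC = f["dC"] * r
    dkap = dkap_m * r
    dkG = f["dkG"] * r
    sphi = np.sin(psi) / r
    cpsi = np.cos(psi)
    dpsi = 2.0 * H - sphi
    K = dpsi * sphi
    Hc = H - C
    # d/ds̃ [dκ_G/ds̃] = κ_G'' r̃² + κ_G' cosψ   (primes: d/dm̃)
    ddkG = f["d2kG"] * r**2 + f["dkG"] * cpsi
    G = (ddkG * np.sin(psi) + dkG * cpsi * dpsi) / r
    dH = (L / r - dkap * Hc) / kap + dC
    dL = r * (
        p_dimless
        + 2.0 * tau * H
        + 2.0 * kap * H * Hc**2
        - 2.0 * kap * Hc * (2.0 * H**2 - K)
        - G
    )
    dtau = 2.0 * kap * Hc * dC - dkap * Hc**2 - dkG * K
    return np.vstack([cpsi, np.sin(psi), dpsi, dH, dL, dtau, r])


# ---------------------------------------------------------------------------
# public ODE / BC views (physical units, full Lagrange-multiplier convention)
# ---------------------------------------------------------------------------


def ode_rhs(state, s, fields: ProfileSet, params: ModelParameters):
    """Physical-units right-hand side of the first-order system.

    ``state`` is ``(r, z, psi, H, flux, lam)`` — optionally with a 7th
    component, the material coordinate m at which the heterogeneity
    fields are evaluated (m = s when omitted, exact on the undeformed
    tube) — and ``lam`` the bare Lagrange multiplier λ.  Returns the
    arclength derivatives; the tension equation uses the variational
    (dimensionally consistent) tangential balance
    λ' = 2[κμφ(H−C) + ασ]σ' − 2βσ'σ'' − κ'(H−C)² − κ_G' K.
    """
    state = [np.asarray(v, dtype=float) for v in state]
    r, z, psi, H, flux, lam = state[:6]
    mcoord = state[6] if len(state) > 6 else np.asarray(s, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive along the membrane (pinch-off)")
    p = params
    stretch = r / p.Rc  # dm/ds
    sig = fields.sigma_fn(mcoord)
    dsig = fields.sigma_fn(mcoord, 1) * stretch
    # σ'' along s: chain rule on σ'(m)·(r/Rc)
    d2sig = (
        fields.sigma_fn(mcoord, 2) * stretch**2
        + fields.sigma_fn(mcoord, 1) * np.cos(psi) / p.Rc
    )
    kap = fields.kappa_fn(mcoord)
    dkap = fields.kappa_fn(mcoord, 1) * stretch
    dkG = fields.kappaG_fn(mcoord, 1) * stretch
    ddkG = (
        fields.kappaG_fn(mcoord, 2) * stretch**2
        + fields.kappaG_fn(mcoord, 1) * np.cos(psi) / p.Rc
    )
    C = p.mu * p.phi * sig
    dC = p.mu * p.phi * dsig
    sphi = np.sin(psi) / r
    dpsi = 2.0 * H - sphi
    K = dpsi * sphi
    Hc = H - C
    G = (ddkG * np.sin(psi) + dkG * np.cos(psi) * dpsi) / r
    dH = (flux / r - dkap * Hc) / kap + dC
    dflux = r * (
        p.p
        + 2.0 * lam * H
        + 2.0 * kap * H * Hc**2
        - 2.0 * kap * Hc * (2.0 * H**2 - K)
        - 2.0 * H * p.alpha * sig**2
        + 2.0 * H * p.beta * dsig**2
        - G
    )
    dlam = (
        2.0 * (kap * p.mu * p.phi * Hc + p.alpha * sig) * dsig
        - 2.0 * p.beta * dsig * d2sig
        - dkap * Hc**2
        - dkG * K
    )
    return np.cos(psi), np.sin(psi), dpsi, dH, dflux, dlam


def boundary_residuals(left_state, right_state, params: ModelParameters,
                       mode: str = "full"):
    """Six mechanical boundary-condition residuals in physical units.

    full-domain: r(0)=R_c, ψ(0)=π/2, z(0)=0 and r(S)=R_c, ψ(S)=π/2,
    λ(S)=λ₀.  half-domain (midpoint on the left): z=0, ψ=π/2, flux=0 at
    the midpoint and the same edge conditions on the right.
    """
    rl, zl, psil = left_state[0], left_state[1], left_state[2]
    fluxl = left_state[4]
    rr, psir, lamr = right_state[0], right_state[2], right_state[5]
    p = params
    if mode == "full":
        return np.array([
            rl - p.Rc, psil - np.pi / 2.0, zl,
            rr - p.Rc, psir - np.pi / 2.0, lamr - p.lambda0,
        ])
    if mode == "half":
        return np.array([
            zl, psil - np.pi / 2.0, fluxl,
            rr - p.Rc, psir - np.pi / 2.0, lamr - p.lambda0,
        ])
    raise ValueError(f"unknown boundary mode {mode!r}")


# ---------------------------------------------------------------------------
# BVP solve
# ---------------------------------------------------------------------------


def _equidistributed_mesh(x: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """Coarsen an adapted mesh to n points, equidistributing solution variation.

    The collocation solver refines but never coarsens; fed forward
    naively during continuation, meshes snowball.  This rebuilds a mesh
    whose density follows the local variation of (r, ψ, H).
    """
    w = np.zeros(x.size - 1)
    dx = np.diff(x)
    for k, scale in ((0, 1.0), (2, 1.0), (3, 1.0)):
        comp = y[k]
        rng = np.ptp(comp)
        if rng > 0:
            w += np.abs(np.diff(comp)) / rng
    cdf = np.concatenate([[0.0], np.cumsum(w + dx / (x[-1] - x[0]))])
    cdf /= cdf[-1]
    xs = np.interp(np.linspace(0.0, 1.0, n), cdf, x)
    # enforce strict monotonicity
    xs = np.maximum.accumulate(xs)
    keep = np.concatenate([[True], np.diff(xs) > 1e-12])
    xs = xs[keep]
    xs[0], xs[-1] = x[0], x[-1]
    return xs


def _shape_from_dimless(x, y, params, fields, residual, mode, sol=None) -> MembraneShape:
    """Convert a dimensionless half/full solution into a physical shape.

    Half-domain solutions (x spanning [0, L_c/(2R_c)], physically the
    interval [L_c/2, L_c]) are mirrored about the midpoint so that
    callers always receive the full tube.
    """
    p = params
    y = np.asarray(y)
    if mode == "half":
        s_right = p.Lc / 2.0 + x * p.Rc
        r_r, z_r, psi_r, H_r, L_r, tau_r, m_r = y
        z_edge = z_r[-1] * p.Rc
        # mirror: s -> Lc - s; psi -> pi - psi; flux odd; m reflects about Lc/2
        s_full = np.concatenate([p.Lc - s_right[::-1][:-1], s_right])
        r_full = np.concatenate([r_r[::-1][:-1], r_r]) * p.Rc
        z_full = np.concatenate(
            [z_edge - z_r[::-1][:-1] * p.Rc, z_edge + z_r * p.Rc]
        )
        psi_full = np.concatenate([np.pi - psi_r[::-1][:-1], psi_r])
        H_full = np.concatenate([H_r[::-1][:-1], H_r]) / p.Rc
        flux_full = np.concatenate([-L_r[::-1][:-1], L_r]) * p.kappa / p.Rc
        tau_full = np.concatenate([tau_r[::-1][:-1], tau_r]) * p.kappa / p.Rc**2
        m_full = np.concatenate([p.Lc - m_r[::-1][:-1] * p.Rc, m_r * p.Rc])
    else:
        s_full = x * p.Rc
        r_full = y[0] * p.Rc
        z_full = y[1] * p.Rc
        psi_full = y[2]
        H_full = y[3] / p.Rc
        flux_full = y[4] * p.kappa / p.Rc
        tau_full = y[5] * p.kappa / p.Rc**2
        m_full = y[6] * p.Rc
    return MembraneShape(
        s=s_full,
        r=r_full,
        z=z_full,
        psi=psi_full,
        H=H_full,
        flux=flux_full,
        lam=tau_full,
        m=m_full,
        sigma=fields.sigma_fn(m_full),
        params=params,
        fields=fields,
        residual=residual,
        symmetry_mode=mode,
        _x=np.asarray(x),
        _y=y,
        _sol=sol,
    )


def solve_shape(
    fields: ProfileSet,
    params: ModelParameters,
    guess: MembraneShape | None = None,
    config: SolverConfig | None = None,
) -> MembraneShape:
    """Solve the boundary-value problem for the equilibrium tube shape.

    With no ``guess``, the exact homogeneous cylinder seeds the solve;
    strongly heterogeneous inputs should be reached by
    :func:`continuation` from zero amplitude.
    """
    config = config or SolverConfig()
    p = params
    mode = config.symmetry_mode
    if mode == "auto":
        mode = "half" if fields.is_symmetric() else "full"
    if mode == "half" and not fields.is_symmetric():
        raise ValueError("half-domain mode requires mirror-symmetric profiles")

    span = (p.Lc / 2.0 if mode == "half" else p.Lc) / p.Rc
    m_anchor = (p.Lc / 2.0 if mode == "half" else 0.0) / p.Rc
    fl = _DimlessFields(fields, p)
    p_dimless = p.p * p.Rc**3 / p.kappa
    tau_edge = p.lambda0 * p.Rc**2 / p.kappa
    r_edge = 1.0 if config.clamp_edge_radius else (
        0.5 * math.sqrt(float(fields.kappa_fn(np.array([p.Lc]))[0]) / p.lambda0) / p.Rc
    )

    def fun(x, y):
        return _rhs_dimless(x, y, fl, p_dimless, p.Rc)

    span_m = p.Lc / p.Rc
    if mode == "half":
        def bc(ya, yb):
            return np.array([
                ya[1], ya[2] - np.pi / 2.0, ya[4],
                yb[0] - r_edge, yb[2] - np.pi / 2.0, yb[5] - tau_edge,
                ya[6] - m_anchor,
            ])
    else:
        def bc(ya, yb):
            # material field centered on the tube: m(0) + m(S) = L_c
            return np.array([
                ya[0] - r_edge, ya[2] - np.pi / 2.0, ya[1],
                yb[0] - r_edge, yb[2] - np.pi / 2.0, yb[5] - tau_edge,
                ya[6] + yb[6] - span_m,
            ])

    if guess is not None and guess.symmetry_mode == mode and guess._x is not None:
        x0 = np.asarray(guess._x)
        y0 = np.asarray(guess._y)
        if x0.size > 4 * config.mesh_size and guess._sol is not None:
            x0 = _equidistributed_mesh(x0, y0, 4 * config.mesh_size)
            y0 = guess._sol(x0)
    elif guess is not None:
        # re-grid a full/half mismatch through physical interpolation
        x0 = np.linspace(0.0, span, config.mesh_size)
        offset = p.Lc / 2.0 if mode == "half" else 0.0
        s_phys = offset + x0 * p.Rc
        z_off = np.interp(offset, guess.s, guess.z)
        y0 = np.vstack([
            np.interp(s_phys, guess.s, guess.r) / p.Rc,
            (np.interp(s_phys, guess.s, guess.z) - z_off) / p.Rc,
            np.interp(s_phys, guess.s, guess.psi),
            np.interp(s_phys, guess.s, guess.H) * p.Rc,
            np.interp(s_phys, guess.s, guess.flux) * p.Rc / p.kappa,
            np.interp(s_phys, guess.s, guess.lam) * p.Rc**2 / p.kappa,
            np.interp(s_phys, guess.s, guess.m) / p.Rc,
        ])
    else:
        x0 = np.linspace(0.0, span, config.mesh_size)
        y0 = np.vstack([
            np.ones_like(x0),
            x0 - x0[0],
            np.full_like(x0, np.pi / 2.0),
            np.full_like(x0, 0.5),
            np.zeros_like(x0),
            np.full_like(x0, tau_edge),
            m_anchor + (x0 - x0[0]),
        ])

    sol = solve_bvp(fun, bc, x0, y0, tol=config.tolerance, max_nodes=config.max_nodes)
    if sol.status != 0:
        raise ConvergenceError(
            f"BVP solver failed ({sol.message}); max residual "
            f"{float(np.max(sol.rms_residuals)):.3e}",
            residual=float(np.max(sol.rms_residuals)),
        )
    if np.any(sol.y[0] <= 0):
        raise ConvergenceError("solution pinched off (r <= 0)")
    return _shape_from_dimless(
        sol.x, sol.y, params, fields,
        residual=float(np.max(sol.rms_residuals)), mode=mode, sol=sol.sol,
    )


# ---------------------------------------------------------------------------
# continuation
# ---------------------------------------------------------------------------


def continuation(
    values: Sequence[float],
    fields_factory: Callable[[float], ProfileSet],
    params: ModelParameters,
    config: SolverConfig | None = None,
    guess: MembraneShape | None = None,
    parameter: str = "value",
    params_factory: Callable[[float], ModelParameters] | None = None,
) -> ContinuationBranch:
    """Trace a family of equilibria along a parameter path.

    Each solve is seeded with the previous solution; a failed step is
    bisected up to ``config.step_halving_limit`` times.  Step underflow
    truncates the branch (recorded in ``failures``), it does not raise.
    ``params_factory`` optionally maps the swept value to modified model
    parameters (e.g. sweeping the edge tension λ₀).
    """
    config = config or SolverConfig()
    values = list(values)
    direction = "forward"
    if len(values) >= 2 and values[-1] < values[0]:
        direction = "backward"
    out_vals: list[float] = []
    shapes: list[MembraneShape] = []
    energies: list[EnergyBreakdown] = []
    converged: list[bool] = []
    failures: dict = {}
    prev = guess

    def attempt(v_prev, v, depth) -> MembraneShape | None:
        nonlocal prev
        fields = fields_factory(v)
        pp = params_factory(v) if params_factory is not None else params
        try:
            sh = solve_shape(fields, pp, guess=prev, config=config)
        except ConvergenceError as err:
            if depth >= config.step_halving_limit or v_prev is None:
                failures[v] = str(err)
                return None
            mid = 0.5 * (v_prev + v)
            sh_mid = attempt(v_prev, mid, depth + 1)
            if sh_mid is None:
                return None
            return attempt(mid, v, depth + 1)
        prev = sh
        return sh

    v_prev = None
    for v in values:
        sh = attempt(v_prev, v, 0)
        if sh is None:
            break  # step underflow: truncated branch with diagnostic
        pp = params_factory(v) if params_factory is not None else params
        out_vals.append(v)
        shapes.append(sh)
        energies.append(total_energy(sh, sh.fields, pp))
        converged.append(True)
        v_prev = v
    return ContinuationBranch(
        parameter=parameter,
        values=out_vals,
        shapes=shapes,
        energies=energies,
        converged=converged,
        direction=direction,
        requested_values=values,
        failures=failures,
    )


# ---------------------------------------------------------------------------
# stationarity oracle
# ---------------------------------------------------------------------------


def verify_stationarity(
    shape: MembraneShape,
    fields: ProfileSet | None = None,
    params: ModelParameters | None = None,
    *,
    n_bumps: int = 5,
    eps: float = 0.5,
    n_grid: int = 4001,
    rng: np.random.Generator | None = None,
) -> float:
    """First-variation test: is the shape a stationary point of the energy?

    The discretized functional  E = ∫ (W + λ) dA − ∫ λ dA₀  (bending and
    protein energy plus the area-incompressibility term, with the solved
    multiplier λ held fixed and dA₀ the unperturbed area element) is
    evaluated under normal perturbations of amplitude ±ε applied through
    compactly supported Gaussian bumps; the material fields ride with
    the nodes.  Returns the largest |dE/dε| · R_c / E_bend over the
    bumps — below ~1e-4 for converged equilibria and orders of magnitude
    larger for non-equilibrium shapes.  This oracle is independent of
    the ODE right-hand side: it only uses the energy densities and
    discrete differential geometry of the meridian.
    """
    fields = fields if fields is not None else shape.fields
    params = params if params is not None else shape.params
    p = params
    dense = shape.resample(n_grid) if shape._sol is not None else shape
    t = dense.s
    r0, z0, psi0 = dense.r, dense.z, dense.psi
    sig = dense.sigma
    dsig_dm = fields.sigma_fn(dense.m, 1)
    kap = fields.kappa_fn(dense.m)
    kG = fields.kappaG_fn(dense.m)
    C = p.mu * p.phi * sig
    lam_full = np.asarray(dense.lagrange_tension)
    a0 = r0.copy()  # reference area density r·g with g0 = 1 (arclength param)
    dsig_dt = dsig_dm * r0 / p.Rc  # material derivative along the curve

    span = t[-1] - t[0]
    width = max(span / 40.0, 4.0 * p.Rc)
    centers = np.linspace(t[0] + 0.15 * span, t[-1] - 0.15 * span, n_bumps)
    if rng is not None:
        centers = centers + rng.uniform(-0.02 * span, 0.02 * span, size=n_bumps)
    nr, nz = np.sin(psi0), -np.cos(psi0)  # outward normal of the meridian

    def energy(rr, zz):
        dr = np.gradient(rr, t)
        dz = np.gradient(zz, t)
        g = np.hypot(dr, dz)
        psi = np.unwrap(np.arctan2(dz, dr))
        cm = np.gradient(psi, t) / g
        cp = np.sin(psi) / rr
        H = 0.5 * (cm + cp)
        K = cm * cp
        grad_sig = dsig_dt / g
        W = (
            kap * (H - C) ** 2
            + kG * K
            - p.alpha * sig**2
            + p.beta * grad_sig**2
        )
        dA = 2.0 * np.pi * rr * g
        dA0 = 2.0 * np.pi * a0
        return np.trapezoid(W * dA + lam_full * (dA - dA0), t)

    bend_scale = abs(
        np.trapezoid(kap * (dense.H - C) ** 2 * 2.0 * np.pi * r0, t)
    )
    worst = 0.0
    for c in centers:
        bump = np.exp(-((t - c) ** 2) / (2.0 * width**2))
        rp = r0 + eps * bump * nr
        zp = z0 + eps * bump * nz
        rm = r0 - eps * bump * nr
        zm = z0 - eps * bump * nz
        fv = (energy(rp, zp) - energy(rm, zm)) / (2.0 * eps)
        worst = max(worst, abs(fv) * p.Rc / bend_scale)
    return worst
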