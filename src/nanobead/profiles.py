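"""Synthetic heterogeneity fields along the nanotube.

Protein density σ(s), bending rigidity κ(s) and Gaussian modulus κ_G(s)
are prescribed as smooth plateaus built from hyperbolic-tangent
transitions: a domain of extent L centered at c contributes

    g(s) = [tanh((s − (c − L/2))/w) − tanh((s − (c + L/2))/w)] / (2 tanh(L/(2w)))

so that g = 1 exactly at the domain center and g → 0 a few transition
widths w outside the domain.  All fields carry analytic first and second
derivatives, which the equilibrium solver uses directly (finite
differences on the prescribed fields would amplify noise in the tension
equation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "DomainSpec",
    "TanhField",
    "ProfileSet",
    "tanh_profile",
    "single_domain_profiles",
    "two_domain_profiles",
    "DEFAULT_TRANSITION_WIDTH_FACTOR",
]

#: default tanh transition half-width, in units of the tube radius R_c
DEFAULT_TRANSITION_WIDTH_FACTOR = 10.0


@dataclass(frozen=True)
class DomainSpec:
    """One heterogeneous plateau along the tube.

    Attributes
    ----------
    center : float
        Arclength position of the domain midpoint [nm].
    length : float
        Plateau extent (e.g. L_protein or L_rigid) [nm].
    amplitude : float
        Field value on the plateau (σ₀, κ_ratio·κ, (1+Δκ_G)·κ_G,lipid).
    transition_width : float
        Half-width w of the tanh transitions [nm]; must satisfy
        w ≪ length.
    """

    center: float
    length: float
    amplitude: float
    transition_width: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"domain length must be positive, got {self.length}")
        if not 0 < self.transition_width <= self.length / 4:
            raise ValueError(
                f"transition_width must satisfy 0 < w <= length/4 "
                f"(got w={self.transition_width}, length={self.length})"
            )

    @property
    def start(self) -> float:
        return self.center - self.length / 2.0

    @property
    def end(self) -> float:
        return self.center + self.length / 2.0


class TanhField:
    """Sum-of-tanh-plateaus scalar field with analytic derivatives."""

    def __init__(self, baseline: float, domains: Sequence[DomainSpec] = ()):
        self.baseline = float(baseline)
        self.domains = tuple(domains)
        _check_overlaps(self.domains)

    def __call__(self, s, order: int = 0):
        s = np.asarray(s, dtype=float)
        out = np.full_like(s, self.baseline) if order == 0 else np.zeros_like(s)
        for d in self.domains:
            amp = d.amplitude - self.baseline
            if amp == 0.0:
                continue
            w = d.transition_width
            norm = amp / (2.0 * math.tanh(d.length / (2.0 * w)))
            ua = (s - d.start) / w
            ub = (s - d.end) / w
            if order == 0:
                out = out + norm * (np.tanh(ua) - np.tanh(ub))
            elif order == 1:
                out = out + norm / w * (_sech2(ua) - _sech2(ub))
            elif order == 2:
                out = out + norm / w**2 * (
                    -2.0 * np.tanh(ua) * _sech2(ua) + 2.0 * np.tanh(ub) * _sech2(ub)
                )
            else:
                raise ValueError(f"derivative order {order} not supported")
        return out

    def is_uniform(self) -> bool:
        return all(d.amplitude == self.baseline for d in self.domains)


def _sech2(u):
    # overflow-safe sech²: 4 e^{-2|u|} / (1 + e^{-2|u|})²
    e = np.exp(-2.0 * np.abs(u))
    return 4.0 * e / (1.0 + e) ** 2


def _check_overlaps(domains: Sequence[DomainSpec]) -> None:
    ds = sorted(domains, key=lambda d: d.start)
    for a, b in zip(ds[:-1], ds[1:]):
        if b.start < a.end and not math.isclose(a.amplitude, b.amplitude):
            raise ValueError(
                f"overlapping domains with different amplitudes "
                f"({a.amplitude} vs {b.amplitude}): plateau value is ambiguous"
            )


def tanh_profile(
    s_grid: np.ndarray,
    domains: Sequence[DomainSpec],
    baseline: float,
) -> np.ndarray:
    """Sample a tanh-plateau field on ``s_grid``.

    Domains must lie inside the grid span with a margin of at least one
    transition width; overlapping domains must share their amplitude.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.ndim != 1 or s_grid.size < 2 or np.any(np.diff(s_grid) <= 0):
        raise ValueError("s_grid must be strictly increasing with >= 2 samples")
    lo, hi = s_grid[0], s_grid[-1]
    for d in domains:
        if d.start - d.transition_width < lo or d.end + d.transition_width > hi:
            raise ValueError(
                f"domain [{d.start}, {d.end}] (w={d.transition_width}) does not "
                f"fit inside the grid span [{lo}, {hi}] with margin >= w"
            )
    return TanhField(baseline, domains)(s_grid)


@dataclass
class ProfileSet:
    """Sampled heterogeneity fields σ(s), κ(s), κ_G(s) with metadata.

    The sampled arrays are the exportable representation; the attached
    :class:`TanhField` objects provide exact derivatives to the solver.
    """

    s_grid: np.ndarray
    sigma: np.ndarray
    kappa_field: np.ndarray
    kappaG_field: np.ndarray
    domain_meta: list[tuple[float, float, float]] = field(default_factory=list)
    sigma_fn: TanhField | None = None
    kappa_fn: TanhField | None = None
    kappaG_fn: TanhField | None = None

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        if np.any(np.diff(self.s_grid) <= 0):
            raise ValueError("s_grid must be strictly increasing")
        for name in ("sigma", "kappa_field", "kappaG_field"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.s_grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.s_grid.shape}")
            setattr(self, name, arr)
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative everywhere")
        if np.any(self.kappa_field <= 0):
            raise ValueError("kappa_field must be positive everywhere")
        if self.sigma_fn is None:
            self.sigma_fn = _spline_field(self.s_grid, self.sigma)
        if self.kappa_fn is None:
            self.kappa_fn = _spline_field(self.s_grid, self.kappa_field)
        if self.kappaG_fn is None:
            self.kappaG_fn = _spline_field(self.s_grid, self.kappaG_field)

    # -- field evaluation ----------------------------------------------
    @property
    def length(self) -> float:
        return float(self.s_grid[-1] - self.s_grid[0])

    def is_symmetric(self, rtol: float = 1e-8) -> bool:
        """True when all fields are mirror-symmetric about the midpoint."""
        mid = 0.5 * (self.s_grid[0] + self.s_grid[-1])
        for fn in (self.sigma_fn, self.kappa_fn, self.kappaG_fn):
            a = fn(self.s_grid)
            b = fn(2.0 * mid - self.s_grid)
            scale = max(np.max(np.abs(a)), 1e-300)
            if np.max(np.abs(a - b)) > rtol * scale:
                return False
        return True

    def is_homogeneous(self) -> bool:
        return (
            np.ptp(self.sigma) == 0.0
            and np.ptp(self.kappa_field) == 0.0
            and np.ptp(self.kappaG_field) == 0.0
        )

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "s_nm": self.s_grid,
                "sigma_nm2": self.sigma,
                "kappa_pNnm": self.kappa_field,
                "kappaG_pNnm": self.kappaG_field,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ProfileSet":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            s_grid=df["s_nm"].to_numpy(),
            sigma=df["sigma_nm2"].to_numpy(),
            kappa_field=df["kappa_pNnm"].to_numpy(),
            kappaG_field=df["kappaG_pNnm"].to_numpy(),
        )


class _SplineField:
    """Fallback field backed by a cubic smoothing-free interpolant."""

    def __init__(self, s, y):
        from scipy.interpolate import CubicSpline

        self._cs = CubicSpline(s, y)

    def __call__(self, s, order: int = 0):
        return self._cs(np.asarray(s, dtype=float), nu=order)

    def is_uniform(self) -> bool:
        return bool(np.ptp(self._cs(self._cs.x)) == 0.0)


def _spline_field(s, y):
    if np.ptp(y) == 0.0:
        return TanhField(float(y[0]))
    return _SplineField(s, y)


# ---------------------------------------------------------------------------
# Profile factories for the canonical experiments
# ---------------------------------------------------------------------------


def _default_width(params: ModelParameters, transition_width: float | None) -> float:
    return (
        float(transition_width)
        if transition_width is not None
        else DEFAULT_TRANSITION_WIDTH_FACTOR * params.Rc
    )


def _default_kappaG(params: ModelParameters, kappaG_lipid: float | None) -> float:
    # typical lipid value: kappa_G ≈ -0.9 kappa
    return float(kappaG_lipid) if kappaG_lipid is not None else -0.9 * params.kappa


def _build_grid(params: ModelParameters, n: int) -> np.ndarray:
    return np.linspace(0.0, params.Lc, n)


def single_domain_profiles(
    params: ModelParameters,
    sigma0: float,
    kappa_ratio: float = 1.0,
    delta_kappaG: float = 0.0,
    L_domain: float = 8000.0,
    *,
    transition_width: float | None = None,
    kappaG_lipid: float | None = None,
    uniform_sigma: bool = False,
    n_grid: int = 2001,
) -> ProfileSet:
    """Profiles with one centered heterogeneous domain.

    ``sigma0`` is the plateau protein density [nm⁻²]; the bending
    rigidity plateau is ``kappa_ratio * params.kappa`` and the Gaussian
    modulus plateau ``(1 + delta_kappaG) * kappaG_lipid``, all sharing
    the same domain geometry.  With ``uniform_sigma=True`` the protein
    density is constant (= sigma0) along the whole tube — the setup of
    the rigidity-only experiments, where composition is uniform and only
    κ varies.
    """
    if sigma0 < 0:
        raise ValueError("sigma0 must be non-negative")
    if not L_domain < params.Lc:
        raise ValueError(f"L_domain={L_domain} must be smaller than Lc={params.Lc}")
    w = _default_width(params, transition_width)
    kG0 = _default_kappaG(params, kappaG_lipid)
    center = params.Lc / 2.0
    s = _build_grid(params, n_grid)

    def domain(amplitude: float) -> DomainSpec:
        return DomainSpec(center=center, length=L_domain, amplitude=amplitude, transition_width=w)

    if uniform_sigma or sigma0 == 0.0:
        sigma_fn = TanhField(sigma0)
    else:
        sigma_fn = TanhField(0.0, [domain(sigma0)])
    kappa_fn = (
        TanhField(params.kappa)
        if kappa_ratio == 1.0
        else TanhField(params.kappa, [domain(kappa_ratio * params.kappa)])
    )
    kappaG_fn = (
        TanhField(kG0)
        if delta_kappaG == 0.0
        else TanhField(kG0, [domain((1.0 + delta_kappaG) * kG0)])
    )
    return ProfileSet(
        s_grid=s,
        sigma=sigma_fn(s),
        kappa_field=kappa_fn(s),
        kappaG_field=kappaG_fn(s),
        domain_meta=[(center, L_domain, sigma0)],
        sigma_fn=sigma_fn,
        kappa_fn=kappa_fn,
        kappaG_fn=kappaG_fn,
    )


def two_domain_profiles(
    params: ModelParameters,
    sigma0: float,
    kappa_ratio: float = 1.0,
    L_domain: float = 8000.0,
    L_separation: float = 4000.0,
    *,
    transition_width: float | None = None,
    kappaG_lipid: float | None = None,
    uniform_sigma: bool = False,
    n_grid: int = 2001,
) -> ProfileSet:
    """Two identical domains placed symmetrically about the tube midpoint.

    ``L_separation`` is the end-to-end gap between the two plateaus;
    ``L_separation = 0`` is the defined touching case.
    """
    if sigma0 < 0:
        raise ValueError("sigma0 must be non-negative")
    if L_separation < 0:
        raise ValueError("L_separation must be non-negative")
    if 2.0 * L_domain + L_separation > params.Lc:
        raise ValueError(
            f"2*L_domain + L_separation = {2 * L_domain + L_separation} "
            f"exceeds the tube length Lc = {params.Lc}"
        )
    w = _default_width(params, transition_width)
    kG0 = _default_kappaG(params, kappaG_lipid)
    mid = params.Lc / 2.0
    offset = (L_separation + L_domain) / 2.0
    centers = [mid - offset, mid + offset]
    s = _build_grid(params, n_grid)

    def domains(amplitude: float) -> list[DomainSpec]:
        return [
            DomainSpec(center=c, length=L_domain, amplitude=amplitude, transition_width=w)
            for c in centers
        ]

    if uniform_sigma or sigma0 == 0.0:
        sigma_fn = TanhField(sigma0)
    else:
        sigma_fn = TanhField(0.0, domains(sigma0))
    kappa_fn = (
        TanhField(params.kappa)
        if kappa_ratio == 1.0
        else TanhField(params.kappa, domains(kappa_ratio * params.kappa))
    )
    kappaG_fn = TanhField(kG0)
    return ProfileSet(
        s_grid=s,
        sigma=sigma_fn(s),
        kappa_field=kappa_fn(s),
        kappaG_field=kappaG_fn(s),
        domain_meta=[(c, L_domain, sigma0) for c in centers],
        sigma_fn=sigma_fn,
        kappa_fn=kappa_fn,
        kappaG_fn=kappaG_fn,
    )
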