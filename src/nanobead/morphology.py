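"""Bead detection, shape classification, and phase diagrams.

A *bead* is a maximal contiguous region of the solved meridian with
r > (1+ε) R_c.  Beads are classified into three morphologies:

* **cylindrical** — the radius is flat over the bead top
  (Δr_b/r_b < 0.01 over the central window),
* **unduloid** — neck-and-bulge: the radius dips between two bulges
  inside the bead (equivalently, the second arclength derivative of the
  mean curvature changes sign at the interior neck),
* **ellipsoidal** — a single smooth hump.

The numeric flatness criterion runs first, then the neck-and-bulge
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .energy import induced_length_scales
from .parameters import ModelParameters
from .profiles import single_domain_profiles
from .solver import ContinuationBranch, MembraneShape, SolverConfig, continuation

__all__ = [
    "BeadMeasurement",
    "MorphologyConfig",
    "PhaseDiagram",
    "measure_beads",
    "classify_bead",
    "phase_diagram",
    "SHAPE_CLASSES",
]

SHAPE_CLASSES = ("ellipsoidal", "cylindrical", "unduloid", "none")


@dataclass(frozen=True)
class MorphologyConfig:
    """Thresholds for bead detection and classification.

    ``detect_epsilon``: a bead needs r > (1+ε) R_c.  ``saddle_fraction``:
    two maxima whose connecting saddle stays above this fraction of the
    smaller maximum count as one bead.  ``plateau_window``: central
    fraction of the bead extent over which Δr_b/r_b is measured.
    ``cylindrical_threshold``: the Δr_b/r_b limit below which a bead is
    flat-topped.  ``smooth_window``: odd number of samples for the
    smoothed H'' estimate.
    """

    detect_epsilon: float = 0.1
    saddle_fraction: float = 0.95
    plateau_window: float = 0.5
    cylindrical_threshold: float = 0.01
    smooth_window: int = 21
    interior_trim: float = 0.15
    sign_tolerance: float = 0.05


@dataclass(frozen=True)
class BeadMeasurement:
    """One detected bead."""

    r_b: float                # max radius over the bead [nm]
    position: float           # arclength of the maximum [nm]
    s_start: float            # bead extent [nm]
    s_end: float
    plateau_variation: float  # Δr_b / r_b over the central window
    shape_class: str = "none"


def _regions_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs (stop inclusive)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    stops = np.concatenate([idx[splits], [idx[-1]]])
    return list(zip(starts, stops))


def measure_beads(
    shape: MembraneShape,
    config: MorphologyConfig | None = None,
) -> list[BeadMeasurement]:
    """Detect and measure beads on a solved shape.

    Regions with r > (1+ε)R_c are found, then regions whose separating
    saddle exceeds ``saddle_fraction`` of the smaller maximum are merged
    (a shallow dip between two bulges is still one bead).  Returns an
    empty list for a bare tube.
    """
    cfg = config or MorphologyConfig()
    Rc = shape.params.Rc
    s, r = np.asarray(shape.s), np.asarray(shape.r)
    mask = r > (1.0 + cfg.detect_epsilon) * Rc
    # candidate peaks: local maxima above the detection threshold
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(r, height=(1.0 + cfg.detect_epsilon) * Rc)
    if peaks.size == 0 and np.any(mask):
        peaks = np.array([int(np.argmax(r))])
    # merge neighboring peaks across shallow saddles: a dip that stays
    # above saddle_fraction of the smaller peak is not a separation
    groups: list[list[int]] = [[int(j)] for j in peaks]
    merged = True
    while merged and len(groups) > 1:
        merged = False
        for k in range(len(groups) - 1):
            ja = max(groups[k], key=lambda j: r[j])
            jb = max(groups[k + 1], key=lambda j: r[j])
            saddle = float(np.min(r[ja: jb + 1]))
            if saddle > cfg.saddle_fraction * min(r[ja], r[jb]):
                groups[k] = groups[k] + groups[k + 1]
                del groups[k + 1]
                merged = True
                break
    # bead extents: walk out from each group's top peak to the threshold
    thr = (1.0 + cfg.detect_epsilon) * Rc
    regions = []
    for g in groups:
        j = max(g, key=lambda j: r[j])
        i0 = j
        while i0 > 0 and r[i0 - 1] > thr and not (i0 - 1 < min(g) and r[i0 - 1] > r[i0]):
            i0 -= 1
        i1 = j
        n = r.size
        while i1 < n - 1 and r[i1 + 1] > thr and not (i1 + 1 > max(g) and r[i1 + 1] > r[i1]):
            i1 += 1
        regions.append((i0, i1))
    out = []
    for i0, i1 in regions:
        seg = slice(i0, i1 + 1)
        j = i0 + int(np.argmax(r[seg]))
        r_b = float(r[j])
        s0, s1 = float(s[i0]), float(s[i1])
        half_w = 0.5 * cfg.plateau_window * (s1 - s0)
        center = 0.5 * (s0 + s1)
        win = (s >= center - half_w) & (s <= center + half_w)
        if np.count_nonzero(win) >= 2:
            rw = r[win]
            plateau_var = float((np.max(rw) - np.min(rw)) / np.max(rw))
        else:
            plateau_var = 0.0
        out.append(
            BeadMeasurement(
                r_b=r_b, position=float(s[j]), s_start=s0, s_end=s1,
                plateau_variation=plateau_var,
            )
        )
    return out


def classify_bead(
    shape: MembraneShape,
    bead: BeadMeasurement,
    config: MorphologyConfig | None = None,
) -> str:
    """Classify a bead as cylindrical / ellipsoidal / unduloid.

    The flatness test runs first (cylindrical when the radius varies by
    less than 1% over the central window); otherwise the smoothed radius
    profile over the trimmed bead interior decides: a dip between two
    bulges deeper than the same 1% threshold marks an unduloid, and a
    single smooth hump an ellipsoid.  The interior dip is where the
    second arclength derivative of the mean curvature flips sign, so
    this is the geometric reading of the curvature-based taxonomy.
    """
    cfg = config or MorphologyConfig()
    if shape.residual > 1e-3:
        raise ValueError("refusing to classify an unconverged shape")
    if bead.plateau_variation < cfg.cylindrical_threshold:
        return "cylindrical"
    # unduloid = neck-and-bulge: the radius has an interior dip between
    # two bulges.  This is the geometric signature of the curvature
    # criterion (the sign of H'' flips at the interior neck); tested on
    # the radius profile it is robust to the smoothing scale.
    from scipy.signal import find_peaks

    trim = cfg.interior_trim * (bead.s_end - bead.s_start)
    lo, hi = bead.s_start + trim, bead.s_end - trim
    n = max(401, cfg.smooth_window * 8 + 1)
    su = np.linspace(lo, hi, n)
    ru = np.interp(su, shape.s, shape.r)
    win = cfg.smooth_window if cfg.smooth_window % 2 == 1 else cfg.smooth_window + 1
    ru_s = savgol_filter(ru, window_length=min(win, n - 2 + (n % 2)), polyorder=3)
    top = float(np.max(ru_s))
    # bulge candidates: local maxima near the bead top (shoulder wiggles
    # far below the top are not bulges)
    peaks, _ = find_peaks(ru_s, height=0.8 * top,
                          prominence=0.1 * cfg.cylindrical_threshold * top)
    if peaks.size >= 2:
        saddle = float(np.min(ru_s[peaks[0]: peaks[-1] + 1]))
        pair_top = float(min(ru_s[peaks[0]], ru_s[peaks[-1]]))
        if 1.0 - saddle / pair_top > cfg.cylindrical_threshold:
            return "unduloid"
    return "ellipsoidal"


@dataclass
class PhaseDiagram:
    """Bead-morphology classes over a 2-D parameter grid."""

    axis1_name: str
    axis2_name: str
    axis1_values: np.ndarray
    axis2_values: np.ndarray
    class_map: np.ndarray      # shape (n2, n1), dtype object (strings)
    log_ratio_map: np.ndarray  # log10(l_sigma / l_kappa) per cell
    r_b_map: np.ndarray
    failures: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for j, v2 in enumerate(self.axis2_values):
            for i, v1 in enumerate(self.axis1_values):
                rows.append(
                    {
                        self.axis1_name: v1,
                        self.axis2_name: v2,
                        "shape_class": self.class_map[j, i],
                        "log_ratio": self.log_ratio_map[j, i],
                        "r_b_nm": self.r_b_map[j, i],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def phase_diagram(
    sigma0_values: Sequence[float],
    kappa_ratio_values: Sequence[float],
    params: ModelParameters,
    config: SolverConfig | None = None,
    morph: MorphologyConfig | None = None,
    L_domain: float = 8000.0,
) -> PhaseDiagram:
    """Morphology classes over a (σ₀, κ_ratio) grid.

    Each κ_ratio row is traced by continuation in σ₀ from the smallest
    value, seeded from the previous row's start; each cell records the
    bead class and log₁₀(l_σ/l_κ) evaluated with λ = λ₀ and
    κ_protein = κ_ratio·κ.  Unconverged cells are marked "none" and
    listed in ``failures``, never interpolated.
    """
    morph = morph or MorphologyConfig()
    s_vals = np.asarray(sigma0_values, dtype=float)
    k_vals = np.asarray(kappa_ratio_values, dtype=float)
    n1, n2 = len(s_vals), len(k_vals)
    class_map = np.full((n2, n1), "none", dtype=object)
    log_map = np.full((n2, n1), np.nan)
    rb_map = np.full((n2, n1), np.nan)
    failures: dict = {}

    # walk up in kappa_ratio at the smallest sigma0, then sweep each row
    k_path = np.unique(np.concatenate([[1.0], k_vals]))
    spine = continuation(
        k_path,
        lambda k: single_domain_profiles(
            params, sigma0=float(s_vals[0]), kappa_ratio=float(k), L_domain=L_domain
        ),
        params,
        config=config,
        parameter="kappa_ratio",
    )
    spine_shapes = dict(zip(spine.values, spine.shapes))
    for j, kr in enumerate(k_vals):
        seed = spine_shapes.get(kr)
        if seed is None:
            failures[(float(s_vals[0]), float(kr))] = "spine continuation failed"
            continue
        row = continuation(
            s_vals,
            lambda v, kr=kr: single_domain_profiles(
                params, sigma0=float(v), kappa_ratio=float(kr), L_domain=L_domain
            ),
            params,
            config=config,
            guess=seed,
            parameter="sigma0",
        )
        got = dict(zip(row.values, row.shapes))
        for i, sv in enumerate(s_vals):
            log_map[j, i] = induced_length_scales(
                float(sv), params.lambda0, float(kr) * params.kappa, params
            )[2]
            sh = got.get(sv)
            if sh is None:
                failures[(float(sv), float(kr))] = row.failures.get(sv, "not reached")
                continue
            beads = measure_beads(sh, morph)
            if not beads:
                class_map[j, i] = "none"
                rb_map[j, i] = sh.params.Rc
            else:
                main = max(beads, key=lambda b: b.r_b)
                class_map[j, i] = classify_bead(sh, main, morph)
                rb_map[j, i] = main.r_b
    return PhaseDiagram(
        axis1_name="sigma0",
        axis2_name="kappa_ratio",
        axis1_values=s_vals,
        axis2_values=k_vals,
        class_map=class_map,
        log_ratio_map=log_map,
        r_b_map=rb_map,
        failures=failures,
    )
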