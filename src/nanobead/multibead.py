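"""Two-domain experiments: bead counting, merging, and snap-through.

Two identical heterogeneous domains separated end-to-end by
``L_separation`` produce two beads when far apart; below a critical
separation the equilibrium switches to a single bead.  The transition
is *smooth* at weak heterogeneity and becomes a *snap-through*
(hysteretic, with an energy gap and no stable intermediate) at strong
heterogeneity.  Snap-through is detected primarily by disagreement
between downward and upward separation sweeps; a discontinuous shape
jump along a single sweep is the fallback criterion when one direction
fails to converge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .morphology import MorphologyConfig, measure_beads
from .parameters import ModelParameters
from .profiles import two_domain_profiles
from .solver import (
    ContinuationBranch,
    MembraneShape,
    SolverConfig,
    continuation,
)

__all__ = ["MergeStudyResult", "count_beads", "merge_study", "merge_criterion_check"]


def count_beads(shape: MembraneShape, config: MorphologyConfig | None = None) -> int:
    """Number of beads on a shape after saddle merging (deterministic)."""
    return len(measure_beads(shape, config))


@dataclass
class MergeStudyResult:
    """Outcome of an L_separation sweep over a two-domain tube."""

    separations: np.ndarray          # swept values, descending order [nm]
    bead_counts: np.ndarray          # from the downward sweep
    r_b: np.ndarray                  # max radius per separation [nm]
    energies: np.ndarray             # total energy per separation [pN·nm]
    critical_separation: float | None  # largest separation with one bead [nm]
    transition_type: str             # "smooth" | "snap_through" | "unresolved"
    hysteresis_width: float = 0.0    # separation range of branch disagreement [nm]
    energy_gap: float = 0.0          # |ΔE| between branches at transition [pN·nm]
    bead_counts_up: np.ndarray | None = None
    r_b_up: np.ndarray | None = None
    energies_up: np.ndarray | None = None
    forward: ContinuationBranch | None = field(default=None, repr=False)
    backward: ContinuationBranch | None = field(default=None, repr=False)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, sep in enumerate(self.separations):
            rows.append(
                {
                    "separation_nm": sep,
                    "n_beads": self.bead_counts[i],
                    "r_b_nm": self.r_b[i],
                    "energy_pNnm": self.energies[i],
                    "direction": "decreasing",
                }
            )
        if self.bead_counts_up is not None:
            for i, sep in enumerate(self.separations[::-1]):
                rows.append(
                    {
                        "separation_nm": sep,
                        "n_beads": self.bead_counts_up[i],
                        "r_b_nm": self.r_b_up[i],
                        "energy_pNnm": self.energies_up[i],
                        "direction": "increasing",
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "critical_separation_nm": self.critical_separation,
            "transition_type": self.transition_type,
            "hysteresis_width_nm": self.hysteresis_width,
            "energy_gap_pNnm": self.energy_gap,
            "separations_nm": [float(v) for v in self.separations],
            "bead_counts": [int(c) for c in self.bead_counts],
        }


def _sweep_stats(branch: ContinuationBranch, morph: MorphologyConfig):
    counts = np.array([count_beads(sh, morph) for sh in branch.shapes])
    r_b = branch.r_b
    energies = branch.totals
    return counts, r_b, energies


def merge_study(
    params: ModelParameters,
    sigma0: float,
    kappa_ratio: float,
    L_domain: float = 8000.0,
    separations: Sequence[float] | None = None,
    direction: str = "both",
    config: SolverConfig | None = None,
    morph: MorphologyConfig | None = None,
) -> MergeStudyResult:
    """Sweep the domain separation and locate the two-to-one transition.

    The two-domain state at the largest separation is first built by
    amplitude continuation (σ₀ from 0, then κ_ratio from 1); the
    separation is then swept downward with each solve seeded from its
    neighbor.  With ``direction="both"`` an upward sweep restarts from
    the small-separation (single-bead) state, and disagreement of the
    bead counts between the sweeps marks a snap-through with its
    hysteresis width and energy gap.
    """
    cfg = config or SolverConfig()
    morph = morph or MorphologyConfig()
    if separations is None:
        separations = np.linspace(4000.0, 0.0, 21)
    seps = np.asarray(sorted(separations, reverse=True), dtype=float)
    if seps[0] > params.Lc - 2.0 * L_domain or seps[-1] < 0:
        raise ValueError(
            f"separation grid [{seps[-1]}, {seps[0]}] outside the geometric "
            f"bounds [0, {params.Lc - 2.0 * L_domain}]"
        )
    if direction not in {"decreasing", "increasing", "both"}:
        raise ValueError(f"unknown direction {direction!r}")

    def fields_at(sep, s0, kr):
        return two_domain_profiles(
            params, sigma0=s0, kappa_ratio=kr, L_domain=L_domain, L_separation=sep
        )

    def warm_up(sep) -> MembraneShape | None:
        """Amplitude continuation to (sigma0, kappa_ratio) at fixed separation."""
        guess = None
        if sigma0 > 0:
            br = continuation(
                np.linspace(0.0, sigma0, 8),
                lambda v: fields_at(sep, v, 1.0),
                params,
                config=cfg,
                parameter="sigma0",
            )
            if br.values and br.values[-1] == sigma0:
                guess = br.shapes[-1]
            else:
                return None
        if kappa_ratio != 1.0:
            br = continuation(
                np.linspace(1.0, kappa_ratio, 8),
                lambda k: fields_at(sep, sigma0, k),
                params,
                config=cfg,
                guess=guess,
                parameter="kappa_ratio",
            )
            if br.values and br.values[-1] == kappa_ratio:
                guess = br.shapes[-1]
            else:
                return None
        if guess is None:  # homogeneous case
            from .solver import solve_shape

            guess = solve_shape(fields_at(sep, sigma0, kappa_ratio), params, config=cfg)
        return guess

    start = warm_up(seps[0])
    if start is None:
        raise RuntimeError("could not build the two-bead starting state")
    down = continuation(
        seps,
        lambda v: fields_at(v, sigma0, kappa_ratio),
        params,
        config=cfg,
        guess=start,
        parameter="L_separation",
    )
    counts, r_b, energies = _sweep_stats(down, morph)
    truncated = len(down.values) < len(seps)

    up = None
    counts_up = r_b_up = energies_up = None
    if direction in {"increasing", "both"}:
        # independent branch: warm up at the smallest separation (the
        # merged state) and sweep upward over the full grid
        try:
            seed_up = warm_up(seps[-1])
        except Exception:
            seed_up = None
        if seed_up is not None:
            up = continuation(
                np.asarray(sorted(seps)),
                lambda v: fields_at(v, sigma0, kappa_ratio),
                params,
                config=cfg,
                guess=seed_up,
                parameter="L_separation",
            )
            counts_up, r_b_up, energies_up = _sweep_stats(up, morph)

    # critical separation: largest separation at which a downward
    # quasi-static sweep yields a single bead.  If the two-bead branch
    # terminates at a fold while the merged branch persists there, the
    # system snaps at the fold and the largest one-bead separation is
    # the first grid value below it.
    crit = None
    for sep, c in zip(down.values, counts):
        if c == 1:
            crit = float(sep)
            break
    transition = "unresolved"
    hyst = 0.0
    egap = 0.0
    if crit is not None:
        transition = "smooth"
    elif truncated and up is not None and up.values:
        fold = float(down.values[-1]) if down.values else float(seps[0])
        below = [
            (v, c) for v, c in zip(up.values, counts_up)
            if v < fold and c == 1
        ]
        if below:
            crit = float(max(v for v, _ in below))
            transition = "snap_through"
    # branch disagreement and shape jumps refine the classification
    if crit is not None and transition == "smooth" and len(down.shapes) >= 3:
        jumps = down.shape_jumps()
        med = float(np.median(jumps))
        if med > 0 and float(np.max(jumps)) > 10.0 * med:
            transition = "snap_through"
            k = int(np.argmax(jumps)) + 1
            egap = abs(float(energies[k] - energies[k - 1]))
    if up is not None and up.values:
        down_map = dict(zip(down.values, counts))
        up_map = dict(zip(up.values, counts_up))
        common = sorted(set(down_map) & set(up_map))
        disagree = [v for v in common if down_map[v] != up_map[v]]
        if disagree:
            transition = "snap_through"
            hyst = float(max(disagree) - min(disagree)) if len(disagree) > 1 else 0.0
            e_down = dict(zip(down.values, energies))
            e_up = dict(zip(up.values, energies_up))
            egap = max(abs(e_down[v] - e_up[v]) for v in disagree)
        elif truncated and counts_up is not None:
            # fold on one branch with the other persisting is hysteretic
            missing = [v for v in up.values
                       if v not in down_map
                       and counts_up[list(up.values).index(v)] == 1]
            if missing:
                transition = "snap_through"
    return MergeStudyResult(
        separations=np.array(down.values),
        bead_counts=counts,
        r_b=r_b,
        energies=energies,
        critical_separation=crit,
        transition_type=transition,
        hysteresis_width=hyst,
        energy_gap=egap,
        bead_counts_up=counts_up,
        r_b_up=r_b_up,
        energies_up=energies_up,
        forward=down,
        backward=up,
    )


def merge_criterion_check(
    result: MergeStudyResult,
    r_b_far: float,
) -> bool | None:
    """Does the merge happen near L_separation = 2 r_b?

    Returns True when the critical separation agrees with twice the
    far-field bead radius to within one separation-grid step, False when
    it does not, and None (indeterminate) when the sweep did not resolve
    the transition.
    """
    if result.critical_separation is None:
        return None
    seps = np.asarray(result.separations, dtype=float)
    if len(seps) < 2:
        return None
    step = float(np.max(np.abs(np.diff(seps))))
    return bool(abs(result.critical_separation - 2.0 * r_b_far) <= step)
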