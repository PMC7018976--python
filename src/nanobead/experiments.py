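"""Figure-level experiment drivers.

Each driver runs a complete computational experiment (continuation
sweeps, morphology measurement, validation oracles) and returns plain
tables plus the underlying branches; when an output directory is given,
results are written as CSV (data) and JSON (metadata).  The pipeline is
deterministic: re-running a driver with the same configuration
reproduces its outputs byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .analytic import AnalyticInput, bead_radius_analytic, bead_radius_linearized, equilibrium_tube_radius
from .morphology import MorphologyConfig, classify_bead, measure_beads, phase_diagram
from .multibead import merge_study
from .parameters import ModelParameters
from .profiles import single_domain_profiles
from .solver import (
    ConvergenceError,
    SolverConfig,
    continuation,
    solve_shape,
    verify_stationarity,
)

logger = logging.getLogger("nanobead")

__all__ = [
    "ExperimentConfig",
    "run_single_bead_sweep",
    "run_rigidity_sweep",
    "run_shape_gallery",
    "run_phase_diagram",
    "run_multibead",
    "run_validation_suite",
]

_KINDS = {
    "single_bead_sweep",
    "rigidity_sweep",
    "shape_gallery",
    "phase_diagram",
    "multibead",
    "validate",
}


@dataclass
class ExperimentConfig:
    """Configuration of one pipeline run."""

    kind: str
    parameters: dict = field(default_factory=dict)   # ModelParameters overrides
    options: dict = field(default_factory=dict)      # experiment-specific knobs
    output_dir: str | None = None
    seed: int = 0                                    # used only by perturbation tests
    solver: dict = field(default_factory=dict)       # SolverConfig overrides

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}; one of {sorted(_KINDS)}")

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = pathlib.Path(path)
        if path.suffix in {".toml", ".tml"}:
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            import yaml

            data = yaml.safe_load(path.read_text())
        return cls(**data)

    def model_parameters(self) -> ModelParameters:
        return ModelParameters.from_dict(self.parameters) if self.parameters else ModelParameters()

    def solver_config(self) -> SolverConfig:
        return SolverConfig(**self.solver) if self.solver else SolverConfig()


def _outdir(config) -> pathlib.Path | None:
    if config is None or config.output_dir is None:
        return None
    out = pathlib.Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_json(path: pathlib.Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def _log_solve(tag: str, value: float, shape) -> None:
    logger.info(
        "solve %s=%.6g residual=%.3e r_b=%.2f nm", tag, value, shape.residual, shape.r_max
    )


def run_single_bead_sweep(
    config: ExperimentConfig | None = None,
    params: ModelParameters | None = None,
    sigma_values: Sequence[float] | None = None,
):
    """Protein-density sweep: bead radius and tension versus σ₀.

    Emits the r_b(σ₀) table with the cylindrical-bead analytic overlay
    and the minimum net tension per state.
    """
    config = config or ExperimentConfig(kind="single_bead_sweep")
    p = params or config.model_parameters()
    cfg = config.solver_config()
    if sigma_values is None:
        sigma_values = config.options.get("sigma_values") or np.linspace(0.0, 1.25e-4, 21)
    sigma_values = np.asarray(sigma_values, dtype=float)
    L_domain = float(config.options.get("L_domain", 8000.0))
    branch = continuation(
        sigma_values,
        lambda v: single_domain_profiles(p, sigma0=float(v), L_domain=L_domain),
        p,
        config=cfg,
        parameter="sigma0",
    )
    for v, sh in zip(branch.values, branch.shapes):
        _log_solve("sigma0", v, sh)
    rows = []
    for v, sh in zip(branch.values, branch.shapes):
        try:
            rb_an = bead_radius_analytic(AnalyticInput(sigma=float(v), params=p))
        except ValueError:
            rb_an = np.nan
        rows.append(
            {
                "sigma0_nm2": v,
                "r_b_nm": sh.r_max,
                "r_b_analytic_nm": rb_an,
                "min_lambda_pN_per_nm": float(np.min(sh.lam)),
            }
        )
    table = pd.DataFrame(rows)
    out = _outdir(config)
    if out is not None:
        table.to_csv(out / "single_bead_sweep.csv", index=False)
        _write_json(out / "single_bead_sweep.json", {
            "parameters": p.to_dict(),
            "requested_sigma0": [float(v) for v in sigma_values],
            "failures": {f"{k:.6g}": v for k, v in branch.failures.items()},
        })
    return branch, table


def run_rigidity_sweep(
    config: ExperimentConfig | None = None,
    params: ModelParameters | None = None,
    kappa_ratios: Sequence[float] | None = None,
):
    """Rigidity-ratio sweep with composition uniform and C = 0.

    The spontaneous-curvature coupling is switched off (φ = 0, modelling
    cylindrical inclusions); only the bending rigidity varies along the
    tube.  Emits r_b(κ_ratio) with the analytic overlays (the analytic
    columns evaluate the cylindrical-bead formulas at σ = 0, since the
    uniform composition enters the mechanics only through the tension
    bookkeeping).
    """
    config = config or ExperimentConfig(kind="rigidity_sweep")
    p = (params or config.model_parameters()).replace(phi=0.0)
    cfg = config.solver_config()
    if kappa_ratios is None:
        kappa_ratios = config.options.get("kappa_ratios") or np.concatenate(
            [[1.0], np.linspace(2.0, 30.0, 15)]
        )
    kappa_ratios = np.asarray(kappa_ratios, dtype=float)
    sigma0 = float(config.options.get("sigma0", 1.25e-4))
    L_domain = float(config.options.get("L_domain", 8000.0))
    branch = continuation(
        kappa_ratios,
        lambda k: single_domain_profiles(
            p, sigma0=sigma0, kappa_ratio=float(k), L_domain=L_domain, uniform_sigma=True
        ),
        p,
        config=cfg,
        parameter="kappa_ratio",
    )
    for v, sh in zip(branch.values, branch.shapes):
        _log_solve("kappa_ratio", v, sh)
    rows = []
    for v, sh in zip(branch.values, branch.shapes):
        inp = AnalyticInput(sigma=0.0, params=p, kappa_ratio=float(v))
        rows.append(
            {
                "kappa_ratio": v,
                "r_b_nm": sh.r_max,
                "r_b_analytic_nm": bead_radius_analytic(inp),
                "r_b_linearized_nm": bead_radius_linearized(inp),
                "min_lambda_pN_per_nm": float(np.min(sh.lam)),
            }
        )
    table = pd.DataFrame(rows)
    out = _outdir(config)
    if out is not None:
        table.to_csv(out / "rigidity_sweep.csv", index=False)
        _write_json(out / "rigidity_sweep.json", {
            "parameters": p.to_dict(),
            "sigma0": sigma0,
            "failures": {f"{k:.6g}": v for k, v in branch.failures.items()},
        })
    return branch, table


def run_shape_gallery(
    config: ExperimentConfig | None = None,
    params: ModelParameters | None = None,
    points: Sequence[tuple[float, float]] | None = None,
):
    """Solve and classify beads at selected (σ₀, κ_ratio) points.

    Defaults to κ_ratio = 11 with the three protein densities spanning
    the ellipsoidal / cylindrical / unduloid morphologies.  Solver
    failures at individual points are recorded and the run continues.
    Returns (records, H-profile table).
    """
    config = config or ExperimentConfig(kind="shape_gallery")
    p = params or config.model_parameters()
    cfg = config.solver_config()
    if points is None:
        points = config.options.get("points") or [
            (2e-5, 11.0),
            (1e-4, 11.0),
            (1.85e-4, 11.0),
        ]
    records = []
    profiles = []
    morph = MorphologyConfig()
    for sigma0, kr in points:
        try:
            pre = continuation(
                np.linspace(1.0, kr, max(2, int(kr))) if kr != 1.0 else [1.0],
                lambda k: single_domain_profiles(p, sigma0=0.0, kappa_ratio=float(k)),
                p,
                config=cfg,
            )
            if not pre.values or pre.values[-1] != kr:
                raise ConvergenceError(f"rigidity leg stopped at {pre.values[-1] if pre.values else None}")
            br = continuation(
                np.linspace(0.0, sigma0, 16)[1:] if sigma0 > 0 else [0.0],
                lambda v: single_domain_profiles(p, sigma0=float(v), kappa_ratio=float(kr)),
                p,
                config=cfg,
                guess=pre.shapes[-1],
            )
            if not br.values or br.values[-1] != sigma0:
                raise ConvergenceError(
                    f"density leg stopped at {br.values[-1] if br.values else None}"
                )
            sh = br.shapes[-1]
            beads = measure_beads(sh, morph)
            cls = classify_bead(sh, max(beads, key=lambda b: b.r_b), morph) if beads else "none"
            records.append(
                {"sigma0_nm2": sigma0, "kappa_ratio": kr, "status": "ok",
                 "shape_class": cls, "r_b_nm": max((b.r_b for b in beads), default=p.Rc)}
            )
            dense = sh.resample(2001)
            for s_, H_ in zip(dense.s, dense.H):
                profiles.append(
                    {"sigma0_nm2": sigma0, "kappa_ratio": kr, "s_nm": s_, "H_per_nm": H_}
                )
        except ConvergenceError as err:
            logger.warning("gallery point (%g, %g) failed: %s", sigma0, kr, err)
            records.append(
                {"sigma0_nm2": sigma0, "kappa_ratio": kr, "status": f"failed: {err}",
                 "shape_class": "none", "r_b_nm": np.nan}
            )
    table = pd.DataFrame(records)
    prof_table = pd.DataFrame(profiles)
    out = _outdir(config)
    if out is not None:
        table.to_csv(out / "shape_gallery.csv", index=False)
        prof_table.to_csv(out / "shape_gallery_H_profiles.csv", index=False)
        _write_json(out / "shape_gallery.json", {"parameters": p.to_dict()})
    return table, prof_table


def run_phase_diagram(
    config: ExperimentConfig | None = None,
    params: ModelParameters | None = None,
):
    """Morphology phase diagram over (σ₀, κ_ratio)."""
    config = config or ExperimentConfig(kind="phase_diagram")
    p = params or config.model_parameters()
    cfg = config.solver_config()
    s_vals = np.asarray(
        config.options.get("sigma0_values", np.linspace(0.0, 3.75e-4, 6)), dtype=float
    )
    k_vals = np.asarray(
        config.options.get("kappa_ratio_values", np.linspace(2.0, 11.0, 6)), dtype=float
    )
    diagram = phase_diagram(s_vals, k_vals, p, config=cfg)
    out = _outdir(config)
    if out is not None:
        diagram.to_csv(out / "phase_diagram.csv")
        _write_json(out / "phase_diagram.json", {
            "parameters": p.to_dict(),
            "failures": {str(k): v for k, v in diagram.failures.items()},
        })
    return diagram


def run_multibead(
    config: ExperimentConfig | None = None,
    params: ModelParameters | None = None,
):
    """Two-domain separation sweep (see :func:`nanobead.multibead.merge_study`)."""
    config = config or ExperimentConfig(kind="multibead")
    p = params or config.model_parameters()
    opts = config.options
    if not opts.get("spontaneous_curvature", True):
        p = p.replace(phi=0.0)
    res = merge_study(
        p,
        sigma0=float(opts.get("sigma0", 1.25e-4)),
        kappa_ratio=float(opts.get("kappa_ratio", 11.0)),
        L_domain=float(opts.get("L_domain", 8000.0)),
        separations=opts.get("separations"),
        direction=opts.get("direction", "both"),
        config=config.solver_config(),
    )
    out = _outdir(config)
    if out is not None:
        res.to_csv(out / "multibead.csv")
        _write_json(out / "multibead.json", res.summary() | {"parameters": p.to_dict()})
    return res


def run_validation_suite(
    config: ExperimentConfig | None = None,
    params: ModelParameters | None = None,
    tolerance_factor: float = 1.0,
) -> dict:
    """Aggregate oracle checks; the release criterion is all-pass.

    ``tolerance_factor`` rescales every threshold (tightening it exposes
    which oracles are marginal).  Returns a machine-readable report; the
    CLI exits nonzero when any check fails.
    """
    config = config or ExperimentConfig(kind="validate")
    p = params or config.model_parameters()
    cfg = config.solver_config()
    report: dict[str, dict] = {}

    def record(name, value, threshold, ok=None):
        ok = bool(value < threshold) if ok is None else ok
        report[name] = {"value": float(value), "threshold": float(threshold), "passed": ok}

    # 1. homogeneous cylinder closed form over a tension range
    worst = 0.0
    for lam in np.linspace(0.004, 0.064, 5):
        pp = p.replace(lambda0=float(lam))
        sh = solve_shape(single_domain_profiles(pp, sigma0=0.0), pp, config=cfg)
        R = equilibrium_tube_radius(p.kappa, float(lam))
        mid = np.argmin(np.abs(sh.s - 0.5 * (sh.s[0] + sh.s[-1])))
        worst = max(worst, abs(sh.r[mid] - R) / R)
    record("cylinder_closed_form", worst, 0.005 * tolerance_factor)

    # 2. small-deformation agreement with the cylindrical-bead formula
    br = continuation(
        np.linspace(0.0, 2e-5, 9),
        lambda v: single_domain_profiles(p, sigma0=float(v)),
        p,
        config=cfg,
    )
    sh = br.shapes[-1]
    rb_num = sh.r_max
    rb_an = bead_radius_analytic(AnalyticInput(sigma=2e-5, params=p))
    record("small_sigma_analytic", abs(rb_num - rb_an) / rb_an, 0.10 * tolerance_factor)

    # 3. stationarity of the solved states
    record("stationarity_cylinder",
           verify_stationarity(br.shapes[0]), 1e-4 * tolerance_factor)
    record("stationarity_bead", verify_stationarity(sh), 1e-4 * tolerance_factor)

    # 4. mirror symmetry in full-domain mode
    full_cfg = SolverConfig(
        mesh_size=cfg.mesh_size, tolerance=cfg.tolerance, max_nodes=cfg.max_nodes,
        symmetry_mode="full",
    )
    shf = solve_shape(single_domain_profiles(p, sigma0=1e-5), p,
                      guess=br.shapes[4], config=full_cfg)
    dense = shf.resample(2001)
    asym = float(np.max(np.abs(dense.r - dense.r[::-1]))) / p.Rc
    record("mirror_symmetry", asym, 1e-3 * tolerance_factor)

    # 5. mesh convergence of the bead radius
    fine_cfg = SolverConfig(
        mesh_size=2 * cfg.mesh_size, tolerance=cfg.tolerance, max_nodes=cfg.max_nodes,
    )
    br_fine = continuation(
        np.linspace(0.0, 2e-5, 9),
        lambda v: single_domain_profiles(p, sigma0=float(v)),
        p,
        config=fine_cfg,
    )
    record("mesh_convergence",
           abs(br_fine.shapes[-1].r_max - rb_num) / rb_num, 0.002 * tolerance_factor)

    # 6. tension drop monotone along the density sweep
    min_lam = np.array([float(np.min(s.lam)) for s in br.shapes])
    drops = np.diff(min_lam)
    record("tension_drop_monotone", float(np.max(drops[1:])), 0.0, ok=bool(np.all(drops[1:] < 1e-12)))

    report["all_passed"] = all(
        v["passed"] for k, v in report.items() if isinstance(v, dict)
    )
    out = _outdir(config)
    if out is not None:
        _write_json(out / "validation.json", report)
    return report
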