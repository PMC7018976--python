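"""Physical parameters of the heterogeneous-nanotube model.

All quantities are kept in the "membrane" unit system used throughout the
package: lengths in nm, forces in pN, energies in pN·nm, tensions in pN/nm,
densities in nm⁻².
"""

from __future__ import annotations

import dataclasses
import pathlib
from dataclasses import dataclass
from typing import Any, Mapping

__all__ = ["ModelParameters", "load_parameters"]


@dataclass(frozen=True)
class ModelParameters:
    """Physical constants of the membrane-nanotube model.

    Parameters
    ----------
    kappa : float
        Bending rigidity of the bare lipid membrane [pN·nm].
    alpha : float
        Strength of the attractive protein-protein (aggregation)
        interaction [pN·nm³].
    beta : float
        Penalty coefficient on protein-density gradients [pN·nm⁴].  The
        default is 0 (term off); a representative nonzero value for
        sensitivity studies is ``beta = 1e10`` pN·nm⁴, for which the
        gradient energy β(σ′)² stays below 10% of the aggregation energy
        ασ² for the default tanh profiles.
    mu : float
        Lipid–protein interaction length scale [nm].
    phi : float
        Cone angle of the membrane proteins (dimensionless, ≤ 0).  Cone
        shaped proteins with φ < 0 induce a negative spontaneous
        curvature C = μφσ; φ = 0 models cylindrical inclusions that
        change composition without curving the membrane.
    lambda0 : float
        Membrane tension applied at the tube edge [pN/nm].
    p : float
        Transmembrane pressure [pN/nm²]; 0 throughout this model.
    Rc : float
        Nanotube radius [nm].
    Lc : float
        Nanotube length [nm].
    kBT : float
        Thermal energy [pN·nm].
    sigma_s : float
        Saturation protein density [nm⁻²]; only used by the (optional)
        entropic term.
    include_entropy : bool
        Whether the entropic k_BT σ(log(σ/σ_s) − 1) term is included in
        energy evaluations.  Off by default: for all parameter
        combinations in the documented ranges k_BT·σ ≪ 1 and the term is
        negligible against bending.
    """

    kappa: float = 320.0
    alpha: float = 1.28e7
    beta: float = 0.0
    mu: float = 200.0
    phi: float = -1.0
    lambda0: float = 0.064
    p: float = 0.0
    Rc: float = 35.0
    Lc: float = 2.0e4
    kBT: float = 4.114
    sigma_s: float = 3.75e-4
    include_entropy: bool = False

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if self.Rc <= 0 or self.Lc <= 0:
            raise ValueError("Rc and Lc must be positive")
        if self.lambda0 < 0:
            raise ValueError(f"lambda0 must be non-negative, got {self.lambda0}")
        if self.phi > 0:
            raise ValueError(
                "phi must be <= 0: the model assumes cone-shaped proteins "
                "inducing a negative spontaneous curvature (phi = 0 switches "
                "curvature induction off)"
            )
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")
        if self.include_entropy and self.sigma_s <= 0:
            raise ValueError("sigma_s must be positive when include_entropy is on")

    def replace(self, **changes: Any) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    # -- convenience derived scalars ------------------------------------
    @property
    def H0(self) -> float:
        """Mean curvature of the undeformed tube, 1/(2 R_c) [nm⁻¹]."""
        return 1.0 / (2.0 * self.Rc)

    @property
    def W0(self) -> float:
        """Energy density of the bare tube, κ H₀² [pN/nm]."""
        return self.kappa * self.H0**2

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(
                f"unknown parameter keys: {sorted(unknown)}; "
                f"recognized keys are {sorted(known)}"
            )
        return cls(**dict(data))


def load_parameters(path: str | pathlib.Path) -> ModelParameters:
    """Load :class:`ModelParameters` from a YAML or TOML file.

    The file must contain a flat mapping whose keys are parameter names
    (optionally nested under a ``parameters`` section).  Unknown keys are
    rejected.
    """
    path = pathlib.Path(path)
    text = path.read_text()
    if path.suffix in {".toml", ".tml"}:
        import tomllib

        data = tomllib.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path} does not contain a parameter mapping")
    if "parameters" in data and isinstance(data["parameters"], Mapping):
        data = data["parameters"]
    return ModelParameters.from_dict(data)
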