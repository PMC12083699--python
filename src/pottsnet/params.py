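"""Model parameters for the Cellular-Potts vasculogenesis simulator.

The parameter set follows the published vasculogenesis model: cells carry a
soft volume and surface constraint, adhere to one another more strongly than
to medium (``j_cell_cell < j_cell_medium``), and chemotax up the gradient of a
cytokine they secrete themselves.  The chemical field obeys a
secretion-diffusion-decay PDE solved on the same periodic lattice.

Units: the lattice spacing and one Monte-Carlo step (MCS) are the units of
length and time.  Energies are in units of the Potts temperature scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

from .errors import ParameterError

#: Neighbor offsets by order: 1 = von Neumann (4), 2 = Moore (8).
NEIGHBOR_OFFSETS = {
    1: ((-1, 0), (1, 0), (0, -1), (0, 1)),
    2: ((-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)),
}


@dataclass
class CPMParams:
    """All constants of the energy functional, the field PDE and the lattice.

    Attributes
    ----------
    lambda_volume : float
        Stiffness of the quadratic volume constraint (energy / pixel^2).
    v_target : float
        Target cell volume in pixels.
    lambda_surface : float
        Stiffness of the quadratic surface constraint.
    s_target : float
        Target cell circumference (in scaled contact units, see
        ``surface_scale``).
    j_cell_medium, j_cell_cell : float
        Contact energies per heterotypic neighbor contact.
    lambda_chemotaxis : float
        Strength of the saturating chemotaxis bias.
    s_saturation : float
        Saturation constant: the chemotactic drive is ``c / (s*c + 1)``.
    k_decay : float
        First-order decay rate of the chemical field (1 / MCS).
    temperature : float
        Boltzmann temperature H' of the copy-acceptance function.
    d_diffusion : float
        Diffusion constant D (pixel^2 / MCS).  D and the secretion rate are
        free constants of the model (the published table omits them).  The
        default gives a short decay length sqrt(D/k) of ~2 pixels: the
        attractant is then a thin halo around the vessel surface, which is
        the regime where the network morphology stays fine-grained and
        persists (slow coarsening) over the 20,000-MCS horizon the training
        protocol requires; longer decay lengths collapse the pattern into a
        few large aggregates within a few thousand MCS.
    secretion_rate : float
        Field added per MCS at every cell-occupied site.  Default equals
        ``k_decay`` so the steady-state plateau concentration inside broad
        vessel regions is 1.0 (which is also the default encoding scale).
    lattice_size : int
        Side of the square periodic lattice.
    pde_substeps_per_mcs : int
        Forward-Euler substeps per MCS; dt = 1/substeps must satisfy the
        explicit stability bound dt <= 1/(4 D).
    neighbor_order : int
        Neighborhood for copy-attempt pairs and the contact-energy sum
        (2 = Moore 8-neighborhood, the common CPM-framework default).
    surface_neighbor_order : int
        Neighborhood used to count a cell's boundary contacts
        (1 = von Neumann, the usual 2-D perimeter estimator).
    surface_scale : float
        Factor applied to the raw boundary-contact count in the energy so
        that a compact cell of ``v_target`` pixels sits near ``s_target``
        (a minimal-perimeter 50-pixel cell has 30 four-neighbor contacts;
        0.56 * 30 = 16.8).
    """

    lambda_volume: float = 5.0
    v_target: float = 50.0
    lambda_surface: float = 1.0
    s_target: float = 16.8
    j_cell_medium: float = 8.2
    j_cell_cell: float = 6.0
    lambda_chemotaxis: float = 2000.0
    s_saturation: float = 0.5
    k_decay: float = 0.6
    temperature: float = 8.0
    d_diffusion: float = 3.0
    secretion_rate: float = 0.6
    lattice_size: int = 256
    pde_substeps_per_mcs: int = 13
    neighbor_order: int = 2
    surface_neighbor_order: int = 1
    surface_scale: float = 0.56

    def __post_init__(self):
        nonneg = (
            "lambda_volume", "lambda_surface", "lambda_chemotaxis",
            "j_cell_medium", "j_cell_cell", "k_decay", "d_diffusion",
            "secretion_rate", "s_saturation", "surface_scale",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.temperature <= 0:
            raise ParameterError("temperature must be > 0")
        if self.lattice_size < 8:
            raise ParameterError("lattice_size must be >= 8")
        if self.v_target <= 0:
            raise ParameterError("v_target must be > 0")
        if self.neighbor_order not in NEIGHBOR_OFFSETS:
            raise ParameterError("neighbor_order must be 1 or 2")
        if self.surface_neighbor_order not in NEIGHBOR_OFFSETS:
            raise ParameterError("surface_neighbor_order must be 1 or 2")
        if self.pde_substeps_per_mcs < 1:
            raise ParameterError("pde_substeps_per_mcs must be >= 1")
        # Positivity-preserving explicit bound dt <= 1/(4D + k): strictly
        # inside the von Neumann limit 2/(8D + k), and strong enough that the
        # negative-clip safeguard never has to fire (which would inject mass).
        bound = self.stable_dt_bound()
        if self.dt > bound + 1e-12:
            raise ParameterError(
                f"dt = 1/{self.pde_substeps_per_mcs} violates the "
                f"positivity/stability bound dt <= 1/(4 D + k) = {bound:g}")

    def stable_dt_bound(self) -> float:
        denom = 4.0 * self.d_diffusion + self.k_decay
        return 1.0 / denom if denom > 0 else float("inf")

    @property
    def dt(self) -> float:
        """PDE time step: one MCS is one time unit split into substeps."""
        return 1.0 / self.pde_substeps_per_mcs

    @property
    def copy_offsets(self) -> np.ndarray:
        return np.asarray(NEIGHBOR_OFFSETS[self.neighbor_order], dtype=np.int64)

    @property
    def surface_offsets(self) -> np.ndarray:
        return np.asarray(NEIGHBOR_OFFSETS[self.surface_neighbor_order], dtype=np.int64)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CPMParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CPMParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
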