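"""PISA-wheel forward model.

Back-calculates the anisotropic ¹⁵N chemical shift (CS) and ¹⁵N-¹H dipolar
coupling (DC) observed in a separated-local-field spectrum for each residue
of an ideal helix at a whole-body topology (tilt θ, rotation ρ, order
parameter S).

Physics: in a flipped bicelle the membrane normal n is parallel to B0, so
the observed CS is the projection of the (rigid) ¹⁵N shift tensor onto the
membrane normal and the observed DC is ν∥·P2(cos θ_NH), where θ_NH is the
angle between the N-H bond and the normal.  The scalar order parameter S
uniformly scales the anisotropic part of both observables about the
isotropic shift (for CS) and about zero (for DC).  In unflipped bicelles
(n ⊥ B0) fast rotation about the normal scales both anisotropic parts by
an additional factor of −1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import HelixGeometry
from .peaklist import Peak, PeakList

#: residue numbering offset used when back-calculating for labelled residues
_DEFAULT_N_RES = 60


@dataclass(frozen=True)
class TensorParameters:
    """¹⁵N shift-tensor and dipolar-coupling constants.

    ``delta11 <= delta22 <= delta33`` are the tensor principal values (ppm);
    ``delta33`` lies in the peptide plane tilted ``beta_33_nh`` degrees from
    the N-H bond (toward the preceding carbonyl carbon for positive values)
    and ``delta22`` is perpendicular to the peptide plane.  ``nu_parallel``
    is the rigid-lattice ¹⁵N-¹H coupling (kHz) for a bond parallel to B0.
    These are configuration, not hard-coded physics: they are the standard
    amide-¹⁵N literature values and can be overridden wholesale.
    """

    delta11: float = 57.3
    delta22: float = 81.2
    delta33: float = 228.1
    beta_33_nh: float = 19.6
    nu_parallel: float = 10.735
    alignment_mode: str = "flipped"  # {"flipped", "unflipped"}

    def __post_init__(self) -> None:
        if not (self.delta11 <= self.delta22 <= self.delta33):
            raise ValueError("tensor principal values must satisfy d11 <= d22 <= d33")
        if self.alignment_mode not in ("flipped", "unflipped"):
            raise ValueError(f"unknown alignment_mode {self.alignment_mode!r}")

    @property
    def delta_iso(self) -> float:
        return (self.delta11 + self.delta22 + self.delta33) / 3.0

    @property
    def mode_factor(self) -> float:
        """Scaling of anisotropic observables by the bicelle alignment."""
        return 1.0 if self.alignment_mode == "flipped" else -0.5


@dataclass
class TopologyState:
    """Whole-body helix topology: tilt θ [0, 90]°, rotation ρ [0, 360)°
    referenced to a named residue, and order parameter S in [0, 1]."""

    theta: float
    rho: float
    s: float = 1.0

    def __post_init__(self) -> None:
        self.theta = float(np.clip(self.theta, 0.0, 90.0))
        self.rho = float(np.mod(self.rho, 360.0))
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"order parameter S={self.s} outside [0, 1]")


def residue_phase(geometry: HelixGeometry, residue_index: int,
                  reference_index: int, rho: float,
                  n_residues: int = _DEFAULT_N_RES) -> float:
    """Azimuthal position (degrees) of a residue's N-H about the helix axis.

    The phase of the reference residue is ρ by definition and successive
    residues advance by 360/residues_per_turn (≈100° for the ideal helix).
    """
    if not (0 <= residue_index < n_residues and 0 <= reference_index < n_residues):
        raise ValueError("residue index outside modeled sequence")
    frames = geometry.residue_frames(n_residues)
    dphi = _phase_sign(geometry) * (
        frames["phase"][residue_index] - frames["phase"][reference_index])
    return float(np.mod(rho + dphi, 360.0))


def _phase_sign(geometry: HelixGeometry) -> float:
    """Orient the azimuth convention so the residue phase advances by
    +|Δ| per residue going N→C (the PISA-wheel traversal direction)."""
    return 1.0 if geometry.phase_per_residue >= 0 else -1.0


class WheelModel:
    """Vectorized forward model for a fixed geometry/tensor configuration.

    Precomputes, in the helix frame, each residue's N-H direction and full
    shift tensor so that observables for arbitrary (θ, ρ) arrays reduce to
    a projection onto the B0 direction.
    """

    #: handedness of the ρ convention (negative = left-handed about the
    #: N→C axis) and the fixed offset of the ρ zero direction from the
    #: reference residue's amide N-H azimuth; both are pure gauge choices
    #: fixed package-wide so spectral fits and coordinate analyses agree
    #: and so that ρ values are directly comparable across datasets.
    RHO_SIGN = -1.0
    RHO_ZERO = 203.0

    def __init__(self, geometry: HelixGeometry, tensors: TensorParameters,
                 residues: np.ndarray, reference_index: int,
                 n_residues: int = _DEFAULT_N_RES):
        residues = np.asarray(residues, dtype=int)
        if residues.size == 0:
            raise ValueError("empty residue list")
        if residues.min() < 1 or residues.max() >= n_residues:
            raise ValueError("residue outside modeled sequence")
        self.geometry = geometry
        self.tensors = tensors
        self.residues = residues
        self.reference_index = reference_index
        frames = geometry.residue_frames(n_residues)
        self._nh = frames["nh"][residues]                      # (R, 3)
        self._sigma = self._build_tensors(frames, residues)    # (R, 3, 3)
        sgn = _phase_sign(geometry)
        self._ref_phase = frames["phase"][reference_index]
        self._sgn = sgn

    def _build_tensors(self, frames: dict, residues: np.ndarray) -> np.ndarray:
        t = self.tensors
        nh = frames["nh"][residues]
        pn = frames["plane_normal"][residues]
        # in-plane unit vector perpendicular to N-H, pointing toward C'(i-1)
        nc = frames["nc_prev"][residues]
        m = nc - np.sum(nc * nh, axis=1, keepdims=True) * nh
        m /= np.linalg.norm(m, axis=1, keepdims=True)
        beta = np.deg2rad(t.beta_33_nh)
        e3 = np.cos(beta) * nh + np.sin(beta) * m
        e2 = pn
        e1 = np.cross(e2, e3)
        sigma = (t.delta11 * np.einsum("ri,rj->rij", e1, e1)
                 + t.delta22 * np.einsum("ri,rj->rij", e2, e2)
                 + t.delta33 * np.einsum("ri,rj->rij", e3, e3))
        return sigma

    def b_direction(self, theta, rho) -> np.ndarray:
        """Unit B0 direction(s) in the helix frame for topology angles in
        degrees; broadcasts over arrays."""
        th = np.deg2rad(np.asarray(theta, dtype=float))
        alpha = np.deg2rad(self._ref_phase) - self.RHO_SIGN * self._sgn * np.deg2rad(
            np.asarray(rho, dtype=float) - self.RHO_ZERO)
        th, alpha = np.broadcast_arrays(th, alpha)
        return np.stack([np.sin(th) * np.cos(alpha),
                         np.sin(th) * np.sin(alpha),
                         np.cos(th)], axis=-1)

    def rigid_observables(self, theta, rho) -> tuple[np.ndarray, np.ndarray]:
        """Rigid-lattice (S=1, flipped) observables.

        Returns (cs, dc) arrays of shape broadcast(theta, rho) + (R,).
        """
        b = self.b_direction(theta, rho)
        cs = np.einsum("...i,rij,...j->...r", b, self._sigma, b)
        cb = np.einsum("...i,ri->...r", b, self._nh)
        dc = self.tensors.nu_parallel * 0.5 * (3.0 * cb ** 2 - 1.0)
        return cs, dc

    def observables(self, topology: TopologyState) -> tuple[np.ndarray, np.ndarray]:
        """Observed (cs ppm, dc kHz) per residue after S- and mode-scaling."""
        cs0, dc0 = self.rigid_observables(topology.theta, topology.rho)
        f = topology.s * self.tensors.mode_factor
        iso = self.tensors.delta_iso
        return iso + f * (cs0 - iso), f * dc0


def back_calc_observables(topology: TopologyState, geometry: HelixGeometry,
                          tensors: TensorParameters, residues,
                          reference_index: int = 31) -> dict[int, tuple[float, float]]:
    """Per-residue (cs ppm, dc kHz) for an ideal helix at the given topology."""
    residues = np.asarray(residues, dtype=int)
    model = WheelModel(geometry, tensors, residues, reference_index)
    cs, dc = model.observables(topology)
    return {int(r): (float(c), float(d)) for r, c, d in zip(residues, cs, dc)}


def simulate_wheel(topology: TopologyState, geometry: HelixGeometry,
                   tensors: TensorParameters, residues,
                   reference_index: int = 31,
                   residue_names: dict[int, str] | None = None,
                   dataset_id: str = "simulated",
                   intensity: float = 1.0) -> PeakList:
    """Simulate an assigned peak list for a helix at the given topology."""
    residues = list(residues)
    if not residues:
        raise ValueError("empty residue list")
    obs = back_calc_observables(topology, geometry, tensors, residues,
                                reference_index)
    peaks = []
    for r in residues:
        name = (residue_names or {}).get(r, "X")
        cs, dc = obs[r]
        # spectral peak lists carry the unsigned dipolar splitting
        peaks.append(Peak(residue_label=f"{name}{r}", cs=cs, dc=abs(dc),
                          intensity=intensity))
    return PeakList(dataset_id=dataset_id, peaks=peaks,
                    reference_residue=f"X{reference_index}"
                    if residue_names is None else
                    f"{residue_names.get(reference_index, 'X')}{reference_index}")
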