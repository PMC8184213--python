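"""Ideal-helix backbone geometry.

Builds explicit backbone coordinates (N, H, Cα, C') for a uniform helix with
identical (φ, ψ) at every residue, and derives from those coordinates the
quantities the PISA forward model needs: the helix axis, the per-residue
azimuthal phase, the N–H bond direction, and the peptide-plane frame that
anchors the ¹⁵N chemical-shift tensor.

Coordinate convention used throughout the package: the membrane normal is
+z and coincides with the magnetic field B0 in flipped-bicelle mode; the
helix axis points from the N- to the C-terminus; the tilt θ is the angle
between the axis and +z; the rotation ρ increases with right-handed rotation
of the helix about its own axis and is referenced to the azimuth of the
reference residue's N–H bond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Engh-Huber backbone bond lengths (Å) and angles (deg)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_OMEGA = 180.0


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D from A-B-C."""
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class HelixGeometry:
    """Uniform ideal-helix geometry.

    Parameters
    ----------
    phi, psi : backbone dihedrals in degrees; (−63, −42) is the ideal
        transmembrane helix used for PISA-wheel analysis.
    ca_n_h_angle : Cα-N-H bond angle in degrees. The amide proton is placed
        in the peptide plane, trans to the carbonyl of the preceding residue.
    n_h_bond_length : N-H bond length in Å (affects only the H position,
        not the N-H direction).
    """

    phi: float = -63.0
    psi: float = -42.0
    ca_n_h_angle: float = 119.0
    n_h_bond_length: float = 1.02

    def __post_init__(self) -> None:
        self._cache: dict = {}

    # -- backbone construction -------------------------------------------

    def build_backbone(self, n_residues: int) -> dict[str, np.ndarray]:
        """Explicit coordinates for ``n_residues`` residues.

        Returns a dict of (n_residues, 3) arrays for atoms N, H, CA, C.
        The first residue has no preceding carbonyl, so its H direction is
        copied from the second residue's local frame; amide observables are
        only ever evaluated for interior residues.
        """
        key = ("bb", n_residues)
        if key in self._cache:
            return self._cache[key]
        n = np.zeros((n_residues, 3))
        ca = np.zeros((n_residues, 3))
        c = np.zeros((n_residues, 3))
        n[0] = (0.0, 0.0, 0.0)
        ca[0] = (_B_N_CA, 0.0, 0.0)
        ang = np.deg2rad(_A_N_CA_C)
        c[0] = ca[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        for i in range(n_residues - 1):
            n[i + 1] = _place_atom(n[i], ca[i], c[i], _B_C_N, _A_CA_C_N, self.psi)
            ca[i + 1] = _place_atom(ca[i], c[i], n[i + 1], _B_N_CA, _A_C_N_CA, _OMEGA)
            c[i + 1] = _place_atom(c[i], n[i + 1], ca[i + 1], _B_CA_C, _A_N_CA_C, self.phi)
        h = np.zeros((n_residues, 3))
        for i in range(1, n_residues):
            h[i] = self._place_amide_h(c[i - 1], n[i], ca[i])
        # residue 0 has no amide frame; reuse the i=1 N->H offset
        h[0] = n[0] + (h[1] - n[1])
        out = {"N": n, "H": h, "CA": ca, "C": c}
        self._cache[key] = out
        return out

    def _place_amide_h(self, c_prev: np.ndarray, n: np.ndarray,
                       ca: np.ndarray) -> np.ndarray:
        u1 = ca - n
        u1 /= np.linalg.norm(u1)
        u2 = c_prev - n
        u2 /= np.linalg.norm(u2)
        t1 = np.deg2rad(self.ca_n_h_angle)
        # planar nitrogen: the three angles around N sum to 360 deg
        t2 = np.deg2rad(360.0 - _A_C_N_CA - self.ca_n_h_angle)
        g = u1 @ u2
        mat = np.array([[1.0, g], [g, 1.0]])
        rhs = np.array([np.cos(t1), np.cos(t2)])
        a, b = np.linalg.solve(mat, rhs)
        d = a * u1 + b * u2
        d /= np.linalg.norm(d)
        return n + self.n_h_bond_length * d

    # -- derived helix parameters ----------------------------------------

    def helix_axis(self, n_residues: int = 40) -> tuple[np.ndarray, np.ndarray]:
        """(axis unit vector N→C, centroid).

        The axis is the screw axis of the exact rigid transform carrying
        one residue's backbone triad onto the next — exact for this
        uniform helix, unlike a fitted line through Cα positions.
        """
        key = ("axis", n_residues)
        if key in self._cache:
            return self._cache[key]
        bb = self.build_backbone(n_residues)
        i = n_residues // 2
        p = np.stack([bb[a][i] for a in ("N", "CA", "C")])
        q = np.stack([bb[a][i + 1] for a in ("N", "CA", "C")])
        pc = p - p.mean(axis=0)
        qc = q - q.mean(axis=0)
        u, _, vt = np.linalg.svd(pc.T @ qc)
        d = np.sign(np.linalg.det(u @ vt))
        rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T   # rot @ pc ≈ qc
        from scipy.spatial.transform import Rotation
        axis = Rotation.from_matrix(rot).as_rotvec()
        axis /= np.linalg.norm(axis)
        if axis @ (bb["CA"][i + 1] - bb["CA"][i]) < 0:
            axis = -axis
        ctr = smooth_ca(bb["CA"]).mean(axis=0)
        out = (axis, ctr)
        self._cache[key] = out
        return out

    @property
    def rise_per_residue(self) -> float:
        """Translation per residue along the helix axis, Å."""
        bb = self.build_backbone(40)
        axis, _ = self.helix_axis(40)
        z = bb["CA"] @ axis
        return float(np.mean(np.diff(z)))

    @property
    def phase_per_residue(self) -> float:
        """Azimuthal advance per residue about the helix axis, degrees.

        Positive values mean a right-handed advance going N→C when viewed
        along the axis (looking from C-terminus toward N-terminus).
        """
        key = "phase"
        if key in self._cache:
            return self._cache[key]
        bb = self.build_backbone(40)
        axis, ctr = self.helix_axis(40)
        phases = _azimuths(bb["CA"][5:35], axis, ctr)
        d = np.rad2deg(np.diff(phases))
        d = (d + 180.0) % 360.0 - 180.0
        val = float(d.mean())
        self._cache[key] = val
        return val

    @property
    def residues_per_turn(self) -> float:
        return 360.0 / abs(self.phase_per_residue)

    # -- per-residue frames in the helix frame ---------------------------

    def residue_frames(self, n_residues: int = 40) -> dict[str, np.ndarray]:
        """Per-residue amide geometry expressed in the canonical helix frame.

        The helix frame has +z along the axis (N→C).  Returns dict with
        keys ``nh`` (unit N→H vectors), ``plane_normal`` (unit peptide-plane
        normals), ``nc_prev`` (unit N→C'(i−1) vectors) and ``phase``
        (azimuth of each residue's N-H about the axis, degrees), all
        (n_residues, ...) with residue 0 repeated from residue 1.
        """
        key = ("frames", n_residues)
        if key in self._cache:
            return self._cache[key]
        bb = self.build_backbone(n_residues)
        axis, ctr = self.helix_axis(n_residues)
        rot = _frame_rotation(axis)
        n = (bb["N"] - ctr) @ rot.T
        h = (bb["H"] - ctr) @ rot.T
        ca = (bb["CA"] - ctr) @ rot.T
        c = (bb["C"] - ctr) @ rot.T
        nh = h - n
        nh /= np.linalg.norm(nh, axis=1, keepdims=True)
        nc = np.empty_like(nh)
        nc[1:] = c[:-1] - n[1:]
        nc[0] = nc[1]
        nc /= np.linalg.norm(nc, axis=1, keepdims=True)
        pn = np.cross(nc, ca - n)
        pn /= np.linalg.norm(pn, axis=1, keepdims=True)
        phase = np.rad2deg(np.arctan2(nh[:, 1], nh[:, 0]))
        phase[0] = phase[1] - self.phase_per_residue
        out = {"nh": nh, "plane_normal": pn, "nc_prev": nc, "phase": phase}
        self._cache[key] = out
        return out


def smooth_ca(ca: np.ndarray, window: int = 4) -> np.ndarray:
    """Local-centroid smoothing of Cα positions over ~one helical turn.

    Averaging four consecutive Cα atoms cancels the helical wobble, leaving
    points that lie on the helix axis; used both here and by the trajectory
    analysis to define the axis of a (possibly distorted) helix.
    """
    if len(ca) < window:
        raise ValueError(f"need at least {window} CA positions, got {len(ca)}")
    kernel = np.ones(window) / window
    out = np.empty((len(ca) - window + 1, 3))
    for k in range(3):
        out[:, k] = np.convolve(ca[:, k], kernel, mode="valid")
    return out


def _frame_rotation(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix whose rows are an orthonormal frame with row 2 = axis."""
    z = axis / np.linalg.norm(axis)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(z @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    x = seed - (seed @ z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def _azimuths(points: np.ndarray, axis: np.ndarray, ctr: np.ndarray) -> np.ndarray:
    rot = _frame_rotation(axis)
    p = (points - ctr) @ rot.T
    return np.arctan2(p[:, 1], p[:, 0])
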