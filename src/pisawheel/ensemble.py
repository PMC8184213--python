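"""Coordinate-ensemble analysis.

Metrics computed on multi-model coordinate ensembles (MD samples or NMR
bundles): helix tilt/rotation from Cα geometry, residue contact
frequencies, hydrogen-bond counts, backbone PCA with structure projections,
Kullback-Leibler-divergence convergence monitoring of the PCA histogram,
and inter-helix tilt-correlation maps.

The tilt/rotation convention is shared with the spectral forward model:
membrane normal = +z, θ is the angle of the N→C helix axis to +z, ρ is
referenced to a residue with the same zero and handedness used by
``pisawheel.wheel``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import smooth_ca, _frame_rotation
from .wheel import WheelModel


# ---------------------------------------------------------------------------
# container

@dataclass
class TrajectoryEnsemble:
    """Frames of labelled atomic coordinates (Å).

    All frames share one atom table (columns ``name``, ``resid``,
    ``resname``, ``chain``, ``element``).
    """

    coordinates: np.ndarray          # (n_frames, n_atoms, 3)
    atoms: pd.DataFrame
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if len(self.atoms) != self.coordinates.shape[1]:
            raise ValueError("atom table does not match coordinate array")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def select(self, *, chain=None, resids=None, names=None,
               resnames=None, elements=None) -> np.ndarray:
        """Indices of atoms matching every given criterion."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= (self.atoms["chain"] == chain).to_numpy()
        if resids is not None:
            mask &= self.atoms["resid"].isin(np.atleast_1d(resids)).to_numpy()
        if names is not None:
            mask &= self.atoms["name"].isin(np.atleast_1d(names)).to_numpy()
        if resnames is not None:
            mask &= self.atoms["resname"].isin(np.atleast_1d(resnames)).to_numpy()
        if elements is not None:
            mask &= self.atoms["element"].isin(np.atleast_1d(elements)).to_numpy()
        return np.flatnonzero(mask)

    @classmethod
    def from_pdb(cls, path) -> "TrajectoryEnsemble":
        """Read a (multi-model) PDB file."""
        import MDAnalysis as mda
        u = mda.Universe(str(path))
        coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory])
        try:
            elements = u.atoms.elements
        except Exception:
            elements = np.array([_guess_element(n) for n in u.atoms.names])
        try:
            chains = u.atoms.chainIDs
        except Exception:
            chains = u.atoms.segids
        atoms = pd.DataFrame({
            "name": u.atoms.names, "resid": u.atoms.resids,
            "resname": u.atoms.resnames, "chain": chains,
            "element": elements,
        })
        return cls(coordinates=coords.astype(float), atoms=atoms)

    def to_pdb(self, path) -> None:
        """Write the ensemble as a multi-model PDB."""
        import MDAnalysis as mda
        n_res = self.atoms["resid"].nunique()
        resid_order = self.atoms["resid"].drop_duplicates().to_numpy()
        res_index = {r: i for i, r in enumerate(resid_order)}
        u = mda.Universe.empty(self.n_atoms, n_residues=n_res,
                               atom_resindex=[res_index[r] for r in
                                              self.atoms["resid"]],
                               trajectory=True)
        u.add_TopologyAttr("names", self.atoms["name"].to_list())
        u.add_TopologyAttr("resids", resid_order)
        first = self.atoms.drop_duplicates("resid")
        u.add_TopologyAttr("resnames", first["resname"].to_list())
        u.add_TopologyAttr("elements", self.atoms["element"].to_list())
        u.add_TopologyAttr("chainIDs", self.atoms["chain"].to_list())
        u.load_new(self.coordinates.astype(np.float32), format="memory")
        with mda.Writer(str(path), multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def _guess_element(name: str) -> str:
    name = name.strip()
    return name[0] if name else "X"


@dataclass
class ContactSpec:
    """Contact criterion: any-atom distance below ``cutoff`` Å."""
    cutoff: float = 3.5


@dataclass
class HBondSpec:
    """Hydrogen-bond criterion: donor-acceptor distance below
    ``distance_cutoff`` Å and donor-H···acceptor deviation from linearity
    below ``angle_cutoff`` degrees."""
    distance_cutoff: float = 3.0
    angle_cutoff: float = 20.0


# ---------------------------------------------------------------------------
# helix topology from coordinates

def helix_axis(ca_positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axis (unit, N→C) and centroid from ≥7 consecutive Cα positions.

    Two stages: the best-fit line through locally-smoothed Cα positions
    (robust, fixes the orientation), refined by the bisector construction —
    for consecutive Cα triplets the vector sum of the two bonds at the
    middle atom points radially at the axis, so cross products of
    consecutive bisectors lie along the axis.  The refinement is exact for
    an ideal uniform helix; the line fit alone carries a small bias from
    the fractional number of residues per turn.
    """
    ca_positions = np.asarray(ca_positions, dtype=float)
    if len(ca_positions) < 7:
        raise ValueError(f"need at least 7 consecutive CA positions, "
                         f"got {len(ca_positions)}")
    sm = smooth_ca(ca_positions)
    ctr = sm.mean(axis=0)
    _, _, vt = np.linalg.svd(sm - ctr)
    axis = vt[0]
    if axis @ (sm[-1] - sm[0]) < 0:
        axis = -axis
    d = np.diff(ca_positions, axis=0)
    v = d[1:] - d[:-1]                      # bisectors, radial at the axis
    cr = np.cross(v[:-1], v[1:])
    norms = np.linalg.norm(cr, axis=1)
    ok = norms > 1e-10
    if ok.any():
        cr = cr[ok] / norms[ok, None]
        cr *= np.sign(cr @ axis)[:, None]
        refined = cr.mean(axis=0)
        n = np.linalg.norm(refined)
        if n > 1e-8:
            axis = refined / n
    return axis, ctr


def helix_axis_and_topology(ens: TrajectoryEnsemble, helix_resids,
                            frame: int = 0, chain=None,
                            reference_residue: int | None = None
                            ) -> tuple[float, float]:
    """(θ, ρ) of one helix in one frame.

    θ is the angle between the N→C axis and +z.  ρ uses the package's
    spectral convention when the reference residue has an amide H (N-H
    azimuth, fixed zero offset); without hydrogens the Cα radial direction
    is used instead, which shifts the zero by a constant.  Returns
    (θ, nan) when the helix is axial (ρ undefined).
    """
    helix_resids = np.sort(np.atleast_1d(helix_resids))
    x = ens.coordinates[frame]
    ca_idx = []
    for r in helix_resids:
        idx = ens.select(resids=[r], names=["CA"], chain=chain)
        if len(idx) != 1:
            raise ValueError(f"residue {r}: expected one CA atom, found {len(idx)}")
        ca_idx.append(idx[0])
    ca = x[np.array(ca_idx)]
    axis, ctr = helix_axis(ca)
    theta = float(np.rad2deg(np.arccos(np.clip(axis[2], -1.0, 1.0))))
    ref = reference_residue if reference_residue is not None else \
        helix_resids[len(helix_resids) // 2]
    rot = _frame_rotation(axis)
    z_lab = rot @ np.array([0.0, 0.0, 1.0])
    if np.hypot(z_lab[0], z_lab[1]) < 1e-12:
        return theta, float("nan")
    alpha = np.rad2deg(np.arctan2(z_lab[1], z_lab[0]))
    n_idx = ens.select(resids=[ref], names=["N"], chain=chain)
    h_idx = ens.select(resids=[ref], names=["H", "HN"], chain=chain)
    if len(n_idx) == 1 and len(h_idx) == 1:
        v = x[h_idx[0]] - x[n_idx[0]]
    else:
        v = ca[np.searchsorted(helix_resids, ref)] - ctr
        v = v - (v @ axis) * axis
    vf = rot @ v
    phi_ref = np.rad2deg(np.arctan2(vf[1], vf[0]))
    rho = (WheelModel.RHO_ZERO - phi_ref + alpha) % 360.0
    return theta, float(rho)


def per_frame_tilts(ens: TrajectoryEnsemble, helix_resids,
                    chain=None) -> np.ndarray:
    """Tilt angle (degrees to +z) of one helix in every frame."""
    helix_resids = np.sort(np.atleast_1d(helix_resids))
    ca_idx = np.concatenate([ens.select(resids=[r], names=["CA"], chain=chain)
                             for r in helix_resids])
    out = np.empty(ens.n_frames)
    for f in range(ens.n_frames):
        axis, _ = helix_axis(ens.coordinates[f, ca_idx])
        out[f] = np.rad2deg(np.arccos(np.clip(axis[2], -1.0, 1.0)))
    return out


# ---------------------------------------------------------------------------
# contacts and hydrogen bonds

def _pair_distances(xa: np.ndarray, xb: np.ndarray,
                    box: np.ndarray | None) -> np.ndarray:
    d = xa[:, None, :] - xb[None, :, :]
    if box is not None:
        d -= box * np.round(d / box)
    return np.sqrt((d ** 2).sum(axis=-1))


def contact_frequency(ens: TrajectoryEnsemble, group_a, group_b,
                      spec: ContactSpec | None = None,
                      box: np.ndarray | None = None) -> pd.DataFrame:
    """Per-residue contact statistics for group_a against group_b.

    For each residue in ``group_a``: the fraction of frames in which any of
    its atoms lies strictly within ``spec.cutoff`` of any ``group_b`` atom,
    and the mean number of contacting atom pairs per frame.  ``box`` turns
    on orthorhombic minimum-image distances.
    """
    spec = spec or ContactSpec()
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("empty atom selection")
    res_a = ens.atoms["resid"].to_numpy()[group_a]
    resids = np.unique(res_a)
    hit = np.zeros((ens.n_frames, len(resids)))
    cnt = np.zeros((ens.n_frames, len(resids)))
    rix = {r: i for i, r in enumerate(resids)}
    for f in range(ens.n_frames):
        xa = ens.coordinates[f, group_a]
        xb = ens.coordinates[f, group_b]
        if box is None and len(xa) * len(xb) > 40000:
            tree = cKDTree(xb)
            neigh = tree.query_ball_point(xa, spec.cutoff)
            for ia, nb in enumerate(neigh):
                if not nb:
                    continue
                dd = np.linalg.norm(xb[nb] - xa[ia], axis=1)
                n = int((dd < spec.cutoff).sum())
                if n:
                    j = rix[res_a[ia]]
                    cnt[f, j] += n
                    hit[f, j] = 1.0
        else:
            dmat = _pair_distances(xa, xb, box) < spec.cutoff
            for r in resids:
                sel = dmat[res_a == r]
                j = rix[r]
                cnt[f, j] = sel.sum()
                hit[f, j] = 1.0 if sel.any() else 0.0
    return pd.DataFrame({"resid": resids,
                         "fraction": hit.mean(axis=0),
                         "mean_contacts": cnt.mean(axis=0)}).set_index("resid")


def _donor_pairs(ens: TrajectoryEnsemble, donors) -> list[tuple[int, int]]:
    """Normalize donors to (heavy, hydrogen) index pairs; hydrogens are
    located by covalent distance (< 1.3 Å) within the same residue."""
    pairs = []
    donors = list(donors)
    for d in donors:
        if isinstance(d, (tuple, list, np.ndarray)):
            pairs.append((int(d[0]), int(d[1])))
            continue
        d = int(d)
        row = ens.atoms.iloc[d]
        cand = ens.select(resids=[row["resid"]], elements=["H"])
        if cand.size == 0:
            cand = np.array([i for i in ens.select(resids=[row["resid"]])
                             if ens.atoms.iloc[i]["name"].startswith("H")])
        x0 = ens.coordinates[0]
        cand = [int(c) for c in cand
                if np.linalg.norm(x0[c] - x0[d]) < 1.3]
        if not cand:
            raise ValueError(
                f"donor atom {row['name']} (resid {row['resid']}) has no "
                "attached hydrogen")
        pairs.extend((d, c) for c in cand)
    return pairs


def hbond_table(ens: TrajectoryEnsemble, donors, acceptors,
                spec: HBondSpec | None = None) -> pd.DataFrame:
    """Average hydrogen bonds per frame grouped by (donor, acceptor) residue.

    ``donors`` may be heavy-atom indices (attached hydrogens are found by
    covalent distance; an atom without one raises an error naming it) or
    explicit (donor, hydrogen) index pairs.  A bond is counted when the
    donor-acceptor distance is below the cutoff and the angle between the
    D→H and H→A directions (deviation from a linear D-H···A arrangement)
    is below the angle cutoff.
    """
    spec = spec or HBondSpec()
    pairs = _donor_pairs(ens, donors)
    acceptors = np.asarray(acceptors, dtype=int)
    if not pairs or acceptors.size == 0:
        raise ValueError("empty donor or acceptor selection")
    resid = ens.atoms["resid"].to_numpy()
    counts: dict[tuple[int, int], float] = {}
    cosmax = np.cos(np.deg2rad(spec.angle_cutoff))
    for f in range(ens.n_frames):
        x = ens.coordinates[f]
        for d, h in pairs:
            dv = x[acceptors] - x[d]
            dist = np.linalg.norm(dv, axis=1)
            ok = dist < spec.distance_cutoff
            if not ok.any():
                continue
            dh = x[h] - x[d]
            dh /= np.linalg.norm(dh)
            ha = x[acceptors[ok]] - x[h]
            ha /= np.linalg.norm(ha, axis=1, keepdims=True)
            lin = (ha @ dh) > cosmax
            for a_idx in acceptors[ok][lin]:
                key = (int(resid[d]), int(resid[a_idx]))
                counts[key] = counts.get(key, 0.0) + 1.0
    rows = [{"donor_resid": k[0], "acceptor_resid": k[1],
             "mean_per_frame": v / ens.n_frames}
            for k, v in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["donor_resid", "acceptor_resid",
                                       "mean_per_frame"])


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    mean_coordinates: np.ndarray       # (n_atoms, 3)
    eigenvectors: np.ndarray           # (3*n_atoms, n_modes), columns
    eigenvalues: np.ndarray            # descending, Å²
    variance_fractions: np.ndarray
    projections: list[np.ndarray]      # per source ensemble, (n_frames, n_modes)
    histogram_bins: int = 75


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigid-body superposition of ``mobile`` onto ``target`` (both (N,3))."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return mc @ rot + target.mean(axis=0)


def backbone_pca(ens_list, n_modes: int | None = None,
                 histogram_bins: int = 75, tol: float = 1e-12,
                 max_iter: int = 1000) -> PCAResult:
    """PCA of the coordinate covariance over one or more ensembles.

    Ensembles are combined, iteratively RMS-fit to their overall mean
    (refitting after each mean update until convergence) and the covariance
    matrix of the flattened coordinates is diagonalized.  Projections are
    returned per source ensemble.
    """
    if isinstance(ens_list, TrajectoryEnsemble):
        ens_list = [ens_list]
    shapes = {e.coordinates.shape[1] for e in ens_list}
    if len(shapes) != 1:
        raise ValueError("ensembles carry different atom sets")
    names = [tuple(e.atoms["name"]) for e in ens_list]
    if len(set(names)) != 1:
        raise ValueError("ensembles carry different atom sets")
    x = np.concatenate([e.coordinates for e in ens_list], axis=0).copy()
    mean = x.mean(axis=0)
    for _ in range(max_iter):
        for f in range(len(x)):
            x[f] = _kabsch(x[f], mean)
        new_mean = x.mean(axis=0)
        shift = np.abs(new_mean - mean).max()
        mean = new_mean
        if shift < tol:
            break
    flat = (x - mean).reshape(len(x), -1)
    cov = flat.T @ flat / len(flat)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    if n_modes is not None:
        evals_keep, evecs = evals[:n_modes], evecs[:, :n_modes]
    else:
        evals_keep = evals
    total = evals.sum()
    fractions = evals_keep / total if total > 0 else np.zeros_like(evals_keep)
    proj_all = flat @ evecs
    projections = []
    start = 0
    for e in ens_list:
        projections.append(proj_all[start:start + e.n_frames])
        start += e.n_frames
    return PCAResult(mean_coordinates=mean, eigenvectors=evecs,
                     eigenvalues=evals_keep, variance_fractions=fractions,
                     projections=projections, histogram_bins=histogram_bins)


def project_structure(pca: PCAResult, coordinates: np.ndarray) -> tuple[float, float]:
    """(PC1, PC2) of a single structure after RMS fit to the PCA mean."""
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != pca.mean_coordinates.shape:
        raise ValueError("structure does not match the PCA atom set")
    fitted = _kabsch(coordinates, pca.mean_coordinates)
    p = (fitted - pca.mean_coordinates).reshape(-1) @ pca.eigenvectors[:, :2]
    return float(p[0]), float(p[1])


# ---------------------------------------------------------------------------
# KLD convergence

def kld_convergence(projections: np.ndarray, n_bins_per_axis: int = 75,
                    times: np.ndarray | None = None) -> pd.DataFrame:
    """KLD(t) between the time-truncated and final 2D (PC1, PC2) histograms.

    The histogram spans the full data range per axis (M = n_bins² bins,
    fixed before truncation so p(x, t) and p(x) share bins); bins with
    p(x, t) = 0 contribute nothing, and KLD at the final time is exactly 0.
    """
    p = np.asarray(projections, dtype=float)[:, :2]
    n = len(p)
    if n < 2:
        raise ValueError("need at least two projection points")
    edges = [np.linspace(p[:, k].min(), p[:, k].max(), n_bins_per_axis + 1)
             for k in range(2)]
    ix = [np.clip(np.searchsorted(edges[k], p[:, k], side="right") - 1,
                  0, n_bins_per_axis - 1) for k in range(2)]
    flat = ix[0] * n_bins_per_axis + ix[1]
    final = np.bincount(flat, minlength=n_bins_per_axis ** 2).astype(float)
    p_final = final / n
    if times is None:
        times = np.arange(1, n + 1)
    times = np.asarray(times, dtype=int)
    out = np.empty(len(times))
    running = np.zeros_like(final)
    pos = 0
    order = np.argsort(times)
    for j in order:
        t = times[j]
        while pos < t:
            running[flat[pos]] += 1
            pos += 1
        pt = running / t
        nz = pt > 0
        out[j] = float(np.sum(pt[nz] * np.log(pt[nz] / p_final[nz])))
    return pd.DataFrame({"t": times, "kld": out})


# ---------------------------------------------------------------------------
# tilt correlations

@dataclass
class CorrelationMap:
    helices: list
    matrix: np.ndarray          # Pearson r of tilt fluctuations, nan if undefined
    tilts: np.ndarray           # (n_helices, n_frames)


def tilt_correlation_map(ens: TrajectoryEnsemble, helix_definitions,
                         chains=None, min_frames: int = 10) -> CorrelationMap:
    """Pearson correlation of per-frame tilt fluctuations between helices.

    ``helix_definitions`` is a list of residue-id collections (one per
    helix); constant tilt series yield undefined (NaN) correlations.
    """
    if len(helix_definitions) < 2:
        raise ValueError("need at least two helices")
    if ens.n_frames < min_frames:
        raise ValueError(f"need at least {min_frames} frames, "
                         f"got {ens.n_frames}")
    chains = chains or [None] * len(helix_definitions)
    tilts = np.stack([per_frame_tilts(ens, h, chain=c)
                      for h, c in zip(helix_definitions, chains)])
    centered = tilts - tilts.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    n = len(helix_definitions)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if sd[i] > 0 and sd[j] > 0:
                mat[i, j] = float(np.mean(centered[i] * centered[j])
                                  / (sd[i] * sd[j]))
    return CorrelationMap(helices=list(helix_definitions), matrix=mat,
                          tilts=tilts)
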