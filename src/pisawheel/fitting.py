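"""Exhaustive PISA-wheel topology fitting with bootstrap uncertainties.

Fits (θ, ρ, S) to an assigned CS/DC peak list by exhaustive grid search
(default increments 0.1° in θ, 1.0° in ρ, 0.01 in S), quantifies parameter
uncertainty by refitting Gaussian-perturbed peak positions (sd = the average
peak linewidths), compares two fitted topologies with an unpaired t-test on
the bootstrap samples, and estimates two-state populations from normalized
peak intensities.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import HelixGeometry
from .peaklist import PeakList, PeakListError
from .wheel import TensorParameters, TopologyState, WheelModel

#: ¹⁵N Larmor frequency (MHz) at the 700-MHz spectrometer used to record
#: the reference spectra; converts chemical-shift residuals from ppm to kHz
#: so both spectral dimensions are compared on the same frequency scale.
N15_LARMOR_MHZ = 70.94
KHZ_PER_PPM = N15_LARMOR_MHZ / 1000.0


@dataclass
class FitConfig:
    """Grid-search and bootstrap settings.

    ``weighting`` selects how CS (ppm) and DC (kHz) residuals are combined:
    ``"frequency"`` (default) converts CS residuals to kHz with the ¹⁵N
    Larmor frequency so both dimensions carry equal weight per Hz;
    ``"fwhm"`` divides each dimension by its average peak linewidth
    (``cs_fwhm``, ``dc_fwhm``) instead.
    """

    theta_step: float = 0.1
    rho_step: float = 1.0
    s_step: float = 0.01
    s_min: float = 0.5
    s_max: float = 1.0
    s_fixed: float | None = None
    cs_fwhm: float = 3.0
    dc_fwhm: float = 0.8
    n_bootstrap: int = 20
    weighting: str = "frequency"

    def __post_init__(self) -> None:
        if min(self.theta_step, self.rho_step, self.s_step) <= 0:
            raise ValueError("grid steps must be positive")
        if self.n_bootstrap < 2:
            raise ValueError("n_bootstrap must be at least 2")
        if self.weighting not in ("frequency", "fwhm"):
            raise ValueError(f"unknown weighting {self.weighting!r}")

    @property
    def weights(self) -> tuple[float, float]:
        """(w_cs, w_dc) multiplying squared residuals in ppm²/kHz²."""
        if self.weighting == "frequency":
            return KHZ_PER_PPM ** 2, 1.0
        return 1.0 / self.cs_fwhm ** 2, 1.0 / self.dc_fwhm ** 2


@dataclass
class FitResult:
    best: TopologyState
    rmsd: float
    per_residue_residuals: list[dict]
    dataset_id: str = ""
    degenerate: bool = False
    theta_sd: float | None = None
    rho_sd: float | None = None
    s_sd: float | None = None
    bootstrap_samples: np.ndarray | None = None  # (n, 3) columns θ, ρ, S

    @property
    def bootstrap_means(self) -> tuple[float, float, float]:
        if self.bootstrap_samples is None:
            raise ValueError("fit carries no bootstrap samples")
        th = float(np.mean(self.bootstrap_samples[:, 0]))
        rho = float(stats.circmean(self.bootstrap_samples[:, 1], high=360.0))
        s = float(np.mean(self.bootstrap_samples[:, 2]))
        return th, rho, s


@dataclass
class ComparisonResult:
    delta_theta: float
    delta_theta_sd: float
    delta_rho: float
    delta_rho_sd: float
    p_theta: float
    p_rho: float


# ---------------------------------------------------------------------------
# forward-model grid cache

_GRID_CACHE: OrderedDict = OrderedDict()
_GRID_CACHE_MAX = 4


def _forward_grid(geometry: HelixGeometry, tensors: TensorParameters,
                  residues: tuple[int, ...], reference: int,
                  cfg: FitConfig):
    """Rigid-lattice (cs−δiso, |dc|) for every residue on the (θ, ρ) grid.

    The grid depends only on the model configuration, not the data, so it
    is cached and shared by every bootstrap repeat.
    """
    key = ((geometry.phi, geometry.psi, geometry.ca_n_h_angle),
           (tensors.delta11, tensors.delta22, tensors.delta33,
            tensors.beta_33_nh, tensors.nu_parallel, tensors.alignment_mode),
           residues, reference, cfg.theta_step, cfg.rho_step)
    if key in _GRID_CACHE:
        _GRID_CACHE.move_to_end(key)
        return _GRID_CACHE[key]
    model = WheelModel(geometry, tensors, np.array(residues), reference)
    theta = np.arange(0.0, 90.0 + cfg.theta_step / 2, cfg.theta_step)
    rho = np.arange(0.0, 360.0, cfg.rho_step)
    th, rh = np.meshgrid(theta, rho, indexing="ij")
    cs0, dc0 = model.rigid_observables(th.ravel(), rh.ravel())
    f = tensors.mode_factor
    entry = (theta, rho, f * (cs0 - tensors.delta_iso), np.abs(f * dc0), model)
    _GRID_CACHE[key] = entry
    if len(_GRID_CACHE) > _GRID_CACHE_MAX:
        _GRID_CACHE.popitem(last=False)
    return entry


# ---------------------------------------------------------------------------
# objective

def _residuals(pl_cs, pl_dc, cs_calc, dc_calc):
    # dipolar splittings are compared as magnitudes on both sides
    return pl_cs - cs_calc, np.abs(pl_dc) - np.abs(dc_calc)


def fit_objective(pl: PeakList, topology: TopologyState,
                  geometry: HelixGeometry, tensors: TensorParameters,
                  cfg: FitConfig | None = None) -> float:
    """Weighted combined RMSD between calculated and experimental CS/DC.

    RMSD = sqrt( Σ_i [w_cs·Δcs_i² + w_dc·Δdc_i²] / 2n ); the mean runs over
    the 2n residual components so a single peak off by one linewidth in one
    dimension contributes 1/√2 under FWHM weighting.  Invariant to peak
    order.  Calculated DC magnitudes are compared with the (unsigned)
    experimental couplings.
    """
    cfg = cfg or FitConfig()
    pl.require_nonempty()
    model = WheelModel(geometry, tensors, np.array(pl.residue_numbers),
                       pl.reference_number)
    cs_calc, dc_calc = model.observables(topology)
    dcs, ddc = _residuals(np.array([p.cs for p in pl.peaks]),
                          np.array([p.dc for p in pl.peaks]), cs_calc, dc_calc)
    wc, wd = cfg.weights
    return float(np.sqrt((wc * dcs ** 2 + wd * ddc ** 2).sum() / (2 * len(pl))))


# ---------------------------------------------------------------------------
# grid search

def _solve_grid(theta, rho, a, d, iso, csobs, dcobs, cfg: FitConfig):
    """Exact grid minimum of the quadratic-in-S objective.

    For each (θ, ρ) the objective is convex in S, so the best grid S is one
    of the two values bracketing the continuous optimum (ties broken toward
    smaller S).  Global ties are then broken toward smaller θ, then ρ, by
    first-occurrence ordering of the θ-major grid.
    """
    wc, wd = cfg.weights
    tcs = csobs - iso
    dcobs = np.abs(dcobs)
    A = wc * (a ** 2).sum(axis=1) + wd * (d ** 2).sum(axis=1)
    B = wc * (a @ tcs) + wd * (d @ dcobs)
    C = float(wc * (tcs ** 2).sum() + wd * (dcobs ** 2).sum())
    if cfg.s_fixed is not None:
        s_best = np.full(A.shape, cfg.s_fixed)
        vals = A * cfg.s_fixed ** 2 - 2 * B * cfg.s_fixed + C
    else:
        n_s = int(round((cfg.s_max - cfg.s_min) / cfg.s_step))
        with np.errstate(divide="ignore", invalid="ignore"):
            s_star = np.where(A > 0, B / np.where(A > 0, A, 1.0), cfg.s_min)
        k = np.clip(np.floor((s_star - cfg.s_min) / cfg.s_step), 0, n_s - 1)
        s_lo = cfg.s_min + k * cfg.s_step
        s_hi = np.minimum(s_lo + cfg.s_step, cfg.s_max)
        v_lo = A * s_lo ** 2 - 2 * B * s_lo + C
        v_hi = A * s_hi ** 2 - 2 * B * s_hi + C
        pick_lo = v_lo <= v_hi
        s_best = np.where(pick_lo, s_lo, s_hi)
        vals = np.where(pick_lo, v_lo, v_hi)
        # the bracket assumes convexity; guard the boundaries explicitly
        v_min = A * cfg.s_min ** 2 - 2 * B * cfg.s_min + C
        v_max = A * cfg.s_max ** 2 - 2 * B * cfg.s_max + C
        better_min = v_min < vals
        s_best = np.where(better_min, cfg.s_min, s_best)
        vals = np.where(better_min, v_min, vals)
        better_max = v_max < vals
        s_best = np.where(better_max, cfg.s_max, s_best)
        vals = np.where(better_max, v_max, vals)
    gi = int(np.argmin(vals))
    n_res = a.shape[1]
    rmsd = float(np.sqrt(max(vals[gi], 0.0) / (2 * n_res)))
    ti, ri = divmod(gi, len(rho))
    return float(theta[ti]), float(rho[ri]), float(s_best[gi]), rmsd


def _check_fittable(pl: PeakList) -> None:
    pl.require_nonempty()
    if all(p.status == "ambiguous" for p in pl.peaks):
        raise PeakListError(
            f"peak list {pl.dataset_id!r} contains only ambiguous "
            "assignments; at least one resolvable assignment is required")


def grid_search_fit(pl: PeakList, geometry: HelixGeometry | None = None,
                    tensors: TensorParameters | None = None,
                    cfg: FitConfig | None = None) -> FitResult:
    """Exhaustive search over θ ∈ [0, 90] × ρ ∈ [0, 360) × S for the lowest
    weighted RMSD between calculated and experimental CS/DC values."""
    geometry = geometry or HelixGeometry()
    tensors = tensors or TensorParameters()
    cfg = cfg or FitConfig()
    _check_fittable(pl)
    residues = tuple(pl.residue_numbers)
    theta, rho, a, d, model = _forward_grid(geometry, tensors, residues,
                                            pl.reference_number, cfg)
    csobs = np.array([p.cs for p in pl.peaks])
    dcobs = np.array([p.dc for p in pl.peaks])
    th, rh, s, rmsd = _solve_grid(theta, rho, a, d, tensors.delta_iso,
                                  csobs, dcobs, cfg)
    degenerate = th <= cfg.theta_step  # wheel collapsed: ρ unidentifiable
    best = TopologyState(theta=th, rho=0.0 if degenerate else rh, s=s)
    if degenerate:
        best.rho = float("nan")
    cs_calc, dc_calc = model.observables(
        TopologyState(theta=th, rho=rh, s=s))
    dcs, ddc = _residuals(csobs, dcobs, cs_calc, dc_calc)
    per_res = [{"residue_label": p.residue_label, "cs_obs": p.cs,
                "cs_calc": float(c), "delta_cs": float(rc),
                "dc_obs": p.dc, "dc_calc": float(abs(dd)),
                "delta_dc": float(rd)}
               for p, c, rc, dd, rd in zip(pl.peaks, cs_calc, dcs, dc_calc, ddc)]
    return FitResult(best=best, rmsd=rmsd, per_residue_residuals=per_res,
                     dataset_id=pl.dataset_id, degenerate=degenerate)


# ---------------------------------------------------------------------------
# bootstrap

def _perturbed_observations(pl: PeakList, cfg: FitConfig, rng) -> tuple:
    """One bootstrap draw: Gaussian-perturb every peak position and permute
    assignments within each ambiguity group."""
    cs = np.array([p.cs for p in pl.peaks])
    dc = np.array([p.dc for p in pl.peaks])
    groups: dict[str, list[int]] = {}
    for i, p in enumerate(pl.peaks):
        if p.status == "ambiguous" and p.ambiguity_group:
            groups.setdefault(p.ambiguity_group, []).append(i)
    for idx in groups.values():
        perm = rng.permutation(len(idx))
        idx = np.array(idx)
        cs[idx], dc[idx] = cs[idx[perm]], dc[idx[perm]]
    cs = cs + rng.normal(0.0, cfg.cs_fwhm, size=cs.shape)
    dc = dc + rng.normal(0.0, cfg.dc_fwhm, size=dc.shape)
    return cs, dc


def bootstrap_uncertainty(pl: PeakList, geometry: HelixGeometry | None = None,
                          tensors: TensorParameters | None = None,
                          cfg: FitConfig | None = None, *,
                          seed: int) -> FitResult:
    """Point fit plus ``cfg.n_bootstrap`` refits of Gaussian-perturbed data.

    Each repeat perturbs every peak's CS and DC independently (overlapped
    duplicates included) by Gaussian noise with sd equal to the average peak
    linewidths, re-draws one assignment permutation per ambiguity group, and
    refits; reported sds are sample standard deviations over the repeats
    (circular for ρ).  All randomness derives from ``seed``.
    """
    geometry = geometry or HelixGeometry()
    tensors = tensors or TensorParameters()
    cfg = cfg or FitConfig()
    rng = np.random.default_rng(seed)
    result = grid_search_fit(pl, geometry, tensors, cfg)
    residues = tuple(pl.residue_numbers)
    theta, rho, a, d, _ = _forward_grid(geometry, tensors, residues,
                                        pl.reference_number, cfg)
    samples = np.empty((cfg.n_bootstrap, 3))
    for k in range(cfg.n_bootstrap):
        cs, dc = _perturbed_observations(pl, cfg, rng)
        th, rh, s, _ = _solve_grid(theta, rho, a, d, tensors.delta_iso,
                                   cs, dc, cfg)
        samples[k] = (th, rh, s)
    result.bootstrap_samples = samples
    result.theta_sd = float(np.std(samples[:, 0], ddof=1))
    result.rho_sd = float(np.rad2deg(stats.circstd(
        np.deg2rad(samples[:, 1]))))
    result.s_sd = float(np.std(samples[:, 2], ddof=1))
    return result


# ---------------------------------------------------------------------------
# statistics

def _circular_center(samples: np.ndarray) -> float:
    return float(np.rad2deg(stats.circmean(np.deg2rad(samples))))


def _unwrap_about(samples: np.ndarray, center: float) -> np.ndarray:
    return center + (samples - center + 180.0) % 360.0 - 180.0


def compare_topologies(a: FitResult, b: FitResult,
                       welch: bool = False) -> ComparisonResult:
    """Topology difference (b − a) with two-sided unpaired t-tests.

    Δθ is the difference of bootstrap mean tilts; Δρ is the circular
    difference of circular-mean rotations mapped to (−180, 180].  The
    default t-test is pooled-variance (the common spreadsheet default);
    ``welch=True`` drops the equal-variance assumption.
    """
    for r in (a, b):
        if r.bootstrap_samples is None:
            raise ValueError("both fits must carry bootstrap samples")
    ta, tb = a.bootstrap_samples[:, 0], b.bootstrap_samples[:, 0]
    dtheta = float(np.mean(tb) - np.mean(ta))
    dtheta_sd = float(np.sqrt(np.var(ta, ddof=1) + np.var(tb, ddof=1)))
    ra_raw, rb_raw = a.bootstrap_samples[:, 1], b.bootstrap_samples[:, 1]
    ca, cb = _circular_center(ra_raw), _circular_center(rb_raw)
    drho = (cb - ca + 180.0) % 360.0 - 180.0
    # unwrap each sample set about its own circular mean for linear stats
    ra = _unwrap_about(ra_raw, ca)
    rb = _unwrap_about(rb_raw, cb)
    drho_sd = float(np.sqrt(np.var(ra, ddof=1) + np.var(rb, ddof=1)))
    def _ttest(x, y):
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            # degenerate samples: identical means are indistinguishable,
            # different means are trivially distinct
            return 1.0 if np.isclose(np.mean(x), np.mean(y)) else 1e-300
        return float(stats.ttest_ind(x, y, equal_var=not welch).pvalue)

    p_theta = _ttest(ta, tb)
    # shift b's unwrapped samples next to a's so the t-test sees the
    # circular difference, not a 360° wrap
    rb_aligned = rb - (cb - ca - drho)
    p_rho = _ttest(ra, rb_aligned)
    return ComparisonResult(delta_theta=dtheta, delta_theta_sd=dtheta_sd,
                            delta_rho=float(drho), delta_rho_sd=drho_sd,
                            p_theta=p_theta, p_rho=p_rho)


def estimate_populations(major: PeakList, minor: PeakList) -> tuple[float, float]:
    """Minor-state population fraction from normalized peak intensities.

    For every residue assigned in both lists the per-residue fraction is
    I_minor/(I_minor + I_major); returns (mean, sd) over residues as
    fractions in [0, 1].
    """
    imaj = {p.residue_label: p.intensity for p in major.peaks
            if p.intensity is not None}
    imin = {p.residue_label: p.intensity for p in minor.peaks
            if p.intensity is not None}
    common = [k for k in imaj if k in imin]
    if not common:
        raise PeakListError("no matched residues with intensities between "
                            "the two peak lists")
    frac = np.array([imin[k] / (imin[k] + imaj[k]) for k in common])
    sd = float(np.std(frac, ddof=1)) if len(frac) > 1 else 0.0
    return float(np.mean(frac)), sd
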