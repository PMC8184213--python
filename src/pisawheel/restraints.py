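"""Replica-averaged orientational-restraint mathematics.

Engine-free implementation of the restraint energies and annealing-cycle
program used for NMR-driven ensemble refinement of a membrane complex:
harmonic penalties on replica-averaged back-calculated CS/DC observables,
flat-bottom distance walls (paramagnetic upper bounds and detachment lower
bounds), and the piecewise-linear temperature/force schedule of the
detach-hold-rebind-sample annealing cycle.

Gradients are returned with respect to the averaged observables (or the
distance), not atomic coordinates: chaining through the back-calculation
and into Cartesian forces is the MD engine's job and out of scope here.
Units are J/mol with force constants in J/(mol·ppm²), J/(mol·kHz²) and
J/(mol·nm²) exactly as conventionally quoted; distances are Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

A_PER_NM = 10.0


@dataclass
class RestraintSet:
    """Experimental CS/DC targets and force constants.

    ``targets`` maps residue number → (cs ppm, dc kHz); either observable
    may be NaN to mark a missing target (contributes zero energy).
    """

    targets: dict[int, tuple[float, float]]
    k_cs: float = 50.0       # J/(mol·ppm²)
    k_dc: float = 800.0      # J/(mol·kHz²)

    def __post_init__(self) -> None:
        if self.k_cs < 0 or self.k_dc < 0:
            raise ValueError("force constants must be non-negative")


@dataclass
class Wall:
    """Flat-bottom harmonic distance wall.

    ``kind="upper"`` penalizes d > bound (paramagnetic-derived upper
    bounds); ``kind="lower"`` penalizes d < bound (detachment pushes).
    ``k`` is in J/(mol·nm²); ``bound`` in Å.
    """

    bound: float
    k: float = 5.0
    kind: str = "upper"

    def __post_init__(self) -> None:
        if self.bound <= 0:
            raise ValueError("wall bound must be positive")
        if self.k < 0:
            raise ValueError("wall force constant must be non-negative")
        if self.kind not in ("upper", "lower"):
            raise ValueError(f"unknown wall kind {self.kind!r}")


@dataclass
class ReplicaObservables:
    """Back-calculated (cs, dc) per residue for each replica.

    ``cs`` and ``dc`` are (n_replicas, n_residues) arrays aligned with
    ``residues``.
    """

    residues: np.ndarray
    cs: np.ndarray
    dc: np.ndarray

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.cs = np.atleast_2d(np.asarray(self.cs, dtype=float))
        self.dc = np.atleast_2d(np.asarray(self.dc, dtype=float))
        if self.cs.shape != self.dc.shape:
            raise ValueError("cs and dc arrays must have identical shape")
        if self.cs.shape[1] != len(self.residues):
            raise ValueError("observable arrays do not match residue list "
                             "(ragged replica sets are not allowed)")
        if self.cs.shape[0] < 1:
            raise ValueError("need at least one replica")

    @property
    def n_replicas(self) -> int:
        return self.cs.shape[0]


def replica_average(obs: ReplicaObservables) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean of (cs, dc) across replicas, per residue."""
    return obs.cs.mean(axis=0), obs.dc.mean(axis=0)


def restraint_energy(residues, avg_cs, avg_dc, restraints: RestraintSet,
                     scale: float = 1.0):
    """Harmonic CS/DC restraint energy and gradients.

    E = scale · Σ_res [ k_cs (⟨cs⟩ − cs_exp)² + k_dc (⟨dc⟩ − dc_exp)² ];
    returns (energy J/mol, dE/d⟨cs⟩ per residue, dE/d⟨dc⟩ per residue).
    Residues without targets (or NaN targets) contribute zero.
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    residues = np.asarray(residues, dtype=int)
    avg_cs = np.asarray(avg_cs, dtype=float)
    avg_dc = np.asarray(avg_dc, dtype=float)
    g_cs = np.zeros_like(avg_cs)
    g_dc = np.zeros_like(avg_dc)
    energy = 0.0
    for i, r in enumerate(residues):
        tgt = restraints.targets.get(int(r))
        if tgt is None:
            continue
        t_cs, t_dc = tgt
        if not np.isnan(t_cs):
            d = avg_cs[i] - t_cs
            energy += restraints.k_cs * d * d
            g_cs[i] = 2.0 * scale * restraints.k_cs * d
        if not np.isnan(t_dc):
            d = avg_dc[i] - t_dc
            energy += restraints.k_dc * d * d
            g_dc[i] = 2.0 * scale * restraints.k_dc * d
    return scale * energy, g_cs, g_dc


def wall_energy(distance: float, wall: Wall, scale: float = 1.0):
    """Flat-bottom wall energy and its derivative w.r.t. the distance.

    Upper wall: E = scale·k·(d − bound)² for d > bound, else 0.
    Lower wall: E = scale·k·(bound − d)² for d < bound, else 0.
    Distances in Å; k in J/(mol·nm²), so the excess is converted to nm.
    Returns (energy J/mol, dE/dd in J/(mol·Å)).
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if scale < 0:
        raise ValueError("scale must be non-negative")
    if wall.kind == "upper":
        excess = max(distance - wall.bound, 0.0)
        sign = 1.0
    else:
        excess = max(wall.bound - distance, 0.0)
        sign = -1.0
    e_nm = excess / A_PER_NM
    energy = scale * wall.k * e_nm * e_nm
    grad = sign * 2.0 * scale * wall.k * e_nm / A_PER_NM
    return energy, grad


# ---------------------------------------------------------------------------
# annealing schedule

@dataclass
class Phase:
    """One linear segment of the annealing cycle.

    Each quantity ramps linearly from its ``*_start`` to ``*_end`` value
    over ``duration_ps``.
    """

    name: str
    duration_ps: float
    temp_start: float
    temp_end: float
    k_scale_start: float
    k_scale_end: float
    detach_start: float
    detach_end: float
    pre_start: float
    pre_end: float

    def __post_init__(self) -> None:
        if self.duration_ps <= 0:
            raise ValueError("phase duration must be positive")


@dataclass
class AnnealingSchedule:
    """Piecewise-linear annealing program, periodic over its cycle length.

    The default cycle detaches the regulator's N-terminus while heating to
    370 K (CS/DC force constants halved for stability), holds, rebinds
    while cooling to 300 K (paramagnetic upper walls re-introduced), and
    samples for 2 ns; the sampling phase is the part retained for analysis.
    """

    phases: list[Phase] = field(default_factory=lambda: [
        Phase("detach", 500.0, 300.0, 370.0, 1.0, 0.5, 0.0, 1.0, 1.0, 0.0),
        Phase("hold", 500.0, 370.0, 370.0, 0.5, 0.5, 1.0, 1.0, 0.0, 0.0),
        Phase("rebind", 1000.0, 370.0, 300.0, 0.5, 1.0, 1.0, 0.0, 0.0, 1.0),
        Phase("sample", 2000.0, 300.0, 300.0, 1.0, 1.0, 0.0, 0.0, 1.0, 1.0),
    ])
    n_cycles: int = 25
    n_replicas: int = 8
    cyclic: bool = True

    def __post_init__(self) -> None:
        pairs = zip(self.phases, self.phases[1:] + self.phases[:1]) \
            if self.cyclic else zip(self.phases, self.phases[1:])
        for prev, nxt in pairs:
            for a, b in (("temp_end", "temp_start"),
                         ("k_scale_end", "k_scale_start"),
                         ("detach_end", "detach_start"),
                         ("pre_end", "pre_start")):
                if not np.isclose(getattr(prev, a), getattr(nxt, b)):
                    raise ValueError(
                        f"schedule discontinuous between {prev.name!r} "
                        f"and {nxt.name!r}")

    @property
    def cycle_ps(self) -> float:
        return sum(p.duration_ps for p in self.phases)

    @property
    def total_ps(self) -> float:
        """Aggregate simulated time over all cycles and replicas."""
        return self.cycle_ps * self.n_cycles * self.n_replicas


def schedule_at(schedule: AnnealingSchedule, t_ps: float):
    """(temperature K, CS/DC force scale, detach-wall scale, PRE-wall
    scale, phase name) at time ``t_ps``, mapped into the cycle by modulo."""
    if t_ps < 0:
        raise ValueError("time must be non-negative")
    t = t_ps % schedule.cycle_ps if schedule.cyclic \
        else min(t_ps, schedule.cycle_ps)
    start = 0.0
    for p in schedule.phases:
        if t <= start + p.duration_ps or p is schedule.phases[-1]:
            f = (t - start) / p.duration_ps
            f = min(max(f, 0.0), 1.0)
            lerp = lambda a, b: a + (b - a) * f
            return (lerp(p.temp_start, p.temp_end),
                    lerp(p.k_scale_start, p.k_scale_end),
                    lerp(p.detach_start, p.detach_end),
                    lerp(p.pre_start, p.pre_end),
                    p.name)
        start += p.duration_ps
    raise AssertionError("unreachable")


def equilibration_schedule(duration_ps: float = 20000.0) -> AnnealingSchedule:
    """Single-phase force ramp used before cycling: CS/DC force constants
    rise linearly from zero to full over the equilibration (default 20 ns);
    no heating, no walls."""
    ramp = Phase("equilibrate", duration_ps, 300.0, 300.0, 0.0, 1.0,
                 0.0, 0.0, 0.0, 0.0)
    return AnnealingSchedule(phases=[ramp], n_cycles=1, cyclic=False)


def schedule_table(schedule: AnnealingSchedule, step_ps: float = 10.0):
    """Tabulate the cycle program (for plotting/validation)."""
    import pandas as pd
    ts = np.arange(0.0, schedule.cycle_ps + step_ps / 2, step_ps)
    rows = [(t, *schedule_at(schedule, min(t, schedule.cycle_ps - 1e-9)))
            for t in ts]
    return pd.DataFrame(rows, columns=["t_ps", "temperature_K",
                                       "k_scale_csdc", "wall_scale_detach",
                                       "wall_scale_pre", "phase"])
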