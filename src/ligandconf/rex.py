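"""Replica-exchange Monte Carlo sampling of torsional degrees of freedom.

A desk-scale analog of replica-exchange (solute-tempering) MD: a single
torsion angle evolves by Metropolis updates on an analytic periodic
potential, with a ladder of temperatures exchanging configurations through
the standard parallel-tempering criterion.  Hot replicas cross barriers
that are insurmountable at the base temperature, and the base-temperature
samples yield torsion histograms, free-energy profiles, radial (spiral)
time series, and ergodicity diagnostics.

Angles are degrees wrapped to the half-open interval [-180, 180).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .constants import R_KCAL

__all__ = [
    "TorsionPotential",
    "ReplicaLadder",
    "TorsionTrajectory",
    "TorsionProfileReport",
    "wrap_angle",
    "build_ladder",
    "run_rex",
    "exchange_accept",
    "torsion_histogram",
    "free_energy_profile",
    "barrier_report",
    "ergodicity_diagnostics",
    "radial_series",
    "make_report",
]


def wrap_angle(phi):
    """Wrap angle(s) in degrees to [-180, 180)."""
    return (np.asarray(phi, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class TorsionPotential:
    """Cosine-series torsional potential.

    ``terms`` is a sequence of ``(n, Vn, gamma)`` with periodicity ``n``,
    amplitude ``Vn`` (kcal/mol) and phase ``gamma`` (degrees):

        V(phi) = sum_n (Vn/2) * (1 + cos(n*phi - gamma))

    the standard force-field torsion functional form.
    """

    terms: tuple
    name: str = "custom"

    def __post_init__(self) -> None:
        terms = tuple((int(n), float(v), float(g)) for n, v, g in self.terms)
        if not terms:
            raise ValueError("potential needs at least one cosine term")
        object.__setattr__(self, "terms", terms)

    def __call__(self, phi):
        phi_rad = np.deg2rad(np.asarray(phi, dtype=float))
        v = np.zeros_like(phi_rad)
        for n, vn, gamma in self.terms:
            v = v + (vn / 2.0) * (1.0 + np.cos(n * phi_rad - np.deg2rad(gamma)))
        return v if v.shape else float(v)

    def scaled(self, factor: float) -> "TorsionPotential":
        return TorsionPotential(
            terms=tuple((n, vn * factor, g) for n, vn, g in self.terms), name=self.name
        )


@dataclass(frozen=True)
class ReplicaLadder:
    """Ascending temperature ladder; the first rung is the base temperature."""

    temperatures: tuple

    def __post_init__(self) -> None:
        temps = tuple(float(t) for t in self.temperatures)
        if not temps:
            raise ValueError("ladder needs at least one temperature")
        if any(t <= 0 for t in temps):
            raise ValueError("temperatures must be positive")
        if any(b < a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be ascending")
        object.__setattr__(self, "temperatures", temps)

    def __len__(self) -> int:
        return len(self.temperatures)

    @property
    def base(self) -> float:
        return self.temperatures[0]


def build_ladder(t_min: float, t_max: float, m: int) -> ReplicaLadder:
    """Geometrically spaced ladder ``T_i = t_min*(t_max/t_min)^(i/(m-1))``.

    Geometric spacing keeps the overlap of neighboring replicas' energy
    distributions roughly constant along the ladder.  ``m = 1`` returns the
    single base temperature.
    """
    if m < 1:
        raise ValueError("replica count must be >= 1")
    if t_min <= 0 or t_max < t_min:
        raise ValueError("need t_max >= t_min > 0")
    if m == 1:
        return ReplicaLadder(temperatures=(t_min,))
    i = np.arange(m)
    temps = t_min * (t_max / t_min) ** (i / (m - 1))
    temps[-1] = t_max  # exact endpoint
    return ReplicaLadder(temperatures=tuple(temps))


@dataclass(frozen=True)
class TorsionTrajectory:
    """Sampler output.

    ``angles``: array (sweeps+1, n_replicas) of per-*temperature-slot*
    angles (row 0 is the initial state); column 0 is the base temperature.
    ``walker_of_slot``: which walker currently occupies each temperature
    slot after each sweep.  ``exchange_attempts``/``exchange_accepts``
    count neighbor swaps per ladder edge.
    """

    angles: np.ndarray
    walker_of_slot: np.ndarray
    ladder: ReplicaLadder
    exchange_attempts: np.ndarray
    exchange_accepts: np.ndarray
    seed: int
    step_deg: float
    exchange_interval: int
    start_angle: float

    @property
    def n_sweeps(self) -> int:
        return self.angles.shape[0] - 1

    def base_angles(self, burn_in: float = 0.0) -> np.ndarray:
        """Base-temperature angle series after discarding a burn-in fraction."""
        if not 0.0 <= burn_in < 1.0:
            raise ValueError("burn_in must be in [0, 1)")
        series = self.angles[1:, 0]
        start = int(np.floor(burn_in * series.size))
        return series[start:]


def exchange_accept(e_i: float, e_j: float, t_i: float, t_j: float, rng_draw: float) -> bool:
    """Parallel-tempering swap criterion.

    Accept a configuration swap between replicas at temperatures ``t_i`` and
    ``t_j`` holding energies ``e_i``, ``e_j`` with probability
    ``min(1, exp((1/(R t_i) - 1/(R t_j)) * (e_i - e_j)))``.
    """
    if t_i <= 0 or t_j <= 0:
        raise ValueError("temperatures must be positive")
    delta = (1.0 / (R_KCAL * t_i) - 1.0 / (R_KCAL * t_j)) * (e_i - e_j)
    if delta >= 0:
        return True
    return rng_draw < np.exp(delta)


def run_rex(
    potential: TorsionPotential,
    ladder: ReplicaLadder,
    sweeps: int,
    start_angle: float = 90.0,
    step_deg: float = 60.0,
    exchange_interval: int = 1,
    seed: int = 0,
) -> TorsionTrajectory:
    """Run the replica-exchange Metropolis sampler.

    Every sweep each temperature slot proposes ``phi' = phi + U(-step, step)``
    (wrapped) and accepts with the Metropolis probability at its own
    temperature; every ``exchange_interval`` sweeps neighboring slots attempt
    configuration swaps (even and odd edges alternating).  The default
    quarter-turn proposal width traverses wells spaced 120 degrees apart,
    and per-sweep swap attempts keep walker diffusion through the ladder
    fast.  A fixed seed gives a bit-identical trajectory.
    """
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    if exchange_interval < 1:
        raise ValueError("exchange_interval must be >= 1")

    rng = np.random.default_rng(seed)
    m = len(ladder)
    betas = 1.0 / (R_KCAL * np.asarray(ladder.temperatures))

    phi = np.full(m, float(wrap_angle(start_angle)))
    energy = np.asarray(potential(phi), dtype=float).reshape(m)
    walker = np.arange(m)

    angles = np.empty((sweeps + 1, m))
    walker_log = np.empty((sweeps + 1, m), dtype=np.int32)
    angles[0] = phi
    walker_log[0] = walker
    n_edges = max(m - 1, 1)
    attempts = np.zeros(n_edges, dtype=np.int64)
    accepts = np.zeros(n_edges, dtype=np.int64)

    parity = 0
    for sweep in range(1, sweeps + 1):
        prop = wrap_angle(phi + rng.uniform(-step_deg, step_deg, size=m))
        e_prop = np.asarray(potential(prop), dtype=float).reshape(m)
        accept = np.log(rng.uniform(size=m)) < -betas * (e_prop - energy)
        phi = np.where(accept, prop, phi)
        energy = np.where(accept, e_prop, energy)

        if m > 1 and sweep % exchange_interval == 0:
            start = parity
            parity ^= 1
            edges = np.arange(start, m - 1, 2)
            if edges.size:
                draws = rng.uniform(size=edges.size)
                for e_idx, u in zip(edges, draws):
                    attempts[e_idx] += 1
                    delta = (betas[e_idx] - betas[e_idx + 1]) * (
                        energy[e_idx] - energy[e_idx + 1]
                    )
                    if delta >= 0 or u < np.exp(delta):
                        accepts[e_idx] += 1
                        phi[[e_idx, e_idx + 1]] = phi[[e_idx + 1, e_idx]]
                        energy[[e_idx, e_idx + 1]] = energy[[e_idx + 1, e_idx]]
                        walker[[e_idx, e_idx + 1]] = walker[[e_idx + 1, e_idx]]

        angles[sweep] = phi
        walker_log[sweep] = walker

    return TorsionTrajectory(
        angles=angles,
        walker_of_slot=walker_log,
        ladder=ladder,
        exchange_attempts=attempts,
        exchange_accepts=accepts,
        seed=seed,
        step_deg=step_deg,
        exchange_interval=exchange_interval,
        start_angle=float(wrap_angle(start_angle)),
    )


def torsion_histogram(
    traj: TorsionTrajectory,
    bins: int = 72,
    burn_in: float = 0.0,
    max_samples: Optional[int] = None,
) -> tuple:
    """Histogram of base-temperature angles over [-180, 180).

    Returns ``(edges, counts)``.  ``max_samples`` evenly subsamples the
    retained series to a fixed frame count (e.g. 1002 frames, the routine
    report size) before binning; counts always sum to the retained samples.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    series = traj.base_angles(burn_in)
    if max_samples is not None and series.size > max_samples:
        idx = np.linspace(0, series.size - 1, max_samples).round().astype(int)
        series = series[idx]
    counts, edges = np.histogram(series, bins=bins, range=(-180.0, 180.0))
    return edges, counts


def free_energy_profile(histogram_counts, temperature: float, edges=None):
    """Free-energy profile ``dG = -R T ln(count/max_count)`` per bin.

    Empty bins are masked (returned as NaN), never +/-inf.  Returns
    ``(centers_or_None, dG)``; centers are provided when ``edges`` is given.
    """
    counts = np.asarray(histogram_counts, dtype=float)
    if counts.max() <= 0:
        raise ValueError("histogram has no counts")
    with np.errstate(divide="ignore"):
        dg = -R_KCAL * temperature * np.log(counts / counts.max())
    dg[counts == 0] = np.nan
    centers = None
    if edges is not None:
        edges = np.asarray(edges, dtype=float)
        centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dg


def _refine_extremum(potential, phi0: float, kind: str, width: float = 1.0) -> float:
    """Brent refinement of a grid-scan extremum inside [phi0-width, phi0+width]."""
    sign = 1.0 if kind == "min" else -1.0
    res = minimize_scalar(
        lambda p: sign * potential(p),
        bounds=(phi0 - width, phi0 + width),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


@dataclass(frozen=True)
class BarrierReport:
    """Stationary-point analysis of a periodic torsional potential."""

    minima: tuple          # angles of minima, ascending
    minima_energies: tuple
    saddles: tuple         # angles of maxima separating adjacent minima
    saddle_energies: tuple
    barriers: tuple        # (from_min_idx, to_min_idx, height) per direction
    headline_barrier: float
    degenerate: bool = False


def barrier_report(potential: TorsionPotential, grid_points: int = 7200) -> BarrierReport:
    """Locate minima and saddles of the periodic potential.

    Dense periodic grid scan followed by bounded local refinement.  For each
    adjacent pair of minima the per-direction barrier is
    ``saddle - departing minimum``; the headline barrier is the lowest
    escape barrier out of the global-minimum well (the "lower of the two
    barriers" convention for a double well with unequal saddles).
    """
    grid = np.linspace(-180.0, 180.0, grid_points, endpoint=False)
    v = np.asarray(potential(grid))
    if np.ptp(v) < 1e-12:
        return BarrierReport((), (), (), (), (), 0.0, degenerate=True)

    left = np.roll(v, 1)
    right = np.roll(v, -1)
    min_idx = np.where((v < left) & (v < right))[0]
    max_idx = np.where((v > left) & (v > right))[0]

    minima = sorted(wrap_angle(_refine_extremum(potential, grid[i], "min")) for i in min_idx)
    saddle_raw = [wrap_angle(_refine_extremum(potential, grid[i], "max")) for i in max_idx]

    # order saddles so saddle[j] lies between minima[j] and minima[j+1] (cyclic)
    minima_arr = np.array(minima)
    saddles = []
    for j in range(len(minima_arr)):
        a = minima_arr[j]
        b = minima_arr[(j + 1) % len(minima_arr)] + (360.0 if j + 1 == len(minima_arr) else 0.0)
        for s in saddle_raw:
            s_un = s if s >= a else s + 360.0
            if a < s_un < b:
                saddles.append(s)
                break

    min_e = tuple(float(potential(p)) for p in minima)
    sad_e = tuple(float(potential(p)) for p in saddles)

    barriers = []
    nmin = len(minima)
    for j, se in enumerate(sad_e):
        barriers.append((j, (j + 1) % nmin, se - min_e[j]))
        barriers.append(((j + 1) % nmin, j, se - min_e[(j + 1) % nmin]))

    g = int(np.argmin(min_e))
    escape = [h for (i, _, h) in barriers if i == g]
    headline = float(min(escape)) if escape else 0.0

    return BarrierReport(
        minima=tuple(minima),
        minima_energies=min_e,
        saddles=tuple(saddles),
        saddle_energies=sad_e,
        barriers=tuple(barriers),
        headline_barrier=headline,
    )


def assign_wells(angles, report: BarrierReport) -> np.ndarray:
    """Assign each angle to a well basin bounded by the saddle angles.

    With m minima the m sorted saddles cut the circle into m cyclic
    intervals, each containing exactly one minimum; interval membership is
    computed by periodic searchsorted (the below-first and above-last
    segments are the same wrap-around basin).
    """
    angles = np.atleast_1d(wrap_angle(angles))
    m = len(report.minima)
    if m <= 1 or not report.saddles:
        return np.zeros(angles.size, dtype=int)
    bounds = np.sort(np.asarray(report.saddles))
    interval_of = lambda x: np.searchsorted(bounds, x, side="right") % m
    lookup = np.empty(m, dtype=int)
    for j, mn in enumerate(report.minima):
        lookup[interval_of(mn)] = j
    return lookup[interval_of(angles)]


@dataclass(frozen=True)
class ErgodicityReport:
    occupancies: tuple
    boltzmann: tuple
    transitions: int
    ergodic: bool


def boltzmann_well_populations(potential: TorsionPotential, report: BarrierReport,
                               temperature: float, grid_points: int = 3600) -> np.ndarray:
    """Equilibrium well populations by numerical Boltzmann integration."""
    grid = np.linspace(-180.0, 180.0, grid_points, endpoint=False)
    v = np.asarray(potential(grid))
    w = np.exp(-(v - v.min()) / (R_KCAL * temperature))
    wells = assign_wells(grid, report)
    nmin = max(len(report.minima), 1)
    pops = np.array([w[wells == j].sum() for j in range(nmin)])
    return pops / pops.sum()


def ergodicity_diagnostics(
    traj: TorsionTrajectory,
    potential: TorsionPotential,
    burn_in: float = 0.0,
    min_transitions: int = 10,
    significant_pop: float = 0.05,
) -> ErgodicityReport:
    """Well occupancies, inter-well transition count, and an ergodicity flag.

    The run is called ergodic when every well whose Boltzmann population at
    the base temperature exceeds ``significant_pop`` was visited AND the
    base-temperature series crossed between wells at least
    ``min_transitions`` times.
    """
    series = traj.base_angles(burn_in)
    if series.size == 0:
        raise ValueError("no samples after burn-in")
    report = barrier_report(potential)
    wells = assign_wells(series, report)
    nmin = max(len(report.minima), 1)
    occ = np.bincount(wells, minlength=nmin) / wells.size
    transitions = int(np.count_nonzero(np.diff(wells)))
    boltz = boltzmann_well_populations(potential, report, traj.ladder.base)
    visited_ok = all(occ[j] > 0 for j in range(nmin) if boltz[j] > significant_pop)
    ergodic = bool(visited_ok and transitions >= min_transitions and nmin > 1)
    if nmin == 1:
        ergodic = True
    return ErgodicityReport(
        occupancies=tuple(float(o) for o in occ),
        boltzmann=tuple(float(b) for b in boltz),
        transitions=transitions,
        ergodic=ergodic,
    )


def radial_series(traj: TorsionTrajectory, burn_in: float = 0.0) -> list:
    """Spiral-plot series: sweep index mapped linearly to radius, angle to
    azimuth.  Entries are ``(radius, angle, flagged)`` with the first and
    last points flagged (the dark start/end dots of the radial plots)."""
    series = traj.base_angles(burn_in)
    n = series.size
    radii = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(n)
    return [
        (float(r), float(a), i == 0 or i == n - 1)
        for i, (r, a) in enumerate(zip(radii, series))
    ]


@dataclass(frozen=True)
class TorsionProfileReport:
    """Everything the per-bond simulation report shows: the analytic
    profile, the sampled histogram, minima/barriers, occupancies and the
    ergodicity verdict."""

    profile_angles: np.ndarray
    profile_energies: np.ndarray
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray
    minima: tuple
    barriers: tuple
    headline_barrier: float
    occupancies: tuple
    transitions: int
    ergodic: bool

    def as_dict(self) -> dict:
        return {
            "profile_angles": self.profile_angles.tolist(),
            "profile_kcal_mol": self.profile_energies.tolist(),
            "histogram_edges": self.histogram_edges.tolist(),
            "histogram_counts": self.histogram_counts.tolist(),
            "minima_deg": list(self.minima),
            "barriers": [list(b) for b in self.barriers],
            "headline_barrier_kcal_mol": self.headline_barrier,
            "occupancies": list(self.occupancies),
            "transitions": self.transitions,
            "ergodic": self.ergodic,
        }


def make_report(
    traj: TorsionTrajectory,
    potential: TorsionPotential,
    bins: int = 72,
    burn_in: float = 0.1,
    max_samples: Optional[int] = None,
) -> TorsionProfileReport:
    """Assemble the histogram-on-profile report for one sampled bond."""
    edges, counts = torsion_histogram(traj, bins=bins, burn_in=burn_in, max_samples=max_samples)
    br = barrier_report(potential)
    erg = ergodicity_diagnostics(traj, potential, burn_in=burn_in)
    grid = np.linspace(-180.0, 180.0, 721)
    return TorsionProfileReport(
        profile_angles=grid,
        profile_energies=np.asarray(potential(grid)),
        histogram_edges=edges,
        histogram_counts=counts,
        minima=br.minima,
        barriers=br.barriers,
        headline_barrier=br.headline_barrier,
        occupancies=erg.occupancies,
        transitions=erg.transitions,
        ergodic=erg.ergodic,
    )
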