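"""Synthetic data generators standing in for the spectrometer and the
commercial MD/QM stack.

Every generator is a pure function of its configuration and seed and embeds
a ``provenance`` block carrying the ground-truth parameters, so recovery
tests never re-derive them.  Conditions emulated:

* EXSY build-up curves with Arrhenius-consistent rates at 300/305/310 K and
  the standard eight mixing times (0.1-2 s);
* variable-temperature lineshape stacks running from slow exchange through
  coalescence to fast exchange;
* analytic torsional potentials with barriers near 20, 6 and 3 kcal/mol
  (hindered biaryl, des-methyl analog, freely rotating threefold bond);
* conformer ensembles with known population weights and noisy predicted
  observables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .constants import R_KCAL
from .conformers import Conformer, ConformerEnsemble, ensemble_average_observables
from .exsy import EXSYCurve, EXSYDataset, buildup_model
from .lineshape import ExchangeSystem, Spectrum, simulate_lineshape
from .popfit import ObservedData, Observable
from .rex import TorsionPotential, barrier_report

__all__ = [
    "ArrheniusTruth",
    "NoiseSpec",
    "STANDARD_MIXING_TIMES",
    "gen_exsy_dataset",
    "gen_vt_spectrum_stack",
    "gen_torsion_potential",
    "gen_conformer_ensemble",
]

#: The eight standard EXSY mixing times (0.1-2 s), seconds.
STANDARD_MIXING_TIMES = (0.1, 0.2, 0.3, 0.4, 0.5, 0.7, 1.0, 2.0)


@dataclass(frozen=True)
class ArrheniusTruth:
    """Ground-truth Arrhenius law k(T) = exp(lnA - Ea/(R T)).

    Ea in kcal/mol, A in 1/s, temperatures in K.
    """

    Ea: float
    lnA: float
    temperatures: tuple = (300.0, 305.0, 310.0)

    def __post_init__(self) -> None:
        if self.Ea <= 0:
            raise ValueError("activation energy must be positive")
        temps = tuple(float(t) for t in self.temperatures)
        if any(t <= 0 for t in temps):
            raise ValueError("temperatures must be positive")
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", temps)

    def k(self, temperature: float) -> float:
        return float(np.exp(self.lnA - self.Ea / (R_KCAL * temperature)))

    @staticmethod
    def from_rate(Ea: float, k_ref: float, t_ref: float,
                  temperatures: Sequence[float] = (300.0, 305.0, 310.0)) -> "ArrheniusTruth":
        """Anchor the law by a known rate at one temperature."""
        lnA = float(np.log(k_ref) + Ea / (R_KCAL * t_ref))
        return ArrheniusTruth(Ea=Ea, lnA=lnA, temperatures=tuple(temperatures))


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise on normalized intensities."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def gen_exsy_dataset(
    truth: ArrheniusTruth,
    mixing_times: Sequence[float] = STANDARD_MIXING_TIMES,
    noise: NoiseSpec = NoiseSpec(),
    include_t1: Optional[float] = None,
) -> EXSYDataset:
    """Simulate a VT selective-EXSY dataset from an Arrhenius ground truth.

    For each temperature the rate is k(T) from the truth law and the
    build-up follows the equal-population two-site model (optionally damped
    by T1); Gaussian noise of width ``noise.sigma`` is added to the
    normalized intensities.  True rates are recorded in provenance.
    """
    tm = np.asarray(mixing_times, dtype=float)
    if tm.size == 0 or np.any(tm <= 0):
        raise ValueError("mixing times must be non-empty and positive")
    rng = np.random.default_rng(noise.seed)
    curves = []
    true_rates = {}
    for T in truth.temperatures:
        k = truth.k(T)
        true_rates[T] = k
        clean = buildup_model(k, tm, include_t1)
        noisy = clean + rng.normal(0.0, noise.sigma, size=tm.size) if noise.sigma > 0 else clean
        curves.append(EXSYCurve(temperature=T, mixing_times=tm, intensities=np.asarray(noisy)))
    provenance = {
        "generator": "gen_exsy_dataset",
        "Ea_kcal_mol": truth.Ea,
        "lnA": truth.lnA,
        "true_rates_per_s": {str(t): k for t, k in true_rates.items()},
        "t1_s": include_t1,
        "noise_sigma": noise.sigma,
        "noise_model": "additive Gaussian on normalized intensity",
        "seed": noise.seed,
    }
    return EXSYDataset(curves=tuple(curves), provenance=provenance)


def gen_vt_spectrum_stack(
    system: ExchangeSystem,
    temperatures: Sequence[float],
    truth: ArrheniusTruth,
    grid: np.ndarray,
) -> list:
    """Variable-temperature lineshape stack with Arrhenius-consistent rates.

    Returns one :class:`Spectrum` per temperature; ``k_ex = 2*k(T)`` since
    the truth law carries the unidirectional rate of a 1:1 pair.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = min(system.nuA, system.nuB), max(system.nuA, system.nuB)
    if grid.size == 0 or grid[0] > lo or grid[-1] < hi:
        raise ValueError("grid must cover both site frequencies")
    stack = []
    for T in temperatures:
        sysT = ExchangeSystem(
            pA=system.pA, pB=system.pB, nuA=system.nuA, nuB=system.nuB,
            R2A=system.R2A, R2B=system.R2B, k_ex=2.0 * truth.k(T),
        )
        stack.append(simulate_lineshape(sysT, grid))
    return stack


# preset -> (terms with unit overall scale, nominal headline barrier kcal/mol)
_PRESET_SHAPES = {
    # symmetric double well, minima near +/-90 deg, unequal saddles; the
    # lower (180 deg) saddle is the headline barrier
    "hindered_biaryl": (((2, 1.0, 0.0), (1, 0.25, 0.0)), 20.0),
    # double well, low barrier, still bimodal
    "desmethyl": (((2, 1.0, 0.0), (1, 0.25, 0.0)), 5.5),
    # three equal minima, freely rotating at room temperature
    "flexible_threefold": (((3, 1.0, 0.0),), 3.0),
}


def gen_torsion_potential(profile) -> TorsionPotential:
    """Build a torsional potential from a named preset or explicit terms.

    Presets: ``"hindered_biaryl"`` (20 kcal/mol lower barrier),
    ``"desmethyl"`` (5.5 kcal/mol), ``"flexible_threefold"`` (3 kcal/mol,
    three equal wells).  Preset amplitudes are scaled so the
    min-to-lowest-saddle difference equals the nominal barrier exactly
    (energies are linear in the overall amplitude, so one scan suffices).
    Explicit terms are passed as a sequence of ``(n, Vn, gamma)``.
    """
    if isinstance(profile, str):
        if profile not in _PRESET_SHAPES:
            raise ValueError(f"unknown preset {profile!r}")
        shape, target = _PRESET_SHAPES[profile]
        base = TorsionPotential(terms=shape, name=profile)
        unit_barrier = barrier_report(base).headline_barrier
        return base.scaled(target / unit_barrier)
    return TorsionPotential(terms=tuple(profile))


def gen_conformer_ensemble(
    true_weights: Sequence[float],
    n_conformers: Optional[int] = None,
    observable_model: Optional[Callable] = None,
    noise: NoiseSpec = NoiseSpec(),
    torsion_centers: Optional[Sequence[float]] = None,
    torsion_spread: float = 0.0,
    n_observables: int = 6,
) -> tuple:
    """Conformer ensemble with known population weights plus observed data.

    ``true_weights`` must lie on the probability simplex; conformers beyond
    its length carry weight 0 (decoys).  Each conformer gets a torsion
    angle (well centers spaced over the circle unless given, jittered by
    ``torsion_spread`` degrees) and predicted chemical shifts from
    ``observable_model(torsion) -> array`` (default: a fixed linear map,
    distinct per observable).  The observed data are the weight-averaged
    predictions plus Gaussian noise; true weights go into provenance.
    """
    w = np.asarray(true_weights, dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("true_weights must be non-negative and sum to 1")
    n_conf = n_conformers if n_conformers is not None else w.size
    if n_conf < w.size:
        raise ValueError("n_conformers must be >= number of weights")

    rng = np.random.default_rng(noise.seed)
    if torsion_centers is None:
        torsion_centers = np.linspace(-180.0, 180.0, n_conf, endpoint=False)
    torsions = np.asarray(torsion_centers, dtype=float)
    if torsion_spread > 0:
        torsions = torsions + rng.normal(0.0, torsion_spread, size=torsions.size)

    if observable_model is None:
        # Karplus-like trigonometric dependence on the torsion, distinct
        # phase/harmonic per observable: conformers at different angles are
        # spectroscopically distinguishable and the design has full rank
        offsets = 1.0 + 0.8 * np.arange(n_observables)
        phases = np.pi / 7.0 * np.arange(n_observables)
        harmonics = 1 + (np.arange(n_observables) % 3)
        observable_model = lambda phi: (
            offsets
            + 0.5 * np.cos(np.deg2rad(phi) + phases)
            + 0.3 * np.sin(harmonics * np.deg2rad(phi))
        )

    names = [f"H{i+1}" for i in range(n_observables)]
    conformers = []
    for i in range(n_conf):
        pred = np.asarray(observable_model(torsions[i]), dtype=float)
        conformers.append(
            Conformer(
                id=f"c{i:03d}",
                torsions=(float(torsions[i]),),
                predicted={name: float(v) for name, v in zip(names, pred)},
            )
        )
    ensemble = ConformerEnsemble(conformers=tuple(conformers))

    full_w = np.zeros(n_conf)
    full_w[: w.size] = w
    averaged = ensemble_average_observables(ensemble, full_w)
    observed_vals = np.array([averaged[name] for name in names])
    if noise.sigma > 0:
        observed_vals = observed_vals + rng.normal(0.0, noise.sigma, size=observed_vals.size)

    observed = ObservedData(
        observables=tuple(
            Observable(name=name, kind="shift", value=float(v), unit="ppm")
            for name, v in zip(names, observed_vals)
        ),
        provenance={
            "generator": "gen_conformer_ensemble",
            "true_weights": full_w.tolist(),
            "noise_sigma": noise.sigma,
            "seed": noise.seed,
        },
    )
    return ensemble, observed
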