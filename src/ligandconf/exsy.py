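"""Selective-EXSY exchange kinetics and rotational barriers.

A 1D selective EXSY experiment inverts one rotamer's signal and follows the
fractional transfer of magnetization to the exchange partner as a function
of mixing time.  For a 1:1 rotamer pair exchanging with unidirectional rate
``k`` (lifetime 1/k per site) the transferred fraction builds up as

    f(tau) = 1/2 * (1 - exp(-2*k*tau))            (no-T1 model)
    f(tau) = 1/2 * (1 - exp(-2*k*tau)) * exp(-tau/T1)

Rates fitted at several temperatures are combined in an Arrhenius plot of
ln(k) against 1/(R*T), whose slope is -Ea directly, and converted to
transition-state free energies with the Eyring equation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from lmfit import Parameters, minimize as lm_minimize

from .constants import KB_OVER_H, LN2, R_KCAL
from .lineshape import coalescence_rate

__all__ = [
    "EXSYCurve",
    "EXSYDataset",
    "RateFit",
    "ArrheniusFit",
    "NarrowTemperatureSpanWarning",
    "normalize_integrals",
    "buildup_model",
    "fit_rate",
    "fit_arrhenius",
    "eyring_barrier",
    "eyring_rate",
    "classify_exchange_regime",
]


class NarrowTemperatureSpanWarning(UserWarning):
    """Raised when an Arrhenius fit spans too small a temperature range to
    constrain Ea well (the classic 10 K VT-EXSY span is borderline)."""


@dataclass(frozen=True)
class EXSYCurve:
    """One build-up curve: normalized transferred intensity vs mixing time."""

    temperature: float
    mixing_times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        tm = np.asarray(self.mixing_times, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if tm.size != it.size:
            raise ValueError("mixing_times and intensities must match in length")
        if tm.size and (np.any(tm <= 0) or np.any(np.diff(tm) <= 0)):
            raise ValueError("mixing times must be positive and strictly increasing")
        object.__setattr__(self, "mixing_times", tm)
        object.__setattr__(self, "intensities", it)


@dataclass(frozen=True)
class EXSYDataset:
    """A variable-temperature series of EXSY build-up curves."""

    curves: tuple
    provenance: Optional[dict] = None

    def __post_init__(self) -> None:
        temps = [c.temperature for c in self.curves]
        if len(set(temps)) != len(temps):
            raise ValueError("curve temperatures must be distinct")
        object.__setattr__(self, "curves", tuple(self.curves))

    @property
    def temperatures(self) -> list:
        return [c.temperature for c in self.curves]

    def to_dataframe(self):
        import pandas as pd

        rows = [
            (c.temperature, t, i)
            for c in self.curves
            for t, i in zip(c.mixing_times, c.intensities)
        ]
        return pd.DataFrame(rows, columns=["temperature_K", "mixing_time_s", "intensity"])

    @staticmethod
    def from_dataframe(df, provenance: Optional[dict] = None) -> "EXSYDataset":
        curves = []
        for temp, grp in df.groupby("temperature_K"):
            grp = grp.sort_values("mixing_time_s")
            curves.append(
                EXSYCurve(
                    temperature=float(temp),
                    mixing_times=grp["mixing_time_s"].to_numpy(),
                    intensities=grp["intensity"].to_numpy(),
                )
            )
        return EXSYDataset(curves=tuple(curves), provenance=provenance)


@dataclass(frozen=True)
class RateFit:
    """Result of fitting one build-up curve."""

    k: float
    t_half: float
    residual_ss: float
    model_tag: str
    temperature: float
    no_exchange: bool = False

    def as_dict(self) -> dict:
        return {
            "k_per_s": self.k,
            "t_half_s": self.t_half,
            "residual_ss": self.residual_ss,
            "model_tag": self.model_tag,
            "temperature_K": self.temperature,
            "no_exchange": self.no_exchange,
        }


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius regression ln(k) = lnA - Ea/(R*T)."""

    Ea: float
    lnA: float
    rates: tuple
    r_squared: float
    narrow_span: bool

    def k_at(self, temperature: float) -> float:
        return float(np.exp(self.lnA - self.Ea / (R_KCAL * temperature)))

    def as_dict(self) -> dict:
        return {
            "Ea_kcal_mol": self.Ea,
            "lnA": self.lnA,
            "rates": [list(r) for r in self.rates],
            "r_squared": self.r_squared,
            "narrow_span": self.narrow_span,
        }


def normalize_integrals(raw_reference: float, raw_exchanged: float) -> dict:
    """Normalize EXSY integrals by calibrating the inverted reference to 100.

    Returns the rescaled reference (always 100), the exchanged-peak integral
    on that scale, and the dimensionless fractional transfer
    ``exchanged/reference``.
    """
    if raw_reference == 0:
        raise ValueError("reference integral must be nonzero")
    scale = 100.0 / raw_reference
    return {
        "reference": 100.0,
        "exchanged": raw_exchanged * scale,
        "fraction": raw_exchanged / raw_reference,
    }


def buildup_model(k: float, tau, t1: Optional[float] = None):
    """Equal-population two-site EXSY build-up fraction at mixing time tau.

    Without T1 relaxation ``f = (1 - exp(-2 k tau))/2``; with T1 the same
    expression is damped by ``exp(-tau/T1)``.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if k < 0:
        raise ValueError("rate must be non-negative")
    if np.any(tau_arr < 0):
        raise ValueError("mixing time must be non-negative")
    f = 0.5 * (1.0 - np.exp(-2.0 * k * tau_arr))
    if t1 is not None:
        if t1 <= 0:
            raise ValueError("T1 must be positive")
        f = f * np.exp(-tau_arr / t1)
    return f if f.shape else float(f)


def buildup_model_unequal(k_ex: float, tau, pB: float):
    """Unequal-population generalization ``f = pB (1 - exp(-k_ex tau))``.

    Non-default; provided for systems away from the 1:1 rotamer case.
    """
    tau_arr = np.asarray(tau, dtype=float)
    f = pB * (1.0 - np.exp(-k_ex * tau_arr))
    return f if f.shape else float(f)


def fit_rate(
    curve: EXSYCurve,
    model_tag: str = "no-t1",
    t1: Optional[float] = None,
) -> RateFit:
    """Nonlinear least-squares fit of the build-up model to one curve.

    ``model_tag`` is ``"no-t1"`` (default) or ``"t1"``; with ``"t1"`` the
    relaxation time is fitted unless ``t1`` is given.  All-zero intensities
    return ``k = 0`` flagged as no-exchange.
    """
    if curve.mixing_times.size < 3:
        raise ValueError("need at least 3 mixing-time points")
    if model_tag not in ("no-t1", "t1"):
        raise ValueError(f"unknown model_tag {model_tag!r}")

    y = curve.intensities
    tau = curve.mixing_times
    if np.allclose(y, 0.0):
        return RateFit(
            k=0.0,
            t_half=np.inf,
            residual_ss=0.0,
            model_tag=model_tag,
            temperature=curve.temperature,
            no_exchange=True,
        )

    params = Parameters()
    # crude initial rate from the earliest point: f ~ k*tau for small tau
    k0 = max(y[0] / tau[0], 1e-3)
    params.add("k", value=k0, min=0.0)
    if model_tag == "t1":
        if t1 is not None:
            params.add("t1", value=t1, vary=False)
        else:
            params.add("t1", value=float(tau[-1]), min=1e-6)

    def resid(p):
        t1v = p["t1"].value if model_tag == "t1" else None
        return buildup_model(p["k"].value, tau, t1v) - y

    out = lm_minimize(resid, params, method="leastsq")
    if not out.success:
        raise RuntimeError(f"build-up fit failed to converge: {out.message}")
    k = float(out.params["k"].value)
    return RateFit(
        k=k,
        t_half=LN2 / k if k > 0 else np.inf,
        residual_ss=float(np.sum(np.asarray(out.residual) ** 2)),
        model_tag=model_tag,
        temperature=curve.temperature,
    )


def fit_dataset(dataset: EXSYDataset, model_tag: str = "no-t1") -> list:
    """Fit every curve of a VT dataset; returns one RateFit per temperature."""
    return [fit_rate(c, model_tag=model_tag) for c in dataset.curves]


def fit_arrhenius(rate_fits: Sequence, span_warn_below: float = 20.0) -> ArrheniusFit:
    """Ordinary least squares of ln(k) against 1/(R*T).

    ``rate_fits`` is a sequence of ``(T, k)`` pairs or :class:`RateFit`
    objects.  The slope of ln(k) vs 1/(R*T) is -Ea and the intercept lnA.
    A temperature span below ``span_warn_below`` K (default 20) triggers a
    :class:`NarrowTemperatureSpanWarning` — Ea from a 10 K window is poorly
    conditioned against rate noise.
    """
    pairs = [
        (rf.temperature, rf.k) if isinstance(rf, RateFit) else (float(rf[0]), float(rf[1]))
        for rf in rate_fits
    ]
    temps = np.array([p[0] for p in pairs])
    ks = np.array([p[1] for p in pairs])
    if len(set(temps.tolist())) != len(temps):
        raise ValueError("duplicate temperatures in Arrhenius input")
    if len(temps) < 2:
        raise ValueError("need at least two temperatures")
    if np.any(ks <= 0):
        raise ValueError("all rates must be positive")

    x = 1.0 / (R_KCAL * temps)
    y = np.log(ks)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    span = float(temps.max() - temps.min())
    narrow = span < span_warn_below
    if narrow:
        warnings.warn(
            f"Arrhenius fit spans only {span:.1f} K; Ea is poorly constrained",
            NarrowTemperatureSpanWarning,
            stacklevel=2,
        )
    return ArrheniusFit(
        Ea=float(-slope),
        lnA=float(intercept),
        rates=tuple(pairs),
        r_squared=r2,
        narrow_span=narrow,
    )


def eyring_barrier(k: float, T: float) -> float:
    """Transition-state free energy ``dG‡ = R T ln(kB T / (h k))`` in kcal/mol."""
    if k <= 0:
        raise ValueError("rate must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return float(R_KCAL * T * np.log(KB_OVER_H * T / k))


def eyring_rate(dG: float, T: float) -> float:
    """Rate from an Eyring barrier: ``k = (kB T/h) exp(-dG‡/(R T))`` in 1/s."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return float(KB_OVER_H * T * np.exp(-dG / (R_KCAL * T)))


def classify_exchange_regime(k: float, delta_nu: float) -> str:
    """Classify exchange as "slow", "intermediate" or "fast" on the NMR
    timescale, comparing the unidirectional rate k with the coalescence
    rate ``k_c = pi*dnu/sqrt(2)``: slow below k_c/10, fast above 10*k_c."""
    k_c = coalescence_rate(delta_nu)
    if k < k_c / 10.0:
        return "slow"
    if k > 10.0 * k_c:
        return "fast"
    return "intermediate"
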