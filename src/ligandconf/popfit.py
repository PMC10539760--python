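"""NAMFIS-style conformer population deconvolution.

Fits simplex-constrained conformer weights w (w_i >= 0, sum w = 1) by
minimizing the weighted sum of squared differences between back-calculated
and experimental observables,

    SSD(w) = sum_obs  lambda_kind * (calc_obs(w) - exp_obs)^2 ,

where calc_obs(w) is the population-weighted average (linear for shifts
and couplings, <r^-6>^(-1/6) for NOE distances).  The shift/coupling part
is convex in w; r^-6 distance averaging is not, hence the deterministic
multi-start (simplex vertices plus barycenter) with the best SSD winning
and ties resolved to the lexicographically smallest weight vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .conformers import ConformerEnsemble, ensemble_average_observables

__all__ = [
    "Observable",
    "ObservedData",
    "PopulationFit",
    "DEFAULT_KIND_WEIGHTS",
    "fit_populations",
    "goodness_report",
    "bioactive_fraction",
]

#: Default per-kind residual weights (per ppm^2 / Hz^2 / A^2).  Couplings
#: are down-weighted because Hz-scale residuals are numerically larger than
#: ppm-scale ones; tunable per call.
DEFAULT_KIND_WEIGHTS = {"shift": 1.0, "coupling": 0.1, "distance": 1.0}


@dataclass(frozen=True)
class Observable:
    """One experimental observable with its kind and fitting weight."""

    name: str
    kind: str
    value: float
    unit: str = ""
    weight: float = 1.0
    include: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("shift", "coupling", "distance"):
            raise ValueError(f"unknown observable kind {self.kind!r}")
        if self.weight <= 0:
            raise ValueError("observable weight must be positive")


@dataclass(frozen=True)
class ObservedData:
    """Experimental observable set used as fitting target."""

    observables: tuple
    provenance: Optional[dict] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "observables", tuple(self.observables))
        names = [o.name for o in self.observables]
        if len(set(names)) != len(names):
            raise ValueError("observable names must be unique")

    def active(self) -> tuple:
        return tuple(o for o in self.observables if o.include)

    def kinds(self) -> dict:
        return {o.name: o.kind for o in self.observables}


@dataclass(frozen=True)
class PopulationFit:
    """Fitted simplex weights with goodness-of-fit."""

    weights: dict            # conformer id -> weight (pruned ids -> 0)
    ssd: float
    residuals: dict          # observable name -> calc - exp
    pruned: tuple            # conformer ids removed below the threshold
    conformer_ids: tuple

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights[cid] for cid in self.conformer_ids])


def _ssd_and_residuals(ensemble, w, observed, kind_weights, distance_averaging):
    # tolerate the optimizer's finite-difference probes slightly off the
    # simplex: clip and renormalize before averaging
    w = np.clip(np.asarray(w, dtype=float), 0.0, None)
    total = w.sum()
    w = w / total if total > 0 else np.full(w.size, 1.0 / w.size)
    kinds = observed.kinds()
    calc = ensemble_average_observables(
        ensemble, w, kinds=kinds, distance_averaging=distance_averaging
    )
    ssd = 0.0
    residuals = {}
    for o in observed.active():
        r = calc[o.name] - o.value
        residuals[o.name] = r
        ssd += kind_weights.get(o.kind, 1.0) * o.weight * r * r
    return ssd, residuals


def _solve_simplex(ensemble, observed, kind_weights, distance_averaging):
    """Multi-start SLSQP minimization over the probability simplex."""
    n = len(ensemble)
    if n == 1:
        w = np.array([1.0])
        ssd, _ = _ssd_and_residuals(ensemble, w, observed, kind_weights, distance_averaging)
        return w, ssd

    def objective(w):
        ssd, _ = _ssd_and_residuals(ensemble, w, observed, kind_weights, distance_averaging)
        return ssd

    constraints = [{"type": "eq", "fun": lambda w: w.sum() - 1.0}]
    bounds = [(0.0, 1.0)] * n
    starts = [np.full(n, 1.0 / n)]
    for i in range(n):
        v = np.full(n, 1e-9)
        v[i] = 1.0
        starts.append(v / v.sum())

    candidates = []
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": 500, "ftol": 1e-14},
        )
        w = np.clip(res.x, 0.0, None)
        w = w / w.sum()
        candidates.append((objective(w), w))

    best_ssd = min(c[0] for c in candidates)
    # ties (within 1e-9) resolved to the lexicographically smallest vector
    tied = [w for ssd, w in candidates if ssd <= best_ssd + 1e-9]
    best = min(tied, key=lambda w: tuple(np.round(w, 9)))
    return best, float(objective(best))


def fit_populations(
    ensemble: ConformerEnsemble,
    observed: ObservedData,
    prune_below: float = 0.01,
    kind_weights: Optional[dict] = None,
    distance_averaging: str = "r6",
) -> PopulationFit:
    """Fit conformer populations to the observed data.

    Every conformer must predict every active observable.  After the first
    converged fit, conformers with weight below ``prune_below`` are removed
    and the fit re-run once on the survivors (pruned ids report weight 0).
    Deterministic for fixed inputs.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if not observed.active():
        raise ValueError("no active observables")
    names = {o.name for o in observed.active()}
    for c in ensemble:
        missing = names - set(c.predicted or {})
        if missing:
            raise ValueError(f"conformer {c.id} lacks predictions for {sorted(missing)}")
    kw = dict(DEFAULT_KIND_WEIGHTS)
    if kind_weights:
        kw.update(kind_weights)

    w, _ = _solve_simplex(ensemble, observed, kw, distance_averaging)

    ids = ensemble.ids()
    pruned = tuple(cid for cid, wi in zip(ids, w) if wi < prune_below)
    if pruned and len(pruned) < len(ids):
        keep = [c for c in ensemble if c.id not in pruned]
        sub = ConformerEnsemble(conformers=tuple(keep), alignment_ref=ensemble.alignment_ref)
        w_sub, _ = _solve_simplex(sub, observed, kw, distance_averaging)
        w = np.zeros(len(ids))
        for cid, wi in zip(sub.ids(), w_sub):
            w[ids.index(cid)] = wi
    else:
        pruned = ()

    ssd, residuals = _ssd_and_residuals(ensemble, w, observed, kw, distance_averaging)
    return PopulationFit(
        weights={cid: float(wi) for cid, wi in zip(ids, w)},
        ssd=float(ssd),
        residuals=residuals,
        pruned=pruned,
        conformer_ids=tuple(ids),
    )


def goodness_report(fit: PopulationFit, observed: ObservedData) -> dict:
    """RMS residual per observable kind (native units) plus the overall SSD.

    Kinds partition the active observable set; each observable contributes
    to exactly one kind.
    """
    kinds = {}
    for o in observed.active():
        kinds.setdefault(o.kind, []).append(fit.residuals[o.name])
    report = {
        kind: float(np.sqrt(np.mean(np.square(res)))) for kind, res in kinds.items()
    }
    report["ssd"] = fit.ssd
    return report


def bioactive_fraction(fit: PopulationFit, bioactive_ids) -> float:
    """Total fitted population of the bioactive conformer family."""
    bio = set(bioactive_ids)
    unknown = bio - set(fit.conformer_ids)
    if unknown:
        raise ValueError(f"unknown conformer ids: {sorted(unknown)}")
    return float(sum(fit.weights[cid] for cid in bio))
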