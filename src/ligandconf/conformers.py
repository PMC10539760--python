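"""Conformer ensembles: clustering to diverse representatives, Boltzmann
populations, and ensemble-averaged NMR observables.

Chemical shifts and scalar couplings average linearly over the ensemble;
NOE-derived interproton distances average as <r^-6>^(-1/6) (NOE intensity
is proportional to r^-6), with an r^-3 option for fast internal motion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .constants import R_KCAL
from .rex import wrap_angle

__all__ = [
    "Conformer",
    "ConformerEnsemble",
    "torsion_distance",
    "cartesian_rmsd",
    "cluster_conformers",
    "boltzmann_populations",
    "ensemble_average_observables",
]


@dataclass(frozen=True)
class Conformer:
    """One conformer: torsions (degrees, wrapped), optional energy
    (kcal/mol), optional labeled 3D coordinates (Angstrom), optional
    predicted observables (name -> value)."""

    id: str
    torsions: tuple = ()
    energy: Optional[float] = None
    coords: Optional[dict] = None
    predicted: Optional[dict] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "torsions", tuple(float(wrap_angle(t)) for t in self.torsions)
        )

    def mirror(self) -> "Conformer":
        """Mirror image: sign-flipped torsions / inverted coordinates."""
        coords = None
        if self.coords is not None:
            coords = {k: tuple(-x for x in v) for k, v in self.coords.items()}
        return Conformer(
            id=self.id + "_mirror",
            torsions=tuple(wrap_angle(-t) for t in self.torsions),
            energy=self.energy,
            coords=coords,
            predicted=self.predicted,
        )


@dataclass(frozen=True)
class ConformerEnsemble:
    """An ordered collection of conformers sharing one schema.

    ``alignment_ref`` optionally records the rigid-core substructure
    (a SMARTS string) the coordinates were aligned on; it is metadata here,
    not interpreted.
    """

    conformers: tuple
    alignment_ref: Optional[str] = None

    def __post_init__(self) -> None:
        confs = tuple(self.conformers)
        ids = [c.id for c in confs]
        if len(set(ids)) != len(ids):
            raise ValueError("conformer ids must be unique")
        nt = {len(c.torsions) for c in confs}
        if len(nt) > 1:
            raise ValueError("conformers must share the torsion schema")
        object.__setattr__(self, "conformers", confs)

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def ids(self) -> list:
        return [c.id for c in self.conformers]

    def to_json(self, path) -> None:
        payload = {
            "alignment_ref": self.alignment_ref,
            "conformers": [
                {
                    "id": c.id,
                    "torsions": list(c.torsions),
                    "energy": c.energy,
                    "coords": {k: list(v) for k, v in c.coords.items()} if c.coords else None,
                    "predicted": c.predicted,
                }
                for c in self.conformers
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @staticmethod
    def from_json(path) -> "ConformerEnsemble":
        with open(path) as fh:
            payload = json.load(fh)
        confs = tuple(
            Conformer(
                id=c["id"],
                torsions=tuple(c.get("torsions", ())),
                energy=c.get("energy"),
                coords={k: tuple(v) for k, v in c["coords"].items()} if c.get("coords") else None,
                predicted=c.get("predicted"),
            )
            for c in payload["conformers"]
        )
        return ConformerEnsemble(conformers=confs, alignment_ref=payload.get("alignment_ref"))


def torsion_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Root-mean-square periodic torsion difference in degrees.

    Each per-angle difference is wrapped to [-180, 180] before squaring,
    so 179 vs -179 differ by 2 degrees, not 358.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("torsion vectors must have equal length")
    d = wrap_angle(a - b)
    return float(np.sqrt(np.mean(d**2)))


def cartesian_rmsd(
    a: dict,
    b: dict,
    superpose: bool = True,
    allow_mirror: bool = False,
) -> float:
    """RMSD (Angstrom) between two labeled coordinate sets.

    With ``superpose`` the sets are centered and optimally rotated
    (Kabsch, proper rotations only); with ``allow_mirror`` the inverted
    copy is also tried and the smaller RMSD returned.
    """
    if set(a) != set(b):
        raise ValueError("atom labels must match")
    labels = sorted(a)
    xa = np.array([a[l] for l in labels], dtype=float)
    xb = np.array([b[l] for l in labels], dtype=float)
    if not superpose:
        return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)

    def _fit(target):
        _, rssd = Rotation.align_vectors(xa, target)
        return float(rssd / np.sqrt(len(labels)))

    rmsd = _fit(xb)
    if allow_mirror:
        rmsd = min(rmsd, _fit(-xb))
    return rmsd


@dataclass(frozen=True)
class ClusterResult:
    representatives: "ConformerEnsemble"
    assignment: dict          # conformer id -> cluster index
    discarded_mirrors: tuple  # ids dropped as mirror duplicates


def _pairwise(conformers, metric):
    n = len(conformers)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = metric(conformers[i], conformers[j])
    return dm


def cluster_conformers(
    ensemble: ConformerEnsemble,
    metric: str = "torsion",
    threshold: float = 30.0,
    discard_mirrors: bool = False,
) -> ClusterResult:
    """Reduce an ensemble to diverse representatives.

    Complete-linkage agglomerative clustering under the chosen metric
    ("torsion": periodic RMS torsion distance in degrees;
    "cartesian-rmsd": superposed RMSD in Angstrom), cut at ``threshold``.
    The representative of each cluster is the member minimizing the summed
    distance to its cluster mates (nearest-to-centroid), ties broken by
    conformer id.  With ``discard_mirrors``, a conformer whose mirror image
    lies within ``threshold`` of an already-kept conformer is dropped
    before clustering.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if metric == "torsion":
        dist = lambda x, y: torsion_distance(x.torsions, y.torsions)
        mirror_dist = lambda x, y: torsion_distance(x.mirror().torsions, y.torsions)
    elif metric == "cartesian-rmsd":
        if any(c.coords is None for c in ensemble):
            raise ValueError("cartesian-rmsd metric requires coordinates")
        dist = lambda x, y: cartesian_rmsd(x.coords, y.coords)
        mirror_dist = lambda x, y: cartesian_rmsd(x.mirror().coords, y.coords)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    conformers = list(ensemble.conformers)
    discarded = []
    if discard_mirrors:
        kept = []
        for c in conformers:
            if any(mirror_dist(c, k) <= threshold for k in kept):
                discarded.append(c.id)
            else:
                kept.append(c)
        conformers = kept
    if not conformers:
        raise ValueError("all conformers discarded as mirrors")

    if len(conformers) == 1:
        labels = np.array([1])
        dm = np.zeros((1, 1))
    else:
        dm = _pairwise(conformers, dist)
        Z = linkage(squareform(dm, checks=False), method="complete")
        labels = fcluster(Z, t=threshold, criterion="distance")

    assignment = {c.id: int(l) for c, l in zip(conformers, labels)}
    reps = []
    for cl in sorted(set(labels)):
        members = np.where(labels == cl)[0]
        sums = dm[np.ix_(members, members)].sum(axis=1)
        # ties broken by id order: stable argmin over (sum, id)
        best = min(zip(sums, [conformers[i].id for i in members], members))[2]
        reps.append(conformers[best])
    return ClusterResult(
        representatives=ConformerEnsemble(
            conformers=tuple(reps), alignment_ref=ensemble.alignment_ref
        ),
        assignment=assignment,
        discarded_mirrors=tuple(discarded),
    )


def boltzmann_populations(energies: Sequence[float], temperature: float) -> np.ndarray:
    """Boltzmann weights w_i proportional to exp(-E_i/(R T)), normalized.

    Invariant under adding a constant to all energies.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("need at least one energy")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    w = np.exp(-(e - e.min()) / (R_KCAL * temperature))
    return w / w.sum()


def ensemble_average_observables(
    ensemble: ConformerEnsemble,
    weights: Sequence[float],
    kinds: Optional[dict] = None,
    distance_averaging: str = "r6",
) -> dict:
    """Population-weighted NMR observables for the ensemble.

    ``kinds`` maps observable name -> "shift" | "coupling" | "distance"
    (default: everything linear).  Shifts and couplings average linearly;
    distances as ``(sum w r^-6)^(-1/6)`` (or r^-3 when
    ``distance_averaging="r3"``).
    """
    w = np.asarray(weights, dtype=float)
    if w.size != len(ensemble):
        raise ValueError("weights must match conformer count")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be a probability vector")
    if distance_averaging not in ("r6", "r3"):
        raise ValueError("distance_averaging must be 'r6' or 'r3'")
    preds = []
    for c in ensemble:
        if c.predicted is None:
            raise ValueError(f"conformer {c.id} lacks predictions")
        preds.append(c.predicted)
    names = set(preds[0])
    for p in preds[1:]:
        if set(p) != names:
            raise ValueError("conformers disagree on predicted observables")

    kinds = kinds or {}
    p_exp = 6.0 if distance_averaging == "r6" else 3.0
    out = {}
    for name in names:
        vals = np.array([p[name] for p in preds], dtype=float)
        if kinds.get(name) == "distance":
            out[name] = float(np.sum(w * vals ** (-p_exp)) ** (-1.0 / p_exp))
        else:
            out[name] = float(np.sum(w * vals))
    return out
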