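"""Conformer distances, clustering, Boltzmann weights, observable averaging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from ligandconf.conformers import (
    Conformer,
    ConformerEnsemble,
    boltzmann_populations,
    cartesian_rmsd,
    cluster_conformers,
    ensemble_average_observables,
    torsion_distance,
)
from ligandconf.constants import R_KCAL

angles = st.lists(
    st.floats(min_value=-180.0, max_value=179.999), min_size=1, max_size=4
)


class TestTorsionDistance:
    def test_identical_is_zero(self):
        assert torsion_distance([10.0, -20.0], [10.0, -20.0]) == 0.0

    def test_wraps_across_180(self):
        assert torsion_distance([179.0], [-179.0]) == pytest.approx(2.0)

    @given(angles, angles)
    def test_symmetry(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        assert torsion_distance(a, b) == pytest.approx(torsion_distance(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            torsion_distance([0.0], [0.0, 1.0])


@pytest.fixture()
def toy_coords():
    # non-planar 4-atom arrangement (chiral under reflection)
    return {
        "C1": (0.0, 0.0, 0.0),
        "C2": (1.5, 0.0, 0.0),
        "N1": (0.0, 1.4, 0.0),
        "O1": (0.3, 0.4, 1.2),
    }


class TestCartesianRMSD:
    def test_identical_zero(self, toy_coords):
        assert cartesian_rmsd(toy_coords, toy_coords) == pytest.approx(0.0, abs=1e-7)

    def test_rotation_invariance(self, toy_coords):
        rot = Rotation.from_euler("xyz", [20.0, -35.0, 110.0], degrees=True)
        rotated = {k: tuple(rot.apply(v)) for k, v in toy_coords.items()}
        assert cartesian_rmsd(toy_coords, rotated) == pytest.approx(0.0, abs=1e-9)

    def test_mirror_not_matched_by_proper_rotations(self, toy_coords):
        mirrored = {k: (-x, y, z) for k, (x, y, z) in toy_coords.items()}
        rmsd = cartesian_rmsd(toy_coords, mirrored, allow_mirror=False)
        assert rmsd > 0.1
        # brute-force proper-rotation search cannot do better
        best = min(
            cartesian_rmsd(
                toy_coords,
                {
                    k: tuple(
                        Rotation.from_euler("xyz", [a, b, c], degrees=True).apply(v)
                    )
                    for k, v in mirrored.items()
                },
            )
            for a in range(0, 360, 45)
            for b in range(0, 360, 45)
            for c in range(0, 360, 45)
        )
        assert rmsd <= best + 1e-6

    def test_mirror_matched_when_allowed(self, toy_coords):
        mirrored = {k: (-x, y, z) for k, (x, y, z) in toy_coords.items()}
        assert cartesian_rmsd(toy_coords, mirrored, allow_mirror=True) == pytest.approx(
            0.0, abs=1e-7
        )

    def test_label_mismatch_rejected(self, toy_coords):
        other = dict(toy_coords)
        other["X9"] = other.pop("O1")
        with pytest.raises(ValueError):
            cartesian_rmsd(toy_coords, other)


def _torsion_ensemble(torsions, prefix="c"):
    return ConformerEnsemble(
        conformers=tuple(
            Conformer(id=f"{prefix}{i:03d}", torsions=(t,)) for i, t in enumerate(torsions)
        )
    )


class TestClustering:
    def test_duplicates_collapse(self):
        ens = _torsion_ensemble([60.0, 60.0, -60.0])
        res = cluster_conformers(ens, metric="torsion", threshold=10.0)
        assert len(res.representatives) == 2

    def test_three_well_synthetic_recovers_well_centers(self):
        rng = np.random.default_rng(0)
        wells = np.array([-60.0, 60.0, 180.0])
        # sigma=3 keeps within-well complete-linkage diameters below the cut
        torsions = [
            float(wells[i % 3] + rng.normal(0, 3.0)) for i in range(500)
        ]
        ens = _torsion_ensemble(torsions)
        res = cluster_conformers(ens, metric="torsion", threshold=30.0)
        reps = sorted(r.torsions[0] for r in res.representatives)
        assert len(reps) == 3
        # wrap-aware: the 180-degree well may report as -180
        devs = [
            min(abs(rep - w) for w in (-60.0, 60.0, 180.0, -180.0)) for rep in reps
        ]
        assert max(devs) < 5.0

    def test_mirror_discarded(self):
        ens = _torsion_ensemble([75.0, -75.0])
        res = cluster_conformers(
            ens, metric="torsion", threshold=10.0, discard_mirrors=True
        )
        assert len(res.representatives) == 1
        assert res.discarded_mirrors == ("c001",)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        torsions = list(rng.uniform(-180, 180, size=40))
        ens = _torsion_ensemble(torsions)
        res_a = cluster_conformers(ens, threshold=40.0)
        perm = rng.permutation(40)
        shuffled = ConformerEnsemble(
            conformers=tuple(ens.conformers[i] for i in perm)
        )
        res_b = cluster_conformers(shuffled, threshold=40.0)
        assert sorted(res_a.representatives.ids()) == sorted(res_b.representatives.ids())

    def test_cartesian_metric_requires_coords(self):
        ens = _torsion_ensemble([0.0, 10.0])
        with pytest.raises(ValueError, match="coord"):
            cluster_conformers(ens, metric="cartesian-rmsd")

    def test_representative_count_in_diverse_report_range(self):
        # report-scale synthetic ensemble: 500 frames over 24 distinguishable
        # torsion states => 15-40 diverse representatives at default threshold
        rng = np.random.default_rng(1)
        centers = np.linspace(-180.0, 180.0, 24, endpoint=False)
        torsions = [
            float(centers[rng.integers(24)] + rng.normal(0, 4.0)) for _ in range(500)
        ]
        res = cluster_conformers(_torsion_ensemble(torsions), threshold=30.0)
        assert 15 <= len(res.representatives) <= 40


class TestBoltzmann:
    def test_equal_energies_equal_weights(self):
        np.testing.assert_allclose(
            boltzmann_populations([3.0, 3.0], 300.0), [0.5, 0.5]
        )

    def test_rt_ln3_gap_gives_75_25(self):
        dE = R_KCAL * 300.0 * np.log(3.0)
        w = boltzmann_populations([0.0, dE], 300.0)
        np.testing.assert_allclose(w, [0.75, 0.25], atol=1e-12)

    @given(st.floats(min_value=-500.0, max_value=500.0))
    def test_gauge_invariance(self, shift):
        base = boltzmann_populations([0.0, 1.0, 2.5], 300.0)
        shifted = boltzmann_populations([shift, 1.0 + shift, 2.5 + shift], 300.0)
        np.testing.assert_allclose(base, shifted, atol=1e-12)

    def test_normalization_exact(self):
        w = boltzmann_populations(np.arange(10.0), 310.0)
        assert abs(w.sum() - 1.0) < 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_populations([], 300.0)


class TestAveraging:
    def _pair(self, preds_a, preds_b):
        return ConformerEnsemble(
            conformers=(
                Conformer(id="a", predicted=preds_a),
                Conformer(id="b", predicted=preds_b),
            )
        )

    def test_single_conformer_identity(self):
        ens = ConformerEnsemble(conformers=(Conformer(id="a", predicted={"H1": 4.2}),))
        assert ensemble_average_observables(ens, [1.0]) == {"H1": 4.2}

    def test_linear_shift_average(self):
        ens = self._pair({"H1": 2.0}, {"H1": 4.0})
        assert ensemble_average_observables(ens, [0.5, 0.5])["H1"] == pytest.approx(3.0)

    def test_r6_distance_average(self):
        ens = self._pair({"noe1": 2.0}, {"noe1": 4.0})
        out = ensemble_average_observables(
            ens, [0.5, 0.5], kinds={"noe1": "distance"}
        )
        assert out["noe1"] == pytest.approx(2.2391, abs=1e-3)

    def test_r3_option(self):
        ens = self._pair({"noe1": 2.0}, {"noe1": 4.0})
        out = ensemble_average_observables(
            ens, [0.5, 0.5], kinds={"noe1": "distance"}, distance_averaging="r3"
        )
        expected = (0.5 * 2.0**-3 + 0.5 * 4.0**-3) ** (-1 / 3)
        assert out["noe1"] == pytest.approx(expected)

    def test_missing_prediction_rejected(self):
        ens = ConformerEnsemble(
            conformers=(Conformer(id="a", predicted={"H1": 1.0}), Conformer(id="b"))
        )
        with pytest.raises(ValueError, match="lacks predictions"):
            ensemble_average_observables(ens, [0.5, 0.5])
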