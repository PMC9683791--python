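"""Kabsch superposition, displacement maps and segment distance metrics."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from aldpkit.conformational import (
    DistanceSpec,
    kabsch_superpose,
    per_residue_displacement,
    residue_pair_min_distance,
    segment_distance,
    state_series_report,
)
from aldpkit.errors import (
    ConditioningError,
    EmptySubsetError,
    PairingError,
    ValidationError,
)
from aldpkit.structure_model import SegmentAnnotation, StructureModel
from aldpkit.synth import HelixSpec, apply_rigid, make_ideal_helix, rotation_about

from conftest import ca_model, make_residue


def brute_force_rmsd(mobile, reference):
    """Independent oracle: direct numeric minimisation over rotation
    (rotation-vector parameterisation) and translation."""

    def cost(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        moved = mobile @ rot.T + params[3:]
        return np.sqrt(((moved - reference) ** 2).sum(axis=1).mean())

    best = np.inf
    for x0 in ([0, 0, 0, 0, 0, 0], [1, 1, 1, 0, 0, 0], [-2, 0.5, 2, 1, -1, 1]):
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identical_sets(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-8)

    def test_recovers_planted_transform(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(30, 3))
        rot = rotation_about((0, 0, 1), 90.0)
        mobile, truth = apply_rigid(ref, rot, (5.0, 0.0, 0.0))
        res = kabsch_superpose(mobile, ref)
        assert res.rmsd < 1e-8
        # recovered transform is the inverse of the planted one
        assert np.allclose(res.rotation, rot.T, atol=1e-8)

    def test_noisy_rmsd_matches_direct_minimizer(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(scale=10.0, size=(200, 3))
        rot = rotation_about((1, 2, 3), 37.0)
        mobile, _ = apply_rigid(ref, rot, (3, -2, 1), noise_sd=0.5, seed=7)
        res = kabsch_superpose(mobile, ref)
        oracle = brute_force_rmsd(mobile, ref)
        assert res.rmsd == pytest.approx(oracle, rel=0.10)
        assert res.rmsd <= oracle + 1e-9  # closed form is the true optimum

    @pytest.mark.parametrize("seed", range(5))
    def test_rmsd_invariant_under_common_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(25, 3))
        b = a + rng.normal(scale=0.3, size=a.shape)
        base = kabsch_superpose(a, b).rmsd
        rot = rotation_about(rng.normal(size=3), float(rng.uniform(0, 360)))
        shift = rng.normal(scale=5, size=3)
        a2, _ = apply_rigid(a, rot, shift)
        b2, _ = apply_rigid(b, rot, shift)
        assert abs(kabsch_superpose(a2, b2).rmsd - base) < 1e-8

    def test_rmsd_never_exceeds_unfitted(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=(15, 3))
            b = rng.normal(size=(15, 3))
            raw = np.sqrt(((a - b) ** 2).sum(axis=1).mean())
            assert kabsch_superpose(a, b).rmsd <= raw + 1e-12

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(4)
        res = kabsch_superpose(rng.normal(size=(10, 3)), rng.normal(size=(10, 3)))
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(PairingError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_degenerate(self):
        line = np.outer(np.arange(10), [1.0, 0, 0])
        with pytest.raises(ConditioningError):
            kabsch_superpose(line, line)


class TestDisplacement:
    def test_rigidly_moved_copy_shows_zero(self):
        coords = make_ideal_helix(HelixSpec(n_residues=20))
        a = ca_model(coords)
        moved, _ = apply_rigid(coords, rotation_about((0, 1, 0), 25.0), (4, 5, 6))
        b = ca_model(moved)
        table = per_residue_displacement(a, b)
        assert max(d for _, d in table.entries) < 1e-8

    def test_single_displaced_residue(self):
        coords = make_ideal_helix(HelixSpec(n_residues=20))
        shifted = coords.copy()
        shifted[10] += np.array([0.0, 0.0, 5.0])
        a, b = ca_model(coords), ca_model(shifted)
        table = per_residue_displacement(a, b, alignment_window=("A", 1, 10))
        disp = {ref.residue_number: d for ref, d in table.entries}
        assert disp[11] == pytest.approx(5.0, abs=1e-9)
        assert all(d < 1e-9 for num, d in disp.items() if num != 11)

    def test_hinge_bend_monotone_with_distance_from_hinge(self):
        # straight CA line along z; residues past the hinge at z=10 rotate
        # about the x axis through (0,0,10): |delta| = 2 sin(t/2) * arm
        z = np.arange(21.0)
        coords = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        hinge = np.array([0.0, 0.0, 10.0])
        rot = rotation_about((1, 0, 0), 20.0)
        bent = coords.copy()
        mask = z > 10
        bent[mask] = (coords[mask] - hinge) @ rot.T + hinge
        # displace x a little so the fixed part is not collinear
        coords[:3, 0] += [0.5, -0.5, 0.25]
        bent[:3, 0] += [0.5, -0.5, 0.25]
        table = per_residue_displacement(
            ca_model(coords), ca_model(bent), alignment_window=("A", 1, 11)
        )
        moved = [(ref.residue_number, d) for ref, d in table.entries if ref.residue_number > 11]
        disps = [d for _, d in sorted(moved)]
        assert all(b > a for a, b in zip(disps, disps[1:]))
        arm = 21.0 - 11.0 - 1.0 + 1.0  # furthest residue: z=20, arm=10
        expected = 2 * np.sin(np.deg2rad(10.0)) * arm
        assert disps[-1] == pytest.approx(expected, rel=1e-6)

    def test_no_shared_residues(self):
        a = ca_model(np.zeros((3, 3)) + np.arange(3)[:, None], start=1)
        b = ca_model(np.zeros((3, 3)) + np.arange(3)[:, None], start=100)
        with pytest.raises(PairingError):
            per_residue_displacement(a, b)


def two_helix_fixture(separation=10.0, radius=2.3):
    a = make_ideal_helix(HelixSpec(n_residues=15, radius=radius, axis_origin=(0, 0, 0)))
    b = make_ideal_helix(
        HelixSpec(n_residues=15, radius=radius, axis_origin=(separation, 0, 0))
    )
    coords = np.vstack([a, b])
    model = ca_model(coords)
    ann = SegmentAnnotation(
        ranges={"TM4": [("A", 1, 15)], "TM6": [("A", 16, 30)]}
    )
    return model, ann, a, b


class TestSegmentDistance:
    def test_min_matches_exhaustive_scan(self):
        model, ann, a, b = two_helix_fixture(10.0)
        spec = DistanceSpec("gate", "TM4", "TM6")
        got = segment_distance(model, ann, spec).value
        oracle = min(
            np.linalg.norm(pa - pb) for pa in a for pb in b
        )
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_single_pair_window(self):
        coords = np.array([[0.0, 0, 0], [7.25, 0, 0], [20, 0, 0], [30, 0, 0]])
        model = ca_model(coords)
        ann = SegmentAnnotation(ranges={"TM4": [("A", 1, 2)], "TM6": [("A", 3, 4)]})
        spec = DistanceSpec("pair", "TM4", "TM6", metric="pair_ca_ca",
                            window_a=(2, 2), window_b=(3, 3))
        m = segment_distance(model, ann, spec)
        assert m.value == pytest.approx(12.75)

    def test_symmetry_and_nonnegativity(self):
        model, ann, *_ = two_helix_fixture(8.0)
        ab = segment_distance(model, ann, DistanceSpec("x", "TM4", "TM6")).value
        ba = segment_distance(model, ann, DistanceSpec("x", "TM6", "TM4")).value
        assert ab == pytest.approx(ba)
        assert ab >= 0

    def test_empty_window_rejected(self):
        model, ann, *_ = two_helix_fixture()
        spec = DistanceSpec("bad", "TM4", "TM6", window_a=(200, 300))
        with pytest.raises(ValidationError):
            segment_distance(model, ann, spec)

    def test_terminal_window_uses_high_numbered_residues(self):
        # TM4 tilted away from TM6 at its start: the terminal-5 window must
        # measure the close (high-numbered) end only
        a = np.column_stack([np.linspace(0, -20, 15), np.zeros(15), np.arange(15.0)])
        b = np.column_stack([np.full(15, 6.0), np.zeros(15), np.arange(15.0)])
        model = ca_model(np.vstack([a, b]))
        ann = SegmentAnnotation(ranges={"TM4": [("A", 1, 15)], "TM6": [("A", 16, 30)]})
        full = segment_distance(model, ann, DistanceSpec("g", "TM4", "TM6")).value
        term = segment_distance(
            model, ann, DistanceSpec("g", "TM4", "TM6", terminal=5)
        ).value
        assert term >= full


class TestResiduePairDistance:
    def build(self):
        trp = make_residue(
            "A", 664, "TRP",
            [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
             ("C", "C", (2.2, 1.3, 0)), ("O", "O", (1.6, 2.3, 0)),
             ("CB", "C", (2.0, -1.2, 0.8)), ("CG", "C", (3.4, -1.5, 0.9))],
        )
        thr = make_residue(
            "A", 693, "THR",
            [("N", "N", (6.0, 0, 0)), ("CA", "C", (6.5, -1.0, 0.5)),
             ("C", "C", (8.0, -1.0, 0.5)), ("O", "O", (8.6, -2.0, 0.5)),
             ("OG1", "O", (6.8, -1.5, 0.9))],
        )
        gly = make_residue("A", 700, "GLY",
                           [("N", "N", (10, 0, 0)), ("CA", "C", (11.5, 0, 0)),
                            ("C", "C", (12.2, 1.3, 0)), ("O", "O", (11.6, 2.3, 0))])
        return StructureModel(entry_id="T", chains={"A": [trp, thr, gly]})

    def test_constructed_side_chain_minimum(self):
        model = self.build()
        got = residue_pair_min_distance(model, ("A", 664), ("A", 693), "side_chain")
        # closest side-chain atoms: CG(3.4,-1.5,0.9) vs OG1(6.8,-1.5,0.9)
        assert got == pytest.approx(3.40, abs=1e-9)

    def test_all_heavy_never_exceeds_side_chain(self):
        model = self.build()
        all_heavy = residue_pair_min_distance(model, ("A", 664), ("A", 693), "all_heavy")
        side = residue_pair_min_distance(model, ("A", 664), ("A", 693), "side_chain")
        assert all_heavy <= side

    def test_glycine_side_chain_is_explicit_error(self):
        with pytest.raises(EmptySubsetError):
            residue_pair_min_distance(self.build(), ("A", 664), ("A", 700), "side_chain")


class TestStateSeries:
    def test_planted_distances(self):
        specs = [DistanceSpec("gate", "TM4", "TM6")]
        states = []
        ann = None
        for name, d in (("open", 20.0), ("bound", 12.0), ("closed", 6.0)):
            # radius-0 helices: parallel CA lines, planted min distance exact
            model, ann_d, *_ = two_helix_fixture(d, radius=0.0)
            states.append((name, model))
            ann = ann_d
        table = state_series_report(states, ann, specs)
        got = table["value_angstrom"].tolist()
        for value, planted in zip(got, (20.0, 12.0, 6.0)):
            assert value == pytest.approx(planted, abs=1e-9)
        assert list(table.columns) == ["state", "spec_name", "value_angstrom"]

    def test_single_state_single_spec(self):
        model, ann, *_ = two_helix_fixture(9.0)
        table = state_series_report([("only", model)], ann,
                                    [DistanceSpec("gate", "TM4", "TM6")])
        assert table.shape == (1, 3)
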