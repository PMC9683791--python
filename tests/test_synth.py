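"""Synthetic-fixture generators: planted truths and determinism."""

import math

import numpy as np
import pytest

from aldpkit.conformational import DistanceSpec, kabsch_superpose, segment_distance
from aldpkit.errors import GeneratorError, NoTransitionError, ValidationError
from aldpkit.kinetics import melt_tm, mm_rate
from aldpkit.synth import (
    HelixSpec,
    apply_rigid,
    make_bundle_model,
    make_cavity_shell,
    make_chain_ligand,
    make_ideal_helix,
    rotation_about,
    simulate_melt_curve,
    simulate_mm_data,
    simulate_variant_table,
)
from aldpkit.variants import call_hotspots, parse_variant_table


class TestIdealHelix:
    def test_chord_length_closed_form(self):
        spec = HelixSpec(n_residues=10, rise=1.5, twist=100.0, radius=2.3)
        xyz = make_ideal_helix(spec)
        d = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        expected = math.sqrt(1.5**2 + (2 * 2.3 * math.sin(math.radians(50))) ** 2)
        assert np.allclose(d, expected, atol=1e-9)
        assert expected == pytest.approx(3.83, abs=0.01)

    def test_zero_radius_collinear(self):
        xyz = make_ideal_helix(HelixSpec(n_residues=8, radius=0.0))
        d = np.diff(xyz, axis=0)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.5)
        assert np.allclose(np.cross(d[0], d[1:]), 0.0, atol=1e-12)

    def test_zero_twist_straight_offset_line(self):
        xyz = make_ideal_helix(HelixSpec(n_residues=8, twist=0.0, radius=2.3))
        d = np.diff(xyz, axis=0)
        assert np.allclose(d, d[0], atol=1e-12)

    def test_invalid_spec(self):
        with pytest.raises(ValidationError):
            HelixSpec(n_residues=2)


class TestBundle:
    HELICES = [
        ("TM4", HelixSpec(n_residues=12, axis_origin=(0, 0, 0), radius=0.0)),
        ("TM6", HelixSpec(n_residues=12, axis_origin=(7.0, 0, 0), radius=0.0)),
    ]

    def test_annotation_covers_all_residues(self):
        model, ann, _ = make_bundle_model(self.HELICES)
        covered = set()
        for seg in ann.ranges:
            for chain, s, e in ann.ranges[seg]:
                covered.update((chain, n) for n in range(s, e + 1))
        actual = {(r.ref.chain_id, r.ref.residue_number) for r in model.residues()}
        assert actual == covered

    def test_dimer_related_by_recorded_operator(self):
        model, _, truth = make_bundle_model(self.HELICES, dimer=True)
        rot = np.array(truth["c2_rotation"])
        center = np.array(truth["c2_center"])
        a = np.array([r.ca.position for r in model.chain("A")])
        b = np.array([r.ca.position for r in model.chain("B")])
        assert np.allclose((a - center) @ rot.T + center, b, atol=1e-9)
        assert model.assembly_symmetry == "C2"

    def test_planted_min_distance_recovered(self):
        model, ann, _ = make_bundle_model(self.HELICES)
        got = segment_distance(
            model, ann, DistanceSpec("gate", "TM4", "TM6", chain_a="A", chain_b="A")
        ).value
        # exhaustive pair scan oracle
        a = np.array([r.ca.position for r in ann.residues_in(model, "TM4", "A")])
        b = np.array([r.ca.position for r in ann.residues_in(model, "TM6", "A")])
        oracle = min(np.linalg.norm(x - y) for x in a for y in b)
        assert got == pytest.approx(oracle) == pytest.approx(7.0)

    def test_clash_recorded(self):
        helices = [
            ("TM1", HelixSpec(n_residues=10, axis_origin=(0, 0, 0), radius=0.0)),
            ("TM2", HelixSpec(n_residues=10, axis_origin=(0.2, 0, 0), radius=0.0)),
        ]
        _, _, truth = make_bundle_model(helices)
        assert truth["clashes"]


class TestApplyRigid:
    def test_identity_no_noise(self):
        pts = np.random.default_rng(0).normal(size=(12, 3))
        out, _ = apply_rigid(pts, np.eye(3), (0, 0, 0))
        assert np.array_equal(out, pts)

    def test_kabsch_recovers_recorded_rotation(self):
        pts = np.random.default_rng(1).normal(size=(30, 3))
        rot = rotation_about((0, 0, 1), 90.0)
        out, truth = apply_rigid(pts, rot, (1, 2, 3))
        res = kabsch_superpose(out, pts)
        assert res.rmsd < 1e-8
        assert np.allclose(res.rotation @ np.array(truth["rotation"]), np.eye(3), atol=1e-8)

    def test_noise_rmsd_matches_small_sample_estimate(self):
        # fitted rmsd after Kabsch loses 3 rigid dof in each of 2 half-sets:
        # E[rmsd] ~ sqrt(3) sigma sqrt((n - 3/2)/n) at large n
        n, sigma = 500, 0.4
        pts = np.random.default_rng(2).normal(scale=8, size=(n, 3))
        out, _ = apply_rigid(pts, rotation_about((1, 0, 0), 30.0), (2, 2, 2),
                             noise_sd=sigma, seed=5)
        rmsd = kabsch_superpose(out, pts).rmsd
        expected = math.sqrt(3) * sigma * math.sqrt((n - 1.5) / n)
        assert rmsd == pytest.approx(expected, rel=0.10)

    def test_non_rotation_rejected(self):
        with pytest.raises(ValidationError):
            apply_rigid(np.zeros((4, 3)), np.diag([1.0, 1.0, -1.0]), (0, 0, 0))


class TestCavityShellGenerator:
    def test_truth_records_analytic_volume(self):
        _, truth = make_cavity_shell(void_radius=10.0)
        assert truth["analytic_volume"] == pytest.approx(4188.79, abs=0.01)

    def test_too_sparse_to_seal(self):
        with pytest.raises(GeneratorError):
            make_cavity_shell(void_radius=8.0, atom_spacing=3.5)

    def test_invalid_radius(self):
        with pytest.raises(ValidationError):
            make_cavity_shell(void_radius=-1.0)


class TestChainLigand:
    def test_two_atoms(self):
        lig, truth = make_chain_ligand(2, spacing=2.0)
        assert truth["collinear_extent"] == 2.0
        assert len(lig.atoms) == 2

    def test_single_atom_rejected(self):
        with pytest.raises(ValidationError):
            make_chain_ligand(1)


class TestVariantTableGenerator:
    def test_planted_counts_recovered(self):
        table, truth = simulate_variant_table(seed=2)
        parsed = parse_variant_table(table)
        hot = call_hotspots(parsed.records)
        assert len(hot.hotspot_residues) == truth["n_hotspots"] == 88
        assert len(hot.affected_residues) == truth["n_affected"] == 232
        assert len(parsed.records) == truth["n_records_missense"] == 970

    def test_zero_hotspots(self):
        table, _ = simulate_variant_table(
            n_residues=100, n_hotspots=0, n_single=20, n_records=30, seed=1
        )
        hot = call_hotspots(parse_variant_table(table).records)
        assert hot.hotspot_residues == []

    def test_seed_determinism_byte_identical(self):
        t1, _ = simulate_variant_table(seed=9)
        t2, _ = simulate_variant_table(seed=9)
        assert t1 == t2
        t3, _ = simulate_variant_table(seed=10)
        assert t1 != t3

    def test_infeasible_request(self):
        with pytest.raises(ValidationError):
            simulate_variant_table(n_residues=10, n_hotspots=8, n_single=5)


class TestSimulatedAssays:
    def test_noiseless_points_on_curve(self):
        data, truth = simulate_mm_data(vmax=100.0, km=0.5)
        assert np.allclose(
            data.rate, mm_rate(data.substrate_conc, 100.0, 0.5), atol=1e-12
        )

    def test_mm_seed_reproducibility(self):
        d1, _ = simulate_mm_data(noise_sd=3.0, seed=4)
        d2, _ = simulate_mm_data(noise_sd=3.0, seed=4)
        assert np.array_equal(d1.rate, d2.rate)

    def test_flat_melt_exercises_no_transition(self):
        curve, _ = simulate_melt_curve(tm=55.0, baselines=(1.0, 1.0))
        with pytest.raises(NoTransitionError):
            melt_tm(curve)

    def test_melt_recovery_sd_under_half_degree(self):
        tms = []
        for seed in range(100):
            curve, _ = simulate_melt_curve(tm=55.0, noise_sd=0.01, seed=seed)
            tms.append(melt_tm(curve, smoothing_window=7).tm)
        assert np.std(tms) < 0.5
        assert abs(np.mean(tms) - 55.0) < 0.5

    def test_melt_tm_out_of_ramp(self):
        with pytest.raises(ValidationError):
            simulate_melt_curve(tm=20.0)
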