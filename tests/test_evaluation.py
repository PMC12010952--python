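"""CAPRI metrics, superposition, enrichment, and KS statistics versus oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from hdxdock.evaluation import (
    EvaluationError,
    capri_class,
    compute_quality,
    enrichment,
    interface_residues,
    ks_two_sample,
    superpose_rmsd,
)
from hdxdock.model_io import AtomRecord, StructureModel
from hdxdock.sampler import Pose, apply_pose, random_rotation_uniform


def _two_residue_complex(gap):
    atoms = [
        AtomRecord("H", 1, "", "ALA", "CA", (0.0, 0.0, 0.0), "C"),
        AtomRecord("H", 1, "", "ALA", "CB", (0.0, 0.0, 1.0), "C"),
        AtomRecord("A", 1, "", "ALA", "CA", (0.0, 0.0, -gap), "C"),
        AtomRecord("A", 1, "", "ALA", "CB", (0.0, 0.0, -gap - 1.0), "C"),
    ]
    return StructureModel("m", atoms, frozenset("H"), frozenset("A"))


class TestInterfaceResidues:
    def test_below_cutoff_both_included(self):
        iface = interface_residues(_two_residue_complex(9.0))
        assert iface == {("H", 1, ""), ("A", 1, "")}

    def test_above_cutoff_empty(self):
        assert interface_residues(_two_residue_complex(11.0)) == set()

    def test_matches_all_pairs_oracle(self, toy):
        _, reference, _ = toy
        got = interface_residues(reference)
        # exhaustive heavy-atom double loop
        ab = [a for a in reference.atoms if a.chain_id in "HL" and not a.is_hydrogen]
        ag = [a for a in reference.atoms if a.chain_id == "A" and not a.is_hydrogen]
        expected = set()
        for x, y in itertools.product(ab, ag):
            d = math.dist(x.coords, y.coords)
            if d < 10.0:
                expected.add(x.residue_key)
                expected.add(y.residue_key)
        assert got == expected
        assert got  # the toy interface is non-trivial


class TestSuperposition:
    def test_identity(self, rng):
        pts = rng.uniform(-10, 10, (12, 3))
        _, _, rmsd = superpose_rmsd(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_removed(self, rng):
        pts = rng.uniform(-10, 10, (12, 3))
        _, _, rmsd = superpose_rmsd(pts, pts + np.array([5.0, 5.0, 5.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rotation_is_proper(self, rng):
        a = rng.uniform(-10, 10, (10, 3))
        b = -a  # a reflection would fit this perfectly; Kabsch must not reflect
        R, _, _ = superpose_rmsd(a, b)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_rotation_matches_numerical_minimizer(self, rng):
        mobile = rng.uniform(-10, 10, (10, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        target = mobile @ Rz.T + 0.5 * rng.normal(size=(10, 3))
        _, _, rmsd = superpose_rmsd(mobile, target)

        def objective(params):
            R = Rotation.from_rotvec(params[:3]).as_matrix()
            moved = mobile @ R.T + params[3:]
            return np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1)))

        best = min(
            minimize(objective, np.concatenate([rv, np.zeros(3)]), method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000}).fun
            for rv in (np.zeros(3), Rotation.from_matrix(Rz).as_rotvec())
        )
        assert rmsd == pytest.approx(best, abs=1e-4)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(EvaluationError):
            superpose_rmsd(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestCapriClass:
    def test_self_comparison_is_high(self, toy):
        _, reference, _ = toy
        q = compute_quality(reference, reference)
        assert q.fnat == pytest.approx(1.0)
        assert q.lrmsd == pytest.approx(0.0, abs=1e-9)
        assert q.irmsd == pytest.approx(0.0, abs=1e-9)
        assert q.capri_class == "high"
        assert q.near_native

    @pytest.mark.parametrize(
        "fnat,lrmsd,irmsd,expected",
        [
            (0.35, 6.0, 1.5, "medium"),
            (0.05, 0.0, 0.0, "incorrect"),
            (0.5, 1.0, 9.0, "high"),
            (0.5, 9.0, 1.0, "high"),
            (0.3, 5.0, 9.0, "medium"),
            (0.1, 10.0, 9.0, "acceptable"),
            (0.1, 11.0, 4.0, "acceptable"),
            (0.1, 11.0, 4.1, "incorrect"),
            (0.29, 2.0, 9.0, "acceptable"),
        ],
    )
    def test_examples(self, fnat, lrmsd, irmsd, expected):
        assert capri_class(fnat, lrmsd, irmsd) == expected

    def test_boundary_grid_matches_cascading_oracle(self):
        fnats = [0.0, 0.05, 0.1, 0.29, 0.3, 0.49, 0.5, 0.8, 1.0]
        rmsds = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 4.0, 4.5, 5.0, 7.0, 10.0, 12.0]
        for fnat, l, i in itertools.product(fnats, rmsds, rmsds):
            # independent literal transcription of the class table
            if fnat >= 0.5 and (l <= 1.0 or i <= 1.0):
                expected = "high"
            elif fnat >= 0.3 and (l <= 5.0 or i <= 2.0):
                expected = "medium"
            elif fnat >= 0.1 and (l <= 10.0 or i <= 4.0):
                expected = "acceptable"
            else:
                expected = "incorrect"
            assert capri_class(fnat, l, i) == expected

    def test_rigid_transform_leaves_quality_invariant(self, toy, rng):
        _, reference, _ = toy
        q0 = compute_quality(reference, reference)
        # move the whole complex rigidly: metrics must not change
        R = random_rotation_uniform(rng)
        t = rng.uniform(-30, 30, 3)
        moved = reference.with_atoms(
            [
                AtomRecord(a.chain_id, a.res_seq, a.icode, a.res_name, a.atom_name,
                           tuple(R @ np.asarray(a.coords) + t), a.element)
                for a in reference.atoms
            ]
        )
        q1 = compute_quality(moved, reference)
        assert q1.fnat == pytest.approx(q0.fnat)
        assert q1.lrmsd == pytest.approx(q0.lrmsd, abs=1e-6)
        assert q1.irmsd == pytest.approx(q0.irmsd, abs=1e-6)

    def test_fnat_counts_reference_contacts_reproduced(self, toy):
        _, reference, _ = toy
        # pull the antibody 3 A away: some contacts break, fnat drops below 1
        pose = Pose(rotation=np.eye(3), translation=np.array([0.0, 0.0, 3.0]))
        moved = apply_pose(reference, pose)
        q = compute_quality(moved, reference)
        assert 0.0 <= q.fnat < 1.0


class TestEnrichment:
    def test_perfect_ranking_gives_maximum(self, rng):
        irmsd = {f"m{i:04d}": float(v) for i, v in enumerate(rng.uniform(0, 20, 1000))}
        scores = dict(irmsd)  # score identical to irmsd
        res = enrichment(scores, irmsd)
        assert res.enrichment == pytest.approx(10.0)
        assert res.P == 100 and res.TP == 100 and res.FP == 0

    def test_anti_perfect_ranking_gives_zero(self, rng):
        irmsd = {f"m{i:04d}": float(v) for i, v in enumerate(rng.uniform(0, 20, 1000))}
        scores = {m: -v for m, v in irmsd.items()}
        assert enrichment(scores, irmsd).enrichment == pytest.approx(0.0)

    def test_random_permutation_mean_near_one(self):
        rng = np.random.default_rng(7)
        irmsd = {f"m{i:04d}": float(v) for i, v in enumerate(rng.uniform(0, 20, 1000))}
        values = np.array(list(irmsd.values()))
        ids = list(irmsd)
        means = []
        for _ in range(200):
            perm = rng.permutation(values)
            scores = dict(zip(ids, perm))
            means.append(enrichment(scores, irmsd).enrichment)
        assert np.mean(means) == pytest.approx(1.0, abs=0.1)

    def test_bounds_and_bookkeeping(self, rng):
        irmsd = {f"m{i}": float(v) for i, v in enumerate(rng.uniform(0, 20, 57))}
        scores = {m: float(v) for m, v in zip(irmsd, rng.normal(size=57))}
        res = enrichment(scores, irmsd)
        assert res.P + res.N == 57
        assert res.TP + res.FP == res.P
        assert 0.0 <= res.enrichment <= (res.P + res.N) / res.P

    def test_small_ensemble_rejected(self):
        with pytest.raises(EvaluationError):
            enrichment({"a": 1.0}, {"a": 1.0})


class TestKS:
    def test_identical_samples_give_zero(self, rng):
        a = rng.normal(size=50)
        d, _ = ks_two_sample(a, a)
        assert d == pytest.approx(0.0)

    def test_disjoint_supports_give_one(self, rng):
        d, p = ks_two_sample(rng.uniform(0, 1, 40), rng.uniform(5, 6, 40))
        assert d == pytest.approx(1.0)
        assert p < 1e-10

    def test_matches_ecdf_scan_oracle(self, rng):
        a = rng.normal(0, 1, 500)
        b = rng.normal(0.3, 1.2, 500)
        d, _ = ks_two_sample(a, b)
        grid = np.concatenate([a, b])
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
        assert d == pytest.approx(np.abs(ecdf_a - ecdf_b).max(), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(EvaluationError):
            ks_two_sample([], [1.0])
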