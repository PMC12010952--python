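"""Flat-harmonic restraint penalties versus exhaustive-pair oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdxdock.fixtures import FixtureSpec, make_decoy_ensemble, make_toy_complex
from hdxdock.model_io import (
    AtomRecord,
    CDRDefinition,
    CDRSegment,
    HDXPeptide,
    RestraintSpec,
    StructureModel,
)
from hdxdock.restraints import (
    RestraintError,
    flat_harmonic,
    model_hdx_penalty,
    penalty_table,
    peptide_effective_distance,
    percent_normalize,
)


def brute_force_effective_distance(pep_xyz, cdr_xyz, k):
    """Independent double-loop oracle: k-th smallest per-residue minimum."""
    minima = []
    for p in pep_xyz:
        best = min(float(np.sqrt(np.sum((p - c) ** 2))) for c in cdr_xyz)
        minima.append(best)
    return sorted(minima)[k - 1]


def _model_from_points(pep_xyz, cdr_xyz, pep_resnames=None):
    atoms = []
    for i, xyz in enumerate(cdr_xyz):
        atoms.append(AtomRecord("H", i + 1, "", "ALA", "CA", tuple(map(float, xyz)), "C"))
    for i, xyz in enumerate(pep_xyz):
        name = pep_resnames[i] if pep_resnames else "ALA"
        atoms.append(AtomRecord("A", i + 1, "", name, "CA", tuple(map(float, xyz)), "C"))
    model = StructureModel("m", atoms, frozenset("H"), frozenset("A"))
    cdrs = CDRDefinition((CDRSegment("H", 1, len(cdr_xyz)),))
    pep = HDXPeptide("p", "A", 1, len(pep_xyz))
    return model, pep, cdrs


class TestFlatHarmonic:
    def test_inside_threshold_is_zero(self):
        assert flat_harmonic(7.2, 10) == 0.0
        assert flat_harmonic(10, 10) == 0.0

    def test_quadratic_beyond_threshold(self):
        assert flat_harmonic(12, 10) == pytest.approx(4.0)

    def test_grid_matches_direct_evaluation(self):
        xs = np.linspace(0, 30, 100)
        ds = np.linspace(0.5, 20, 100)
        for d in ds:
            expected = np.where(xs <= d, 0.0, (xs - d) ** 2)
            got = np.array([flat_harmonic(x, d) for x in xs])
            np.testing.assert_allclose(got, expected, rtol=1e-14, atol=0)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(RestraintError):
            flat_harmonic(1.0, 0.0)


class TestEffectiveDistance:
    def test_single_pair_geometry(self):
        model, pep, cdrs = _model_from_points([(0, 0, 0)], [(0, 0, 6)])
        x = peptide_effective_distance(model, pep, cdrs, RestraintSpec(k=1))
        assert x == pytest.approx(6.0)

    def test_all_proline_peptide_errors(self):
        model, pep, cdrs = _model_from_points(
            [(0, 0, 0), (3.8, 0, 0)], [(0, 0, 6)], pep_resnames=["PRO", "PRO"]
        )
        with pytest.raises(RestraintError, match="p"):
            peptide_effective_distance(model, pep, cdrs, RestraintSpec())

    def test_proline_excluded_only_on_peptide_side(self):
        # the nearest peptide residue is a proline: it must not count
        model, pep, cdrs = _model_from_points(
            [(0, 0, 3), (0, 0, -8)], [(0, 0, 6)], pep_resnames=["PRO", "ALA"]
        )
        x = peptide_effective_distance(model, pep, cdrs, RestraintSpec())
        assert x == pytest.approx(14.0)
        x_incl = peptide_effective_distance(
            model, pep, cdrs, RestraintSpec(exclude_proline=False)
        )
        assert x_incl == pytest.approx(3.0)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_random_clouds_match_brute_force(self, k, rng):
        for _ in range(5):
            pep_xyz = rng.uniform(-20, 20, size=(20, 3))
            cdr_xyz = rng.uniform(-20, 20, size=(30, 3))
            model, pep, cdrs = _model_from_points(pep_xyz, cdr_xyz)
            got = peptide_effective_distance(model, pep, cdrs, RestraintSpec(k=k))
            assert got == pytest.approx(
                brute_force_effective_distance(pep_xyz, cdr_xyz, k), abs=1e-9
            )


class TestModelPenalty:
    def test_satisfied_restraints_give_zero_total(self, toy):
        _, reference, config = toy
        mp = model_hdx_penalty(
            reference, config.hdx_peptides, config.cdrs, config.restraint_spec
        )
        assert mp.total == 0.0
        assert all(p.penalty == 0.0 for p in mp.peptides)

    def test_total_is_sum_of_flat_harmonics(self):
        pep_xyz = [(0, 0, 22), (0, 0, 23)]
        cdr_xyz = [(0, 0, 0)]
        atoms = [AtomRecord("H", 1, "", "ALA", "CA", (0.0, 0.0, 0.0), "C")]
        atoms += [
            AtomRecord("A", i + 1, "", "ALA", "CA", tuple(map(float, x)), "C")
            for i, x in enumerate(pep_xyz)
        ]
        model = StructureModel("m", atoms, frozenset("H"), frozenset("A"))
        cdrs = CDRDefinition((CDRSegment("H", 1, 1),))
        peps = [HDXPeptide("a", "A", 1, 1), HDXPeptide("b", "A", 2, 2)]
        mp = model_hdx_penalty(model, peps, cdrs, RestraintSpec(d=10))
        # distances 22 and 23: penalties (12)^2 and (13)^2... with d=10 -> 144+169
        assert mp.total == pytest.approx(144.0 + 169.0)

    def test_ensemble_totals_match_raw_coordinate_recomputation(self, small_ensemble):
        reference, config, models, _, _ = small_ensemble
        spec = config.restraint_spec
        table = penalty_table(models, config.hdx_peptides, config.cdrs, spec)
        for model in models:
            cdr_xyz = [
                xyz
                for key, xyz in model.ca_map(model.ab_chains).items()
                if config.cdrs.contains(key)
            ]
            for pep in config.hdx_peptides:
                pep_xyz = [
                    xyz
                    for key, xyz in model.ca_map(model.ag_chains).items()
                    if pep.covers(key)
                ]
                x = brute_force_effective_distance(pep_xyz, cdr_xyz, spec.k)
                expected = 0.0 if x <= spec.d else (x - spec.d) ** 2
                assert table.loc[model.model_id, pep.label] == pytest.approx(expected)

    def test_stringency_ordering(self, small_ensemble):
        reference, config, models, _, _ = small_ensemble
        model = models[-1]

        def total(d, k):
            return model_hdx_penalty(
                model, config.hdx_peptides, config.cdrs, RestraintSpec(d=d, k=k)
            ).total

        assert total(5, 1) >= total(8, 1) >= total(10, 1)
        assert total(10, 3) >= total(10, 2) >= total(10, 1)

    def test_rigid_transform_invariance(self, toy, rng):
        _, reference, config = toy
        from hdxdock.sampler import random_rotation_uniform

        R = random_rotation_uniform(rng)
        t = rng.uniform(-50, 50, 3)
        moved = reference.with_atoms(
            [
                AtomRecord(
                    a.chain_id, a.res_seq, a.icode, a.res_name, a.atom_name,
                    tuple(R @ np.asarray(a.coords) + t), a.element,
                )
                for a in reference.atoms
            ]
        )
        spec = RestraintSpec(d=5.0)  # tight threshold so penalties are nonzero
        before = model_hdx_penalty(reference, config.hdx_peptides, config.cdrs, spec)
        after = model_hdx_penalty(moved, config.hdx_peptides, config.cdrs, spec)
        assert after.total == pytest.approx(before.total, abs=1e-6)


class TestPercentNormalize:
    def test_proportionality(self):
        np.testing.assert_allclose(percent_normalize([0, 5, 10]), [0, 50, 100])

    def test_all_zero_convention(self):
        np.testing.assert_allclose(percent_normalize([0, 0, 0]), [0, 0, 0])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=1, max_size=50)
    )
    def test_max_is_exactly_100(self, values):
        out = percent_normalize(values)
        assert out.max() == pytest.approx(100.0)
        assert (out >= 0).all()

    def test_empty_rejected(self):
        with pytest.raises(RestraintError):
            percent_normalize([])
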