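"""Distribution fitting, the pair energy S, and the neighborhood update S'."""

import math

import numpy as np
import pytest

from vorbind import pair_statistics as ps
from vorbind import structure_model as sm
from vorbind import synthetic_fixtures as fx
from vorbind.features_and_property import FEATURES, PropertyProfile


def _profile(keys, value=1.0):
    prof = PropertyProfile()
    for k in keys:
        prof.surface_ratio[k] = 0.5
        prof.res_types[k] = "ALA"
        for f in FEATURES:
            prof.values[(k, f)] = value
    return prof


class TestFitting:
    def test_parameter_recovery_from_planted_joint(self):
        planted = ps.BivariateNormalParams(1.89, 2.21, 1.0, 1.0, 0.4)
        pairs, _ = fx.sample_property_pairs(planted, 10_000, seed=11)
        fit = ps.fit_bivariate(pairs, symmetrize=False)
        assert fit.mu1 == pytest.approx(1.89, abs=0.05)
        assert fit.mu2 == pytest.approx(2.21, abs=0.05)
        assert fit.rho == pytest.approx(0.4, abs=0.03)

    def test_symmetrized_fit_order_invariant(self):
        planted = ps.BivariateNormalParams(1.0, 3.0, 1.0, 2.0, 0.5)
        pairs, _ = fx.sample_property_pairs(planted, 2_000, seed=2)
        f1 = ps.fit_bivariate(pairs)
        f2 = ps.fit_bivariate(pairs[:, ::-1])
        assert (f1.mu1, f1.mu2, f1.sd1, f1.sd2, f1.rho) == pytest.approx(
            (f2.mu1, f2.mu2, f2.sd1, f2.sd2, f2.rho))
        assert f1.mu1 == pytest.approx(f1.mu2)
        assert f1.sd1 == pytest.approx(f1.sd2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            ps.fit_bivariate(np.ones((50, 2)))
        with pytest.raises(ValueError, match="zero-variance feature: hydrophobicity"):
            ps.fit_model_from_samples({"hydrophobicity": np.ones((50, 2))})

    def test_fit_model_from_complexes_and_side_exchange(self, toy_complex):
        # build enough planted contacts for the pair floor
        training = []
        swapped = []
        for seed in range(4):
            sub_a, sub_b, _ = fx.make_toy_complex(12, 12, 6, seed=seed)
            profs = {}
            for tag, sub in (("a", sub_a), ("b", sub_b)):
                from vorbind import tessellation as tv
                from vorbind.features_and_property import property_profile
                st = sm.Structure([sub])
                tess = tv.build_tessellation(tv.sites_from_structure(st))
                profs[tag] = property_profile(st, tv.residue_areas(tess, st))
            training.append(ps.TrainingComplex(sub_a, sub_b, profs["a"], profs["b"]))
            swapped.append(ps.TrainingComplex(sub_b, sub_a, profs["b"], profs["a"]))
        model = ps.fit_model(training, min_pairs=20)
        mirror = ps.fit_model(swapped, min_pairs=20)
        for f in FEATURES:
            assert model.joints[f].mu1 == pytest.approx(mirror.joints[f].mu1)
            assert model.joints[f].rho == pytest.approx(mirror.joints[f].rho)
            assert model.marginals[f].mean == pytest.approx(mirror.marginals[f].mean)

    def test_insufficient_pairs_rejected(self):
        sub_a, sub_b, _ = fx.make_toy_complex(6, 6, 1, seed=0)
        prof_a = _profile([r.key for r in sub_a.residues])
        prof_b = _profile([r.key for r in sub_b.residues])
        tc = ps.TrainingComplex(sub_a, sub_b, prof_a, prof_b)
        with pytest.raises(ValueError, match="insufficient"):
            ps.fit_model([tc, tc])


class TestPairEnergy:
    def test_independence_gives_zero_everywhere(self):
        model = ps.PairStatModel(
            marginals={"hydrophobicity": ps.NormalParams(1.0, 2.0)},
            joints={"hydrophobicity": ps.BivariateNormalParams(1.0, 1.0, 2.0, 2.0, 0.0)},
            weights={"hydrophobicity": 1.0})
        for x1 in (-3.0, 0.0, 1.0, 4.0):
            for x2 in (-2.0, 1.0, 5.0):
                assert ps.pair_energy(x1, x2, model) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_gaussian(self, single_feature_model):
        # joint 1/(2 pi sqrt(0.75)), marginals 1/(2 pi) at the origin
        s = ps.pair_energy(0.0, 0.0, single_feature_model)
        assert s == pytest.approx(-math.log(1.0 / math.sqrt(0.75)), abs=1e-6)
        assert s == pytest.approx(-0.14384, abs=1e-5)

    def test_far_tail_floored_and_finite(self, single_feature_model):
        s = ps.pair_energy(50.0, -50.0, single_feature_model)
        assert math.isfinite(s)

    def test_kbt_scales_energy(self):
        m1 = ps.PairStatModel(
            marginals={"hydrophobicity": ps.NormalParams(0, 1)},
            joints={"hydrophobicity": ps.BivariateNormalParams(0, 0, 1, 1, 0.5)},
            weights={"hydrophobicity": 1.0})
        m2 = ps.PairStatModel(marginals=m1.marginals, joints=m1.joints,
                              kbt=2.5, weights={"hydrophobicity": 1.0})
        assert ps.pair_energy(0.3, -0.2, m2) == pytest.approx(
            2.5 * ps.pair_energy(0.3, -0.2, m1))

    def test_json_round_trip_scores_identical(self, three_feature_model, rng):
        restored = ps.PairStatModel.from_json(three_feature_model.to_json())
        for _ in range(20):
            p1 = {f: float(rng.normal(2, 2)) for f in FEATURES}
            p2 = {f: float(rng.normal(2, 2)) for f in FEATURES}
            assert ps.pair_energy(p1, p2, restored) == ps.pair_energy(p1, p2, three_feature_model)

    def test_negative_s_enrichment_on_planted_pairs(self):
        planted = ps.BivariateNormalParams(1.89, 1.89, 1.0, 1.0, 0.6)
        pairs, decoys = fx.sample_property_pairs(planted, 4_000, seed=7)
        model = ps.fit_model_from_samples({"hydrophobicity": pairs})
        s_pairs = np.mean([ps.pair_energy(a, b, model) for a, b in pairs])
        s_decoys = np.mean([ps.pair_energy(a, b, model) for a, b in decoys])
        assert s_pairs < s_decoys


class TestScoreAllPairs:
    def test_cross_product_matches_loop_oracle(self, three_feature_model, rng):
        prof_a = _profile([("A", str(i)) for i in range(1, 4)])
        prof_b = _profile([("B", str(i)) for i in range(1, 5)])
        for (k, f) in list(prof_a.values):
            prof_a.values[(k, f)] = float(rng.normal(2, 1))
        for (k, f) in list(prof_b.values):
            prof_b.values[(k, f)] = float(rng.normal(2, 1))
        scores = ps.score_all_pairs(prof_a, prof_b, three_feature_model)
        assert len(scores) == 12
        for s in scores:
            expected = ps.pair_energy(prof_a.vector(s.res_a), prof_b.vector(s.res_b),
                                      three_feature_model)
            assert s.S == pytest.approx(expected)

    def test_deterministic_ordering(self, three_feature_model):
        prof_a = _profile([("A", "2"), ("A", "1")])
        prof_b = _profile([("B", "1")])
        scores = ps.score_all_pairs(prof_a, prof_b, three_feature_model)
        assert [s.res_a for s in scores] == [("A", "1"), ("A", "2")]

    def test_empty_profile_rejected(self, three_feature_model):
        with pytest.raises(ValueError, match="empty"):
            ps.score_all_pairs(PropertyProfile(), _profile([("B", "1")]),
                               three_feature_model)


def _linear_subunit(sid, chain, spacings):
    """Single-CA residues at cumulative x offsets."""
    residues, x = [], 0.0
    for i, gap in enumerate([0.0] + list(spacings)):
        x += gap
        residues.append(sm.Residue(chain, str(i + 1), "ALA",
                                   [sm.Atom("CA", "C", (x, 0, 0), True)]))
    return sm.Subunit(sid, residues)


class TestNeighborhoodUpdate:
    def test_isolated_pair_unchanged(self):
        sub_a = _linear_subunit("A", "A", [])
        sub_b = _linear_subunit("B", "B", [])
        scores = [ps.PairScore(("A", "1"), ("B", "1"), -2.0)]
        out = ps.neighborhood_update(scores, sub_a, sub_b)
        assert out[0].S_prime == pytest.approx(-2.0)

    def test_hand_computed_single_neighbor(self):
        # neighbor r1 of x1 at 5 A with S(r1, x2) = -2 -> S' = S - 0.4
        sub_a = _linear_subunit("A", "A", [5.0])
        sub_b = _linear_subunit("B", "B", [])
        scores = [ps.PairScore(("A", "1"), ("B", "1"), 1.0),
                  ps.PairScore(("A", "2"), ("B", "1"), -2.0)]
        out = ps.neighborhood_update(scores, sub_a, sub_b)
        by_key = {(s.res_a, s.res_b): s for s in out}
        assert by_key[(("A", "1"), ("B", "1"))].S_prime == pytest.approx(1.0 - 0.4)
        # and symmetrically the other pair receives 1.0 / 5
        assert by_key[(("A", "2"), ("B", "1"))].S_prime == pytest.approx(-2.0 + 0.2)

    def test_boundary_radius_inclusive(self):
        sub_a = _linear_subunit("A", "A", [10.0])
        sub_b = _linear_subunit("B", "B", [])
        scores = [ps.PairScore(("A", "1"), ("B", "1"), 0.0),
                  ps.PairScore(("A", "2"), ("B", "1"), -5.0)]
        out = ps.neighborhood_update(scores, sub_a, sub_b)
        by_key = {(s.res_a, s.res_b): s for s in out}
        assert by_key[(("A", "1"), ("B", "1"))].S_prime == pytest.approx(-0.5)
        # just beyond the radius the contribution vanishes
        sub_a2 = _linear_subunit("A", "A", [10.001])
        out2 = ps.neighborhood_update(scores, sub_a2, sub_b)
        by_key2 = {(s.res_a, s.res_b): s for s in out2}
        assert by_key2[(("A", "1"), ("B", "1"))].S_prime == pytest.approx(0.0)

    def test_tiny_radius_is_identity(self, rng):
        sub_a = _linear_subunit("A", "A", [4.0, 6.0])
        sub_b = _linear_subunit("B", "B", [5.0])
        scores = [ps.PairScore((f"A", str(i)), ("B", str(j)), float(rng.normal()))
                  for i in range(1, 4) for j in range(1, 3)]
        out = ps.neighborhood_update(scores, sub_a, sub_b, radius=1e-9)
        for before, after in zip(scores, out):
            assert after.S_prime == pytest.approx(before.S)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            ps.neighborhood_update([], _linear_subunit("A", "A", []),
                                   _linear_subunit("B", "B", []), radius=0.0)

    def test_missing_calpha_skipped(self, caplog):
        res_no_ca = sm.Residue("A", "2", "ALA", [sm.Atom("CB", "C", (5, 0, 0), True)])
        sub_a = sm.Subunit("A", [_linear_subunit("A", "A", []).residues[0], res_no_ca])
        sub_b = _linear_subunit("B", "B", [])
        scores = [ps.PairScore(("A", "1"), ("B", "1"), 1.0),
                  ps.PairScore(("A", "2"), ("B", "1"), -2.0)]
        out = ps.neighborhood_update(scores, sub_a, sub_b)
        by_key = {(s.res_a, s.res_b): s for s in out}
        # the Calpha-less neighbor contributes nothing
        assert by_key[(("A", "1"), ("B", "1"))].S_prime == pytest.approx(1.0)
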