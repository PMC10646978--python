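import math

import numpy as np
import pandas as pd
import pytest

from immunoloop import hts_data
from immunoloop.hts_data import (CGAMP, CONTROL_POSITIVE, CPG, ENHANCE, IRF,
                                 LPS, MPLA, NFKB, SUPPRESS, DataError,
                                 GoalSpec, ModulationProfile,
                                 NormalizationError, all_goals,
                                 apply_viability_filter, count_modulators,
                                 goal_score, log2_fold, merge_replicates,
                                 normalize_plate, profiles_from_frame,
                                 profiles_to_frame, top_performers)


def _readings(rows):
    return pd.DataFrame(rows, columns=["plate_id", "well", "molecule_id",
                                       "channel", "agonist", "raw_value"])


def _profile(mol_id, fold_by_channel, viable=True):
    p = ModulationProfile(molecule_id=mol_id)
    for ch, f in fold_by_channel.items():
        p.fold[ch] = f
        p.fold_err[ch] = 0.0
    p.viable = viable
    return p


class TestGoals:
    def test_exactly_twelve(self):
        goals = all_goals()
        assert len(goals) == 12
        assert len({g.goal_id for g in goals}) == 12

    def test_pathway_agonist_constraints(self):
        for g in all_goals():
            if g.pathway == NFKB:
                assert CGAMP not in g.agonists
            else:
                assert CPG not in g.agonists
                assert g.direction == ENHANCE

    def test_generalist_groups(self):
        gens = [g for g in all_goals() if g.is_generalist]
        assert len(gens) == 3  # NF-kB enhance + suppress, IRF enhance
        for g in gens:
            expected = (LPS, MPLA, CPG) if g.pathway == NFKB else (LPS, MPLA, CGAMP)
            assert g.agonists == expected


class TestNormalizePlate:
    def test_well_equal_to_control_mean_gives_unity(self):
        df = _readings([("P1", "c1", CONTROL_POSITIVE, NFKB, LPS, 20.0),
                        ("P1", "w1", "m1", NFKB, LPS, 20.0)])
        out = normalize_plate(df)
        assert out.loc[out.molecule_id == "m1", "fold"].iloc[0] == 1.0

    def test_hand_arithmetic(self):
        df = _readings([("P1", "c1", CONTROL_POSITIVE, NFKB, LPS, 10.0),
                        ("P1", "c2", CONTROL_POSITIVE, NFKB, LPS, 20.0),
                        ("P1", "w1", "m1", NFKB, LPS, 45.0)])
        out = normalize_plate(df)
        assert out["fold"].iloc[0] == pytest.approx(45.0 / 15.0)

    def test_missing_controls_names_plate(self):
        df = _readings([("P9", "w1", "m1", NFKB, LPS, 45.0)])
        with pytest.raises(NormalizationError, match="P9"):
            normalize_plate(df)

    def test_modulator_only_wells_reported_separately(self):
        df = _readings([
            ("P1", "c1", CONTROL_POSITIVE, NFKB, LPS, 10.0),
            ("P1", "w1", "m1", NFKB, LPS, 20.0),
            ("P1", "c2", CONTROL_POSITIVE, NFKB, hts_data.NO_AGONIST, 5.0),
            ("P1", "w2", "m1", NFKB, hts_data.NO_AGONIST, 10.0)])
        out = normalize_plate(df)
        none_rows = out[out.agonist == hts_data.NO_AGONIST]
        assert none_rows["fold"].iloc[0] == pytest.approx(2.0)
        lps_rows = out[out.agonist == LPS]
        assert lps_rows["fold"].iloc[0] == pytest.approx(2.0)

    def test_plate_invariance(self):
        rows = [("P1", "c1", CONTROL_POSITIVE, NFKB, LPS, 10.0),
                ("P1", "w1", "m1", NFKB, LPS, 37.0),
                ("P2", "c1", CONTROL_POSITIVE, NFKB, LPS, 10.0),
                ("P2", "w1", "m2", NFKB, LPS, 14.0)]
        base = normalize_plate(_readings(rows))
        scaled_rows = [(p, w, m, c, a, v * 7.3 if p == "P1" else v)
                       for p, w, m, c, a, v in rows]
        scaled = normalize_plate(_readings(scaled_rows))
        np.testing.assert_allclose(base["fold"], scaled["fold"])

    def test_idempotent_on_normalized_plate(self):
        rows = [("P1", "c1", CONTROL_POSITIVE, NFKB, LPS, 1.0),
                ("P1", "w1", "m1", NFKB, LPS, 2.5)]
        once = normalize_plate(_readings(rows))
        assert once["fold"].iloc[0] == pytest.approx(2.5)


class TestMergeReplicates:
    def _folds(self, a, b):
        return pd.DataFrame({
            "plate_id": ["R1", "R2"], "molecule_id": ["m1", "m1"],
            "channel": [NFKB, NFKB], "agonist": [LPS, LPS], "fold": [a, b]})

    def test_identical_replicates(self):
        prof = merge_replicates(self._folds(2.0, 2.0))[0]
        assert prof.fold[(NFKB, LPS)] == 2.0
        assert prof.fold_err[(NFKB, LPS)] == 0.0

    def test_sigma_of_mean_for_two(self):
        prof = merge_replicates(self._folds(1.0, 3.0))[0]
        assert prof.fold[(NFKB, LPS)] == 2.0
        assert prof.fold_err[(NFKB, LPS)] == pytest.approx(1.0)  # |a-b|/2

    def test_log2_error_propagation(self):
        val, err = log2_fold(2.0, 1.0)
        assert val == 1.0
        assert err == pytest.approx(1.0 / (2.0 * math.log(2)))  # ~0.721

    def test_missing_replicate_flags_incomplete(self):
        df = self._folds(1.0, 3.0).iloc[:1]
        prof = merge_replicates(df, n_replicates=2)[0]
        assert prof.incomplete


class TestViability:
    def test_clearly_viable(self):
        profs = [_profile("m1", {})]
        viable, _ = apply_viability_filter(profs, {"m1": (1.00, 0.95)})
        assert viable and viable[0].viable is True

    def test_one_mask_below_threshold(self):
        profs = [_profile("m1", {})]
        _, nonviable = apply_viability_filter(profs, {"m1": (0.90, 0.69)})
        assert nonviable and nonviable[0].viable is False

    def test_boundary_strictly_greater(self):
        profs = [_profile("m1", {})]
        _, nonviable = apply_viability_filter(profs, {"m1": (0.70, 0.90)})
        assert nonviable  # exactly 0.70 is not "higher than 70%"

    def test_missing_scores_marked_unknown(self):
        profs = [_profile("m1", {})]
        viable, nonviable = apply_viability_filter(profs, {})
        assert not viable
        assert nonviable[0].viable is None


class TestGoalScore:
    def test_specialist_enhance(self):
        g = GoalSpec("g", NFKB, (LPS,), ENHANCE)
        assert goal_score(_profile("m", {(NFKB, LPS): 2.0}), g) == 1.0

    def test_specialist_suppress_sign_flip(self):
        g = GoalSpec("g", NFKB, (LPS,), SUPPRESS)
        assert goal_score(_profile("m", {(NFKB, LPS): 0.25}), g) == 2.0

    def test_generalist_arithmetic_mean(self):
        g = GoalSpec("g", NFKB, (LPS, MPLA, CPG), ENHANCE)
        p = _profile("m", {(NFKB, LPS): 2.0, (NFKB, MPLA): 4.0, (NFKB, CPG): 2.0})
        assert goal_score(p, g) == pytest.approx(math.log2(8 / 3))  # ~1.415

    def test_geometric_switch(self):
        g = GoalSpec("g", NFKB, (LPS, MPLA), ENHANCE)
        p = _profile("m", {(NFKB, LPS): 2.0, (NFKB, MPLA): 8.0})
        assert goal_score(p, g, aggregate="geometric") == pytest.approx(2.0)

    def test_suppress_is_negated_enhance(self):
        ge = GoalSpec("e", NFKB, (LPS,), ENHANCE)
        gs = GoalSpec("s", NFKB, (LPS,), SUPPRESS)
        for fold in (0.1, 0.9, 1.0, 3.7):
            p = _profile("m", {(NFKB, LPS): fold})
            assert goal_score(p, gs) == -goal_score(p, ge)

    def test_nonpositive_fold_is_data_error(self):
        g = GoalSpec("g", NFKB, (LPS,), ENHANCE)
        with pytest.raises(DataError):
            goal_score(_profile("m", {(NFKB, LPS): 0.0}), g)


class TestCountModulators:
    def test_boundary_inclusive(self):
        p = _profile("m", {(NFKB, LPS): 2.0})
        assert count_modulators([p], 2.0) == 1

    def test_below_threshold(self):
        p = _profile("m", {ch: 1.9 for ch in hts_data.GOAL_CHANNELS})
        assert count_modulators([p], 2.0) == 0

    def test_suppression_counts(self):
        p = _profile("m", {(NFKB, CPG): 0.45})
        assert count_modulators([p], 2.0) == 1

    def test_nonviable_excluded(self):
        p = _profile("m", {(NFKB, LPS): 5.0}, viable=False)
        assert count_modulators([p], 2.0) == 0

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            count_modulators([], 1.0)

    def test_monotone_nonincreasing_in_threshold(self, rng):
        profs = [_profile(f"m{i}",
                          {ch: float(2.0 ** rng.normal(0, 1.2))
                           for ch in hts_data.GOAL_CHANNELS})
                 for i in range(60)]
        counts = [count_modulators(profs, t) for t in (1.2, 1.5, 2, 3, 5, 10)]
        assert counts == sorted(counts, reverse=True)


class TestTopPerformers:
    def test_rank_one(self):
        g = GoalSpec("g", NFKB, (LPS,), ENHANCE)
        profs = [_profile(f"m{i}", {(NFKB, LPS): f}) for i, f in enumerate([3, 2, 1])]
        prof, fold = top_performers(profs, g, k=1)
        assert prof.molecule_id == "m0" and fold == 3

    def test_matches_full_sort_oracle(self, rng):
        g = GoalSpec("g", IRF, (MPLA,), ENHANCE)
        profs = [_profile(f"m{i:02d}", {(IRF, MPLA): float(2 ** rng.normal())})
                 for i in range(50)]
        expected = sorted(profs, key=lambda p: (-p.fold[(IRF, MPLA)], p.molecule_id))
        for k in range(1, 51):
            prof, _ = top_performers(profs, g, k=k)
            assert prof.molecule_id == expected[k - 1].molecule_id

    def test_out_of_range(self):
        g = GoalSpec("g", NFKB, (LPS,), ENHANCE)
        with pytest.raises(IndexError):
            top_performers([_profile("m", {(NFKB, LPS): 1.0})], g, k=2)

    def test_tie_break_by_id(self):
        g = GoalSpec("g", NFKB, (LPS,), ENHANCE)
        profs = [_profile("zz", {(NFKB, LPS): 2.0}),
                 _profile("aa", {(NFKB, LPS): 2.0})]
        prof, _ = top_performers(profs, g, k=1)
        assert prof.molecule_id == "aa"


def test_profile_frame_round_trip():
    p = _profile("m1", {(NFKB, LPS): 2.0, (IRF, CGAMP): 0.5})
    p.confluency_scores = (0.9, 0.8)
    df = profiles_to_frame([p])
    back = profiles_from_frame(df)[0]
    assert back.fold == p.fold
    assert back.viable is True
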