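"""Target-generation engine: noise, option sets, randomization, leaderboards."""

import math

import numpy as np
import pytest
from scipy import stats

import stepcompare as sc
from stepcompare.errors import ConfigError, InvalidInputError


class TestApplyNoise:
    def test_stays_within_two_percent(self, rng):
        draws = [sc.apply_noise(10000, 0.02, rng) for _ in range(10_000)]
        assert min(draws) >= 9800 and max(draws) <= 10200

    def test_zero_noise_is_identity(self, rng):
        assert sc.apply_noise(10000, 0.0, rng) == 10000

    def test_uniform_distribution_by_ks(self, rng):
        # the noise multiplier should be uniform on [-2%, +2%]
        draws = np.array([sc.apply_noise(100_000, 0.02, rng) for _ in range(10_000)])
        u = (draws / 100_000 - 1.0 + 0.02) / 0.04
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_negative_input_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            sc.apply_noise(-1, 0.02, rng)

    def test_deterministic_under_seed(self):
        a = [sc.apply_noise(5000, 0.02, np.random.default_rng(3)) for _ in range(1)]
        b = [sc.apply_noise(5000, 0.02, np.random.default_rng(3)) for _ in range(1)]
        assert a == b


class TestGenerateTargetSet:
    def test_study2_downward_only_nominals(self, rng):
        design = sc.study_design(2)
        profiles = sc.generate_target_set(10000, "downward_only", design, rng)
        assert [p.nominal_scale for p in profiles] == [0.9, 0.8, 0.7, 0.6]
        for p in profiles:
            nominal = p.nominal_scale * 10000
            assert abs(p.displayed_steps - nominal) <= math.ceil(0.02 * nominal) + 0.5
            assert p.direction == "downward"

    def test_study1_noise_off_exact(self, rng):
        design = sc.study_design(1).without_noise()
        profiles = sc.generate_target_set(10000, "fixed", design, rng)
        assert {p.displayed_steps for p in profiles} == {11000, 13000, 9000, 7000}

    def test_zero_steps_degenerate(self, rng):
        design = sc.study_design(2)
        profiles = sc.generate_target_set(0, "upward_only", design, rng)
        assert all(p.displayed_steps == 0 and p.direction == "lateral" for p in profiles)

    def test_unknown_condition_raises(self, rng):
        with pytest.raises(ConfigError, match="sideways"):
            sc.generate_target_set(10000, "sideways", sc.study_design(2), rng)

    def test_usernames_unique_within_set(self, rng):
        profiles = sc.generate_target_set(8000, "mixed", sc.study_design(2), rng)
        names = [p.username for p in profiles]
        assert len(set(names)) == len(names)

    def test_direction_matches_sign_everywhere(self, rng):
        design = sc.study_design(2)
        for label in design.condition_labels:
            for _ in range(50):
                anchor = int(rng.integers(100, 20000))
                for p in sc.generate_target_set(anchor, label, design, rng,
                                                with_details=False):
                    expected = ("upward" if p.displayed_steps > anchor
                                else "downward" if p.displayed_steps < anchor
                                else "lateral")
                    assert p.direction == expected


class TestAssignConditions:
    def test_nine_days_exactly_balanced(self, rng):
        schedule = sc.assign_conditions("p1", 9, sc.study_design(2), rng)
        labels = [a.condition_label for a in schedule]
        assert all(labels.count(c) == 3 for c in ("downward_only", "mixed", "upward_only"))

    def test_single_day(self, rng):
        (a,) = sc.assign_conditions("p1", 1, sc.study_design(2), rng)
        assert a.condition_label in sc.study_design(2).condition_labels
        assert a.day_index == 0

    def test_counts_differ_by_at_most_one(self, rng):
        for n_days in (1, 2, 4, 7, 8, 10):
            labels = [a.condition_label
                      for a in sc.assign_conditions("p1", n_days, sc.study_design(2), rng)]
            counts = [labels.count(c) for c in sc.study_design(2).condition_labels]
            assert max(counts) - min(counts) <= 1

    def test_cohort_marginal_exact_thirds(self, rng):
        # 53 participants x 9 days: every condition appears exactly 159 times
        counts = {c: 0 for c in sc.study_design(2).condition_labels}
        for i in range(53):
            for a in sc.assign_conditions(f"p{i}", 9, sc.study_design(2), rng):
                counts[a.condition_label] += 1
        assert set(counts.values()) == {159}

    def test_reproducible_under_seed(self):
        d = sc.study_design(2)
        a = sc.assign_conditions("p1", 9, d, np.random.default_rng(5))
        b = sc.assign_conditions("p1", 9, d, np.random.default_rng(5))
        assert a == b


class TestFabricatedSteps:
    def test_below_noise_off(self, rng):
        assert sc.generate_fabricated_steps(8000, 6000, "fab_below", rng, 0.0) == 4800

    def test_above_noise_off(self, rng):
        assert sc.generate_fabricated_steps(8000, 6000, "fab_above", rng, 0.0) == 9600

    def test_between_noise_off_is_midpoint(self, rng):
        assert sc.generate_fabricated_steps(8000, 6000, "fab_between", rng, 0.0) == 7000

    def test_between_stays_strictly_inside(self, rng):
        for _ in range(10_000):
            v = sc.generate_fabricated_steps(8000, 6000, "fab_between", rng)
            assert 6000 < v < 8000

    def test_below_above_strictly_outside_both(self, rng):
        # at 20% offsets the 2% noise can never cross a live total >= 100
        for _ in range(2000):
            a, b = int(rng.integers(100, 20000)), int(rng.integers(100, 20000))
            lo = sc.generate_fabricated_steps(a, b, "fab_below", rng)
            hi = sc.generate_fabricated_steps(a, b, "fab_above", rng)
            assert lo < min(a, b) and hi > max(a, b)

    def test_equal_live_totals_between_degrades(self, rng):
        assert sc.generate_fabricated_steps(7000, 7000, "fab_between", rng) == 7000

    def test_unknown_placement(self, rng):
        with pytest.raises(ConfigError):
            sc.generate_fabricated_steps(1, 2, "fab_sideways", rng)


class TestLeaderboard:
    def _entry(self, name, steps, **kw):
        return sc.LeaderboardEntry(name, steps, **kw)

    def test_descending_order(self):
        board = sc.build_leaderboard(
            self._entry("me", 5000, is_self=True),
            [self._entry("B", 7000), self._entry("C", 6000)],
        )
        assert [e.username for e in board.entries] == ["B", "C", "me"]
        assert board.self_rank == 3

    def test_tie_broken_by_username(self):
        board = sc.build_leaderboard(
            self._entry("zz", 5000, is_self=True), [self._entry("aa", 5000)]
        )
        assert [e.username for e in board.entries] == ["aa", "zz"]

    def test_invariant_to_input_order(self, rng):
        entries = [self._entry("a", 100), self._entry("b", 300), self._entry("c", 200)]
        me = self._entry("me", 250, is_self=True)
        orders = []
        for _ in range(10):
            perm = [entries[i] for i in rng.permutation(3)]
            orders.append([e.username for e in sc.build_leaderboard(me, perm).entries])
        assert len({tuple(o) for o in orders}) == 1

    def test_duplicate_usernames_rejected(self):
        with pytest.raises(InvalidInputError):
            sc.build_leaderboard(
                self._entry("me", 100, is_self=True), [self._entry("me", 200)]
            )


class TestStudyDesignConfig:
    def test_canonical_sets_enforced(self):
        with pytest.raises(ConfigError):
            sc.StudyDesign(
                study_id=2,
                scales_per_condition={"downward_only": (0.5,)},
                options_per_day=4,
            )

    def test_noise_halfwidth_bounds(self):
        with pytest.raises(ConfigError):
            sc.study_design(2, noise_halfwidth=0.5)

    def test_packaged_configs_round_trip(self, tmp_path):
        from importlib import resources

        for study in (1, 2, 3):
            text = resources.files("stepcompare.data").joinpath(f"study{study}.yaml").read_text()
            p = tmp_path / f"study{study}.yaml"
            p.write_text(text)
            design = sc.load_design(p)
            assert design.study_id == study
            assert design.to_dict() == sc.study_design(study).to_dict()

    def test_determinism_byte_identical_sets(self):
        import json

        def gen(seed):
            rng = np.random.default_rng(seed)
            sets = [
                [p.to_dict() for p in sc.generate_target_set(
                    9000, "mixed", sc.study_design(2), rng)]
                for _ in range(5)
            ]
            return json.dumps(sets)

        assert gen(11) == gen(11)
        assert gen(11) != gen(12)
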