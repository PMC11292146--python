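"""Attribute space, design generation, prohibitions, dominance, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import screenpref as sp
from screenpref.design import ConfigurationError


class TestAttributeSpace:
    def test_default_space_shape(self, space):
        assert len(space) == 6
        assert [len(a.levels) for a in space.attributes] == [5, 2, 4, 4, 5, 2]
        assert space.n_dummies() == 16

    def test_reference_levels_follow_current_screening_convention(self, space):
        assert space["procedure"].reference == "stool_2day"
        assert space["sensitivity"].reference == "80"
        assert space["recommendation"].reference == "neither"
        assert space["cost"].reference == "0"
        assert space["cost"].levels == ("0", "5", "30", "400", "1000")

    def test_reference_must_be_a_level(self):
        with pytest.raises(ConfigurationError):
            sp.Attribute("pain", ("no_pain", "mild_pain"), reference="severe")

    def test_duplicate_levels_rejected(self):
        with pytest.raises(ConfigurationError):
            sp.Attribute("pain", ("no_pain", "no_pain"), reference="no_pain")


class TestProhibitions:
    def test_stool_high_cost_prohibited(self, space):
        prohib = sp.default_prohibitions()
        profile = sp.Profile.from_dict(
            {"procedure": "stool_2day", "pain": "no_pain", "sensitivity": "80",
             "recommendation": "neither", "cost": "400", "risk": "no_risk"}
        )
        assert any(p.violated_by(profile) for p in prohib)

    def test_blood_high_cost_allowed(self, space):
        prohib = sp.default_prohibitions()
        profile = sp.Profile.from_dict(
            {"procedure": "blood", "pain": "no_pain", "sensitivity": "80",
             "recommendation": "neither", "cost": "1000", "risk": "no_risk"}
        )
        assert not any(p.violated_by(profile) for p in prohib)

    def test_colonoscopy_untouched_by_clauses(self, space):
        prohib = sp.default_prohibitions()
        profile = sp.Profile.from_dict(
            {"procedure": "colonoscopy", "pain": "mild_pain", "sensitivity": "60",
             "recommendation": "neither", "cost": "400", "risk": "1pct_adverse"}
        )
        assert not any(p.violated_by(profile) for p in prohib)

    def test_stool_mild_pain_prohibited(self, space):
        legal = sp.enumerate_profiles(space, sp.default_prohibitions())
        assert not any(
            p["procedure"].startswith("stool") and p["pain"] == "mild_pain"
            for p in legal
        )


class TestGeneration:
    def test_default_dimensions_and_fixed_task_count(self):
        d = sp.generate_design(seed=1)
        assert d.n_blocks == 20 and d.tasks_per_block == 10
        tasks = d.all_tasks()
        assert len(tasks) == 200
        assert sum(t.is_validity_task for t in tasks) == 20
        for block in d.blocks:
            assert sum(t.is_validity_task for t in block) == 1

    def test_deterministic_given_seed(self):
        assert sp.generate_design(seed=5) == sp.generate_design(seed=5)
        assert sp.generate_design(seed=5) != sp.generate_design(seed=6)

    def test_unsatisfiable_prohibitions_raise(self, space):
        prohib = [
            sp.Prohibition(frozenset({("procedure", proc), ("cost", cost)}))
            for proc in space["procedure"].levels
            for cost in space["cost"].levels
        ]
        with pytest.raises(ConfigurationError):
            sp.generate_design(prohibitions=prohib, seed=0)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_generated_profiles_never_violate_prohibitions(self, seed):
        d = sp.generate_design(n_blocks=3, tasks_per_block=5, seed=seed)
        for task in d.all_tasks():
            for profile in (task.left, task.right):
                assert not any(p.violated_by(profile) for p in d.prohibitions)

    def test_level_counts_roughly_uniform(self, space):
        # appearance counts over legal levels should pass a chi-square sanity
        # bound for a large random design (conditional on the prohibitions,
        # marginal level frequencies differ, so compare against expected
        # frequencies from the legal-profile enumeration)
        d = sp.generate_design(n_blocks=40, tasks_per_block=10, seed=11)
        rep = sp.coverage_report(d)
        legal = sp.enumerate_profiles(space, sp.default_prohibitions())
        n_profiles = 2 * len([t for t in d.all_tasks() if not t.is_validity_task])
        from scipy import stats

        for a in space.attributes:
            expected_freq = np.array(
                [sum(p[a.name] == lv for p in legal) / len(legal) for lv in a.levels]
            )
            observed = np.array(
                [rep.level_counts[(a.name, lv)] for lv in a.levels], dtype=float
            )
            # remove the fixed task's deterministic contribution
            for t in d.all_tasks():
                if t.is_validity_task:
                    for profile in (t.left, t.right):
                        observed[a.levels.index(profile[a.name])] -= 1
            chi2 = ((observed - n_profiles * expected_freq) ** 2
                    / (n_profiles * expected_freq)).sum()
            assert chi2 < stats.chi2.ppf(0.999, df=len(a.levels) - 1)


class TestDominance:
    def test_clear_dominance(self, space):
        a = sp.Profile.from_dict(
            {"procedure": "stool_1day", "pain": "no_pain", "sensitivity": "95",
             "recommendation": "hpb", "cost": "5", "risk": "no_risk"}
        )
        b = sp.Profile.from_dict(
            {"procedure": "stool_1day", "pain": "no_pain", "sensitivity": "60",
             "recommendation": "hpb", "cost": "400", "risk": "1pct_adverse"}
        )
        assert sp.is_dominant(sp.ChoiceTask(a, b), space)

    def test_tradeoff_is_not_dominant(self, space):
        base = {"procedure": "blood", "pain": "no_pain", "recommendation": "hpb",
                "risk": "no_risk"}
        a = sp.Profile.from_dict({**base, "sensitivity": "95", "cost": "400"})
        b = sp.Profile.from_dict({**base, "sensitivity": "60", "cost": "5"})
        assert not sp.is_dominant(sp.ChoiceTask(a, b), space)

    def test_unordered_difference_blocks_dominance(self, space):
        base = {"pain": "no_pain", "recommendation": "hpb", "risk": "no_risk"}
        a = sp.Profile.from_dict(
            {**base, "procedure": "blood", "sensitivity": "95", "cost": "5"}
        )
        b = sp.Profile.from_dict(
            {**base, "procedure": "colonoscopy", "sensitivity": "60", "cost": "400"}
        )
        assert not sp.is_dominant(sp.ChoiceTask(a, b), space)

    def test_default_fixed_task_is_dominant(self, space):
        assert sp.is_dominant(sp.default_fixed_task(), space)


class TestCoverage:
    def test_generated_design_estimable(self, small_design):
        assert sp.coverage_report(small_design).estimable

    def test_degenerate_design_not_estimable(self, space):
        fixed = sp.default_fixed_task()
        other = sp.ChoiceTask(fixed.left, fixed.right)
        d = sp.Design(
            space=space,
            blocks=((fixed, other),),
            fixed_task=fixed,
            prohibitions=(),
            seed=0,
        )
        rep = sp.coverage_report(d)
        assert not rep.estimable
        assert rep.missing_levels

    def test_level_counts_sum_to_twice_tasks(self, small_design):
        rep = sp.coverage_report(small_design)
        n_tasks = len(small_design.all_tasks())
        for a in small_design.space.attributes:
            total = sum(rep.level_counts[(a.name, lv)] for lv in a.levels)
            assert total == 2 * n_tasks


class TestJohnsonOrme:
    @pytest.mark.parametrize(
        "c,t,a,expected", [(5, 2, 10, 125), (2, 2, 10, 50), (1, 1, 500, 1), (3, 2, 7, 108)]
    )
    def test_minimum_sample_size(self, c, t, a, expected):
        assert sp.johnson_orme_min_n(c, t, a) == expected

    @pytest.mark.parametrize("bad", [(0, 2, 10), (5, -1, 10), (5, 2, 0)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            sp.johnson_orme_min_n(*bad)
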