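"""Statistic computations over the risk set and design assembly."""

import math

import numpy as np
import pytest

from remkit.core import DyadicEvent, RawEvent, ValidationError, build_risk_set
from remkit.ingest import split_group_events
from remkit.stats import (
    Calendar,
    EffectCalculator,
    EffectSpec,
    build_design,
    scale_per_event,
    stat_baseline,
    stat_category_pair,
    stat_group,
    stat_inertia,
    stat_interaction,
    stat_shared_partners,
    stat_trait_extreme,
    stat_type_dummy,
    stat_type_inertia,
    stat_type_shared_partners,
    stat_weekend,
)


def _dyadic(t, a, b, duration=30.0, group_size=2, setting=None, gid=0):
    return DyadicEvent(
        time=t, t_stat=t, actors=(a, b), setting=setting, duration=duration,
        group_size=group_size, group_id=gid,
    )


class TestExogenousStats:
    def test_baseline_all_ones(self, actors5):
        rs = build_risk_set(actors5)
        np.testing.assert_array_equal(stat_baseline(rs), np.ones(10))

    def test_gender_pair_indicators(self, actors5):
        rs = build_risk_set(actors5)
        both_male = stat_category_pair(rs, actors5, "gender", "both_level", "male")
        mixed = stat_category_pair(rs, actors5, "gender", "mixed")
        idx = {e: i for i, e in enumerate(rs.entries())}
        assert both_male[idx[("ben", "chris")]] == 1  # male-male
        assert mixed[idx[("ben", "chris")]] == 0
        assert both_male[idx[("anne", "ben")]] == 0  # mixed pair
        assert mixed[idx[("anne", "ben")]] == 1
        assert both_male[idx[("anne", "emma")]] == 0  # female-female reference
        assert mixed[idx[("anne", "emma")]] == 0

    def test_unknown_level_rejected(self, actors5):
        rs = build_risk_set(actors5)
        with pytest.raises(ValidationError):
            stat_category_pair(rs, actors5, "gender", "both_level", "robot")

    def test_trait_extremes_symmetric(self, actors5):
        rs = build_risk_set(actors5)
        lo = stat_trait_extreme(rs, actors5, "extraversion", "min")
        hi = stat_trait_extreme(rs, actors5, "extraversion", "max")
        scores = dict(zip(actors5.ids, actors5.trait_values("extraversion")))
        for e, (a, b) in enumerate(rs.entries()):
            assert lo[e] == pytest.approx(min(scores[a], scores[b]))
            assert hi[e] == pytest.approx(max(scores[a], scores[b]))
        assert (lo <= hi).all()

    @pytest.mark.parametrize(
        "start_weekday, t, expected",
        [
            (0, 100, 0.0),           # Monday, day 0
            (0, 5 * 1440 + 10, 1.0), # day 5 from Monday = Saturday
            (5, 100, 1.0),           # starts on Saturday
            (6, 1440 + 10, 0.0),     # Sunday start, day 1 = Monday
        ],
    )
    def test_weekend_calendar_arithmetic(self, start_weekday, t, expected):
        assert stat_weekend(t, Calendar(start_weekday)) == expected

    def test_weekend_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            stat_weekend(-5, Calendar(0))

    def test_group_indicator(self):
        assert stat_group(3) == 1.0
        assert stat_group(2) == 0.0


class TestEndogenousStats:
    def test_inertia_empty_history_zero(self, actors5):
        rs = build_risk_set(actors5)
        np.testing.assert_array_equal(stat_inertia([], rs, 100), np.zeros(10))

    def test_inertia_weights(self, actors5):
        rs = build_risk_set(actors5)
        idx = rs.index_of("anne", "ben")
        # one past dyadic 30-min event -> ln 30
        vals = stat_inertia([_dyadic(10, "anne", "ben", 30)], rs, 100)
        assert vals[idx] == pytest.approx(math.log(30), abs=1e-4)
        # same event inside a 4-person group -> ln 30 / 3
        vals = stat_inertia([_dyadic(10, "anne", "ben", 30, group_size=4)], rs, 100)
        assert vals[idx] == pytest.approx(math.log(30) / 3, abs=1e-4)

    def test_inertia_count_weighting(self, actors5):
        rs = build_risk_set(actors5)
        history = [_dyadic(10, "anne", "ben", 30, group_size=4), _dyadic(20, "anne", "ben", 200)]
        vals = stat_inertia(history, rs, 100, weighting="count")
        assert vals[rs.index_of("anne", "ben")] == 2.0

    def test_inertia_history_strictly_before_t(self, actors5):
        rs = build_risk_set(actors5)
        vals = stat_inertia([_dyadic(100, "anne", "ben")], rs, 100)
        assert vals[rs.index_of("anne", "ben")] == 0.0

    def test_inertia_window_start_excludes_old_events(self, actors5):
        rs = build_risk_set(actors5)
        history = [_dyadic(10, "anne", "ben"), _dyadic(60, "anne", "ben")]
        full = stat_inertia(history, rs, 100)
        windowed = stat_inertia(history, rs, 100, window_start=50)
        idx = rs.index_of("anne", "ben")
        assert full[idx] == pytest.approx(2 * math.log(30))
        assert windowed[idx] == pytest.approx(math.log(30))
        np.testing.assert_array_equal(
            stat_inertia(history, rs, 100, window_start=0), full
        )

    def test_shared_partners_enumeration(self, actors5):
        rs = build_risk_set(actors5)
        history = [
            _dyadic(1, "anne", "chris"),
            _dyadic(2, "ben", "chris"),
            _dyadic(3, "ben", "dan"),
        ]
        vals = stat_shared_partners(history, rs, 100)
        assert vals[rs.index_of("anne", "ben")] == 1  # chris
        assert vals[rs.index_of("anne", "dan")] == 0
        assert vals[rs.index_of("chris", "dan")] == 1  # ben

    def test_own_dyad_never_counts_as_partner(self, actors5):
        rs = build_risk_set(actors5)
        vals = stat_shared_partners([_dyadic(1, "anne", "ben")], rs, 100)
        assert vals[rs.index_of("anne", "ben")] == 0

    def test_monotone_in_history(self, actors5):
        rs = build_risk_set(actors5)
        history = [
            _dyadic(1, "anne", "chris"),
            _dyadic(2, "ben", "chris"),
            _dyadic(3, "anne", "ben"),
            _dyadic(4, "dan", "emma"),
        ]
        for stat in (stat_inertia, stat_shared_partners):
            prev = np.zeros(10)
            for i in range(len(history) + 1):
                cur = stat(history[:i], rs, 100)
                assert (cur >= prev - 1e-12).all()
                prev = cur


class TestTypedStats:
    def test_type_dummy_counts(self, actors5):
        rs = build_risk_set(actors5, ("leisure", "study"))
        dummy = stat_type_dummy(rs, "study")
        assert dummy.sum() == 10
        complement = stat_type_dummy(rs, "leisure")
        np.testing.assert_array_equal(dummy + complement, np.ones(20))

    def test_type_dummy_requires_types(self, actors5):
        rs = build_risk_set(actors5)
        with pytest.raises(ValidationError):
            stat_type_dummy(rs, "study")

    def test_type_inertia_setting_restriction(self, actors5):
        rs = build_risk_set(actors5, ("leisure", "study"))
        history = [_dyadic(10, "anne", "ben", 30, setting="leisure")]
        vals = stat_type_inertia(history, rs, 100)
        assert vals[rs.index_of("anne", "ben", "leisure")] == pytest.approx(math.log(30))
        assert vals[rs.index_of("anne", "ben", "study")] == 0.0

    def test_type_inertia_partitions_untyped(self, actors5):
        rs_typed = build_risk_set(actors5, ("leisure", "study"))
        rs_plain = build_risk_set(actors5)
        history = [
            _dyadic(1, "anne", "ben", 30, setting="leisure"),
            _dyadic(2, "anne", "ben", 60, setting="study"),
            _dyadic(3, "ben", "chris", 10, setting="study", group_size=3),
        ]
        typed = stat_type_inertia(history, rs_typed, 100)
        plain = stat_inertia(history, rs_plain, 100)
        for d, (a, b) in enumerate(rs_plain.entries()):
            total = sum(typed[rs_typed.index_of(a, b, c)] for c in ("leisure", "study"))
            assert total == pytest.approx(plain[d])

    def test_type_shared_partners_within_type(self, actors5):
        rs = build_risk_set(actors5, ("leisure", "study"))
        history = [
            _dyadic(1, "anne", "chris", setting="study"),
            _dyadic(2, "ben", "chris", setting="study"),
            _dyadic(3, "ben", "dan", setting="leisure"),
        ]
        vals = stat_type_shared_partners(history, rs, 100)
        assert vals[rs.index_of("anne", "ben", "study")] == 1
        assert vals[rs.index_of("anne", "ben", "leisure")] == 0

    def test_within_type_bounded_by_untyped(self, actors5):
        rs_typed = build_risk_set(actors5, ("leisure", "study"))
        rs_plain = build_risk_set(actors5)
        history = [
            _dyadic(1, "anne", "chris", setting="study"),
            _dyadic(2, "ben", "chris", setting="leisure"),
            _dyadic(3, "ben", "chris", setting="study"),
        ]
        typed = stat_type_shared_partners(history, rs_typed, 100)
        plain = stat_shared_partners(history, rs_plain, 100)
        for e in range(len(rs_typed)):
            d = rs_typed.dyad_index[e]
            assert typed[e] <= plain[rs_plain.dyad_index[d]] + 1e-12


class TestScaling:
    def test_unit_sample_sd_example(self):
        np.testing.assert_allclose(scale_per_event(np.array([1.0, 2, 3])), [-1, 0, 1])

    def test_degenerate_constant_maps_to_zero(self):
        np.testing.assert_array_equal(scale_per_event(np.full(5, 7.0)), np.zeros(5))

    def test_hand_computed_values(self):
        got = scale_per_event(np.array([0.0, 0.0, 6.0]))
        np.testing.assert_allclose(got, [-0.5774, -0.5774, 1.1547], atol=1e-4)

    def test_too_few_entries_rejected(self):
        with pytest.raises(ValidationError):
            scale_per_event(np.array([1.0]))

    def test_interaction_product(self):
        a = np.array([-1.0, 0.0, 1.0])
        b = np.array([2.0, 2.0, 2.0])
        np.testing.assert_array_equal(stat_interaction(a, b), [-2, 0, 2])
        np.testing.assert_array_equal(stat_interaction(a, b), stat_interaction(b, a))
        with pytest.raises(ValidationError):
            stat_interaction(a, np.ones(4))


class TestBuildDesign:
    def test_baseline_only_design(self, actors5, first_dyadic):
        rs = build_risk_set(actors5)
        design = build_design(first_dyadic, rs, actors5, [EffectSpec("baseline", "baseline")])
        assert design.X.shape == (4, 10, 1)
        np.testing.assert_array_equal(design.X, np.ones_like(design.X))
        np.testing.assert_array_equal(design.dt, [1, 60, 60, 30])

    def test_first_event_endogenous_columns_zero(self, actors5, first_dyadic):
        rs = build_risk_set(actors5)
        specs = [EffectSpec("baseline", "baseline"), EffectSpec("inertia", "inertia"),
                 EffectSpec("sp", "shared_partners")]
        design = build_design(first_dyadic, rs, actors5, specs)
        np.testing.assert_array_equal(design.X[0, :, 1:], 0.0)

    def test_inertia_at_fourth_event_is_scaled_ln30(self, actors5, first_dyadic):
        # by t=151 the only past (anne, ben) event is the 30-min one at t=1
        rs = build_risk_set(actors5)
        specs = [EffectSpec("inertia", "inertia")]
        design = build_design(first_dyadic, rs, actors5, specs)
        history = first_dyadic[:3]
        raw = stat_inertia(history, rs, 151)
        assert raw[rs.index_of("anne", "ben")] == pytest.approx(math.log(30))
        np.testing.assert_allclose(design.X[3, :, 0], scale_per_event(raw))

    def test_scaled_columns_standardized_at_every_event(self, actors5, first_dyadic):
        rs = build_risk_set(actors5)
        specs = [EffectSpec("inertia", "inertia"), EffectSpec("sp", "shared_partners")]
        design = build_design(first_dyadic, rs, actors5, specs)
        for g in range(design.X.shape[0]):
            for p in range(design.X.shape[2]):
                col = design.X[g, :, p]
                if np.allclose(col, 0):
                    continue
                assert col.mean() == pytest.approx(0, abs=1e-12)
                assert col.std(ddof=1) == pytest.approx(1)

    def test_group_block_shares_statistics_no_self_feedback(self, actors5):
        raw = [
            RawEvent(10, ("anne", "ben"), None, 30),
            RawEvent(20, ("anne", "ben", "chris"), None, 60),
        ]
        dyadic, _ = split_group_events(raw, seed=3)
        rs = build_risk_set(actors5)
        specs = [EffectSpec("inertia", "inertia", scaled=False)]
        design = build_design(dyadic, rs, actors5, specs)
        # the three dyadic events of the group share one block computed
        # before any of them entered the history
        group_blocks = design.event_block[design.group_ids == 1]
        assert len(set(group_blocks.tolist())) == 1
        col = design.X[group_blocks[0], :, 0]
        assert col[rs.index_of("anne", "ben")] == pytest.approx(math.log(30))
        assert col[rs.index_of("anne", "chris")] == 0.0

    def test_untyped_stats_replicate_across_types(self, actors5, first_dyadic):
        rs = build_risk_set(actors5, ("leisure", "study"))
        specs = [EffectSpec("inertia", "inertia", scaled=False),
                 EffectSpec("ext.min", "trait_min", attribute="extraversion")]
        design = build_design(first_dyadic, rs, actors5, specs)
        for g in range(design.X.shape[0]):
            for p in range(2):
                col = design.X[g, :, p]
                np.testing.assert_array_equal(
                    col[rs.type_index == 0], col[rs.type_index == 1]
                )

    def test_window_start_none_equals_zero(self, actors5, first_dyadic):
        rs = build_risk_set(actors5)
        specs = [EffectSpec("baseline", "baseline"), EffectSpec("inertia", "inertia")]
        d_none = build_design(first_dyadic, rs, actors5, specs, window_start=None)
        d_zero = build_design(first_dyadic, rs, actors5, specs, window_start=0)
        np.testing.assert_array_equal(d_none.X, d_zero.X)
        np.testing.assert_array_equal(d_none.dt, d_zero.dt)

    def test_observed_dyad_outside_active_risk_set_rejected(self, actors5, first_dyadic):
        actors5.availability["anne"] = [(1000.0, 2000.0)]  # anne unavailable early
        rs = build_risk_set(actors5)
        with pytest.raises(ValidationError, match="anne"):
            build_design(first_dyadic, rs, actors5, [EffectSpec("baseline", "baseline")])

    def test_interaction_uses_scaled_components(self, actors5, first_dyadic):
        rs = build_risk_set(actors5)
        specs = [
            EffectSpec("inertia", "inertia"),
            EffectSpec("ext.min", "trait_min", attribute="extraversion"),
            EffectSpec("inertia.x.ext.min", "interaction", components=("inertia", "ext.min")),
        ]
        design = build_design(first_dyadic, rs, actors5, specs)
        np.testing.assert_allclose(
            design.X[..., 2], design.X[..., 0] * design.X[..., 1], atol=1e-12
        )

    def test_interaction_referencing_later_effect_rejected(self, actors5, first_dyadic):
        rs = build_risk_set(actors5)
        specs = [EffectSpec("i.x.e", "interaction", components=("inertia", "ext.min"))]
        with pytest.raises(ValidationError):
            build_design(first_dyadic, rs, actors5, specs)


class TestCalculatorMatchesReferenceFunctions:
    """The incremental engine and the history-list functions must agree."""

    def test_untyped_agreement_on_random_history(self, actors5):
        rng = np.random.default_rng(0)
        rs = build_risk_set(actors5)
        ids = list(actors5.ids)
        history = []
        t = 0.0
        for gid in range(30):
            t += rng.exponential(10)
            i, j = rng.choice(5, 2, replace=False)
            gs = int(rng.choice([2, 3, 4]))
            history.append(
                _dyadic(t, *sorted((ids[i], ids[j])), duration=float(rng.uniform(5, 300)),
                        group_size=gs, gid=gid)
            )
        specs = [EffectSpec("inertia", "inertia", scaled=False),
                 EffectSpec("sp", "shared_partners", scaled=False)]
        calc = EffectCalculator(rs, actors5, specs)
        calc.update(history)
        got = calc.compute(t + 1)
        np.testing.assert_allclose(got[:, 0], stat_inertia(history, rs, t + 1), atol=1e-10)
        np.testing.assert_allclose(got[:, 1], stat_shared_partners(history, rs, t + 1), atol=1e-10)

    def test_typed_agreement(self, actors5):
        rng = np.random.default_rng(1)
        rs = build_risk_set(actors5, ("leisure", "study"))
        ids = list(actors5.ids)
        history = []
        for gid in range(25):
            i, j = rng.choice(5, 2, replace=False)
            history.append(
                _dyadic(float(gid + 1), *sorted((ids[i], ids[j])),
                        duration=float(rng.uniform(5, 100)),
                        setting=str(rng.choice(["leisure", "study"])), gid=gid)
            )
        specs = [EffectSpec("si", "type_inertia", scaled=False),
                 EffectSpec("ssp", "type_shared_partners", scaled=False)]
        calc = EffectCalculator(rs, actors5, specs)
        calc.update(history)
        got = calc.compute(1000.0)
        np.testing.assert_allclose(got[:, 0], stat_type_inertia(history, rs, 1000.0), atol=1e-10)
        np.testing.assert_allclose(
            got[:, 1], stat_type_shared_partners(history, rs, 1000.0), atol=1e-10
        )
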