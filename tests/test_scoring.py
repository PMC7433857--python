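import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semloss import (
    InvariantViolationError,
    ItemOutcomes,
    NoMissedItemsError,
    ParticipantRecord,
    UndefinedRatioError,
    consistency_score_aggregate,
    consistency_score_items,
    cue_retrieval_score,
    naming_general_ratio,
    round_half_away,
    score_cohort,
    ssl_score,
)


def make_record(naming, cued, wpmt, mmse, pid="p1", **kw):
    return ParticipantRecord(
        participant_id=pid,
        naming_correct=naming,
        cued_correct=cued,
        wpmt_correct=wpmt,
        mmse=mmse,
        **kw,
    )


def make_items(named, cue, recog, pid="p1", mmse=20):
    """Build ItemOutcomes from counts: `named` spontaneous hits first, then
    `cue` cue-recoveries among the misses, `recog` recognitions among a
    supplied per-item boolean list."""
    spont = [i < named for i in range(64)]
    cued = [False] * 64
    placed = 0
    for i in range(64):
        if not spont[i] and placed < cue:
            cued[i] = True
            placed += 1
    return ItemOutcomes(
        participant_id=pid,
        named_spontaneously=tuple(spont),
        named_with_cue=tuple(cued),
        recognized_in_wpmt=tuple(recog),
        mmse=mmse,
    )


class TestCueRetrievalScore:
    def test_mr_row(self):
        assert cue_retrieval_score(51, 61) == pytest.approx(10 / 13)

    def test_no_cue_recovery(self):
        assert cue_retrieval_score(11, 11) == 0.0

    def test_all_recovered(self):
        assert cue_retrieval_score(57, 64) == 1.0

    def test_no_missed_items(self):
        with pytest.raises(NoMissedItemsError):
            cue_retrieval_score(64, 64)

    def test_cued_below_naming(self):
        with pytest.raises(InvariantViolationError):
            cue_retrieval_score(30, 20)


class TestConsistencyAggregate:
    def test_mr_row(self):
        score, clamped = consistency_score_aggregate(51, 63)
        assert score == pytest.approx(12 / 13)
        assert not clamped

    def test_mg_row(self):
        score, _ = consistency_score_aggregate(31, 45)
        assert score == pytest.approx(14 / 33)

    def test_no_additional_recognition(self):
        assert consistency_score_aggregate(10, 10) == (0.0, False)

    def test_clamped_when_wpmt_below_naming(self):
        score, clamped = consistency_score_aggregate(51, 43)
        assert score == 0.0
        assert clamped

    def test_no_missed_items(self):
        with pytest.raises(NoMissedItemsError):
            consistency_score_aggregate(64, 64)


class TestConsistencyItems:
    def test_direct_count(self):
        # 13 missed, 12 of those recognized
        recog = [False] * 64
        for i in range(51, 63):
            recog[i] = True
        items = make_items(51, 0, recog)
        assert consistency_score_items(items) == pytest.approx(12 / 13)

    def test_all_missed_unrecognized(self):
        items = make_items(30, 0, [i < 30 for i in range(64)])
        assert consistency_score_items(items) == 0.0

    def test_divergence_from_aggregate(self):
        # aggregate counts naming=31, wpmt=45, but 3 spontaneously named
        # items were NOT recognized: item-level gives 17/33, aggregate 14/33
        recog = [i < 28 for i in range(64)]  # 28 of the 31 named recognized
        for i in range(31, 48):  # 17 of the 33 missed recognized
            recog[i] = True
        items = make_items(31, 0, recog)
        assert items.wpmt_correct == 45
        assert consistency_score_items(items) == pytest.approx(17 / 33)
        agg, _ = consistency_score_aggregate(31, 45)
        assert agg == pytest.approx(14 / 33)

    def test_zero_missed_raises(self):
        items = make_items(64, 0, [True] * 64)
        with pytest.raises(NoMissedItemsError):
            consistency_score_items(items)

    def test_cued_baseline_variant(self):
        # non-canonical: condition on items missed even with a cue
        recog = [False] * 64
        for i in range(40, 52):
            recog[i] = True
        items = make_items(30, 10, recog)
        # 64 - 30 - 10 = 24 missed even with cue (items 40..63); 12 recognized
        assert consistency_score_items(items, baseline="cued") == pytest.approx(12 / 24)


class TestNamingGeneralRatio:
    def test_equal_proportions(self):
        assert naming_general_ratio(32, 15) == pytest.approx(0.5)

    def test_mr_row(self):
        assert naming_general_ratio(51, 19) == pytest.approx(0.796875 / (0.796875 + 19 / 30))

    def test_zero_mmse(self):
        assert naming_general_ratio(40, 0) == 1.0

    def test_both_zero(self):
        with pytest.raises(UndefinedRatioError):
            naming_general_ratio(0, 0)

    def test_custom_maxima(self):
        assert naming_general_ratio(10, 5, naming_max=20, mmse_max=10) == 0.5


class TestSslScore:
    def test_row_mr(self):
        comp = ssl_score(make_record(51, 61, 63, 19))
        assert comp.ssl == pytest.approx(10 / 39 + 12 / 39 + (51 / 64) / (51 / 64 + 19 / 30) / 3)
        assert comp.ssl_display == 0.75

    def test_row_mc(self):
        comp = ssl_score(make_record(12, 16, 24, 17))
        assert comp.ssl == pytest.approx(0.1854, abs=5e-5)
        assert comp.ssl_display == 0.19

    def test_all_maximal_recovery(self):
        comp = ssl_score(make_record(63, 64, 64, 0))
        assert (comp.c_cue, comp.c_consistency, comp.c_ratio) == (1.0, 1.0, 1.0)
        assert comp.ssl == 1.0

    def test_flags_aggregate(self):
        comp = ssl_score(make_record(51, 61, 63, 19))
        assert "aggregate-mode" in comp.flags

    def test_clamped_flag(self):
        comp = ssl_score(make_record(27, 51, 43, 17))  # WPMT below naming? no
        assert "clamped" not in comp.flags
        comp = ssl_score(make_record(51, 60, 43, 17))
        assert "clamped" in comp.flags

    def test_item_level_mode(self):
        recog = [True] * 64
        items = make_items(30, 5, recog)
        comp = ssl_score(items, mode="item_level")
        assert "item-level-mode" in comp.flags
        assert comp.c_consistency == 1.0

    def test_item_level_requires_items(self):
        with pytest.raises(TypeError):
            ssl_score(make_record(10, 12, 20, 15), mode="item_level")


class TestScoreCohort:
    def test_fixture_reproduction(self, fixture28):
        scored = score_cohort(fixture28.records)
        merged = scored.merge(
            fixture28.frame[["participant_id", "ssl_printed", "reproducible"]],
            on="participant_id",
        )
        consistent = merged[merged.reproducible]
        assert len(consistent) == 26
        assert (consistent.ssl_display == consistent.ssl_printed).all()

    def test_empty_input(self):
        assert len(score_cohort([])) == 0

    def test_unscorable_retained(self):
        rows = score_cohort([make_record(64, 64, 64, 20)])
        assert len(rows) == 1
        assert rows.unscorable_reason.iloc[0] == "no-missed-items"
        assert math.isnan(rows.ssl.iloc[0])

    def test_duplicate_id(self):
        recs = [make_record(10, 12, 20, 15), make_record(11, 12, 20, 15)]
        with pytest.raises(InvariantViolationError):
            score_cohort(recs)


class TestRecordValidation:
    def test_cued_below_naming_rejected(self):
        with pytest.raises(ValueError):
            make_record(30, 20, 40, 15)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            make_record(10, 12, 70, 15)
        with pytest.raises(ValueError):
            make_record(10, 12, 40, 31)

    def test_roi_ratio_positive(self):
        with pytest.raises(ValueError):
            make_record(10, 12, 40, 15, roi_ratios={"atl_left": 0.0})


class TestRounding:
    def test_half_away_from_zero(self):
        assert round_half_away(0.505, 2) == 0.51
        assert round_half_away(0.125, 2) == 0.13
        assert round_half_away(-0.125, 2) == -0.13

    def test_plain_cases(self):
        assert round_half_away(0.4348, 2) == 0.43


# ---------------------------------------------------------------------------
# property tests

record_strategy = st.tuples(
    st.integers(0, 63),  # naming (< 64 so the record is scorable)
    st.integers(0, 64),
    st.integers(0, 64),
    st.integers(0, 30),
).map(lambda t: (t[0], max(t[0], t[1]), t[2], t[3]))


@given(record_strategy)
def test_ssl_is_mean_of_components_and_in_unit_interval(params):
    naming, cued, wpmt, mmse = params
    if naming == 0 and mmse == 0:
        return
    comp = ssl_score(make_record(naming, cued, wpmt, mmse))
    assert comp.ssl == (comp.c_cue + comp.c_consistency + comp.c_ratio) / 3
    for v in (comp.c_cue, comp.c_consistency, comp.c_ratio, comp.ssl):
        assert 0.0 <= v <= 1.0


@given(record_strategy, st.integers(1, 5))
def test_monotone_in_cued(params, delta):
    naming, cued, wpmt, mmse = params
    if naming == 0 and mmse == 0:
        return
    hi = min(64, cued + delta)
    lo = ssl_score(make_record(naming, cued, wpmt, mmse)).ssl
    assert ssl_score(make_record(naming, hi, wpmt, mmse)).ssl >= lo - 1e-12


@given(record_strategy, st.integers(1, 5))
def test_monotone_in_wpmt(params, delta):
    naming, cued, wpmt, mmse = params
    if naming == 0 and mmse == 0:
        return
    hi = min(64, wpmt + delta)
    lo = ssl_score(make_record(naming, cued, wpmt, mmse)).ssl
    assert ssl_score(make_record(naming, cued, hi, mmse)).ssl >= lo - 1e-12


@given(record_strategy, st.integers(1, 5))
def test_antitone_in_mmse(params, delta):
    naming, cued, wpmt, mmse = params
    if naming == 0:
        return
    hi = min(30, mmse + delta)
    lo = ssl_score(make_record(naming, cued, wpmt, mmse)).ssl
    assert ssl_score(make_record(naming, cued, wpmt, hi)).ssl <= lo + 1e-12


@settings(max_examples=200)
@given(st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans()), min_size=64, max_size=64))
def test_item_aggregate_agreement_under_nesting(triples):
    """When every spontaneously named item is recognized, the two consistency
    routes agree exactly."""
    named = [t[0] for t in triples]
    if all(named):
        return
    cued = [(not n) and t[1] for n, t in zip(named, triples)]
    recog = [n or t[2] for n, t in zip(named, triples)]  # force nesting
    items = ItemOutcomes(
        participant_id="h",
        named_spontaneously=tuple(named),
        named_with_cue=tuple(cued),
        recognized_in_wpmt=tuple(recog),
        mmse=20,
    )
    agg, clamped = consistency_score_aggregate(items.naming_correct, items.wpmt_correct)
    assert not clamped
    assert consistency_score_items(items) == pytest.approx(agg, abs=1e-12)
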