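"""Deviation, symmetry index, trial aggregation and change scores."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stancemcid import (
    InsufficientDataError,
    PairingError,
    TrialMeasurement,
    UndefinedSymmetryIndexError,
    ValidationError,
    aggregate_cohort,
    aggregate_trials,
    build_change_table,
    compute_change,
    compute_deviation,
    compute_symmetry_index,
)


def make_trials(dog, tp, hind_pairs, fore_split=True):
    """Trials with given (lh, rh) pairs; forelimbs absorb the rest."""
    out = []
    for i, (lh, rh) in enumerate(hind_pairs, start=1):
        fore = (100.0 - lh - rh) / 2.0
        out.append(TrialMeasurement(dog, tp, i, fore, fore, lh, rh))
    return out


class TestDeviation:
    @pytest.mark.parametrize(
        "wb, expected",
        [(20.0, 0.0), (16.5, 3.5), (23.0, 3.0), (0.0, 20.0), (100.0, 80.0)],
    )
    def test_values(self, wb, expected):
        assert compute_deviation(wb) == pytest.approx(expected)

    @pytest.mark.parametrize("wb", [-0.1, 100.1, 250.0])
    def test_out_of_range_rejected(self, wb):
        with pytest.raises(ValidationError):
            compute_deviation(wb)

    @given(st.floats(0.0, 100.0))
    def test_zero_iff_normal_load(self, wb):
        dev = compute_deviation(wb)
        assert dev >= 0.0
        assert (dev == 0.0) == (wb == 20.0)


class TestSymmetryIndex:
    @pytest.mark.parametrize(
        "wbr, wbl, expected",
        [(20.0, 20.0, 0.0), (15.0, 25.0, 50.0), (25.0, 15.0, 50.0), (10.0, 0.0, 200.0)],
    )
    def test_values(self, wbr, wbl, expected):
        assert compute_symmetry_index(wbr, wbl) == pytest.approx(expected)

    def test_undefined_when_both_zero(self):
        with pytest.raises(UndefinedSymmetryIndexError):
            compute_symmetry_index(0.0, 0.0)

    def test_negative_load_rejected(self):
        with pytest.raises(ValidationError):
            compute_symmetry_index(-1.0, 20.0)

    @given(
        st.floats(0.01, 100.0),
        st.floats(0.01, 100.0),
    )
    def test_symmetric_in_arguments(self, a, b):
        assert compute_symmetry_index(a, b) == pytest.approx(
            compute_symmetry_index(b, a)
        )

    @given(
        st.floats(0.1, 50.0),
        st.floats(0.1, 50.0),
        st.floats(0.1, 2.0),
    )
    def test_scale_invariant(self, a, b, k):
        assert compute_symmetry_index(k * a, k * b) == pytest.approx(
            compute_symmetry_index(a, b), rel=1e-9
        )

    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    def test_bounded_by_200(self, a, b):
        if a + b > 0:
            assert 0.0 <= compute_symmetry_index(a, b) <= 200.0


class TestAggregateTrials:
    def test_identity_case(self):
        trials = make_trials("d", "T0", [(20.0, 20.0)] * 20)
        left, right, dog = aggregate_trials(trials)
        assert left.deviation == right.deviation == 0.0
        assert dog.si == 0.0
        assert left.n_trials == 20

    def test_alternating_trials_average_out(self):
        pairs = [(20.0, 18.0), (20.0, 22.0)] * 10
        _, right, _ = aggregate_trials(make_trials("d", "T0", pairs))
        assert right.wb_mean == pytest.approx(20.0)
        assert right.deviation == pytest.approx(0.0)

    def test_too_few_trials(self):
        with pytest.raises(InsufficientDataError):
            aggregate_trials(make_trials("d", "T0", [(20.0, 20.0)] * 19))

    def test_invalid_trial_names_index(self):
        trials = make_trials("d", "T0", [(20.0, 20.0)] * 20)
        bad = TrialMeasurement("d", "T0", 7, 40.0, 40.0, 20.0, 20.0)  # sums to 120
        trials[6] = bad
        with pytest.raises(ValidationError, match="trial 7"):
            aggregate_trials(trials)

    def test_mixed_sessions_rejected(self):
        trials = make_trials("d", "T0", [(20.0, 20.0)] * 19) + make_trials(
            "d", "D15", [(20.0, 20.0)]
        )
        with pytest.raises(ValidationError, match="mix"):
            aggregate_trials(trials)

    def test_order_invariance(self, rng):
        hind = [(18.0 + 0.1 * i, 19.0 - 0.05 * i) for i in range(25)]
        trials = make_trials("d", "T0", hind)
        shuffled = list(trials)
        rng.shuffle(shuffled)
        a = aggregate_trials(trials)
        b = aggregate_trials(shuffled)
        assert a[0].wb_mean == pytest.approx(b[0].wb_mean)
        assert a[2].si == pytest.approx(b[2].si)

    def test_si_from_limb_means_matches_aggregate(self):
        # SI after aggregation equals SI of the limb means
        hind = [(18.0 + 0.2 * i, 16.0 + 0.1 * i) for i in range(20)]
        left, right, dog = aggregate_trials(make_trials("d", "T0", hind))
        assert dog.si == pytest.approx(compute_symmetry_index(right.wb_mean, left.wb_mean))


class TestChange:
    @pytest.mark.parametrize(
        "t0, d15, expected",
        [(3.0, 1.6, -1.4), (5.0, 5.0, 0.0), (37.8, 13.9, -23.9)],
    )
    def test_change_values(self, t0, d15, expected):
        assert compute_change(t0, d15).change == pytest.approx(expected)

    def test_missing_timepoint(self):
        with pytest.raises(PairingError):
            compute_change(3.0, None, unit_id="x", measurement="deviation")
        with pytest.raises(PairingError):
            compute_change(float("nan"), 1.0)


class TestCohortTables:
    def test_change_table_shapes_and_replication(self, small_trials):
        limb, dog = aggregate_cohort(small_trials)
        assert len(limb) == 8  # 2 dogs x 2 sides x 2 timepoints
        assert len(dog) == 4
        changes = build_change_table(limb, dog)
        # 4 deviation rows (per limb) + 4 SI rows (dog SI replicated per limb)
        assert len(changes) == 8
        assert changes.attrs["si_replicated"]
        si = changes[changes.measurement == "si"]
        for _, grp in si.groupby("dog_id"):
            assert grp["change"].nunique() == 1  # replicated, not recomputed

    def test_known_deviations(self, small_trials):
        limb, _ = aggregate_cohort(small_trials)
        row = limb[(limb.dog_id == "b") & (limb.side == "left") & (limb.timepoint == "T0")]
        assert row.deviation.item() == pytest.approx(5.0)
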