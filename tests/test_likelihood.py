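import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cclr import (
    ACMG_ORDER,
    CarrierFrequencyWarning,
    CaseControlDataset,
    FrequencyError,
    IncidenceTable,
    PenetranceModel,
    RelativeRiskCurve,
    acmg_strength,
    bundled_model,
    combined_lr,
    filter_dataset,
    screen_carrier_frequency,
    stratum_lr,
)
from cclr.likelihood import FLAG_NO_CARRIERS
from conftest import dataset
from oracles import naive_lr


# a deliberately lumpy piecewise model for oracle comparisons
ORACLE_INC_BREAKS = [0.0, 40.0, 60.0, 81.0]
ORACLE_INC_RATES = [0.002, 0.01, 0.02]
ORACLE_RR_BREAKS = [0.0, 45.0, 81.0]
ORACLE_RR_LOGS = [math.log(8.0), math.log(3.0)]


@pytest.fixture(scope="module")
def lumpy_model():
    return PenetranceModel(
        IncidenceTable(ORACLE_INC_BREAKS, ORACLE_INC_RATES),
        RelativeRiskCurve(ORACLE_RR_BREAKS, ORACLE_RR_LOGS),
        age_range=(21.0, 80.0),
    )


def test_toy_example_case_carrier(const_model, toy4):
    assert stratum_lr(toy4, const_model) == pytest.approx(4 / 3, rel=1e-10)


def test_toy_example_control_carrier(const_model, toy4_control_carrier):
    assert stratum_lr(toy4_control_carrier, const_model) == pytest.approx(
        2 / 3, rel=1e-10
    )


def test_null_hypothesis_gives_unit_lr():
    model = PenetranceModel(
        IncidenceTable([0, 80], [0.01]), RelativeRiskCurve.null(0, 80), (21, 80)
    )
    ds = dataset([1, 0, 1, 0, 0], [1, 1, 0, 0, 1], [25.0, 40.0, 55.0, 70.0, 80.0])
    assert stratum_lr(ds, model) == pytest.approx(1.0, abs=1e-14)


def test_no_carriers_yields_unit_lr_with_flag(const_model):
    ds = dataset([0, 0, 0], [1, 0, 1], [50.0, 60.0, 70.0])
    assert stratum_lr(ds, const_model) == 1.0
    res = combined_lr(ds, const_model)
    assert res.lr == 1.0
    assert FLAG_NO_CARRIERS in res.flags


@given(
    rows=st.lists(
        st.tuples(
            st.integers(0, 1), st.integers(0, 1), st.floats(21.0, 80.0)
        ),
        min_size=1,
        max_size=12,
    )
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_stratum_lr_matches_bruteforce_oracle(lumpy_model, rows):
    """The log-space vectorized LR equals the naive first-principles product."""
    ds = dataset([r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows])
    expected = naive_lr(rows, ORACLE_INC_BREAKS, ORACLE_INC_RATES,
                        ORACLE_RR_BREAKS, ORACLE_RR_LOGS)
    assert stratum_lr(ds, lumpy_model) == pytest.approx(expected, rel=1e-10)


def test_lr_invariant_under_reordering(lumpy_model):
    rng = np.random.default_rng(5)
    carrier = rng.integers(0, 2, 30)
    status = rng.integers(0, 2, 30)
    age = rng.uniform(21, 80, 30)
    ds = dataset(carrier, status, age)
    perm = rng.permutation(30)
    ds_perm = dataset(carrier[perm], status[perm], age[perm])
    assert stratum_lr(ds, lumpy_model) == pytest.approx(
        stratum_lr(ds_perm, lumpy_model), rel=1e-12
    )


def test_moving_carrier_from_control_to_case_increases_lr(const_model):
    base_status = [1, 1, 0, 0]
    ages = [50.0, 44.0, 50.0, 61.0]
    lr_control = stratum_lr(dataset([0, 0, 1, 0], base_status, ages), const_model)
    lr_case = stratum_lr(dataset([1, 0, 0, 0], base_status, ages), const_model)
    assert lr_case > lr_control


@pytest.mark.parametrize("k", [1, 2, 3])
def test_single_status_single_age_gives_unit_lr(const_model, k):
    """All-controls (or all-cases) at one common age: LR = 1 for any K."""
    carrier = [1] * k + [0] * (5 - k)
    assert stratum_lr(dataset(carrier, [0] * 5, [60.0] * 5), const_model) == (
        pytest.approx(1.0, rel=1e-12)
    )
    assert stratum_lr(dataset(carrier, [1] * 5, [60.0] * 5), const_model) == (
        pytest.approx(1.0, rel=1e-12)
    )


def test_combined_single_stratum_equals_unstratified(const_model, toy4):
    labeled = dataset([1, 0, 0, 0], [1, 1, 0, 0], [50.0] * 4, stratum=["uk"] * 4)
    res = combined_lr(labeled, const_model, stratify_by="stratum")
    assert res.lr == pytest.approx(stratum_lr(toy4, const_model), rel=1e-12)


def test_combined_lr_is_product_of_strata(const_model):
    two = dataset(
        [1, 0, 0, 0] * 2,
        [1, 1, 0, 0] * 2,
        [50.0] * 8,
        stratum=["a"] * 4 + ["b"] * 4,
    )
    res = combined_lr(two, const_model, stratify_by="stratum")
    assert res.lr == pytest.approx((4 / 3) ** 2, rel=1e-10)
    prod = np.prod([s.lr for s in res.per_stratum.values()])
    assert res.lr == pytest.approx(prod, rel=1e-10)
    assert res.k_total == 2 and res.n_total == 8


def test_zero_carrier_stratum_contributes_unit_factor(const_model):
    mixed = dataset(
        [1, 0, 0, 0, 0, 0],
        [1, 1, 0, 0, 1, 0],
        [50.0] * 6,
        stratum=["a"] * 4 + ["b"] * 2,
    )
    res = combined_lr(mixed, const_model, stratify_by="stratum")
    assert res.lr == pytest.approx(4 / 3, rel=1e-10)
    assert FLAG_NO_CARRIERS in res.per_stratum["b"].flags


def test_stratify_requires_labels(const_model, toy4):
    with pytest.raises(ValueError, match="stratum label"):
        combined_lr(toy4, const_model, stratify_by="stratum")


def test_unknown_ages_rejected_before_lr(const_model):
    ds = dataset([1, 0], [1, 0], [50.0, np.nan])
    with pytest.raises(ValueError, match="unknown"):
        stratum_lr(ds, const_model)


# ---------------------------------------------------------------------------
# ACMG/AMP mapping
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "lr, code",
    [
        (350.0, "pathogenic_very_strong"),
        (400.0, "pathogenic_very_strong"),
        (18.7, "pathogenic_strong"),
        (349.99, "pathogenic_strong"),
        (4.33, "pathogenic_moderate"),
        (18.69, "pathogenic_moderate"),
        (2.08, "pathogenic_supporting"),
        (4.32, "pathogenic_supporting"),
        (1.0, "none"),
        (2.0799, "none"),
        (0.4801, "none"),
        (0.48, "benign_supporting"),
        (0.232, "benign_supporting"),
        (0.231, "benign_moderate"),
        (0.0531, "benign_moderate"),
        (0.053, "benign_strong"),
        (0.00291, "benign_strong"),
        (0.0029, "benign_very_strong"),
        (1e-9, "benign_very_strong"),
    ],
)
def test_acmg_strength_thresholds(lr, code):
    assert acmg_strength(lr) == code


def test_acmg_strength_is_monotone_step_function():
    lrs = np.sort(np.concatenate([
        np.logspace(-4, 4, 300),
        [0.0029, 0.053, 0.231, 0.48, 2.08, 4.33, 18.7, 350.0],
    ]))
    ranks = [ACMG_ORDER.index(acmg_strength(x)) for x in lrs]
    assert all(a <= b for a, b in zip(ranks, ranks[1:]))


def test_acmg_strength_rejects_nonpositive():
    for bad in (0.0, -1.0, np.nan, np.inf):
        with pytest.raises(ValueError):
            acmg_strength(bad)


# ---------------------------------------------------------------------------
# Filtering and frequency screen
# ---------------------------------------------------------------------------


def test_filter_drops_out_of_range_ages(const_model):
    ds = dataset([0, 0, 0, 1], [1, 1, 0, 0], [20.0, 21.0, 80.0, 81.0])
    kept, report = filter_dataset(ds, const_model)
    assert sorted(kept.frame["age"]) == [21.0, 80.0]
    assert report.n_age_out_of_range == 2
    assert report.n_output == 2


def test_filter_all_known_is_noop(const_model, toy4):
    kept, report = filter_dataset(toy4, const_model)
    pd.testing.assert_frame_equal(kept.frame, toy4.frame)
    assert report.n_age_out_of_range == 0
    assert report.n_unknown_assigned == 0


def test_filter_unknown_age_oldest_band():
    model = bundled_model("brca1")  # oldest incidence band [75, 81) clipped at 80
    ds = dataset([0, 1], [0, 1], [50.0, np.nan])
    kept, report = filter_dataset(ds, model, unknown_age_policy="oldest")
    assert report.n_unknown_assigned == 1
    assert report.assigned_age == pytest.approx(77.5)
    assert kept.frame["age"].iloc[1] == pytest.approx(77.5)


def test_filter_unknown_age_exclude(const_model):
    ds = dataset([0, 1], [0, 1], [50.0, np.nan])
    kept, report = filter_dataset(ds, const_model, unknown_age_policy="exclude")
    assert len(kept) == 1
    assert report.n_unknown_excluded == 1


def test_filter_unknown_age_fixed(const_model):
    ds = dataset([0, 1], [0, 1], [50.0, np.nan])
    kept, _ = filter_dataset(ds, const_model, unknown_age_policy=65)
    assert kept.frame["age"].iloc[1] == 65.0


def test_filter_empty_result_errors(const_model):
    ds = dataset([1], [1], [90.0])
    with pytest.raises(ValueError, match="no individuals"):
        filter_dataset(ds, const_model, unknown_age_policy="exclude")


def test_frequency_screen_warns_and_hard_filters(const_model):
    common = dataset([1, 1, 0, 0], [1, 1, 0, 0], [50.0] * 4)  # freq 0.5
    with pytest.warns(CarrierFrequencyWarning):
        freq = screen_carrier_frequency(common, threshold=0.001)
    assert freq == 0.5
    with pytest.raises(FrequencyError):
        screen_carrier_frequency(common, threshold=0.001, hard=True)
    import warnings
    rare = dataset([1] + [0] * 9, [1] * 5 + [0] * 5, [50.0] * 10)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        screen_carrier_frequency(rare, threshold=0.2)


def test_dataset_validation():
    with pytest.raises(ValueError, match="non-binary"):
        CaseControlDataset(pd.DataFrame({"carrier": [2], "status": [1], "age": [50.0]}))
    with pytest.raises(ValueError, match="at least one"):
        CaseControlDataset(pd.DataFrame({"carrier": [], "status": [], "age": []}))
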