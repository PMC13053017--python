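"""Mixed-model analyses against degenerate-limit and arithmetic oracles."""

import numpy as np
import pandas as pd
import pytest

from promkin.errors import ParameterError
from promkin.models import (
    accuracy_by_movement_test,
    fit_condition_model,
    fit_gradient_model,
    movement_boost_test,
)


def _trial_frame(rows):
    return pd.DataFrame(rows)


def _cond_rows(cond_means, n_speakers=4, n_items=8, noise=None, rng=None):
    rows = []
    conds = list(cond_means)
    for s in range(n_speakers):
        for i in range(n_items):
            c = conds[i % len(conds)]
            y = cond_means[c]
            if noise is not None:
                y = y + rng.normal(0, noise)
            rows.append(
                dict(speaker_id=f"s{s}", item_id=f"i{i}", movement=True,
                     condition=c, asynchrony_ms=y, distance=0,
                     production_class="correct_L2", peak_intensity=0.2)
            )
    return _trial_frame(rows)


def test_zero_noise_condition_model_recovers_exact_means():
    means = {"matching_correct": -48.0, "precede_correct": -88.0,
             "follow_correct": 45.0}
    fit = fit_condition_model(_cond_rows(means))
    for c, m in means.items():
        assert fit[c] == pytest.approx(m, abs=1e-6)


def test_balanced_two_condition_fixed_effects_equal_raw_means():
    rng = np.random.default_rng(0)
    df = _cond_rows(
        {"matching_correct": -50.0, "follow_correct": 40.0},
        n_speakers=6, n_items=12, noise=30.0, rng=rng,
    )
    fit = fit_condition_model(df, re_speaker=False, re_item=False)
    raw = df.groupby("condition", observed=True)["asynchrony_ms"].mean()
    assert fit["matching_correct"] == pytest.approx(raw["matching_correct"], abs=1e-6)
    assert fit["follow_correct"] == pytest.approx(raw["follow_correct"], abs=1e-6)


def test_gradient_slope_exact_on_noiseless_linear_data():
    rows = []
    s_true = -77.0
    for s in range(4):
        for i, d in enumerate([-2, -1, 1, 2] * 3):
            rows.append(
                dict(speaker_id=f"s{s}", item_id=f"i{i}", movement=True,
                     condition="precede_correct" if d < 0 else "follow_correct",
                     asynchrony_ms=s_true * d, distance=d,
                     production_class="correct_L2", peak_intensity=0.2)
            )
    fit = fit_gradient_model(_trial_frame(rows))
    assert fit["distance"] == pytest.approx(s_true, abs=1e-6)
    assert fit["intercept"] == pytest.approx(0.0, abs=1e-6)


def test_gradient_slope_null_case_not_significant():
    rng = np.random.default_rng(1)
    rows = []
    for s in range(6):
        for i, d in enumerate([-2, -1, 1, 2] * 6):
            rows.append(
                dict(speaker_id=f"s{s}", item_id=f"i{i}", movement=True,
                     condition="precede_correct" if d < 0 else "follow_correct",
                     asynchrony_ms=rng.normal(0, 50), distance=d,
                     production_class="correct_L2", peak_intensity=0.2)
            )
    fit = fit_gradient_model(_trial_frame(rows))
    assert abs(fit["distance"]) < 25.0
    assert fit.pvalue("distance") > 0.016


def test_gradient_constant_distance_rejected():
    rows = [
        dict(speaker_id="s0", item_id=f"i{k}", movement=True,
             condition="precede_correct", asynchrony_ms=-88.0, distance=-1,
             production_class="correct_L2", peak_intensity=0.2)
        for k in range(10)
    ]
    with pytest.raises(ParameterError):
        fit_gradient_model(_trial_frame(rows))


def test_intensity_boost_exact_difference_of_means():
    rows = []
    b = 0.04
    for s in range(4):
        for i in range(10):
            for mv in (False, True):
                rows.append(
                    dict(speaker_id=f"s{s}", item_id=f"i{i}", movement=mv,
                         condition="matching_correct", asynchrony_ms=None,
                         distance=0, production_class="correct_L2",
                         peak_intensity=0.20 + (b if mv else 0.0))
                )
    fit = movement_boost_test(_trial_frame(rows))
    assert fit["movement"] == pytest.approx(b, abs=1e-6)


def test_intensity_boost_needs_both_conditions():
    rows = [
        dict(speaker_id="s0", item_id=f"i{k}", movement=True,
             condition="matching_correct", asynchrony_ms=None, distance=0,
             production_class="correct_L2", peak_intensity=0.2)
        for k in range(6)
    ]
    with pytest.raises(ParameterError):
        movement_boost_test(_trial_frame(rows))


def _accuracy_rows(p_mv, p_nm, n_speakers=10, n_items=24, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_speakers):
        for i in range(n_items):
            for mv, p in ((True, p_mv), (False, p_nm)):
                correct = rng.random() < p
                rows.append(
                    dict(speaker_id=f"s{s}", item_id=f"i{i}", movement=mv,
                         condition="matching_correct", asynchrony_ms=None,
                         distance=0,
                         production_class="correct_L2" if correct else "other",
                         peak_intensity=0.2)
                )
    return _trial_frame(rows)


def test_accuracy_null_retained_when_rates_equal():
    fit = accuracy_by_movement_test(_accuracy_rows(0.6, 0.6, seed=2))
    assert fit.pvalue("movement") > 0.016


def test_accuracy_detects_large_difference_with_correct_sign():
    df = _accuracy_rows(0.9, 0.5, n_speakers=15, n_items=30, seed=3)
    fit = accuracy_by_movement_test(df)
    assert fit["movement"] > 0
    assert fit.pvalue("movement") < 0.016
    # two-proportion oracle: log-odds difference of the raw rates
    p_mv = (df[df.movement].production_class == "correct_L2").mean()
    p_nm = (df[~df.movement].production_class == "correct_L2").mean()
    lo = np.log(p_mv / (1 - p_mv)) - np.log(p_nm / (1 - p_nm))
    assert fit["movement"] == pytest.approx(lo, abs=0.5)


def test_summary_table_shape():
    means = {"matching_correct": -48.0, "precede_correct": -88.0}
    fit = fit_condition_model(_cond_rows(means))
    tab = fit.summary()
    assert list(tab.columns) == ["term", "estimate", "se", "z", "p", "significant"]
    assert len(tab) == 2
    lo, hi = fit.conf_int("matching_correct")
    assert lo <= fit["matching_correct"] <= hi
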