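import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from painmod.classify import (
    BootstrapConfig,
    bootstrap_mean_samples,
    classify_cohort,
    classify_subject,
    classify_subject_exact,
    exact_bootstrap_p,
    subject_rng,
)
from painmod.preprocess import StimulusBlockSeries


def series(values, sid="s", idx=1):
    return StimulusBlockSeries(sid, idx, np.asarray(values, dtype=float))


CONFIG = BootstrapConfig(n_resamples=10_000, alpha=0.05, seed=11)


# --- bootstrap_mean_samples -------------------------------------------------


def test_constant_input_gives_constant_resampled_means():
    means = bootstrap_mean_samples(np.full(8, 50.0), 500, subject_rng(0, "a"))
    assert means.shape == (500,)
    np.testing.assert_array_equal(means, 50.0)


def test_resampled_mean_is_unbiased_and_zero_fraction_matches_closed_form():
    vals = np.array([0, 0, 0, 0, 0, 0, 0, 80.0])
    means = bootstrap_mean_samples(vals, 20_000, subject_rng(0, "b"))
    # P(all 8 draws miss the single nonzero value) = (7/8)^8
    p = (7 / 8) ** 8
    se = np.sqrt(p * (1 - p) / 20_000)
    assert np.mean(means == 0.0) == pytest.approx(p, abs=3 * se)
    assert means.mean() == pytest.approx(vals.mean(), abs=3 * vals.std() / np.sqrt(20_000))


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        bootstrap_mean_samples(np.array([]), 10, subject_rng(0, "c"))


# --- classify_subject -------------------------------------------------------


def test_identical_constant_series_is_nonresponder():
    r = classify_subject(series([50.0] * 8), series([50.0] * 8, idx=2), CONFIG)
    assert (r.p_inhibit, r.p_facilitate) == (1.0, 1.0)
    assert r.label == "nonresponder"
    assert r.mean_diff == 0.0


def test_disjoint_constant_series_is_inhibitor():
    r = classify_subject(series([50.0] * 8), series([10.0] * 8, idx=2), CONFIG)
    assert r.p_inhibit == 0.0
    assert r.p_facilitate == 1.0
    assert r.label == "inhibitor"
    assert r.mean_diff == -40.0


def test_shifted_series_is_facilitator_and_matches_exact_oracle():
    control = np.array([42, 44, 46, 48, 50, 52, 54, 56.0])
    r = classify_subject(series(control), series(control + 15, idx=2), CONFIG)
    assert r.label == "facilitator"
    p_i, p_f = exact_bootstrap_p(control, control + 15)
    se = np.sqrt(max(p_f * (1 - p_f), 1 / CONFIG.n_resamples) / CONFIG.n_resamples)
    assert r.p_facilitate == pytest.approx(p_f, abs=3 * se)


def test_mismatched_subjects_and_nonfinite_values_rejected():
    with pytest.raises(ValueError):
        classify_subject(series([50] * 8, sid="a"), series([50] * 8, sid="b"), CONFIG)
    with pytest.raises(ValueError):
        classify_subject(series([50] * 8), series([np.nan] * 8, idx=2), CONFIG)


def test_classification_is_deterministic_given_seed():
    rng = np.random.default_rng(5)
    c, t = rng.uniform(30, 60, 8), rng.uniform(30, 60, 8)
    r1 = classify_subject(series(c), series(t, idx=2), CONFIG)
    r2 = classify_subject(series(c), series(t, idx=2), CONFIG)
    assert (r1.p_inhibit, r1.p_facilitate, r1.label) == (
        r2.p_inhibit,
        r2.p_facilitate,
        r2.label,
    )


# --- exact oracle -----------------------------------------------------------


def test_exact_oracle_trivial_cases():
    assert exact_bootstrap_p([50.0] * 8, [50.0] * 8) == (1.0, 1.0)
    assert exact_bootstrap_p([50.0] * 8, [10.0] * 8) == (0.0, 1.0)


def test_exact_oracle_swap_symmetry_is_exact():
    rng = np.random.default_rng(2)
    for _ in range(5):
        a, b = rng.uniform(20, 70, 8), rng.uniform(20, 70, 8)
        p_i, p_f = exact_bootstrap_p(a, b)
        q_i, q_f = exact_bootstrap_p(b, a)
        assert p_i == pytest.approx(q_f, abs=1e-12)
        assert p_f == pytest.approx(q_i, abs=1e-12)


def test_monte_carlo_matches_exact_within_binomial_error():
    rng = np.random.default_rng(9)
    hits = 0
    n_pairs = 20
    for i in range(n_pairs):
        c = rng.normal(45, 5, 8)
        t = rng.normal(45, 5, 8)
        p_exact, _ = exact_bootstrap_p(c, t)
        r = classify_subject(
            series(c, sid=f"p{i}"), series(t, sid=f"p{i}", idx=2), CONFIG
        )
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-4) / CONFIG.n_resamples)
        hits += abs(r.p_inhibit - p_exact) <= 3 * se
    assert hits >= int(0.95 * n_pairs)


def test_monte_carlo_swap_symmetry_within_tolerance():
    rng = np.random.default_rng(4)
    c, t = rng.normal(45, 6, 8), rng.normal(45, 6, 8)
    fwd = classify_subject(series(c), series(t, idx=2), CONFIG)
    rev = classify_subject(series(t), series(c, idx=2), CONFIG)
    tol = 3 * np.sqrt(0.25 / CONFIG.n_resamples)
    assert fwd.p_inhibit == pytest.approx(rev.p_facilitate, abs=tol)
    assert fwd.p_facilitate == pytest.approx(rev.p_inhibit, abs=tol)


# --- invariants -------------------------------------------------------------


@settings(deadline=None, max_examples=30)
@given(
    c=st.lists(st.floats(0, 100), min_size=8, max_size=8),
    t=st.lists(st.floats(0, 100), min_size=8, max_size=8),
)
def test_tail_masses_overlap_and_labels_are_exclusive(c, t):
    """Ties count toward both tails, so the tail masses always cover the
    whole distribution at least once and only one label can be
    significant at any alpha < 0.5."""
    cfg = BootstrapConfig(n_resamples=300, alpha=0.05, seed=1)
    r = classify_subject(series(c), series(t, idx=2), cfg)
    assert r.p_inhibit + r.p_facilitate >= 1.0
    assert not (r.p_inhibit < cfg.alpha and r.p_facilitate < cfg.alpha)
    assert r.label in ("inhibitor", "nonresponder", "facilitator")
    p_i, p_f = exact_bootstrap_p(c, t)
    assert p_i + p_f >= 1.0 - 1e-12


def test_inhibitor_detection_power_is_monotone_in_effect_size():
    """Classification-as-inhibitor rate grows with |delta| at fixed noise
    (exact oracle on simulated block-mean pairs)."""
    rng = np.random.default_rng(12)
    rates = []
    for delta in (0.0, -4.0, -8.0, -16.0):
        hits = 0
        n = 60
        for i in range(n):
            c = rng.normal(45, 4, 8)
            t = rng.normal(45 + delta, 4, 8)
            hits += classify_subject_exact(series(c), series(t, idx=2)) == "inhibitor"
        rates.append(hits / n)
    assert all(b >= a for a, b in zip(rates, rates[1:]))
    assert rates[-1] > 0.9


# --- cohort -----------------------------------------------------------------


def test_null_cohort_is_all_nonresponders_and_percentages_sum():
    pairs = [
        (series([50.0] * 8, sid=f"s{i}"), series([50.0] * 8, sid=f"s{i}", idx=2))
        for i in range(10)
    ]
    results, props = classify_cohort(pairs, CONFIG)
    assert all(r.label == "nonresponder" for r in results)
    overall = props[props["stratum"] == "overall"]
    assert overall["percent"].sum() == pytest.approx(100.0)
    assert overall.set_index("label").loc["nonresponder", "count"] == 10


def test_duplicate_subject_rejected():
    pairs = [
        (series([50.0] * 8, sid="dup"), series([50.0] * 8, sid="dup", idx=2))
    ] * 2
    with pytest.raises(ValueError):
        classify_cohort(pairs, CONFIG)


def test_subject_streams_are_order_independent():
    rng = np.random.default_rng(0)
    c1, t1 = rng.uniform(30, 60, 8), rng.uniform(30, 60, 8)
    alone = classify_subject(series(c1, sid="x"), series(t1, sid="x", idx=2), CONFIG)
    pairs = [
        (series([40.0] * 8, sid="other"), series([45.0] * 8, sid="other", idx=2)),
        (series(c1, sid="x"), series(t1, sid="x", idx=2)),
    ]
    results, _ = classify_cohort(pairs, CONFIG)
    in_cohort = next(r for r in results if r.subject_id == "x")
    assert (in_cohort.p_inhibit, in_cohort.p_facilitate) == (
        alone.p_inhibit,
        alone.p_facilitate,
    )
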