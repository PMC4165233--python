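"""Grid runner, majority profiles, Mann-Whitney, Bayes classifier,
feature correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import dendrofire as df
from dendrofire.population import (
    POSITIVE_CLASS,
    basal_profile,
    bayes_evaluate,
    bayes_predict,
    bayes_train,
    feature_correlation,
    mann_whitney,
    run_grid,
)

# ----------------------------------------------------------------------
# majority-vote profile
# ----------------------------------------------------------------------


def test_profile_majority_rule():
    assert basal_profile(["RS"] * 60 + ["IB"] * 52) == "RS"
    # exactly half RS is not "more than half"
    assert basal_profile(["RS"] * 56 + ["IB"] * 56) == "IB"
    # quiescent cells count in the denominator
    assert basal_profile(["RS"] * 55 + ["Q"] * 2 + ["IB"] * 55) == "IB"
    assert basal_profile(["RS"] * 57 + ["Q"] * 2 + ["IB"] * 53) == "RS"
    with pytest.raises(ValueError):
        basal_profile([])


# ----------------------------------------------------------------------
# Mann-Whitney
# ----------------------------------------------------------------------


def test_mann_whitney_textbook_example():
    u, p = mann_whitney([1, 2], [3, 4])
    assert u == 0.0
    assert p == pytest.approx(2 / 6, rel=1e-12)


def test_mann_whitney_degenerate_samples():
    with pytest.warns(UserWarning, match="degenerate"):
        _, p = mann_whitney([5.0, 5.0], [5.0, 5.0, 5.0])
    assert p == 1.0


def test_mann_whitney_identical_samples_give_p_one(rng):
    x = rng.normal(size=12)
    u, p = mann_whitney(x, x.copy())
    assert u == pytest.approx(len(x) ** 2 / 2)
    assert p == pytest.approx(1.0)


def test_mann_whitney_exact_matches_scipy(rng):
    """Enumeration branch cross-checked against scipy's independent exact
    implementation on random tie-free samples."""
    for n, m in itertools.product(range(2, 8), range(2, 8)):
        for _ in range(3):
            x = rng.normal(size=n)
            y = rng.normal(loc=rng.uniform(-1, 1), size=m)
            u, p = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_mann_whitney_large_samples_use_corrected_normal(rng):
    x = rng.normal(size=40)
    y = rng.normal(loc=0.8, size=35)
    _, p = mann_whitney(x, y)
    ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic")
    assert p == pytest.approx(ref.pvalue, rel=1e-9)
    assert p < 0.01


def test_mann_whitney_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


# ----------------------------------------------------------------------
# Bayes classifier
# ----------------------------------------------------------------------


def test_bayes_separated_classes_are_learned():
    model = bayes_train([0.0, 0.1, -0.1, 10.0, 10.1, 9.9],
                        ["RS", "RS", "RS", "IB", "IB", "IB"])
    assert bayes_predict(model, 1.0) == "RS"
    assert bayes_predict(model, 9.0) == "IB"


def test_bayes_posterior_tie_goes_to_positive_class():
    # perfectly symmetric classes around 0 -> tie at exactly 0
    model = bayes_train([-2.0, -1.0, 1.0, 2.0], ["RS", "RS", "IB", "IB"])
    assert bayes_predict(model, 0.0) == POSITIVE_CLASS


def test_bayes_evaluate_separated_accuracy_is_one(rng):
    v = np.concatenate([rng.normal(0, 0.01, 20), rng.normal(10, 0.01, 20)])
    lab = np.array(["RS"] * 20 + ["IB"] * 20)
    rep = bayes_evaluate(v, lab, seed=1)
    assert rep.accuracy == 1.0
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0


def test_bayes_evaluate_gaussian_calibration():
    """Two equal-variance Gaussians two SD apart: mean test accuracy near
    the analytic Bayes rate Phi(1) ~ 0.841."""
    local = np.random.default_rng(5)
    v = np.concatenate([local.normal(0, 1, 50), local.normal(2, 1, 50)])
    lab = np.array(["RS"] * 50 + ["IB"] * 50)
    rep = bayes_evaluate(v, lab, seed=3)
    assert rep.accuracy == pytest.approx(sps.norm.cdf(1.0), abs=0.05)


def test_bayes_evaluate_balances_classes(rng):
    v = np.concatenate([rng.normal(0, 1, 60), rng.normal(3, 1, 15)])
    lab = np.array(["RS"] * 60 + ["IB"] * 15)
    rep = bayes_evaluate(v, lab, seed=3)
    assert rep.n_per_class == 15


def test_bayes_evaluate_preconditions(rng):
    v = rng.normal(size=12)
    lab = np.array(["RS"] * 6 + ["IB"] * 6)
    with pytest.raises(ValueError, match="per class"):
        bayes_evaluate(v, lab)  # default floor of 10 per class
    with pytest.raises(ValueError, match="two classes"):
        bayes_evaluate(v, np.array(["RS"] * 12))


def test_bayes_training_never_sees_test_values(rng):
    """Information-leak check: with the repeat seed fixed, replacing the
    held-out observations by garbage leaves the fitted model bit-identical
    (the split indices depend only on the seed, the fit only on the
    training values)."""
    values = np.concatenate([rng.normal(0, 1, 20), rng.normal(4, 1, 20)])
    labels = np.array(["RS"] * 20 + ["IB"] * 20)
    seed = 11
    n_min, frac = 20, 0.8
    n_train = int(round(frac * n_min))

    def train_once(vals):
        rng2 = np.random.default_rng(seed)
        tr_idx = []
        for cls in ("IB", "RS"):
            idx = np.nonzero(labels == cls)[0]
            chosen = rng2.choice(idx, size=n_min, replace=False)
            perm = rng2.permutation(n_min)
            tr_idx.extend(chosen[perm[:n_train]])
        return bayes_train(vals[tr_idx], labels[tr_idx])

    m1 = train_once(values)
    corrupted = values.copy()
    rng3 = np.random.default_rng(0)
    # corrupt everything outside the training indices of this seed
    m_ref = train_once(values)
    test_mask = np.ones(len(values), bool)
    # recompute training indices to find the complement
    rng2 = np.random.default_rng(seed)
    for cls in ("IB", "RS"):
        idx = np.nonzero(labels == cls)[0]
        chosen = rng2.choice(idx, size=n_min, replace=False)
        perm = rng2.permutation(n_min)
        test_mask[chosen[perm[:n_train]]] = False
    corrupted[test_mask] = rng3.normal(100, 50, test_mask.sum())
    m2 = train_once(corrupted)
    assert m1.params == m_ref.params == m2.params


def test_metrics_stay_in_unit_interval(rng):
    v = np.concatenate([rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)])
    lab = np.array(["RS"] * 30 + ["IB"] * 30)
    rep = bayes_evaluate(v, lab, seed=5)
    for col in ("sensitivity", "specificity", "accuracy"):
        assert ((rep.per_repeat[col] >= 0) & (rep.per_repeat[col] <= 1)).all()
    # on balanced test sets accuracy is the mean of the two recalls
    per = rep.per_repeat
    assert np.allclose(
        per["accuracy"], (per["sensitivity"] + per["specificity"]) / 2
    )


# ----------------------------------------------------------------------
# feature correlation
# ----------------------------------------------------------------------


def test_correlation_exact_linear():
    t = pd.DataFrame(
        {"total_length_um": [1.0, 2, 3, 4], "volume_um3": [2.0, 4, 6, 8],
         "branch_number": [3, 1, 4, 2]}
    )
    out = feature_correlation(t)
    r_lv = out[(out.feature_a == "total_length_um")
               & (out.feature_b == "volume_um3")].r.iloc[0]
    assert r_lv == pytest.approx(1.0)


def test_correlation_null_bound(rng):
    t = pd.DataFrame(
        {
            "total_length_um": rng.normal(size=1000),
            "volume_um3": rng.normal(size=1000),
            "branch_number": rng.normal(size=1000),
        }
    )
    out = feature_correlation(t)
    assert (out.r.abs() < 0.1).all()


def test_correlation_matches_covariance_formula(rng):
    t = pd.DataFrame(
        {
            "total_length_um": rng.normal(size=50),
            "volume_um3": rng.normal(size=50),
            "branch_number": rng.normal(size=50),
        }
    )
    out = feature_correlation(t)
    for _, row in out.iterrows():
        x = t[row.feature_a].to_numpy()
        y = t[row.feature_b].to_numpy()
        r = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert row.r == pytest.approx(r, rel=1e-12)


def test_correlation_flags_zero_variance():
    t = pd.DataFrame(
        {"total_length_um": [1.0, 1.0, 1.0], "volume_um3": [1.0, 2, 3],
         "branch_number": [1, 2, 3]}
    )
    with pytest.warns(UserWarning, match="zero-variance"):
        out = feature_correlation(t)
    assert out.r.isna().any()


# ----------------------------------------------------------------------
# simulation grid
# ----------------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_grid_inputs():
    fx = df.fixture_suite()
    return fx["mini_basal"], fx["y_tree"], fx["simple_apical"]


def test_grid_smoke_single_cell(tiny_grid_inputs):
    soma, basal, apical = tiny_grid_inputs
    res = run_grid([basal], [apical], soma, rin_control=100.0,
                   stim_dur_ms=300.0)
    assert res.n_basal == res.n_apical == 1
    lab = res.labels[0][0]
    assert lab.category in {"RS", "IB", "Q"}
    assert res.counts()["failed"] == 0


def test_grid_is_deterministic(tiny_grid_inputs):
    soma, basal, apical = tiny_grid_inputs
    kw = dict(rin_control=100.0, stim_dur_ms=300.0)
    r1 = run_grid([basal, soma], [apical], soma, **kw)
    r2 = run_grid([basal, soma], [apical], soma, **kw)
    assert r1.to_dataframe().equals(r2.to_dataframe())


def test_grid_records_failures_per_cell(tiny_grid_inputs):
    soma, basal, apical = tiny_grid_inputs
    # the apical fixture has no basal points -> its cell fails to graft
    res = run_grid([basal, apical], [apical], soma, rin_control=100.0,
                   stim_dur_ms=300.0)
    assert res.counts()["failed"] == 1
    assert res.labels[1][0] is None
    assert (1, 0) in res.failures
    assert res.labels[0][0] is not None
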