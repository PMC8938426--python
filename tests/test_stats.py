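import numpy as np
import pandas as pd
import pytest

from tnmismatch import (
    ComparisonSpec,
    benjamini_hochberg,
    chi_square_frequency,
    default_config,
    fit_longitudinal_lme,
    generate_cohort,
    generate_longitudinal,
    lrt_group_comparison,
    pairwise_vs_reference,
    slope_contrasts,
)


def bh_stepup_oracle(p):
    """Literal step-up definition, written independently of the implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def test_benjamini_hochberg_matches_stepup_oracle():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        p = rng.random(rng.integers(1, 20))
        np.testing.assert_allclose(benjamini_hochberg(p), bh_stepup_oracle(p),
                                   atol=1e-12)


def test_bh_handles_worked_example_and_monotonicity():
    p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
    adj = benjamini_hochberg(p)
    assert np.all(adj <= 0.05)  # all five rejected at FDR 0.05
    assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)
    assert np.all(benjamini_hochberg(np.ones(4)) == 1.0)


def _covariate_frame(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "sex": rng.choice(["F", "M"], n),
        "age": rng.normal(74, 8, n),
        "education": rng.normal(16, 2.6, n),
    })


def test_lrt_on_constant_outcome_is_null():
    d = _covariate_frame(90)
    d["grp"] = np.repeat(["a", "b", "c"], 30)
    d["y"] = 5.0
    spec = ComparisonSpec("y", ["sex", "age", "education"], "grp", "a")
    stat, df, p = lrt_group_comparison(d, spec)
    assert stat == pytest.approx(0.0, abs=1e-8)
    assert df == 2
    assert p == pytest.approx(1.0)


def test_lrt_detects_one_sd_group_effect():
    rng = np.random.default_rng(1)
    for rep in range(10):
        d = _covariate_frame(300, seed=rep)
        d["grp"] = rng.choice(["a", "b", "c"], 300)
        d["y"] = rng.normal(0, 1, 300) + (d["grp"] == "b") * 1.0
        spec = ComparisonSpec("y", ["sex", "age", "education"], "grp", "a")
        _, _, p = lrt_group_comparison(d, spec)
        assert p < 0.001


def test_lrt_rejects_collinear_covariates():
    d = _covariate_frame(60)
    d["grp"] = np.repeat(["a", "b"], 30)
    d["age_twice"] = 2 * d["age"]
    d["y"] = 1.0 * d["age"]
    spec = ComparisonSpec("y", ["age", "age_twice"], "grp", "a")
    with pytest.raises(ValueError, match="collinear.*age_twice"):
        lrt_group_comparison(d, spec)


def test_lrt_statistic_invariant_to_outcome_rescaling():
    rng = np.random.default_rng(2)
    d = _covariate_frame(120)
    d["grp"] = rng.choice(["a", "b", "c"], 120)
    d["y"] = rng.normal(size=120) + (d["grp"] == "c") * 0.5
    spec = ComparisonSpec("y", ["sex", "age"], "grp", "a")
    stat1, _, _ = lrt_group_comparison(d, spec)
    d["y"] = 3.0 * d["y"] - 7.0
    stat2, _, _ = lrt_group_comparison(d, spec)
    assert stat1 == pytest.approx(stat2, rel=1e-8)


def test_pairwise_vs_reference_applies_bh_within_family():
    rng = np.random.default_rng(3)
    d = _covariate_frame(500)
    d["grp"] = rng.choice(list("abcde"), 500)
    d["y"] = rng.normal(size=500) + (d["grp"] == "e") * 1.5
    spec = ComparisonSpec("y", ["sex", "age"], "grp", "a")
    out = pairwise_vs_reference(d, spec)
    assert list(out["group"]) == list("bcde")
    ranked = out.sort_values("p_raw")
    assert np.all(np.diff(ranked["p_adjusted"]) >= -1e-12)
    assert out.set_index("group").loc["e", "significant"]


def test_chi_square_examples():
    stat, df, p = chi_square_frequency([[10, 10], [10, 10]])
    assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)
    stat, df, _ = chi_square_frequency([[20, 5], [5, 20]])
    assert stat == pytest.approx(18.0)
    assert df == 1
    stat2, _, _ = chi_square_frequency([[40, 10], [10, 40]])
    assert stat2 == pytest.approx(2 * stat)
    with pytest.raises(ValueError, match="margin"):
        chi_square_frequency([[0, 0], [5, 5]])


@pytest.fixture(scope="module")
def longitudinal_fit():
    cfg = default_config(n_participants=300, seed=31)
    *_, participants, labels = generate_cohort(cfg)
    long = generate_longitudinal(cfg, labels)
    parts = participants.copy()
    parts["archetype"] = labels
    parts["a_status"] = np.where(
        parts["amyloid_composite_suvr"].fillna(1.0) >= 1.11, "A+", "A-")
    spec = ComparisonSpec("score", group_col="archetype", reference_group="canonical")
    table = fit_longitudinal_lme(long, parts, spec)
    return cfg, table


def test_mixed_model_recovers_planted_slopes(longitudinal_fit):
    cfg, table = longitudinal_fit
    planted = {a.name: a.cognitive_slope for a in cfg.archetypes}
    # 3 SE per group keeps the family-wise false-alarm rate low across the
    # six simultaneous checks (2 SE each would fail ~1 in 4 cohorts by chance)
    for name, row in table.iterrows():
        assert abs(row["slope"] - planted[name]) < 3 * row["slope_se"], name


def test_reference_cluster_slope_is_the_time_coefficient(longitudinal_fit):
    _, table = longitudinal_fit
    ref = table.loc["canonical"]
    assert ref["interaction"] == 0.0
    assert np.isnan(ref["p_raw"])


def test_slope_contrasts_exclude_reference(longitudinal_fit):
    _, table = longitudinal_fit
    contrasts = slope_contrasts(table)
    assert "canonical" not in contrasts.index
    assert len(contrasts) == 5
    # strongly divergent decline (limbic susceptible +3.9 vs canonical +0.8)
    assert contrasts.loc["limbic_susceptible", "significant"]


def test_single_visit_data_refused():
    cfg = default_config(n_participants=40, seed=5)
    cfg.visit_schedule = (0.0,)
    *_, participants, labels = generate_cohort(cfg)
    long = generate_longitudinal(cfg, labels)
    parts = participants.copy()
    parts["archetype"] = labels
    spec = ComparisonSpec("score", group_col="archetype", reference_group="canonical")
    with pytest.raises(ValueError, match="two distinct visit"):
        fit_longitudinal_lme(long, parts, spec, covariates=[])


def test_zero_slopes_low_noise_give_flat_trajectories():
    cfg = default_config(n_participants=120, seed=6)
    for a in cfg.archetypes:
        a.cognitive_slope = 0.0
    cfg.visit_noise_sd = 1e-6
    *_, participants, labels = generate_cohort(cfg)
    long = generate_longitudinal(cfg, labels)
    parts = participants.copy()
    parts["archetype"] = labels
    spec = ComparisonSpec("score", group_col="archetype", reference_group="canonical")
    table = fit_longitudinal_lme(long, parts, spec, covariates=[])
    assert np.abs(table["slope"]).max() < 1e-4
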