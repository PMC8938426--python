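import numpy as np
import pandas as pd
import pytest

from tnmismatch import (
    ArchetypeSpec,
    GeneratorConfig,
    compute_residual_matrix,
    default_config,
    generate_cohort,
    generate_longitudinal,
    generate_null_cohort,
)
from tnmismatch.simulate import _fill_roi_params, default_archetypes


def canonical_only_config(n=300, seed=0, noise=None):
    cfg = GeneratorConfig(n_participants=n, seed=seed,
                          archetypes=[ArchetypeSpec("canonical", 1.0, {}, 0.8)])
    _fill_roi_params(cfg)
    if noise is not None:
        cfg.noise_sd = np.full(104, noise)
    return cfg


def test_zero_noise_canonical_cohort_lies_on_the_regression_line():
    cfg = canonical_only_config(n=60, noise=0.0)
    tau, fdg, rois, _, _ = generate_cohort(cfg)
    expected = cfg.alpha + cfg.beta * np.log(tau.to_numpy())
    np.testing.assert_allclose(fdg.to_numpy(), expected, atol=1e-12)
    rset = compute_residual_matrix(tau, fdg, rois)
    assert np.abs(rset.residuals.to_numpy()).max() < 1e-8


def test_same_seed_reproduces_identical_tables():
    cfg1 = default_config(80, seed=5)
    cfg2 = default_config(80, seed=5)
    out1 = generate_cohort(cfg1)
    out2 = generate_cohort(cfg2)
    pd.testing.assert_frame_equal(out1[0], out2[0])
    pd.testing.assert_frame_equal(out1[1], out2[1])
    pd.testing.assert_frame_equal(out1[3], out2[3])
    pd.testing.assert_series_equal(out1[4], out2[4])
    long1 = generate_longitudinal(cfg1, out1[4])
    long2 = generate_longitudinal(cfg2, out2[4])
    pd.testing.assert_frame_equal(long1, long2)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="positive"):
        cfg = default_config(10)
        cfg.n_participants = 0
        generate_cohort(cfg)
    cfg = default_config(10)
    cfg.archetypes[0].mixing_weight += 0.2
    with pytest.raises(ValueError, match="sum to 1"):
        generate_cohort(cfg)
    cfg = default_config(10)
    cfg.visit_schedule = ()
    with pytest.raises(ValueError, match="visit schedule"):
        cfg.validate()
    cfg = default_config(10)
    cfg.visit_schedule = (0.5, 1.0)
    with pytest.raises(ValueError, match="start at 0"):
        cfg.validate()


def test_planted_proportions_match_mixing_weights():
    cfg = default_config(2000, seed=3)
    *_, labels = generate_cohort(cfg)
    counts = labels.value_counts(normalize=True)
    for a in cfg.archetypes:
        se = np.sqrt(a.mixing_weight * (1 - a.mixing_weight) / 2000)
        assert abs(counts[a.name] - a.mixing_weight) < 4 * se, a.name


def test_regression_recovers_planted_coupling_within_3_se():
    # canonical-only cohort so the per-ROI line is the data-generating line
    cfg = canonical_only_config(n=300, seed=9, noise=0.05)
    tau, fdg, rois, _, _ = generate_cohort(cfg)
    rset = compute_residual_matrix(tau, fdg, rois)
    for j in range(0, 104, 13):
        fit = rset.fits[j]
        x = np.log(tau.iloc[:, j].to_numpy())
        se_beta = 0.05 / (x.std(ddof=1) * np.sqrt(300))
        se_alpha = se_beta * np.sqrt(np.mean(x**2))
        assert abs(fit.beta - cfg.beta[j]) < 3 * se_beta
        assert abs(fit.alpha - cfg.alpha[j]) < 3 * se_alpha


def test_archetype_offsets_obey_direction_conventions():
    from tnmismatch.rois import generate_roi_metadata

    rois = generate_roi_metadata()
    for spec in default_archetypes():
        off = spec.regional_offsets(rois)
        if spec.name == "canonical":
            assert np.all(off == 0)
        elif "resilient" in spec.name:
            assert off.mean() >= 0
        else:
            assert off.mean() <= 0


def test_amyloid_measures_straddle_positivity_cutoffs():
    cfg = default_config(600, seed=2)
    _, _, _, participants, _ = generate_cohort(cfg)
    fbp = participants[participants["amyloid_tracer"] == "florbetapir"]
    fbb = participants[participants["amyloid_tracer"] == "florbetaben"]
    csf = participants[participants["amyloid_tracer"] == "csf"]
    assert (fbp["amyloid_composite_suvr"] >= 1.11).any()
    assert (fbp["amyloid_composite_suvr"] < 1.11).any()
    assert (fbb["amyloid_composite_suvr"] >= 1.08).any()
    assert (fbb["amyloid_composite_suvr"] < 1.08).any()
    assert csf["amyloid_composite_suvr"].isna().all()
    assert (csf["csf_abeta42"] < 980).any() and (csf["csf_abeta42"] >= 980).any()


def test_longitudinal_zero_slope_zero_noise_is_constant():
    cfg = canonical_only_config(n=40, seed=1)
    cfg.archetypes[0].cognitive_slope = 0.0
    cfg.visit_noise_sd = 0.0
    *_, labels = generate_cohort(cfg)
    long = generate_longitudinal(cfg, labels)
    spread = long.groupby("participant_id")["score"].agg(lambda s: s.max() - s.min())
    assert np.all(spread.to_numpy() < 1e-9)


def test_longitudinal_rejects_mismatched_labels():
    cfg = default_config(20, seed=0)
    *_, labels = generate_cohort(cfg)
    with pytest.raises(ValueError, match="labels length"):
        generate_longitudinal(cfg, labels.iloc[:10])


def test_null_cohort_has_no_planted_structure():
    cfg = default_config(100, seed=4)
    tau1, fdg1, rois, parts1, glab1 = generate_null_cohort(cfg)
    tau2, fdg2, _, _, glab2 = generate_null_cohort(cfg)
    pd.testing.assert_frame_equal(fdg1, fdg2)
    pd.testing.assert_series_equal(glab1, glab2)
    # imaging follows the canonical line: residuals are pure noise,
    # uncorrelated with the random group labels
    rset = compute_residual_matrix(tau1, fdg1, rois)
    group_means = rset.residuals.groupby(glab1).mean().mean(axis=1)
    assert np.abs(group_means).max() < 0.02
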