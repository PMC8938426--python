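"""Synthetic cohort generator.

Produces participant x ROI tau-PET and FDG-PET SUVR tables with the
statistical structure the mismatch analysis assumes: per ROI *j*, metabolism
couples linearly to log tau burden,

    FDG_ij = alpha_j + beta_j * log(tau_ij) + offset_a(i)(j) + eps_ij,

with tau_ij log-normal (so log tau is Gaussian), eps_ij ~ N(0, noise_sd_j),
and an archetype-specific regional residual offset for participant i's
archetype a(i).  Six archetypes mirror the group taxonomy recovered by the
analysis: canonical (zero offsets), high/low cortical resilient (positive
offsets on neocortical ROIs), limbic resilient (positive offsets on limbic
ROIs), and cortical/limbic susceptible (negative offsets).  The generator
also draws demographic covariates, a bimodal amyloid composite straddling the
tracer positivity cutoffs, and longitudinal ADAS-Cog-like scores with
archetype-specific annual slopes.

All randomness flows from a single seed; identical configurations produce
identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .rois import RoiMeta, generate_roi_metadata, roi_groups, roi_metadata_frame

__all__ = [
    "ArchetypeSpec",
    "GeneratorConfig",
    "default_config",
    "generate_cohort",
    "generate_longitudinal",
    "generate_null_cohort",
    "write_cohort_csvs",
]

ARCHETYPE_NAMES = (
    "canonical",
    "high_cortical_resilient",
    "low_cortical_resilient",
    "limbic_resilient",
    "cortical_susceptible",
    "limbic_susceptible",
)


@dataclass
class ArchetypeSpec:
    """One planted participant archetype.

    ``regional_offset_spec`` maps a region-group name (see
    :func:`tnmismatch.rois.roi_groups`: ``limbic``, ``cortical``,
    ``anterior_cortical``, ``posterior_cortical``, ``temporal_cortical``) or
    an individual region name to a constant FDG-SUVR residual offset applied
    to every matching ROI (later entries override earlier ones);
    ``marker_shift`` adds targeted regional offsets that emulate copathology
    imaging signatures (``cingulate_island`` spares posterior cingulate,
    ``mtl_asymmetry`` depresses left MTL, ``i_mtl_fso`` depresses frontal
    supraorbital cortex).
    """

    name: str
    mixing_weight: float
    regional_offset_spec: dict = field(default_factory=dict)
    cognitive_slope: float = 0.0  # outcome points / year
    marker_shift: dict = field(default_factory=dict)

    def regional_offsets(self, rois: list[RoiMeta]) -> np.ndarray:
        """Resolve per-ROI offsets (FDG SUVR units) for this archetype."""
        groups = roi_groups()
        by_region: dict[str, float] = {}
        for key, value in self.regional_offset_spec.items():
            names = groups.get(key, {key})
            for n in names:
                by_region[n] = float(value)
        off = np.array([by_region.get(r.name, 0.0) for r in rois])
        for marker, value in self.marker_shift.items():
            if marker == "cingulate_island":
                sel = ["posterior_cingulate" in r.composite_tags for r in rois]
                off[np.array(sel)] += value
            elif marker == "mtl_asymmetry":
                sel = ["mtl" in r.composite_tags and r.hemisphere == "left" for r in rois]
                off[np.array(sel)] -= value
            elif marker == "i_mtl_fso":
                sel = ["fso" in r.composite_tags for r in rois]
                off[np.array(sel)] -= value
            else:
                raise ValueError(f"unknown marker_shift key: {marker!r}")
        return off


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort."""

    n_participants: int = 300
    seed: int = 0
    roi_preset: str = "adni104"
    # per-ROI coupling FDG = alpha + beta * log(tau); arrays of length n_rois
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    noise_sd: np.ndarray | None = None
    # log tau ~ Normal(tau_log_mu, tau_log_sigma) per ROI
    tau_log_mu: np.ndarray | None = None
    tau_log_sigma: np.ndarray | None = None
    archetypes: list[ArchetypeSpec] = field(default_factory=list)
    visit_schedule: tuple = (0.0, 0.5, 1.0, 1.5, 2.0)
    # covariates
    age_mean: float = 74.0
    age_sd: float = 8.0
    education_mean: float = 16.0
    education_sd: float = 2.6
    p_female: float = 0.5
    # amyloid: mixture of A- and A+ components per tracer
    p_amyloid_positive: float = 0.6
    tracer_probs: dict = field(
        default_factory=lambda: {"florbetapir": 0.80, "florbetaben": 0.15, "csf": 0.05}
    )
    # longitudinal outcome (ADAS-Cog-like; higher = worse)
    baseline_mean: float = 16.0
    baseline_sd: float = 6.0
    visit_noise_sd: float = 1.2
    outcome_name: str = "ADAS"

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not self.archetypes:
            raise ValueError("at least one archetype required")
        w = np.array([a.mixing_weight for a in self.archetypes])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("archetype mixing weights must be nonnegative and sum to 1")
        t = np.asarray(self.visit_schedule, dtype=float)
        if t.size == 0:
            raise ValueError("visit schedule empty")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0) or np.any(t < 0):
            raise ValueError("visit times must start at 0 and strictly increase")
        if self.noise_sd is not None and np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be nonnegative")


# Default archetype geometry.  Offsets are in FDG-SUVR units, magnitudes in
# the 0.15-0.20 band, and each archetype occupies a distinct regional
# support: the high cortical resilient pattern covers anterior neocortex,
# the low cortical pattern posterior neocortex (hence the smaller
# cortex-wide mean), the limbic patterns limbic/medial-temporal ROIs (the
# susceptible one extending posteriorly), with positive and negative
# patterns weighted so each ROI's offset mixture is near zero mean and the
# canonical group sits on the regression line.  This regional patterning,
# rather than a uniform class-wide shift, is what makes the six groups
# mutually distinguishable rather than points along one residual axis.
# Mixing weights follow the relative group sizes the taxonomy describes
# (canonical largest, limbic resilient rarest).  Cognitive slopes in
# ADAS-Cog points/year: canonical +0.8, resilient -0.07/+0.6/+0.6,
# cortical susceptible +2.4, limbic susceptible +3.9.
def default_archetypes() -> list[ArchetypeSpec]:
    return [
        ArchetypeSpec("canonical", 0.28, {}, 0.8),
        ArchetypeSpec("high_cortical_resilient", 0.21,
                      {"anterior_cortical": 0.20}, -0.07),
        ArchetypeSpec("low_cortical_resilient", 0.17,
                      {"posterior_cortical": 0.15}, 0.6),
        ArchetypeSpec("limbic_resilient", 0.08,
                      {"limbic": 0.20, "temporal_cortical": 0.15}, 0.6),
        ArchetypeSpec(
            "cortical_susceptible", 0.16, {"anterior_cortical": -0.18}, 2.4,
            marker_shift={"cingulate_island": 0.08},
        ),
        ArchetypeSpec(
            "limbic_susceptible", 0.10,
            {"limbic": -0.15, "posterior_cortical": -0.20}, 3.9,
            marker_shift={"mtl_asymmetry": 0.06, "i_mtl_fso": 0.08},
        ),
    ]


def default_config(n_participants: int = 300, seed: int = 0) -> GeneratorConfig:
    """Default six-archetype study configuration."""
    cfg = GeneratorConfig(n_participants=n_participants, seed=seed,
                          archetypes=default_archetypes())
    _fill_roi_params(cfg)
    return cfg


def _fill_roi_params(cfg: GeneratorConfig) -> list[RoiMeta]:
    """Populate per-ROI coupling arrays with deterministic defaults."""
    rois = generate_roi_metadata(cfg.roi_preset)
    p = len(rois)
    if cfg.alpha is None:
        cfg.alpha = np.linspace(1.15, 1.45, p)
    if cfg.beta is None:
        cfg.beta = np.linspace(-0.55, -0.25, p)
    if cfg.noise_sd is None:
        # measurement noise kept small relative to the planted archetype
        # heterogeneity, which dominates the total residual SD (~0.1)
        cfg.noise_sd = np.full(p, 0.015)
    if cfg.tau_log_mu is None:
        # limbic/MTL regions accumulate tau earlier -> higher typical SUVR
        cfg.tau_log_mu = np.array(
            [np.log(1.45) if r.region_class == "limbic" else np.log(1.25) for r in rois]
        )
    if cfg.tau_log_sigma is None:
        cfg.tau_log_sigma = np.full(p, 0.18)
    for name in ("alpha", "beta", "noise_sd", "tau_log_mu", "tau_log_sigma"):
        arr = np.asarray(getattr(cfg, name), dtype=float)
        if arr.shape == ():
            arr = np.full(p, float(arr))
        if arr.shape != (p,):
            raise ValueError(f"{name} must have one entry per ROI ({p})")
        setattr(cfg, name, arr)
    return rois


def generate_cohort(cfg: GeneratorConfig):
    """Generate imaging tables, participant covariates and planted labels.

    Returns
    -------
    (tau, fdg, roi_meta, participants, labels)
        ``tau``/``fdg`` are participant x ROI DataFrames indexed by
        participant_id; ``roi_meta`` the list of :class:`RoiMeta`;
        ``participants`` the covariate table; ``labels`` a Series of planted
        archetype names.
    """
    cfg.validate()
    rois = _fill_roi_params(cfg)
    n, p = cfg.n_participants, len(rois)
    rng = np.random.default_rng(cfg.seed)

    weights = np.array([a.mixing_weight for a in cfg.archetypes])
    arch_idx = rng.choice(len(cfg.archetypes), size=n, p=weights)
    offsets = np.stack([a.regional_offsets(rois) for a in cfg.archetypes])  # A x p

    log_tau = rng.normal(cfg.tau_log_mu, cfg.tau_log_sigma, size=(n, p))
    tau = np.exp(log_tau)
    eps = rng.normal(0.0, 1.0, size=(n, p)) * cfg.noise_sd
    fdg = cfg.alpha + cfg.beta * log_tau + offsets[arch_idx] + eps
    # SUVRs are strictly positive by construction of the defaults; guard anyway
    fdg = np.maximum(fdg, 0.05)

    ids = [f"P{i:04d}" for i in range(n)]
    roi_ids = [r.roi_id for r in rois]
    tau_df = pd.DataFrame(tau, index=pd.Index(ids, name="participant_id"), columns=roi_ids)
    fdg_df = pd.DataFrame(fdg, index=tau_df.index, columns=roi_ids)
    labels = pd.Series([cfg.archetypes[k].name for k in arch_idx],
                       index=tau_df.index, name="archetype")

    participants = _draw_covariates(cfg, rng, ids)
    return tau_df, fdg_df, rois, participants, labels


def _draw_covariates(cfg: GeneratorConfig, rng: np.random.Generator,
                     ids: list[str]) -> pd.DataFrame:
    n = len(ids)
    sex = np.where(rng.random(n) < cfg.p_female, "F", "M")
    age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    edu = np.clip(rng.normal(cfg.education_mean, cfg.education_sd, n), 6, 24)
    dx = rng.choice(["CN", "MCI", "AD"], size=n, p=[0.3, 0.45, 0.25])

    tracers = list(cfg.tracer_probs)
    tracer = rng.choice(tracers, size=n, p=list(cfg.tracer_probs.values()))
    apos = rng.random(n) < cfg.p_amyloid_positive
    # bimodal composites straddling the 1.11 (florbetapir) / 1.08 (florbetaben)
    # cutoffs; CSF-only participants get an Abeta42 value around the 980 pg/ml
    # threshold instead.
    suvr = np.where(apos, rng.normal(1.35, 0.12, n), rng.normal(0.96, 0.07, n))
    fbb = tracer == "florbetaben"
    suvr = np.where(fbb & apos, rng.normal(1.30, 0.11, n),
                    np.where(fbb & ~apos, rng.normal(0.93, 0.06, n), suvr))
    csf = np.where(apos, rng.normal(700.0, 120.0, n), rng.normal(1400.0, 250.0, n))
    is_csf = tracer == "csf"
    return pd.DataFrame(
        {
            "participant_id": ids,
            "sex": sex,
            "age": np.round(age, 1),
            "education": np.round(edu, 1),
            "diagnosis": dx,
            "amyloid_tracer": tracer,
            "amyloid_composite_suvr": np.where(is_csf, np.nan, np.round(suvr, 4)),
            "csf_abeta42": np.round(np.maximum(csf, 200.0), 1),
        }
    ).set_index("participant_id")


def generate_longitudinal(cfg: GeneratorConfig, labels: pd.Series) -> pd.DataFrame:
    """Repeated cognitive scores with archetype-specific annual slopes.

    score_it = baseline_i + slope_a(i) * t + e_it, with the participant
    random intercept baseline_i ~ N(baseline_mean, baseline_sd^2) and visit
    noise e_it ~ N(0, visit_noise_sd^2).  Long format: one row per
    participant-visit.
    """
    cfg.validate()
    if len(labels) != cfg.n_participants:
        raise ValueError("labels length must equal n_participants")
    times = np.asarray(cfg.visit_schedule, dtype=float)
    slope_by_name = {a.name: a.cognitive_slope for a in cfg.archetypes}
    # independent stream so imaging tables are unchanged by longitudinal draws
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    n = len(labels)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n)
    slopes = labels.map(slope_by_name).to_numpy(dtype=float)
    noise = rng.normal(0.0, cfg.visit_noise_sd, size=(n, times.size))
    scores = baseline[:, None] + slopes[:, None] * times[None, :] + noise
    out = pd.DataFrame(
        {
            "participant_id": np.repeat(labels.index.to_numpy(), times.size),
            "visit_time_years": np.tile(times, n),
            "outcome_name": cfg.outcome_name,
            "score": np.round(scores.ravel(), 4),
        }
    )
    return out


def generate_null_cohort(cfg: GeneratorConfig, n_groups: int = 6):
    """Cohort with no true group structure.

    Imaging follows the canonical coupling only (all offsets zero) and group
    labels are assigned uniformly at random, so no outcome differs between
    groups in expectation.  Used for type-I-error calibration of the group
    comparison statistics.
    """
    null_cfg = GeneratorConfig(**{**asdict_shallow(cfg), "archetypes": [
        ArchetypeSpec("canonical", 1.0, {}, cfg.archetypes[0].cognitive_slope
                      if cfg.archetypes else 0.0)
    ]})
    tau, fdg, rois, participants, _ = generate_cohort(null_cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    labels = pd.Series(rng.integers(0, n_groups, len(participants)).astype(str),
                       index=participants.index, name="group")
    return tau, fdg, rois, participants, labels


def asdict_shallow(cfg: GeneratorConfig) -> dict:
    d = dict(cfg.__dict__)
    return d


# ---------------------------------------------------------------------------
# configuration and table round-trips

def config_to_yaml(cfg: GeneratorConfig, path) -> None:
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = [float(x) for x in v]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> GeneratorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["archetypes"] = [ArchetypeSpec(**a) for a in d.get("archetypes", [])]
    for k in ("alpha", "beta", "noise_sd", "tau_log_mu", "tau_log_sigma"):
        if d.get(k) is not None:
            d[k] = np.asarray(d[k], dtype=float)
    if "visit_schedule" in d:
        d["visit_schedule"] = tuple(d["visit_schedule"])
    return GeneratorConfig(**d)


def write_cohort_csvs(outdir, tau, fdg, rois, participants, labels=None,
                      longitudinal=None) -> None:
    """Write the standard CSV bundle (tau/fdg wide, metadata, covariates)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tau.to_csv(outdir / "tau_suvr.csv")
    fdg.to_csv(outdir / "fdg_suvr.csv")
    roi_metadata_frame(rois).to_csv(outdir / "roi_metadata.csv", index=False)
    participants.to_csv(outdir / "participants.csv")
    if labels is not None:
        labels.to_frame().to_csv(outdir / "truth_labels.csv")
    if longitudinal is not None:
        longitudinal.to_csv(outdir / "longitudinal.csv", index=False)
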