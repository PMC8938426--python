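"""Group-comparison statistics for mismatch clusters.

Cross-sectional outcomes are compared across clusters with covariate-adjusted
likelihood-ratio tests (full linear model ``outcome ~ group + covariates``
vs. reduced ``outcome ~ covariates``, both by maximum likelihood; the
statistic is chi-squared with #groups - 1 degrees of freedom).  Pairwise
comparisons against the reference (canonical) group are refit on the
two-group subset and Benjamini-Hochberg adjusted at FDR 0.05.  Categorical
frequencies use Pearson chi-squared without continuity correction.

Longitudinal trajectories are fit with a random-intercept linear mixed model
(maximum likelihood): fixed effects are baseline score, time from scan,
cluster, cluster x time, plus covariates.  Each cluster's annual slope is
the time coefficient plus its cluster x time interaction (zero for the
reference cluster by coding); between-group decline differences are judged
by the interaction coefficients, BH-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonSpec",
    "benjamini_hochberg",
    "lrt_group_comparison",
    "pairwise_vs_reference",
    "chi_square_frequency",
    "fit_longitudinal_lme",
    "slope_contrasts",
]

DEFAULT_COVARIATES = ["sex", "age", "education", "a_status", "it_tau_suvr"]


@dataclass
class ComparisonSpec:
    """What to compare: outcome column, covariates, grouping, FDR level."""

    outcome: str
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    group_col: str = "archetype"
    reference_group: str = "canonical"
    fdr: float = 0.05

    def validate(self, data: pd.DataFrame) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        missing = [c for c in [self.outcome, self.group_col, *self.covariates]
                   if c not in data.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing}")
        if self.reference_group not in set(data[self.group_col]):
            raise ValueError(f"reference group {self.reference_group!r} not present")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _design(data: pd.DataFrame, columns: list) -> pd.DataFrame:
    """Numeric design block: passthrough numerics, dummy-coded categoricals."""
    parts = []
    for col in columns:
        s = data[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float).to_frame(col))
        else:
            d = pd.get_dummies(s.astype(str), prefix=col, drop_first=True, dtype=float)
            parts.append(d)
    if not parts:
        return pd.DataFrame(index=data.index)
    return pd.concat(parts, axis=1)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns incrementally
        bad = []
        kept = np.ones((len(X), 1))
        for j, col in enumerate(X.columns):
            cand = np.column_stack([kept, X.iloc[:, j].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(col)
            else:
                kept = cand
        raise ValueError(f"collinear covariates: {bad}")


def _drop_small_groups(data: pd.DataFrame, group_col: str, min_size: int = 2) -> pd.DataFrame:
    sizes = data[group_col].value_counts()
    small = sizes[sizes < min_size].index.tolist()
    if small:
        warnings.warn(f"excluding groups with < {min_size} members: {small}")
        data = data[~data[group_col].isin(small)]
    return data


def lrt_group_comparison(data: pd.DataFrame, spec: ComparisonSpec):
    """Omnibus covariate-adjusted likelihood-ratio test of a group effect.

    Returns ``(statistic, df, p)``.
    """
    spec.validate(data)
    cols = [spec.outcome, spec.group_col, *spec.covariates]
    d = data[cols].dropna()
    d = _drop_small_groups(d, spec.group_col)
    groups = sorted(d[spec.group_col].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups with >= 2 members")
    y = d[spec.outcome].astype(float).to_numpy()
    X_cov = _design(d, spec.covariates)
    _check_full_rank(X_cov)
    X_full = pd.concat([X_cov, _design(d, [spec.group_col])], axis=1)
    full = sm.OLS(y, sm.add_constant(X_full.to_numpy(dtype=float))).fit()
    reduced = sm.OLS(y, sm.add_constant(X_cov.to_numpy(dtype=float)) if len(X_cov.columns)
                     else np.ones((len(d), 1))).fit()
    stat = 2.0 * (full.llf - reduced.llf)
    df = len(groups) - 1
    p = float(sps.chi2.sf(max(stat, 0.0), df))
    return float(max(stat, 0.0)), int(df), p


def pairwise_vs_reference(data: pd.DataFrame, spec: ComparisonSpec) -> pd.DataFrame:
    """Each non-reference group vs. the reference, BH-adjusted.

    Each pairwise LRT is refit on the two-group subset.  Returns a table
    (group, statistic, df, p_raw, p_adjusted, significant).
    """
    spec.validate(data)
    groups = sorted(g for g in data[spec.group_col].astype(str).unique()
                    if g != spec.reference_group)
    rows = []
    for g in groups:
        sub = data[data[spec.group_col].astype(str).isin([spec.reference_group, g])]
        stat, df, p = lrt_group_comparison(sub, spec)
        rows.append({"group": g, "statistic": stat, "df": df, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = benjamini_hochberg(out["p_raw"].to_numpy())
    out["significant"] = out["p_adjusted"] <= spec.fdr
    return out


def chi_square_frequency(counts) -> tuple[float, int, float]:
    """Pearson chi-squared test on an r x c contingency table (no Yates)."""
    table = np.asarray(counts, dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has an all-zero margin")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def fit_longitudinal_lme(longitudinal: pd.DataFrame, participants: pd.DataFrame,
                         spec: ComparisonSpec,
                         covariates: list | None = None) -> pd.DataFrame:
    """Random-intercept mixed model of cognitive change; per-cluster slopes.

    ``longitudinal`` is long-format (participant_id, visit_time_years,
    score); ``participants`` carries the cluster labels (``spec.group_col``)
    and covariates.  The score at time 0 enters as the baseline covariate and
    follow-up visits as outcomes.  Returns a slope table indexed by cluster:
    slope (units/year), slope_se, interaction coefficient/SE, raw and
    BH-adjusted interaction p-values.
    """
    if covariates is None:
        covariates = [c for c in ("sex", "age", "education", "a_status")
                      if c in participants.columns]
    long = longitudinal.copy()
    if long["visit_time_years"].nunique() < 2:
        raise ValueError("longitudinal fit needs at least two distinct visit times")
    base = (long[long["visit_time_years"] == long["visit_time_years"].min()]
            .set_index("participant_id")["score"].rename("baseline_score"))
    follow = long[long["visit_time_years"] > long["visit_time_years"].min()]
    if follow.empty:
        raise ValueError("no follow-up visits after baseline")
    d = follow.merge(base, left_on="participant_id", right_index=True)
    d = d.merge(participants[[spec.group_col, *covariates]],
                left_on="participant_id", right_index=True).dropna(
        subset=["score", "baseline_score", spec.group_col])

    ref = spec.reference_group
    clusters = sorted(d[spec.group_col].astype(str).unique())
    if ref not in clusters:
        raise ValueError(f"reference cluster {ref!r} absent")
    others = [c for c in clusters if c != ref]

    X = pd.DataFrame(index=d.index)
    X["baseline_score"] = d["baseline_score"].astype(float)
    X["time"] = d["visit_time_years"].astype(float)
    for c in others:
        ind = (d[spec.group_col].astype(str) == c).astype(float)
        X[f"grp[{c}]"] = ind
        X[f"grp[{c}]:time"] = ind * X["time"]
    cov_block = _design(d, covariates)
    X = pd.concat([X, cov_block], axis=1)
    exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    names = ["const", *X.columns]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(d["score"].astype(float).to_numpy(), exog,
                           groups=d["participant_id"].to_numpy())
        fit = model.fit(reml=False)
    if not fit.converged:
        warnings.warn("mixed model did not converge; estimates may be unreliable")
    params = pd.Series(fit.fe_params, index=names)
    cov = pd.DataFrame(np.asarray(fit.cov_params())[: len(names), : len(names)],
                       index=names, columns=names)

    rows = []
    t = "time"
    rows.append({
        "cluster": ref,
        "slope": params[t],
        "slope_se": float(np.sqrt(cov.loc[t, t])),
        "interaction": 0.0,
        "interaction_se": np.nan,
        "p_raw": np.nan,
    })
    for c in others:
        it = f"grp[{c}]:time"
        slope = params[t] + params[it]
        var = cov.loc[t, t] + cov.loc[it, it] + 2.0 * cov.loc[t, it]
        z = params[it] / np.sqrt(cov.loc[it, it])
        rows.append({
            "cluster": c,
            "slope": slope,
            "slope_se": float(np.sqrt(max(var, 0.0))),
            "interaction": params[it],
            "interaction_se": float(np.sqrt(cov.loc[it, it])),
            "p_raw": float(2.0 * sps.norm.sf(abs(z))),
        })
    table = pd.DataFrame(rows).set_index("cluster")
    adj = benjamini_hochberg(table.loc[others, "p_raw"].to_numpy())
    table["p_adjusted"] = np.nan
    table.loc[others, "p_adjusted"] = adj
    return table


def slope_contrasts(table: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Pairwise decline-rate contrasts vs. the reference cluster.

    The reference row (zero interaction by coding) is excluded.
    """
    out = table[table["interaction_se"].notna()].copy()
    out = out[["interaction", "interaction_se", "p_raw", "p_adjusted"]]
    out["significant"] = out["p_adjusted"] <= fdr
    return out
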