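"""Subsampling stability validation of the mismatch clustering.

The reference solution (fit on the full cohort) is stress-tested by
re-running the entire procedure — robust regressions, discretization, Ward
clustering at the reference k — on random subsamples ("folds"), matching
each fold's clusters to the reference clusters by maximum shared membership,
and asking how often a participant's majority-vote fold identity agrees with
their reference identity.  The default protocol is 10 folds of 52% of the
cohort, mirroring a 150-of-289 subsampling design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cluster import ClusterSolution, ward_cluster
from .mismatch import compute_residual_matrix, discretize_residuals

__all__ = ["StabilityResult", "run_fold_validation", "match_clusters", "summarize_shifts"]

MIN_SUBSAMPLE = 10


@dataclass
class StabilityResult:
    n_folds: int
    subsample_size: int
    fold_labels: pd.DataFrame  # fold x participant, NaN where unsampled
    matched_labels: pd.DataFrame  # same, in reference-cluster indices
    majority_identity: pd.Series  # participant -> reference-cluster index
    match_fraction: float
    directional_shift_fraction: float
    n_never_sampled: int


def match_clusters(fold_labels: pd.Series, reference_labels: pd.Series) -> dict[int, int]:
    """Map fold-cluster indices to reference-cluster indices.

    Optimal one-to-one assignment maximizing total shared membership on the
    contingency table (Hungarian algorithm; ties resolved toward smaller
    indices by the deterministic solver).  With unequal cluster counts the
    assignment is rectangular and unmatched fold clusters map to -1.
    """
    common = fold_labels.index.intersection(reference_labels.index)
    f = fold_labels.loc[common]
    r = reference_labels.loc[common]
    table = pd.crosstab(f, r)
    rows, cols = linear_sum_assignment(-table.to_numpy())
    mapping = {int(table.index[i]): int(table.columns[j]) for i, j in zip(rows, cols)}
    for lab in table.index:
        mapping.setdefault(int(lab), -1)
    return mapping


def run_fold_validation(tau: pd.DataFrame, fdg: pd.DataFrame,
                        reference: ClusterSolution, n_folds: int = 10,
                        subsample_size: int | None = None, seed: int = 0,
                        threshold_sd: float = 0.6) -> StabilityResult:
    """Re-run the full pipeline on random subsamples and score agreement.

    Parameters
    ----------
    tau, fdg
        The full-cohort SUVR tables the reference solution was fit on.
    reference
        Full-cohort clustering; folds are cut at ``reference.k``.
    subsample_size
        Participants per fold, sampled without replacement.  Defaults to
        ``round(0.52 * n)``.
    """
    n = len(tau)
    if subsample_size is None:
        subsample_size = int(round(0.52 * n))
    if subsample_size < MIN_SUBSAMPLE:
        raise ValueError(f"subsample_size must be >= {MIN_SUBSAMPLE}")
    if subsample_size > n:
        raise ValueError("subsample_size exceeds cohort size")
    rng = np.random.default_rng(seed)

    fold_rows = []
    matched_rows = []
    for fold in range(n_folds):
        idx = np.sort(rng.choice(n, size=subsample_size, replace=False))
        sub_tau = tau.iloc[idx]
        sub_fdg = fdg.iloc[idx]
        rset = discretize_residuals(compute_residual_matrix(sub_tau, sub_fdg),
                                    threshold_sd=threshold_sd)
        sol = ward_cluster(rset.discretized, k=reference.k)
        mapping = match_clusters(sol.labels, reference.labels)
        fold_rows.append(sol.labels.reindex(tau.index))
        matched_rows.append(sol.labels.map(mapping).reindex(tau.index))

    fold_labels = pd.DataFrame(fold_rows, index=[f"fold{i}" for i in range(n_folds)])
    matched = pd.DataFrame(matched_rows, index=fold_labels.index)

    sampled = matched.notna().any(axis=0)
    majority = pd.Series(index=tau.index, dtype=float)
    for pid in tau.index[sampled]:
        votes = matched[pid].dropna().astype(int)
        counts = votes.value_counts()
        top = counts[counts == counts.max()].index
        if len(top) > 1 and int(reference.labels[pid]) in set(top):
            majority[pid] = int(reference.labels[pid])  # tie -> reference identity
        else:
            majority[pid] = int(sorted(top)[0])
    agree = majority[sampled] == reference.labels[sampled].astype(float)
    match_fraction = float(agree.mean())

    shift_frac = _directional_shift_fraction(reference, majority, sampled, agree)
    return StabilityResult(
        n_folds=n_folds,
        subsample_size=subsample_size,
        fold_labels=fold_labels,
        matched_labels=matched,
        majority_identity=majority,
        match_fraction=match_fraction,
        directional_shift_fraction=shift_frac,
        n_never_sampled=int((~sampled).sum()),
    )


def _direction(name: str) -> str:
    if "resilient" in name:
        return "resilient"
    if "susceptible" in name:
        return "susceptible"
    return "canonical"


def _directional_shift_fraction(reference, majority, sampled, agree) -> float:
    """Fraction of sampled participants whose identity shifted but stayed in
    the same residual direction (e.g. high -> low cortical resilient)."""
    if not reference.archetype_names:
        return float("nan")
    same_dir = 0
    for pid in majority.index[sampled]:
        if agree.get(pid, True):
            continue
        ref_name = reference.archetype_names.get(int(reference.labels[pid]), "")
        maj = int(majority[pid])
        maj_name = reference.archetype_names.get(maj, "") if maj >= 0 else ""
        if maj_name and _direction(ref_name) == _direction(maj_name):
            same_dir += 1
    return same_dir / int(sampled.sum())


def summarize_shifts(result: StabilityResult, reference: ClusterSolution) -> pd.DataFrame:
    """Per-participant stability report with directional shift classification."""
    names = reference.archetype_names
    rows = []
    sampled = result.matched_labels.notna().any(axis=0)
    for pid in result.majority_identity.index:
        if not sampled[pid]:
            continue
        ref_c = int(reference.labels[pid])
        maj_c = int(result.majority_identity[pid])
        ref_name = names.get(ref_c, str(ref_c))
        maj_name = names.get(maj_c, str(maj_c)) if maj_c >= 0 else "unmatched"
        match = ref_c == maj_c
        shift = (
            "none" if match
            else "same_direction" if _direction(ref_name) == _direction(maj_name)
            else "cross_direction"
        )
        rows.append(
            {
                "participant_id": pid,
                "reference_archetype": ref_name,
                "majority_archetype": maj_name,
                "n_folds_sampled": int(result.matched_labels[pid].notna().sum()),
                "match_flag": match,
                "shift": shift,
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")
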