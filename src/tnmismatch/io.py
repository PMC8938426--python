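"""CSV schemas and validated cohort loading.

Interchange format is plain UTF-8 CSV.  Wide imaging tables have one row per
participant (``participant_id`` index) and one column per ROI; the
longitudinal table is long format (participant_id, visit_time_years,
outcome_name, score).  Files written by the pipeline carry a ``# key=value``
comment header (including the run's config hash); readers skip ``#`` lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .rois import RoiMeta, rois_from_frame

__all__ = ["CohortValidationError", "read_cohort", "write_table"]


class CohortValidationError(ValueError):
    """Input files are inconsistent or violate the schema."""


def write_table(df: pd.DataFrame, path, meta: dict | None = None,
                index: bool = True) -> None:
    """Write a CSV with an optional ``# key=value`` comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=index)


def _read_csv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def read_cohort(tau_path, fdg_path, roi_path, participants_path,
                longitudinal_path=None):
    """Load and cross-validate the cohort CSV bundle.

    Returns ``(tau, fdg, rois, participants, longitudinal)``; the last is
    None when no longitudinal file is given.

    Raises
    ------
    CohortValidationError
        On participant-set mismatches between files, ROI mismatches, or
        nonpositive SUVR values (reported with row/column coordinates).
    """
    tau = _read_csv(tau_path, index_col="participant_id")
    fdg = _read_csv(fdg_path, index_col="participant_id")
    roi_frame = _read_csv(roi_path)
    participants = _read_csv(participants_path, index_col="participant_id")

    problems: list[str] = []
    only_tau = tau.index.difference(fdg.index)
    only_fdg = fdg.index.difference(tau.index)
    if len(only_tau) or len(only_fdg):
        problems.append(
            f"participants only in tau file: {list(only_tau[:5])}; "
            f"only in fdg file: {list(only_fdg[:5])}"
        )
    if set(tau.columns) != set(fdg.columns):
        problems.append("tau and fdg files cover different ROI sets")
    rois = rois_from_frame(roi_frame)
    roi_ids = [r.roi_id for r in rois]
    if set(roi_ids) != set(tau.columns):
        problems.append("ROI metadata does not match imaging columns")
    missing_cov = tau.index.difference(participants.index)
    if len(missing_cov):
        problems.append(f"participants without covariates: {list(missing_cov[:5])}")
    if problems:
        raise CohortValidationError("; ".join(problems))

    fdg = fdg.loc[tau.index, tau.columns]
    for name, table in (("tau", tau), ("fdg", fdg)):
        vals = table.to_numpy(dtype=float)
        bad = np.argwhere(~(vals > 0) & ~np.isnan(vals))
        if bad.size:
            i, j = bad[0]
            raise CohortValidationError(
                f"nonpositive {name} SUVR at participant "
                f"{table.index[i]!r}, ROI {table.columns[j]!r}"
            )
    participants = participants.loc[tau.index]

    longitudinal = None
    if longitudinal_path is not None:
        longitudinal = _read_csv(longitudinal_path)
        need = {"participant_id", "visit_time_years", "score"}
        if not need.issubset(longitudinal.columns):
            raise CohortValidationError(
                f"longitudinal file needs columns {sorted(need)}"
            )
    return tau, fdg, rois, participants, longitudinal
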