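"""Derived imaging markers of non-AD copathology and amyloid status.

Three FDG-PET measures with established copathology associations:

* **Cingulate island ratio (CIR)** — posterior cingulate FDG over the mean
  of precuneus and cuneus FDG; relative posterior-cingulate sparing is a
  marker of Lewy body disease.
* **I/MTL/FSO ratio** — inferior temporal FDG over the mean of the medial
  temporal (MTL) and frontal supraorbital (FSO) composites; higher values
  signify worse MTL hypometabolism, associated with TDP-43 pathology (LATE).
* **MTL asymmetry index** — |left - right| / (left + right) of the MTL
  composite, in [0, 1]; asymmetric hippocampal involvement is also
  LATE-associated.

Amyloid status (A+/A-) comes from tracer-specific composite SUVR cutoffs
(florbetapir >= 1.11, florbetaben >= 1.08) with a CSF Abeta42 < 980 pg/ml
fallback when no amyloid PET is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rois import RoiMeta

__all__ = [
    "cingulate_island_ratio",
    "i_mtl_fso_ratio",
    "asymmetry_index",
    "classify_a_status",
    "build_marker_panel",
]

FLORBETAPIR_CUTOFF = 1.11
FLORBETABEN_CUTOFF = 1.08
CSF_ABETA42_CUTOFF = 980.0


def _combine(values, how: str) -> float:
    if how == "mean":
        return float(np.mean(values))
    if how == "sum":
        return float(np.sum(values))
    raise ValueError(f"unknown denominator combination: {how!r}")


def cingulate_island_ratio(fdg_pcc: float, fdg_precuneus: float, fdg_cuneus: float,
                           denominator: str = "mean") -> float:
    """Posterior cingulate FDG relative to precuneus and cuneus."""
    if min(fdg_pcc, fdg_precuneus, fdg_cuneus) <= 0:
        raise ValueError("all SUVR inputs must be strictly positive")
    return fdg_pcc / _combine([fdg_precuneus, fdg_cuneus], denominator)


def i_mtl_fso_ratio(fdg_it: float, fdg_mtl: float, fdg_fso: float,
                    denominator: str = "mean") -> float:
    """Inferior temporal FDG relative to the MTL and FSO composites."""
    if min(fdg_it, fdg_mtl, fdg_fso) <= 0:
        raise ValueError("all SUVR inputs must be strictly positive")
    return fdg_it / _combine([fdg_mtl, fdg_fso], denominator)


def asymmetry_index(left: float, right: float) -> float:
    """|left - right| / (left + right); in [0, 1], 0 iff symmetric."""
    if left < 0 or right < 0:
        raise ValueError("inputs must be nonnegative")
    total = left + right
    if total == 0:
        raise ValueError("asymmetry undefined when both sides are zero")
    return abs(left - right) / total


def classify_a_status(tracer: str, composite_suvr: float | None = None,
                      csf_abeta42: float | None = None) -> tuple[str, str]:
    """Amyloid positivity from PET composite or CSF fallback.

    Returns ``(status, source)`` with status in {"A+", "A-"}.  PET cutoffs
    are inclusive (>=); the CSF rule is strict (< 980 pg/ml).  CSF is used
    only when no PET composite is available.
    """
    has_pet = composite_suvr is not None and np.isfinite(composite_suvr)
    if has_pet:
        if tracer == "florbetapir":
            return ("A+" if composite_suvr >= FLORBETAPIR_CUTOFF else "A-", "florbetapir")
        if tracer == "florbetaben":
            return ("A+" if composite_suvr >= FLORBETABEN_CUTOFF else "A-", "florbetaben")
        raise ValueError(f"unknown amyloid tracer: {tracer!r}")
    if csf_abeta42 is not None and np.isfinite(csf_abeta42):
        return ("A+" if csf_abeta42 < CSF_ABETA42_CUTOFF else "A-", "csf")
    raise ValueError("no amyloid measure available")


def _composite(fdg_row: pd.Series, rois: list[RoiMeta], tag: str,
               hemisphere: str | None = None) -> float:
    ids = [
        r.roi_id
        for r in rois
        if tag in r.composite_tags and (hemisphere is None or r.hemisphere == hemisphere)
    ]
    if not ids:
        raise ValueError(f"no ROIs tagged {tag!r}")
    return float(fdg_row[ids].mean())


def build_marker_panel(fdg: pd.DataFrame, participants: pd.DataFrame,
                       rois: list[RoiMeta], denominator: str = "mean") -> pd.DataFrame:
    """Compute every marker for every participant.

    Bilateral regions are averaged across hemispheres before ratio
    computation; the MTL asymmetry uses the left/right MTL composites.
    ``participants`` must carry ``amyloid_tracer``, ``amyloid_composite_suvr``
    and ``csf_abeta42`` columns for A-status.
    """
    rows = []
    for pid, fdg_row in fdg.iterrows():
        pcc = _composite(fdg_row, rois, "posterior_cingulate")
        prec = _composite(fdg_row, rois, "precuneus")
        cun = _composite(fdg_row, rois, "cuneus")
        it = _composite(fdg_row, rois, "inferior_temporal")
        mtl = _composite(fdg_row, rois, "mtl")
        fso = _composite(fdg_row, rois, "fso")
        mtl_l = _composite(fdg_row, rois, "mtl", "left")
        mtl_r = _composite(fdg_row, rois, "mtl", "right")
        cov = participants.loc[pid]
        status, source = classify_a_status(
            cov["amyloid_tracer"],
            cov.get("amyloid_composite_suvr"),
            cov.get("csf_abeta42"),
        )
        rows.append(
            {
                "participant_id": pid,
                "cingulate_island_ratio": cingulate_island_ratio(pcc, prec, cun, denominator),
                "i_mtl_fso_ratio": i_mtl_fso_ratio(it, mtl, fso, denominator),
                "mtl_asymmetry_fdg": asymmetry_index(mtl_l, mtl_r),
                "amyloid_composite_suvr": cov.get("amyloid_composite_suvr"),
                "a_status": status,
                "a_status_source": source,
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")
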