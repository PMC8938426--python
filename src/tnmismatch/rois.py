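"""Region-of-interest universe for the mismatch analysis.

The default atlas preset (``adni104``) provides 104 gray-matter ROIs as 52
bilateral region pairs spanning neocortex, limbic/medial-temporal structures
and subcortical gray matter.  Each ROI carries a hemisphere, a coarse
``region_class`` (``limbic`` / ``cortical`` / ``other``) used for archetype
labeling, and a set of composite tags used by the derived imaging markers:

* ``amyloid_composite`` — the 8 regions entering the global amyloid SUVR
  composite (middle frontal, anterior cingulate, posterior cingulate,
  inferior parietal, precuneus, supramarginal, middle temporal, superior
  temporal cortex);
* ``mtl`` — medial temporal lobe constituents (entorhinal, parahippocampal,
  hippocampus, amygdala);
* ``fso`` — frontal supraorbital constituents;
* ``inferior_temporal`` / ``posterior_cingulate`` / ``precuneus`` /
  ``cuneus`` — single-region tags used by the metabolic ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["RoiMeta", "generate_roi_metadata", "roi_metadata_frame", "roi_groups"]


@dataclass(frozen=True)
class RoiMeta:
    """Metadata for one region of interest."""

    roi_id: str
    name: str
    hemisphere: str  # left | right | midline
    region_class: str  # limbic | cortical | other
    composite_tags: frozenset = field(default_factory=frozenset)


# (name, region_class, tags) for the 52 bilateral region pairs.
_MTL = {"mtl"}
_FSO = {"fso"}
_AMY = {"amyloid_composite"}

_ADNI104_REGIONS = [
    # limbic / medial temporal
    ("entorhinal_cortex", "limbic", _MTL),
    ("parahippocampal_gyrus", "limbic", _MTL),
    ("hippocampus", "limbic", _MTL),
    ("amygdala", "limbic", _MTL),
    ("temporal_pole", "limbic", set()),
    ("anterior_insula", "limbic", set()),
    ("posterior_insula", "limbic", set()),
    ("subcallosal_area", "limbic", set()),
    # subcortical gray
    ("caudate", "other", set()),
    ("putamen", "other", set()),
    ("thalamus", "other", set()),
    ("globus_pallidus", "other", set()),
    ("nucleus_accumbens", "other", set()),
    ("ventral_diencephalon", "other", set()),
    # neocortex
    ("middle_frontal_gyrus", "cortical", _AMY),
    ("anterior_cingulate_gyrus", "cortical", _AMY),
    ("posterior_cingulate_gyrus", "cortical", _AMY | {"posterior_cingulate"}),
    ("inferior_parietal_lobule", "cortical", _AMY),
    ("precuneus", "cortical", _AMY | {"precuneus"}),
    ("supramarginal_gyrus", "cortical", _AMY),
    ("middle_temporal_gyrus", "cortical", _AMY),
    ("superior_temporal_gyrus", "cortical", _AMY),
    ("cuneus", "cortical", {"cuneus"}),
    ("inferior_temporal_gyrus", "cortical", {"inferior_temporal"}),
    ("gyrus_rectus", "cortical", _FSO),
    ("medial_orbital_gyrus", "cortical", _FSO),
    ("anterior_orbital_gyrus", "cortical", _FSO),
    ("posterior_orbital_gyrus", "cortical", _FSO),
    ("lateral_orbital_gyrus", "cortical", set()),
    ("superior_frontal_gyrus", "cortical", set()),
    ("superior_frontal_gyrus_medial", "cortical", set()),
    ("inferior_frontal_gyrus_opercular", "cortical", set()),
    ("inferior_frontal_gyrus_triangular", "cortical", set()),
    ("inferior_frontal_gyrus_orbital", "cortical", set()),
    ("precentral_gyrus", "cortical", set()),
    ("postcentral_gyrus", "cortical", set()),
    ("paracentral_lobule", "cortical", set()),
    ("superior_parietal_lobule", "cortical", set()),
    ("angular_gyrus", "cortical", set()),
    ("superior_occipital_gyrus", "cortical", set()),
    ("middle_occipital_gyrus", "cortical", set()),
    ("inferior_occipital_gyrus", "cortical", set()),
    ("occipital_pole", "cortical", set()),
    ("lingual_gyrus", "cortical", set()),
    ("fusiform_gyrus", "cortical", set()),
    ("calcarine_cortex", "cortical", set()),
    ("planum_temporale", "cortical", set()),
    ("transverse_temporal_gyrus", "cortical", set()),
    ("frontal_operculum", "cortical", set()),
    ("central_operculum", "cortical", set()),
    ("parietal_operculum", "cortical", set()),
    ("supplementary_motor_cortex", "cortical", set()),
]


# Named region groups used by the synthetic generator's archetype patterns.
_POSTERIOR_CORTICAL = {
    "posterior_cingulate_gyrus", "inferior_parietal_lobule", "precuneus",
    "supramarginal_gyrus", "cuneus", "superior_parietal_lobule", "angular_gyrus",
    "superior_occipital_gyrus", "middle_occipital_gyrus", "inferior_occipital_gyrus",
    "occipital_pole", "lingual_gyrus", "fusiform_gyrus", "calcarine_cortex",
    "paracentral_lobule", "postcentral_gyrus", "parietal_operculum",
}
_TEMPORAL_CORTICAL = {
    "middle_temporal_gyrus", "superior_temporal_gyrus", "inferior_temporal_gyrus",
    "fusiform_gyrus", "planum_temporale", "transverse_temporal_gyrus",
}


def roi_groups() -> dict[str, set]:
    """Region-name groups addressable in archetype offset specifications."""
    cortical = {n for n, cls, _ in _ADNI104_REGIONS if cls == "cortical"}
    return {
        "limbic": {n for n, cls, _ in _ADNI104_REGIONS if cls == "limbic"},
        "cortical": cortical,
        "other": {n for n, cls, _ in _ADNI104_REGIONS if cls == "other"},
        "posterior_cortical": _POSTERIOR_CORTICAL,
        "anterior_cortical": cortical - _POSTERIOR_CORTICAL,
        "temporal_cortical": _TEMPORAL_CORTICAL,
    }


def generate_roi_metadata(preset: str = "adni104") -> list[RoiMeta]:
    """Return the ROI universe for a named atlas preset.

    Parameters
    ----------
    preset
        ``"adni104"`` for the default 104-ROI bilateral gray-matter atlas.

    Raises
    ------
    ValueError
        If the preset is not recognized.
    """
    if preset != "adni104":
        raise ValueError(f"unknown ROI preset: {preset!r} (available: 'adni104')")
    rois: list[RoiMeta] = []
    for name, region_class, tags in _ADNI104_REGIONS:
        for hemi, suffix in (("left", "l"), ("right", "r")):
            rois.append(
                RoiMeta(
                    roi_id=f"{name}_{suffix}",
                    name=name,
                    hemisphere=hemi,
                    region_class=region_class,
                    composite_tags=frozenset(tags),
                )
            )
    assert len(rois) == 104
    return rois


def roi_metadata_frame(rois: list[RoiMeta]) -> pd.DataFrame:
    """Tabular view of ROI metadata (tags joined with ``;``)."""
    return pd.DataFrame(
        {
            "roi_id": [r.roi_id for r in rois],
            "name": [r.name for r in rois],
            "hemisphere": [r.hemisphere for r in rois],
            "region_class": [r.region_class for r in rois],
            "composite_tags": [";".join(sorted(r.composite_tags)) for r in rois],
        }
    )


def rois_from_frame(frame: pd.DataFrame) -> list[RoiMeta]:
    """Inverse of :func:`roi_metadata_frame`."""
    out = []
    for row in frame.itertuples(index=False):
        tags = frozenset(t for t in str(row.composite_tags).split(";") if t and t != "nan")
        out.append(
            RoiMeta(
                roi_id=row.roi_id,
                name=row.name,
                hemisphere=row.hemisphere,
                region_class=row.region_class,
                composite_tags=tags,
            )
        )
    return out
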