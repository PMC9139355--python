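"""Feature-table assembly over images, VOIs and filters.

Each (image, VOI) pair yields 107 features without filtering (14 shape +
18 first-order + 75 texture) and 93 more on the Laplacian-of-Gaussian
filtered image (shape excluded), i.e. 200 per image and VOI.  With both
VOIs a single image contributes 400 columns; the data-set combinations
follow the additive counting convention:

=============  ======================================  ========
data set       images                                  columns
=============  ======================================  ========
cMRI           CE-T1w, FLAIR                                800
advMRI         cMRI + ADC + CBV                            1600
phyMRI         µCBV, MVD, VSI, MTI, OEF, CMRO2, PO2        2800
cMRI+phyMRI                                                3600
advMRI+phyMRI                                              4400
=============  ======================================  ========

Column names are ``<source>_<voi>_<filter>_<family>_<feature>`` with
filter ``orig`` or ``log``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..constants import ANATOMICAL_BIN_WIDTH, ANATOMICAL_RANGE, DATASET_IMAGES, MAP_SPECS
from .firstorder import first_order_features
from .preprocess import DiscretizationSpec, discretize, log_filter
from .shape import shape_features
from .texture import texture_features

__all__ = ["extract_features", "extract_feature_table", "feature_count",
            "discretization_for"]


def discretization_for(image_name: str) -> DiscretizationSpec:
    """Table-driven discretization: quantitative maps use their
    physiological range and bin width, anatomical images the z-score
    range [−3, 3] with bin width 0.1."""
    if image_name in MAP_SPECS:
        spec = MAP_SPECS[image_name]
        return DiscretizationSpec(spec.vmin, spec.vmax, spec.bin_width)
    return DiscretizationSpec(*ANATOMICAL_RANGE, ANATOMICAL_BIN_WIDTH)


def feature_count(data_set: str, vois: str = "both", with_log: bool = True) -> int:
    """Expected number of feature columns for a data-set / VOI choice."""
    n_images = len(DATASET_IMAGES[data_set])
    n_vois = 2 if vois == "both" else 1
    per = 107 + (93 if with_log else 0)
    return n_images * n_vois * per


def extract_features(image: np.ndarray, mask: np.ndarray, spacing,
                     image_name: str, voi_name: str,
                     valid: np.ndarray | None = None,
                     with_log: bool = True, log_sigma_mm: float = 1.0,
                     spec: DiscretizationSpec | None = None,
                     shape_cache: dict | None = None) -> dict:
    """All features of one image within one VOI.

    ``valid`` restricts the intensity mask (e.g. after physiological
    thresholding) without affecting the shape features, which are
    geometric properties of the VOI itself.  The LoG-filtered image is
    re-discretized with the parent's bin count over the filtered value
    range inside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"empty VOI {voi_name!r} for image {image_name!r}")
    imask = mask & valid if valid is not None else mask
    if not imask.any():
        raise ValueError(
            f"no valid voxels in VOI {voi_name!r} for image {image_name!r}")
    if spec is None:
        spec = discretization_for(image_name)
    voxel_volume = float(np.prod(spacing))
    prefix = f"{image_name}_{voi_name}"
    out: dict[str, float] = {}

    # shape depends only on the VOI geometry; cache across images
    if shape_cache is not None and voi_name in shape_cache:
        shape_vals = shape_cache[voi_name]
    else:
        shape_vals = shape_features(mask, spacing)
        if shape_cache is not None:
            shape_cache[voi_name] = shape_vals
    for name, val in shape_vals.items():
        out[f"{prefix}_orig_shape_{name}"] = val

    levels, ng = discretize(image, spec, imask)
    for name, val in first_order_features(image, imask, levels,
                                          voxel_volume).items():
        out[f"{prefix}_orig_firstorder_{name}"] = val
    for name, val in texture_features(levels, ng).items():
        out[f"{prefix}_orig_{name}"] = val

    if with_log:
        filtered = log_filter(image, log_sigma_mm, spacing)
        fvals = filtered[imask]
        lo, hi = float(fvals.min()), float(fvals.max())
        if hi <= lo:
            hi = lo + 1.0
        fspec = DiscretizationSpec(lo, hi, (hi - lo) / ng)
        flevels, fng = discretize(filtered, fspec, imask)
        for name, val in first_order_features(filtered, imask, flevels,
                                              voxel_volume).items():
            out[f"{prefix}_log_firstorder_{name}"] = val
        for name, val in texture_features(flevels, fng).items():
            out[f"{prefix}_log_{name}"] = val
    return out


def extract_feature_table(cases: list[dict], data_set: str,
                          vois: str = "both", with_log: bool = True,
                          log_sigma_mm: float = 1.0) -> pd.DataFrame:
    """Cases × features table for one data-set / VOI combination.

    Each case is a dict with ``images`` (name → array), ``masks``
    (``tumor`` / ``edema`` → bool array), optional ``valid`` (name →
    bool array), ``spacing`` and ``label``.  Raises ``KeyError`` naming
    the first missing modality.  The label goes into column ``entity``.
    """
    if data_set not in DATASET_IMAGES:
        raise ValueError(f"unknown data set {data_set!r}")
    voi_names = ("tumor", "edema") if vois == "both" else (vois,)
    rows = []
    for case in cases:
        row: dict[str, float] = {}
        shape_cache: dict = {}
        for image_name in DATASET_IMAGES[data_set]:
            if image_name not in case["images"]:
                raise KeyError(f"case is missing modality {image_name!r}")
            image = case["images"][image_name]
            valid = case.get("valid", {}).get(image_name)
            for voi in voi_names:
                row.update(extract_features(
                    image, case["masks"][voi], case["spacing"], image_name,
                    voi, valid=valid, with_log=with_log,
                    log_sigma_mm=log_sigma_mm, shape_cache=shape_cache))
        row["entity"] = case["label"]
        rows.append(row)
    return pd.DataFrame(rows)
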