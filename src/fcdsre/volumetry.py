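"""Structure volumes from segmentation label maps, head-size normalization,
and the log transform.

Volumes are voxel counts scaled by the voxel volume taken from the absolute
determinant of the affine's 3x3 linear part, which is robust to oblique and
rotated acquisitions.  Head-size correction follows the cohort-mean-ICV
convention::

    normalized volume = raw volume * mean ICV of the cohort / subject ICV

so a subject with an exactly average head is unchanged, and the cohort mean of
normalized ICV equals the mean ICV identically.  Normalized lesion volumes are
log10-transformed before parametric group comparisons to correct their skew.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import nibabel as nib
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "mask_volume",
    "normalize_volume",
    "log10_volume",
    "thalamus_sides",
    "cohort_mean_icv",
    "load_label_map",
    "VolumeRecord",
    "ICVNormalizer",
    "THALAMUS_LABELS",
]

# default label ids for the thalamus under the common automatic whole-brain
# segmentation convention; configurable because tools differ
THALAMUS_LABELS = {"left": 10, "right": 49}


def load_label_map(path):
    """Load a NIfTI label map (.nii/.nii.gz)."""
    return nib.load(str(path))


def _label_data(image):
    data = np.asanyarray(image.dataobj)
    return np.rint(data).astype(np.int64), np.asarray(image.affine, dtype=float)


def voxel_volume_mm3(affine) -> float:
    """Volume of one voxel: |det| of the affine's 3x3 linear part."""
    det = float(np.linalg.det(np.asarray(affine, dtype=float)[:3, :3]))
    if det == 0.0:
        raise ValueError("non-invertible affine: voxel volume undefined")
    return abs(det)


def mask_volume(image, target_labels) -> float:
    """Volume (mm³) of all voxels whose label lies in ``target_labels``.

    ``image`` is a nibabel spatial image whose data are integer labels.
    Returns 0 with a logged warning when no voxel matches.
    """
    target = set(int(t) for t in target_labels)
    if not target:
        raise ValueError("target_labels must be nonempty")
    data, affine = _label_data(image)
    vox = voxel_volume_mm3(affine)
    count = int(np.isin(data, sorted(target)).sum())
    if count == 0:
        logger.warning("no voxels matched labels %s", sorted(target))
    return count * vox


def normalize_volume(raw: float, icv: float, mean_icv: float) -> float:
    """Head-size-corrected volume: raw * mean_icv / icv (all mm³, all > 0)."""
    raw, icv, mean_icv = float(raw), float(icv), float(mean_icv)
    if raw <= 0 or icv <= 0 or mean_icv <= 0:
        raise ValueError("volumes and ICVs must be positive")
    return raw * mean_icv / icv


def log10_volume(v) -> float:
    """Base-10 log of a positive volume (vectorized over arrays)."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("volume must be positive and finite")
    out = np.log10(v)
    return float(out) if out.ndim == 0 else out


def thalamus_sides(left_mm3: float, right_mm3: float, lesion_side: str):
    """Reorder (left, right) thalamic volumes to (ipsilateral, contralateral)
    relative to the lesion hemisphere."""
    if lesion_side not in ("left", "right"):
        raise ValueError(
            "lesion side missing or invalid: exclude patient from thalamic "
            f"analysis (got {lesion_side!r})")
    if lesion_side == "left":
        return float(left_mm3), float(right_mm3)
    return float(right_mm3), float(left_mm3)


def cohort_mean_icv(cohort, scope: str = "all") -> float:
    """Arithmetic mean ICV over the cohort.

    scope="all" uses every patient with a processed MRI (the default:
    every record carries an ICV); scope="measurable" restricts to patients
    with a delineable lesion.
    """
    if scope not in ("all", "measurable"):
        raise ValueError("scope must be 'all' or 'measurable'")
    recs = [r for r in cohort if scope == "all" or r.measurable]
    if not recs:
        raise ValueError("empty scope: no patients with an ICV")
    return float(np.mean([r.icv_mm3 for r in recs]))


@dataclass
class VolumeRecord:
    """One structure volume for one patient, in raw, normalized, and log10
    normalized form."""

    patient_id: str
    structure: str
    raw_volume_mm3: float
    icv_mm3: float
    normalized_volume_mm3: float
    log10_normalized: float

    @classmethod
    def compute(cls, patient_id, structure, raw, icv, mean_icv):
        norm = normalize_volume(raw, icv, mean_icv)
        return cls(patient_id, structure, float(raw), float(icv), norm,
                   log10_volume(norm))


class ICVNormalizer(BaseEstimator, TransformerMixin):
    """Head-size correction as a transformer.

    ``X`` has two columns: ``[structure volume, subject ICV]`` (both mm³).
    ``fit`` learns the cohort mean ICV from the ICV column (or uses
    ``mean_icv`` when given); ``transform`` returns the normalized volume
    ``raw * mean_icv_ / icv`` as a single column.

    Attributes
    ----------
    mean_icv_ : float
        Cohort mean intracranial volume in mm³.
    """

    def __init__(self, mean_icv: float | None = None):
        self.mean_icv = mean_icv

    def fit(self, X, y=None):
        X = check_array(X)
        if X.shape[1] != 2:
            raise ValueError("expected columns [volume_mm3, icv_mm3]")
        if np.any(X <= 0):
            raise ValueError("volumes and ICVs must be positive")
        self.mean_icv_ = (float(np.mean(X[:, 1])) if self.mean_icv is None
                          else float(self.mean_icv))
        self.n_features_in_ = 2
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_icv_")
        X = check_array(X)
        if X.shape[1] != 2:
            raise ValueError("expected columns [volume_mm3, icv_mm3]")
        if np.any(X <= 0):
            raise ValueError("volumes and ICVs must be positive")
        return (X[:, 0] * self.mean_icv_ / X[:, 1]).reshape(-1, 1)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["normalized_volume_mm3"], dtype=object)
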