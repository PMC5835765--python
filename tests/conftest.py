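import numpy as np
import pytest

from fcdsre.cohort import build_published_cohort, SMALL_LESION_THRESHOLD_MM3


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_published_cohort()


@pytest.fixture(scope="session")
def is_small():
    T = SMALL_LESION_THRESHOLD_MM3

    def pred(r):
        return r.measurable and r.lesion_volume_mm3 < T

    return pred


@pytest.fixture
def make_label_image():
    """Build an in-memory NIfTI label image from an array and affine."""
    import nibabel as nib

    def build(data, affine=None):
        data = np.asarray(data, dtype=np.int16)
        if affine is None:
            affine = np.eye(4)
        return nib.Nifti1Image(data, np.asarray(affine, dtype=float))

    return build
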