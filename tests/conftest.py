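import numpy as np
import pandas as pd
import pytest

from ezpet.atlas import LabelAtlas
from ezpet.image import Volume
from ezpet.phantom import PhantomSpec, make_control, make_template_and_atlas


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def template_and_atlas(default_spec):
    return make_template_and_atlas(default_spec)


@pytest.fixture(scope="session")
def controls(default_spec, template_and_atlas):
    template, _ = template_and_atlas
    return [make_control(default_spec, i, template) for i in range(default_spec.n_controls)]


def build_toy_atlas(shape=(24, 24, 24), spacing=(2.0, 2.0, 2.0)):
    """A small atlas: 10 cortical 3x3x3 blobs (L/R x MT,LT,F,P,O) + a core."""
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = -(np.array(shape) - 1) / 2.0 * np.array(spacing)
    labels = np.zeros(shape, dtype=np.int16)
    rows = []
    regions = ["MT", "LT", "F", "P", "O"]
    lab = 0
    for j, region in enumerate(regions):
        for side, i0 in (("L", 3), ("R", 17)):
            lab += 1
            j0 = 2 + 4 * j
            labels[i0 : i0 + 3, j0 : j0 + 3, 10:13] = lab
            rows.append({"id": lab, "name": f"{side}-{region}", "side": side, "sublobar": region, "cortical": True})
    labels[10:14, 10:14, 10:14] = 11
    rows.append({"id": 11, "name": "core", "side": "midline", "sublobar": "other", "cortical": False})
    return LabelAtlas(Volume(labels, aff), pd.DataFrame(rows))


@pytest.fixture()
def toy_atlas():
    return build_toy_atlas()


@pytest.fixture(scope="session")
def phantom_tmap(default_spec, template_and_atlas, controls):
    """A lesioned patient's smoothed, normalized t-map on the shared cohort."""
    import warnings

    from ezpet.phantom import make_patient
    from ezpet.preprocess import intensity_normalize_parabola, smooth_gaussian
    from ezpet.statmap import build_cohort, gray_matter_mask, tmap

    template, atlas = template_and_atlas
    mask = gray_matter_mask(atlas)
    norm = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for ctl in controls:
            norm.append(intensity_normalize_parabola(ctl, template, mask).apply(ctl))
        ref = template.with_data(np.mean([v.data for v in norm], axis=0))
        cohort = build_cohort([smooth_gaussian(v, 8.0) for v in norm])
        patient, truth, _ = make_patient(default_spec, 777, template, atlas)
        pn = intensity_normalize_parabola(patient, ref, mask).apply(patient)
    tm = tmap(smooth_gaussian(pn, 8.0), cohort, mask)
    return tm, atlas, truth
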