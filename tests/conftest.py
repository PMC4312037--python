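import dataclasses

import numpy as np
import pytest

from murine_dce_quant import ct_quant, phantom, pipeline


def infarct_wedge(target_fraction: float = 0.32,
                  dia=(2.0, 2.0, 3.3), wall=1.0, apical=0.75):
    span = phantom.azimuth_span_for_infarct_fraction(
        target_fraction, dia, wall, apical)
    return (-100.0, -100.0 + span, apical)


@pytest.fixture(scope="session")
def noisefree_spec():
    """Noise-free phantom with a ~32% infarct at the full study resolution."""
    return phantom.PhantomSpec.from_ef(0.36, infarct_wedge=infarct_wedge(),
                                       noise_sd_hu=0.0, seed=7)


@pytest.fixture(scope="session")
def noisefree_delayed(noisefree_spec):
    """Noise-free delayed-enhancement volume at the first acquisition time."""
    return phantom.build_heart_phantom(noisefree_spec, "diastole", 13.0)


@pytest.fixture(scope="session")
def noisy_spec():
    return phantom.PhantomSpec.from_ef(0.36, infarct_wedge=infarct_wedge(),
                                       noise_sd_hu=30.0, seed=11)


@pytest.fixture(scope="session")
def noisy_bloodpool_pair(noisy_spec):
    dia = phantom.build_heart_phantom(noisy_spec, "diastole", 5.0,
                                      washout=noisy_spec.washout_blood_pool)
    sys_ = phantom.build_heart_phantom(noisy_spec, "systole", 5.0,
                                       washout=noisy_spec.washout_blood_pool)
    return dia, sys_


def segment_blood_auto(vol, params: ct_quant.SegmentationParams | None = None):
    """Blood-pool segmentation with an automatically placed centre seed."""
    params = params or ct_quant.SegmentationParams()
    seed = pipeline.auto_blood_seed(vol, params.blood_hu_range)
    return ct_quant.segment_lv_blood(
        vol, dataclasses.replace(params, seed_points=(seed,)))


def true_infarct_pct(spec) -> float:
    mask = phantom._phantom_labels(spec, "diastole")
    ti = mask.count(phantom.INFARCT)
    tm = mask.count(phantom.MYOCARDIUM)
    return 100.0 * ti / (ti + tm)
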