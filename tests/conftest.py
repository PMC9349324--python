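import warnings

import numpy as np
import pytest

from octaquant.magnification import AnnulusSpec, EyeBiometry, annulus_mask, bennett_actual_scan_length, pixel_scale
from octaquant.synthetic import (
    CcParams,
    EyeRecord,
    FazParams,
    VesselFieldParams,
    generate_eye,
)

warnings.filterwarnings("ignore", category=FutureWarning)

NOMINAL_SCALE = 3.0 / 245  # mm per pixel of an emmetropic 3-mm scan


@pytest.fixture(scope="session")
def nominal_annulus():
    return annulus_mask((245, 245), AnnulusSpec(), NOMINAL_SCALE)


def make_record(axial_length=23.3, group="MS"):
    return EyeRecord(
        participant_id="T001", eye="OD", group=group, age=40.0, gender="female",
        iop_mmHg=16.0, axial_length_mm=axial_length, hypertension=0,
        signal_strength=9, duration_years=8.0, episodes=3, rnfl_um=90.0,
    )


def make_eye(seed=1, pd_scp=0.431, lv=0.0655, pd_dcp=0.392, faz_s=0.25,
             faz_d=1.23, irr_s=0.2, irr_d=0.25, fd=0.166, axial_length=23.3,
             n_large_vessels=4):
    """One synthetic eye at study-typical parameter values."""
    rec = make_record(axial_length)
    vf_s = VesselFieldParams(pd_scp, n_large_vessels=n_large_vessels,
                             lv_target_density=lv if n_large_vessels else None, seed=seed)
    vf_d = VesselFieldParams(pd_dcp, n_large_vessels=0, seed=seed + 1)
    return generate_eye(
        vf_s, vf_d,
        FazParams(faz_s, irr_s, seed=seed + 2),
        FazParams(faz_d, irr_d, seed=seed + 3),
        CcParams(fd, seed=seed + 4),
        rec,
    )


@pytest.fixture(scope="session")
def study_eye():
    """A single generated eye shared by read-only tests."""
    return make_eye(seed=11)
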