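import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("default")


@pytest.fixture
def toy_plate_files(tmp_path):
    """3-well plate (1 blank, 2 samples) with 5 time points, plus its map."""
    run = tmp_path / "plate.csv"
    run.write_text(
        "time_h,B1_od,B1_fluo,S1_od,S1_fluo,S2_od,S2_fluo\n"
        "0,0.04,50,0.09,50,0.09,50\n"
        "1,0.04,50,0.14,150,0.14,250\n"
        "2,0.04,50,0.24,350,0.24,650\n"
        "3,0.04,50,0.44,750,0.44,1450\n"
        "4,0.04,50,0.64,1550,0.64,3050\n")
    pmap = tmp_path / "map.csv"
    pmap.write_text(
        "well_id,role,inducer_nM,induction_time_h,dilution_factor,"
        "replicate_group\n"
        "B1,blank,,0,1,\n"
        "S1,sample,50,0,1,g1\n"
        "S2,sample,100,0,1,g1\n")
    return run, pmap


@pytest.fixture
def rfp_calibration():
    """Calibration matching the fluorescent variant's published line."""
    from mersense.calibration import (Calibration, HillFit,
                                      LinearCalibration, compute_lod)

    m, y0, sigma0 = 0.84, 3.1, 0.12
    linear = LinearCalibration(
        m=m, y0=y0, sigma0=sigma0, range_nM=(1.0, 1000.0),
        lod_nM=compute_lod(m, sigma0), n_points=8, r_squared=0.99)
    hill = HillFit(psi_min=150.0, psi_max=6000.0, K=305.0, h=1.6,
                   rss=0.0, converged=True)
    return Calibration(hill=hill, linear=linear)


@pytest.fixture
def blue_calibration():
    """Calibration matching the colorimetric variant's published line."""
    from mersense.calibration import (Calibration, HillFit,
                                      LinearCalibration, compute_lod)

    m, y0, sigma0 = 0.36, 3.2, 0.091
    linear = LinearCalibration(
        m=m, y0=y0, sigma0=sigma0, range_nM=(2.0, 125.0),
        lod_nM=compute_lod(m, sigma0), n_points=6, r_squared=0.99)
    hill = HillFit(psi_min=0.9088, psi_max=161.74, K=23.67, h=0.6986,
                   rss=0.0, converged=True)
    return Calibration(hill=hill, linear=linear)
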