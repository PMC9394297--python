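import pytest
from hypothesis import HealthCheck, settings

import isobolab as ib

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

FLAT_COUNTS = tuple((t, 5) for t in ib.study.STANDARD_GRID)


def make_timecourse(subject, arm, counts):
    return ib.TimeCourse(subject, arm, tuple(zip(ib.study.STANDARD_GRID, counts)))


@pytest.fixture
def tiny_study():
    """Control + one treated arm, 2 subjects each, full 12-bin grid."""
    control = ib.TreatmentArm("control", (), ib.ArmRole.VEHICLE_CONTROL, 2)
    ibu = ib.TreatmentArm(
        "IBU-40",
        (ib.DoseSpec("IBU", 40.0, ib.DoseUnit.MG_PER_KG, ib.Route.SYSTEMIC),),
        ib.ArmRole.MONOTHERAPY,
        2,
    )
    tcs = [
        make_timecourse("c1", "control", [30, 12, 4, 8, 14, 18, 20, 19, 16, 12, 8, 5]),
        make_timecourse("c2", "control", [28, 10, 5, 9, 13, 17, 21, 18, 15, 11, 9, 4]),
        make_timecourse("t1", "IBU-40", [29, 11, 4, 6, 10, 12, 14, 13, 11, 8, 6, 3]),
        make_timecourse("t2", "IBU-40", [31, 13, 5, 5, 9, 13, 13, 12, 10, 9, 5, 4]),
    ]
    return ib.study_from_records([control, ibu], tcs)


@pytest.fixture
def noise_off_config():
    """Deterministic generator (no frailty, no count noise)."""
    return ib.default_paper_config(dispersion=float("inf"), frailty_sd=0.0)
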