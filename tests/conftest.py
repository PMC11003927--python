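import numpy as np
import pytest
from hypothesis import settings

from molarage import (
    Cohort,
    CorrelationSet,
    JointParameters,
    ModelConfig,
    MolarClass,
    Participant,
    PerToothFit,
    Sex,
    SexStructure,
    ToothRecord,
    VarianceWeight,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def volumes_for_y(y: float) -> tuple[float, float, float]:
    """A consistent (hard, low, high) volume triple with total 1 ml."""
    soft = float(np.exp(min(y, -1e-9)))
    return 1.0 - soft, soft / 2.0, soft / 2.0


def single_tooth_cohort(tooth, ages, sexes, ys) -> Cohort:
    """Cohort with one record per participant, all on the same tooth."""
    participants, records = [], []
    for i, (a, s, y) in enumerate(zip(ages, sexes, ys)):
        pid = f"P{i:04d}"
        participants.append(Participant(pid, s, float(a)))
        hard, low, high = volumes_for_y(float(y))
        records.append(ToothRecord(pid, tooth, hard, low, high))
    return Cohort(participants, records)


def make_fit(
    tooth=46,
    structure=SexStructure.COMMON,
    weight=VarianceWeight.CONSTANT,
    beta0=-1.0,
    beta1=-0.08,
    beta2=0.0,
    beta3=0.0,
    sigma=0.2,
) -> PerToothFit:
    return PerToothFit(
        ModelConfig(tooth, structure, weight),
        beta0=beta0, beta1=beta1, beta2=beta2, beta3=beta3, sigma=sigma,
    )


def make_joint(fits_by_class, rho_12=0.0, rho_13=0.0, rho_23=0.0) -> JointParameters:
    tooth_by_class = {c: f.config.tooth for c, f in fits_by_class.items()}
    return JointParameters(
        tooth_by_class, dict(fits_by_class),
        CorrelationSet(rho_12, rho_13, rho_23),
    )


@pytest.fixture
def simple_cohort() -> Cohort:
    """Small two-sex cohort on tooth 46 with a clean negative age trend."""
    rng = np.random.default_rng(42)
    ages = rng.uniform(14, 24, size=40)
    sexes = [Sex.M if i % 2 else Sex.F for i in range(40)]
    ys = -1.2 - 0.07 * ages + rng.normal(0, 0.15, size=40)
    return single_tooth_cohort(46, ages, sexes, ys)
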