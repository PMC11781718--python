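import numpy as np
import pytest

from ossim import AgeSchedule, ParameterSet, default_parameters
from ossim.params import N_AGES


@pytest.fixture(scope="session")
def base_params() -> ParameterSet:
    """The calibrated synthetic base case (shared across the suite)."""
    return default_parameters(seed=0)


def make_params(
    bg=0.0,
    inc=0.0,
    ocd=0.0,
    hysterectomy=0.0,
    he_bso=0.0,
    sterilization=0.0,
    other_gyn=0.0,
    nongyn=0.0,
    **kwargs,
) -> ParameterSet:
    """Hand-built ParameterSet from constant-or-array schedules (defaults all
    zero), for exactly computable scenarios."""

    def sched(v):
        if np.isscalar(v):
            return AgeSchedule.constant(v)
        return AgeSchedule(np.asarray(v, dtype=float))

    p = ParameterSet(
        background_mortality=sched(bg),
        oc_incidence=sched(inc),
        oc_mortality_post_dx=sched(ocd),
        surgery={
            "hysterectomy": sched(hysterectomy),
            "he_bso": sched(he_bso),
            "sterilization": sched(sterilization),
            "other_gyn": sched(other_gyn),
            "nongyn": sched(nongyn),
        },
        sterilization_multiplier=kwargs.pop("sterilization_multiplier", 1.0),
        **kwargs,
    )
    return p.validate()


def age_indicator(age: int, value: float = 1.0) -> np.ndarray:
    """Schedule that is ``value`` at one age and zero elsewhere."""
    p = np.zeros(N_AGES)
    p[age - 20] = value
    return p
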