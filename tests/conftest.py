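"""Shared fixtures: deterministic synthetic subjects and simple cycles."""

import numpy as np
import pytest

from coawave.synthetic import CohortParams, generate_cohort
from coawave.waveforms import AorticCycle, BrachialBP


@pytest.fixture(scope="session")
def zero_noise_params():
    return CohortParams(n_patients=20, n_controls=20, seed=11, noise_sd_area=0.0, noise_sd_flow=0.0)


@pytest.fixture(scope="session")
def zero_noise_cohort(zero_noise_params):
    """40 noiseless subjects with ground truth (exact closed-loop recovery)."""
    records, truths, _ = generate_cohort(zero_noise_params)
    return records, truths


@pytest.fixture(scope="session")
def default_cohort():
    """Seeded study-sized cohort at generator-default noise."""
    records, truths, manifest = generate_cohort(CohortParams(seed=5))
    return records, truths, manifest


def simple_cycle(n=100, dt=0.0096, a_d=5.0, pulse=1.0, q_peak=400.0, ej_frac=0.36):
    """Smooth single-cycle waveform: raised-cosine area bump + sin^2 ejection.

    The default ejection fraction puts a sample exactly on the area peak, so
    A_s = a_d + pulse holds exactly (handy for closed-form checks).
    """
    t = np.arange(n) * dt
    t_ej = ej_frac * n * dt
    phase = np.clip(t / t_ej, 0.0, 1.0)
    area = a_d + pulse * np.sin(np.pi * phase) ** 2
    flow = q_peak * np.sin(np.pi * phase) ** 2
    return AorticCycle(time=t, area=area, flow=flow)


@pytest.fixture
def cycle():
    return simple_cycle()


@pytest.fixture
def bp():
    return BrachialBP(sbp=140.0, dbp=80.0, mbp=100.0)
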