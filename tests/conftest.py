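import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_movie():
    """Short rendered 100W50 movie with one sudden ejection at t=10 s."""
    from nucleoafm import synthetic as syn

    schedule = syn.planted_schedule([10.0])
    return syn.simulate_movie(
        spec=syn.TET_100W50, schedule=schedule, fps=1.0, n_frames=21,
        seed=11, shape=(100, 100),
        noise=syn.NoiseModel(height_sigma=0.1))


@pytest.fixture(scope="session")
def centered_nucleosome():
    """Noiseless tip-free nucleosome render on a 100x100 grid at 1.9 nm/px."""
    from nucleoafm import synthetic as syn

    state = syn.build_construct(syn.NUC_200W100)
    state.core_center = np.array([95.0, 95.0])  # pixel (50, 50)
    frame, mask = syn.render_frame(
        state, syn.TipModel(0.0), syn.NOISELESS, 1.9, (100, 100))
    return frame, mask, state
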