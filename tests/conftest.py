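import numpy as np
import pytest

from castress.eda import EDARecording, scr_kernel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(
    conductance: np.ndarray,
    fs: float = 4.0,
    temp: float = 33.0,
    start_time: float = 0.0,
) -> EDARecording:
    """A still, in-range recording around the given conductance trace."""
    n = len(conductance)
    return EDARecording(
        sampling_rate=fs,
        conductance=conductance,
        accel=np.tile([0.0, 0.0, 1.0], (n, 1)),
        temperature=np.full(n, temp),
        start_time=start_time,
    )


def inject_scr(conductance: np.ndarray, fs: float, t_onset: float, amplitude: float) -> None:
    """Add one canonical SCR kernel of the given amplitude, in place."""
    k = scr_kernel(fs)
    i = int(round(t_onset * fs))
    seg = conductance[i : i + len(k)]
    seg += amplitude * k[: len(seg)]


@pytest.fixture
def random_small_hmm(rng):
    """Factory for random small-state models (exhaustive-enumeration scale)."""
    from castress.stress_hmm import StressHMM

    def make(n_states: int, alpha_dirichlet: float = 1.0) -> StressHMM:
        pi = rng.dirichlet(np.full(n_states, alpha_dirichlet))
        T = rng.dirichlet(np.full(n_states, alpha_dirichlet), size=n_states)
        em = rng.dirichlet(np.full(3, alpha_dirichlet), size=(n_states, 8))
        return StressHMM(pi=pi, T=T, emissions=em)

    return make
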