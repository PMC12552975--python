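import numpy as np
import pytest

from i4dsim import (
    SignalTrace,
    SurrogateSpec,
    WaveformSpec,
    apply_surrogate,
    from_waveform,
    generate_waveform,
)


@pytest.fixture
def cos6_spec():
    return WaveformSpec("cos6", a_p2p_mm=15.0, t_cycle_s=3.0, duration_s=60.0)


@pytest.fixture
def cos6_wave(cos6_spec):
    return generate_waveform(cos6_spec)


@pytest.fixture
def cos6_trace(cos6_wave):
    return from_waveform(cos6_wave)


@pytest.fixture
def sin_wave():
    return generate_waveform(WaveformSpec("sinusoid", a_p2p_mm=10.0, t_cycle_s=4.0,
                                          duration_s=60.0))


def make_delayed_pair(wave, latency_s, noise_sd=0.0, seed=0):
    """Reference trace plus a copy measured through a delay + noise chain."""
    ref = from_waveform(wave)
    test = apply_surrogate(wave, SurrogateSpec(latency_s=latency_s, noise_sd_mm=noise_sd,
                                               seed=seed))
    return test, ref


def subsample_lag_ms(measured: SignalTrace, truth: SignalTrace,
                     lag_grid_ms=np.arange(-120, 120.5, 1.0), margin=500):
    """Independent sub-sample lag estimate: minimum-RMSE scan over a dense
    interpolated shift grid (brute-force oracle, no shared code path with
    align())."""
    t = truth.timestamps[margin:-margin]
    meas = np.interp(t, measured.timestamps, measured.amplitudes)
    best_lag, best_rmse = None, np.inf
    for lag_ms in lag_grid_ms:
        shifted = np.interp(t - lag_ms / 1000.0, truth.timestamps, truth.amplitudes)
        rmse = float(np.sqrt(np.mean((meas - shifted) ** 2)))
        if rmse < best_rmse:
            best_lag, best_rmse = float(lag_ms), rmse
    return best_lag, best_rmse
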