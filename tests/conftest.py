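import numpy as np
import pytest

import mstates as ms


@pytest.fixture(scope="session")
def montage24() -> ms.Montage:
    return ms.demo_montage(24)


@pytest.fixture(scope="session")
def templates4(montage24) -> ms.MicrostateMapSet:
    return ms.make_template_maps(montage24, 4, seed=11)


@pytest.fixture(scope="session")
def planted_recording(montage24, templates4):
    """20 s of 4-state EEG at SNR 10 with its ground-truth label sequence."""
    spec = ms.SimulationSpec(n_channels=24, duration_s=20.0, snr=10.0)
    rng = np.random.default_rng(42)
    seq = ms.simulate_state_sequence(spec, rng)
    rec = ms.simulate_eeg(templates4, seq, spec, montage24, rng)
    return rec, seq, spec


@pytest.fixture(scope="session")
def group_maps(templates4) -> ms.MicrostateMapSet:
    return ms.MicrostateMapSet(maps=templates4.maps,
                               channel_names=templates4.channel_names,
                               level="group")
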