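import numpy as np
import pytest

from locorhythm import ingest, synthetic as syn
from locorhythm.core import ChannelInfo, IntegratedNeurogram


def tone_envelope(freq=0.33, duration=170.0, fs=19.0, amp=1.0, offset=1.0,
                  mode="drug"):
    """Envelope container holding a raised sinusoid at a single frequency."""
    t = np.arange(int(duration * fs)) / fs
    x = offset + amp * np.sin(2 * np.pi * freq * t)
    epochs = {"pre": (0.0, 55.0), "light": (55.0, 115.0),
              "post": (115.0, duration)}
    return IntegratedNeurogram(env=x[None], fs=fs,
                               channels=[ChannelInfo("tone")],
                               epochs=epochs, corners=(200, 10, 5), mode=mode)


def envelope_from(x, fs=19.0, epochs=None, mode="drug", name="env"):
    return IntegratedNeurogram(
        env=np.atleast_2d(x), fs=fs, channels=[ChannelInfo(name)],
        epochs=epochs or {}, corners=(200, 10, 5), mode=mode)


@pytest.fixture(scope="session")
def wholecord_trial():
    """One simulated whole-cord trial and its integrated 19 Hz envelope."""
    design = syn.design_cohort("wholecord-arch", 4, seed=11, n_trials=1)[0]
    item = syn.simulate_experiment(design, seed=11)[0]
    rec, truth = item["recording"], item["truth"]
    trial = ingest.align_trials(rec, "drug")
    env19 = ingest.resample_envelope(ingest.integrate_neurogram(trial), 19.0)
    return {"design": design, "recording": rec, "truth": truth,
            "aligned": trial, "env19": env19}


@pytest.fixture(scope="session")
def hemicord_trial():
    """One simulated hemicord trial (10 s tonic onset) and its envelope."""
    design = syn.design_cohort("hemicord-arch", 4, seed=7, n_trials=1)[1]
    item = syn.simulate_experiment(design, seed=7)[0]
    rec, truth = item["recording"], item["truth"]
    trial = ingest.align_trials(rec, "drug")
    env19 = ingest.resample_envelope(ingest.integrate_neurogram(trial), 19.0)
    return {"design": design, "recording": rec, "truth": truth,
            "aligned": trial, "env19": env19}
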