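from dataclasses import replace

import pytest
from hypothesis import settings

from gammaloop import closed_loop, synth_data

settings.register_profile("deterministic", derandomize=True, deadline=None, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def synth_rec_truth():
    """One 60 s artifact-free synthetic recording with ground truth."""
    cfg = synth_data.SynthConfig(duration_s=60.0, seed=3, artifact_rate_hz=0.0)
    return synth_data.generate_recording(cfg)


@pytest.fixture(scope="session")
def loop_scenario():
    """Closed-loop run on a 120 s synthetic recording with a calibrated threshold.

    The threshold multiplier is calibrated on a burst-free baseline recording
    (the simulator's analogue of per-animal tuning), then the loop runs over
    a burst-rich recording in both polarities.
    """
    cfg = synth_data.SynthConfig(
        duration_s=120.0, seed=7, burst_rate_hz=0.4, artifact_rate_hz=0.0
    )
    rec, truth = synth_data.generate_recording(cfg)
    baseline_rec, _ = synth_data.generate_recording(
        replace(cfg, burst_rate_hz=0.0, seed=1007)
    )
    lc = closed_loop.LoopConfig(threshold_window_s=10.0)
    k = closed_loop.calibrate_threshold_k(baseline_rec, target_trigger_rate_hz=0.1, config=lc)
    lc = replace(lc, threshold_k=k)
    res_in = closed_loop.run_closed_loop(rec, lc)
    res_anti = closed_loop.run_closed_loop(rec, replace(lc, polarity="anti_phase"))
    return {
        "rec": rec,
        "truth": truth,
        "config": lc,
        "in_phase": res_in,
        "anti_phase": res_anti,
    }
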