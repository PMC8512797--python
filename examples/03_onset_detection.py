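"""Locate the push-initiation window on a force trace.

The analysis epoch of a push trial is the 0.5 s interval starting at the
first sample where the hand force strictly exceeds 20 N. A trace that never
reaches the threshold is a documented failure, not a silent empty window —
batch processing records it against the trial.
"""

import numpy as np

from hdemg import (
    NoInitiationError,
    SimulationConfig,
    detect_initiation,
    generate_force_trace,
)

config = SimulationConfig(duration=3.0, onset_time=1.2, force_plateau=120.0, seed=5)
trace = generate_force_trace(config)
window = detect_initiation(trace, threshold=20.0, window_s=0.5)
t0 = window.start / trace.sampling_rate
print(f"force crosses 20 N at t = {t0:.3f} s (configured onset {config.onset_time} s)")
print(f"analysis window: samples [{window.start}, {window.end}) "
      f"= [{t0:.3f}, {window.end / trace.sampling_rate:.3f}) s")
print(f"peak force: {np.max(trace.force):.1f} N")

weak = generate_force_trace(SimulationConfig(duration=3.0, force_plateau=12.0, seed=5))
try:
    detect_initiation(weak)
except NoInitiationError as exc:
    print(f"sub-threshold trace -> {type(exc).__name__}: {exc}")
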