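"""Render an activation map as a heat image.

A clustered trial produces a hot spot around the territory center; the
masked upper-right electrode stays blank. The figure is written under
scratch/ (created if needed).
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

from hdemg import SimulationConfig, TrialWindow, build_map, generate_grid_emg
from hdemg.viz import plot_map

config = SimulationConfig(duration=2.0, clustering=0.9, noise_sd=0.05, seed=13)
recording = generate_grid_emg(config)
map_ = build_map(recording, TrialWindow(500, 1000))

ax = plot_map(map_)
out = Path("scratch/activation_map.png")
out.parent.mkdir(exist_ok=True)
ax.figure.savefig(out, dpi=120, bbox_inches="tight")
hottest = map_.layout.valid_positions[int(map_.valid_values.argmax())]
print(f"wrote {out} — hottest electrode at (row, col) = {hottest} "
      f"of {map_.n_valid} channels")
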