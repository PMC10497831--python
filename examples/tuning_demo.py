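"""Spatial tuning of single cells on the circular belt.

Builds one synthetic session with cells of known field width (von Mises
concentration kappa), runs the preprocessing + tuning chain, and prints
each cell's circular tuning index next to the infinite-data closed form
I1(kappa)/I0(kappa) it should approach.
"""

import numpy as np
import pandas as pd
from scipy.special import i0, i1

from dgspace import (
    AnalysisConfig,
    generate_cell_traces,
    generate_track,
    movement_epochs,
    threshold_events,
    tuning_vector,
    young_defaults,
)

params = young_defaults(session_length=300.0, noise_sd=0.02)
rng = np.random.default_rng(0)
track = generate_track(params, rng)

kappas = [0.0, 0.5, 2.0, 8.0]
truth = pd.DataFrame(
    {
        "cell_id": [f"kappa={k}" for k in kappas],
        "preferred_cm": [40.0, 80.0, 120.0, 160.0],
        "kappa": kappas,
    }
)
traces = generate_cell_traces(track, truth, params, rng)

cfg = AnalysisConfig()
mask = movement_epochs(track, cfg.speed_threshold, cfg.min_move_duration)
thresholded = threshold_events(traces.events, cfg.threshold_k)
result = tuning_vector(thresholded, track, mask, cfg.n_tuning_bins, params.belt_length)

print(f"{track.total_distance / 100:.0f} m run, "
      f"{mask.moving.mean():.0%} of frames in movement epochs\n")
print(f"{'cell':>10s} {'tuning index':>13s} {'I1/I0 limit':>12s} {'preferred bin':>14s}")
for i, k in enumerate(kappas):
    limit = i1(k) / i0(k)
    print(f"{traces.cell_ids[i]:>10s} {result.tuning_index[i]:13.3f} "
          f"{limit:12.3f} {result.preferred_bin[i]:14d}")
print("\nThe index is the resultant length of the occupancy-normalized rate "
      "map on the circle: 0 = untuned, 1 = active in a single bin. With a "
      "finite number of events the estimate is noisy around the limit: "
      "weakly tuned cells are biased upward (even a random walk has a "
      "nonzero resultant), while strongly tuned cells sit slightly below.")
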