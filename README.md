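# adhesionlag

Quantification of focal-adhesion cluster **recruitment kinetics** from
two-channel time-lapse TIRF movies.

During cell spreading, adhesion proteins arrive at nascent adhesion sites in
a defined order: clusters of the scaffold protein Cas (red reference
channel) form first and are joined later by proteins such as vinculin,
β1 integrin, or Crk (green query channel). `adhesionlag` measures that
ordering as a per-cluster time lag

```
Δt½ = t½(green) − t½(red)
```

where *t½* is the interpolated time at which a cluster's [0, 1]-rescaled
intensity trace first reaches 0.5. A positive Δt½ means the query protein
arrives after the reference. The package also implements the matching
fixed-image analyses (axial line profiles along adhesions and
Yen/Triangle-threshold cluster counting) and ships a synthetic-movie
generator with exact ground truth, so every stage is testable without any
microscopy data.

## Pipeline

For each movie (`(frame, channel, row, col)` hyperstack, 0.16 µm/px and
15–20 s/frame typical):

1. **Drift correction** — frame-to-frame phase correlation on the reference
   channel, with a confidence gate against structure-free frames; both
   channels translated identically.
2. **Preprocessing** — per-frame 3×3 median filter, then white top-hat with
   a 15 px disk to equalize the background.
3. **Segmentation** — per channel, threshold = ¼ of the 50th-brightest
   pixel intensity (per frame by default, per dataset optionally); cluster
   mask = union of the channel masks; 8-connected components must exceed
   20 px (0.5 µm²).
4. **Tracking** — masks stacked into an XYT volume, 3D connected components
   (26-connectivity); tracks spanning fewer than 3 frames (≥40 s at
   20 s/frame) are discarded.
5. **Trace extraction** — for each tracked frame's mask, the mean intensity
   over the whole time axis; the per-cluster averaged trace is the mean of
   those series per channel.
6. **Kinetics** — rescale to [0, 1], 3-frame moving average, interpolate
   the first upward 0.5-crossing per channel, Δt½ = green − red.

Per cell: median Δt½ with a distribution-free 95% CI (exact binomial order
statistics) and a one-sided signed-rank test of median > 0. Across cells:
mean of medians ± SEM, with Mann–Whitney *U* (exact for small samples) and
Kruskal–Wallis + Dunn group comparisons.

## Worked example

```python
import numpy as np
from adhesionlag import default_cell, generate_movie, run_pipeline

# one simulated spreading cell: 50 clusters, true lag 60 s, peak SNR 5
spec = default_cell(true_lag_s=60.0, snr=5.0, n_clusters=50, seed=11)
movie, truth = generate_movie(spec)

result = run_pipeline(movie)
valid = result.table[result.table["valid"]]
print(len(valid), float(np.median(valid["delta_t_half_s"])))
```

prints

```
51 59.75
```

i.e. 51 tracked clusters were quantified and the recovered per-cell median
lag is 59.7 s against a simulated truth of 60 s — within a fraction of one
20 s frame interval. The same analysis is available from the shell:

```bash
adhesionlag simulate --out demo.tif --lag-s 60 --snr 5 --seed 4
adhesionlag run --movie demo.tif --out results/
```

which writes `clusters.csv` (one row per tracked cluster: t½ per channel,
Δt½, area, persistence, validity) and `labels.tif` (the tracked label
volume).

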