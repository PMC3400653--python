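# fluotrack

Two-camera fluorescence video tracking for small animals (flies, worms)
expressing fluorescent reporter proteins.  Recorded under emission-filtered
dark-field illumination, each animal appears as a bright silhouette against a
dark background; `fluotrack` detects those silhouettes, quantifies their
fluorescence, reconstructs the animal's 3D trajectory from the two calibrated
views, and summarizes motion and reporter-induction time courses.  A synthetic
scene generator with exported ground truth makes every stage testable without
recorded video.

## Method

**Silhouette detection.** The background is modeled per pixel by a running
Gaussian average of the detection channel (green for GFP; red/blue
configurable).  A pixel of frame *I* is foreground when |*I* − μ| > *T* for an
empirically chosen threshold *T*; the model is then updated *selectively* on
background pixels only,

    μ ← (1 − α) μ + α I,

with adaptation rate α ∈ [0, 1] trading stability against speed of update.
The initial background averages a small fraction (default 1%) of the whole
recording sampled at even intervals.  Change masks are cleaned by
morphological opening with a 3×3 square structural element, and silhouettes
are the 8-connected foreground components above a minimum pixel size.

**Fluorescence quantification.** Per component and channel, pixels are split
into four intensity bins of increasing brightness (G1–G4 for green), keeping
per-bin pixel counts and intensity sums.  Background and tissue
autofluorescence fall almost entirely into G1, while reporter signal fills the
upper bins, so binning preserves signal that a plain mean would dilute when
the fluorescing region's size varies between animals.  To compare samples,
the highest bin populated in every sample is used, extended downward (G4,
then G4+G3, …) when necessary.  Pooled per-frame intensities are averaged per
minute and smoothed by LOESS (tricube-weighted local polynomial regression,
default span 0.1, degree 2).

**3D reconstruction.** Each camera is a 3×4 projection matrix *P* mapping
homogeneous world points to pixels, *s* (u, v, 1)ᵀ = *P* (X, Y, Z, 1)ᵀ, with
optical center *C* the null-space point of *P*.  A centroid observation
back-projects to the viewing ray through *C*; for frames where exactly one
silhouette is seen in each view, the 3D position is the midpoint of the
shortest segment between the two rays, with the segment length (the "gap")
reported as a per-point quality diagnostic.  Motion statistics (speed,
heading-change frequency, path length) are computed from the track.

## Worked example

Render a synthetic two-view recording of one animal spiraling through a
vial-shaped chamber, then run the full pipeline on it:

```python
import numpy as np
import fluotrack as ft
from fluotrack.tracking import components_to_observations

cfg = ft.SceneConfig(n_frames=600)           # 20 s at 30 fps, 320x240
cams = ft.default_cameras(cfg)               # two views, 90 degrees apart
traj = ft.make_trajectory("helix", cfg)
seq1, seq2, truth = ft.render_sequence([traj], cams, cfg)

obs = []
for view_id, seq in enumerate((seq1, seq2), start=1):
    model = ft.initialize_background(seq, 0.01, threshold=50)
    res = ft.process_sequence(seq, model, min_size=5, view_id=view_id)
    obs.append(components_to_observations(res, "green", (3, 4)))

pairs, skips = ft.pair_observations(*obs)
track, _ = ft.reconstruct_trajectory(pairs, cams[0], cams[1])
pos = np.array([p.position for p in track])
err = np.linalg.norm(pos - traj[[p.frame_index for p in track]], axis=1)
print(f"frames tracked: {len(track)}/600")
print(f"mean 3D error:  {err.mean():.3f} world units "
      f"({100 * err.mean() / cfg.chamber_diameter:.2f}% of chamber diameter)")
```

Output:

```
frames tracked: 600/600
mean 3D error:  0.037 world units (0.18% of chamber diameter)
```

Every frame yields a 3D point (the blob is visible in both views throughout),
and the reconstructed path tracks the programmed helix to well under a pixel's
worth of world-space error.

The same workflow is available from the shell:

```sh
fluotrack synth --out fixture/                # render fixture + ground truth
fluotrack preview-threshold --video fixture/view1 --threshold 50 --out masks/
fluotrack batch --config run.yaml             # detections/fluorescence/track CSVs
fluotrack plot-track --trajectory out/trajectory.csv --out track.png
```

`run.yaml` holds the `RunConfig` keys (video/matrix paths, `threshold`,
`alpha`, `sample_fraction`, `min_component_size`, `channel`, LOESS settings,
`chunk_frames`, …).  Long recordings are streamed in chunks — by default
108,000 frames, one hour at 30 fps — with a single persistent background
model per view, so outputs are independent of the chunking.

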