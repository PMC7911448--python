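# capstrack

Feature-point-tracking localization of colon capsule endoscopes.

A colon capsule endoscope films the large bowel while travelling
passively with peristalsis; the video carries no position information,
yet a follow-up colonoscopy needs to know *where* a polyp or bleed was
seen.  `capstrack` estimates the capsule's motion frame by frame from
the images alone, under a local cylinder model of the bowel, and
reconstructs ensembles of 3-D capsule paths whose spread quantifies
the localization uncertainty.  It is aimed at researchers working on
capsule-endoscopy localization who need a complete, testable reference
pipeline with a synthetic ground-truth generator.

## The model in brief

The bowel is locally a cylinder of radius `R`.  A wall point at axial
distance `D` subtends the inclination `θ = atan(R/D)`; after the
capsule moves a distance `d` it subtends `atan(R/(D−d))`, so each
tracked feature point yields

```
d_P = R · (cot θ_{P,t} − cot θ_{P,t+1})
```

Frames are unwrapped to `(x = Lφ/2π, y = r)` so roll becomes
horizontal translation; feature points are detected (SIFT by default),
matched with a symmetric ratio test, and RANSAC-filtered.  Per frame,
the speed `v`, roll `γ`, and tilt `(Ω, ω)` are the **modes** of the
per-point estimate ensembles (KDE argmax — the most likely value, not
the mean), pitch/yaw follow as `α = Ω cos ω`, `β = Ω sin ω`, and the
track integrates as

```
s_{t+1} = Q_{t+1} s_t ,   Q_{t+1} = R_t Rx(γ) Ry(β) Rz(α) R_t⁻¹
x_{t+1} = x_t + (v/f) s_t
```

Because neither the bowel radius nor the (re-exported) frame rate `f`
is observable, both are drawn per frame from priors — truncated
Gaussian (`T`) or uniform (`U`), combined as T-T / T-U / U-T / U-U —
and the reconstruction is repeated `N` times into a path ensemble.
Frames with cleanliness level 0 (pixel-SVM score) or fewer than 20
matched feature points advance instead by a history-noise fallback.
Details, assumptions and limitations: [docs/methods.md](docs/methods.md).

## Worked example

A 250-frame synthetic colon video with known ground truth, observed
at the correspondence level (exact feature tracks; `observe_frames`
runs the same estimators on rendered images), reconstructed 200 times
under two prior combinations:

```python
import numpy as np
from capstrack.simulator import (TrajectoryConfig, simulate_trajectory,
                                 simulate_correspondences)
from capstrack.geometry import CameraGeometry
from capstrack.pipeline import observe_matchsets, run_ensemble
from capstrack.priors import prior_combo
from capstrack.evaluation import auto_place_boxes, path_difference

g = CameraGeometry()
traj = simulate_trajectory(TrajectoryConfig(n_frames=250, dirt_fraction=0.03),
                           np.random.default_rng(21))
matchsets = simulate_correspondences(traj, g, n_points=120,
                                     rng=np.random.default_rng(22))
levels = [0 if s.dirty else 3 for s in traj.samples]
obs = observe_matchsets(matchsets, levels=levels, seed=0)

boxes = auto_place_boxes(traj.positions(), pad=1.0)
for name in ("tt", "uu"):
    ens = run_ensemble(obs, prior_combo(name), N=200, master_seed=3)
    lengths = [float(np.sum(np.abs(p.records["v"] / p.records["f_drawn"])))
               for p in ens.paths]
    summary = path_difference(ens, boxes)
    print(f"{ens.label}: true arc {traj.arc_length:.1f} cm, "
          f"ensemble mean {np.mean(lengths):.1f} cm")
    print("   ", "  ".join(f"{s}={summary.mean[s]:.2f}" for s in summary.sections()))
```

prints

```
T-T: true arc 30.3 cm, ensemble mean 30.9 cm
    I=0.07  II=0.18  III=0.68  IV=1.30  V=1.77  VI=2.28
U-U: true arc 30.3 cm, ensemble mean 40.9 cm
    I=0.22  II=0.63  III=1.81  IV=3.12  V=3.92  VI=6.59
```

Under the truncated-Gaussian priors (T-T) the ensemble recovers the
travelled arc to within 2%, and the between-path spread (the "path
difference", in cm) grows from the anus (section I) toward the
ascending colon (VI) — dead-reckoning uncertainty accumulating along
the bowel.  The uninformative uniform priors (U-U) are two to three
times worse in every section, which is exactly why the per-section
statistics exist: they show how much localization confidence each
prior choice buys.

A CLI wraps the same pipeline for shell use:

```sh
capstrack simulate --out video/ --n-frames 300 --seed 1
capstrack track --frames video/ --out path.csv --seed 1
capstrack ensemble --frames video/ -N 200 --out ens.npz --seed 1
capstrack evaluate --ensemble ens.npz --truth video/ground_truth.csv --out-prefix eval
capstrack compare-heads --ensemble1 a.npz --ensemble2 b.npz
```

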