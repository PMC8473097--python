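# gaitlidar

Contactless gait assessment from planar LiDAR range scans.

Clinically relevant spatio-temporal gait parameters — step length, step
time, stride length, cycle time, cadence and walking velocity — are usually
measured on a pressure-sensitive walkway or with body-worn inertial
sensors. `gaitlidar` implements the alternative: a room instrumented with
planar laser scanners (three at shin height, one at torso height, each
sweeping 2162 beams over 270° at 40 Hz) tracks both shins of a walking
person without any body contact, which makes long-term gait monitoring in a
home-like environment possible.

The processing pipeline has five stages:

1. **Background removal** — while the room is empty, every beam's range is
   modelled as a Gaussian (per-beam sample mean and sd over a 50 s
   sequence). A beam in a later scan is foreground when its two-sided tail
   probability is below 10⁻⁵ *and* it is shorter than the background mean.
2. **Multi-sensor registration** — rigid per-sensor transforms into the
   room frame plus nearest-timestamp frame grouping; the shin sensors'
   foreground is overlaid into one cloud per frame.
3. **Clustering** — threshold-based breakpoint detection (equivalent to
   single-linkage connected components), removal of clusters under five
   points, a 50 cm gate around the upper-body centroid, k-means refinement
   when both legs are visible, and an SIR particle filter that imputes an
   occluded leg using the upper-body velocity scaled by a factor drawn from
   [0.5, 2.0].
4. **Tracking** — the initial left/right assignment from the sign of the
   cross product between the walking direction and each body-referenced leg
   vector; labels then propagate by nearest previous position.
5. **Gait analysis** — per-leg speed profiles (moving average), stance
   events at speed minima and swing peaks at maxima, and the six gait
   parameters derived from the alternating event series.

Because the study recordings are not public, the package ships a raycasting
simulator (`gaitlidar.simulate`) that generates per-sensor polar scans of a
parametric walker in a furnished room, with exact ground truth — including
the study's fixed walk conditions (30 cm steps at 100/120 steps·min⁻¹,
60 cm steps at 60/120 steps·min⁻¹), a u-turn walk, and the 12 h static
two-pipe scene used for drift assessment. Device-agreement statistics
(paired t with Bonferroni, Pearson r, regression R², ICC(3,1),
Bland–Altman, and the paired-t power analysis) live in
`gaitlidar.evaluation`.

## Worked example

```python
from gaitlidar import simulate
from gaitlidar.geometry import SensorSpec
from gaitlidar.pipeline import PipelineConfig, run_pipeline

spec = SensorSpec()                    # 2162 beams, 270°, 40 Hz
room = simulate.default_room()
poses = simulate.default_sensors()     # three shin sensors + one torso sensor

background = simulate.synthesize_background(room, poses, spec, seed=1)
walk = simulate.preset_walk("60-60", seed=7)      # 60 cm steps, 60 steps/min
scans, truth = simulate.synthesize_walk(walk, room, poses, spec)

result = run_pipeline(scans, background, PipelineConfig(spec=spec, poses=poses, seed=7))
for key, value in result.params.summary().items():
    if value is not None:
        print(f"{key:>24}: {value:7.2f}")
```

prints

```
     step_length_cm_mean:   59.98
       step_length_cm_sd:    0.30
        step_time_s_mean:    1.00
          step_time_s_sd:    0.00
   stride_length_cm_mean:  119.95
     stride_length_cm_sd:    0.28
       cycle_time_s_mean:    2.00
         cycle_time_s_sd:    0.00
             cadence_spm:   60.00
            velocity_cms:   60.56
```

The walker was programmed with 60 cm steps at 60 steps·min⁻¹ (hence a
2.0 s gait cycle and a mean velocity of 60 cm·s⁻¹); the pipeline recovers
all six parameters to within a centimetre, a hundredth of a second and one
step per minute, from nothing but raw range scans.

The same pipeline is scriptable from the shell:

```sh
gaitlidar simulate --preset 60-60 --seed 7 -o walk/
gaitlidar analyze walk/walk.jsonl --background walk/background.jsonl -o gait.csv
gaitlidar compare gait.csv reference.csv -o report.csv
```

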