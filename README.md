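# tugspeed

Markerless measurement of Timed Up and Go (TUG) subtask speeds from a
single sagittal video, with a motion-capture reference path and the
agreement statistics used to compare them.

The TUG trial — rise from a chair, walk 3 m, turn, walk back, sit — is
split into nine subtasks (V1 sit-to-stand, V2–V4 outbound metres, V5
turn, V6–V8 inbound metres, V9 stand-to-sit) and a mean speed in m/s is
reported for each.

## What is inside

| module | purpose |
| --- | --- |
| `tugspeed.calibration` | two-point planar pixel→metre calibration from four scene markers (3 m walkway pair, 0.5 m vertical pair) |
| `tugspeed.foreground` | grayscale background subtraction (τ = 50), 5×5 binary median filter, silhouette centroid |
| `tugspeed.kinematics` | world-coordinate centroid track, gap interpolation, signed windowed speeds (4 frames at 60 Hz = 1/15 s) |
| `tugspeed.segmentation` | nine-subtask boundary detection (standing-height band, metre-mark crossings, peak-excursion turn margin) and per-subtask mean speeds |
| `tugspeed.mocap` | reference path: zero-phase 4th-order 6 Hz Butterworth, four-pelvis-marker COM, same segmentation machinery at 120 Hz |
| `tugspeed.agreement` | Pearson r with interpretation bands, ICC(3,2) (two-way mixed, consistency, average measures) with 95% CI, Bland–Altman limits of agreement |
| `tugspeed.synthetic` | fully scripted synthetic trials: ground-truth trajectory, rendered video frames, matched mocap tracks, bivariate paired tables |
| `tugspeed.pipeline`, `tugspeed.cli` | end-to-end orchestration and the command-line interface |

## CLI

```sh
# render a synthetic trial (frames/, background.png, mocap.csv, sync.json, ground_truth.json)
tugspeed simulate --out trial/ --seed 1 --condition comfortable --noise 0.005

# analyse a video (directory of PNG frames or a video container)
tugspeed analyze trial/frames \
    --background trial/background.png \
    --markers 560,330,60,330,30,330,30,250 \
    --sync-start 36 --sync-stop 601 \
    --out results/

# reference speeds from a pelvis-marker CSV (columns R_ASIS_x … L_PSIS_z, metres)
tugspeed mocap trial/mocap.csv --sync-start 72 --sync-stop 1202 --out results/

# agreement statistics between two per-subject tables (subject_id, v1..v9)
tugspeed validate video.csv mocap.csv --out validity.json
tugspeed reliability session1.csv session2.csv --out reliability.json
```

Marker pixel coordinates are supplied in the order M1 (far walkway
marker), M2 (chair-side walkway marker = world origin), M3 (floor), M4
(0.5 m above M3). Every `analyze` flag can instead be given in a plain
`key = value` file passed with `--config`.

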