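# clawtrack

Motion tracking and wave-synchrony analysis for claw-waving fiddler crabs
in field video.

Male fiddler crabs attract mates by rhythmically waving their enlarged
claw, and in many species neighbors wave in sync — one of the most
accessible natural examples of collective synchronization. Measuring it is
the hard part: field recordings are low-resolution and cluttered, the
crabs are ~15 px specks that blend into the mud, and appearance-based
trackers built for lab arenas fail. `clawtrack` implements a
motion-centric pipeline for exactly this regime, for behavioral ecologists
and synchronization researchers who want per-individual wave phases and
group-synchrony numbers straight from video:

1. **Dense optical flow** between consecutive frames (pyramidal iterative
   Lucas–Kanade) — motion, not appearance, is the signal;
2. **Grid averaging + magnitude threshold** — the field is averaged over
   8 px cells and cells below a user-set cutoff are zeroed, leaving a
   sparse, noise-robust set of motion vectors;
3. **DBSCAN clustering** (ε = 30 px, minpts = 2) groups motion cells into
   individuals without a preset count;
4. **Centroid ID tracking** — greedy nearest-centroid matching under a
   maximum-displacement threshold keeps identities over time;
5. **Wave phase extraction** — each ID's speed trace is smoothed, its
   peaks (moments of highest claw speed) are detected and treated as phase
   zero, and phase is interpolated linearly between successive peaks while
   the crab is actively waving;
6. **Synchrony** — the Kuramoto order parameter
   R(t) = |(1/N) Σⱼ exp(iθⱼ(t))| over active individuals, its time mean,
   and a seeded Monte-Carlo chance level for the same ensemble size
   (E[R] = 2/π for n = 2, ≈ √π/(2√n) for large n).

Detection accuracy against human annotation is quantified with net error
(N_alg − N_hum), relative error (|N_alg − N_hum|/N_hum × 100 %), and
agreement accuracy (100 % − relative error).

Because field footage is not distributable, the package ships a
ground-truthed **synthetic scene generator** (static textured background,
~15 px claw patches producing one speed peak per wave, optional pixel
noise, everything seeded) so the whole chain is testable offline; see
`docs/methods.md` for what the scenes do and do not emulate.

## Worked example

`examples/` contains one short script per capability. The end-to-end one:

```bash
$ python examples/02_track_synthetic_scene.py
scene: 3 wavers, 300 frames @ 30 fps
recovered 3 tracks (IDs with at least one full claw wave)
  track 0 -> waver 1: mean position off by 1.9 px, present 299/300 frames
  track 1 -> waver 0: mean position off by 1.5 px, present 299/300 frames
  track 2 -> waver 2: mean position off by 1.6 px, present 299/300 frames
 frame   time_s  id  x_px  y_px  x_m  y_m  speed_px_per_frame
     1 0.033333   0 196.5  28.5  NaN  NaN            0.690534
     1 0.033333   1  71.5 147.5  NaN  NaN            0.741420
     1 0.033333   2 305.9 152.3  NaN  NaN            0.509258
     2 0.066667   0 196.5  28.5  NaN  NaN            0.644528
```

Each planted crab maps to one persistent ID whose mean position lies
within ~2 px of the claw's true orbit center; the per-frame speed column
is the claw-wave signal that the phase/synchrony stage consumes. And the
synchrony math on a planted trio with offsets {0, 0, π}:

```bash
$ python examples/03_wave_phases_and_synchrony.py
planted offsets [0.    0.    3.142] -> R = |e^i0 + e^i0 + e^ipi| / 3
R while all 3 are waving    : 0.3333 (exact: 0.3333)
mean R over active instants : 0.3857 (higher: at the clip edges only the in-phase pair is active, where R = 1)
chance level, n=3 oscillators: 0.5239
chance level, n=2 (closed form 2/pi = 0.6366): 0.6377
single-instant check, phases {0, 0, pi}: R = 0.3333
```

Note the chance level: small groups of *independent* wavers average a
sizeable R, so sample size matters when reading synchrony values.

## Command line

For shell use the same pipeline is exposed as a thin CLI:

```bash
clawtrack simulate --out scene --n-wavers 5 --seed 1      # render a scene + ground truth
clawtrack track scene/frames --out run --frame-rate 30    # video/PNG dir -> tracks.csv
clawtrack analyze run/tracks.csv --out run                # -> phases.csv, sync.csv, summary.json
clawtrack evaluate run/tracks.csv --human-count 5 \
          --truth scene/peaks.csv --out run/metrics.json  # accuracy vs annotation
```

Every parameter lives in one YAML config (`--config`, overridable by
flags), and a serialized copy is written next to each output for
provenance. Identical config + seed reproduces outputs byte for byte.

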