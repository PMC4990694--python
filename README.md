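# pnpmrf

Plug-and-play MR fingerprinting with heterogeneous transmit fields, end to
end on synthetic phantoms:

- **`pnpmrf.epg`** — extended-phase-graph simulation of voxel fingerprints
  under an arbitrary 480-excitation schedule, with slice-profile support.
  **`pnpmrf.isochromat`** holds the independent brute-force Bloch oracle the
  EPG is validated against.
- **`pnpmrf.schedule`** — construction/validation of the four-segment
  sequence (coil-interleaved RF-spoiled segments, dedicated-coil 0/180
  phase-cycled segments, inter-segment recovery delays), CSV serialization
  and content hashing.
- **`pnpmrf.dictionary`** — the 4-D parameter grid (T1, T2, B1 per transmit
  channel; 5% geometric T1/T2 steps, 0.2 uT B1 steps), numba-parallel batch
  simulation, and the view-sharing compression that turns 480 complex
  samples into 32 real values (sets of 15 consecutive same-coil samples,
  summed, modulus taken).
- **`pnpmrf.encoding`** — radial trajectories (spokes rotated by 14·6/N
  degrees between excitations), acceleration-factor accounting, a
  Kaiser-Bessel gridding NUFFT (forward/adjoint, ~1e-7 accurate), ramp
  density compensation, pooled view-shared reconstruction, optional
  corner-covering least-squares inversion, receive-sensitivity estimation
  and matched-filter combination.
- **`pnpmrf.matcher`** — exhaustive compressed-dictionary search producing
  PD/T1/T2/B1/correlation maps.
- **`pnpmrf.tx_fields`** — analytic ring-array transmit fields, orthogonal
  coil modes (CP/gradient), approximate-CP calibration,
  magnitude-least-squares shimming, field-uniformity CV.
- **`pnpmrf.phantom_pipeline`** — digital phantoms, forward simulation to
  noisy radial k-space, full pipeline execution and recovery reporting.

## CLI

```sh
pnpmrf validate-schedule [--config sched.cfg]
pnpmrf build-dict --out dict.h5 [--reduced] [--config sched.cfg]
pnpmrf simulate --config scenario.cfg --dict dict.h5 --seed 5 --out k.h5
pnpmrf match --kspace k.h5 --dict dict.h5 --out maps/
pnpmrf report --config scenario.cfg --dict dict.h5 --seed 5 --out run/
```

Configs are flat `key = value` text files (`#` comments).  Schedule keys
mirror `pnpmrf.schedule.ScheduleConfig` (tr, te, inter_segment_delay, peak
flips, RF-spoil increment, ...); scenario keys mirror
`pnpmrf.phantom_pipeline.ScenarioConfig` (matrix_size,
spokes_per_timepoint, noise_sd, field_preset, phantom_preset, ...).
Dictionaries and k-space series are HDF5 containers; maps are written as
NIfTI with a JSON provenance sidecar.

## Conventions

- EPG phase convention: a 90-degree, phase-0 pulse on equilibrium gives
  `F+_0 = -i·m0`.
- Achieved flip = relative drive x |B1|/reference_B1 x reference flip
  (reference B1 = 6 uT), so the default 25/60-degree peak trains span a
  5-60 degree range over 0.5-6 uT fields.
- k-space in cycles/FOV, spokes span the diameter, angles in [0, pi) from
  the kx axis, centred-FFT image convention, 2x readout oversampling.
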