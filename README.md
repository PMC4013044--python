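# homecage

Analysis of group-housed rodent home-cage corner-visit event logs from
sensor-equipped cages (per-animal RFID tracking of corner visits, nose pokes
and bottle licks), together with an agent-based cohort simulator so the whole
pipeline can be exercised and validated without real cage data.

## What it does

- **`homecage.event_log`** — canonical tab-separated event dialect (one corner
  visit per row: `animal_id, corner, t_start, t_end, nosepokes_left/right,
  licks_left/right`), validated reading/writing, and slicing by schedule
  intervals (half-open windows, selectors like `"last 4 alcohol"`).
- **`homecage.schedule`** — machine-readable experiment schedules:
  intermittent two-bottle alcohol access (three 24 h sessions/week, reward
  corners alternating {1,3}/{2,4}, 4→8→12% v/v ramp), quinine-adulteration
  sequence, progressive-ratio session lists (PR1/PR3), and punishment-risk
  sessions (air puff, 100%/25% risk, optional 2 s delay).
- **`homecage.synthetic`** — simulator producing event tables with circadian
  two-peak dark-phase activity, log-normal visit durations, configurable
  alcohol preference and bottle-side bias, FR/PR/risk contingencies, and
  injectable leader→follower relationships with latencies inside the social
  analysis window. Bit-for-bit reproducible under a fixed seed.
- **`homecage.metrics`** — preference ratio (alcohol/(alcohol+water) licks),
  side-bias index ((R−L)/(R+L), |index|>0.6 "strong"), daily activity
  summaries, hourly circadian profiles, log-binned duration/revisit
  histograms, lick→intake→dose conversion (3 µl/lick, ethanol density
  0.789 g/ml) and a linear blood-ethanol estimate (300 licks/h ↔ 0.1‰ w/v).
- **`homecage.operant`** — progressive-ratio breakpoint extraction (stage
  completed within a single corner visit; no stage skipping; inter-criterion
  and post-breakpoint visit counts) and punishment-risk lick splits.
- **`homecage.social`** — follow/avoid inference: per-corner entry sequences,
  adjacent-pair counts gap-filtered to [1 s, 60 s], a permutation null that
  shuffles each corner's letters over its fixed time slots (default 100
  permutations), z-like scores `(observed − null mean)/null SD`, two-sided
  normal-tail p-values (|z|=2 → 0.0455; z=3.5 → <0.0005), column-stochastic
  count normalisation, optional removal of same-mouse repeat entries, and
  edge-list/node-table export.

## Command line

```bash
# build a 4-week intermittent schedule
homecage schedule build --design intermittent --weeks 4 --out sched.yaml

# simulate a cohort (see tests/test_cli.py for the config schema)
homecage simulate --config cohort.yaml --seed 17 --out events.tsv --roster-out roster.yaml

# per-mouse, per-session metrics
homecage metrics summarize --events events.tsv --schedule sched.yaml --out metrics.tsv

# progressive-ratio breakpoints / punishment-risk licks
homecage operant pr   --events events.tsv --schedule pr.yaml --session-index 5 --out pr.tsv
homecage operant risk --events events.tsv --schedule risk.yaml --session-index 2 --out risk.tsv

# social scores over the last 4 alcohol sessions
homecage social score --events events.tsv --schedule sched.yaml \
    --window "last 4 alcohol" --n-perm 100 --seed 7 --out-prefix social

# end-to-end pipeline (simulate -> metrics -> social) with a manifest
homecage run --config run.yaml --out-dir out/
```

Exit codes: 0 ok, 2 configuration error, 3 data error.

A minimal cohort config:

```yaml
cohort:
  seed: 17
  mice:
    - {animal_id: a, sex: M, weight_g: 26, p_alcohol: 0.7, side_bias: -0.3}
    - {animal_id: b, follow: [{target: a, p_follow: 0.8}]}
  schedule: {weeks: 4, exchange_hour: 16, access_mode: free}
```

## Notes

- The permutation score is interpreted on a normal scale only approximately;
  when observed pair frequencies are non-normal or dependent, the p-values
  are indicative, not exact.
- The lick→mass intake conversion uses % v/v and ethanol density
  0.789 g/ml; a directly measured intake mass can be supplied to
  `metrics.intake_dose` to bypass the lick conversion.
- 100 permutations mirror the original design; ≥1000 is recommended when
  runtime permits (`--n-perm`).
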