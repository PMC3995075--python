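# gravikin

Graviproprioceptive bending of elongating plant shoots: a tested simulator
and analysis library for tropic curvature dynamics on a growing organ.

An organ midline is modelled as a Lagrangian chain of material elements
carrying curvature. Differential growth — commanded by graviception (local
inclination) and proprioception (local curvature) — drives curvature
change, while the mean elongation stretches elements, producing two
destabilizing growth effects: passive orientation drift and curvature
fixation outside the growth zone. The package provides:

- `gravikin.model_core` — the pure model equations: differential-growth
  response, curvature-rate kinematics (small-curvature and full quadratic
  prefactor), flank-rate decomposition, growth-rate profiles
  (whole-organ/exponential and subapical step), drift rate, parameter
  bookkeeping (`ModelParams`, `GrowthProfile`, `OrganState`).
- `gravikin.simulator` — explicit-Euler time integration on a growing
  material grid with element freezing and split-only remeshing, steady
  state detection, and the drift-stability boundary finder.
- `gravikin.steady_state` — closed-form steady profiles (exponential decay
  for the non-elongating model; a real-order Bessel profile under uniform
  elongation), the model-discrimination statistic and its critical
  proprioceptive gain.
- `gravikin.criteria` — regime diagnostics: active-control condition,
  convergence vs fixation timescales, fixed-zone bookkeeping.
- `gravikin.phenotyping` — bending-number estimation from digitized
  midlines: frame-superposition effective length, exponential fit of the
  convergence length, `B = L_eff / L_c`.
- `gravikin.fixtures` — synthetic midline generators (named regime
  scenarios, seeded orientation noise) so everything is testable offline.
- `gravikin.io_cli` — JSON config, CSV I/O and the `gravikin` CLI.

## CLI

```sh
gravikin simulate --scenario fig5b --out run            # trajectory CSV + JSON
gravikin simulate --config cfg.json --out run
gravikin steady --model ace --gamma-tilde 10 --out s.csv
gravikin mu-threshold --a0 1.0 --mu 0.05                # critical gain (~6.05)
gravikin diagnose --config cfg.json                     # regime report JSON
gravikin generate --scenario ac_reference --noise-sd 0.05 --out mid
gravikin phenotype --input mid.csv --out phen.json
```

Minimal config (`beta_tilde` derived from the bending number `B` through
the effective length):

```json
{"params": {"B": 10, "gamma_tilde": 10, "L0": 100},
 "mode": "ace", "growth_mode": "exponential"}
```

Exit codes: 0 success, 2 validation/usage error, 1 runtime error. Every
run writes a `*.provenance.json` record (config, seed, package version).

## Conventions

Vertical is +y; the tangent angle `A` is measured from vertical (positive
counterclockwise); `C = dA/ds` with arclength from the clamped base to the
apex. Organs start straight and horizontal (`A0 = pi/2`) unless configured
otherwise. Internally everything is dimensional; tests and scenarios use
`R = 1`, `E0 = 1` so times are in units of the elongation time and lengths
in organ radii.
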