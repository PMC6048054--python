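# neuroctrl

Model-free closed-loop control of simulated neural systems with a
from-scratch (NumPy) implementation of Deep Deterministic Policy
Gradients (DDPG).

Three control problems are included, each driven by independent
per-unit actor-critic agents:

- **Fully-actuated spike-train induction** — a network of stochastic
  leaky integrate-and-fire (SLIF) neurons with alpha-conductance
  synapses; one agent per cell injects current to reproduce a random
  Poisson target spike train (reward +1 / −1 / 0 for induced spike /
  mismatch / correct silence).
- **Under-actuated latent-trajectory induction** — a symmetric
  block-community SLIF network with one stimulated cell per community;
  population spiking is projected onto leading principal components and
  the agents steer the phase of that latent oscillation onto a target
  schedule (half-circle agreement reward).
- **Kuramoto synchronization by entrainment** — weakly coupled phase
  oscillators (K below the critical coupling); one agent per
  non-reference oscillator applies bounded phase increments, with a
  shaped reward mixing the global order parameter, synchronization with
  a randomly chosen reference oscillator, and an action-norm penalty.

## Layout

| module | contents |
| --- | --- |
| `neuroctrl.ddpg_core` | stacked MLPs + Adam, OU exploration noise, replay buffer, DDPG agent (critic TD update, deterministic policy gradient, Polyak-averaged targets) |
| `neuroctrl.slif_model` | SLIF network simulator (Euler–Maruyama), alpha-conductance synapses, random/block network generators |
| `neuroctrl.kuramoto_model` | Kuramoto simulator with additive control, order parameter, reference synchronization, one-step control inversion |
| `neuroctrl.latent_phase` | raster smoothing, PCA (covariance eigendecomposition, deterministic signs), latent projection, phase estimation (atan2 / quadrature delay embedding), target schedules |
| `neuroctrl.control_tasks` | the three environments and their reward functions |
| `neuroctrl.experiments_cli` | experiment configs/presets, training/evaluation driver, uncontrolled baselines, fixtures, CLI |

## CLI

```sh
# train a controller (desk-scale preset) and write CSV/JSON logs
neuroctrl run --task kuramoto_sync --preset desk --seed 1 --out results/sync

# run from an explicit config file (fields echoed in results/config.json)
neuroctrl run --config my_config.json --out results/run1

# uncontrolled (zero-action) baseline rollouts
neuroctrl baseline --task kuramoto_sync --preset desk --seed 1

# deterministic plain-text fixtures
neuroctrl fixture --kind latent --size 8 --seed 0 --out fixtures/
```

`--preset paper` selects the published scale (20 cells / 20 oscillators,
400/300 and 1200/1000 hidden units); `--preset desk` is the reduced
scale used by the test suite. Exit code 2 signals a configuration
error.

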