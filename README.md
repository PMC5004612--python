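# respiro

Input estimation (deconvolution) for flow-through respirometry and other
linear time-invariant physiological measurement systems.

## The problem

In flow-through respirometry an animal sits in a chamber that is flushed
at a constant flow rate; a downstream gas analyzer records CO₂ (or O₂,
or water vapor) concentration. The analyzer does not see the animal's
instantaneous gas exchange `u(t)`: every burst is smeared by the chamber
washout, so the record `y(t)` is the convolution of `u` with the
system's impulse response `h` (measurable by injecting a short
calibration pulse). Sampled at interval `δt`, this is the linear system

    y = H u,        H[i, j] = h[i − j]   (lower-triangular Toeplitz),

and recovering `u` from `y` is an ill-conditioned inverse problem: naive
inversion amplifies measurement noise into a useless estimate, and for
hour-long records at 10 Hz the dense system is also too large to treat
at once. `respiro` implements two complementary estimators built for
exactly this setting:

* **Sequential Tikhonov** — the regularized estimate
  `û = argmin ‖Hu − y‖² + γ‖Qu‖²` (with `Q` the identity or a first- or
  second-difference operator), applied block by block: solve
  `n + n₀` points, accept the first `n` inputs, subtract their forward
  contribution from the data still to come, advance. One matrix
  factorization serves every block, so records of any length cost a pair
  of triangular solves per block.
* **Dimension reduction** — constrain the input to be constant over
  windows of `m` samples (`u = Lv` with `L` the block-indicator matrix),
  which shrinks the problem `m`-fold and repairs its conditioning, solve
  the projected least-squares problem, then slide the window `m` times
  and average the shifted solutions to restore single-sample resolution.
  Transport delay (leading zeros of `h`) can make the projected system
  singular; the package provides both remedies — trimming the delay
  (which provably does not change the solution) and a ridge term.

Each method has one tuning parameter (`γ` or `m`) that trades noise
robustness against fidelity to fast input changes; `sweep_gamma` /
`sweep_m` grid-tune them against a calibration recording with known
input. A simulator of the full validation protocol (28 ml chamber at
250/500 ml/min, three-pulse inputs at 0.1–2 Hz, 10 Hz sampling, 0.01–10%
Gaussian noise) makes the package self-validating.

## Worked example

```python
import numpy as np
from respiro import (ChamberConfig, NoiseConfig, PartitionPlan,
                     PulseTrainConfig, add_noise, forward_convolve,
                     pearson_correlation, recover, synth_impulse_response,
                     synth_pulse_train)

# virtual experiment: 28 ml chamber at 500 ml/min, 0.5 Hz pulses, 1% noise
h = synth_impulse_response(ChamberConfig(volume=28.0, flow=500.0, delay=1.0))
u_true = synth_pulse_train(PulseTrainConfig(frequency=0.5, n_pulses=3), 6000, 0.1)
y = add_noise(forward_convolve(u_true, h), NoiseConfig(level=1.0, seed=0))

plan = PartitionPlan(n=780, n_overlap=720)   # 1500-sample blocks at 10 Hz
for method, kw in (("tikhonov", {"gamma": 1e-2}), ("dr", {"m": 8})):
    u_hat, report = recover(y, h, method=method, plan=plan, **kw)
    ok = ~report.flagged_mask                # drop low-confidence tail
    r = pearson_correlation(u_hat.values[ok], u_true.values[ok])
    print(f"{method:9s} r = {r:.3f}   params = {report.params}")
```

prints

```
tikhonov  r = 0.903   params = {'gamma': 0.01, 'reg_kind': 'second_difference', 'block_n': 780, 'block_overlap': 720}
dr        r = 0.930   params = {'m': 8, 'averaging': True, 'trim_delay': True, 'gamma': 0.0, 'block_n': 780, 'block_overlap': 720, 'delay_offset': 10}
```

i.e. both methods recover the 1 s pulses from the washout-smeared, noisy
record with Pearson correlation ≈ 0.9 against the true input; the
`delay_offset` shows the dimension-reduction path trimmed the 1 s
transport delay before solving.

The same pipeline is available from the shell for two-column
(time, concentration) text records:

```sh
respiro simulate --preset reduced --out-dir sim
respiro recover --method tikhonov --gamma 1e-2 \
    --impulse-response sim/ImpulseResponse_flow500.txt \
    --data sim/Data_flow500_f0.5Hz_noise1pct.txt
respiro benchmark --preset tiny --frequencies 0.5,1 --noise-levels 1,5
```

`recover` writes the conventional three-column output files
(`Recovered_Tikhonov.txt` / `Recovered_DimentionReduction.txt`).

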