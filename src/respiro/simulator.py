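"""Synthetic flow-through respirometry experiments.

Generates the three ingredients of a virtual validation run: a chamber
washout kernel, a rectangular pulse-train input (bursts of gas release),
and the noisy analyzer record obtained by forward convolution plus
additive Gaussian noise.  The defaults mirror a bench-top setup: a 28 ml
chamber flushed at 250 or 500 ml/min, 10 Hz sampling, three-pulse inputs
at 0.1-2 Hz, and noise from 0.01% up to 10% of the clean output's peak.

The washout kernel is modeled as a delayed first-order (well-mixed
chamber) response, ``h(t) = (1/tau_w) exp(-(t - delay)/tau_w)`` for
``t >= delay``, with time constant ``tau_w = volume / flow``.  Measured
kernels from a real rig can be substituted via
:func:`respiro.signal_model.discretize_impulse_response`; the generator
exists so the package is self-contained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal_model import ImpulseResponse, TimeSeries, forward_convolve


@dataclass(frozen=True)
class ChamberConfig:
    """Geometry and sampling of the virtual respirometry chamber.

    volume (ml), flow (ml/min) set the washout time constant
    tau_w = volume/flow (converted to seconds); delay (s) is the transport
    lag through the tubing; support_duration (s) is where the kernel is
    truncated (None -> delay + 8 tau_w).
    """

    volume: float = 28.0
    flow: float = 500.0
    delay: float = 1.0
    dt: float = 0.1
    support_duration: float | None = None

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.flow <= 0:
            raise ValueError("volume and flow must be positive")
        if self.delay < 0:
            raise ValueError("delay must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def tau_w(self) -> float:
        """Washout time constant in seconds."""
        return self.volume / self.flow * 60.0


@dataclass(frozen=True)
class PulseTrainConfig:
    """Rectangular pulse train: ``n_pulses`` pulses repeating at
    ``frequency`` Hz, each on for ``duty`` of the period (duty 0.5 at
    1 Hz means 0.5 s pulses)."""

    frequency: float = 0.5
    n_pulses: int = 3
    amplitude: float = 1.0
    duty: float = 0.5
    start_time: float = 5.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if not 0 < self.duty <= 1:
            raise ValueError("duty must lie in (0, 1]")
        if self.n_pulses < 0:
            raise ValueError("n_pulses must be nonnegative")


@dataclass(frozen=True)
class NoiseConfig:
    """Zero-mean Gaussian noise at ``level`` percent of the reference
    amplitude of the clean record (``peak`` = max absolute value,
    ``rms`` = root mean square)."""

    level: float = 1.0
    seed: int = 0
    reference: str = "peak"

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("noise level must be nonnegative")
        if self.reference not in ("peak", "rms"):
            raise ValueError("reference must be 'peak' or 'rms'")


def synth_impulse_response(cfg: ChamberConfig) -> ImpulseResponse:
    """Discretized delayed-exponential washout kernel, unit area.

    Kernel weights are the exact per-bin integrals of the continuous
    response, so no quadrature error enters; the truncated tail mass is
    folded back in by the final normalization.  ``n0_delay`` is the number
    of whole sampling intervals inside the transport delay.
    """
    tau = cfg.tau_w
    support = cfg.support_duration
    if support is None:
        support = cfg.delay + 8.0 * tau
    elif support < cfg.delay + 5.0 * tau:
        warnings.warn(
            f"support_duration={support}s truncates the kernel before "
            f"5 tau_w ({cfg.delay + 5 * tau:.1f}s); mass will be folded "
            "into the normalization", stacklevel=2)
    n = max(1, int(np.ceil(support / cfg.dt)))
    edges = cfg.dt * np.arange(n + 1)
    # integral of (1/tau) exp(-(t-delay)/tau) over [a, b) intersect [delay, inf)
    lo = np.maximum(edges[:-1], cfg.delay)
    hi = np.maximum(edges[1:], cfg.delay)
    h = np.exp(-(lo - cfg.delay) / tau) - np.exp(-(hi - cfg.delay) / tau)
    n0 = int(round(cfg.delay / cfg.dt))
    h[:n0] = 0.0
    h = h / h.sum()
    return ImpulseResponse(cfg.dt, h, n0_delay=n0)


def synth_pulse_train(cfg: PulseTrainConfig, n_samples: int, dt: float,
                      ) -> TimeSeries:
    """Rectangular pulse train sampled on the standard grid.

    Sample k is on when its interval start ``k*dt`` falls inside a pulse.
    Consecutive pulses must not overlap (guaranteed for duty < 1).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    period = 1.0 / cfg.frequency
    width = cfg.duty * period
    last_end = cfg.start_time + (cfg.n_pulses - 1) * period + width
    if cfg.n_pulses and last_end > n_samples * dt:
        raise ValueError(
            f"pulse train extends to {last_end:.2f}s but the record is "
            f"{n_samples * dt:.2f}s long")
    u = np.zeros(n_samples)
    eps = 1e-9 * dt
    for j in range(cfg.n_pulses):
        t_on = cfg.start_time + j * period
        k0 = int(np.ceil((t_on - eps) / dt))
        k1 = int(np.ceil((t_on + width - eps) / dt))
        u[k0:k1] = cfg.amplitude
    return TimeSeries(dt, u)


def add_noise(y: TimeSeries, cfg: NoiseConfig) -> TimeSeries:
    """Additive Gaussian noise, seeded and reproducible."""
    if cfg.level == 0:
        return y.with_values(y.values.copy())
    if cfg.reference == "peak":
        ref = np.max(np.abs(y.values))
    else:
        ref = float(np.sqrt(np.mean(y.values ** 2)))
    sigma = cfg.level / 100.0 * ref
    rng = np.random.default_rng(cfg.seed)
    return y.with_values(y.values + rng.normal(0.0, sigma, len(y)))


@dataclass(frozen=True)
class BenchmarkInstance:
    """One virtual experiment: truth, clean and noisy records, kernel."""

    u_true: TimeSeries
    y_clean: TimeSeries
    y_noisy: TimeSeries
    h: ImpulseResponse
    flow: float
    frequency: float
    noise_pct: float
    seed: int


#: Record lengths, in samples at 10 Hz, for the named presets.  "full" is
#: a one-hour virtual experiment; "reduced" a ten-minute desk-scale run;
#: "tiny" a smoke-test size.
PRESET_SAMPLES = {"full": 36_000, "reduced": 6_000, "tiny": 1_200}

DEFAULT_FLOWS = (250.0, 500.0)
DEFAULT_FREQUENCIES = (0.1, 0.2, 0.5, 1.0, 2.0)
DEFAULT_NOISE_LEVELS = (0.01, 0.1, 1.0, 2.0, 5.0, 10.0)


def make_benchmark_suite(flows=DEFAULT_FLOWS,
                         frequencies=DEFAULT_FREQUENCIES,
                         noise_levels=DEFAULT_NOISE_LEVELS,
                         seed: int = 0,
                         preset: str = "reduced",
                         n_samples: int | None = None,
                         dt: float = 0.1,
                         volume: float = 28.0,
                         delay: float = 1.0,
                         amplitude: float = 1.0,
                         ) -> list[BenchmarkInstance]:
    """Grid of virtual experiments over flow x frequency x noise level.

    Every instance uses a three-pulse input with duty 0.5.  One master
    seed fans out per-instance seeds deterministically, so the suite is
    reproducible as a whole and each instance in isolation.
    """
    if n_samples is None:
        n_samples = PRESET_SAMPLES[preset]
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(flows) * len(frequencies) * len(noise_levels))
    instances = []
    i = 0
    for flow in flows:
        cfg = ChamberConfig(volume=volume, flow=flow, delay=delay, dt=dt)
        h = synth_impulse_response(cfg)
        for freq in frequencies:
            pulses = PulseTrainConfig(frequency=freq, n_pulses=3,
                                      amplitude=amplitude, duty=0.5,
                                      start_time=5.0)
            u = synth_pulse_train(pulses, n_samples, dt)
            y_clean = forward_convolve(u, h)
            for level in noise_levels:
                inst_seed = int(child_seeds[i]) % (2 ** 31)
                i += 1
                y_noisy = add_noise(y_clean,
                                    NoiseConfig(level=level, seed=inst_seed))
                instances.append(BenchmarkInstance(
                    u_true=u, y_clean=y_clean, y_noisy=y_noisy, h=h,
                    flow=flow, frequency=freq, noise_pct=level,
                    seed=inst_seed))
    return instances
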