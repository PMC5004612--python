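"""Discrete forward model for linear time-invariant measurement systems.

A gas analyzer downstream of a flow-through respirometry chamber does not
see the animal's instantaneous gas exchange ``u(t)``; it sees a smeared
version ``y(t)``, the convolution of ``u`` with the chamber's impulse
response ``h``.  Sampling at interval ``dt`` turns the convolution into a
lower-triangular Toeplitz system ``y = H u``, where the first column of
``H`` is the discretized kernel.  This module provides the domain types
(:class:`TimeSeries`, :class:`ImpulseResponse`, :class:`ConvolutionOperator`,
:class:`RegularizerSpec`) and the constructors that the solver modules
build on.

Conventions
-----------
* 0-based sample indices; sample ``k`` represents the average of the
  continuous signal over the half-open interval ``[k*dt, (k+1)*dt)``.
* Inputs before time zero are assumed zero (causal system at rest).
* A kernel's support ends where its recording ends; no tail is
  extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import DegenerateKernelError, SamplingError

#: Largest N for which a dense N x N operator realization is materialized.
DENSE_CAP = 20_000

#: Leading kernel samples with |h| <= DELAY_THRESHOLD * max|h| count as
#: transport-delay zeros.  Recorded kernels carry baseline noise, so the
#: threshold is relative, not exact zero.
DELAY_THRESHOLD = 1e-3

_REG_KINDS = ("identity", "first_difference", "second_difference")


@dataclass(frozen=True, eq=False)
class TimeSeries:
    """Uniformly sampled real-valued signal.

    Parameters
    ----------
    dt : float
        Sampling interval in seconds, strictly positive.
    values : numpy.ndarray
        Ordered samples; sample ``k`` covers ``[t0 + k*dt, t0 + (k+1)*dt)``.
    t0 : float
        Time of the first sample, seconds.
    """

    dt: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise SamplingError(f"sampling interval must be positive, got {self.dt}")
        v = np.atleast_1d(np.asarray(self.values, dtype=float))
        if v.ndim != 1 or v.size == 0:
            raise SamplingError("values must be a non-empty 1-D sequence")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Left edge of every sampling interval."""
        return self.t0 + self.dt * np.arange(self.values.size)

    def with_values(self, values: np.ndarray, t0: float | None = None) -> "TimeSeries":
        """Copy carrying new samples (and optionally a new origin)."""
        return TimeSeries(self.dt, np.asarray(values, dtype=float),
                          self.t0 if t0 is None else t0)


@dataclass(frozen=True, eq=False)
class ImpulseResponse:
    """Finite-support discretized system kernel.

    ``h[k]`` is the integral of the continuous impulse response over the
    k-th sampling interval.  ``n0_delay`` counts the leading zero samples
    caused by the transport delay between chamber and analyzer; those
    entries are exactly zero.  The kernel is considered fully washed out
    after ``support_len = len(h)`` samples.
    """

    dt: float
    h: np.ndarray
    n0_delay: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise SamplingError(f"sampling interval must be positive, got {self.dt}")
        h = np.atleast_1d(np.asarray(self.h, dtype=float))
        if h.size == 0 or not np.all(np.isfinite(h)):
            raise DegenerateKernelError("kernel must be non-empty and finite")
        if not np.any(h):
            raise DegenerateKernelError("kernel is identically zero")
        if not 0 <= self.n0_delay <= h.size:
            raise ValueError(f"n0_delay={self.n0_delay} outside [0, {h.size}]")
        if np.any(h[: self.n0_delay] != 0.0):
            raise ValueError("the first n0_delay kernel samples must be exactly zero")
        if self.n0_delay < h.size and h[self.n0_delay] == 0.0:
            raise ValueError("kernel sample at index n0_delay must be nonzero")
        object.__setattr__(self, "h", h)

    @property
    def support_len(self) -> int:
        return self.h.size

    def normalized(self) -> "ImpulseResponse":
        """Unit-area copy (sum(h) == 1)."""
        s = self.h.sum()
        if s == 0:
            raise DegenerateKernelError("kernel has zero total area; cannot normalize")
        return ImpulseResponse(self.dt, self.h / s, self.n0_delay)


@dataclass(frozen=True)
class RegularizerSpec:
    """Choice of roughness penalty ``gamma * ||Q u||^2``.

    kind
        ``identity`` penalizes solution magnitude, ``first_difference``
        slope, ``second_difference`` curvature (the usual default for
        respirometry; switch to first differences when sharp input
        transitions must survive).
    gamma
        Nonnegative weight balancing data fidelity against smoothness.
    """

    kind: str = "second_difference"
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _REG_KINDS:
            raise ValueError(f"kind must be one of {_REG_KINDS}, got {self.kind!r}")
        if not self.gamma >= 0:
            raise ValueError(f"gamma must be nonnegative, got {self.gamma}")


class ConvolutionOperator:
    """Lower-triangular Toeplitz forward map y = H u.

    ``H[i, j] = h[i - j]`` for ``0 <= i - j < support_len`` and zero
    otherwise.  A dense realization is available up to :data:`DENSE_CAP`;
    matrix-free application (direct causal convolution) works for any N.
    """

    def __init__(self, h: ImpulseResponse, n: int):
        if n < 1:
            raise ValueError(f"output length must be >= 1, got {n}")
        self.h = h
        self.n = n
        self._dense: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n, self.n)

    def apply(self, u: np.ndarray) -> np.ndarray:
        """Causal convolution of ``u`` with the kernel, truncated to N."""
        u = np.asarray(u, dtype=float)
        if u.shape != (self.n,):
            raise ValueError(f"expected input of length {self.n}, got {u.shape}")
        return np.convolve(u, self.h.h)[: self.n]

    def __matmul__(self, u: np.ndarray) -> np.ndarray:
        return self.apply(u)

    def dense(self) -> np.ndarray:
        """Explicit N x N matrix; cached. Refuses N beyond DENSE_CAP."""
        if self._dense is None:
            if self.n > DENSE_CAP:
                raise ValueError(
                    f"dense realization capped at N={DENSE_CAP}; "
                    "use apply() for matrix-free application")
            col = np.zeros(self.n)
            k = min(self.n, self.h.support_len)
            col[:k] = self.h.h[:k]
            row = np.zeros(self.n)
            row[0] = col[0]
            self._dense = scipy.linalg.toeplitz(col, row)
        return self._dense


def discretize_impulse_response(raw: TimeSeries, normalize: bool = True,
                                delay_threshold: float = DELAY_THRESHOLD,
                                ) -> ImpulseResponse:
    """Turn a recorded calibration-pulse response into a discrete kernel.

    Each kernel weight is the rectangle-rule integral of the recording over
    one sampling interval, ``h[k] = raw.values[k] * dt``.  Leading samples
    whose magnitude is at most ``delay_threshold * max|h|`` are treated as
    transport-delay zeros and forced to exactly zero.  With ``normalize``
    the kernel is scaled to unit area so that totals are conserved by the
    forward model.
    """
    h = raw.values * raw.dt
    peak = np.max(np.abs(h))
    if peak == 0:
        raise DegenerateKernelError("recorded response is identically zero")
    small = np.abs(h) <= delay_threshold * peak
    n0 = 0
    while n0 < h.size and small[n0]:
        n0 += 1
    h = h.copy()
    h[:n0] = 0.0
    if normalize:
        area = h.sum()
        if area == 0:
            raise DegenerateKernelError("response has zero net area; cannot normalize")
        h = h / area
    return ImpulseResponse(raw.dt, h, n0_delay=n0)


def build_convolution_operator(h: ImpulseResponse, n: int) -> ConvolutionOperator:
    """Forward map for an output record of length ``n``."""
    return ConvolutionOperator(h, n)


def forward_convolve(u: TimeSeries, h: ImpulseResponse) -> TimeSeries:
    """Measured output produced by input ``u`` through kernel ``h``.

    Causal: inputs before time zero are zero; the output has the same
    length and sampling as ``u``.
    """
    if abs(u.dt - h.dt) > 1e-9 * max(u.dt, h.dt):
        raise SamplingError(
            f"input sampled at dt={u.dt} but kernel at dt={h.dt}")
    y = np.convolve(u.values, h.h)[: len(u)]
    return u.with_values(y)


def build_regularizer(spec: RegularizerSpec, n: int) -> np.ndarray:
    """Dense N x N penalty operator Q for the requested difference order.

    identity -> I; first_difference -> lower-triangular Toeplitz with first
    column (1, -1, 0, ...); second_difference -> (1, -2, 1, 0, ...).
    """
    if spec.kind == "identity":
        if n < 1:
            raise ValueError("identity regularizer needs N >= 1")
        return np.eye(n)
    stencil = (1.0, -1.0) if spec.kind == "first_difference" else (1.0, -2.0, 1.0)
    if n < len(stencil):
        raise ValueError(
            f"{spec.kind} regularizer needs N >= {len(stencil)}, got {n}")
    col = np.zeros(n)
    col[: len(stencil)] = stencil
    row = np.zeros(n)
    row[0] = col[0]
    return scipy.linalg.toeplitz(col, row)
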