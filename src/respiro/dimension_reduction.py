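"""Dimension-reduction deconvolution: projected least squares with
sliding-average reconstruction.

Instead of penalizing roughness, this method regularizes by constraining
the input to be constant over windows of ``m`` consecutive samples.  With
``L`` the N x n block-indicator matrix of that constraint (n = N/m), the
projected problem ``min_v ||H L v - y||`` is far better conditioned than
the original system — columns of ``HL`` are sums of m neighboring columns
of the Toeplitz operator, which breaks their near linear dependence — and
is solved by ordinary least squares.  The lifted solution

    u_hat = L v = L (L'H'HL)^{-1} L'H' y  =:  M y

is piecewise constant, so it cannot track changes inside a window and
shows spurious jumps at window edges.  The sliding average removes both
artifacts: for each shift k = 0..m-1, shift the data down by k (zeros
enter at the top; the system is at rest before time zero), solve, shift
the estimate back up, and average the m solutions.  Equivalently
``u_hat = M_bar y`` with ``M_bar = (1/m) sum_k S_k' M S_k`` built from
lower shift matrices ``S_k`` — each term a shifted submatrix of M.

Transport delay makes the first ``n0_delay`` kernel samples zero, which
zeroes rows and columns of ``H`` and can make ``HL`` rank deficient when
``m <= n0_delay``.  Two remedies are provided: trim the delay from both
kernel and data (:func:`eliminate_delay` — this does not change the
solution), or add a ridge term to the projected normal equations
(:func:`dr_solve_regularized`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.linalg

from .errors import SingularSystemError
from .signal_model import (ConvolutionOperator, ImpulseResponse,
                           RegularizerSpec, TimeSeries, build_regularizer)

#: Relative singular-value / pivot threshold used for numerical rank.
RANK_TOL = 1e-10


@dataclass(frozen=True)
class ProjectionSpec:
    """Configuration of the piecewise-constant projection.

    m
        Window width in samples; m=1 reduces the method to plain least
        squares on the full system.  Useful values in practice fall
        roughly between 4 and 30.
    use_averaging
        Apply the m-fold shift-and-average reconstruction (recommended).
    gamma, reg_kind
        Optional ridge term ``gamma ||Q v||^2`` added to the projected
        problem; Q is built at the projected dimension n.
    """

    m: int
    use_averaging: bool = True
    gamma: float = 0.0
    reg_kind: str = "second_difference"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"window width m must be >= 1, got {self.m}")
        if not self.gamma >= 0:
            raise ValueError(f"gamma must be nonnegative, got {self.gamma}")


class Projection(NamedTuple):
    """Block-indicator matrix plus padding bookkeeping."""

    L: np.ndarray       # (n_padded, n) block indicator
    n: int              # projected dimension
    pad: int            # zero samples appended so m divides the length
    n_padded: int


@dataclass
class DRSolution:
    """Estimated input plus bookkeeping (mirrors TikhonovSolution)."""

    u_hat: TimeSeries
    spec: ProjectionSpec
    diagnostics: dict = field(default_factory=dict)


def build_projection(n_samples: int, m: int) -> Projection:
    """Indicator matrix mapping window values to samples.

    Entry (i, j) is 1 iff sample i falls in window j of m consecutive
    samples.  If m does not divide ``n_samples`` the length is padded up
    to the next multiple and the padding recorded.  Columns are orthogonal
    with squared norm m, so L'L = m I.
    """
    if n_samples < 1 or m < 1:
        raise ValueError("n_samples and m must be positive")
    pad = (-n_samples) % m
    n_padded = n_samples + pad
    n = n_padded // m
    L = np.kron(np.eye(n), np.ones((m, 1)))
    return Projection(L=L, n=n, pad=pad, n_padded=n_padded)


def shift_matrix(n: int, k: int) -> np.ndarray:
    """Lower shift by k: (S x)[i] = x[i-k], zeros entering at the top."""
    if not 0 <= k <= n:
        raise ValueError(f"shift k must be in [0, {n}], got {k}")
    return np.eye(n, k=-k)


def reconstruction_matrix(h: ImpulseResponse, n_samples: int, m: int,
                          gamma: float = 0.0,
                          reg_kind: str = "second_difference") -> np.ndarray:
    """Explicit dense solve-and-lift map M = L (L'H'HL + gamma Q'Q)^{-1} L'H'.

    Built literally from its definition; intended for analysis and as a
    cross-check on small problems.  Production solvers use a factorized,
    matrix-free-friendly path instead.  Requires m | n_samples.
    """
    if n_samples % m:
        raise ValueError("explicit reconstruction requires m to divide n_samples")
    proj = build_projection(n_samples, m)
    H = ConvolutionOperator(h, n_samples).dense()
    A = H @ proj.L
    G = A.T @ A
    if gamma > 0:
        Q = build_regularizer(RegularizerSpec(reg_kind, gamma), proj.n)
        G = G + gamma * (Q.T @ Q)
    elif np.linalg.matrix_rank(A, tol=RANK_TOL * np.linalg.norm(A, 2)) < proj.n:
        raise SingularSystemError(
            "HL is rank deficient; trim the transport delay "
            "(eliminate_delay) or add a ridge term (gamma > 0)")
    return proj.L @ np.linalg.solve(G, A.T)


def averaged_reconstruction_matrix(h: ImpulseResponse, n_samples: int, m: int,
                                   gamma: float = 0.0,
                                   reg_kind: str = "second_difference",
                                   ) -> np.ndarray:
    """Explicit dense sliding-average map M_bar = (1/m) sum_k S_k' M S_k."""
    M = reconstruction_matrix(h, n_samples, m, gamma, reg_kind)
    n = M.shape[0]
    acc = np.zeros_like(M)
    for k in range(m):
        S = shift_matrix(n, k)
        acc += S.T @ M @ S
    return acc / m


class _DRFactor:
    """Pivoted QR of [HL; sqrt(gamma) Q], reusable across shifts and blocks."""

    def __init__(self, h: ImpulseResponse, n_samples: int, spec: ProjectionSpec):
        self.proj = build_projection(n_samples, spec.m)
        # Column j of HL is the kernel convolved with window j's indicator:
        # the m-sample moving sum of h, placed at row j*m.
        w = np.convolve(h.h, np.ones(spec.m))
        A = np.zeros((self.proj.n_padded, self.proj.n))
        for j in range(self.proj.n):
            r0 = j * spec.m
            k = min(w.size, self.proj.n_padded - r0)
            A[r0:r0 + k, j] = w[:k]
        self.A = A
        if spec.gamma > 0:
            order = {"identity": 1, "first_difference": 2,
                     "second_difference": 3}[spec.reg_kind]
            kind = spec.reg_kind if self.proj.n >= order else "identity"
            Q = build_regularizer(RegularizerSpec(kind, spec.gamma), self.proj.n)
            stacked = np.vstack([A, np.sqrt(spec.gamma) * Q])
        else:
            stacked = A
        q_fac, self.R, self.piv = scipy.linalg.qr(stacked, mode="economic",
                                                  pivoting=True)
        diag = np.abs(np.diag(self.R))
        if spec.gamma == 0.0 and (diag.min() <= RANK_TOL * diag.max()):
            raise SingularSystemError(
                "HL is rank deficient (transport-delay zeros with window "
                f"width m={spec.m}); trim the delay (eliminate_delay) or "
                "add a ridge term (dr_solve_regularized with gamma > 0)")
        self.Q1T = np.ascontiguousarray(q_fac[:self.proj.n_padded].T)

    def solve_window_values(self, y_padded: np.ndarray) -> np.ndarray:
        z = scipy.linalg.solve_triangular(self.R, self.Q1T @ y_padded)
        v = np.empty_like(z)
        v[self.piv] = z
        return v


_FACTOR_CACHE: dict[tuple, _DRFactor] = {}
_FACTOR_CACHE_MAX = 8


def _factor(h: ImpulseResponse, n_samples: int, spec: ProjectionSpec) -> _DRFactor:
    key = (h.h.tobytes(), h.dt, n_samples, spec.m, float(spec.gamma),
           spec.reg_kind if spec.gamma > 0 else None)
    fac = _FACTOR_CACHE.get(key)
    if fac is None:
        fac = _DRFactor(h, n_samples, spec)
        if len(_FACTOR_CACHE) >= _FACTOR_CACHE_MAX:
            _FACTOR_CACHE.pop(next(iter(_FACTOR_CACHE)))
        _FACTOR_CACHE[key] = fac
    return fac


def _solve_core(y: np.ndarray, h: ImpulseResponse, spec: ProjectionSpec,
                averaging: bool) -> np.ndarray:
    fac = _factor(h, y.size, spec)
    y_pad = np.concatenate([y, np.zeros(fac.proj.pad)]) if fac.proj.pad else y
    n_pad = fac.proj.n_padded
    shifts = spec.m if averaging else 1
    acc = np.zeros(n_pad)
    for k in range(shifts):
        if k:
            y_k = np.concatenate([np.zeros(k), y_pad[:n_pad - k]])
        else:
            y_k = y_pad
        v = fac.solve_window_values(y_k)
        u_k = np.repeat(v, spec.m)
        if k:  # shift the estimate back up, zeros entering at the bottom
            u_k = np.concatenate([u_k[k:], np.zeros(k)])
        acc += u_k
    u = acc / shifts
    return u[:y.size]


def _package(y: TimeSeries, h: ImpulseResponse, spec: ProjectionSpec,
             u: np.ndarray) -> DRSolution:
    n = len(y)
    flagged = min(h.support_len, n)
    mask = np.zeros(n, dtype=bool)
    mask[n - flagged:] = True
    return DRSolution(u_hat=y.with_values(u), spec=spec,
                      diagnostics={"flagged_tail": flagged,
                                   "low_confidence": mask,
                                   "n_blocks": 1})


def dr_solve_single(y: TimeSeries, h: ImpulseResponse,
                    spec: ProjectionSpec) -> DRSolution:
    """Single projected solve without averaging; estimate is piecewise
    constant on windows of m."""
    u = _solve_core(y.values, h, spec, averaging=False)
    return _package(y, h, spec, u)


def dr_solve_averaged(y: TimeSeries, h: ImpulseResponse,
                      spec: ProjectionSpec) -> DRSolution:
    """Sliding-average reconstruction: mean of the m shifted projected
    solves.  The trailing kernel-support samples are flagged
    low-confidence (the shifts cannot pin them down)."""
    u = _solve_core(y.values, h, spec, averaging=True)
    return _package(y, h, spec, u)


def dr_solve_regularized(y: TimeSeries, h: ImpulseResponse,
                         spec: ProjectionSpec) -> DRSolution:
    """Ridge-stabilized projected solve (remedy for a singular HL).

    Identical to :func:`dr_solve_averaged` / :func:`dr_solve_single`
    (per ``spec.use_averaging``) with the projected normal matrix replaced
    by ``L'H'HL + gamma Q'Q``; requires gamma > 0.
    """
    if not spec.gamma > 0:
        raise ValueError("dr_solve_regularized requires gamma > 0; "
                         "use dr_solve_single for the plain solve")
    u = _solve_core(y.values, h, spec, averaging=spec.use_averaging)
    return _package(y, h, spec, u)


def eliminate_delay(y: TimeSeries, h: ImpulseResponse,
                    ) -> tuple[TimeSeries, ImpulseResponse, int]:
    """Remove the transport delay from both kernel and data.

    Drops the ``n0_delay`` leading zeros of the kernel and the same number
    of leading output samples; the returned offset re-aligns recovered
    inputs (the trimmed system estimates inputs 0..N-n0_delay-1 of the
    original record).  The solution itself is unchanged by this trim — it
    only removes the structural singularity.
    """
    n0 = h.n0_delay
    if n0 == 0:
        warnings.warn("kernel has no leading delay zeros; nothing to trim",
                      stacklevel=2)
        return y, h, 0
    if len(y) <= n0:
        raise ValueError("record shorter than the transport delay")
    h_trim = ImpulseResponse(h.dt, h.h[n0:], n0_delay=0)
    y_trim = TimeSeries(y.dt, y.values[n0:], t0=y.t0 + n0 * y.dt)
    return y_trim, h_trim, n0


def dr_solve_sequential(y: TimeSeries, h: ImpulseResponse,
                        spec: ProjectionSpec, plan) -> DRSolution:
    """Partitioned dimension-reduction solve for long records.

    Same accept/subtract/advance loop as the sequential Tikhonov scheme,
    with the block solved by the (averaged) projected method; the block
    factorization is computed once and reused for all equal-sized blocks.
    ``plan`` is a :class:`respiro.tikhonov.PartitionPlan`.
    """
    n_tot = len(y)
    if plan.n_overlap < h.support_len - 1:
        warnings.warn(
            f"n_overlap={plan.n_overlap} is smaller than the kernel "
            f"contribution window ({h.support_len - 1}); accepted inputs "
            "will be biased near block boundaries", stacklevel=2)
    if plan.block >= n_tot:
        sol = (dr_solve_averaged if spec.use_averaging else dr_solve_single)(
            y, h, spec)
        return sol

    y_work = y.values.copy()
    u_hat = np.zeros(n_tot)
    n_blocks = 0
    s = 0
    while n_tot - s > plan.block:
        yb = y_work[s:s + plan.block]
        ub = _solve_core(yb, h, spec, averaging=spec.use_averaging)
        u_hat[s:s + plan.n] = ub[:plan.n]
        contrib = np.convolve(ub[:plan.n], h.h)
        end = min(n_tot, s + contrib.size)
        y_work[s:end] -= contrib[:end - s]
        s += plan.n
        n_blocks += 1
    ub = _solve_core(y_work[s:], h, spec, averaging=spec.use_averaging)
    u_hat[s:] = ub
    n_blocks += 1

    flagged = min(max(plan.n_overlap, h.support_len), n_tot)
    mask = np.zeros(n_tot, dtype=bool)
    mask[n_tot - flagged:] = True
    return DRSolution(u_hat=y.with_values(u_hat), spec=spec,
                      diagnostics={"flagged_tail": flagged,
                                   "low_confidence": mask,
                                   "n_blocks": n_blocks})


@dataclass
class MSweepResult:
    best_m: int
    table: "object"  # pandas.DataFrame: m, pearson_r


def sweep_m(y_cal: TimeSeries, u_true_cal: TimeSeries, h: ImpulseResponse,
            ms=tuple(range(1, 33)), use_averaging: bool = True,
            gamma: float = 0.0, reg_kind: str = "second_difference",
            plan=None) -> MSweepResult:
    """Grid-sweep calibration of the window width m.

    Window widths whose projected system is singular (and no ridge was
    requested) score NaN and are skipped when picking the best.
    """
    import pandas as pd

    from .evaluation_io import pearson_correlation

    ms = list(ms)
    if not ms:
        raise ValueError("m grid must be non-empty")
    rows = []
    for m in ms:
        spec = ProjectionSpec(m=m, use_averaging=use_averaging,
                              gamma=gamma, reg_kind=reg_kind)
        try:
            if plan is None:
                sol = (dr_solve_averaged if use_averaging
                       else dr_solve_single)(y_cal, h, spec)
            else:
                sol = dr_solve_sequential(y_cal, h, spec, plan)
        except SingularSystemError:
            rows.append({"m": m, "pearson_r": np.nan})
            continue
        ok = ~sol.diagnostics["low_confidence"]
        r = pearson_correlation(sol.u_hat.values[ok], u_true_cal.values[ok])
        rows.append({"m": m, "pearson_r": r})
    table = pd.DataFrame(rows)
    if table["pearson_r"].isna().all():
        raise SingularSystemError(
            "every window width in the grid yielded a singular system")
    best = table.loc[table["pearson_r"].idxmax()]
    return MSweepResult(best_m=int(best["m"]), table=table)
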