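"""Tikhonov deconvolution: full-data solver and the sequential extension.

The regularized estimate of the input is

    u_hat = argmin_u ||H u - y||^2 + gamma ||Q u||^2
          = (H'H + gamma Q'Q)^{-1} H' y,

computed here through a QR factorization of the stacked matrix
``[H; sqrt(gamma) Q]`` rather than the explicit inverse — mathematically
identical, numerically stabler.

For recordings too long to treat as one dense system, the sequential
scheme exploits the finite kernel support: the input over ``n`` samples
only influences the following ``n + n_overlap`` output samples (with
``n_overlap`` covering the kernel's contribution window).  Each cycle
solves a block of ``n + n_overlap`` points, accepts the first ``n``
estimated inputs, subtracts their forward contribution from the remaining
data, and advances.  Equal-sized blocks share one matrix factorization, so
the per-cycle cost is a pair of triangular solves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import IllConditionedError
from .signal_model import (ConvolutionOperator, ImpulseResponse,
                           RegularizerSpec, TimeSeries, build_regularizer)

#: Condition-number cap above which an unregularized (gamma = 0) solve is
#: refused.
COND_CAP = 1e10


@dataclass(frozen=True)
class PartitionPlan:
    """Blocking scheme for sequential solves.

    n
        Inputs accepted per cycle.
    n_overlap
        Look-ahead samples appended to each block; should cover the
        kernel's contribution window (at least ``support_len - 1``).

    The defaults (n=780, n_overlap=720 at 10 Hz, i.e. blocks of 1500
    samples) match the block sizes used in the validation experiments this
    package reproduces; scale them proportionally for other sampling rates.
    """

    n: int = 780
    n_overlap: int = 720

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.n_overlap < 0:
            raise ValueError(f"n_overlap must be >= 0, got {self.n_overlap}")

    @property
    def block(self) -> int:
        return self.n + self.n_overlap


@dataclass
class TikhonovSolution:
    """Estimated input plus bookkeeping.

    diagnostics keys: ``residual_norms`` (per-cycle ||H u_b - y_b|| over
    each cycle's accepted samples),
    ``n_blocks``, ``flagged_tail`` (number of trailing low-confidence
    samples), ``low_confidence`` (boolean mask over the estimate).
    """

    u_hat: TimeSeries
    gamma: float
    regularizer: RegularizerSpec
    diagnostics: dict = field(default_factory=dict)


class _StackedFactor:
    """QR factorization of [H; sqrt(gamma) Q], reusable across solves."""

    def __init__(self, h: ImpulseResponse, n: int, reg: RegularizerSpec):
        self.H = ConvolutionOperator(h, n).dense()
        self.n = n
        if reg.gamma == 0.0:
            cond = np.linalg.cond(self.H)
            if cond > COND_CAP:
                raise IllConditionedError(
                    f"unregularized solve refused: cond(H) ~ {cond:.3g} exceeds "
                    f"{COND_CAP:.0e}; set gamma > 0")
            stacked = self.H
        else:
            order = {"identity": 1, "first_difference": 2,
                     "second_difference": 3}[reg.kind]
            q_spec = reg if n >= order else RegularizerSpec("identity", reg.gamma)
            Q = build_regularizer(q_spec, n)
            stacked = np.vstack([self.H, np.sqrt(reg.gamma) * Q])
        q_fac, self.R = scipy.linalg.qr(stacked, mode="economic")
        self.Q1T = np.ascontiguousarray(q_fac[:n].T)  # rows matching the data block

    def solve(self, y: np.ndarray) -> np.ndarray:
        return scipy.linalg.solve_triangular(self.R, self.Q1T @ y)


_FACTOR_CACHE: dict[tuple, _StackedFactor] = {}
_FACTOR_CACHE_MAX = 8


def _factor(h: ImpulseResponse, n: int, reg: RegularizerSpec) -> _StackedFactor:
    key = (h.h.tobytes(), h.dt, n, reg.kind, float(reg.gamma))
    fac = _FACTOR_CACHE.get(key)
    if fac is None:
        fac = _StackedFactor(h, n, reg)
        if len(_FACTOR_CACHE) >= _FACTOR_CACHE_MAX:
            _FACTOR_CACHE.pop(next(iter(_FACTOR_CACHE)))
        _FACTOR_CACHE[key] = fac
    return fac


def tikhonov_solve_full(y: TimeSeries, h: ImpulseResponse,
                        reg: RegularizerSpec) -> TikhonovSolution:
    """Solve the whole record as one regularized least-squares system.

    Suitable while the dense N x N operator fits comfortably in memory;
    for longer records use :func:`tikhonov_solve_sequential`.
    """
    n = len(y)
    fac = _factor(h, n, reg)
    u = fac.solve(y.values)
    resid = float(np.linalg.norm(fac.H @ u - y.values))
    return TikhonovSolution(
        u_hat=y.with_values(u), gamma=reg.gamma, regularizer=reg,
        diagnostics={"residual_norms": [resid], "n_blocks": 1,
                     "flagged_tail": 0,
                     "low_confidence": np.zeros(n, dtype=bool)})


def tikhonov_solve_sequential(y: TimeSeries, h: ImpulseResponse,
                              reg: RegularizerSpec,
                              plan: PartitionPlan) -> TikhonovSolution:
    """Partitioned Tikhonov estimation for arbitrarily long records.

    Per cycle: solve the current ``n + n_overlap``-point block, accept the
    first ``n`` estimated inputs, forward-convolve them and subtract their
    contribution from the not-yet-processed data, advance by ``n``.  The
    final (possibly smaller) block is solved whole; its last ``n_overlap``
    estimates are kept but flagged low-confidence, since the data that
    would pin them down was never recorded.
    """
    n_tot = len(y)
    if plan.n_overlap < h.support_len - 1:
        warnings.warn(
            f"n_overlap={plan.n_overlap} is smaller than the kernel "
            f"contribution window ({h.support_len - 1}); accepted inputs "
            "will be biased near block boundaries", stacklevel=2)
    if plan.block >= n_tot:
        # Degenerate single-block plan: identical to the full solve.
        sol = tikhonov_solve_full(y, h, reg)
        flagged = min(plan.n_overlap, n_tot)
        mask = np.zeros(n_tot, dtype=bool)
        mask[n_tot - flagged:] = True
        sol.diagnostics["flagged_tail"] = flagged
        sol.diagnostics["low_confidence"] = mask
        return sol

    fac = _factor(h, plan.block, reg)
    y_work = y.values.copy()
    u_hat = np.zeros(n_tot)
    residuals: list[float] = []
    s = 0
    while n_tot - s > plan.block:
        yb = y_work[s:s + plan.block]
        ub = fac.solve(yb)
        # residual over the accepted samples only: the block tail is
        # re-estimated next cycle, so its misfit is not this cycle's.
        residuals.append(float(np.linalg.norm((fac.H @ ub - yb)[:plan.n])))
        accepted = ub[:plan.n]
        u_hat[s:s + plan.n] = accepted
        contrib = np.convolve(accepted, h.h)
        end = min(n_tot, s + contrib.size)
        y_work[s:end] -= contrib[:end - s]
        s += plan.n

    # Final block: everything that remains (<= block samples).
    rem = n_tot - s
    fac_tail = _factor(h, rem, reg) if rem != plan.block else fac
    yb = y_work[s:]
    ub = fac_tail.solve(yb)
    residuals.append(float(np.linalg.norm(fac_tail.H @ ub - yb)))
    u_hat[s:] = ub

    flagged = min(plan.n_overlap, rem)
    mask = np.zeros(n_tot, dtype=bool)
    mask[n_tot - flagged:] = True
    return TikhonovSolution(
        u_hat=y.with_values(u_hat), gamma=reg.gamma, regularizer=reg,
        diagnostics={"residual_norms": residuals,
                     "n_blocks": len(residuals),
                     "flagged_tail": flagged,
                     "low_confidence": mask})


@dataclass
class GammaSweepResult:
    best_gamma: float
    best_kind: str
    table: "object"  # pandas.DataFrame: kind, gamma, pearson_r


def sweep_gamma(y_cal: TimeSeries, u_true_cal: TimeSeries, h: ImpulseResponse,
                reg_kinds=("second_difference",),
                gammas=(1e-8, 1e-6, 1e-4, 1e-2, 1.0),
                plan: PartitionPlan | None = None) -> GammaSweepResult:
    """Grid-sweep calibration of the regularization weight.

    Given a calibration pair where the true input is known (a recorded
    injection pattern or simulator output), score every (kind, gamma)
    combination by the Pearson correlation between the recovered and true
    input on the unflagged region, and return the best.
    """
    import pandas as pd

    from .evaluation_io import pearson_correlation

    gammas = list(gammas)
    if not gammas:
        raise ValueError("gamma grid must be non-empty")
    rows = []
    for kind in reg_kinds:
        for g in gammas:
            reg = RegularizerSpec(kind, g)
            if plan is None:
                sol = tikhonov_solve_full(y_cal, h, reg)
            else:
                sol = tikhonov_solve_sequential(y_cal, h, reg, plan)
            ok = ~sol.diagnostics["low_confidence"]
            r = pearson_correlation(sol.u_hat.values[ok], u_true_cal.values[ok])
            rows.append({"kind": kind, "gamma": g, "pearson_r": r})
    table = pd.DataFrame(rows)
    best = table.loc[table["pearson_r"].idxmax()]
    return GammaSweepResult(best_gamma=float(best["gamma"]),
                            best_kind=str(best["kind"]), table=table)
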