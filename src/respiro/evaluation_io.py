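"""Metrics, plain-text signal formats, benchmark evaluation, and the CLI.

File conventions match the field's habit of exchanging gas-analyzer
records as headerless delimited text: signals are two columns (time,
concentration); recovered results are three columns (time, original,
corrected).  Default output names are ``Recovered_Tikhonov.txt`` and
``Recovered_DimentionReduction.txt`` — the second spelling is kept for
drop-in compatibility with existing workflows and is configurable.
"""

from __future__ import annotations

import re
import sys
from dataclasses import dataclass
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import dimension_reduction as dr
from . import simulator, tikhonov
from .errors import ConstantSeriesError, SamplingError
from .signal_model import ImpulseResponse, RegularizerSpec, TimeSeries, \
    discretize_impulse_response

#: Significant digits in text outputs.
OUTPUT_DIGITS = 9

_SPLIT = re.compile(r"[,\s]+")


@dataclass
class RecoveryReport:
    """Outcome of an input-recovery run (with known truth, when scoring)."""

    method: str
    params: dict
    pearson_r: float | None = None
    flagged_mask: np.ndarray | None = None
    grid: pd.DataFrame | None = None


def pearson_correlation(a, b, mask=None) -> float:
    """Product-moment correlation over the unmasked samples.

    Accepts :class:`TimeSeries` or arrays.  Raises
    :class:`ConstantSeriesError` when either side is constant on the
    evaluated region — a correlation of a flat trace is undefined, not 0.
    """
    av = np.asarray(a.values if isinstance(a, TimeSeries) else a, dtype=float)
    bv = np.asarray(b.values if isinstance(b, TimeSeries) else b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"length mismatch: {av.shape} vs {bv.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        av, bv = av[mask], bv[mask]
    if av.size < 2 or np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ConstantSeriesError(
            "Pearson correlation is undefined for constant series")
    return float(np.corrcoef(av, bv)[0, 1])


def read_signal_file(path) -> TimeSeries:
    """Parse a two-column (time, value) text record.

    Whitespace and comma delimiters are both accepted; the sampling
    interval is inferred from the median time step and steps must be
    uniform to 1e-6 relative tolerance.
    """
    times, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in _SPLIT.split(line) if p]
            if len(parts) < 2:
                raise SamplingError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise SamplingError(f"{path}:{lineno}: {exc}") from None
    if len(times) < 2:
        raise SamplingError(f"{path}: need at least two samples")
    t = np.asarray(times)
    steps = np.diff(t)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0)) + 2
        raise SamplingError(f"{path}:{bad}: time column is not increasing")
    dt = float(np.median(steps))
    if np.max(np.abs(steps - dt)) > 1e-6 * dt:
        bad = int(np.argmax(np.abs(steps - dt))) + 2
        raise SamplingError(
            f"{path}:{bad}: non-uniform sampling (step deviates from "
            f"median dt={dt:g} by more than 1e-6 relative)")
    return TimeSeries(dt, np.asarray(values), t0=float(t[0]))


def write_signal_file(path, ts: TimeSeries) -> None:
    """Two-column (time, value) text record at full working precision."""
    fmt = f"%.{OUTPUT_DIGITS}g"
    with open(path, "w") as fh:
        for t, v in zip(ts.times, ts.values):
            fh.write(f"{fmt % t}\t{fmt % v}\n")


def write_recovered_file(path, time, original, corrected) -> None:
    """Three-column (time, original signal, corrected signal) record."""
    time = np.asarray(time, dtype=float)
    original = np.asarray(original, dtype=float)
    corrected = np.asarray(corrected, dtype=float)
    if not time.shape == original.shape == corrected.shape:
        raise ValueError("time, original and corrected must share a length")
    fmt = f"%.{OUTPUT_DIGITS}g"
    with open(path, "w") as fh:
        for t, o, c in zip(time, original, corrected):
            fh.write(f"{fmt % t}\t{fmt % o}\t{fmt % c}\n")


def recover(y: TimeSeries, h: ImpulseResponse, method: str = "tikhonov",
            gamma: float = 1e-4, reg_kind: str = "second_difference",
            m: int = 8, averaging: bool = True, trim_delay: bool = True,
            plan: tikhonov.PartitionPlan | None = None,
            ) -> tuple[TimeSeries, RecoveryReport]:
    """Library entry point shared by both methods (and the CLI).

    For the dimension-reduction method the transport delay is trimmed
    first (the recommended singularity remedy) unless ``trim_delay`` is
    off; the recovered input is re-aligned to the original time base with
    the unestimated tail set to NaN and flagged.
    """
    if plan is None:
        plan = tikhonov.PartitionPlan()
    if method == "tikhonov":
        reg = RegularizerSpec(reg_kind, gamma)
        sol = tikhonov.tikhonov_solve_sequential(y, h, reg, plan)
        params = {"gamma": gamma, "reg_kind": reg_kind,
                  "block_n": plan.n, "block_overlap": plan.n_overlap}
        return sol.u_hat, RecoveryReport(method=method, params=params,
                                         flagged_mask=sol.diagnostics["low_confidence"])
    if method == "dr":
        offset = 0
        y_s, h_s = y, h
        if trim_delay and h.n0_delay > 0:
            y_s, h_s, offset = dr.eliminate_delay(y, h)
        spec = dr.ProjectionSpec(m=m, use_averaging=averaging, gamma=gamma
                                 if gamma and not trim_delay else 0.0,
                                 reg_kind=reg_kind)
        sol = dr.dr_solve_sequential(y_s, h_s, spec, plan)
        n = len(y)
        u = np.full(n, np.nan)
        u[:n - offset] = sol.u_hat.values
        mask = np.ones(n, dtype=bool)
        inner = ~sol.diagnostics["low_confidence"]
        mask[:n - offset] = ~inner
        params = {"m": m, "averaging": averaging, "trim_delay": trim_delay,
                  "gamma": spec.gamma, "block_n": plan.n,
                  "block_overlap": plan.n_overlap, "delay_offset": offset}
        return y.with_values(u), RecoveryReport(method=method, params=params,
                                                flagged_mask=mask)
    raise ValueError(f"unknown method {method!r}; expected 'tikhonov' or 'dr'")


def evaluate_suite(instances, gamma: float = 1e-4, m: int = 8,
                   reg_kind: str = "second_difference",
                   plan: tikhonov.PartitionPlan | None = None,
                   methods=("tikhonov", "dr")) -> pd.DataFrame:
    """Run both methods over a benchmark suite and score each recovery.

    Returns a table with one row per (instance, method): flow, frequency,
    noise level, method, and the Pearson correlation between the recovered
    and true input on the unflagged region.
    """
    rows = []
    for inst in instances:
        for method in methods:
            u_hat, report = recover(inst.y_noisy, inst.h, method=method,
                                    gamma=gamma, m=m, reg_kind=reg_kind,
                                    plan=plan)
            ok = ~report.flagged_mask
            r = pearson_correlation(u_hat.values[ok], inst.u_true.values[ok])
            rows.append({"flow": inst.flow, "frequency": inst.frequency,
                         "noise_pct": inst.noise_pct, "method": method,
                         "pearson_r": r})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Command-line interface
# ----------------------------------------------------------------------

DEFAULT_OUTPUT_NAMES = {"tikhonov": "Recovered_Tikhonov.txt",
                        "dr": "Recovered_DimentionReduction.txt"}


@click.group()
def cli() -> None:
    """Input estimation for flow-through respirometry records."""


@cli.command("recover")
@click.option("--impulse-response", "ir_path", required=True,
              type=click.Path(exists=True),
              help="Two-column recording of the calibration pulse response.")
@click.option("--data", "data_path", required=True,
              type=click.Path(exists=True),
              help="Two-column measured output (time, concentration).")
@click.option("--method", type=click.Choice(["tikhonov", "dr"]),
              default="tikhonov", show_default=True)
@click.option("--gamma", type=float, default=1e-4, show_default=True,
              help="Regularization weight (Tikhonov, or DR ridge).")
@click.option("--reg-kind", type=click.Choice(
    ["identity", "first_difference", "second_difference"]),
    default="second_difference", show_default=True)
@click.option("--m", "m", type=int, default=8, show_default=True,
              help="DR window width in samples.")
@click.option("--averaging/--no-averaging", default=True, show_default=True)
@click.option("--trim-delay/--no-trim-delay", default=True, show_default=True)
@click.option("--block-n", type=int, default=780, show_default=True)
@click.option("--block-overlap", type=int, default=720, show_default=True)
@click.option("--out", "out_path", type=click.Path(), default=None,
              help="Output path (default: the method's conventional name).")
def cli_recover(ir_path, data_path, method, gamma, reg_kind, m, averaging,
                trim_delay, block_n, block_overlap, out_path):
    """Recover the true input from a measured record."""
    raw_ir = read_signal_file(ir_path)
    y = read_signal_file(data_path)
    if abs(raw_ir.dt - y.dt) > 1e-9 * max(raw_ir.dt, y.dt):
        raise SamplingError(
            f"kernel sampled at dt={raw_ir.dt} but data at dt={y.dt}")
    h = discretize_impulse_response(raw_ir)
    plan = tikhonov.PartitionPlan(n=block_n, n_overlap=block_overlap)
    u_hat, report = recover(y, h, method=method, gamma=gamma,
                            reg_kind=reg_kind, m=m, averaging=averaging,
                            trim_delay=trim_delay, plan=plan)
    if out_path is None:
        out_path = DEFAULT_OUTPUT_NAMES[method]
    corrected = np.nan_to_num(u_hat.values, nan=0.0)
    write_recovered_file(out_path, y.times, y.values, corrected)
    click.echo(f"method={method} params={report.params}")
    click.echo(f"wrote {out_path}")


@cli.command("simulate")
@click.option("--preset", type=click.Choice(list(simulator.PRESET_SAMPLES)),
              default="reduced", show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out-dir", type=click.Path(), default="simulated",
              show_default=True)
@click.option("--flows", default="250,500", show_default=True)
@click.option("--frequencies", default="0.1,0.2,0.5,1,2", show_default=True)
@click.option("--noise-levels", default="0.01,0.1,1,2,5,10", show_default=True)
def cli_simulate(preset, seed, out_dir, flows, frequencies, noise_levels):
    """Write a suite of virtual experiments as two-column text files."""
    flows = [float(x) for x in flows.split(",")]
    freqs = [float(x) for x in frequencies.split(",")]
    levels = [float(x) for x in noise_levels.split(",")]
    suite = simulator.make_benchmark_suite(flows=flows, frequencies=freqs,
                                           noise_levels=levels, seed=seed,
                                           preset=preset)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written_kernels = set()
    for inst in suite:
        tag = f"flow{inst.flow:g}_f{inst.frequency:g}Hz_noise{inst.noise_pct:g}pct"
        write_signal_file(out / f"Data_{tag}.txt", inst.y_noisy)
        write_signal_file(out / f"Truth_{tag}.txt", inst.u_true)
        if inst.flow not in written_kernels:
            # analyzer-style recording: concentration samples, not bin areas
            ir = TimeSeries(inst.h.dt, inst.h.h / inst.h.dt)
            write_signal_file(out / f"ImpulseResponse_flow{inst.flow:g}.txt", ir)
            written_kernels.add(inst.flow)
    click.echo(f"wrote {len(suite)} instances to {out}")


@cli.command("tune")
@click.option("--impulse-response", "ir_path", required=True,
              type=click.Path(exists=True))
@click.option("--data", "data_path", required=True,
              type=click.Path(exists=True))
@click.option("--truth", "truth_path", required=True,
              type=click.Path(exists=True),
              help="Known true input of the calibration record.")
@click.option("--method", type=click.Choice(["tikhonov", "dr"]),
              default="tikhonov", show_default=True)
@click.option("--gammas", default="1e-8,1e-6,1e-4,1e-2,1", show_default=True)
@click.option("--ms", default="1,2,4,8,16,32", show_default=True)
def cli_tune(ir_path, data_path, truth_path, method, gammas, ms):
    """Sweep the tuning parameter against a calibration pair."""
    h = discretize_impulse_response(read_signal_file(ir_path))
    y = read_signal_file(data_path)
    u_true = read_signal_file(truth_path)
    if method == "tikhonov":
        res = tikhonov.sweep_gamma(
            y, u_true, h, gammas=[float(g) for g in gammas.split(",")])
        click.echo(res.table.to_string(index=False))
        click.echo(f"best: kind={res.best_kind} gamma={res.best_gamma:g}")
    else:
        y2, h2, _ = (dr.eliminate_delay(y, h) if h.n0_delay
                     else (y, h, 0))
        u2 = TimeSeries(u_true.dt, u_true.values[:len(y2)], t0=u_true.t0)
        res = dr.sweep_m(y2, u2, h2, ms=[int(x) for x in ms.split(",")])
        click.echo(res.table.to_string(index=False))
        click.echo(f"best: m={res.best_m}")


@cli.command("benchmark")
@click.option("--preset", type=click.Choice(list(simulator.PRESET_SAMPLES)),
              default="reduced", show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--gamma", type=float, default=1e-4, show_default=True)
@click.option("--m", "m", type=int, default=8, show_default=True)
@click.option("--flows", default="250,500", show_default=True)
@click.option("--frequencies", default="0.1,0.2,0.5,1,2", show_default=True)
@click.option("--noise-levels", default="0.01,0.1,1,2,5,10", show_default=True)
@click.option("--out", "out_path", type=click.Path(), default=None,
              help="Optional path for the score table (TSV).")
def cli_benchmark(preset, seed, gamma, m, flows, frequencies, noise_levels,
                  out_path):
    """Score both methods over a simulated suite; emit the correlation grid."""
    suite = simulator.make_benchmark_suite(
        flows=[float(x) for x in flows.split(",")],
        frequencies=[float(x) for x in frequencies.split(",")],
        noise_levels=[float(x) for x in noise_levels.split(",")],
        seed=seed, preset=preset)
    table = evaluate_suite(suite, gamma=gamma, m=m)
    grid = table.pivot_table(index=["method", "flow", "frequency"],
                             columns="noise_pct", values="pearson_r")
    click.echo(grid.round(4).to_string())
    if out_path:
        table.to_csv(out_path, sep="\t", index=False)
        click.echo(f"wrote {out_path}")


def cli_main(argv=None) -> int:
    """Entry point returning an exit status (used by the console script)."""
    try:
        cli.main(args=argv, prog_name="respiro", standalone_mode=False)
    except click.ClickException as exc:
        exc.show()
        return exc.exit_code
    except click.Abort:
        return 1
    except SamplingError as exc:
        click.echo(f"error: {exc}", err=True)
        return 2
    except SystemExit as exc:
        return int(exc.code or 0)
    return 0


if __name__ == "__main__":  # pragma: no cover
    sys.exit(cli_main())
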