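"""Experiment drivers: release-grid sweeps, the April-limited scenario,
cage-trial batches, and the Hill dose-response fitting utility.

Every stochastic run derives its seed deterministically from a base seed and
the cell coordinates, so any row of a sweep CSV can be reproduced with a
single :func:`ssims.swd_abm.run_season` call using the recorded seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .environment import TemperatureSeries
from .swd_abm import (
    ReleaseStrategy,
    SeasonConfig,
    days_to_eradication,
    run_season,
)

__all__ = [
    "SweepSpec",
    "HillFit",
    "HillFitError",
    "run_sweep",
    "AprilResult",
    "april_limited_run",
    "fit_hill",
    "derive_seed",
]

DEFAULT_STRATEGIES = (
    "RIDL",
    "FL",
    "SSIMS_male_only",
    "SSIMS_single_amp",
    "SSIMS_double_amp",
)


@dataclass(frozen=True)
class SweepSpec:
    """Grid of release strategies × release sizes × intervals × replicates."""

    strategies: tuple[str, ...] = DEFAULT_STRATEGIES
    sizes: tuple[int, ...] = (10, 20, 40, 80)
    intervals: tuple[int, ...] = (7, 14, 25, 50)
    replicates: int = 10
    seed_base: int = 0

    def __post_init__(self) -> None:
        if not self.strategies or not self.sizes or not self.intervals:
            raise ValueError("strategy, size, and interval grids must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def derive_seed(seed_base: int, *coords: int) -> int:
    """Deterministic per-run seed from a base seed and integer coordinates."""
    ss = np.random.SeedSequence([int(seed_base), *[int(c) for c in coords]])
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(
    spec: SweepSpec, config: SeasonConfig, temperature: TemperatureSeries
) -> pd.DataFrame:
    """Run the full release grid and return one long-format row per run.

    Columns: strategy, N, F, replicate, seed, cumulative_wt, eradication_day
    (NaN when eradication is not reached). Rerunning any row's seed through
    :func:`run_season` reproduces its numbers exactly.
    """
    rows = []
    for si, strat in enumerate(spec.strategies):
        for n in spec.sizes:
            for f in spec.intervals:
                for rep in range(spec.replicates):
                    seed = derive_seed(spec.seed_base, si, n, f, rep)
                    cfg = replace(
                        config,
                        strategy=ReleaseStrategy(kind=strat, size=n, interval=f)
                        if n > 0
                        else ReleaseStrategy(),
                    )
                    summary = run_season(cfg, temperature, seed)
                    day = days_to_eradication(summary)
                    rows.append(
                        {
                            "strategy": strat,
                            "N": n,
                            "F": f,
                            "replicate": rep,
                            "seed": seed,
                            "cumulative_wt": summary.cumulative_wt_hatched,
                            "eradication_day": np.nan if day is None else day,
                        }
                    )
    return pd.DataFrame(rows)


def sweep_cell_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean ± s.d. of cumulative wild-type hatch and mean
    eradication day, from a long-format sweep table."""
    return (
        table.groupby(["strategy", "N", "F"])
        .agg(
            cumulative_wt_mean=("cumulative_wt", "mean"),
            cumulative_wt_sd=("cumulative_wt", "std"),
            eradication_day_mean=("eradication_day", "mean"),
        )
        .reset_index()
    )


@dataclass
class AprilResult:
    """Traces and checkpoint counts from the April-limited release scenario."""

    traces: pd.DataFrame       # replicate, day, date, wt, gm
    checkpoints: pd.DataFrame  # replicate, date, wt, gm


def april_limited_run(
    config: SeasonConfig,
    temperature: TemperatureSeries,
    seeds: tuple[int, ...] | list[int],
    size: int = 80,
) -> AprilResult:
    """Weekly releases of ``size`` agents on four successive April weeks.

    Uses the strategy kind from ``config.strategy`` with the release window
    pinned to April 1–22 and a 7-day interval; reports full-season wild-type
    and engineered traces per replicate plus counts at June 1 and July 1.
    """
    start = config.start or temperature.start
    year = start.year
    strategy = replace(
        config.strategy,
        size=size,
        interval=7,
        window_start=dt.date(year, 4, 1),
        window_end=dt.date(year, 4, 22),
    )
    cfg = replace(config, strategy=strategy)
    trace_rows = []
    cp_rows = []
    for rep, seed in enumerate(seeds):
        summary = run_season(cfg, temperature, int(seed))
        wt = summary.wt_alive
        gm = summary.gm_alive
        dates = [start + dt.timedelta(days=i) for i in range(summary.n_days)]
        trace_rows.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "day": np.arange(1, summary.n_days + 1),
                    "date": dates,
                    "wt": wt,
                    "gm": gm,
                }
            )
        )
        for cp in (dt.date(year, 6, 1), dt.date(year, 7, 1)):
            i = (cp - start).days
            cp_rows.append(
                {
                    "replicate": rep,
                    "date": cp,
                    "wt": int(wt[i]),
                    "gm": int(gm[i]),
                }
            )
    return AprilResult(
        traces=pd.concat(trace_rows, ignore_index=True),
        checkpoints=pd.DataFrame(cp_rows),
    )


# ---------------------------------------------------------------------------
# Hill fitting
# ---------------------------------------------------------------------------

class HillFitError(RuntimeError):
    """Degenerate data or failed convergence in the Hill fit."""


@dataclass
class HillFit:
    """Least-squares Hill fit: response = top · d^h / (ec50^h + d^h)."""

    top: float
    ec50: float
    hill: float
    r_squared: float
    t_value: float
    residuals: np.ndarray


def _hill(d: np.ndarray, top: float, ec50: float, h: float) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    out = np.zeros_like(d)
    pos = d > 0
    out[pos] = top * d[pos] ** h / (ec50**h + d[pos] ** h)
    return out


def fit_hill(doses, responses) -> HillFit:
    """Fit a three-parameter Hill curve and report R² and the slope t-value.

    The t-value is the Hill-coefficient estimate divided by its standard
    error from the fit covariance. Requires at least four dose points;
    constant responses raise :class:`HillFitError`.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.size < 4:
        raise HillFitError(f"need at least 4 dose points, got {d.size}")
    if np.any(d < 0):
        raise HillFitError("doses must be non-negative")
    if np.ptp(y) == 0:
        raise HillFitError("responses are constant; Hill fit is degenerate")
    top0 = float(y.max())
    ec0 = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    try:
        popt, pcov = curve_fit(
            _hill,
            d,
            y,
            p0=(top0, ec0, 2.0),
            bounds=((0.0, 1e-9, 1e-3), (np.inf, np.inf, 50.0)),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise HillFitError(f"Hill fit did not converge: {exc}") from exc
    fitted = _hill(d, *popt)
    resid = y - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    se_h = float(np.sqrt(pcov[2, 2]))
    t_val = float(popt[2] / se_h) if se_h > 0 and np.isfinite(se_h) else np.inf
    return HillFit(
        top=float(popt[0]),
        ec50=float(popt[1]),
        hill=float(popt[2]),
        r_squared=r2,
        t_value=t_val,
        residuals=resid,
    )
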