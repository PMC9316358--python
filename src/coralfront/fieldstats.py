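"""Environmental logger summaries and survival statistics.

Field context: coral colonies are monitored with HOBO temperature/light
loggers on two platforms (10-m and 2-m depth) and survival of chimeric vs
non-chimeric colonies is censused at fixed timepoints.  This module turns
the raw logger series into the per-depth summary statistics used to
characterise the translocation stress (temperature range and coefficient of
variation, mean light, maximum light within the diurnal peak window) and
provides the exact binomial confidence intervals and 2x2 chi-square tests
used for the survival comparison.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnvSummary",
    "summarize_logger",
    "clopper_pearson_ci",
    "chisq_2x2",
    "survival_report",
]

#: default diurnal light-peak window (local clock time, inclusive endpoints)
DEFAULT_WINDOW = (_dt.time(10, 0), _dt.time(16, 0))


@dataclass
class EnvSummary:
    """Per-depth environmental summary.

    ``temp_cv`` is the sample standard deviation divided by the mean of the
    raw Celsius readings (dimensionless).  ``light_max_window`` is the
    maximum light reading among records whose local clock time falls inside
    ``window`` (inclusive on both ends).
    """

    depth: str
    n_records: int
    temp_min: float
    temp_max: float
    temp_mean: float
    temp_cv: float
    light_mean: float
    light_max: float
    light_max_window: float
    window: tuple = field(default=DEFAULT_WINDOW)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "depth", "n_records", "temp_min", "temp_max", "temp_mean",
            "temp_cv", "light_mean", "light_max", "light_max_window")}
        d["window"] = [t.isoformat() for t in self.window]
        return d


def _validate_series(series: pd.DataFrame) -> pd.DataFrame:
    required = {"timestamp", "temperature_C", "light_lux", "depth"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"logger series missing columns: {sorted(missing)}")
    out = series.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    if out["light_lux"].lt(0).any():
        raise ValueError("negative light readings")
    if not np.isfinite(out["temperature_C"]).all():
        raise ValueError("non-finite temperature readings")
    return out


def summarize_logger(series: pd.DataFrame,
                     window: tuple = DEFAULT_WINDOW,
                     kelvin_cv: bool = False) -> dict[str, EnvSummary]:
    """Summarise a logger series per depth.

    Parameters
    ----------
    series
        Data frame with columns ``timestamp, temperature_C, light_lux,
        depth``.  Record order is irrelevant; rows are sorted by timestamp
        within each depth.
    window
        ``(start, end)`` local clock times delimiting the diurnal light
        peak, inclusive.  Default 10:00-16:00.
    kelvin_cv
        Compute the temperature CV on the Kelvin scale instead of raw
        Celsius.  The Celsius CV is the conventional field report; the flag
        exists because a ratio statistic on an interval scale is
        unit-dependent.
    """
    series = _validate_series(series)
    out: dict[str, EnvSummary] = {}
    for depth, grp in series.groupby("depth", sort=True):
        grp = grp.sort_values("timestamp")
        if len(grp) < 2:
            raise ValueError(f"depth {depth!r} has fewer than 2 records")
        temp = grp["temperature_C"].to_numpy(float)
        light = grp["light_lux"].to_numpy(float)
        t_for_cv = temp + 273.15 if kelvin_cv else temp
        mean_cv = t_for_cv.mean()
        cv = float(t_for_cv.std(ddof=1) / mean_cv) if mean_cv != 0 else np.inf
        clock = grp["timestamp"].dt.time
        in_win = clock.map(lambda t: window[0] <= t <= window[1]).to_numpy()
        lmw = float(light[in_win].max()) if in_win.any() else float("nan")
        out[str(depth)] = EnvSummary(
            depth=str(depth), n_records=len(grp),
            temp_min=float(temp.min()), temp_max=float(temp.max()),
            temp_mean=float(temp.mean()), temp_cv=cv,
            light_mean=float(light.mean()), light_max=float(light.max()),
            light_max_window=lmw, window=window,
        )
    return out


def clopper_pearson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n.

    Uses the Beta-distribution quantile form: the lower bound is the
    ``alpha/2`` quantile of ``Beta(k, n-k+1)`` (0 when ``k == 0``) and the
    upper bound the ``1 - alpha/2`` quantile of ``Beta(k+1, n-k)`` (1 when
    ``k == n``).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    alpha = 1.0 - conf
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def chisq_2x2(table, continuity_correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test for a 2x2 contingency table (1 df).

    Without correction the statistic is the closed form
    ``N * (ad - bc)^2 / (r1 * r2 * c1 * c2)``; with the Yates flag each
    ``|O - E|`` is reduced by 0.5 before squaring.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = t.sum()
    if (r == 0).any() or (c == 0).any():
        raise ValueError("zero margin in 2x2 table")
    if continuity_correction:
        expected = np.outer(r, c) / n
        adj = np.maximum(np.abs(t - expected) - 0.5, 0.0)
        statistic = float((adj ** 2 / expected).sum())
    else:
        (a, b), (cc, d) = t
        statistic = float(n * (a * d - b * cc) ** 2 / (r[0] * r[1] * c[0] * c[1]))
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p


def survival_report(table: pd.DataFrame, conf: float = 0.95,
                    continuity_correction: bool = False) -> pd.DataFrame:
    """Survival comparison between two groups at each timepoint.

    ``table`` has columns ``group, timepoint, n_alive, n_total``.  For each
    timepoint a Clopper-Pearson interval is attached per group and the two
    groups are compared with an independent 2x2 chi-square test
    (alive/dead x group), mirroring one test per census rather than a
    longitudinal model.
    """
    required = {"group", "timepoint", "n_alive", "n_total"}
    if not required <= set(table.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    if (table["n_alive"] > table["n_total"]).any() or (table["n_alive"] < 0).any():
        raise ValueError("need 0 <= n_alive <= n_total")
    rows = []
    for tp, grp in table.groupby("timepoint", sort=True):
        if grp["group"].nunique() != 2:
            raise ValueError(f"timepoint {tp!r} does not have exactly 2 groups")
        grp = grp.sort_values("group")
        g = grp["group"].tolist()
        alive = grp["n_alive"].to_numpy(int)
        total = grp["n_total"].to_numpy(int)
        ct = np.array([[alive[0], total[0] - alive[0]],
                       [alive[1], total[1] - alive[1]]])
        statistic, p = chisq_2x2(ct, continuity_correction=continuity_correction)
        row = {"timepoint": tp, "chi2": statistic, "p_value": p}
        for i, name in enumerate(g):
            lo, hi = clopper_pearson_ci(int(alive[i]), int(total[i]), conf)
            row[f"{name}_rate"] = alive[i] / total[i]
            row[f"{name}_ci_low"] = lo
            row[f"{name}_ci_high"] = hi
        rows.append(row)
    return pd.DataFrame(rows)
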