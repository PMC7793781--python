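"""Stage contrasts: F-test variance gate, pooled vs Satterthwaite t-test.

Each metric × location × band (or PSD frequency bin) cell is compared
between the Preparation and Generation stages with a two-tailed unpaired
t-test at α = 0.05.  A Fisher–Snedecor F-test first assesses variance
equality; when it rejects, the Welch statistic with Satterthwaite degrees
of freedom replaces the pooled-variance test.  Per-group 95% confidence
intervals accompany each comparison.  The unit of analysis is the session
mean.  No multiple-comparison correction is applied by default (an
optional Benjamini–Hochberg flag is provided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

COMPARISON_COLUMNS = (
    "metric", "location", "band_or_freq",
    "mean_prep", "ci_lo_prep", "ci_hi_prep",
    "mean_gen", "ci_lo_gen", "ci_hi_gen",
    "n_prep", "n_gen",
    "f_stat", "f_p", "test_used",
    "t_stat", "df", "p", "significant", "skipped",
)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    ci_x: tuple[float, float]
    ci_y: tuple[float, float]


def f_test_equal_var(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher–Snedecor F-test of variance equality.

    F = s_x²/s_y²; p = 2·min(P(F≤f), P(F≥f)) on F(n_x−1, n_y−1).
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 or vy == 0:
        raise ValueError("zero variance in a sample")
    f = vx / vy
    dist = sps.f(x.size - 1, y.size - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


def _group_ci(x: np.ndarray, alpha: float = ALPHA) -> tuple[float, float]:
    n = x.size
    half = sps.t.ppf(1 - alpha / 2, n - 1) * x.std(ddof=1) / np.sqrt(n)
    m = x.mean()
    return float(m - half), float(m + half)


def two_sample_t(x: np.ndarray, y: np.ndarray,
                 equal_var: bool, alpha: float = ALPHA) -> TTestResult:
    """Two-tailed unpaired t-test with per-group (1−α) confidence intervals.

    ``equal_var=True`` uses the pooled-variance statistic with
    df = n_x + n_y − 2; ``False`` the Welch statistic with Satterthwaite
    degrees of freedom.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if equal_var:
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = np.sqrt(sp2 * (1 / nx + 1 / ny))
    else:
        se2x, se2y = vx / nx, vy / ny
        se = np.sqrt(se2x + se2y)
        df = (se2x + se2y) ** 2 / (
            se2x**2 / (nx - 1) + se2y**2 / (ny - 1)
        )
    t = (x.mean() - y.mean()) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p),
                       ci_x=_group_ci(x, alpha), ci_y=_group_ci(y, alpha))


def compare_stages(
    feature_table: pd.DataFrame,
    alpha: float = ALPHA,
    fdr: bool = False,
) -> pd.DataFrame:
    """Stage contrast for every metric × location × band/bin cell.

    ``feature_table`` is tidy with columns
    ``session_id, stage, metric, location, band_or_freq, value`` and one
    row per session per cell.  Cells with fewer than two sessions in
    either stage are emitted with ``skipped=True`` rather than dropped.
    With ``fdr=True``, significance is re-assessed on Benjamini–Hochberg
    adjusted p-values (raw p is still reported).
    """
    required = {"session_id", "stage", "metric", "location",
                "band_or_freq", "value"}
    missing = required - set(feature_table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    rows = []
    grouped = feature_table.groupby(
        ["metric", "location", "band_or_freq"], sort=True, observed=True
    )
    for (metric, location, band), cell in grouped:
        x = cell.loc[cell["stage"] == "Preparation", "value"].to_numpy(float)
        y = cell.loc[cell["stage"] == "Generation", "value"].to_numpy(float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        row = {
            "metric": metric, "location": location, "band_or_freq": band,
            "n_prep": x.size, "n_gen": y.size,
        }
        if x.size < 2 or y.size < 2:
            row.update({k: np.nan for k in (
                "mean_prep", "ci_lo_prep", "ci_hi_prep", "mean_gen",
                "ci_lo_gen", "ci_hi_gen", "f_stat", "f_p", "t_stat",
                "df", "p")})
            row.update(test_used="", significant=False, skipped=True)
            rows.append(row)
            continue
        try:
            f_stat, f_p = f_test_equal_var(x, y)
        except ValueError:
            f_stat, f_p = np.nan, 1.0  # degenerate variance: keep pooled test
        equal_var = f_p >= alpha
        res = two_sample_t(x, y, equal_var=equal_var, alpha=alpha)
        row.update(
            mean_prep=float(x.mean()), ci_lo_prep=res.ci_x[0],
            ci_hi_prep=res.ci_x[1],
            mean_gen=float(y.mean()), ci_lo_gen=res.ci_y[0],
            ci_hi_gen=res.ci_y[1],
            f_stat=f_stat, f_p=f_p,
            test_used="pooled" if equal_var else "satterthwaite",
            t_stat=res.t, df=res.df, p=res.p,
            significant=bool(res.p < alpha), skipped=False,
        )
        rows.append(row)
    out = pd.DataFrame(rows, columns=list(COMPARISON_COLUMNS))
    if fdr and len(out):
        tested = out.loc[~out["skipped"], "p"]
        if len(tested):
            adj = _benjamini_hochberg(tested.to_numpy())
            out.loc[~out["skipped"], "p_adj"] = adj
            out.loc[~out["skipped"], "significant"] = adj < alpha
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def psd_significant_ranges(comparison: pd.DataFrame) -> pd.DataFrame:
    """Summarize contiguous significant PSD bins as frequency ranges.

    Returns ``channel, range_lo_hz, range_hi_hz`` rows, one per maximal
    run of adjacent significant bins on each channel's frequency grid.
    """
    psd_rows = comparison[
        (comparison["metric"] == "psd") & ~comparison["skipped"]
    ].copy()
    out = []
    if len(psd_rows):
        psd_rows["freq"] = psd_rows["band_or_freq"].astype(float)
        for channel, grp in psd_rows.groupby("location"):
            grp = grp.sort_values("freq")
            freqs = grp["freq"].to_numpy()
            sig = grp["significant"].to_numpy()
            step = np.min(np.diff(freqs)) if freqs.size > 1 else 1.0
            start = None
            prev = None
            for fhz, s in zip(freqs, sig):
                if s and start is None:
                    start = fhz
                elif s and prev is not None and fhz - prev > 1.5 * step:
                    out.append({"channel": channel, "range_lo_hz": start,
                                "range_hi_hz": prev})
                    start = fhz
                elif not s and start is not None:
                    out.append({"channel": channel, "range_lo_hz": start,
                                "range_hi_hz": prev})
                    start = None
                if s:
                    prev = fhz
            if start is not None:
                out.append({"channel": channel, "range_lo_hz": start,
                            "range_hi_hz": prev})
    return pd.DataFrame(out, columns=["channel", "range_lo_hz", "range_hi_hz"])
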