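"""Turbidity-curve modelling, saturation-concentration estimation and
blockiness-vs-C_sat correlation analysis.

Turbidity (OD600) versus protein concentration is modelled as a
four-parameter log-logistic sigmoid

    od(c) = baseline + od_max / (1 + (c_sat / c)^h)

so the fitted ``c_sat`` is exactly the concentration at which the
turbidity rise reaches half of its maximum above baseline — the
operational definition of the saturation concentration for
liquid-liquid phase separation.  ``h`` (steepness) controls how sharply
the solution becomes turbid around the threshold.

Fits use damped least squares (scipy) from three deterministic starting
points and keep the solution with the lowest residual sum of squares.
A fit that fails to converge, or whose c_sat falls outside the measured
concentration range, is flagged rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


class PhaseSepError(ValueError):
    """Invalid turbidity data or correlation input."""


@dataclass(frozen=True)
class TurbidityCurve:
    """One turbidity titration: OD600 at strictly increasing concentrations (µM)."""

    construct_id: str
    concentrations: np.ndarray = field(repr=False)
    od600: np.ndarray = field(repr=False)
    replicate: str = "1"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if c.shape != od.shape or c.ndim != 1:
            raise PhaseSepError("concentrations and od600 must be 1-D and equal length")
        if np.any(c <= 0):
            raise PhaseSepError("concentrations must be strictly positive")
        if np.any(np.diff(c) <= 0):
            raise PhaseSepError("concentrations must be strictly increasing")
        if np.any(od < 0):
            raise PhaseSepError("od600 values must be non-negative")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "od600", od)

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class CsatFit:
    construct_id: str
    c_sat: float  # µM
    od_max: float
    steepness: float
    baseline: float
    rss: float
    converged: bool
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    message: str = ""


def _model(c: np.ndarray, baseline: float, od_max: float, c_sat: float, h: float) -> np.ndarray:
    return baseline + od_max / (1.0 + (c_sat / c) ** h)


def fit_csat(
    curve: TurbidityCurve,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> CsatFit:
    """Fit the log-logistic turbidity model and report C_sat.

    Requires at least 5 points spanning both the low- and high-turbidity
    regimes.  Multi-start optimisation from 3 deterministic
    initialisations; the fitted baseline is bounded at 0.  Optional
    residual-bootstrap confidence interval (2.5/97.5 percentiles) when
    ``n_bootstrap`` > 0.

    Never raises on a bad curve: degenerate input or a c_sat outside the
    measured range yields ``converged=False`` with a diagnostic message.
    """
    c = curve.concentrations
    od = curve.od600
    if len(c) < 5:
        return _failed(curve, "fewer than 5 points")
    od_span = od.max() - od.min()
    if od_span <= 0 or od.max() <= 1e-12:
        return _failed(curve, "flat or all-zero turbidity curve")

    baseline0 = float(od.min())
    odmax0 = float(od_span)
    half = baseline0 + odmax0 / 2.0
    # first concentration where the curve crosses half-max, interpolated
    above = np.flatnonzero(od >= half)
    if len(above) == 0 or above[0] == 0:
        c_half = float(np.exp(np.mean(np.log(c))))
    else:
        i = above[0]
        f = (half - od[i - 1]) / (od[i] - od[i - 1]) if od[i] != od[i - 1] else 0.5
        c_half = float(np.exp(np.log(c[i - 1]) + f * (np.log(c[i]) - np.log(c[i - 1]))))
    geo_mean = float(np.exp(np.mean(np.log(c))))
    starts = [
        (baseline0, odmax0, c_half, 2.0),
        (baseline0, odmax0, c_half, 6.0),
        (baseline0, odmax0, geo_mean, 3.0),
    ]
    bounds = (
        np.array([0.0, 1e-9, c[0] / 100.0, 0.05]),
        np.array([od.max(), 10 * od.max(), c[-1] * 100.0, 50.0]),
    )

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _model(c, *theta) - od

    best = None
    for theta0 in starts:
        theta0 = np.clip(np.asarray(theta0, float), bounds[0], bounds[1])
        try:
            sol = optimize.least_squares(
                residuals, theta0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:  # numerical failure on one start is not fatal
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol, rss)
    if best is None:
        return _failed(curve, "optimizer failed from all starts")
    sol, rss = best
    baseline, od_max, c_sat, h = (float(v) for v in sol.x)
    in_range = c[0] <= c_sat <= c[-1]
    converged = bool(sol.success) and in_range
    message = "" if converged else ("c_sat outside data range" if not in_range else "no convergence")

    ci_low = ci_high = float("nan")
    if converged and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        fitted = _model(c, baseline, od_max, c_sat, h)
        resid = od - fitted
        estimates = []
        for _ in range(n_bootstrap):
            od_star = np.clip(fitted + rng.choice(resid, size=len(resid)), 0, None)
            try:
                sol_b = optimize.least_squares(
                    lambda t: _model(c, *t) - od_star,
                    sol.x,
                    bounds=bounds,
                )
                estimates.append(float(sol_b.x[2]))
            except Exception:
                continue
        if estimates:
            ci_low, ci_high = (
                float(np.percentile(estimates, 2.5)),
                float(np.percentile(estimates, 97.5)),
            )

    return CsatFit(
        construct_id=curve.construct_id,
        c_sat=c_sat,
        od_max=od_max,
        steepness=h,
        baseline=baseline,
        rss=rss,
        converged=converged,
        ci_low=ci_low,
        ci_high=ci_high,
        message=message,
    )


def _failed(curve: TurbidityCurve, message: str) -> CsatFit:
    return CsatFit(
        construct_id=curve.construct_id,
        c_sat=float("nan"),
        od_max=float("nan"),
        steepness=float("nan"),
        baseline=float("nan"),
        rss=float("nan"),
        converged=False,
        message=message,
    )


def read_turbidity(path) -> list[TurbidityCurve]:
    """Read a TSV of (construct, replicate, concentration_uM, od600) rows
    into one curve per (construct, replicate)."""
    df = pd.read_csv(path, sep="\t")
    required = {"construct", "replicate", "concentration_uM", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise PhaseSepError(f"turbidity table missing columns {sorted(missing)}")
    curves = []
    for (construct, replicate), grp in df.groupby(["construct", "replicate"], sort=False):
        grp = grp.sort_values("concentration_uM")
        curves.append(
            TurbidityCurve(
                construct_id=str(construct),
                concentrations=grp["concentration_uM"].to_numpy(float),
                od600=grp["od600"].to_numpy(float),
                replicate=str(replicate),
            )
        )
    return curves


def write_turbidity(curves: list[TurbidityCurve], path) -> None:
    rows = [
        {
            "construct": cu.construct_id,
            "replicate": cu.replicate,
            "concentration_uM": c,
            "od600": od,
        }
        for cu in curves
        for c, od in zip(cu.concentrations, cu.od600)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# correlation of sequence metrics with C_sat

@dataclass(frozen=True)
class MetricCorrelation:
    """Association between one sequence metric and C_sat across constructs.

    Spearman rho is computed on (metric, c_sat); Pearson r on
    (metric, log c_sat).  ``trend`` holds the least-squares slope and
    intercept of log10(c_sat) on the metric.
    """

    metric_name: str
    metric_values: tuple[float, ...]
    csat_values: tuple[float, ...]
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    trend_slope: float
    trend_intercept: float
    defined: bool
    construct_ids: tuple[str, ...] = ()


def correlate(
    metric_values,
    csat_values,
    metric_name: str,
    construct_ids: tuple[str, ...] = (),
) -> MetricCorrelation:
    """Correlate a sequence metric with measured C_sat values.

    Requires >= 3 complete pairs.  A constant metric vector leaves the
    correlation undefined (``defined=False``) rather than raising.
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(csat_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PhaseSepError("metric and c_sat vectors must be 1-D and equal length")
    if len(x) < 3:
        raise PhaseSepError(f"need >= 3 pairs, got {len(x)}")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise PhaseSepError("missing values are not allowed in correlation input")
    if np.any(y <= 0):
        raise PhaseSepError("c_sat values must be positive (µM)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return MetricCorrelation(
            metric_name=metric_name,
            metric_values=tuple(x),
            csat_values=tuple(y),
            spearman_rho=float("nan"),
            spearman_p=float("nan"),
            pearson_r=float("nan"),
            trend_slope=float("nan"),
            trend_intercept=float("nan"),
            defined=False,
            construct_ids=tuple(construct_ids),
        )
    rho, p = stats.spearmanr(x, y)
    r, _ = stats.pearsonr(x, np.log(y))
    slope, intercept = np.polyfit(x, np.log10(y), 1)
    return MetricCorrelation(
        metric_name=metric_name,
        metric_values=tuple(x),
        csat_values=tuple(y),
        spearman_rho=float(rho),
        spearman_p=float(p),
        pearson_r=float(r),
        trend_slope=float(slope),
        trend_intercept=float(intercept),
        defined=True,
        construct_ids=tuple(construct_ids),
    )


def compare_metrics(correlations: list[MetricCorrelation]) -> pd.DataFrame:
    """Rank metric-vs-C_sat correlations by |Spearman rho|.

    All records must cover the same construct set (when construct ids are
    recorded).  Ties break alphabetically by metric name.  The returned
    frame carries a ``blockiness_outranks_net_charge`` attribute flagging
    whether a blockiness metric (B_LC or D_seg) outranks net charge.
    """
    if len(correlations) < 1:
        raise PhaseSepError("need at least one correlation record")
    id_sets = {c.construct_ids for c in correlations if c.construct_ids}
    if len(id_sets) > 1:
        raise PhaseSepError("correlation records cover different construct sets")
    rows = [
        {
            "metric": c.metric_name,
            "spearman_rho": c.spearman_rho,
            "abs_rho": abs(c.spearman_rho) if c.defined else float("nan"),
            "pearson_r_log": c.pearson_r,
            "defined": c.defined,
        }
        for c in correlations
    ]
    df = (
        pd.DataFrame(rows)
        .sort_values(["abs_rho", "metric"], ascending=[False, True])
        .reset_index(drop=True)
    )
    df["rank"] = np.arange(1, len(df) + 1)
    ranked = list(df["metric"])
    blockiness = [m for m in ranked if m in ("B_LC", "D_seg")]
    flag = bool(
        blockiness
        and "net_charge" in ranked
        and min(ranked.index(m) for m in blockiness) < ranked.index("net_charge")
    )
    df.attrs["blockiness_outranks_net_charge"] = flag
    return df
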