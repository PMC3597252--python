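"""Trophic-balance (Pb:Pp) series assembly and statistical models.

The ratio of bacterial to phytoplankton biomass production is the central
response variable: values below 1 indicate autotrophy-dominated carbon
flow, above 1 microbial heterotrophy. This module builds the annual ratio
series, aligns it with area-specific riverine TOC load under a year lag,
and fits the models used to characterise the response:

* exponential response  ratio = a * exp(b * load)  via ln-linearisation
  (the classical curve-estimation approach; a nonlinear refit is optional),
* cubic polynomial in time for interannual trend significance and peak-year
  location,
* Model II (reduced major axis) regression with case-resampling bootstrap
  standard errors,
* ARI(p, d): autoregressive fit to a d-times-differenced series,
* a GUM-style combined-standard-uncertainty partition attributing ratio
  variance to the Pb and Pp components,
* distributional assumption checks (Shapiro-Wilk, Levene, ACF/PACF) with a
  Pearson-vs-Spearman recommendation, and the between-method calibration
  regression on ln scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "TrophicSeries",
    "ExponentialFit",
    "CubicFit",
    "RMAFit",
    "ARIModel",
    "UncertaintyPartition",
    "AssumptionReport",
    "CalibrationResult",
    "build_series",
    "lag_align",
    "fit_exponential",
    "fit_cubic",
    "fit_rma",
    "fit_ari",
    "partition_uncertainty",
    "check_assumptions",
    "calibration_regression",
]

ALPHA = 0.05  # two-tailed type-I error level used throughout


@dataclass
class TrophicSeries:
    """Annual Pb, Pp and their ratio for one basin."""

    basin: str
    years: np.ndarray
    pb: np.ndarray  # g C m^-2 yr^-1
    pp: np.ndarray
    ratio: np.ndarray
    interpolated_years: tuple = ()

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "pb": self.pb, "pp": self.pp, "ratio": self.ratio}
        ).set_index("year")


@dataclass(frozen=True)
class ExponentialFit:
    """ratio = a * exp(b * load); coefficients with SEs, p-values, fit R^2."""

    a: float
    b: float
    se_a: float
    se_b: float
    p_a: float
    p_b: float
    r2: float
    n: int
    method: str = "loglinear"

    def predict(self, x):
        return self.a * np.exp(self.b * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class CubicFit:
    coefficients: tuple  # (b0, b1, b2, b3) on centered time
    t_center: float
    r2: float
    p_model: float
    peak_year: float | None  # interior maximum from the first derivative, if any


@dataclass(frozen=True)
class RMAFit:
    slope: float
    intercept: float
    bootstrap_se_slope: float
    bootstrap_se_intercept: float
    n_boot: int
    seed: int
    r: float
    n: int


@dataclass(frozen=True)
class ARIModel:
    order_p: int
    order_d: int
    ar_coefficients: tuple
    intercept: float
    r2: float
    residual_acf_ok: bool
    residual_acf1: float
    stationary: bool


@dataclass(frozen=True)
class UncertaintyPartition:
    frac_pb: float  # % of ratio variance attributed to Pb
    frac_pp: float


@dataclass(frozen=True)
class AssumptionReport:
    shapiro_p: tuple
    levene_p: float | None
    acf_flags: tuple  # True where lag-1 ACF exceeds +-2/sqrt(n)
    recommendation: str  # "pearson" | "spearman"


@dataclass(frozen=True)
class CalibrationResult:
    factor: float
    ci_low: float
    ci_high: float
    rma_slope: float
    n: int


def build_series(
    pb_annuals: Mapping[int, float],
    pp_annuals: Mapping[int, float],
    basin: str = "",
) -> TrophicSeries:
    """Assemble the annual Pb:Pp series over the common year span.

    A single interior year missing from either series has its *ratio*
    filled by linear interpolation and is flagged; more than one interior
    gap is an error (mirroring the one-interpolation-per-basin allowance),
    and leading/trailing gaps are never filled.
    """
    pb = pd.Series(dict(pb_annuals), dtype=float).sort_index()
    pp = pd.Series(dict(pp_annuals), dtype=float).sort_index()
    observed = sorted(set(pb.index) & set(pp.index))
    if not observed or observed[-1] - observed[0] < 2:
        raise ValueError("need a common span of >= 3 years")
    span = np.arange(observed[0], observed[-1] + 1)
    pb = pb.reindex(span)
    pp = pp.reindex(span)
    if (pp[pp.notna() & pb.notna()] <= 0).any():
        raise ValueError("Pp must be > 0 in every retained year")
    ratio = pb / pp
    missing = [int(y) for y in span if not np.isfinite(ratio[y])]
    if len(missing) > 1:
        raise ValueError(
            f"{len(missing)} interior gaps ({missing}); only one may be interpolated"
        )
    if missing:
        ratio = ratio.interpolate(method="index")
    return TrophicSeries(
        basin=basin,
        years=span.astype(int),
        pb=pb.to_numpy(),
        pp=pp.to_numpy(),
        ratio=ratio.to_numpy(),
        interpolated_years=tuple(missing),
    )


def lag_align(
    x_by_year: Mapping[int, float],
    y_by_year: Mapping[int, float],
    lag: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair x in year y with the response in year y + lag.

    The driver in a given calendar year predicts the response ``lag`` years
    later, so a 13-year overlap at lag 2 yields 11 pairs. Returns
    (x, y, driver_years).
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    xs = pd.Series(dict(x_by_year), dtype=float)
    ys = pd.Series(dict(y_by_year), dtype=float)
    years = sorted(
        y for y in xs.index
        if (y + lag) in ys.index and np.isfinite(xs[y]) and np.isfinite(ys[y + lag])
    )
    if not years:
        raise ValueError(f"no overlapping pairs at lag {lag}")
    x = xs.reindex(years).to_numpy()
    y = ys.reindex([yr + lag for yr in years]).to_numpy()
    return x, y, np.asarray(years, dtype=int)


def fit_exponential(x, y, method: str = "loglinear") -> ExponentialFit:
    """Fit ratio = a * exp(b * x) to positive responses.

    Default path is ordinary least squares on ln(y) (exactly the log-linear
    curve-estimation model); a, its SE (delta method: se_a = a * se_lnA)
    and both p-values come from that linear fit, and R^2 is reported on the
    ln scale. ``method="nls"`` refits by nonlinear least squares from the
    log-linear start.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.any(y <= 0):
        raise ValueError("responses must be > 0 for the exponential model")
    res = sm.OLS(np.log(y), sm.add_constant(x)).fit()
    ln_a, b = res.params
    a = float(np.exp(ln_a))
    fit = ExponentialFit(
        a=a,
        b=float(b),
        se_a=float(a * res.bse[0]),
        se_b=float(res.bse[1]),
        p_a=float(res.pvalues[0]),
        p_b=float(res.pvalues[1]),
        r2=float(res.rsquared),
        n=int(x.size),
    )
    if method == "loglinear":
        return fit
    if method != "nls":
        raise ValueError(f"unknown method {method!r}")
    popt, pcov = scipy.optimize.curve_fit(
        lambda xx, aa, bb: aa * np.exp(bb * xx), x, y, p0=[fit.a, fit.b], maxfev=10000
    )
    se = np.sqrt(np.diag(pcov))
    resid = y - popt[0] * np.exp(popt[1] * x)
    r2 = 1.0 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
    tvals = popt / se
    pvals = 2 * scipy.stats.t.sf(np.abs(tvals), df=x.size - 2)
    return ExponentialFit(
        a=float(popt[0]), b=float(popt[1]), se_a=float(se[0]), se_b=float(se[1]),
        p_a=float(pvals[0]), p_b=float(pvals[1]), r2=float(r2), n=int(x.size),
        method="nls",
    )


def fit_cubic(t, y) -> CubicFit:
    """Cubic trend fit y = b0 + b1 t + b2 t^2 + b3 t^3 on centered time.

    Centering at the series midpoint conditions the design matrix; the
    model F-test gives the trend p-value. An interior maximum is located
    from the real roots of the first derivative (reported on the original
    time scale), matching the practice of reading the peak year off the
    zero of the fitted derivative.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size or t.size < 5:
        raise ValueError("need >= 5 observations for a cubic fit")
    if np.unique(t).size < 4:
        raise ValueError("degenerate time axis for a cubic fit")
    t0 = float(t.mean())
    tc = t - t0
    design = sm.add_constant(np.column_stack([tc, tc**2, tc**3]))
    res = sm.OLS(y, design).fit()
    b0, b1, b2, b3 = (float(v) for v in res.params)
    peak = None
    # dy/dt = 3 b3 tc^2 + 2 b2 tc + b1 = 0
    deriv = [3 * b3, 2 * b2, b1]
    if not np.allclose(deriv, 0.0):
        roots = np.roots([c for c in deriv])
        for r in roots:
            if abs(r.imag) > 1e-9:
                continue
            rc = float(r.real)
            if tc.min() <= rc <= tc.max():
                second = 6 * b3 * rc + 2 * b2
                if second < 0:
                    peak = rc + t0
                    break
    p_model = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0
    return CubicFit(
        coefficients=(b0, b1, b2, b3), t_center=t0,
        r2=float(res.rsquared), p_model=p_model, peak_year=peak,
    )


def _rma_coeffs(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    return slope, intercept, r


def fit_rma(x, y, n_boot: int = 2000, seed: int | None = None) -> RMAFit:
    """Model II regression with the reduced-major-axis loss.

    slope = sign(r) * s_y / s_x, the line through the centroid; standard
    errors come from case-resampling bootstrap replicates driven by the
    mandatory seed. Appropriate when both variables carry measurement error.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    slope, intercept, r = _rma_coeffs(x, y)
    rng = np.random.default_rng(seed)
    boot_s, boot_i = [], []
    n = x.size
    for _ in range(int(n_boot)):
        idx = rng.integers(0, n, size=n)
        try:
            s_b, i_b, _ = _rma_coeffs(x[idx], y[idx])
        except ValueError:  # degenerate resample; skip
            continue
        boot_s.append(s_b)
        boot_i.append(i_b)
    se_s = float(np.std(boot_s, ddof=1)) if len(boot_s) > 1 else 0.0
    se_i = float(np.std(boot_i, ddof=1)) if len(boot_i) > 1 else 0.0
    return RMAFit(
        slope=slope, intercept=intercept,
        bootstrap_se_slope=se_s, bootstrap_se_intercept=se_i,
        n_boot=int(n_boot), seed=int(seed), r=r, n=int(n),
    )


def fit_ari(series, p: int = 1, d: int = 1) -> ARIModel:
    """ARI(p, d): AR(p) fitted by least squares to the d-times-differenced series.

    Differencing removes polynomial trend of degree d; the AR part captures
    the remaining serial dependence. Residual lag-1 autocorrelation is
    checked against the +-2/sqrt(n) band, and the AR polynomial's roots are
    checked for stationarity.
    """
    z = np.asarray(series, dtype=float)
    if d < 1:
        raise ValueError("order_d must be >= 1")
    if z.size <= p + d + 2:
        raise ValueError(f"series of length {z.size} too short for ARI({p},{d})")
    w = np.diff(z, n=d)
    if np.var(w) < 1e-20 * (1.0 + abs(float(np.mean(w)))) ** 2:
        # differencing annihilated the series (polynomial of degree <= d):
        # nothing left for the AR part to explain
        return ARIModel(
            order_p=int(p), order_d=int(d), ar_coefficients=(0.0,) * p,
            intercept=float(np.mean(w)), r2=0.0, residual_acf_ok=True,
            residual_acf1=0.0, stationary=True,
        )
    # lagged design: w_t on w_{t-1}..w_{t-p} with intercept (drift)
    rows = [w[p - j - 1 : w.size - j - 1] for j in range(p)]
    design = sm.add_constant(np.column_stack(rows)) if p else np.ones((w.size, 1))
    target = w[p:] if p else w
    res = sm.OLS(target, design).fit()
    coeffs = tuple(float(c) for c in res.params[1:])
    resid = res.resid
    n_res = resid.size
    if n_res > 1 and np.var(resid) > 0:
        acf1 = float(
            np.corrcoef(resid[:-1], resid[1:])[0, 1]
        )
    else:
        acf1 = 0.0
    acf_ok = abs(acf1) <= 2.0 / np.sqrt(max(n_res, 1))
    if coeffs:
        # stationarity: roots of 1 - phi_1 z - ... - phi_p z^p outside unit circle
        poly = np.concatenate([[1.0], -np.asarray(coeffs)])
        roots = np.roots(poly[::-1])
        stationary = bool(np.all(np.abs(roots) > 1.0)) if roots.size else True
    else:
        stationary = True
    r2 = float(res.rsquared) if np.isfinite(res.rsquared) else 0.0
    return ARIModel(
        order_p=int(p), order_d=int(d), ar_coefficients=coeffs,
        intercept=float(res.params[0]), r2=r2,
        residual_acf_ok=bool(acf_ok), residual_acf1=acf1, stationary=stationary,
    )


def partition_uncertainty(
    pb_mean: float, pb_sd: float, pp_mean: float, pp_sd: float
) -> UncertaintyPartition:
    """Split Pb:Pp ratio variance into Pb and Pp contributions.

    First-order (combined standard uncertainty) propagation for R = Pb/Pp
    with independent components gives (u_R/R)^2 = (u_Pb/Pb)^2 + (u_Pp/Pp)^2;
    each term's share of the sum is its percentage contribution.
    """
    if pb_mean <= 0 or pp_mean <= 0:
        raise ValueError("means must be > 0")
    if pb_sd < 0 or pp_sd < 0:
        raise ValueError("sds must be >= 0")
    rel_pb = (pb_sd / pb_mean) ** 2
    rel_pp = (pp_sd / pp_mean) ** 2
    total = rel_pb + rel_pp
    if total == 0:
        raise ValueError("at least one sd must be > 0")
    frac_pb = rel_pb / total * 100.0
    return UncertaintyPartition(frac_pb=frac_pb, frac_pp=100.0 - frac_pb)


def check_assumptions(
    groups: Sequence[Sequence[float]], alpha: float = ALPHA
) -> AssumptionReport:
    """Distributional checks ahead of correlation/ANOVA.

    Shapiro-Wilk normality per group, Levene variance homogeneity across
    groups (when more than one), and a lag-1 autocorrelation flag per group
    against the +-2/sqrt(n) band. Recommends Pearson correlation when no
    group rejects normality at ``alpha``, Spearman otherwise.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if not arrays or any(a.size < 3 for a in arrays):
        raise ValueError("each group needs >= 3 values")
    shapiro_p = tuple(float(scipy.stats.shapiro(a).pvalue) for a in arrays)
    levene_p = (
        float(scipy.stats.levene(*arrays).pvalue) if len(arrays) > 1 else None
    )
    flags = []
    for a in arrays:
        if a.size > 2 and np.var(a) > 0:
            acf1 = float(np.corrcoef(a[:-1], a[1:])[0, 1])
            flags.append(abs(acf1) > 2.0 / np.sqrt(a.size))
        else:
            flags.append(False)
    rec = "pearson" if all(p >= alpha for p in shapiro_p) else "spearman"
    return AssumptionReport(
        shapiro_p=shapiro_p, levene_p=levene_p,
        acf_flags=tuple(flags), recommendation=rec,
    )


def calibration_regression(
    method_a, method_b, n_boot: int = 2000, seed: int | None = None
) -> CalibrationResult:
    """Between-method calibration on ln scale via Model II regression.

    The RMA line through the centroid of (ln A, ln B) implies a
    multiplicative correction factor exp(mean ln B - mean ln A) at the data
    centroid (the geometric-mean ratio of the methods); the 95% CI comes
    from case-resampling bootstrap percentiles.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap")
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 paired measurements")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("calibration values must be > 0 for ln transform")
    la, lb = np.log(a), np.log(b)
    try:
        slope, _, _ = _rma_coeffs(la, lb)
    except ValueError:
        slope = float("nan")  # replicate pairs with zero spread still calibrate
    factor = float(np.exp(lb.mean() - la.mean()))
    rng = np.random.default_rng(seed)
    n = a.size
    boots = np.empty(int(n_boot))
    for i in range(int(n_boot)):
        idx = rng.integers(0, n, size=n)
        boots[i] = np.exp(lb[idx].mean() - la[idx].mean())
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return CalibrationResult(
        factor=factor, ci_low=float(lo), ci_high=float(hi),
        rma_slope=slope, n=int(n),
    )
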