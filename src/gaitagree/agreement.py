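"""Time-domain agreement and reliability statistics.

Implements the method-comparison core: two-way absolute-agreement single-rater
ICC with its F-based confidence interval, the non-parametric (U-statistic)
concordance correlation coefficient, percentile Bland-Altman limits of
agreement with bootstrap confidence intervals, Spearman correlation of the
differences against the criterion, classic dynamic time warping, and the
normalized similarity index NSI = (M - d) / M.

Sign convention throughout: differences are criterion minus sensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


class AgreementError(ValueError):
    """Raised for degenerate or mismatched statistical inputs."""


@dataclass
class EstimateCI:
    """A point estimate with a two-sided confidence interval."""

    value: float
    ci_lower: float
    ci_upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        eps = 1e-12
        if not (self.ci_lower <= self.value + eps
                and self.value <= self.ci_upper + eps):
            raise AgreementError(
                f"CI [{self.ci_lower}, {self.ci_upper}] does not bracket "
                f"estimate {self.value}")


def _paired(x, y, min_n: int = 5) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise AgreementError(f"length mismatch ({x.size} vs {y.size})")
    if x.size < min_n:
        raise AgreementError(f"need at least {min_n} pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise AgreementError("non-finite values in input")
    return x, y


# ---------------------------------------------------------------------------
# ICC: two-way, absolute agreement, single rater
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    """ICC(A,1): two-way model, absolute agreement, single measurement.

    Variance decomposition uses grid points as rows and trials as columns;
    the absolute-agreement form penalizes a systematic offset between
    trials.  The CI is the standard F-based interval for this form.
    """

    icc: float
    ci_lower: float
    ci_upper: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_rows: int
    n_cols: int
    model: str = "two-way, absolute agreement, single rater"


def icc_two_way_absolute_single(trial1, trial2, *more_trials,
                                level: float = 0.95) -> ICCResult:
    """ICC(A,1) between repeated trials measured at common grid points.

    ``ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))`` from the
    two-way ANOVA with n rows (points) and k columns (trials).  The
    confidence interval follows the McGraw-Wong F approach with a
    Satterthwaite degrees-of-freedom approximation.
    """
    cols = [np.asarray(t, dtype=float).ravel()
            for t in (trial1, trial2, *more_trials)]
    n = cols[0].size
    if any(c.size != n for c in cols):
        raise AgreementError("trials must have equal lengths")
    if n < 5:
        raise AgreementError("need at least 5 grid points")
    y = np.column_stack(cols)
    if not np.all(np.isfinite(y)):
        raise AgreementError("non-finite values in input")
    k = y.shape[1]
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sse = float(np.sum((y - row_means[:, None] - col_means[None, :]
                        + grand) ** 2))
    if ssr + ssc + sse == 0:
        raise AgreementError("zero total variance: ICC undefined")
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if mse == 0 and msc == 0:
        # duplicated trials: perfect agreement
        return ICCResult(1.0, 1.0, 1.0, msr, msc, mse, n, k)
    icc = (msr - mse) / denom
    alpha = 1.0 - level
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_hi = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_hi * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr)
    else:
        lower = upper = icc
    lower = float(min(lower, icc))
    upper = float(min(max(upper, icc), 1.0))
    return ICCResult(float(icc), lower, upper, msr, msc, mse, n, k)


# ---------------------------------------------------------------------------
# non-parametric concordance correlation coefficient
# ---------------------------------------------------------------------------

def ccc_nonparametric(x, y, level: float = 0.95,
                      ci_method: str = "jackknife",
                      n_boot: int = 2000, seed: int | None = 0) -> EstimateCI:
    """U-statistic concordance correlation coefficient with 95% CI.

    ``ccc = 1 - E|X - Y|^2 / E|X - Y'|^2`` where the numerator expectation is
    over paired observations and the denominator over independent draws from
    the two marginals; both are estimated by U-statistics (within-pair mean
    and the mean over all cross pairs i != j).  The default CI applies the
    Fisher z-transform with a jackknife variance estimate; ``ci_method=
    "bootstrap"`` uses the percentile bootstrap instead.
    """
    x, y = _paired(x, y)
    n = x.size

    def _components(sx, sy, sxx, syy, sxy, sd2, m):
        num = sd2 / m
        den = (m * (sxx + syy) - 2.0 * sx * sy - sd2) / (m * (m - 1))
        return num, den

    sx, sy = x.sum(), y.sum()
    sxx, syy = float(x @ x), float(y @ y)
    sxy = float(x @ y)
    d2 = (x - y) ** 2
    sd2 = float(d2.sum())
    num, den = _components(sx, sy, sxx, syy, sxy, sd2, n)
    if den <= 0:
        raise AgreementError(
            "degenerate input: cross-pair variability is zero")
    if num == 0.0:
        return EstimateCI(1.0, 1.0, 1.0, level)
    ccc = 1.0 - num / den
    alpha = 1.0 - level
    zq = sps.norm.ppf(1 - alpha / 2)

    if ci_method == "jackknife":
        # leave-one-out estimates from running sums (O(n))
        m = n - 1
        sx_i, sy_i = sx - x, sy - y
        sxx_i, syy_i = sxx - x ** 2, syy - y ** 2
        sd2_i = sd2 - d2
        num_i = sd2_i / m
        den_i = (m * (sxx_i + syy_i) - 2.0 * sx_i * sy_i - sd2_i) \
            / (m * (m - 1))
        ok = den_i > 0
        ccc_i = np.where(ok, 1.0 - num_i / np.where(ok, den_i, 1.0), ccc)
        z_i = np.arctanh(np.clip(ccc_i, -1 + 1e-12, 1 - 1e-12))
        z = np.arctanh(np.clip(ccc, -1 + 1e-12, 1 - 1e-12))
        z_bar = z_i.mean()
        var_z = (n - 1) / n * float(np.sum((z_i - z_bar) ** 2))
        se = np.sqrt(var_z)
        lo, hi = np.tanh(z - zq * se), np.tanh(z + zq * se)
    elif ci_method == "bootstrap":
        if n_boot < 100:
            raise AgreementError("need at least 100 bootstrap resamples")
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        bx, by = x[idx], y[idx]
        bnum = np.mean((bx - by) ** 2, axis=1)
        bsx, bsy = bx.sum(axis=1), by.sum(axis=1)
        bsxx = np.sum(bx ** 2, axis=1)
        bsyy = np.sum(by ** 2, axis=1)
        bden = (n * (bsxx + bsyy) - 2 * bsx * bsy - bnum * n) / (n * (n - 1))
        good = bden > 0
        reps = 1.0 - bnum[good] / bden[good]
        lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        raise AgreementError(f"unknown ci_method {ci_method!r}")
    lo = float(min(lo, ccc))
    hi = float(max(hi, ccc))
    return EstimateCI(float(ccc), max(lo, -1.0), min(hi, 1.0), level)


def ccc_lin(x, y) -> float:
    """Lin's moment-based CCC (used as an independent cross-check)."""
    x, y = _paired(x, y)
    sxy = float(np.cov(x, y, ddof=0)[0, 1])
    vx, vy = x.var(), y.var()
    denom = vx + vy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise AgreementError("degenerate input for Lin's CCC")
    return 2.0 * sxy / denom


# ---------------------------------------------------------------------------
# percentile Bland-Altman
# ---------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    """Non-parametric Bland-Altman summary of criterion-minus-sensor differences.

    bias is the median difference; the limits of agreement are the empirical
    2.5th and 97.5th percentiles (linear-interpolation definition), so the
    LoA interval contains 95% of the differences.  CIs are percentile
    bootstrap.
    """

    bias: EstimateCI
    loa_lower: EstimateCI
    loa_upper: EstimateCI
    n: int
    n_boot: int

    def __post_init__(self) -> None:
        eps = 1e-12
        if not (self.loa_lower.value <= self.bias.value + eps
                <= self.loa_upper.value + 2 * eps):
            raise AgreementError("LoAs do not bracket the bias")


def bland_altman_percentile(x, y, n_boot: int = 2000,
                            seed: int | None = 0,
                            level: float = 0.95,
                            min_n: int = 20) -> BlandAltmanResult:
    """Percentile Bland-Altman with bootstrap CIs.

    `x` is the criterion series and `y` the sensor series; differences are
    ``x - y``.  Percentiles use numpy's linear interpolation between order
    statistics.
    """
    x, y = _paired(x, y, min_n=min_n)
    if n_boot < 100:
        raise AgreementError("need at least 100 bootstrap resamples")
    d = x - y
    q = np.array([2.5, 50.0, 97.5])
    lo_pt, bias_pt, hi_pt = np.percentile(d, q)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    boot = np.percentile(d[idx], q, axis=1)
    alpha = 1.0 - level
    cis = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)],
                        axis=1)

    def wrap(point, col):
        return EstimateCI(float(point),
                          float(min(cis[0, col], point)),
                          float(max(cis[1, col], point)), level)

    return BlandAltmanResult(bias=wrap(bias_pt, 1),
                             loa_lower=wrap(lo_pt, 0),
                             loa_upper=wrap(hi_pt, 2),
                             n=d.size, n_boot=n_boot)


def spearman_diff_vs_criterion(x, y) -> float:
    """Spearman rank correlation between (criterion - sensor) and criterion.

    A rho near zero indicates the bias is stable across the criterion range;
    ties are handled by midranks.
    """
    x, y = _paired(x, y)
    d = x - y
    if np.ptp(d) == 0 or np.ptp(x) == 0:
        raise AgreementError("constant input: Spearman rho undefined")
    rho = sps.spearmanr(d, x).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# dynamic time warping and the normalized similarity index
# ---------------------------------------------------------------------------

@dataclass
class DTWResult:
    """Classic DTW outcome: cumulative cost and one optimal warping path."""

    distance: float
    path: list[tuple[int, int]] = field(repr=False)

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise AgreementError("DTW distance cannot be negative")


def dtw(a, b) -> DTWResult:
    """Dynamic time warping with absolute-difference cost.

    Symmetric step set {(1,0), (0,1), (1,1)}, no window, no slope weighting;
    the returned distance is the raw cumulative cost along one optimal path
    (ties broken preferring the diagonal step).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise AgreementError("DTW needs sequences of length >= 2")
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        row = acc[i]
        prev = acc[i - 1]
        for j in range(1, m):
            row[j] = cost[i, j] + min(prev[j - 1], prev[j], row[j - 1])
    # backtrack, preferring the diagonal on ties
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            options = (acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1])
            pick = int(np.argmin(options))  # argmin takes the first == diagonal
            if pick == 0:
                i, j = i - 1, j - 1
            elif pick == 1:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return DTWResult(float(acc[n - 1, m - 1]), path)


def nsi(criterion, sens) -> float:
    """Normalized similarity index ``(M - d) / M``.

    ``d`` is the DTW distance between the two series and ``M`` is the number
    of criterion samples times the criterion amplitude range
    (max - min).  1 means identical shape; values below 0 indicate
    pathological dissimilarity.
    """
    criterion = np.asarray(criterion, dtype=float).ravel()
    rng = float(np.ptp(criterion))
    if rng == 0:
        raise AgreementError(
            "constant criterion: NSI normalizer is zero (undefined)")
    m = criterion.size * rng
    d = dtw(criterion, sens).distance
    return float((m - d) / m)


# ---------------------------------------------------------------------------
# normality screen
# ---------------------------------------------------------------------------

def ks_normality(x, alpha: float = 0.05) -> tuple[float, float]:
    """Lilliefors-type Kolmogorov-Smirnov test against a fitted normal.

    Tests against a normal with the sample mean and SD (critical values
    corrected for the estimated parameters).  Used to route the analysis to
    the non-parametric CCC and percentile Bland-Altman when normality is
    rejected.  Returns ``(statistic, p_value)``.
    """
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(x, dtype=float).ravel()
    if x.size < 5:
        raise AgreementError("need at least 5 observations")
    if np.ptp(x) == 0:
        raise AgreementError("zero-variance input: normality test undefined")
    stat, p = lilliefors(x, dist="norm")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# bundled per-axis comparison
# ---------------------------------------------------------------------------

@dataclass
class AgreementResult:
    """Full time-domain agreement summary for one channel.

    Differences are criterion minus sensor.  ``nsi`` may be None when the
    DTW-based index is not applicable (e.g. pooled heterogeneous features).
    """

    ccc: EstimateCI
    bias: EstimateCI
    loa_lower: EstimateCI
    loa_upper: EstimateCI
    spearman_rho: float
    nsi: float | None
    n_points: int
    dtw_distance: float | None = None
    ks_p: float | None = None

    def __post_init__(self) -> None:
        if self.nsi is not None and self.nsi > 1 + 1e-9:
            raise AgreementError("NSI cannot exceed 1")


def compare_series(criterion, sens, n_boot: int = 2000,
                   seed: int | None = 0, include_dtw: bool = True,
                   min_n: int = 20) -> AgreementResult:
    """All time-domain agreement statistics for one criterion/sensor pair."""
    x, y = _paired(criterion, sens, min_n=min_n)
    ba = bland_altman_percentile(x, y, n_boot=n_boot, seed=seed, min_n=min_n)
    ccc = ccc_nonparametric(x, y)
    try:
        rho = spearman_diff_vs_criterion(x, y)
    except AgreementError:
        rho = 0.0  # identical series: flat differences, no trend to detect
    if include_dtw:
        d = dtw(x, y).distance
        sim = nsi(x, y)
    else:
        d = sim = None
    try:
        _, ks_p = ks_normality(x - y)
    except AgreementError:
        ks_p = None
    return AgreementResult(ccc=ccc, bias=ba.bias, loa_lower=ba.loa_lower,
                           loa_upper=ba.loa_upper, spearman_rho=rho,
                           nsi=sim, n_points=x.size, dtw_distance=d,
                           ks_p=ks_p)
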