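"""Group-level statistics for the two-condition block design.

Implements the analysis chain applied to hemoglobin change rates:
baseline-ratio normalisation, 13-period segmentation, two-way
repeated-measures ANOVA (condition x period) with Mauchly's sphericity
test and the Greenhouse-Geisser correction, per-period paired t tests
with Cohen's d and noncentral-t post-hoc power, a-priori sample size,
and the nonparametric alternatives (Wilcoxon matched-pairs signed rank,
Shapiro-Wilk normality) used for the subjective-rating comparisons.

Two Cohen's d variants are reported for a paired contrast: ``d_av``
divides the mean difference by the pooled average of the two condition
SDs (the tabled effect size), ``d_z`` divides by the SD of the paired
differences. Post-hoc power follows the matched-pairs noncentral-t
convention with noncentrality ``d * sqrt(n)`` applied to the tabled d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .design import ExperimentDesign

__all__ = [
    "RmAnovaEffect",
    "RmAnovaResult",
    "PairedComparison",
    "WilcoxonResult",
    "NormalityResult",
    "normalize_baseline",
    "segment_periods",
    "gg_epsilon",
    "mauchly",
    "rm_anova",
    "paired_t",
    "posthoc_power",
    "required_n",
    "wilcoxon_signed_rank",
    "shapiro_wilk",
]


# --- time-series preprocessing ---------------------------------------------

def normalize_baseline(values: np.ndarray, design: ExperimentDesign) -> np.ndarray:
    """Divide every sample by the mean of the pre-record baseline window.

    ``values`` holds the full record including the ``design.baseline_samples``
    leading baseline samples. The output is a dimensionless change-rate
    series whose baseline mean is 1 by construction; multiplying the input
    by any positive constant leaves it unchanged.
    """
    values = np.asarray(values, dtype=float)
    nb = design.baseline_samples
    if values.shape[0] < nb + 1:
        raise ValueError(
            f"record has {values.shape[0]} samples; need more than the "
            f"{nb} baseline samples"
        )
    baseline = float(np.mean(values[:nb]))
    if baseline <= 0:
        raise ValueError(f"baseline mean must be positive, got {baseline}")
    return values / baseline


def segment_periods(change_rate: np.ndarray, design: ExperimentDesign) -> np.ndarray:
    """Mean change rate in each of the 13 one-minute periods.

    Windows are half-open ``[start, end)``: a sample on a boundary instant
    belongs to the later period. The input must cover all windows.
    """
    change_rate = np.asarray(change_rate, dtype=float)
    if change_rate.shape[0] != design.n_samples:
        raise ValueError(
            f"expected {design.n_samples} samples (incl. baseline), "
            f"got {change_rate.shape[0]}"
        )
    t = design.sample_times()
    idx = design.period_index(t)
    means = np.empty(design.n_periods)
    for p in range(design.n_periods):
        mask = idx == p
        if not mask.any():
            raise ValueError(f"period {design.periods[p]} contains no samples")
        means[p] = change_rate[mask].mean()
    return means


# --- repeated-measures ANOVA ------------------------------------------------

@dataclass(frozen=True)
class RmAnovaEffect:
    F: float
    df1: float
    df2: float
    p: float
    df1_corr: float
    df2_corr: float
    p_corr: float


@dataclass(frozen=True)
class RmAnovaResult:
    """Two-way within-subject ANOVA with sphericity handling.

    ``condition`` is uncorrected (2 levels need no correction, so its
    corrected fields equal the raw ones); ``period`` and ``interaction``
    carry Greenhouse-Geisser corrected df and p alongside the raw ones.
    """

    condition: RmAnovaEffect
    period: RmAnovaEffect
    interaction: RmAnovaEffect
    epsilon_gg_period: float
    epsilon_gg_interaction: float
    mauchly_p_period: float
    mauchly_p_interaction: float
    n_subjects: int


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """A (k, k-1) orthonormal basis of the contrast space (Helmert-based)."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
    return h / np.linalg.norm(h, axis=0, keepdims=True)


def gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of an (n_subjects, k) within-factor score
    matrix, via the covariance of orthonormal contrast scores (Box's
    formula). Bounded by 1/(k-1) and 1; equals 1 under exact sphericity.
    A zero covariance (identical rows) degenerates to 1."""
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    c = _orthonormal_contrasts(k)
    z = scores @ c
    s = np.cov(z, rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    tr = np.trace(s)
    tr2 = np.sum(s * s.T)
    if tr2 <= 0:
        return 1.0
    eps = tr**2 / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly(scores: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on an (n, k) score matrix.

    Returns (W, p) from the chi-square approximation. Degenerate cases
    (singular contrast covariance, e.g. n - 1 < k - 1 or constant data)
    return (nan, nan) - sphericity then cannot be tested, only corrected.
    """
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    d = k - 1
    if d < 2:
        return float("nan"), float("nan")
    z = scores @ _orthonormal_contrasts(k)
    s = np.cov(z, rowvar=False, ddof=1)
    sign, logdet = np.linalg.slogdet(s)
    tr = np.trace(s)
    if sign <= 0 or tr <= 0:
        return float("nan"), float("nan")
    log_w = logdet - d * np.log(tr / d)
    w = float(np.exp(log_w))
    df = d * (d + 1) // 2 - 1
    f_corr = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f_corr * log_w
    p = float(sps.chi2.sf(chi2, df))
    return w, p


def _f_or_zero(ss_eff: float, df_eff: float, ss_err: float, df_err: float) -> tuple[float, float]:
    ms_err = ss_err / df_err
    ms_eff = ss_eff / df_eff
    if ms_err == 0:
        return (0.0, 1.0) if ms_eff == 0 else (float("inf"), 0.0)
    f = ms_eff / ms_err
    return f, float(sps.f.sf(f, df_eff, df_err))


def rm_anova(data: np.ndarray) -> RmAnovaResult:
    """Two-way fully within-subject ANOVA on a complete, balanced
    (n_subjects, n_conditions, n_periods) array.

    Each effect is tested against its own effect-by-subject error term.
    Greenhouse-Geisser epsilon for the period main effect comes from the
    condition-averaged period scores; for the interaction, from the
    between-condition difference scores (exact for a 2-level condition
    factor). Missing cells are a hard error - no imputation.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected (subjects, conditions, periods) array")
    if np.any(~np.isfinite(data)):
        raise ValueError("RM-ANOVA requires a complete matrix: NaN cells found")
    n, a, b = data.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if a != 2:
        raise ValueError(f"the design has exactly 2 conditions, got {a}")

    grand = data.mean()
    m_s = data.mean(axis=(1, 2))            # subject means
    m_a = data.mean(axis=(0, 2))            # condition means
    m_b = data.mean(axis=(0, 1))            # period means
    m_sa = data.mean(axis=2)                # subject x condition
    m_sb = data.mean(axis=1)                # subject x period
    m_ab = data.mean(axis=0)                # condition x period

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        data
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    df_a, df_b, df_ab = a - 1.0, b - 1.0, (a - 1.0) * (b - 1.0)
    df_as, df_bs, df_abs = (n - 1.0) * df_a, (n - 1.0) * df_b, (n - 1.0) * df_ab

    f_a, p_a = _f_or_zero(ss_a, df_a, ss_as, df_as)
    f_b, p_b = _f_or_zero(ss_b, df_b, ss_bs, df_bs)
    f_ab, p_ab = _f_or_zero(ss_ab, df_ab, ss_abs, df_abs)

    period_scores = data.mean(axis=1)            # average over conditions
    diff_scores = data[:, 0, :] - data[:, 1, :]  # 2-level condition contrast
    eps_b = gg_epsilon(period_scores)
    eps_ab = gg_epsilon(diff_scores)
    _, mauchly_p_b = mauchly(period_scores)
    _, mauchly_p_ab = mauchly(diff_scores)

    d1b, d2b = eps_b * df_b, eps_b * df_bs
    p_b_corr = float(sps.f.sf(f_b, d1b, d2b)) if np.isfinite(f_b) else 0.0
    d1ab, d2ab = eps_ab * df_ab, eps_ab * df_abs
    p_ab_corr = float(sps.f.sf(f_ab, d1ab, d2ab)) if np.isfinite(f_ab) else 0.0

    return RmAnovaResult(
        condition=RmAnovaEffect(f_a, df_a, df_as, p_a, df_a, df_as, p_a),
        period=RmAnovaEffect(f_b, df_b, df_bs, p_b, d1b, d2b, p_b_corr),
        interaction=RmAnovaEffect(f_ab, df_ab, df_abs, p_ab, d1ab, d2ab, p_ab_corr),
        epsilon_gg_period=eps_b,
        epsilon_gg_interaction=eps_ab,
        mauchly_p_period=mauchly_p_b,
        mauchly_p_interaction=mauchly_p_ab,
        n_subjects=n,
    )


# --- paired comparisons, effect size, power ---------------------------------

@dataclass(frozen=True)
class PairedComparison:
    t: float
    df: int
    p: float
    d: float        # d_av: mean difference / pooled average condition SD
    d_z: float      # mean difference / SD of paired differences
    power: float    # post-hoc power at alpha, noncentrality d * sqrt(n)
    extreme: bool = False

    @property
    def d_av(self) -> float:
        return self.d


def paired_t(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> PairedComparison:
    """Two-tailed paired t test of x vs y with effect sizes and power.

    ``d`` (= d_av) standardises the mean difference by the average of the
    two condition SDs and feeds the post-hoc power; ``d_z`` uses the SD of
    the differences. A zero-variance difference with nonzero mean is
    reported as an extreme result (t = +-inf, p = 0) and flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t needs two equal-length 1-D samples")
    n = x.shape[0]
    if n < 2:
        raise ValueError("paired_t needs n >= 2")
    d = x - y
    md = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    s_av = np.sqrt((x.std(ddof=1) ** 2 + y.std(ddof=1) ** 2) / 2.0)
    d_av = md / s_av if s_av > 0 else (0.0 if md == 0 else np.inf * np.sign(md))
    if sd == 0:
        if md == 0:
            return PairedComparison(0.0, df, 1.0, 0.0, 0.0, alpha)
        t = float(np.inf * np.sign(md))
        return PairedComparison(
            t, df, 0.0, float(d_av), t, 1.0, extreme=True
        )
    t = md / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    d_z = md / sd
    power = posthoc_power(abs(float(d_av)), n, alpha) if np.isfinite(d_av) else 1.0
    return PairedComparison(float(t), df, p, float(d_av), float(d_z), power)


def posthoc_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Two-tailed paired-design power from the noncentral t distribution
    with df = n - 1 and noncentrality d * sqrt(n)."""
    if d < 0:
        raise ValueError(f"effect size d must be >= 0, got {d}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    df = n - 1
    nc = d * np.sqrt(n)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def required_n(
    d: float, alpha: float = 0.05, power_target: float = 0.8, n_max: int = 100_000
) -> int:
    """Smallest n with posthoc_power(d, n, alpha) >= power_target."""
    if d <= 0:
        raise ValueError(f"effect size d must be positive, got {d}")
    if not 0 < power_target < 1:
        raise ValueError(f"power target must be in (0, 1), got {power_target}")
    for n in range(2, n_max + 1):
        if posthoc_power(d, n, alpha) >= power_target:
            return n
    raise ValueError(
        f"power target {power_target} unreachable for d={d} within n <= {n_max}"
    )


# --- nonparametrics ----------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    w: float        # sum of signed ranks
    p: float
    n_used: int     # pairs remaining after dropping zero differences


@dataclass(frozen=True)
class NormalityResult:
    w_stat: float
    p: float
    degenerate: bool = False

    @property
    def normal_at(self) -> float:
        return self.p


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> WilcoxonResult:
    """Wilcoxon matched-pairs signed rank test, reporting the sum of signed
    ranks W (so all-positive differences over n pairs give n(n+1)/2).

    Zero differences are dropped before ranking; ties get midranks. The
    two-tailed p is exact (full sign enumeration) for n <= 25 without ties,
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("wilcoxon_signed_rank needs two equal-length 1-D samples")
    d = x - y
    d = d[d != 0]
    n = d.shape[0]
    if n == 0:
        raise ValueError("all paired differences are zero: test undefined")
    ranks = sps.rankdata(np.abs(d))
    w = float(np.sum(np.sign(d) * ranks))
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    p = float(sps.wilcoxon(d, method=method).pvalue)
    return WilcoxonResult(w=w, p=p, n_used=n)


def shapiro_wilk(values: np.ndarray) -> NormalityResult:
    """Shapiro-Wilk normality test (Royston's algorithm via scipy).

    Constant input is degenerate: flagged, with NaN statistics.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or not 3 <= values.shape[0] <= 5000:
        raise ValueError("shapiro_wilk needs a 1-D sample with 3 <= n <= 5000")
    if np.ptp(values) == 0:
        return NormalityResult(float("nan"), float("nan"), degenerate=True)
    w, p = sps.shapiro(values)
    return NormalityResult(float(w), float(p))
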