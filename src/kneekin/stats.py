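"""Two-group comparisons and the power / detectable-difference analysis.

The rotation comparisons are two-sample t-tests (Welch by default: the
group SDs of maximum-flexion rotation differ by a factor of ~3, so the
pooled-variance assumption is untenable; pooled is available as an
option).  Categorical demographics use Pearson's chi-square without
continuity correction.  The power analysis uses the noncentral-t
distribution with Welch-Satterthwaite degrees of freedom computed from
the two group SDs; the default is one-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sps

from .errors import ParameterError


@dataclass
class GroupSample:
    """One group's per-knee rotation values (degrees)."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ParameterError(f"group {self.label!r} needs n >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError(f"group {self.label!r} contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    kind: str  # welch | pooled | chi_square

    def as_dict(self) -> dict:
        return dict(statistic=self.statistic, df=self.df, p_value=self.p_value,
                    mean_a=self.mean_a, sd_a=self.sd_a,
                    mean_b=self.mean_b, sd_b=self.sd_b, kind=self.kind)


def two_sample_t(a: GroupSample, b: GroupSample, kind: str = "welch") -> TestResult:
    """Two-sided two-sample t-test (Welch default, pooled optional)."""
    if kind not in ("welch", "pooled"):
        raise ParameterError(f"kind must be welch|pooled, got {kind!r}")
    res = sps.ttest_ind(a.values, b.values, equal_var=(kind == "pooled"))
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      a.mean, a.sd, b.mean, b.sd, kind)


def chi_square(counts) -> TestResult:
    """Pearson's chi-square on a 2x2 table, no continuity correction."""
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ParameterError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ParameterError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ParameterError("chi-square undefined: table has a zero margin")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    row = table[0].astype(float)
    tot = table.sum(axis=0).astype(float)
    return TestResult(float(stat), float(df), float(p),
                      mean_a=row[0] / tot[0], sd_a=np.nan,
                      mean_b=row[1] / tot[1], sd_b=np.nan, kind="chi_square")


# ---------------------------------------------------------------------------
# power analysis


@dataclass(frozen=True)
class PowerSpec:
    """Design of the two-group rotation comparison used for power:
    n = 25 knees per group, alpha = 0.05, target power 0.80, and group
    SDs of rotation in arcs of extension of 2.9 deg (TKA) and 4.6 deg
    (native).  One-sided by default."""

    n_per_group: int = 25
    alpha: float = 0.05
    target_power: float = 0.80
    sd_a: float = 2.9
    sd_b: float = 4.6
    sided: str = "one"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError("alpha must be in (0, 1)")
        if not (0.0 < self.target_power < 1.0):
            raise ParameterError("target_power must be in (0, 1)")
        if self.sd_a <= 0 or self.sd_b <= 0:
            raise ParameterError("group SDs must be > 0")
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if self.sided not in ("one", "two"):
            raise ParameterError(f"sided must be one|two, got {self.sided!r}")

    @property
    def se(self) -> float:
        return float(np.sqrt(self.sd_a**2 / self.n_per_group
                             + self.sd_b**2 / self.n_per_group))

    @property
    def welch_df(self) -> float:
        va = self.sd_a**2 / self.n_per_group
        vb = self.sd_b**2 / self.n_per_group
        return float((va + vb) ** 2
                     / (va**2 / (self.n_per_group - 1) + vb**2 / (self.n_per_group - 1)))


def power_at(delta: float, spec: PowerSpec = PowerSpec()) -> float:
    """Rejection probability of the Welch test at true group difference
    ``delta`` (deg), via the noncentral-t distribution."""
    if delta < 0:
        raise ParameterError(f"delta must be >= 0, got {delta}")
    df = spec.welch_df
    nc = delta / spec.se
    if spec.sided == "one":
        t_crit = sps.t.ppf(1.0 - spec.alpha, df)
        return float(sps.nct.sf(t_crit, df, nc))
    t_crit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(sps.nct.sf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc))


def detectable_difference(spec: PowerSpec = PowerSpec()) -> float:
    """Smallest true group difference (deg) whose power reaches the
    target, by root-finding on the noncentral-t power curve."""
    target = spec.target_power

    def gap(delta):
        return power_at(delta, spec) - target

    hi = spec.se
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6 * spec.se:  # pragma: no cover - defensive
            raise ParameterError("power never reaches the target")
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-10))


def simulate_power(delta: float, spec: PowerSpec = PowerSpec(),
                   n_reps: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo cross-check of :func:`power_at`: draw both groups,
    run the Welch test vectorized over replicates, return the rejection
    rate."""
    rng = np.random.default_rng(seed)
    n = spec.n_per_group
    a = rng.normal(delta, spec.sd_a, size=(n_reps, n))
    b = rng.normal(0.0, spec.sd_b, size=(n_reps, n))
    va = a.var(axis=1, ddof=1) / n
    vb = b.var(axis=1, ddof=1) / n
    t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n - 1) + vb**2 / (n - 1))
    if spec.sided == "one":
        reject = t > sps.t.ppf(1.0 - spec.alpha, df)
    else:
        reject = np.abs(t) > sps.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(reject.mean())


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class Summary:
    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> tuple[float, float]:
        return (self.q1, self.q3)


def summarize(values) -> Summary:
    """Mean/SD (n-1), range, median and IQR (linear-interpolation
    quantiles) of a sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("summarize: empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return Summary(int(v.size), float(v.mean()), sd, float(v.min()), float(v.max()),
                   float(med), float(q1), float(q3))
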