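"""Statistical layer for tunnel-widening cohorts.

Implements the analysis applied to paired Year-0 / Year-1 tunnel
measurements: per-subject widening in mm and percent, paired t-tests within
each surgical technique, Welch two-sample tests between the single-bundle
(SB) and double-bundle (DB) groups, ICC(2,1) rater reliability with
nonparametric bootstrap confidence intervals, and the a-priori paired-design
power / sample-size computation based on the noncentral t distribution.

The ICC is the single-measures, absolute-agreement intraclass correlation
under a two-way random-effects model:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with MSR / MSC / MSE the subject, rater and error mean squares of the
two-way ANOVA over an n-subjects x k-raters matrix.

The main entry point is :class:`TunnelWideningModel`, a statsmodels-style
model object built from a long-format measurement table whose ``fit()``
returns a :class:`TunnelWideningResults` carrying per-tunnel widening tables,
group comparisons and a text ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AclTunnelError

ALPHA_DEFAULT = 0.05
BOOTSTRAP_B_DEFAULT = 2000


# ---------------------------------------------------------------------------
# widening records


@dataclass(frozen=True)
class WideningRecord:
    subject_id: str
    tunnel: str
    level: str
    d0: float
    d1: float

    def __post_init__(self):
        if self.d0 <= 0:
            raise ValueError("Year-0 diameter must be positive")

    @property
    def delta_mm(self) -> float:
        return self.d1 - self.d0

    @property
    def delta_pct(self) -> float:
        return 100.0 * (self.d1 - self.d0) / self.d0


def widening_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Pair Year-0/Year-1 rows into one widening record per subject x tunnel x level.

    Expects long format with columns subject, tunnel, level, timepoint
    (``year0``/``year1``) and diameter_mm (a ``group`` column is carried
    through if present).  Unmatched pairs are rejected.
    """
    required = {"subject", "tunnel", "level", "timepoint", "diameter_mm"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table is missing columns {sorted(missing)}")
    keys = ["subject", "tunnel", "level"]
    if "group" in measurements.columns:
        keys = ["subject", "group", "tunnel", "level"]
    wide = measurements.pivot_table(
        index=keys, columns="timepoint", values="diameter_mm", aggfunc="first"
    )
    if "year0" not in wide.columns or "year1" not in wide.columns:
        raise ValueError("need both year0 and year1 timepoints")
    if wide[["year0", "year1"]].isna().any().any():
        bad = wide[wide[["year0", "year1"]].isna().any(axis=1)].index.tolist()
        raise ValueError(f"unmatched year0/year1 pairs for {bad[:5]}...")
    out = wide.reset_index().rename(columns={"year0": "d0", "year1": "d1"})
    if (out["d0"] <= 0).any():
        raise ValueError("non-positive Year-0 diameters in the table")
    out["delta_mm"] = out["d1"] - out["d0"]
    out["delta_pct"] = 100.0 * out["delta_mm"] / out["d0"]
    out.columns.name = None
    return out


def ratio_of_means_pct(mean_delta_mm: float, mean_d0_mm: float) -> float:
    """Percentage widening from group means, 100 * mean(delta) / mean(d0)."""
    if mean_d0_mm <= 0:
        raise ValueError("mean Year-0 diameter must be positive")
    return 100.0 * mean_delta_mm / mean_d0_mm


# ---------------------------------------------------------------------------
# t-tests


@dataclass(frozen=True)
class StatsResult:
    """A paired or Welch t-test outcome with its 95 % confidence interval."""

    test: str
    estimate: float
    ci95: tuple[float, float]
    t_stat: float
    df: float
    p_value: float
    n: int
    n2: Optional[int] = None

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.estimate <= hi):
            raise AclTunnelError("confidence interval does not bracket the estimate")
        if not (0.0 <= self.p_value <= 1.0):
            raise AclTunnelError("p-value outside [0, 1]")


def paired_t(deltas: Sequence[float], alpha: float = ALPHA_DEFAULT) -> StatsResult:
    """One-sample t-test of paired differences against zero (two-sided)."""
    d = np.asarray(deltas, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2 differences")
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        kind = "all-zero (no effect)" if mean == 0.0 else "constant nonzero"
        raise ValueError(f"zero variance in differences: {kind} input is degenerate")
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    tc = sps.t.ppf(1.0 - alpha / 2.0, df)
    return StatsResult(
        test="paired_t", estimate=mean, ci95=(mean - tc * se, mean + tc * se),
        t_stat=float(t), df=float(df), p_value=float(min(p, 1.0)), n=n,
    )


def welch_t(deltas_a: Sequence[float], deltas_b: Sequence[float],
            alpha: float = ALPHA_DEFAULT) -> StatsResult:
    """Welch two-sample t-test (unequal variances, Welch-Satterthwaite df)."""
    a = np.asarray(deltas_a, dtype=float)
    b = np.asarray(deltas_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch test needs n >= 2 in both groups")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0.0:
        raise ValueError("both groups have zero variance")
    est = float(a.mean() - b.mean())
    t = est / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    tc = sps.t.ppf(1.0 - alpha / 2.0, df)
    half = tc * np.sqrt(se2)
    return StatsResult(
        test="welch_t", estimate=est, ci95=(est - half, est + half),
        t_stat=float(t), df=float(df), p_value=float(min(p, 1.0)), n=na, n2=nb,
    )


# ---------------------------------------------------------------------------
# ICC(2,1) and bootstrap CI


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci95: Optional[tuple[float, float]]
    n_subjects: int
    k_raters: int
    b_resamples: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.icc > 1.0 + 1e-12:
            raise AclTunnelError("ICC cannot exceed 1")


def icc_2_1(data: np.ndarray) -> ICCResult:
    """Single-measures absolute-agreement ICC, two-way random effects.

    ``data`` is an n-subjects x k-raters matrix with no missing cells.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("ICC input must be a subjects x raters matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 subjects and >= 2 raters, got {n} x {k}")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported (no imputation)")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom) if denom != 0 else 1.0
    return ICCResult(icc=icc, ci95=None, n_subjects=n, k_raters=k)


def bootstrap_icc_ci(
    data: np.ndarray, b: int = BOOTSTRAP_B_DEFAULT, seed: int = 0,
    level: float = 0.95,
) -> ICCResult:
    """Percentile bootstrap CI for ICC(2,1), resampling subjects (rows).

    Seeded and reproducible; the interval is widened if needed so it always
    brackets the point estimate.  Percentile intervals are known to
    under-cover slightly for ICCs near 1.
    """
    if b < 200:
        raise ValueError("use at least 200 bootstrap resamples")
    x = np.asarray(data, dtype=float)
    point = icc_2_1(x)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    boots = np.empty(b)
    for i in range(b):
        rows = rng.integers(0, n, size=n)
        xb = x[rows]
        # degenerate resample (constant rows) -> ICC of 1 by convention
        try:
            boots[i] = icc_2_1(xb).icc
        except (ValueError, ZeroDivisionError):
            boots[i] = 1.0
    q = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [q, 1.0 - q])
    lo = min(float(lo), point.icc)
    hi = max(float(hi), point.icc)
    return ICCResult(
        icc=point.icc, ci95=(lo, hi), n_subjects=n, k_raters=x.shape[1],
        b_resamples=b, seed=seed,
    )


def rater_matrix(df: pd.DataFrame, value: str = "value", rater: str = "rater",
                 unit: str = "subject") -> np.ndarray:
    """Pivot a long rater table into the units x raters matrix for the ICC.

    ``unit`` selects the sampling unit: ``"subject"`` (tunnels averaged
    within subject, the default) or ``"tunnel"`` (each tunnel its own row,
    requiring a ``tunnel`` column).
    """
    if unit == "subject":
        grouped = df.groupby(["subject", rater])[value].mean().unstack(rater)
    elif unit == "tunnel":
        grouped = df.groupby(["subject", "tunnel", rater])[value].mean().unstack(rater)
    else:
        raise ValueError(f"unknown sampling unit {unit!r}")
    if grouped.isna().any().any():
        raise ValueError("incomplete rater table (missing cells)")
    return grouped.to_numpy()


# ---------------------------------------------------------------------------
# power / sample size


@dataclass(frozen=True)
class PowerSpec:
    """A-priori paired-design power specification."""

    delta: float
    sd: float
    alpha: float = ALPHA_DEFAULT
    power: float = 0.80
    sided: str = "two"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.sd <= 0 or self.delta <= 0:
            raise ValueError("delta and sd must be positive")
        if self.sided not in ("two", "one"):
            raise ValueError("sided must be 'two' or 'one'")


def paired_t_power(n: int, ps: PowerSpec) -> float:
    """Exact power of the paired-difference t-test at sample size n."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = ps.delta / ps.sd * np.sqrt(n)
    if ps.sided == "two":
        tc = sps.t.ppf(1.0 - ps.alpha / 2.0, df)
        upper = sps.nct.sf(tc, df, nc)
        lower = sps.nct.cdf(-tc, df, nc)  # scipy yields nan at extreme nc
        if not np.isfinite(lower):
            lower = 0.0
        return float(upper + lower)
    tc = sps.t.ppf(1.0 - ps.alpha, df)
    return float(sps.nct.sf(tc, df, nc))


def required_sample_size(ps: PowerSpec, n_max: int = 100000,
                         approximation: str = "noncentral_t") -> int:
    """Smallest n giving the target power for a paired-difference t-test.

    Iterates n over the exact noncentral-t power (default) or a normal
    approximation.  With the published planning inputs (detectable widening
    0.5 mm, SD 0.74 mm, alpha 0.05, power 0.80) this yields n <= 20 patients.
    """
    if approximation == "normal":
        za = sps.norm.ppf(1.0 - ps.alpha / (2.0 if ps.sided == "two" else 1.0))
        zb = sps.norm.ppf(ps.power)
        return max(2, int(np.ceil(((za + zb) * ps.sd / ps.delta) ** 2)))
    if approximation != "noncentral_t":
        raise ValueError(f"unknown approximation {approximation!r}")
    for n in range(2, n_max + 1):
        if paired_t_power(n, ps) >= ps.power:
            return n
    raise AclTunnelError(f"no n <= {n_max} reaches the requested power")


# ---------------------------------------------------------------------------
# enrollment bookkeeping


@dataclass(frozen=True)
class EnrollmentFlow:
    """Study-flow arithmetic from screened patients to the analysed cohort."""

    screened: int = 56
    withdrawals: tuple = (
        ("logistical", 8),
        ("declined_radiation", 1),
        ("lost_to_followup", 2),
        ("technical_ct_errors", 3),
    )
    group_sizes: tuple = (("DB", 20), ("SB", 22))

    def analyzed(self) -> int:
        n = self.screened - sum(k for _, k in self.withdrawals)
        groups = dict(self.group_sizes)
        if sum(groups.values()) != n:
            raise AclTunnelError(
                f"group sizes {groups} do not sum to screened minus withdrawals ({n})"
            )
        return n


# ---------------------------------------------------------------------------
# report tables (Model / Results)

#: SB-vs-DB comparisons reported per measurement level.
GROUP_COMPARISONS = (
    ("femur", "femur_AM"),
    ("femur", "femur_PL"),
    ("tibia", "tibia_AM"),
    ("tibia", "tibia_PL"),
)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; reports default to raw p)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _p_display(p: float, alpha: float = ALPHA_DEFAULT) -> str:
    if p >= alpha:
        return "ns"
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


def per_tunnel_widening(records: pd.DataFrame, alpha: float = ALPHA_DEFAULT,
                        adjust: str = "none") -> pd.DataFrame:
    """Per-tunnel widening summary: Year-0/Year-1 means, widening CI, paired t.

    Percentage widening is computed per subject (100 * delta / d0) and
    averaged, with the ratio-of-means variant reported alongside; both round
    to the same printed integers at the default study conditions.
    """
    rows = []
    for (group, tunnel, level), sub in records.groupby(["group", "tunnel", "level"]):
        res = paired_t(sub["delta_mm"].to_numpy(), alpha=alpha)
        res_pct = paired_t(sub["delta_pct"].to_numpy(), alpha=alpha)
        rows.append({
            "group": group, "tunnel": tunnel, "level": level, "n": len(sub),
            "year0_mean": sub["d0"].mean(), "year0_sd": sub["d0"].std(ddof=1),
            "year1_mean": sub["d1"].mean(), "year1_sd": sub["d1"].std(ddof=1),
            "widening_mm": res.estimate,
            "widening_mm_ci_lo": res.ci95[0], "widening_mm_ci_hi": res.ci95[1],
            "widening_pct": res_pct.estimate,
            "widening_pct_ci_lo": res_pct.ci95[0],
            "widening_pct_ci_hi": res_pct.ci95[1],
            "widening_pct_ratio_of_means": ratio_of_means_pct(
                res.estimate, sub["d0"].mean()
            ),
            "t_stat": res.t_stat, "p_value": res.p_value,
            "p_display": _p_display(res.p_value, alpha),
        })
    out = pd.DataFrame(rows)
    if adjust == "holm" and len(out):
        out["p_holm"] = holm_adjust(out["p_value"].to_numpy())
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def group_comparison(records: pd.DataFrame, alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """SB-vs-DB Welch comparisons of widening per measurement level."""
    rows = []
    for level in sorted(records["level"].unique()):
        sub = records[records["level"] == level]
        for sb_tunnel, db_tunnel in GROUP_COMPARISONS:
            a = sub[(sub["group"] == "SB") & (sub["tunnel"] == sb_tunnel)]["delta_mm"]
            b = sub[(sub["group"] == "DB") & (sub["tunnel"] == db_tunnel)]["delta_mm"]
            if len(a) < 2 or len(b) < 2:
                continue
            res = welch_t(a.to_numpy(), b.to_numpy(), alpha=alpha)
            rows.append({
                "level": level, "sb_tunnel": sb_tunnel, "db_tunnel": db_tunnel,
                "sb_mean": a.mean(), "sb_sd": a.std(ddof=1), "sb_n": len(a),
                "db_mean": b.mean(), "db_sd": b.std(ddof=1), "db_n": len(b),
                "difference": res.estimate, "t_stat": res.t_stat, "df": res.df,
                "p_value": res.p_value, "p_display": _p_display(res.p_value, alpha),
            })
    return pd.DataFrame(rows)


def cohort_report(measurements: pd.DataFrame, alpha: float = ALPHA_DEFAULT,
                  adjust: str = "none") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: per-tunnel widening table + group-comparison table."""
    records = widening_table(measurements)
    return (per_tunnel_widening(records, alpha, adjust=adjust),
            group_comparison(records, alpha))


class TunnelWideningModel:
    """Statsmodels-style model over a long-format tunnel measurement table.

    Parameters
    ----------
    data : DataFrame with columns subject, group, tunnel, level, timepoint,
        diameter_mm (one row per subject x tunnel x level x timepoint).
    """

    def __init__(self, data: pd.DataFrame, alpha: float = ALPHA_DEFAULT):
        self.data = data.copy()
        self.alpha = alpha
        self.records = widening_table(self.data)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "TunnelWideningModel":
        return cls(data, **kw)

    @classmethod
    def from_csv(cls, path: str, **kw) -> "TunnelWideningModel":
        return cls(pd.read_csv(path), **kw)

    def fit(self, rater_data: Optional[pd.DataFrame] = None,
            bootstrap_b: int = BOOTSTRAP_B_DEFAULT, seed: int = 0,
            power_spec: Optional[PowerSpec] = None) -> "TunnelWideningResults":
        per_tunnel = per_tunnel_widening(self.records, self.alpha)
        comparisons = group_comparison(self.records, self.alpha)
        icc = None
        if rater_data is not None:
            icc = bootstrap_icc_ci(rater_matrix(rater_data), b=bootstrap_b, seed=seed)
        if power_spec is None:
            power_spec = PowerSpec(delta=0.5, sd=0.74)
        n_required = required_sample_size(power_spec)
        return TunnelWideningResults(
            model=self, per_tunnel=per_tunnel, comparisons=comparisons,
            icc=icc, power_spec=power_spec, n_required=n_required,
        )


@dataclass
class TunnelWideningResults:
    """Fitted widening analysis: estimates, CIs, reliability and power."""

    model: TunnelWideningModel
    per_tunnel: pd.DataFrame
    comparisons: pd.DataFrame
    icc: Optional[ICCResult]
    power_spec: PowerSpec
    n_required: int

    def summary(self) -> str:
        lines = ["Tunnel widening analysis", "=" * 56]
        lines.append("\nPer-tunnel widening (paired t, Year 1 - Year 0):")
        for _, r in self.per_tunnel.iterrows():
            lines.append(
                f"  {r['group']:>2} {r['tunnel']:<10} {r['level']:<8} "
                f"{r['year0_mean']:.1f}±{r['year0_sd']:.1f} -> "
                f"{r['year1_mean']:.1f}±{r['year1_sd']:.1f} mm   "
                f"Δ {r['widening_mm']:.1f} [{r['widening_mm_ci_lo']:.1f}, "
                f"{r['widening_mm_ci_hi']:.1f}] mm "
                f"({r['widening_pct']:.0f} %)  p {r['p_display']}"
            )
        lines.append("\nSB vs DB widening (Welch t):")
        for _, r in self.comparisons.iterrows():
            lines.append(
                f"  {r['level']:<8} SB {r['sb_tunnel']:<6} "
                f"{r['sb_mean']:.1f}±{r['sb_sd']:.1f} vs DB {r['db_tunnel']:<9} "
                f"{r['db_mean']:.1f}±{r['db_sd']:.1f} mm  p {r['p_display']}"
            )
        if self.icc is not None:
            lo, hi = self.icc.ci95
            lines.append(
                f"\nRater reliability ICC(2,1): {self.icc.icc:.3f} "
                f"[{lo:.3f}, {hi:.3f}] "
                f"({self.icc.n_subjects} subjects x {self.icc.k_raters} raters, "
                f"B={self.icc.b_resamples})"
            )
        ps = self.power_spec
        lines.append(
            f"\nA-priori sample size: n = {self.n_required} for delta {ps.delta} mm, "
            f"SD {ps.sd} mm, alpha {ps.alpha}, power {ps.power:.0%}"
        )
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "per_tunnel": self.per_tunnel.to_dict(orient="records"),
            "comparisons": self.comparisons.to_dict(orient="records"),
            "icc": None if self.icc is None else {
                "icc": self.icc.icc, "ci95": list(self.icc.ci95),
                "n_subjects": self.icc.n_subjects, "k_raters": self.icc.k_raters,
                "b": self.icc.b_resamples, "seed": self.icc.seed,
            },
            "power": {
                "delta_mm": self.power_spec.delta, "sd_mm": self.power_spec.sd,
                "alpha": self.power_spec.alpha, "power": self.power_spec.power,
                "n_required": self.n_required,
            },
        }
        return json.dumps(payload, indent=2, default=float)
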