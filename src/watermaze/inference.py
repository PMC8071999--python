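"""The inferential suite: t tests, effect sizes, 2×2 mixed ANOVA, rank-sum
test, and default JZS Bayes factors.

The JZS (Jeffreys–Zellner–Siow) Bayes factor places a Cauchy(0, r) prior on
the standardized effect size under H1 (default r = √2/2, the conventional
"medium" scale) and a Jeffreys prior on the variance, and compares the
marginal likelihood of the observed t statistic under H1 against the point
null.  Writing the Cauchy as a scale mixture of normals with an
inverse-χ²(1) mixing variable g, the Bayes factor is a one-dimensional
integral

    BF10 = ∫₀^∞ (1 + N·g·r²)^(−1/2) [1 + t²/((1+N·g·r²)ν)]^(−(ν+1)/2)
                 (2π)^(−1/2) g^(−3/2) e^(−1/(2g)) dg
           ───────────────────────────────────────────────────────────
                         [1 + t²/ν]^(−(ν+1)/2)

with ν the degrees of freedom and N the effective sample size (n for a
one-sample design, n₁n₂/(n₁+n₂) for two samples).  The integral is
evaluated by adaptive quadrature on a log-transformed axis.

The 2×2 mixed ANOVA (one between-subject factor, one within-subject factor,
both at two levels) is computed from classical sums of squares with the
subject nested in group; with unequal group sizes the main-effect tests are
Type III (unweighted means), which for this design reduce to exact pooled-t
identities on subject means and on within-subject difference scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate, stats

DEFAULT_R_SCALE = math.sqrt(2) / 2


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    d: float
    kind: str  # 'one_sample' | 'welch_two_sample'


@dataclass(frozen=True)
class EffectResult:
    name: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaResult:
    between: EffectResult
    within: EffectResult
    interaction: EffectResult
    ss_table: dict  # stratum -> (SS, df)


@dataclass(frozen=True)
class RankSumResult:
    w: float
    p: float
    exact: bool


@dataclass(frozen=True)
class BFResult:
    bf10: float
    r_scale: float
    method: str  # 'one_sample_t' | 'two_sample_t'

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """One-sample t test with Cohen's d = t/√n = (mean − mu0)/sd."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("one-sample t requires n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("one-sample t undefined for zero variance")
    t = (x.mean() - mu0) / (sd / math.sqrt(n))
    df = n - 1
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p),
                       d=float(t / math.sqrt(n)), kind="one_sample")


def welch_two_sample_t(x, y) -> TTestResult:
    """Welch's two-sample t test; d = |mean difference| / pooled SD (n−1 weights)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch t requires n >= 2 per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("Welch t undefined when both groups have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    sp = math.sqrt(((len(x) - 1) * vx + (len(y) - 1) * vy) / (len(x) + len(y) - 2))
    d = abs(x.mean() - y.mean()) / sp if sp > 0 else math.inf
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue), d=float(d), kind="welch_two_sample")


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """ηp² = F·df1 / (F·df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("require F >= 0 and positive degrees of freedom")
    return F * df1 / (F * df1 + df2)


def _pooled_var(a: np.ndarray, b: np.ndarray) -> float:
    return (((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2))


def mixed_anova_2x2(df, dv: str = "value", between: str = "group",
                    within: str = "condition", subject: str = "subject") -> AnovaResult:
    """Mixed 2×2 ANOVA (between-group × within-condition) from sums of squares.

    Every subject must contribute both within-condition values.  Main-effect
    tests are Type III (unweighted group means), exact for this design:
    the between-group F equals the squared pooled two-sample t on subject
    means; the interaction F equals the squared pooled t on difference
    scores; the within F tests the unweighted mean of the groups'
    difference-score means.  The SS table carries both error strata.
    """
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("every subject must have a value in both conditions")
    conds = list(wide.columns)
    if len(conds) != 2:
        raise ValueError("within factor must have exactly 2 levels")
    groups = sorted(wide.index.get_level_values(between).unique())
    if len(groups) != 2:
        raise ValueError("between factor must have exactly 2 levels")
    gA = wide.index.get_level_values(between) == groups[0]
    if gA.sum() < 2 or (~gA).sum() < 2:
        raise ValueError("need >= 2 subjects per group")
    smean = wide.mean(axis=1).to_numpy()           # subject means (between stratum)
    diff = (wide[conds[0]] - wide[conds[1]]).to_numpy()  # within-subject differences
    nA, nB = int(gA.sum()), int((~gA).sum())
    N = nA + nB
    inv_n = 1.0 / nA + 1.0 / nB

    # between-subjects stratum (each subject mean carries 2 observations)
    sp2 = _pooled_var(smean[gA], smean[~gA])
    delta_g = smean[gA].mean() - smean[~gA].mean()
    ss_group = 2.0 * delta_g ** 2 / inv_n
    ss_subj = 2.0 * ((smean[gA] - smean[gA].mean()) ** 2).sum() \
        + 2.0 * ((smean[~gA] - smean[~gA].mean()) ** 2).sum()
    ms_err_b = ss_subj / (N - 2)
    F_group = ss_group / ms_err_b if ms_err_b > 0 else (0.0 if ss_group == 0 else math.inf)

    # within-subjects stratum, built from difference scores (2 levels)
    sd2 = _pooled_var(diff[gA], diff[~gA])
    c = (diff[gA].mean() + diff[~gA].mean()) / 2.0   # unweighted condition effect
    ss_cond = 2.0 * c ** 2 / inv_n
    delta_d = diff[gA].mean() - diff[~gA].mean()
    ss_inter = delta_d ** 2 / (2.0 * inv_n)
    ss_err_w = (((diff[gA] - diff[gA].mean()) ** 2).sum()
                + ((diff[~gA] - diff[~gA].mean()) ** 2).sum()) / 2.0
    ms_err_w = ss_err_w / (N - 2)
    F_cond = (ss_cond / ms_err_w if ms_err_w > 0
              else (0.0 if ss_cond == 0 else math.inf))
    F_inter = (ss_inter / ms_err_w if ms_err_w > 0
               else (0.0 if ss_inter == 0 else math.inf))

    def effect(name, F, df2):
        F = float(F)
        return EffectResult(name=name, F=F, df1=1, df2=df2,
                            p=float(stats.f.sf(F, 1, df2)),
                            partial_eta_sq=partial_eta_squared(F, 1, df2) if math.isfinite(F) else 1.0)

    ss_table = {
        "between_group": (float(ss_group), 1),
        "subjects_within_group": (float(ss_subj), N - 2),
        "within_condition": (float(ss_cond), 1),
        "interaction": (float(ss_inter), 1),
        "condition_x_subjects": (float(ss_err_w), N - 2),
    }
    return AnovaResult(between=effect(between, F_group, N - 2),
                       within=effect(within, F_cond, N - 2),
                       interaction=effect("interaction", F_inter, N - 2),
                       ss_table=ss_table)


def wilcoxon_rank_sum(x, y, exact: Optional[bool] = None) -> RankSumResult:
    """Rank-sum test; W is the first sample's rank sum minus n_x(n_x+1)/2.

    Exact permutation p when the combined sample is ≤ 20 with no ties,
    otherwise the normal approximation with tie correction (and continuity
    correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < len(combined)
    if exact is None:
        exact = len(combined) <= 20 and not ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return RankSumResult(w=float(res.statistic), p=float(res.pvalue), exact=bool(exact))


def jzs_bayes_factor(t: float, n1: int, n2: Optional[int] = None,
                     r_scale: float = DEFAULT_R_SCALE) -> BFResult:
    """Default JZS Bayes factor for a t statistic (one- or two-sample design).

    Accurate to ~1e-6 relative error via adaptive quadrature over the
    log-transformed scale-mixture variable.
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    if n1 < 2 or (n2 is not None and n2 < 2):
        raise ValueError("each sample requires n >= 2")
    if n2 is None:
        N, df, method = float(n1), n1 - 1, "one_sample_t"
    else:
        N, df, method = n1 * n2 / (n1 + n2), n1 + n2 - 2, "two_sample_t"
    r2 = r_scale * r_scale
    t2 = t * t

    def log_integrand(u: float) -> float:
        g = math.exp(u)
        a = 1.0 + N * g * r2
        return (-0.5 * math.log(a)
                - (df + 1) / 2.0 * math.log1p(t2 / (a * df))
                - 0.5 * math.log(2 * math.pi) - 1.5 * u - 1.0 / (2.0 * g)
                + u)  # + u: Jacobian of g = e^u

    # peak-normalised integrand keeps quad well-scaled for large |t|
    us = np.linspace(-25.0, 25.0, 201)
    peak = max(log_integrand(u) for u in us)
    num, err = integrate.quad(lambda u: math.exp(log_integrand(u) - peak),
                              -30.0, 30.0, epsabs=0.0, epsrel=1e-9, limit=400)
    if not math.isfinite(num) or num <= 0:
        raise ArithmeticError(
            f"JZS integrand failed (t={t}, N={N}, df={df}, integral={num}, abserr={err})")
    log_null = -(df + 1) / 2.0 * math.log1p(t2 / df)
    bf10 = math.exp(math.log(num) + peak - log_null)
    return BFResult(bf10=float(bf10), r_scale=float(r_scale), method=method)


def interpret_bf(bf: BFResult) -> str:
    """Evidence label on the conventional 1–3 / 3–10 / >10 scale.

    The label applies to max(BF10, BF01) with its direction (H1 when the
    alternative is favoured, H0 when the null is); BF = 1 carries no
    direction.
    """
    best = max(bf.bf10, bf.bf01)
    direction = "H1" if bf.bf10 > 1 else ("H0" if bf.bf10 < 1 else None)
    if best <= 3:
        label = "anecdotal"
    elif best <= 10:
        label = "substantial"
    else:
        label = "strong"
    return f"{label} for {direction}" if direction else label
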