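"""Group-comparison statistics used throughout the toolkit.

The test statistics are computed from first principles (sums of squares,
pooled variances, studentized-range and multivariate-t adjustments) with
scipy supplying only the reference distributions.  Covered: Student's t
(pooled or Welch), one-way ANOVA, Tukey-Kramer HSD, Dunnett many-to-one
comparisons (Monte-Carlo multivariate-t critical values), and two-way
repeated-measures (split-plot) ANOVA with one between factor and one
within factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError

__all__ = [
    "TTestResult",
    "AnovaResult",
    "PairwiseComparison",
    "t_test",
    "anova_oneway",
    "tukey_hsd",
    "tukey_critical_value",
    "dunnett",
    "dunnett_critical_value",
    "rm_anova_two_way",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    diff: float
    statistic: float
    p_adj: float
    significant: bool


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        items = groups.items()
    else:
        items = ((str(i), g) for i, g in enumerate(groups))
    out = {str(k): np.asarray(v, dtype=float).ravel() for k, v in items}
    for k, v in out.items():
        if v.size < 2:
            raise ConfigurationError(f"group {k!r} needs >= 2 values")
    return out


def t_test(a, b, welch: bool = False) -> TTestResult:
    """Two-sided two-sample t test (pooled variance by default).

    Degenerate inputs with zero variance in both groups follow the
    convention t = 0, p = 1 when the means are equal (and p = 0 when they
    differ, since any nonzero difference is then infinitely many SDs).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each group needs n >= 2")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            return TTestResult(0.0, na + nb - 2, 1.0) if diff == 0 else TTestResult(math.inf, na + nb - 2, 0.0)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = diff / math.sqrt(se2)
    else:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 == 0:
            return TTestResult(0.0, df, 1.0) if diff == 0 else TTestResult(math.inf, df, 0.0)
        t = diff / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(min(p, 1.0)))


def anova_oneway(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA (between/within decomposition)."""
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ConfigurationError("need >= 2 groups")
    all_vals = np.concatenate(list(gs.values()))
    grand = all_vals.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs.values())
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs.values())
    dfb = len(gs) - 1
    dfw = all_vals.size - len(gs)
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(0.0, dfb, dfw, 1.0, 0.0)
        return AnovaResult(math.inf, dfb, dfw, 0.0, 0.0)
    msb = ssb / dfb
    msw = ssw / dfw
    F = msb / msw
    p = float(sps.f.sf(F, dfb, dfw))
    return AnovaResult(float(F), dfb, dfw, p, float(msw))


def tukey_critical_value(n_groups: int, df_within: int, alpha: float = 0.05) -> float:
    """Studentized-range critical value q for Tukey's HSD."""
    return float(sps.studentized_range.ppf(1.0 - alpha, n_groups, df_within))


def tukey_hsd(groups, alpha: float = 0.05) -> list[PairwiseComparison]:
    """All-pairs comparisons via the studentized range (Tukey-Kramer).

    Unequal group sizes use the Tukey-Kramer standard error
    ``sqrt(MSW/2 * (1/n_i + 1/n_j))``; adjusted p-values come from the
    studentized-range distribution with the one-way ANOVA within-group df.
    """
    gs = _as_groups(groups)
    an = anova_oneway(gs)
    k = len(gs)
    labels = list(gs)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = gs[labels[i]], gs[labels[j]]
            diff = a.mean() - b.mean()
            if an.ms_within == 0:
                q = 0.0 if diff == 0 else math.inf
            else:
                se = math.sqrt(an.ms_within / 2.0 * (1.0 / a.size + 1.0 / b.size))
                q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, an.df_within)) if math.isfinite(q) else 0.0
            out.append(PairwiseComparison(labels[i], labels[j], float(diff),
                                          float(q), min(p, 1.0), p < alpha))
    return out


def dunnett_critical_value(treatment_ns, control_n: int, df_within: int,
                           alpha: float = 0.05, n_mc: int = 100_000,
                           seed: int = 0) -> float:
    """Monte-Carlo critical value for Dunnett's max-|t| statistic.

    Draws the joint null distribution of the treatment-vs-control t
    statistics from the multivariate t implied by the shared control mean
    (corr(T_i, T_j) = sqrt(lambda_i lambda_j), lambda_i = n_i/(n_i+n0))
    and returns the (1 - alpha) quantile of max |T|.
    """
    ns = np.asarray(treatment_ns, dtype=float)
    lam = ns / (ns + control_n)
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_mc)
    zi = rng.standard_normal((n_mc, ns.size))
    z = np.sqrt(lam) * z0[:, None] + np.sqrt(1.0 - lam) * zi
    w = rng.chisquare(df_within, n_mc)
    max_abs_t = np.max(np.abs(z), axis=1) / np.sqrt(w / df_within)
    return float(np.quantile(max_abs_t, 1.0 - alpha))


def dunnett(groups, control_label: str, alpha: float = 0.05,
            n_mc: int = 100_000, seed: int = 0) -> list[PairwiseComparison]:
    """Many-to-one comparisons of each treatment against a control.

    Adjusted p-values are Monte-Carlo estimates of
    ``P(max_j |T_j| >= |t_i|)`` under the joint null, using the same
    multivariate-t draws as :func:`dunnett_critical_value`.
    """
    gs = _as_groups(groups)
    if control_label not in gs:
        raise ConfigurationError(f"control group {control_label!r} missing")
    treatments = [k for k in gs if k != control_label]
    if not treatments:
        raise ConfigurationError("need at least one treatment group")
    an = anova_oneway(gs)
    ctrl = gs[control_label]
    ns = np.array([gs[k].size for k in treatments], dtype=float)

    # joint null draws of max |T|
    lam = ns / (ns + ctrl.size)
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_mc)
    zi = rng.standard_normal((n_mc, ns.size))
    z = np.sqrt(lam) * z0[:, None] + np.sqrt(1.0 - lam) * zi
    w = rng.chisquare(an.df_within, n_mc)
    max_abs_t = np.max(np.abs(z), axis=1) / np.sqrt(w / an.df_within)

    out = []
    for k in treatments:
        g = gs[k]
        diff = g.mean() - ctrl.mean()
        if an.ms_within == 0:
            t = 0.0 if diff == 0 else math.inf
        else:
            se = math.sqrt(an.ms_within * (1.0 / g.size + 1.0 / ctrl.size))
            t = diff / se
        p = float(np.mean(max_abs_t >= abs(t))) if math.isfinite(t) else 0.0
        out.append(PairwiseComparison(k, control_label, float(diff),
                                      float(t), p, p < alpha))
    return out


def rm_anova_two_way(data: pd.DataFrame, unit: str = "unit", group: str = "group",
                     time: str = "time", value: str = "value") -> pd.DataFrame:
    """Split-plot ANOVA: one between factor (group) and one within factor (time).

    Each unit (worm) must be observed at every timepoint; missing cells
    raise rather than impute.  Returns a table with F, df and p for the
    group effect (tested against subjects-within-groups), the time effect
    and the group x time interaction (tested against the within-subjects
    residual).  Sums of squares follow the classical balanced-design
    decomposition; no sphericity correction is applied.
    """
    df = data[[unit, group, time, value]].copy()
    wide = df.pivot_table(index=[group, unit], columns=time, values=value)
    if wide.isna().any().any():
        raise ConfigurationError("incomplete time grid: every unit needs every timepoint")
    y = wide.to_numpy()  # subjects x times
    n_subj, n_time = y.shape
    group_of = wide.index.get_level_values(0).to_numpy()
    labels, counts = np.unique(group_of, return_counts=True)
    n_groups = labels.size
    if n_groups < 2:
        raise ConfigurationError("need >= 2 groups")
    if np.any(counts < 2):
        raise ConfigurationError("each group needs >= 2 units")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    time_means = y.mean(axis=0)
    group_means = np.array([subj_means[group_of == g].mean() for g in labels])
    cell_means = np.vstack([y[group_of == g].mean(axis=0) for g in labels])

    ss_group = n_time * float(np.sum(counts * (group_means - grand) ** 2))
    ss_subj_within = n_time * float(np.sum((subj_means - group_means[np.searchsorted(labels, group_of)]) ** 2))
    ss_time = n_subj * float(np.sum((time_means - grand) ** 2))
    ss_inter = float(np.sum(counts[:, None] * (cell_means - group_means[:, None]
                                               - time_means[None, :] + grand) ** 2))
    ss_within_subj = float(np.sum((y - subj_means[:, None]) ** 2))
    ss_err = ss_within_subj - ss_time - ss_inter

    # wash out floating-point residue so degenerate designs give exact zeros
    ss_total = float(np.sum((y - grand) ** 2))
    tol = 1e-12 * max(1.0, ss_total)
    ss_group, ss_time, ss_inter, ss_err = (
        0.0 if abs(s) < tol else s for s in (ss_group, ss_time, ss_inter, ss_err))

    df_group = n_groups - 1
    df_subj = n_subj - n_groups
    df_time = n_time - 1
    df_inter = df_group * df_time
    df_err = df_subj * df_time

    def _row(ss, dfe, ss_err_, df_err_):
        ms = ss / dfe
        mse = ss_err_ / df_err_
        if mse == 0:
            F = 0.0 if ms == 0 else math.inf
            p = 1.0 if ms == 0 else 0.0
        else:
            F = ms / mse
            p = float(sps.f.sf(F, dfe, df_err_))
        return {"SS": ss, "df1": dfe, "df2": df_err_, "F": float(F), "p": p}

    table = pd.DataFrame({
        "group": _row(ss_group, df_group, ss_subj_within, df_subj),
        "time": _row(ss_time, df_time, max(ss_err, 0.0), df_err),
        "group:time": _row(ss_inter, df_inter, max(ss_err, 0.0), df_err),
    }).T
    return table
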