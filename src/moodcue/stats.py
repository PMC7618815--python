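"""Inferential layer: mixed-design ANOVA, t-tests, normality-gated correlations.

The mixed ANOVA implements the classical sums-of-squares decomposition for a
one between-subjects x one within-subjects design, with partial eta squared
effect sizes, Greenhouse-Geisser epsilon from the doubly-centred pooled
within-group covariance, and a Mauchly sphericity test gating the correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

_ZERO_SS_TOL = 1e-12


@dataclass
class AnovaEffect:
    """One effect line of a mixed-design ANOVA table."""

    name: str
    ss: float
    df1: float
    df2: float
    F: float
    p_unc: float
    partial_eta_sq: float
    eps: float | None = None          # GG epsilon (within effects only)
    df1_gg: float | None = None
    df2_gg: float | None = None
    p_gg: float | None = None
    gg_applied: bool = False
    degenerate: bool = False

    @property
    def p(self) -> float:
        """Reported p: GG-adjusted when the correction was applied."""
        return self.p_gg if self.gg_applied else self.p_unc


@dataclass
class AnovaResult:
    """Mixed-ANOVA result: between, within and interaction effects."""

    between: AnovaEffect
    within: AnovaEffect
    interaction: AnovaEffect
    sphericity_w: float | None = None
    sphericity_p: float | None = None
    n_subjects: int = 0
    n_levels: int = 0

    def effects(self):
        return (self.between, self.within, self.interaction)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.effects():
            rows.append({"effect": e.name, "SS": e.ss, "df1": e.df1, "df2": e.df2,
                         "F": e.F, "p_unc": e.p_unc, "p": e.p,
                         "partial_eta_sq": e.partial_eta_sq, "eps": e.eps,
                         "gg_applied": e.gg_applied, "degenerate": e.degenerate})
        return pd.DataFrame(rows)


def _gg_epsilon(S: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a doubly-centred covariance matrix."""
    k = S.shape[0]
    J = np.eye(k) - np.ones((k, k)) / k
    A = J @ S @ J
    lam = np.linalg.eigvalsh(A)
    lam = lam[lam > 1e-12 * max(lam.max(), 1.0)]
    if lam.size == 0:
        return 1.0
    eps = lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum())
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _mauchly(S: np.ndarray, df_resid: int) -> tuple[float, float]:
    """Mauchly's sphericity test on a pooled covariance matrix.

    Returns ``(W, p)``.  With two within levels sphericity holds trivially
    (W = 1, p = 1); degenerate covariances return p = NaN so callers can
    fall back to applying the correction.
    """
    k = S.shape[0]
    if k <= 2:
        return 1.0, 1.0
    C = helmert(k, full=False)
    A = C @ S @ C.T
    det = np.linalg.det(A)
    tr = np.trace(A)
    if det <= 0 or tr <= 0:
        return np.nan, np.nan
    W = det / (tr / (k - 1)) ** (k - 1)
    d = k - 1
    f = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * df_resid)
    chi2 = -f * df_resid * np.log(W)
    ddof = d * (d + 2) // 2 - 1
    return float(W), float(sps.chi2.sf(chi2, ddof))


def mixed_anova(data: pd.DataFrame, dv: str, within: str, between: str,
                subject: str, *, correction: str = "auto") -> AnovaResult:
    """Mixed-design repeated-measures ANOVA (classical sums of squares).

    ``data`` is long-format with one observation per subject x within-level.
    The design must be complete and balanced within subjects: every subject
    contributes exactly one value at every within level.  ``correction``
    governs the Greenhouse-Geisser adjustment of within-subject effects:
    ``"auto"`` applies it when Mauchly's test rejects sphericity at .05 (or
    is undefined), ``"always"`` and ``"never"`` force it on or off.

    Degenerate inputs with zero error sums of squares report F = 0 with the
    ``degenerate`` flag set rather than failing.
    """
    if correction not in ("auto", "always", "never"):
        raise ValueError(f"unknown correction mode {correction!r}")
    wide = data.pivot_table(index=[subject, between], columns=within,
                            values=dv, aggfunc="mean", observed=True)
    if wide.isna().any().any():
        raise ValueError("unbalanced design: every subject needs every within level")
    counts = data.groupby([subject, within], observed=True).size()
    if (counts != 1).any():
        raise ValueError("unbalanced design: duplicate subject x level observations")

    Y = wide.to_numpy(dtype=float)
    groups = wide.index.get_level_values(between).to_numpy()
    glabels, ginv = np.unique(groups, return_inverse=True)
    n_subj, k = Y.shape
    n_groups = glabels.size
    if n_subj < 2 * n_groups or min(np.bincount(ginv)) < 2:
        raise ValueError("need at least 2 subjects per group")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    level_means = Y.mean(axis=0)
    group_means = np.array([subj_means[ginv == g].mean() for g in range(n_groups)])
    cell_means = np.vstack([Y[ginv == g].mean(axis=0) for g in range(n_groups)])
    n_per_group = np.bincount(ginv)

    ss_total = ((Y - grand) ** 2).sum()
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = k * (n_per_group * (group_means - grand) ** 2).sum()
    ss_err_between = ss_between_subj - ss_group
    ss_within_total = ss_total - ss_between_subj
    ss_level = n_subj * ((level_means - grand) ** 2).sum()
    ss_inter = (n_per_group[:, None] * (cell_means - group_means[:, None]
                                        - level_means[None, :] + grand) ** 2).sum()
    ss_err_within = ss_within_total - ss_level - ss_inter

    df_group, df_errb = n_groups - 1, n_subj - n_groups
    df_level = k - 1
    df_inter = df_group * df_level
    df_errw = df_errb * df_level

    scale = max(ss_total, 1.0)

    def make_effect(name, ss, df1, ss_err, df2) -> AnovaEffect:
        degenerate = ss_err <= _ZERO_SS_TOL * scale
        if degenerate:
            return AnovaEffect(name, float(ss), df1, df2, 0.0, 1.0,
                               float(ss / (ss + ss_err)) if ss + ss_err > 0 else 0.0,
                               degenerate=True)
        F = (ss / df1) / (ss_err / df2)
        return AnovaEffect(name, float(ss), df1, df2, float(F),
                           float(sps.f.sf(F, df1, df2)),
                           float(ss / (ss + ss_err)))

    between_eff = make_effect(between, ss_group, df_group, ss_err_between, df_errb)
    within_eff = make_effect(within, ss_level, df_level, ss_err_within, df_errw)
    inter_eff = make_effect(f"{between} * {within}", ss_inter, df_inter,
                            ss_err_within, df_errw)

    # Pooled within-group covariance of the repeated measures.
    resid = Y - cell_means[ginv]
    S = resid.T @ resid / df_errb
    eps = _gg_epsilon(S)
    W, p_spher = _mauchly(S, df_errb)
    if correction == "always":
        apply_gg = k > 2
    elif correction == "never":
        apply_gg = False
    else:
        apply_gg = k > 2 and (np.isnan(p_spher) or p_spher < 0.05)
    for eff in (within_eff, inter_eff):
        eff.eps = eps
        eff.df1_gg, eff.df2_gg = eps * eff.df1, eps * eff.df2
        if not eff.degenerate:
            eff.p_gg = float(sps.f.sf(eff.F, eff.df1_gg, eff.df2_gg))
            eff.gg_applied = apply_gg
        else:
            eff.p_gg = 1.0
    return AnovaResult(between_eff, within_eff, inter_eff, W, p_spher,
                       n_subjects=n_subj, n_levels=k)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    cohens_d: float
    n1: int
    n2: int
    mean_diff: float


def two_sample_t(values, groups, *, welch: bool = False) -> TTestResult:
    """Independent-samples t-test with Cohen's d (pooled SD).

    Student's pooled-variance t by default (df = n1 + n2 - 2); Welch
    available via flag.  Groups with zero pooled variance and equal means
    report t = 0, d = 0.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels.size}")
    x1, x2 = v[g == labels[0]], v[g == labels[1]]
    if min(x1.size, x2.size) < 2:
        raise ValueError("need at least 2 observations per group")
    n1, n2 = x1.size, x2.size
    s2p = (((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1))
           / (n1 + n2 - 2))
    diff = x1.mean() - x2.mean()
    if s2p == 0.0:
        t_val = 0.0 if diff == 0 else np.inf * np.sign(diff)
        d = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
        return TTestResult(float(t_val), float(n1 + n2 - 2), p, float(d),
                           n1, n2, float(diff))
    res = sps.ttest_ind(x1, x2, equal_var=not welch)
    d = diff / np.sqrt(s2p)
    return TTestResult(float(res.statistic), float(res.df),
                       float(res.pvalue), float(d), n1, n2, float(diff))


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    coefficient: float
    p: float
    n: int
    shapiro_p_x: float
    shapiro_p_y: float


def gated_correlation(x, y, *, alpha: float = 0.05) -> CorrelationResult:
    """Pearson or Spearman correlation gated by Shapiro-Wilk normality tests.

    Pearson when both variables pass normality at ``alpha``; Spearman
    otherwise.  Constant input is an error (the coefficient is undefined).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 4:
        raise ValueError("need paired samples of length >= 4")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant variable")
    px = float(sps.shapiro(xa).pvalue)
    py = float(sps.shapiro(ya).pvalue)
    if px < alpha or py < alpha:
        r, p = sps.spearmanr(xa, ya)
        method = "spearman"
    else:
        r, p = sps.pearsonr(xa, ya)
        method = "pearson"
    return CorrelationResult(method, float(r), float(p), int(xa.size), px, py)
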