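"""Repeated-measures inference for within-subject binding designs.

Implements the classical univariate within-subject ANOVA decomposition
(each effect tested against its participant-by-effect interaction),
Mauchly's sphericity test and the Greenhouse–Geisser correction via
orthonormal-contrast covariances, Bonferroni-corrected pairwise paired
t-tests, partial eta-squared, and Cousineau within-subject confidence
intervals.

All operations take long-format data with one row per participant × cell
(trials are aggregated to cell means before they get here — the dependent
variable is the participant's mean baseline-corrected judgment error, not
individual trials).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import helmert

__all__ = [
    "rm_anova",
    "partial_eta_squared",
    "bonferroni_pairwise",
    "cousineau_ci",
    "PairwiseResult",
]


def partial_eta_squared(F: float, df_effect: float, df_error: float) -> float:
    """Partial eta-squared from an F statistic: F·df1 / (F·df1 + df2)."""
    if F < 0 or df_effect <= 0 or df_error <= 0:
        raise ValueError("need F >= 0 and positive degrees of freedom")
    return F * df_effect / (F * df_effect + df_error)


def _pivot(data: pd.DataFrame, dv: str, within: list[str], subject: str) -> tuple[np.ndarray, list]:
    """Return Y of shape (n_subjects, *levels) and the level labels per factor.

    Raises if any participant is missing a cell or has duplicates.
    """
    levels = [list(pd.unique(data[f])) for f in within]
    wide = data.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="mean", observed=True
    )
    counts = data.groupby([subject] + within, observed=True)[dv].size()
    full = pd.MultiIndex.from_product(levels, names=within) if len(within) > 1 else pd.Index(
        levels[0], name=within[0]
    )
    wide = wide.reindex(columns=full)
    if wide.isna().any().any():
        r, c = np.where(wide.isna().to_numpy())
        bad = [f"{wide.index[i]} × {full[j]}" for i, j in list(zip(r, c))[:5]]
        raise ValueError(f"incomplete within design; missing cells: {bad}")
    if (counts > 1).any():
        raise ValueError(
            "multiple observations per participant × cell; aggregate to cell means first"
        )
    shape = (len(wide),) + tuple(len(lv) for lv in levels)
    return wide.to_numpy(float).reshape(shape), levels


def _sphericity(Y2: np.ndarray, C: np.ndarray) -> dict:
    """Mauchly's W and Greenhouse–Geisser ε from contrast-transformed scores.

    ``Y2`` is (n_subjects, p) cell scores for the effect, ``C`` a p × d
    orthonormal contrast matrix spanning the effect (d = effect df).
    """
    n, _ = Y2.shape
    d = C.shape[1]
    T = Y2 @ C
    S = np.cov(T, rowvar=False, ddof=1).reshape(d, d)
    tr = np.trace(S)
    eps_den = d * np.trace(S @ S)
    gg_eps = float(tr**2 / eps_den) if eps_den > 0 else 1.0
    gg_eps = min(1.0, max(gg_eps, 1.0 / d))
    out = {"gg_epsilon": gg_eps, "mauchly_W": np.nan, "mauchly_p": np.nan}
    if d < 2:  # two-level effects are trivially spherical
        out["gg_epsilon"] = 1.0
        return out
    if n - 1 <= d:  # covariance singular: test undefined
        return out
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0 or tr <= 0:
        return out
    logW = logdet - d * math.log(tr / d)
    f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * logW
    ddof = d * (d + 1) // 2 - 1
    out["mauchly_W"] = float(math.exp(logW))
    out["mauchly_p"] = float(stats.chi2.sf(chi2, ddof))
    return out


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: str | list[str],
    subject: str,
    alpha_sphericity: float = 0.05,
) -> pd.DataFrame:
    """One- or two-way fully within-subject repeated-measures ANOVA.

    Classical univariate sums-of-squares decomposition: each main effect and
    the interaction is tested against its own participant-by-effect error
    term.  For effects with three or more levels, Mauchly's test and the
    Greenhouse–Geisser ε are computed from the orthonormal-contrast
    covariance of the per-participant effect scores; the GG-corrected p is
    always reported and ``correction_applied`` marks effects where
    Mauchly's p < ``alpha_sphericity`` (the convention of correcting only
    demonstrably non-spherical effects).

    Returns a DataFrame indexed by effect with columns ``F, df_effect,
    df_error, p, partial_eta_sq, mauchly_W, mauchly_p, gg_epsilon, p_gg,
    correction_applied``.
    """
    within = [within] if isinstance(within, str) else list(within)
    if len(within) not in (1, 2):
        raise ValueError("rm_anova supports one or two within factors")
    Y, levels = _pivot(data, dv, within, subject)
    if len(within) == 1:
        Y = Y[:, :, None]
        names = [within[0]]
    else:
        names = [within[0], within[1], f"{within[0]} × {within[1]}"]
    n, a, b = Y.shape
    if n < 2:
        raise ValueError("need at least 2 participants")

    grand = Y.mean()
    subj = Y.mean(axis=(1, 2))           # (n,)
    A = Y.mean(axis=(0, 2))              # (a,)
    B = Y.mean(axis=(0, 1))              # (b,)
    AB = Y.mean(axis=0)                  # (a, b)
    iA = Y.mean(axis=2)                  # (n, a)
    iB = Y.mean(axis=1)                  # (n, b)

    def effect_row(ss_eff, df_eff, ss_err, df_err, scores, C):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
        p = float(stats.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
        sph = _sphericity(scores, C)
        eps = sph["gg_epsilon"]
        p_gg = (
            float(stats.f.sf(F, df_eff * eps, df_err * eps)) if np.isfinite(F) else 0.0
        )
        applied = bool(
            not np.isnan(sph["mauchly_p"]) and sph["mauchly_p"] < alpha_sphericity
        )
        return {
            "F": float(F),
            "df_effect": df_eff,
            "df_error": df_err,
            "p": p,
            "partial_eta_sq": partial_eta_squared(float(F), df_eff, df_err)
            if np.isfinite(F)
            else 1.0,
            "mauchly_W": sph["mauchly_W"],
            "mauchly_p": sph["mauchly_p"],
            "gg_epsilon": eps,
            "p_gg": p_gg,
            "correction_applied": applied,
        }

    CA = helmert(a, full=False).T if a > 1 else np.zeros((1, 0))
    CB = helmert(b, full=False).T if b > 1 else np.zeros((1, 0))

    rows = {}
    # main effect of the first factor, error = participant × A residual
    ss_a = n * b * ((A - grand) ** 2).sum()
    res_a = iA - subj[:, None] - A[None, :] + grand
    ss_as = b * (res_a**2).sum()
    rows[names[0]] = effect_row(ss_a, a - 1, ss_as, (a - 1) * (n - 1), iA, CA)

    if len(within) == 2:
        ss_b = n * a * ((B - grand) ** 2).sum()
        res_b = iB - subj[:, None] - B[None, :] + grand
        ss_bs = a * (res_b**2).sum()
        rows[names[1]] = effect_row(ss_b, b - 1, ss_bs, (b - 1) * (n - 1), iB, CB)

        ss_ab = n * ((AB - A[:, None] - B[None, :] + grand) ** 2).sum()
        res_ab = (
            Y
            - iA[:, :, None]
            - iB[:, None, :]
            + subj[:, None, None]
            - AB[None, :, :]
            + A[None, :, None]
            + B[None, None, :]
            - grand
        )
        ss_abs = (res_ab**2).sum()
        df_ab = (a - 1) * (b - 1)
        rows[names[2]] = effect_row(
            ss_ab,
            df_ab,
            ss_abs,
            df_ab * (n - 1),
            Y.reshape(n, a * b),
            np.kron(CA, CB),
        )

    out = pd.DataFrame(rows).T
    out.index.name = "effect"
    for col in ("df_effect", "df_error"):
        out[col] = out[col].astype(int)
    out["correction_applied"] = out["correction_applied"].astype(bool)
    return out


@dataclass(frozen=True)
class PairwiseResult:
    """One Bonferroni-corrected paired contrast on participant cell means."""

    contrast: str
    mean_diff: float
    t: float
    df: int
    p_uncorrected: float
    p_bonferroni: float
    cohens_d_dz: float
    cohens_d_pooled: float


def bonferroni_pairwise(
    data: pd.DataFrame,
    dv: str,
    factor: str,
    subject: str,
    where: tuple[str, object] | None = None,
) -> list[PairwiseResult]:
    """Paired t-tests for every pair of factor levels, Bonferroni-corrected.

    ``where=(other_factor, level)`` restricts the data to one level of a
    second factor (e.g. tone binding only).  p-values are multiplied by the
    number of pairs and capped at 1.  Cohen's d is reported both as
    dz (mean difference / SD of paired differences) and with the pooled-SD
    denominator √((SD₁² + SD₂²)/2).
    """
    if where is not None:
        data = data[data[where[0]] == where[1]]
    wide = data.pivot_table(index=subject, columns=factor, values=dv, observed=True)
    levels = [lv for lv in pd.unique(data[factor]) if lv in wide.columns]
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    results = []
    for x, y in pairs:
        sub = wide[[x, y]].dropna()
        d = sub[x] - sub[y]
        n = len(d)
        sd_d = d.std(ddof=1)
        md = float(d.mean())
        if sd_d == 0:
            t, p = (0.0, 1.0) if md == 0 else (np.inf, 0.0)
        else:
            t = md / (sd_d / math.sqrt(n))
            p = float(2 * stats.t.sf(abs(t), n - 1))
        pooled = math.sqrt((sub[x].std(ddof=1) ** 2 + sub[y].std(ddof=1) ** 2) / 2)
        results.append(
            PairwiseResult(
                contrast=f"{x} vs {y}",
                mean_diff=md,
                t=float(t),
                df=n - 1,
                p_uncorrected=p,
                p_bonferroni=min(1.0, p * m),
                cohens_d_dz=md / sd_d if sd_d > 0 else 0.0,
                cohens_d_pooled=md / pooled if pooled > 0 else 0.0,
            )
        )
    return results


def cousineau_ci(
    data: pd.DataFrame,
    dv: str,
    within: str | list[str],
    subject: str,
    level: float = 0.95,
    morey: bool = False,
) -> pd.DataFrame:
    """Within-subject confidence intervals by participant-mean normalization.

    Each observation is re-centred as y − participant mean + grand mean,
    removing between-participant level differences; the CI half-width per
    condition is t(n−1) × SD(normalized)/√n.  With ``morey=True`` the
    half-widths are inflated by √(J/(J−1)) for J conditions (off by
    default).

    Returns a DataFrame with one row per condition cell: mean, half-width,
    n, and the confidence level.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    Y, levels = _pivot(data, dv, within, subject)
    n = Y.shape[0]
    flat = Y.reshape(n, -1)
    J = flat.shape[1]
    norm = flat - flat.mean(axis=1, keepdims=True) + flat.mean()
    sd = norm.std(axis=0, ddof=1)
    tcrit = stats.t.ppf(0.5 + level / 2, n - 1)
    half = tcrit * sd / math.sqrt(n)
    if morey:
        half = half * math.sqrt(J / (J - 1))
    cells = list(itertools.product(*levels))
    out = pd.DataFrame(cells, columns=within)
    out["mean"] = flat.mean(axis=0)
    out["ci_half_width"] = half
    out["n"] = n
    out["level"] = level
    return out
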