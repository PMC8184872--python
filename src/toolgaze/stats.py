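"""Repeated-measures inference on subject x condition cell means.

Implements a fully-within-subject factorial ANOVA of arbitrary order by
explicit sums-of-squares decomposition (every effect is tested against
its own effect-by-subject interaction stratum), the Greenhouse-Geisser
sphericity correction estimated from the covariance of within-subject
contrast scores, generalized eta squared with all subject-related
variance in the denominator, and classical paired t-tests with optional
Holm adjustment.

The input is a long table with one value per subject per condition cell
(a balanced complete crossing); an unbalanced table is a hard error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

__all__ = [
    "EffectResult",
    "PairwiseResult",
    "rm_anova",
    "gg_epsilon",
    "paired_t",
    "pairwise_t",
    "generalized_eta_squared",
    "effects_to_frame",
]

T_CAP = 1e6  # reported in place of an infinite statistic (zero-variance diff)


@dataclass
class EffectResult:
    """One within-subject effect from the ANOVA decomposition."""

    effect: str
    ss_effect: float
    ss_error: float
    df1_unc: int
    df2_unc: int
    epsilon_gg: float
    df1_corr: float
    df2_corr: float
    F: float
    p_unc: float
    p_gg: float
    eta_g2: float


@dataclass
class PairwiseResult:
    """One paired comparison between two condition levels."""

    pair: str
    t: float
    df: int
    mean_diff: float
    p_raw: float
    p_adjusted: float | None = None
    degenerate: bool = False


def _pivot(table: pd.DataFrame, dv: str, within: list[str], subject: str):
    """Balanced long table -> data array (n_subj, k1, ..., km) + levels."""
    levels = [sorted(table[f].unique().tolist()) for f in within]
    subjects = sorted(table[subject].unique().tolist())
    counts = table.groupby([subject, *within], observed=True)[dv].count()
    full = pd.MultiIndex.from_product([subjects, *levels],
                                      names=[subject, *within])
    missing = full.difference(counts.index)
    if len(missing):
        raise ValueError(
            f"unbalanced design: missing cells {list(missing[:5])}"
            + ("..." if len(missing) > 5 else ""))
    if (counts > 1).any():
        dup = counts[counts > 1].index[:5].tolist()
        raise ValueError(f"multiple values per subject-cell: {dup}")
    wide = table.set_index([subject, *within])[dv].reindex(full)
    shape = (len(subjects), *(len(lv) for lv in levels))
    return wide.to_numpy(dtype=float).reshape(shape), levels, subjects


def _subset_ss(data: np.ndarray) -> dict[frozenset, float]:
    """SS for every nonempty subset of axes of a balanced cell-mean array.

    Axis 0 is subject; axes 1..m are the within factors.  Effect
    components are built by inclusion-exclusion over marginal means; each
    squared component is weighted by the number of observations collapsed
    into its cell.
    """
    axes = tuple(range(data.ndim))
    n_total = data.size
    means: dict[frozenset, np.ndarray] = {}
    for r in range(data.ndim + 1):
        for sub in itertools.combinations(axes, r):
            keep = frozenset(sub)
            drop = tuple(a for a in axes if a not in keep)
            means[keep] = data.mean(axis=drop, keepdims=True)
    ss: dict[frozenset, float] = {}
    for keep in means:
        if not keep:
            continue
        comp = np.zeros_like(means[keep])
        for r in range(len(keep) + 1):
            for sub in itertools.combinations(sorted(keep), r):
                sign = (-1) ** (len(keep) - r)
                comp = comp + sign * means[frozenset(sub)]
        weight = n_total / np.prod([data.shape[a] for a in keep])
        ss[keep] = float(weight * np.sum(comp**2))
    return ss


def _helmert(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast matrix (columns orthogonal to 1)."""
    return linalg.helmert(k).T


def _epsilon_from_scores(Y: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subjects x cells scores and an
    orthonormal contrast basis C (cells x df)."""
    df = C.shape[1]
    if df < 1 or Y.shape[0] < 2:
        return 1.0
    sigma = np.cov(Y, rowvar=False)
    M = C.T @ np.atleast_2d(sigma) @ C
    tr = np.trace(M)
    denom = df * np.trace(M @ M)
    if denom <= 0:
        return 1.0
    eps = tr**2 / denom
    return float(np.clip(eps, 1.0 / df, 1.0))


def gg_epsilon(cell_matrix: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for a subjects x conditions matrix."""
    Y = np.asarray(cell_matrix, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("need a 2-D subjects x conditions matrix, k >= 2")
    return _epsilon_from_scores(Y, _helmert(Y.shape[1]))


def generalized_eta_squared(ss_effect: float,
                            subject_related_ss: float) -> float:
    """eta_G^2 = SS_effect / (SS_effect + all subject-related SS).

    With every factor manipulated within subjects, the subject-related SS
    is the subject main effect plus every effect-by-subject error stratum.
    """
    denom = ss_effect + subject_related_ss
    return float(ss_effect / denom) if denom > 0 else 0.0


def rm_anova(
    table: pd.DataFrame,
    dv: str = "dv",
    within: list[str] | None = None,
    subject: str = "subject",
) -> list[EffectResult]:
    """Fully-within-subject factorial ANOVA.

    Every within effect (main effects and all interactions) is tested
    against its effect-by-subject stratum.  The G-G correction is applied
    to every effect with more than one numerator df (epsilon is exactly 1
    when df1 == 1); corrected dfs are ``epsilon * df``.
    """
    within = within or [c for c in table.columns
                        if c not in (subject, dv)]
    if not within:
        raise ValueError("no within-subject factors given")
    data, levels, subjects = _pivot(table, dv, within, subject)
    n = len(subjects)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    ss = _subset_ss(data)
    subj_axis = 0
    factor_axes = list(range(1, data.ndim))
    # all subject-related SS: subject main effect + every error stratum
    subject_ss_total = sum(v for k, v in ss.items() if subj_axis in k)

    results = []
    for r in range(1, len(factor_axes) + 1):
        for combo in itertools.combinations(factor_axes, r):
            key = frozenset(combo)
            err_key = key | {subj_axis}
            df1 = int(np.prod([len(levels[a - 1]) - 1 for a in combo]))
            df2 = df1 * (n - 1)
            ss_eff = ss[key]
            ss_err = ss[err_key]
            F = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else np.inf
            # contrast scores: collapse factors not in the effect
            drop = tuple(a for a in factor_axes if a not in key)
            Y = data.mean(axis=drop) if drop else data
            Y = Y.reshape(n, -1)
            C = _helmert(len(levels[combo[0] - 1]))
            for a in combo[1:]:
                C = np.kron(C, _helmert(len(levels[a - 1])))
            eps = _epsilon_from_scores(Y, C) if df1 > 1 else 1.0
            p_unc = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
            p_gg = (float(sps.f.sf(F, eps * df1, eps * df2))
                    if np.isfinite(F) else 0.0)
            eta = generalized_eta_squared(ss_eff, subject_ss_total)
            results.append(EffectResult(
                effect=" x ".join(within[a - 1] for a in combo),
                ss_effect=ss_eff, ss_error=ss_err,
                df1_unc=df1, df2_unc=df2, epsilon_gg=eps,
                df1_corr=eps * df1, df2_corr=eps * df2,
                F=float(F), p_unc=p_unc, p_gg=p_gg, eta_g2=eta))
    return results


def effects_to_frame(effects: list[EffectResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(e) for e in effects])


def paired_t(
    table: pd.DataFrame,
    level_a,
    level_b,
    factor: str = "tool_end",
    dv: str = "dv",
    subject: str = "subject",
) -> PairwiseResult:
    """Classical paired t-test on per-subject means of two factor levels.

    Other factors are collapsed by subject-level averaging first.  A
    zero-variance difference yields a capped statistic with the
    ``degenerate`` flag instead of an infinity.
    """
    means = (table.groupby([subject, factor], observed=True)[dv]
             .mean().unstack(factor))
    for lv in (level_a, level_b):
        if lv not in means.columns:
            raise ValueError(f"level {lv!r} missing from factor {factor!r}")
    a = means[level_a].to_numpy(dtype=float)
    b = means[level_b].to_numpy(dtype=float)
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValueError("both levels must be present for every subject")
    d = a - b
    n = len(d)
    df = n - 1
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    label = f"{level_a} - {level_b}"
    if sd == 0.0:
        if mean_diff == 0.0:
            return PairwiseResult(label, 0.0, df, 0.0, 1.0)
        t = np.sign(mean_diff) * T_CAP
        return PairwiseResult(label, float(t), df, mean_diff, 0.0,
                              degenerate=True)
    t, p = sps.ttest_rel(a, b)
    return PairwiseResult(label, float(t), df, mean_diff, float(p))


def pairwise_t(
    table: pd.DataFrame,
    factor: str = "tool_end",
    dv: str = "dv",
    subject: str = "subject",
    levels: list | None = None,
) -> list[PairwiseResult]:
    """All pairwise paired t-tests for one factor, Holm-adjusted across
    the family (raw p-values are kept alongside)."""
    levels = levels or sorted(table[factor].unique().tolist())
    res = [paired_t(table, a, b, factor=factor, dv=dv, subject=subject)
           for a, b in itertools.combinations(levels, 2)]
    # Holm step-down
    order = np.argsort([r.p_raw for r in res])
    m = len(res)
    prev = 0.0
    for rank, idx in enumerate(order):
        adj = min(1.0, (m - rank) * res[idx].p_raw)
        prev = max(prev, adj)
        res[idx].p_adjusted = prev
    return res
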