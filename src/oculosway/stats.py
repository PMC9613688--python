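"""Nonparametric statistical battery over per-subject condition summaries.

Inputs are long-format tables with one value per (subject, condition,
parameter).  The battery mirrors common practice for small within-subject
dual-task designs:

* distributional checks — Brown-Forsythe (median-centred Levene) homogeneity
  across conditions and Shapiro-Wilk normality of pooled residuals;
* a rank-based factorial analysis of the 4 (environment) x 2 (saccade task)
  within-subject design over conditions #4-11, via the aligned rank
  transform (ART): for each effect the data are aligned (everything but
  that effect removed, with subject blocking), ranked globally, and a
  repeated-measures ANOVA on the ranks tests that effect against its
  effect-by-subject error term.  A per-factor Friedman test is exposed as a
  cross-check;
* pairwise Wilcoxon signed-rank tests with exact small-sample p values
  (rank-sum dynamic program over all sign assignments, valid under ties),
  effect size r = |Z| / sqrt(n) with tie- and zero-corrected variance, and
  Holm (default) multiplicity adjustment per parameter family;
* Spearman rank-correlation matrices between parameters within a condition.

Effect-size magnitude labels: r >= 0.5 large, 0.3 <= r < 0.5 moderate,
0.1 <= r < 0.3 small, below 0.1 none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SUBJECT", "CONDITION", "PARAMETER", "VALUE",
    "FACTORIAL_CONDITIONS", "condition_factors", "paper_comparison_pairs",
    "DistributionCheck", "check_distributions",
    "ArtAnovaResult", "art_rm_anova", "rank_factorial_anova",
    "friedman_by_factor",
    "PairwiseResult", "wilcoxon_signed_rank", "wilcoxon_pairwise",
    "effect_size_magnitude", "adjust_p",
    "AssociationMatrix", "spearman_matrix",
]

SUBJECT, CONDITION, PARAMETER, VALUE = "subject", "condition", "parameter", "value"

#: conditions entering the 4x2 factorial analysis, mapped to factor levels
FACTORIAL_CONDITIONS = (4, 5, 6, 7, 8, 9, 10, 11)
_ENV_LEVELS = ("2D", "3D", "VM", "SO")
_TASK_LEVELS = ("pro", "anti")


def condition_factors(index: int) -> tuple[str, str]:
    """(environment, saccade_task) factor levels for conditions #4-11."""
    if index not in FACTORIAL_CONDITIONS:
        raise ValueError(f"condition #{index} is not in the factorial design")
    env = _ENV_LEVELS[(index - 4) // 2]
    task = _TASK_LEVELS[(index - 4) % 2]
    return env, task


def paper_comparison_pairs(include_tasks: bool = True) -> list[tuple[int, int]]:
    """The pairwise comparison scheme: environments compared within the same
    saccade task, and pro vs anti within the same environment."""
    pairs: list[tuple[int, int]] = []
    for offset in (0, 1):  # pro row, anti row
        conds = [4 + offset, 6 + offset, 8 + offset, 10 + offset]
        pairs += [(a, b) for i, a in enumerate(conds) for b in conds[i + 1:]]
    if include_tasks:
        pairs += [(c, c + 1) for c in (4, 6, 8, 10)]
    return pairs


def _validate_long(table: pd.DataFrame) -> None:
    missing = {SUBJECT, CONDITION, PARAMETER, VALUE} - set(table.columns)
    if missing:
        raise ValueError(f"long table missing columns: {sorted(missing)}")
    dup = table.duplicated([SUBJECT, CONDITION, PARAMETER])
    if dup.any():
        raise ValueError("duplicate (subject, condition, parameter) rows")


# ---------------------------------------------------------------------------
# distributional checks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionCheck:
    parameter: str
    levene_p: float
    shapiro_p: float
    degenerate: bool = False


def check_distributions(table: pd.DataFrame) -> list[DistributionCheck]:
    """Brown-Forsythe homogeneity across conditions and Shapiro-Wilk
    normality of pooled within-condition residuals, per parameter."""
    _validate_long(table)
    out = []
    for param, sub in table.groupby(PARAMETER, sort=True):
        groups = [g[VALUE].to_numpy() for _, g in sub.groupby(CONDITION)]
        if any(len(g) < 3 for g in groups) or len(groups) < 2:
            raise ValueError(f"parameter {param!r}: need >= 3 obs in >= 2 groups")
        degenerate = all(np.ptp(g) == 0 for g in groups)
        if degenerate:
            lev_p = 1.0
        else:
            _, lev_p = sps.levene(*groups, center="median")
        resid = np.concatenate([g - g.mean() for g in groups])
        if np.ptp(resid) == 0:
            sh_p = float("nan")
            degenerate = True
        else:
            _, sh_p = sps.shapiro(resid)
        out.append(DistributionCheck(param, float(lev_p), float(sh_p), degenerate))
    return out


# ---------------------------------------------------------------------------
# aligned rank transform factorial ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtAnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float


def _rm_f_main(Y: np.ndarray, axis: int) -> tuple[float, int, int]:
    """F for one main effect of an (s, a, b) within-subject array, tested
    against its effect-by-subject interaction."""
    s, a, b = Y.shape
    grand = Y.mean()
    other = 2 if axis == 1 else 1
    n_lev = Y.shape[axis]
    n_oth = Y.shape[other]
    eff_mean = Y.mean(axis=(0, other))                     # (n_lev,)
    subj_mean = Y.mean(axis=(1, 2))                        # (s,)
    es_mean = Y.mean(axis=other)                           # (s, n_lev)
    ss_eff = s * n_oth * float(((eff_mean - grand) ** 2).sum())
    ss_err = n_oth * float(
        ((es_mean - eff_mean[None, :] - subj_mean[:, None] + grand) ** 2).sum()
    )
    df1 = n_lev - 1
    df2 = (n_lev - 1) * (s - 1)
    if ss_err <= 0:
        F = 0.0 if ss_eff <= 0 else np.inf  # constant levels -> no effect
    else:
        F = (ss_eff / df1) / (ss_err / df2)
    return F, df1, df2


def _rm_f_interaction(Y: np.ndarray) -> tuple[float, int, int]:
    s, a, b = Y.shape
    grand = Y.mean()
    cell = Y.mean(axis=0)              # (a, b)
    amean = Y.mean(axis=(0, 2))        # (a,)
    bmean = Y.mean(axis=(0, 1))        # (b,)
    smean = Y.mean(axis=(1, 2))        # (s,)
    asm = Y.mean(axis=2)               # (s, a)
    bsm = Y.mean(axis=1)               # (s, b)
    inter = cell - amean[:, None] - bmean[None, :] + grand
    ss_ab = s * float((inter ** 2).sum())
    resid = (Y - asm[:, :, None] - bsm[:, None, :] - cell[None, :, :]
             + amean[None, :, None] + bmean[None, None, :]
             + smean[:, None, None] - grand)
    ss_err = float((resid ** 2).sum())
    df1 = (a - 1) * (b - 1)
    df2 = (a - 1) * (b - 1) * (s - 1)
    if ss_err <= 0:
        F = 0.0 if ss_ab <= 0 else np.inf
    else:
        F = (ss_ab / df1) / (ss_err / df2)
    return F, df1, df2


def art_rm_anova(data: np.ndarray,
                 effect_names: tuple[str, str] = ("A", "B")) -> list[ArtAnovaResult]:
    """Aligned-rank-transform two-way repeated-measures ANOVA.

    ``data`` has shape (n_subjects, a, b): a fully crossed within-subject
    design with one observation per cell.  For each effect the response is
    aligned (cell means and subject effects stripped, the effect's own
    estimate restored), midranked over all observations, and the
    repeated-measures F for that effect is computed on the ranks.
    """
    Y = np.asarray(data, dtype=float)
    if Y.ndim != 3:
        raise ValueError("data must have shape (n_subjects, a, b)")
    s, a, b = Y.shape
    if s < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")
    grand = Y.mean()
    cell = Y.mean(axis=0)
    amean = Y.mean(axis=(0, 2))
    bmean = Y.mean(axis=(0, 1))
    smean = Y.mean(axis=(1, 2))
    resid = Y - cell[None, :, :] - smean[:, None, None] + grand

    estimates = {
        effect_names[0]: (amean - grand)[None, :, None],
        effect_names[1]: (bmean - grand)[None, None, :],
        f"{effect_names[0]}:{effect_names[1]}":
            (cell - amean[:, None] - bmean[None, :] + grand)[None, :, :],
    }
    out = []
    for i, (name, est) in enumerate(estimates.items()):
        aligned = resid + np.broadcast_to(est, Y.shape)
        ranks = sps.rankdata(aligned.ravel()).reshape(Y.shape)
        if i == 0:
            F, df1, df2 = _rm_f_main(ranks, axis=1)
        elif i == 1:
            F, df1, df2 = _rm_f_main(ranks, axis=2)
        else:
            F, df1, df2 = _rm_f_interaction(ranks)
        p = float(sps.f.sf(F, df1, df2))
        out.append(ArtAnovaResult(name, float(F), df1, df2, p))
    return out


def _factorial_cube(table: pd.DataFrame, parameter: str) -> tuple[np.ndarray, list]:
    sub = table[(table[PARAMETER] == parameter)
                & (table[CONDITION].isin(FACTORIAL_CONDITIONS))]
    wide = sub.pivot(index=SUBJECT, columns=CONDITION, values=VALUE)
    missing = [(subj, cond) for cond in FACTORIAL_CONDITIONS
               for subj in wide.index
               if cond not in wide.columns or pd.isna(wide.at[subj, cond])]
    if missing:
        raise ValueError(f"missing cells for {parameter!r}: {missing}")
    wide = wide[list(FACTORIAL_CONDITIONS)]
    cube = wide.to_numpy().reshape(len(wide), 4, 2)  # (subject, env, task)
    return cube, list(wide.index)


def rank_factorial_anova(table: pd.DataFrame) -> pd.DataFrame:
    """ART main effects of environment (4 levels) and saccade task (2
    levels) plus their interaction, per parameter, over conditions #4-11."""
    _validate_long(table)
    rows = []
    for param in sorted(table[PARAMETER].unique()):
        cube, _ = _factorial_cube(table, param)
        for res in art_rm_anova(cube, effect_names=("environment", "saccade_task")):
            rows.append({"parameter": param, "effect": res.effect, "F": res.F,
                         "df1": res.df1, "df2": res.df2, "p": res.p})
    return pd.DataFrame(rows)


def friedman_by_factor(table: pd.DataFrame) -> pd.DataFrame:
    """Friedman cross-check: per factor, average over the other factor's
    levels within subject and test across this factor's levels."""
    _validate_long(table)
    rows = []
    for param in sorted(table[PARAMETER].unique()):
        cube, _ = _factorial_cube(table, param)
        env_means = cube.mean(axis=2)   # (s, 4)
        task_means = cube.mean(axis=1)  # (s, 2)
        stat_e, p_e = sps.friedmanchisquare(*env_means.T)
        # two levels: Friedman reduces to a sign test; use Wilcoxon instead
        w = wilcoxon_signed_rank(task_means[:, 0], task_means[:, 1])
        rows.append({"parameter": param, "effect": "environment",
                     "statistic": float(stat_e), "p": float(p_e)})
        rows.append({"parameter": param, "effect": "saccade_task",
                     "statistic": w.statistic, "p": w.p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with exact small-sample p
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float       # W+ (sum of positive ranks)
    p: float               # two-sided
    z: float               # tie/zero-corrected normal deviate
    effect_size: float     # r = |z| / sqrt(n_pairs)
    n_pairs: int           # pairs entering the test (zeros dropped)
    n_total: int           # pairs supplied
    exact: bool
    all_zero: bool = False


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for W+ by dynamic programming.

    Under H0 each of the 2^n sign assignments is equally likely; the DP
    convolves the rank masses (midranks doubled to stay integral), giving
    the exact permutation distribution even under ties.
    """
    r2 = np.rint(ranks * 2).astype(int)  # midranks are multiples of 1/2
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(w_plus * 2))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    *,
    zero_method: str = "wilcox",
    exact_max_n: int = 25,
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped by default (``zero_method='wilcox'``;
    ``'pratt'`` keeps them in the ranking then discards their ranks).  The
    p value is exact (sign-assignment permutation distribution, valid under
    ties) for n <= ``exact_max_n`` nonzero pairs, otherwise a normal
    approximation with tie and zero corrections.  The effect size
    r = |Z|/sqrt(n) always uses the corrected normal deviate, with n the
    number of pairs entering the test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    d = x - y
    n_total = len(d)
    nz = d != 0
    if not nz.any():
        return WilcoxonResult(0.0, 1.0, 0.0, 0.0, 0, n_total, True, all_zero=True)

    if zero_method == "wilcox":
        d_use = d[nz]
        ranks = sps.rankdata(np.abs(d_use))
        zero_ranksum = 0.0
        n = len(d_use)
        e_w = n * (n + 1) / 4.0
    elif zero_method == "pratt":
        ranks_all = sps.rankdata(np.abs(d))
        ranks = ranks_all[nz]
        d_use = d[nz]
        n = len(d_use)
        n0 = n_total - n
        e_w = (n_total * (n_total + 1) / 2.0 - n0 * (n0 + 1) / 2.0) / 2.0
    else:
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")

    w_plus = float(ranks[d_use > 0].sum())
    # tie/zero-corrected variance of W+
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0
    var -= (counts ** 3 - counts).sum() / 48.0
    if zero_method == "pratt":
        n0 = n_total - n
        var = (n_total * (n_total + 1) * (2 * n_total + 1)
               - n0 * (n0 + 1) * (2 * n0 + 1)) / 24.0 - (counts ** 3 - counts).sum() / 48.0
    z = (w_plus - e_w) / np.sqrt(var) if var > 0 else 0.0

    exact = n <= exact_max_n and zero_method == "wilcox"
    if exact:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    r = abs(z) / np.sqrt(n) if n > 0 else 0.0
    return WilcoxonResult(w_plus, p, float(z), float(min(1.0, r)), n, n_total, exact)


def effect_size_magnitude(r: float) -> str:
    """Label r per the conventional thresholds (0.1 / 0.3 / 0.5)."""
    r = abs(r)
    if r >= 0.5:
        return "large"
    if r >= 0.3:
        return "moderate"
    if r >= 0.1:
        return "small"
    return "none"


@dataclass(frozen=True)
class PairwiseResult:
    parameter: str
    condition_a: int
    condition_b: int
    p_raw: float
    p_adjusted: float
    effect_size: float
    magnitude: str
    all_zero: bool = False


def wilcoxon_pairwise(
    table: pd.DataFrame,
    pairs: Iterable[tuple[int, int]] | None = None,
    *,
    zero_method: str = "wilcox",
    adjust: str = "holm",
) -> list[PairwiseResult]:
    """Pairwise signed-rank comparisons with Holm-adjusted p per parameter.

    ``pairs`` defaults to the dual-task comparison scheme (environments
    within task, tasks within environment over #4-11).  Pairs drawn from
    the factorial conditions must share a task or an environment; control
    conditions (#1-3) may be paired freely for the posture post hoc.
    """
    _validate_long(table)
    if pairs is None:
        pairs = paper_comparison_pairs()
    pairs = list(pairs)
    for a, b in pairs:
        if a in FACTORIAL_CONDITIONS and b in FACTORIAL_CONDITIONS:
            ea, ta = condition_factors(a)
            eb, tb = condition_factors(b)
            if ea != eb and ta != tb:
                raise ValueError(
                    f"pair ({a}, {b}) crosses both environment and task"
                )
    results: list[PairwiseResult] = []
    for param in sorted(table[PARAMETER].unique()):
        sub = table[table[PARAMETER] == param]
        wide = sub.pivot(index=SUBJECT, columns=CONDITION, values=VALUE)
        raw: list[WilcoxonResult] = []
        for a, b in pairs:
            if a not in wide.columns or b not in wide.columns:
                raise ValueError(f"condition #{a} or #{b} missing for {param!r}")
            paired = wide[[a, b]].dropna()
            raw.append(wilcoxon_signed_rank(paired[a], paired[b],
                                            zero_method=zero_method))
        adj = adjust_p([w.p for w in raw], method=adjust)
        for (a, b), w, pa in zip(pairs, raw, adj):
            results.append(
                PairwiseResult(param, a, b, w.p, pa, w.effect_size,
                               effect_size_magnitude(w.effect_size),
                               all_zero=w.all_zero)
            )
    return results


def adjust_p(p_values: Sequence[float], method: str = "holm") -> list[float]:
    """Multiplicity adjustment: 'holm' (default), 'bonferroni', or 'bh'."""
    p = list(p_values)
    if not p:
        return []
    if any(not (0.0 <= v <= 1.0) for v in p):
        raise ValueError("p values must lie in [0, 1]")
    sm_method = {"holm": "holm", "bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return list(multipletests(p, method=sm_method)[1])


# ---------------------------------------------------------------------------
# Spearman association matrices
# ---------------------------------------------------------------------------

@dataclass
class AssociationMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    condition: int
    alpha: float = 0.05


def spearman_matrix(
    table: pd.DataFrame,
    condition: int,
    parameter_set: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> AssociationMatrix:
    """Pairwise Spearman rank correlations between parameters within one
    condition, across subjects; flags unadjusted significance at ``alpha``.

    Constant columns yield masked (NaN) correlations.
    """
    _validate_long(table)
    sub = table[table[CONDITION] == condition]
    wide = sub.pivot(index=SUBJECT, columns=PARAMETER, values=VALUE)
    params = list(parameter_set) if parameter_set is not None else sorted(wide.columns)
    wide = wide[params].dropna()
    if len(wide) < 5:
        raise ValueError("need >= 5 complete subject rows")
    k = len(params)
    rho = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            xi, xj = wide.iloc[:, i], wide.iloc[:, j]
            if xi.nunique() < 2 or xj.nunique() < 2:
                continue  # constant column: masked
            if i == j:
                rho[i, j], pmat[i, j] = 1.0, 0.0
                continue
            r, p = sps.spearmanr(xi, xj)
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    rho_df = pd.DataFrame(rho, index=params, columns=params)
    p_df = pd.DataFrame(pmat, index=params, columns=params)
    sig = (p_df < alpha) & np.isfinite(rho_df) & ~np.eye(k, dtype=bool)
    return AssociationMatrix(rho_df, p_df, sig, condition, alpha)
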