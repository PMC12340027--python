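"""Group statistics: repeated-measures ANOVA, post-hoc cascade, rank
correlations with exact permutation p-values, FDR, and the
precision-pattern classifier.

All tests operate on the per-subject condition summaries (one row per
subject x design cell). The ANOVA is the classical fully-within-subject
factorial decomposition: each effect's sum of squares comes from its
marginal cell means and is tested against the matching
effect-by-subject interaction. Sphericity of every effect with two or
more numerator degrees of freedom is assessed with Mauchly's W on the
orthonormalised contrast covariance; when Mauchly rejects (p < .05 by
default) the degrees of freedom are scaled by the Greenhouse-Geisser
epsilon and the p-value recomputed. The Huynh-Feldt epsilon is reported
for information but never applied.

Everything here is deterministic given its input tables: the exact
Spearman p-value enumerates all n! rank pairings rather than sampling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DIRECTIONS, LEVELS
from .errors import DomainError, StructuralError
from .metrics import CONDITION_KEYS, REPORTED_METRICS, exemplar_group_means, metrics_frame
from .paradigm import TrialSet

#: display order of factor levels when pivoting summaries to arrays
FACTOR_ORDERS = {
    "precision_level": list(LEVELS),
    "mean_change_level": list(LEVELS),
    "direction": list(DIRECTIONS),
}

_SHORT = {
    "precision_level": "precision",
    "mean_change_level": "mean_change",
    "direction": "direction",
}


# ---------------------------------------------------------------------------
# pivoting and the factorial decomposition


def _levels_of(summaries: pd.DataFrame, factor: str) -> list:
    if factor in FACTOR_ORDERS:
        order = [l for l in FACTOR_ORDERS[factor] if l in set(summaries[factor])]
        return order
    return sorted(summaries[factor].unique())


def pivot_to_array(
    summaries: pd.DataFrame,
    dv: str,
    factors: Sequence[str],
    subject: str = "subject_id",
) -> tuple[np.ndarray, list[list]]:
    """Pivot a summaries table to an (n_subjects, k1, ..., kf) array.

    Raises :class:`StructuralError` unless the design is complete and
    balanced (every subject exactly once in every cell).
    """
    levels = [_levels_of(summaries, f) for f in factors]
    subjects = sorted(summaries[subject].unique())
    sizes = summaries.pivot_table(
        index=subject, columns=list(factors), values=dv, aggfunc="size",
        observed=True,
    )
    n_cells = int(np.prod([len(l) for l in levels]))
    if sizes.shape[1] != n_cells or sizes.isna().any().any() or (sizes != 1).any().any():
        raise DomainError(
            "incomplete or unbalanced design: every subject must appear "
            "exactly once in every design cell (no imputation is performed)"
        )
    means = summaries.pivot_table(
        index=subject, columns=list(factors), values=dv, aggfunc="mean",
        observed=True,
    )
    # reindex columns into canonical level order
    if len(factors) == 1:
        means = means.reindex(columns=levels[0])
    else:
        means = means.reindex(columns=pd.MultiIndex.from_product(levels))
    y = means.loc[subjects].to_numpy().reshape(len(subjects), *[len(l) for l in levels])
    if np.isnan(y).any():
        raise DomainError("missing cells after pivot; design must be complete")
    return y, levels


def _pure_interaction(a: np.ndarray) -> np.ndarray:
    """Highest-order centred interaction term of an n-d array.

    Inclusion–exclusion over all subsets of axes: the result has zero
    marginal means over every axis.
    """
    d = a.ndim
    out = np.zeros_like(a, dtype=float)
    for r in range(d + 1):
        for keep in itertools.combinations(range(d), r):
            drop = tuple(ax for ax in range(d) if ax not in keep)
            term = a.mean(axis=drop, keepdims=True) if drop else a
            out += (-1) ** (d - r) * term
    return out


def _effect_F(y: np.ndarray, effect_axes: tuple[int, ...]) -> tuple[float, int, int, float, float]:
    """F statistic of one within-subject effect from the data array.

    ``y`` has shape (n_subjects, k1, ..., kf); ``effect_axes`` indexes the
    factor axes (1-based within ``y``) belonging to the effect.
    """
    n = y.shape[0]
    factor_axes = tuple(range(1, y.ndim))
    uninvolved = tuple(ax for ax in factor_axes if ax not in effect_axes)
    mult = int(np.prod([y.shape[ax] for ax in uninvolved])) if uninvolved else 1

    cell = y.mean(axis=uninvolved) if uninvolved else y  # (n, kE...)
    eff = _pure_interaction(cell.mean(axis=0))
    ss_eff = n * mult * float((eff**2).sum())
    err = _pure_interaction(cell)  # the effect x subject interaction term
    ss_err = mult * float((err**2).sum())
    df_eff = int(np.prod([y.shape[ax] - 1 for ax in effect_axes]))
    df_err = df_eff * (n - 1)
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    F = ms_eff / ms_err if ms_err > 0 else math.inf
    p = float(sps.f.sf(F, df_eff, df_err)) if math.isfinite(F) else 0.0
    return F, df_eff, df_err, p, ss_err


# ---------------------------------------------------------------------------
# sphericity: Mauchly's W and the epsilon corrections


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the centred (contrast) space."""
    basis = np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]])
    q, _ = np.linalg.qr(basis)
    return q[:, 1:].T


def effect_contrast_matrix(shape: Sequence[int], effect_axes: Iterable[int]) -> np.ndarray:
    """Orthonormal contrast matrix of an effect in a factorial design.

    ``shape`` lists the factor level counts in axis order; rows of the
    returned (q x prod(shape)) matrix span the effect subspace of the
    flattened (C-order) cell vector.
    """
    effect_axes = set(effect_axes)
    mats = []
    for ax, k in enumerate(shape):
        if ax in effect_axes:
            mats.append(_orthonormal_contrasts(k))
        else:
            mats.append(np.ones((1, k)) / math.sqrt(k))
    C = mats[0]
    for m in mats[1:]:
        C = np.kron(C, m)
    return C


@dataclass(frozen=True)
class SphericityResult:
    mauchly_W: float
    mauchly_p: float
    gg_epsilon: float
    hf_epsilon: float
    applicable: bool
    note: str = ""


def sphericity_from_scores(Z: np.ndarray) -> SphericityResult:
    """Mauchly's test and epsilon estimates from contrast scores (n x q)."""
    n, q = Z.shape
    if q < 2:
        return SphericityResult(1.0, 1.0, 1.0, 1.0, applicable=False,
                                note="single contrast: sphericity holds trivially")
    S = np.cov(Z, rowvar=False, ddof=1)
    tr = float(np.trace(S))
    if not np.isfinite(tr) or tr <= 0:
        return SphericityResult(np.nan, np.nan, 1.0, 1.0, applicable=False,
                                note="degenerate contrast covariance")
    eig = np.linalg.eigvalsh(S)
    eig = np.clip(eig, 0.0, None)
    gg = tr**2 / (q * float((eig**2).sum()))
    gg = float(np.clip(gg, 1.0 / q, 1.0))
    denom = q * (n - 1 - q * gg)
    hf = (n * q * gg - 2.0) / denom if denom > 0 else 1.0
    hf = float(np.clip(hf, gg, 1.0))
    det = float(np.prod(eig))
    if det <= 0 or n - 1 <= q:
        return SphericityResult(np.nan, np.nan, gg, hf, applicable=False,
                                note="singular covariance: Mauchly test skipped")
    W = det / (tr / q) ** q
    f = 1.0 - (2.0 * q**2 + q + 2.0) / (6.0 * q * (n - 1.0))
    chi2 = -(n - 1.0) * f * math.log(W)
    df = q * (q + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df))
    return SphericityResult(float(W), p, gg, hf, applicable=True)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

EFFECTS_COLUMNS = [
    "effect", "F", "df_num", "df_den", "p_uncorrected",
    "mauchly_W", "mauchly_p", "gg_epsilon", "hf_epsilon",
    "corrected", "df_num_corr", "df_den_corr", "p_reported",
]


def rm_anova(
    summaries: pd.DataFrame,
    dv: str = "mean_psc",
    factors: Sequence[str] = tuple(CONDITION_KEYS),
    subject: str = "subject_id",
    correct_sphericity: bool = True,
    mauchly_alpha: float = 0.05,
) -> pd.DataFrame:
    """Fully within-subject factorial ANOVA with sphericity handling.

    Returns one row per effect (all main effects and interactions, in
    order of increasing order), with uncorrected and — where Mauchly's
    test rejects at ``mauchly_alpha`` — Greenhouse-Geisser corrected
    degrees of freedom and p-values.
    """
    y, levels = pivot_to_array(summaries, dv, factors, subject)
    return rm_anova_from_array(
        y,
        effect_names=[_SHORT.get(f, f) for f in factors],
        correct_sphericity=correct_sphericity,
        mauchly_alpha=mauchly_alpha,
    )


def rm_anova_from_array(
    y: np.ndarray,
    effect_names: Sequence[str] | None = None,
    correct_sphericity: bool = True,
    mauchly_alpha: float = 0.05,
) -> pd.DataFrame:
    """ANOVA core on an (n_subjects, k1, ..., kf) array (no pandas pivot)."""
    n = y.shape[0]
    nf = y.ndim - 1
    if n < 2:
        raise DomainError("need at least 2 subjects")
    names = list(effect_names or [f"f{i}" for i in range(nf)])
    shape = y.shape[1:]
    Yflat = y.reshape(n, -1)

    rows = []
    for order in range(1, nf + 1):
        for combo in itertools.combinations(range(nf), order):
            effect_axes = tuple(ax + 1 for ax in combo)
            F, df1, df2, p, _ = _effect_F(y, effect_axes)
            name = ":".join(names[i] for i in combo)
            sph = SphericityResult(np.nan, np.nan, 1.0, 1.0, applicable=False)
            if df1 >= 2:
                C = effect_contrast_matrix(shape, combo)
                Z = Yflat @ C.T
                sph = sphericity_from_scores(Z)
            corrected = bool(
                correct_sphericity
                and sph.applicable
                and sph.mauchly_p < mauchly_alpha
            )
            if corrected:
                df1c, df2c = df1 * sph.gg_epsilon, df2 * sph.gg_epsilon
                p_rep = float(sps.f.sf(F, df1c, df2c))
            else:
                df1c, df2c, p_rep = float(df1), float(df2), p
            rows.append(
                (name, F, df1, df2, p, sph.mauchly_W, sph.mauchly_p,
                 sph.gg_epsilon if df1 >= 2 else 1.0,
                 sph.hf_epsilon if df1 >= 2 else 1.0,
                 corrected, df1c, df2c, p_rep)
            )
    return pd.DataFrame(rows, columns=EFFECTS_COLUMNS)


def sphericity_correction(
    summaries: pd.DataFrame,
    effect: str | Sequence[str],
    dv: str = "mean_psc",
    factors: Sequence[str] = tuple(CONDITION_KEYS),
    subject: str = "subject_id",
) -> SphericityResult:
    """Sphericity diagnostics for one named effect of the design.

    ``effect`` is either a colon-joined short name ("precision:mean_change")
    or a sequence of factor column names.
    """
    if isinstance(effect, str):
        wanted = effect.split(":")
        inv = {v: k for k, v in _SHORT.items()}
        cols = [inv.get(w, w) for w in wanted]
    else:
        cols = list(effect)
    y, _ = pivot_to_array(summaries, dv, factors, subject)
    combo = tuple(list(factors).index(c) for c in cols)
    q = int(np.prod([y.shape[ax + 1] - 1 for ax in combo]))
    if q < 2:
        return SphericityResult(1.0, 1.0, 1.0, 1.0, applicable=False,
                                note="effect has < 2 df: correction is identity")
    C = effect_contrast_matrix(y.shape[1:], combo)
    Z = y.reshape(y.shape[0], -1) @ C.T
    return sphericity_from_scores(Z)


# ---------------------------------------------------------------------------
# post-hoc cascade

CASCADE_COLUMNS = [
    "stage", "context", "test", "statistic_name", "statistic",
    "df1", "df2", "p", "m_stage", "p_adj", "significant", "neighbouring",
]


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, m * p)


def _row_p(effects: pd.DataFrame, effect: str) -> float:
    r = effects.loc[effects["effect"] == effect]
    return float(r["p_reported"].iloc[0]) if len(r) else np.nan


def posthoc_cascade(
    summaries: pd.DataFrame,
    effects: pd.DataFrame,
    alpha: float = 0.05,
    dv: str = "mean_psc",
    subject: str = "subject_id",
) -> pd.DataFrame:
    """Hierarchical post-hoc testing with Bonferroni adjustment per stage.

    Stage 1: if the three-way interaction is significant, two-way ANOVAs
    of each factor pair within every level of the third factor. Stage 2:
    simple main effects for every significant two-way model (omnibus or
    stage-1). Stage 3: pairwise paired t-tests between precision levels
    wherever a precision main effect (omnibus or simple) is significant.
    Each stage's p-values are Bonferroni-multiplied by the number of
    tests in that stage. Returns the cascade table (possibly empty).
    """
    factors = list(CONDITION_KEYS)
    short = [_SHORT[f] for f in factors]
    three_way = ":".join(short)
    recs: list[dict] = []

    # ----- stage 1: break the three-way into two-way interactions
    stage1: list[dict] = []
    if _row_p(effects, three_way) < alpha:
        for slice_i, slice_f in enumerate(factors):
            pair = [f for f in factors if f != slice_f]
            pair_name = ":".join(_SHORT[f] for f in pair)
            for lev in _levels_of(summaries, slice_f):
                sub = summaries[summaries[slice_f] == lev]
                tab = rm_anova(sub, dv=dv, factors=pair, subject=subject)
                r = tab.loc[tab["effect"] == pair_name].iloc[0]
                stage1.append(dict(
                    stage="two_way_breakdown",
                    context=f"{_SHORT[slice_f]}={lev}",
                    test=pair_name,
                    statistic_name="F", statistic=r["F"],
                    df1=r["df_num_corr"], df2=r["df_den_corr"],
                    p=r["p_reported"], neighbouring=np.nan,
                ))
    m1 = len(stage1)
    for r in stage1:
        r["m_stage"] = m1
        r["p_adj"] = _bonferroni(r["p"], m1)
        r["significant"] = r["p_adj"] < alpha
    recs.extend(stage1)

    # ----- stage 2: simple main effects of significant two-way models
    sig_two_way: list[tuple[str, list[str]]] = []  # (context, pair)
    for f, g in itertools.combinations(factors, 2):
        name = ":".join([_SHORT[f], _SHORT[g]])
        if _row_p(effects, name) < alpha:
            sig_two_way.append(("all", [f, g]))
    for r in stage1:
        if r["significant"]:
            pair_cols = [f for f in factors
                         if _SHORT[f] in r["test"].split(":")]
            sig_two_way.append((r["context"], pair_cols))

    stage2: list[dict] = []
    for context, pair in sig_two_way:
        sub = summaries
        if context != "all":
            cf_short, lev = context.split("=")
            cf = {v: k for k, v in _SHORT.items()}[cf_short]
            sub = summaries[summaries[cf] == lev]
        for f in pair:
            other = pair[0] if pair[1] == f else pair[1]
            for lev in _levels_of(sub, other):
                cell = sub[sub[other] == lev]
                # collapse any remaining factor to subject x f cell means
                cell = (
                    cell.groupby([subject, f], observed=True)[dv]
                    .mean()
                    .reset_index()
                )
                tab = rm_anova(cell, dv=dv, factors=[f], subject=subject)
                r = tab.iloc[0]
                ctx = f"{context};{_SHORT[other]}={lev}" if context != "all" \
                    else f"{_SHORT[other]}={lev}"
                stage2.append(dict(
                    stage="simple_main_effect",
                    context=ctx,
                    test=_SHORT[f],
                    statistic_name="F", statistic=r["F"],
                    df1=r["df_num_corr"], df2=r["df_den_corr"],
                    p=r["p_reported"], neighbouring=np.nan,
                ))
    m2 = len(stage2)
    for r in stage2:
        r["m_stage"] = m2
        r["p_adj"] = _bonferroni(r["p"], m2)
        r["significant"] = r["p_adj"] < alpha
    recs.extend(stage2)

    # ----- stage 3: pairwise precision comparisons
    prec = "precision_level"
    contexts: list[str] = []
    if _row_p(effects, "precision") < alpha:
        contexts.append("all")
    contexts += [r["context"] for r in stage2
                 if r["test"] == "precision" and r["significant"]]

    stage3: list[dict] = []
    for context in contexts:
        sub = summaries
        if context != "all":
            inv = {v: k for k, v in _SHORT.items()}
            for clause in context.split(";"):
                cf_short, lev = clause.split("=")
                sub = sub[sub[inv[cf_short]] == lev]
        cellmeans = (
            sub.groupby([subject, prec], observed=True)[dv].mean().unstack(prec)
        )
        levs = [l for l in FACTOR_ORDERS[prec] if l in cellmeans.columns]
        for a, b in itertools.combinations(levs, 2):
            t, p = sps.ttest_rel(cellmeans[a], cellmeans[b])
            stage3.append(dict(
                stage="pairwise_precision",
                context=context,
                test=f"{a} vs {b}",
                statistic_name="t", statistic=float(t),
                df1=float(len(cellmeans) - 1), df2=np.nan,
                p=float(p),
                neighbouring=(levs.index(b) - levs.index(a) == 1),
            ))
    m3 = len(stage3)
    for r in stage3:
        r["m_stage"] = m3
        r["p_adj"] = _bonferroni(r["p"], m3)
        r["significant"] = r["p_adj"] < alpha
    recs.extend(stage3)

    if not recs:
        return pd.DataFrame(columns=CASCADE_COLUMNS)
    return pd.DataFrame(recs)[CASCADE_COLUMNS]


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up


def benjamini_hochberg(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Step-up FDR q-values: q_(i) = min_{j >= i} m p_(j) / j, capped at 1.

    NaN entries are ignored (and returned as NaN); ``m`` defaults to the
    number of valid p-values.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if pv.size == 0:
        return q
    if np.any((pv < 0) | (pv > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    mm = int(m) if m is not None else pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * mm / np.arange(1, pv.size + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.clip(qv, 0.0, 1.0)
    out = np.empty_like(qv)
    out[order] = qv
    q[valid] = out
    return q


# ---------------------------------------------------------------------------
# Spearman correlation with exact permutation p


@lru_cache(maxsize=3)
def _all_permutations(n: int) -> np.ndarray:
    if n > 10:
        raise DomainError(f"exact enumeration limited to n <= 10, got {n}")
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def spearman(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Spearman rho (mid-rank ties) with a two-sided p-value.

    ``method='exact'`` enumerates all n! pairings of the rank vectors
    (default for n <= 10); ``'asymptotic'`` uses the large-sample t
    approximation. Returns (nan, nan) when either variable is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StructuralError("need two equal-length vectors with n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if method == "auto":
        method = "exact" if n <= 10 else "asymptotic"
    if method == "asymptotic":
        return rho, float(sps.spearmanr(x, y).pvalue)
    if method != "exact":
        raise DomainError(f"unknown method {method!r}")
    perms = _all_permutations(n)
    centre = n * rx.mean() * ry.mean()
    dev_obs = abs(float(rx @ ry) - centre) - 1e-9
    count = 0
    total = perms.shape[0]
    chunk = 500_000
    for i in range(0, total, chunk):
        T = ry[perms[i : i + chunk]] @ rx
        count += int(np.count_nonzero(np.abs(T - centre) >= dev_obs))
    return rho, count / total


# ---------------------------------------------------------------------------
# the 54-cell extreme-value correlation table

CORRELATION_COLUMNS = [
    *CONDITION_KEYS, "metric", "n", "rho", "p", "q_bh", "flagged",
]


def extreme_value_correlations(
    trial_set: TrialSet,
    responses: pd.DataFrame,
    method: str = "auto",
    metrics: Sequence[str] = REPORTED_METRICS,
) -> pd.DataFrame:
    """Per condition x metric: Spearman rho across exemplars, p, BH q.

    For the default presets this is exactly 18 x 3 = 54 rows, with n = 10
    exemplar pairs per correlation; q-values apply Benjamini-Hochberg
    step-up across all rows of the table. Conditions in which a metric or
    the group-mean rating is constant yield a flagged row with NaN rho.
    """
    gm = exemplar_group_means(responses, trial_set)
    met = metrics_frame(trial_set)
    merged = gm.merge(
        met[["trial_id", *metrics]], on="trial_id", validate="one_to_one"
    )
    rows = []
    conds = merged[CONDITION_KEYS].drop_duplicates()
    conds = conds.sort_values(
        CONDITION_KEYS,
        key=lambda s: s.map(
            {l: i for i, l in enumerate(FACTOR_ORDERS[s.name])}
        ),
        kind="mergesort",
    )
    for _, c in conds.iterrows():
        mask = (merged[CONDITION_KEYS] == c.values).all(axis=1)
        sub = merged[mask].sort_values("exemplar_index")
        for metric in metrics:
            xv = sub[metric].to_numpy()
            yv = sub["mean_psc"].to_numpy()
            if np.std(xv) == 0 or np.std(yv) == 0:
                rows.append((*c.values, metric, len(sub), np.nan, np.nan, True))
                continue
            rho, p = spearman(xv, yv, method=method)
            rows.append((*c.values, metric, len(sub), rho, p, False))
    out = pd.DataFrame(
        rows, columns=[*CONDITION_KEYS, "metric", "n", "rho", "p", "flagged"]
    )
    out["q_bh"] = benjamini_hochberg(out["p"].to_numpy(), m=len(out))
    return out[CORRELATION_COLUMNS]


# ---------------------------------------------------------------------------
# precision-pattern classification

PATTERN_LABELS = ("bayesian", "non_bayesian", "counter_bayesian", "mixed")


@dataclass(frozen=True)
class PatternLabel:
    """Regime label of one design slice (mean-change level x direction)."""

    slice_id: str
    label: str
    slope_statistic: float  # mean linear trend of rating across precision
    evidence_p: float  # two-sided p of the linear trend
    quad_statistic: float
    quad_p: float
    n_subjects: int


def _one_sample_p(values: np.ndarray) -> float:
    """Two-sided one-sample t-test p, with the degenerate zero-variance
    case resolved by consistency: identical non-zero values are perfect
    evidence (p = 0), identical zeros none (p = 1)."""
    sd = float(np.std(values, ddof=1))
    if sd == 0:
        return 1.0 if float(np.mean(values)) == 0 else 0.0
    t, p = sps.ttest_1samp(values, 0.0)
    return float(p)


def classify_precision_pattern(
    summaries: pd.DataFrame,
    mean_change_level: str | None = None,
    direction: str | None = None,
    dv: str = "mean_psc",
    alpha: float = 0.05,
    subject: str = "subject_id",
) -> PatternLabel:
    """Label the precision–rating pattern of one design slice.

    Each subject's ratings at (low, med, high) precision give a linear
    contrast (high - low) and a quadratic contrast (low - 2 med + high);
    both are tested against zero at ``alpha / 2`` each (Bonferroni within
    the two-contrast family). A significantly positive linear trend is
    ``bayesian``, negative ``counter_bayesian``; with no linear trend, a
    flat quadratic means ``non_bayesian`` and a significant one
    ``mixed`` (non-monotone). With both slice arguments ``None`` the
    overall pattern (collapsing mean change and direction) is labelled.
    """
    sub = summaries
    parts = []
    if mean_change_level is not None:
        sub = sub[sub["mean_change_level"] == mean_change_level]
        parts.append(f"mean_change={mean_change_level}")
    if direction is not None:
        sub = sub[sub["direction"] == direction]
        parts.append(f"direction={direction}")
    slice_id = ";".join(parts) or "overall"

    cellmeans = (
        sub.groupby([subject, "precision_level"], observed=True)[dv]
        .mean()
        .unstack("precision_level")
        .reindex(columns=list(LEVELS))
    )
    if cellmeans.isna().any().any():
        raise StructuralError(
            f"slice {slice_id!r} lacks complete low/med/high precision data"
        )
    arr = cellmeans.to_numpy()
    lin = arr @ np.array([-1.0, 0.0, 1.0])
    quad = arr @ np.array([1.0, -2.0, 1.0])
    p_lin = _one_sample_p(lin)
    p_quad = _one_sample_p(quad)
    cut = alpha / 2.0
    if p_lin < cut:
        label = "bayesian" if lin.mean() > 0 else "counter_bayesian"
    elif p_quad < cut:
        label = "mixed"
    else:
        label = "non_bayesian"
    return PatternLabel(
        slice_id=slice_id,
        label=label,
        slope_statistic=float(lin.mean()),
        evidence_p=p_lin,
        quad_statistic=float(quad.mean()),
        quad_p=p_quad,
        n_subjects=len(cellmeans),
    )


def classify_patterns(
    summaries: pd.DataFrame, dv: str = "mean_psc", alpha: float = 0.05
) -> pd.DataFrame:
    """Pattern labels for all six mean-change x direction slices + overall."""
    labels = [classify_precision_pattern(summaries, dv=dv, alpha=alpha)]
    for m in LEVELS:
        for d in DIRECTIONS:
            labels.append(
                classify_precision_pattern(
                    summaries, mean_change_level=m, direction=d, dv=dv, alpha=alpha
                )
            )
    return pd.DataFrame([vars(l) for l in labels])
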