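"""Hierarchical group comparisons for cohort measurement tables.

The study design is a fixed-effects factorial: age (12/22/30 months) x
sex (M/F) x genotype (control vs induced knockout).  Measurements
repeated within a scan are averaged per scan, scan averages are
averaged per animal, and all inference runs on the animal-level
values -- the animal is the experimental unit.

The three-way ANOVA uses sum-to-zero (effects) coding and marginal
(Type III) sums of squares, which coincide with the classical balanced
decomposition when cell sizes are equal and stay well-defined under
imbalance.  Post hoc pairwise comparisons use the Tukey HSD
studentized-range criterion.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "animal_average",
    "AnovaResult",
    "three_way_anova",
    "factorial_anova",
    "tukey_hsd",
    "tukey_max_q",
    "effect_recovery_report",
]

DEFAULT_FACTORS = ("age", "sex", "genotype")


def animal_average(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    factors: tuple[str, ...] = DEFAULT_FACTORS,
    animal_col: str = "animal",
    scan_col: str = "scan",
) -> pd.DataFrame:
    """Two-level averaging: repeats -> scan means -> animal mean.

    Each scan's repeated measurements are averaged first and the scan
    means are then averaged per animal with equal weight, so scans
    with more repeats do not dominate (pooling raw repeats across
    scans is deliberately *not* equivalent and not offered).

    Returns one row per animal with its factor levels and trait means.
    Rows with missing trait values are dropped with a warning.  Raises
    if an animal appears in more than one factor cell.
    """
    if traits is None:
        reserved = {animal_col, scan_col, *factors}
        traits = [c for c in table.columns if c not in reserved]
    cells = table.groupby(animal_col)[list(factors)].nunique()
    bad = cells[(cells > 1).any(axis=1)].index.tolist()
    if bad:
        raise ValueError(f"animals mapped to multiple factor cells: {bad}")
    n_missing = int(table[traits].isna().any(axis=1).sum())
    if n_missing:
        warnings.warn(f"dropping {n_missing} rows with missing trait values")
        table = table.dropna(subset=traits)
    scan_means = (
        table.groupby([animal_col, scan_col, *factors], observed=True)[traits]
        .mean()
        .reset_index()
    )
    return (
        scan_means.groupby([animal_col, *factors], observed=True)[traits]
        .mean()
        .reset_index()
    )


@dataclass
class AnovaResult:
    """Fixed-effects factorial ANOVA table.

    ``table`` has one row per term (main effects, then interactions)
    with columns ``ss, df, F, p``; residual SS/df are separate fields.
    """

    table: pd.DataFrame
    ss_residual: float
    df_residual: int
    ms_residual: float
    n_obs: int
    alpha: float = 0.05

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _sum_code(series: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero contrast columns for one categorical factor."""
    levels = sorted(pd.unique(series))
    L = len(levels)
    if L < 2:
        raise ValueError(f"factor needs >= 2 observed levels, got {levels}")
    idx = series.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    X = np.zeros((len(series), L - 1))
    for j in range(L - 1):
        X[idx == j, j] = 1.0
        X[idx == L - 1, j] = -1.0
    return X, levels


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def factorial_anova(
    table: pd.DataFrame,
    trait: str,
    factors: tuple[str, ...] = DEFAULT_FACTORS,
    alpha: float = 0.05,
) -> AnovaResult:
    """Fixed-effects full-factorial ANOVA with Type III sums of squares.

    Every interaction up to the full order is included.  Each term's
    SS is the increase in residual SS when that term's sum-coded
    columns are dropped from the full model (marginal SS; classical
    decomposition for balanced data).  Empty design cells raise with
    the offending cells listed; so does zero residual df.
    """
    y = table[trait].to_numpy(float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"non-finite values in trait {trait!r}")

    # explicit empty-cell check before any fitting
    observed = set(map(tuple, table[list(factors)].itertuples(index=False)))
    levels = [sorted(pd.unique(table[f])) for f in factors]
    empty = [cell for cell in itertools.product(*levels) if cell not in observed]
    if empty:
        raise ValueError(f"empty design cells: {empty}")

    codes = {f: _sum_code(table[f]) for f in factors}
    term_cols: dict[str, np.ndarray] = {}
    order = []
    for k in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, k):
            mats = [codes[f][0] for f in combo]
            X = mats[0]
            for M in mats[1:]:
                X = np.einsum("ni,nj->nij", X, M).reshape(len(y), -1)
            name = ":".join(combo)
            term_cols[name] = X
            order.append(name)

    X_full = np.column_stack([np.ones(len(y))] + [term_cols[t] for t in order])
    p_full = X_full.shape[1]
    df_res = len(y) - p_full
    if df_res <= 0:
        raise ValueError(
            f"zero residual degrees of freedom (n={len(y)}, parameters={p_full}); "
            "need >= 2 animals in some cell"
        )
    rss_full = _rss(X_full, y)
    ss_total = float(np.sum((y - y.mean()) ** 2))

    rows = []
    for t in order:
        keep = [np.ones((len(y), 1))] + [term_cols[u] for u in order if u != t]
        rss_r = _rss(np.column_stack(keep), y)
        ss = max(rss_r - rss_full, 0.0)
        df_t = term_cols[t].shape[1]
        ms_res = rss_full / df_res
        if ss <= 1e-12 * max(ss_total, 1.0):
            f_stat, p = 0.0, 1.0
        elif ms_res == 0.0:
            f_stat, p = float("inf"), 0.0
        else:
            f_stat = (ss / df_t) / ms_res
            p = float(sps.f.sf(f_stat, df_t, df_res))
        rows.append({"term": t, "ss": ss, "df": df_t, "F": f_stat, "p": p})

    out = pd.DataFrame(rows).set_index("term")
    return AnovaResult(
        table=out,
        ss_residual=rss_full,
        df_residual=df_res,
        ms_residual=rss_full / df_res,
        n_obs=len(y),
        alpha=alpha,
    )


def three_way_anova(
    table: pd.DataFrame,
    trait: str,
    factors: tuple[str, str, str] = DEFAULT_FACTORS,
    alpha: float = 0.05,
) -> AnovaResult:
    """Age x sex x genotype ANOVA on an animal-level table."""
    if len(factors) != 3:
        raise ValueError("three_way_anova needs exactly three factors")
    return factorial_anova(table, trait, factors, alpha)


def _group_stats(table, trait, grouping):
    grouped = table.groupby(list(grouping), observed=True)[trait]
    means = grouped.mean()
    ns = grouped.size()
    if len(means) < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    return means, ns


def _pairwise_q(means, ns, ms_resid):
    pairs, qs, diffs = [], [], []
    keys = list(means.index)
    for a, b in itertools.combinations(keys, 2):
        diff = means[a] - means[b]
        se = np.sqrt(ms_resid / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        pairs.append((a, b))
        diffs.append(diff)
        qs.append(np.abs(diff) / se if se > 0 else np.inf * (diff != 0))
    return pairs, np.asarray(diffs, float), np.asarray(qs, float)


def tukey_hsd(
    table: pd.DataFrame,
    trait: str,
    grouping: tuple[str, ...] | str,
    ms_resid: float | None = None,
    df_resid: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairwise Tukey HSD comparisons on animal-level means.

    Groups are the observed cells of ``grouping`` (one factor or a
    tuple, e.g. ``("age", "genotype")``).  The standard error uses
    ``ms_resid`` -- pass the residual mean square of a previously
    fitted ANOVA for the classical post hoc test; by default the
    pooled within-group variance (the one-way residual MS over the
    grouping cells) is used.  Adjusted p-values come from the
    studentized-range distribution with the number of groups as range
    parameter.
    """
    if isinstance(grouping, str):
        grouping = (grouping,)
    means, ns = _group_stats(table, trait, grouping)
    k = len(means)
    if ms_resid is None or df_resid is None:
        y = table[trait].to_numpy(float)
        cells = table.groupby(list(grouping), observed=True)[trait]
        ssw = float(sum(((g - g.mean()) ** 2).sum() for _, g in cells))
        df_resid = len(y) - k
        if df_resid <= 0:
            raise ValueError("no residual degrees of freedom for Tukey HSD")
        ms_resid = ssw / df_resid
    pairs, diffs, qs = _pairwise_q(means, ns, ms_resid)
    with np.errstate(invalid="ignore"):
        p_adj = sps.studentized_range.sf(qs, k, df_resid)
    p_adj = np.where(np.isfinite(qs), p_adj, np.where(qs > 0, 0.0, 1.0))
    p_adj = np.where(qs == 0.0, 1.0, p_adj)
    return pd.DataFrame(
        {
            "group1": [p[0] for p in pairs],
            "group2": [p[1] for p in pairs],
            "diff": diffs,
            "q": qs,
            "p_adj": np.clip(p_adj, 0.0, 1.0),
            "reject": np.clip(p_adj, 0.0, 1.0) < alpha,
        }
    )


def tukey_max_q(
    table: pd.DataFrame,
    trait: str,
    grouping: tuple[str, ...] | str,
) -> tuple[float, int, int]:
    """Largest pairwise studentized-range statistic and its (k, df).

    Shares the group-mean / pooled-variance / q computation with
    :func:`tukey_hsd` but skips the (expensive) studentized-range tail
    evaluation, so simulation loops can compare ``max q`` against a
    single critical value: ``any adjusted p < alpha`` is equivalent to
    ``max q > studentized_range.isf(alpha, k, df)``.
    """
    if isinstance(grouping, str):
        grouping = (grouping,)
    means, ns = _group_stats(table, trait, grouping)
    k = len(means)
    y = table[trait].to_numpy(float)
    cells = table.groupby(list(grouping), observed=True)[trait]
    ssw = float(sum(((g - g.mean()) ** 2).sum() for _, g in cells))
    df_resid = len(y) - k
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    ms = ssw / df_resid
    _, _, qs = _pairwise_q(means, ns, ms)
    return float(np.max(qs)), k, df_resid


def effect_recovery_report(
    table: pd.DataFrame,
    truth: pd.DataFrame,
    factor: str = "genotype",
    baseline_level: str = "control",
    factors: tuple[str, ...] = DEFAULT_FACTORS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare recovered factor effects against planted multipliers.

    For every trait in the cohort table: animals are averaged, the
    factorial ANOVA is fitted, and the estimated effect of ``factor``
    is the ratio of its unweighted marginal cell means (non-baseline /
    baseline).  The planted multiplier is read off the generator truth
    table (ratio of true cell means, marginal over the other factors).

    Returns one row per trait: ``estimated_ratio, true_ratio, p,
    significant``.
    """
    traits = sorted(truth["trait"].unique())
    animals = animal_average(table, traits=traits, factors=factors)
    levels = [lv for lv in table[factor].unique() if lv != baseline_level]
    if len(levels) != 1:
        raise ValueError("effect_recovery_report expects a two-level factor")
    alt = levels[0]
    other = [f for f in factors if f != factor]
    rows = []
    for trait in traits:
        res = factorial_anova(animals, trait, factors, alpha)
        cell_means = animals.groupby(list(factors), observed=True)[trait].mean()
        m_alt = cell_means.xs(alt, level=factor).mean()
        m_base = cell_means.xs(baseline_level, level=factor).mean()
        t_cells = truth[truth["trait"] == trait].set_index(list(factors))["cell_mean"]
        t_alt = t_cells.xs(alt, level=factor).mean()
        t_base = t_cells.xs(baseline_level, level=factor).mean()
        p = res.p_value(factor)
        rows.append(
            {
                "trait": trait,
                "estimated_ratio": m_alt / m_base,
                "true_ratio": t_alt / t_base,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("trait")
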