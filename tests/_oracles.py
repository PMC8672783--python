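"""Independent test oracles, kept free of the package's own code paths.

The balanced three-way ANOVA oracle computes every sum of squares
directly from cell means by the classical textbook decomposition
(inclusion-exclusion over factor margins), with no design matrices.
"""

import itertools

import numpy as np


def balanced_three_way_ss(table, trait, factors=("age", "sex", "genotype")):
    """Classical balanced-design SS decomposition from cell means.

    Returns ``(ss: dict term -> SS, df: dict term -> df, ss_resid,
    df_resid)``.  Requires every cell to have the same count n.
    """
    grand = table[trait].mean()
    levels = {f: sorted(table[f].unique()) for f in factors}
    counts = table.groupby(list(factors), observed=True)[trait].count()
    n = counts.iloc[0]
    assert (counts == n).all(), "oracle requires a balanced design"

    def mean_over(subset_factors, subset_levels):
        sel = np.ones(len(table), bool)
        for f, lv in zip(subset_factors, subset_levels):
            sel &= (table[f] == lv).to_numpy()
        return table.loc[sel, trait].mean()

    # deviation terms d_T(cell) defined by inclusion-exclusion
    def deviation(term, cell_levels):
        total = 0.0
        k = len(term)
        for r in range(k + 1):
            for sub in itertools.combinations(range(k), r):
                fs = [term[i] for i in sub]
                lvs = [cell_levels[i] for i in sub]
                m = mean_over(fs, lvs) if fs else grand
                total += (-1) ** (k - r) * m
        return total

    ss, df = {}, {}
    N = len(table)
    for k in range(1, len(factors) + 1):
        for term in itertools.combinations(factors, k):
            name = ":".join(term)
            reps = N // int(np.prod([len(levels[f]) for f in term]))
            s = 0.0
            for cell in itertools.product(*[levels[f] for f in term]):
                s += reps * deviation(term, cell) ** 2
            ss[name] = s
            df[name] = int(np.prod([len(levels[f]) - 1 for f in term]))

    cells = table.groupby(list(factors), observed=True)[trait]
    ss_resid = float(sum(((g - g.mean()) ** 2).sum() for _, g in cells))
    df_resid = N - int(np.prod([len(levels[f]) for f in factors]))
    return ss, df, ss_resid, df_resid
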