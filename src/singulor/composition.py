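"""Donor-level pseudobulk cell-type composition and rank tests.

Each donor contributes one independent composition estimate: the
proportion of its cells assigned to each cell type,

    P(d, c) = N(d, c) / sum_c' N(d, c').

Stage-wise differences per cell type use the Kruskal-Wallis test on donor
proportions, excluding cell types present in fewer than three donors in
any stage; sex differences use two-sided Wilcoxon rank-sum tests.  Rank
tests make both analyses invariant to monotone transforms of the
proportions, so the log transform used for plotting never enters a test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CompositionTable",
    "pseudobulk_proportions",
    "stagewise_test",
    "sex_fraction_test",
    "log_fractions",
]


@dataclass
class CompositionTable:
    proportions: pd.DataFrame  # donors x cell types, rows sum to 1
    donor_meta: pd.DataFrame  # donor, stage, sex (sex optional)


def pseudobulk_proportions(
    cells: pd.DataFrame,
    donor_sex: pd.Series | dict | None = None,
) -> CompositionTable:
    """Per-donor cell-type proportions from a cell annotation table.

    ``cells`` needs donor / stage / cell_type columns; ``donor_sex`` maps
    donor to sex when sex tests are wanted.  Donors with zero cells cannot
    appear in a cell table, so every emitted row sums to one.
    """
    for col in ("donor", "stage", "cell_type"):
        if col not in cells.columns:
            raise ValueError(f"cell annotation lacks {col!r} column")
    counts = pd.crosstab(cells["donor"], cells["cell_type"])
    props = counts.div(counts.sum(axis=1), axis=0)
    stage_of = cells.groupby("donor")["stage"].first()
    meta = pd.DataFrame({"donor": props.index, "stage": stage_of.loc[props.index].to_numpy()})
    if donor_sex is not None:
        sexmap = dict(donor_sex) if not isinstance(donor_sex, pd.Series) else donor_sex.to_dict()
        meta["sex"] = meta["donor"].map(sexmap)
    return CompositionTable(props, meta.reset_index(drop=True))


def _kw_permutation_p(groups: list[np.ndarray], max_enumeration: int = 200_000) -> float:
    """Exact permutation p for the Kruskal-Wallis statistic on small data."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    obs = stats.kruskal(*groups).statistic
    n = len(pooled)
    idx = np.arange(n)

    def stat_for(assignment: np.ndarray) -> float:
        parts, start = [], 0
        for s in sizes:
            parts.append(pooled[assignment[start:start + s]])
            start += s
        return stats.kruskal(*parts).statistic

    # enumerate distinct assignments of indices to ordered groups
    count = 0
    hits = 0
    for perm in itertools.permutations(idx):
        count += 1
        if count > max_enumeration:
            raise ValueError("instance too large for exact enumeration")
        if stat_for(np.array(perm)) >= obs - 1e-12:
            hits += 1
    return hits / count


def stagewise_test(
    table: CompositionTable,
    min_donors: int = 3,
    method: str = "asymptotic",
) -> pd.DataFrame:
    """Kruskal-Wallis across stages on donor proportions, per cell type.

    A cell type enters the comparison only when it is present (P > 0) in at
    least ``min_donors`` donors in every stage; excluded types are reported
    with ``excluded=True``.  ``method="permutation"`` replaces the
    asymptotic chi-square p-value with an exact permutation p-value
    (feasible only for small donor counts).  BH-adjusted values are
    reported in an ``fdr`` column across the tested types.
    """
    if method not in ("asymptotic", "permutation"):
        raise ValueError("method must be 'asymptotic' or 'permutation'")
    props, meta = table.proportions, table.donor_meta
    stages = meta.set_index("donor")["stage"]
    rows = []
    for ct in props.columns:
        vals = props[ct]
        present_per_stage = (
            pd.DataFrame({"stage": stages.loc[vals.index], "present": (vals > 0).to_numpy()})
            .groupby("stage")["present"]
            .sum()
        )
        if (present_per_stage < min_donors).any():
            rows.append((ct, True, np.nan, np.nan))
            continue
        groups = [
            vals[stages.loc[vals.index] == s].to_numpy()
            for s in stages.unique()
        ]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            rows.append((ct, True, np.nan, np.nan))
            continue
        if np.ptp(np.concatenate(groups)) == 0:
            # identical proportions everywhere: no rank information
            rows.append((ct, False, 0.0, 1.0))
            continue
        if method == "asymptotic":
            res = stats.kruskal(*groups)
            rows.append((ct, False, float(res.statistic), float(res.pvalue)))
        else:
            p = _kw_permutation_p(groups)
            rows.append((ct, False, float(stats.kruskal(*groups).statistic), p))
    out = pd.DataFrame(rows, columns=["cell_type", "excluded", "statistic", "p_value"])
    tested = ~out["excluded"] & out["p_value"].notna()
    out["fdr"] = np.nan
    if tested.any():
        from .contingency import bh_adjust

        out.loc[tested, "fdr"] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    return out


def sex_fraction_test(table: CompositionTable) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test of donor fractions, female vs male.

    Exact enumeration is used when there are no ties (scipy's exact
    Mann-Whitney path); ties fall back to the tie-corrected normal
    approximation without continuity correction, so identical groups give
    p = 1.  Types with a single donor per sex are reported but flagged
    ``underpowered``.
    """
    props, meta = table.proportions, table.donor_meta
    if "sex" not in meta.columns:
        raise ValueError("donor metadata lacks a sex column")
    sex = meta.set_index("donor")["sex"]
    rows = []
    for ct in props.columns:
        vals = props[ct]
        f = vals[sex.loc[vals.index] == "female"].to_numpy()
        m = vals[sex.loc[vals.index] == "male"].to_numpy()
        if len(f) == 0 or len(m) == 0:
            rows.append((ct, np.nan, np.nan, True))
            continue
        if np.ptp(np.concatenate([f, m])) == 0:
            rows.append((ct, len(f) * len(m) / 2, 1.0, len(f) == 1 or len(m) == 1))
            continue
        res = stats.mannwhitneyu(
            f, m, alternative="two-sided", method="auto", use_continuity=False
        )
        rows.append((ct, float(res.statistic), float(res.pvalue), len(f) == 1 or len(m) == 1))
    return pd.DataFrame(rows, columns=["cell_type", "statistic", "p_value", "underpowered"])


def log_fractions(table: CompositionTable, offset: float = 1e-4) -> pd.DataFrame:
    """log10(P + offset) for visualization only; zeros stay plottable."""
    if offset <= 0:
        raise ValueError("offset must be positive")
    return np.log10(table.proportions + offset)
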