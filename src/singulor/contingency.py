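"""Contingency analysis of cell identity versus OR-count categories.

The association between cell identity (immediate neuronal precursors vs
immature olfactory sensory neurons) and the number of expressed ORs per
cell (0 / 1 / 2 / 3+) is tested with a Pearson chi-square test without
continuity correction; effect size is Cramér's V with a multinomial
bootstrap percentile interval.  Per-bin post-hoc tests contrast each
category against the pooled remainder (bin-vs-rest 2x2 tables) and are
Benjamini-Hochberg corrected across bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dominance import OR_COUNT_CATEGORIES

__all__ = [
    "ContingencyResult",
    "build_contingency",
    "pearson_chi2",
    "cramers_v",
    "bootstrap_v_ci",
    "bh_adjust",
    "posthoc_per_bin",
    "contingency_analysis",
    "worked_example_table",
]


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: np.ndarray
    chi2: float
    df: int
    p_value: float
    cramers_v: float
    v_ci: tuple[float, float] | None
    per_bin: pd.DataFrame  # bin, p_raw, p_adj, stars


def build_contingency(
    categories: np.ndarray,
    cell_types: np.ndarray,
    types: tuple[str, ...] = ("INP", "iOSN"),
    category_labels: tuple[str, ...] = OR_COUNT_CATEGORIES,
) -> pd.DataFrame:
    """Types x categories table of cell counts; other cell types excluded."""
    categories = np.asarray(categories, dtype=object)
    cell_types = np.asarray(cell_types, dtype=object)
    if categories.shape != cell_types.shape:
        raise ValueError("categories and cell_types length mismatch")
    table = pd.DataFrame(0, index=list(types), columns=list(category_labels), dtype=int)
    for t in types:
        mask = cell_types == t
        if not mask.any():
            raise ValueError(f"requested cell type {t!r} absent from input")
        vals, counts = np.unique(categories[mask], return_counts=True)
        for v, c in zip(vals, counts):
            if v not in table.columns:
                raise ValueError(f"unknown category label {v!r}")
            table.loc[t, v] = int(c)
    return table


def _as_array(observed) -> np.ndarray:
    arr = np.asarray(observed, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if arr.sum() <= 0:
        raise ValueError("contingency table has zero grand total")
    if np.any(arr < 0):
        raise ValueError("negative counts in contingency table")
    return arr


def pearson_chi2(observed, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square with expected counts from the table margins.

    A zero row or column margin leaves expected counts undefined and is
    rejected.  The p-value is from the chi-square survival function; the
    test statistic is one-tailed by construction even when reported for a
    two-sided hypothesis.
    """
    arr = _as_array(observed)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table; expected counts undefined")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=yates)
    return float(chi2), int(df), float(p)


def cramers_v(observed) -> float:
    """V = sqrt(chi2 / (N * min(r-1, c-1)))."""
    arr = _as_array(observed)
    chi2, _, _ = pearson_chi2(arr)
    n = arr.sum()
    k = min(arr.shape[0] - 1, arr.shape[1] - 1)
    return float(np.sqrt(chi2 / (n * k)))


def bootstrap_v_ci(
    observed,
    b: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile interval of Cramér's V over multinomial table resamples.

    Cell counts are resampled at fixed grand total from the observed cell
    probabilities.  Resamples with a zero row or column margin (possible
    for sparse tables) are discarded.  The published interval for the
    worked example has no stated method; this bootstrap is the package's
    declared, reproducible construction.
    """
    if b < 100:
        raise ValueError("need at least 100 resamples")
    arr = _as_array(observed)
    n = int(arr.sum())
    probs = (arr / arr.sum()).ravel()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs, size=b)
    vs = []
    for flat in draws:
        t = flat.reshape(arr.shape)
        if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
            continue
        vs.append(cramers_v(t))
    if not vs:
        raise ValueError("all bootstrap resamples degenerate")
    alpha = 1 - level
    lo, hi = np.percentile(vs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _stars(padj: float) -> str:
    if padj < 0.001:
        return "***"
    if padj < 0.01:
        return "**"
    if padj < 0.05:
        return "*"
    return "ns"


def posthoc_per_bin(observed) -> pd.DataFrame:
    """Bin-vs-rest 2x2 chi-square tests with BH correction across bins.

    For each column j of a 2-row table, the 2x2 table contrasts column j
    with the pooled remaining columns.  Degenerate 2x2 margins record p = 1
    with a warning rather than failing the whole analysis.
    """
    if isinstance(observed, pd.DataFrame):
        labels = list(observed.columns)
        arr = _as_array(observed.to_numpy())
    else:
        arr = _as_array(observed)
        labels = [str(j) for j in range(arr.shape[1])]
    if arr.shape[0] != 2:
        raise ValueError("post-hoc per-bin tests require exactly 2 rows")
    raw = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        rest = arr.sum(axis=1) - col
        t = np.column_stack([col, rest])
        try:
            _, _, p = pearson_chi2(t)
        except ValueError:
            warnings.warn(f"degenerate margins for bin {labels[j]!r}; p set to 1", stacklevel=2)
            p = 1.0
        raw.append(p)
    adj = bh_adjust(raw)
    return pd.DataFrame(
        {
            "bin": labels,
            "p_raw": raw,
            "p_adj": adj,
            "stars": [_stars(q) for q in adj],
        }
    )


def contingency_analysis(
    observed,
    bootstrap: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> ContingencyResult:
    """Full analysis of a 2 x c table: chi-square, V (+CI), per-bin post-hoc."""
    if isinstance(observed, pd.DataFrame):
        table = observed
    else:
        arr = _as_array(observed)
        table = pd.DataFrame(arr.astype(int))
    arr = _as_array(table.to_numpy())
    chi2, df, p = pearson_chi2(arr)
    expected = stats.contingency.expected_freq(arr)
    v = cramers_v(arr)
    ci = bootstrap_v_ci(arr, b=bootstrap, level=level, seed=seed) if bootstrap else None
    per_bin = posthoc_per_bin(table)
    return ContingencyResult(table, expected, chi2, df, p, v, ci, per_bin)


def worked_example_table() -> pd.DataFrame:
    """The bundled worked-example table: OR-count categories in INP and iOSN
    of a first-trimester human fetal olfactory epithelium cohort."""
    ref = resources.files("singulor.data").joinpath("or_category_counts_example.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [str(c) for c in df.columns]
    return df
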