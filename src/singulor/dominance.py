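"""Per-cell olfactory-receptor dominance statistics.

For each cell, restricted to OR genes, let x1 and x2 be the transcript
counts of the most and second-most expressed OR.  The dominance score

    D = ((x1 - x2) / (x1 + x2 + eps)) * log(1 + x1)

contrasts relative difference with absolute magnitude of the top OR
(natural log; eps = 1e-9 for numerical stability).  Cells without
detectable OR expression score zero.  High-dominance cells satisfy
D > 1, x1 >= 1 and at most 3 co-expressed ORs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "DOMINANCE_BIN_LABELS",
    "OR_COUNT_CATEGORIES",
    "per_cell_or_stats",
    "dominance_score",
    "bin_dominance",
    "classify_high_dominance",
    "or_count_category",
    "summarize_or_cells",
    "dominant_or_frequency",
    "diagonal_order",
    "chromosome_profile",
]

DOMINANCE_BIN_LABELS = ("≤0.5", "0.5–1", "1–1.5", "1.5–2", ">2")
_BIN_EDGES = (0.5, 1.0, 1.5, 2.0)
OR_COUNT_CATEGORIES = ("0", "1", "2", "3+")

DEFAULT_EPSILON = 1e-9


def per_cell_or_stats(
    counts: np.ndarray, gene_ids: np.ndarray
) -> tuple[int, int, int, str | None]:
    """(x1, x2, n_expressed, dominant_or) for one cell's OR count vector.

    Ties at the top are broken lexicographically by gene_id so frequency
    tables get a deterministic label; x2 is 0 when fewer than two ORs are
    expressed.
    """
    counts = np.asarray(counts).ravel()
    if counts.shape != np.asarray(gene_ids).shape:
        raise ValueError("counts and gene_ids length mismatch")
    expressed = counts > 0
    n_expressed = int(expressed.sum())
    if n_expressed == 0:
        return 0, 0, 0, None
    order = np.argsort(counts, kind="stable")  # stable => ties keep input order
    top = order[-1]
    x1 = int(counts[top])
    # lexicographic tie-break among all argmax genes
    tied = np.flatnonzero(counts == x1)
    dominant = min(gene_ids[tied])
    x2 = int(counts[order[-2]]) if len(counts) > 1 else 0
    return x1, x2, n_expressed, dominant


def dominance_score(x1: float, x2: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """Scaled dominance score; zero when no OR is detected (x1 = 0)."""
    if x2 > x1:
        raise ValueError("x2 must not exceed x1")
    if x2 < 0:
        raise ValueError("counts must be non-negative")
    if x1 == 0:
        return 0.0
    return ((x1 - x2) / (x1 + x2 + epsilon)) * np.log1p(x1)


def bin_dominance(d: float) -> str:
    """Fixed-threshold bins ≤0.5 / 0.5–1 / 1–1.5 / 1.5–2 / >2.

    Intervals above the first are left-open right-closed, so a boundary
    value belongs to the lower-labelled bin (D = 1.0 -> "0.5–1").
    """
    if d < 0:
        raise ValueError("dominance score must be non-negative")
    for edge, label in zip(_BIN_EDGES, DOMINANCE_BIN_LABELS):
        if d <= edge:
            return label
    return DOMINANCE_BIN_LABELS[-1]


def classify_high_dominance(
    d: float, x1: float, n_expressed: int, d_min: float = 1.0, x_min: float = 1.0, max_co: int = 3
) -> bool:
    """D > d_min AND x1 >= x_min AND n_expressed <= max_co (defaults 1/1/3)."""
    return bool(d > d_min and x1 >= x_min and n_expressed <= max_co)


def or_count_category(n_expressed: int) -> str:
    """Pool expressed-OR counts into the categories 0 / 1 / 2 / 3+."""
    if n_expressed < 0:
        raise ValueError("n_expressed must be non-negative")
    return str(n_expressed) if n_expressed < 3 else "3+"


def summarize_or_cells(
    or_cm: CountMatrix,
    epsilon: float = DEFAULT_EPSILON,
    d_min: float = 1.0,
    x_min: float = 1.0,
    max_co: int = 3,
) -> pd.DataFrame:
    """Full per-cell summary over an OR-only count matrix.

    Columns: cell_id, x1, x2, n_expressed_ors, dominant_or, dominance_score,
    dominance_bin, is_high_dominance, or_count_category.
    """
    csr = or_cm.counts.tocsr()
    gene_ids = or_cm.gene_ids
    rows = []
    for i in range(or_cm.n_cells):
        start, stop = csr.indptr[i], csr.indptr[i + 1]
        data = csr.data[start:stop]
        idx = csr.indices[start:stop]
        if len(data) == 0:
            x1 = x2 = n = 0
            dom = None
        else:
            x1, x2, n, dom = per_cell_or_stats(data, gene_ids[idx])
            if len(data) == 1:
                x2 = 0
        d = dominance_score(x1, x2, epsilon)
        rows.append(
            (
                or_cm.cell_ids[i],
                x1,
                x2,
                n,
                dom,
                d,
                bin_dominance(d),
                classify_high_dominance(d, x1, n, d_min, x_min, max_co),
                or_count_category(n),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "x1",
            "x2",
            "n_expressed_ors",
            "dominant_or",
            "dominance_score",
            "dominance_bin",
            "is_high_dominance",
            "or_count_category",
        ],
    )


def dominant_or_frequency(
    summary: pd.DataFrame,
    top_k: int = 20,
    group_by: str | None = None,
) -> pd.DataFrame:
    """Counts of high-dominance cells per dominant OR, descending.

    ``group_by`` names a column of ``summary`` (e.g. a merged stage label)
    to stratify by; ties in count are ordered lexicographically by gene.
    """
    hd = summary[summary["is_high_dominance"]]
    if hd.empty:
        cols = ["or_gene", "n_high_dominance_cells"]
        if group_by:
            cols.insert(0, group_by)
        return pd.DataFrame(columns=cols)
    keys = [group_by, "dominant_or"] if group_by else ["dominant_or"]
    counts = hd.groupby(keys, sort=True).size().rename("n_high_dominance_cells").reset_index()
    counts = counts.rename(columns={"dominant_or": "or_gene"})
    sort_keys = ([group_by] if group_by else []) + ["n_high_dominance_cells", "or_gene"]
    counts = counts.sort_values(
        sort_keys, ascending=([True] if group_by else []) + [False, True]
    ).reset_index(drop=True)
    if group_by:
        counts = counts.groupby(group_by, sort=True).head(top_k).reset_index(drop=True)
    else:
        counts = counts.head(top_k)
    return counts


def diagonal_order(
    or_cm: CountMatrix, summary: pd.DataFrame | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cell and OR orderings that expose the one-cell/one-receptor diagonal.

    Cells are sorted by (dominant-OR rank, descending top count); ORs are
    ordered by first appearance as a dominant gene.  OR-negative cells keep
    their input order at the end; ORs never dominant follow in input order.
    Returns (cell index order, OR column index order).
    """
    if summary is None:
        summary = summarize_or_cells(or_cm)
    dom = summary["dominant_or"].to_numpy(object)
    x1 = summary["x1"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(or_cm.gene_ids)}

    # OR order: first appearance among cells scanned in input order
    or_order: list[int] = []
    seen = set()
    for g in dom:
        if g is not None and g not in seen:
            seen.add(g)
            or_order.append(gene_pos[g])
    used = set(or_order)
    or_order.extend(i for i in range(len(or_cm.gene_ids)) if i not in used)
    or_rank = {or_cm.gene_ids[i]: r for r, i in enumerate(or_order)}

    positive = [i for i in range(len(dom)) if dom[i] is not None]
    negative = [i for i in range(len(dom)) if dom[i] is None]
    positive.sort(key=lambda i: (or_rank[dom[i]], -x1[i]))
    return np.array(positive + negative, dtype=int), np.array(or_order, dtype=int)


def chromosome_profile(or_cm: CountMatrix, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome OR gene counts and summed expression.

    Genes lacking a chromosome label are bucketed under "unknown"; totals
    over chromosomes conserve the matrix total.
    """
    genes = genes.set_index("gene_id").loc[list(or_cm.gene_ids)]
    chroms = genes["chromosome"].fillna("unknown").replace("", "unknown").to_numpy(object)
    sums = np.asarray(or_cm.counts.sum(axis=0)).ravel()
    df = pd.DataFrame({"chromosome": chroms, "expression": sums})
    out = (
        df.groupby("chromosome", sort=True)
        .agg(n_or_genes=("expression", "size"), summed_expression=("expression", "sum"))
        .reset_index()
    )
    return out
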