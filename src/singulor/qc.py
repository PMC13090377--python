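"""Cell filtering and maternal-contamination detection.

Basic filters remove nuclei with low library complexity (<500 detected
genes or <500 UMIs by default), high mitochondrial content (>5%), or
outlying complexity/mito metrics (>5 median absolute deviations).

Maternal blood contamination is detected with a two-signal rule: a cell is
flagged only when its sex call (log2 XIST / summed Y-linked expression)
disagrees with the majority-voted sex of its sample AND its erythroid
score (summed hemoglobin expression) strictly exceeds the global 95th
percentile.  Both signals are computed on log-normalized values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, NormalizedMatrix

__all__ = [
    "FilterReport",
    "SexQCResult",
    "basic_cell_filters",
    "sex_score",
    "classify_sex",
    "erythroid_score",
    "flag_erythroid_high",
    "infer_sample_sex",
    "sex_qc",
    "flag_contaminated",
]


@dataclass
class FilterReport:
    per_cell: pd.DataFrame  # cell_id, n_genes, n_umis, pct_mito, *_flag, kept
    removed_per_rule: dict[str, int]

    @property
    def kept(self) -> np.ndarray:
        return self.per_cell["kept"].to_numpy()


@dataclass
class SexQCResult:
    per_cell: pd.DataFrame  # cell_id, sample, sex_score, sex_call, erythroid_score,
    #                         erythroid_high, contaminated
    per_sample: pd.DataFrame  # sample, inferred_sex, n_cells, removal_fraction


def _mad_outliers(x: np.ndarray, k: float) -> np.ndarray:
    """|x - median| > k * MAD; a zero MAD flags nothing."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros(len(x), dtype=bool)
    return np.abs(x - med) > k * mad


def basic_cell_filters(
    cm: CountMatrix,
    genes: pd.DataFrame,
    min_genes: int = 500,
    min_umis: int = 500,
    max_mito_pct: float = 5.0,
    mad_k: float = 5.0,
) -> FilterReport:
    """Per-cell quality filters; a cell is kept iff no rule fires.

    Threshold rules are strict as printed: exactly ``min_genes`` detected
    genes or exactly ``max_mito_pct`` percent mitochondrial reads pass.
    The MAD rule is applied to log10 library complexity (genes and UMIs)
    and to the mitochondrial percentage.
    """
    n_umis = cm.cell_totals()
    n_genes = np.asarray((cm.counts > 0).sum(axis=1)).ravel()
    mito_mask = (genes["marker_role"] == "mitochondrial").to_numpy()
    has_mito = bool(mito_mask.any())
    if has_mito:
        mito_counts = np.asarray(cm.counts[:, np.flatnonzero(mito_mask)].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            pct_mito = np.where(n_umis > 0, 100.0 * mito_counts / np.maximum(n_umis, 1), 0.0)
    else:
        warnings.warn("no mitochondrial genes annotated; mito filters skipped", stacklevel=2)
        pct_mito = np.zeros(cm.n_cells)

    low_genes = n_genes < min_genes
    low_umis = n_umis < min_umis
    high_mito = (pct_mito > max_mito_pct) if has_mito else np.zeros(cm.n_cells, dtype=bool)

    with np.errstate(divide="ignore"):
        log_umis = np.log10(np.maximum(n_umis, 1))
        log_genes = np.log10(np.maximum(n_genes, 1))
    mad_flag = _mad_outliers(log_umis, mad_k) | _mad_outliers(log_genes, mad_k)
    if has_mito:
        mad_flag |= _mad_outliers(pct_mito, mad_k)

    kept = ~(low_genes | low_umis | high_mito | mad_flag)
    per_cell = pd.DataFrame(
        {
            "cell_id": cm.cell_ids,
            "n_genes": n_genes,
            "n_umis": n_umis,
            "pct_mito": pct_mito,
            "low_genes": low_genes,
            "low_umis": low_umis,
            "high_mito": high_mito,
            "mad_flag": mad_flag,
            "kept": kept,
        }
    )
    removed = {
        "low_genes": int(low_genes.sum()),
        "low_umis": int(low_umis.sum()),
        "high_mito": int(high_mito.sum()),
        "mad_flag": int(mad_flag.sum()),
        "total_removed": int((~kept).sum()),
    }
    return FilterReport(per_cell, removed)


def sex_score(
    norm: NormalizedMatrix, genes: pd.DataFrame, pseudocount: float = 1.0
) -> np.ndarray:
    """Per-cell S = log2((XIST + c) / (sum of Y-panel expression + c)).

    The pseudocount keeps the ratio finite when either side is zero; it is
    applied on log-normalized values.
    """
    xist_mask = (genes["marker_role"] == "xist").to_numpy()
    y_mask = (genes["marker_role"] == "y_linked").to_numpy()
    if not xist_mask.any():
        raise ValueError("no XIST gene annotated (marker_role='xist')")
    if not y_mask.any():
        raise ValueError("no Y-linked genes annotated (marker_role='y_linked')")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = np.asarray(norm.values[:, np.flatnonzero(xist_mask)].sum(axis=1)).ravel()
    y = np.asarray(norm.values[:, np.flatnonzero(y_mask)].sum(axis=1)).ravel()
    return np.log2((x + pseudocount) / (y + pseudocount))


def classify_sex(
    scores: np.ndarray, t_female: float = 1.0, t_male: float = -1.0
) -> np.ndarray:
    """female_like if S >= t_female, male_like if S <= t_male, else ambiguous."""
    if t_female <= t_male:
        raise ValueError("t_female must exceed t_male")
    scores = np.asarray(scores, dtype=float)
    out = np.full(scores.shape, "ambiguous", dtype=object)
    out[scores >= t_female] = "female_like"
    out[scores <= t_male] = "male_like"
    return out


def erythroid_score(norm: NormalizedMatrix, genes: pd.DataFrame) -> np.ndarray:
    """Summed log-normalized expression over the hemoglobin panel."""
    hb_mask = (genes["marker_role"] == "hemoglobin").to_numpy()
    if not hb_mask.any():
        raise ValueError("no hemoglobin genes annotated (marker_role='hemoglobin')")
    return np.asarray(norm.values[:, np.flatnonzero(hb_mask)].sum(axis=1)).ravel()


def flag_erythroid_high(scores: np.ndarray, percentile: float = 95.0) -> np.ndarray:
    """Flag cells whose score strictly exceeds the global percentile.

    The percentile uses linear interpolation; on a constant vector nothing
    strictly exceeds it, so nothing is flagged.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    cutoff = np.percentile(scores, percentile)
    return scores > cutoff


def infer_sample_sex(sex_calls: np.ndarray) -> str:
    """Strict majority vote (>50% of all cells, ambiguous in denominator)."""
    calls = np.asarray(sex_calls, dtype=object)
    if calls.size == 0:
        raise ValueError("no cells in sample")
    n = calls.size
    for call, label in (("female_like", "female"), ("male_like", "male")):
        if (calls == call).sum() > n / 2:
            return label
    return "undetermined"


def sex_qc(
    norm: NormalizedMatrix,
    genes: pd.DataFrame,
    cells: pd.DataFrame,
    sample_col: str = "donor",
    pseudocount: float = 1.0,
    t_female: float = 1.0,
    t_male: float = -1.0,
    percentile: float = 95.0,
) -> SexQCResult:
    """Compute per-cell sex/erythroid scores and per-sample inferred sex."""
    S = sex_score(norm, genes, pseudocount)
    calls = classify_sex(S, t_female, t_male)
    E = erythroid_score(norm, genes)
    ehigh = flag_erythroid_high(E, percentile)
    samples = cells[sample_col].to_numpy(object)
    per_cell = pd.DataFrame(
        {
            "cell_id": norm.cell_ids,
            "sample": samples,
            "sex_score": S,
            "sex_call": calls,
            "erythroid_score": E,
            "erythroid_high": ehigh,
            "contaminated": False,
        }
    )
    sample_rows = []
    for s, grp in per_cell.groupby("sample", sort=True):
        sample_rows.append((s, infer_sample_sex(grp["sex_call"].to_numpy()), len(grp), 0.0))
    per_sample = pd.DataFrame(
        sample_rows, columns=["sample", "inferred_sex", "n_cells", "removal_fraction"]
    )
    return SexQCResult(per_cell, per_sample)


_DISCORDANT = {"female": "male_like", "male": "female_like"}


def flag_contaminated(result: SexQCResult, drop_ambiguous: bool = False) -> SexQCResult:
    """Apply the conjunction rule: discordant sex call AND erythroid-high.

    Ambiguous cells are never discordant; with ``drop_ambiguous`` they are
    additionally marked for removal (``dropped_ambiguous`` column).  For a
    sample with undetermined inferred sex no discordance is computable and
    nothing is flagged (with a warning).
    """
    per_cell = result.per_cell.copy()
    per_sample = result.per_sample.copy()
    sex_of = dict(zip(per_sample["sample"], per_sample["inferred_sex"]))
    contaminated = np.zeros(len(per_cell), dtype=bool)
    for s, inferred in sex_of.items():
        mask = (per_cell["sample"] == s).to_numpy()
        if inferred == "undetermined":
            warnings.warn(
                f"sample {s!r}: inferred sex undetermined, no contamination flags",
                stacklevel=2,
            )
            continue
        discordant = (per_cell["sex_call"] == _DISCORDANT[inferred]).to_numpy()
        contaminated |= mask & discordant & per_cell["erythroid_high"].to_numpy()
    per_cell["contaminated"] = contaminated
    if drop_ambiguous:
        per_cell["dropped_ambiguous"] = (per_cell["sex_call"] == "ambiguous").to_numpy()
    frac = (
        per_cell.groupby("sample", sort=True)["contaminated"].mean().rename("removal_fraction")
    )
    per_sample = per_sample.drop(columns=["removal_fraction"]).merge(
        frac.reset_index(), on="sample", how="left"
    )
    per_sample["removal_fraction"] = per_sample["removal_fraction"].fillna(0.0)
    return SexQCResult(per_cell, per_sample)
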