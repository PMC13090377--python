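"""Synthetic cohorts with recorded ground truth.

The generator emulates the statistical structure the downstream analyses
assume, not a full transcriptome:

* immature olfactory sensory neurons (iOSN) choose a single OR gene with a
  stage-dependent monogenic probability and express it strongly, with a
  minority co-expressing a weaker second receptor;
* immediate neuronal precursors (INP) are mostly OR-negative;
* every cell receives a small amount of stray ("background") OR signal;
* sex-marker genes (XIST vs a Y-linked panel) follow the donor's sex;
* hemoglobin genes are near zero except in planted maternal-blood
  contamination, which also flips the sex signature;
* a 1-D respiratory-to-olfactory spatial strip places cell types along an
  axis with stated density profiles.

All "expressed" draws use zero-truncated Poisson counts so planted
structure is detectable at any depth.  A single random stream drawn from
the config seed is consumed in documented order (gene panel, then cells in
row order, then contamination), so a fixed seed gives bit-identical
cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, validate_cell_annotation, validate_gene_annotation

__all__ = [
    "SimulationConfig",
    "SpatialStripConfig",
    "GroundTruth",
    "simulate_cohort",
    "plant_contamination",
    "simulate_spatial_strip",
    "expected_single_or_fraction",
]

HEMOGLOBIN_GENES = ("HBB", "HBA1", "HBA2", "HBE1", "HBG1", "HBG2", "HBM")
Y_PANEL_GENES = ("UTY", "RPS4Y1", "ZFY", "DDX3Y", "KDM5D")

_DEFAULT_CELLS_PER_STAGE = {
    "iOSN": 150,
    "INP": 120,
    "GBC": 80,
    "SUS": 60,
    "MV": 40,
    "OHBC": 30,
    "RHBC": 50,
}
# 5 female / 3 male donors, as in the profiled fetal cohort
_DEFAULT_DONOR_SEXES = ("female", "male", "female", "male", "female", "male", "female", "female")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the cohort generator.

    Defaults are stand-ins chosen to reproduce the qualitative structure of
    a first-trimester olfactory-epithelium cohort (monogenic iOSN, sparse
    INP expression, a rising dominance ramp across stages); no generative
    parameters are published for the real data.
    """

    seed: int = 0
    stages: tuple[str, ...] = ("PCW7", "PCW8", "PCW10", "PCW12")
    cells_per_stage: Mapping[str, Mapping[str, int]] | None = None
    donors_per_stage: int = 2
    donor_sexes: tuple[str, ...] = _DEFAULT_DONOR_SEXES
    n_or_genes: int = 169
    n_background_genes: int = 800
    n_mito_genes: int = 13
    #: per-stage probability that an iOSN commits to a single OR; a scalar
    #: applies to every stage, None gives a linear ramp 0.2 -> 0.9
    monogenic_fraction: Mapping[str, float] | float | None = None
    co_expression_rate: float = 0.1
    background_or_rate: float = 0.02
    dominant_mean: float = 5.0
    secondary_ratio: float = 4.0
    inp_or_positive_rate: float = 0.33
    inp_dominant_mean: float = 2.0
    mean_depth: float = 1500.0
    depth_sigma: float = 0.3
    mito_fraction: float = 0.015
    xist_mean: float = 5.0
    y_total_mean: float = 5.0
    sex_leak_mean: float = 0.05
    hb_background_rate: float = 0.02
    contamination_fraction: float = 0.0
    contamination_hb_mean: float = 20.0

    def stage_cells(self) -> dict[str, dict[str, int]]:
        if self.cells_per_stage is not None:
            return {s: dict(self.cells_per_stage[s]) for s in self.stages}
        return {s: dict(_DEFAULT_CELLS_PER_STAGE) for s in self.stages}

    def monogenic_by_stage(self) -> dict[str, float]:
        if isinstance(self.monogenic_fraction, Mapping):
            return {s: float(self.monogenic_fraction[s]) for s in self.stages}
        if self.monogenic_fraction is not None:
            return {s: float(self.monogenic_fraction) for s in self.stages}
        n = len(self.stages)
        if n == 1:
            return {self.stages[0]: 0.9}
        return {
            s: 0.2 + (0.9 - 0.2) * i / (n - 1) for i, s in enumerate(self.stages)
        }

    def validate(self) -> None:
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")
        total = sum(sum(v.values()) for v in self.stage_cells().values())
        if total <= 0:
            raise ValueError("configuration requests zero cells")
        for name in ("co_expression_rate", "inp_or_positive_rate", "contamination_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for s, pi in self.monogenic_by_stage().items():
            if not 0.0 <= pi <= 1.0:
                raise ValueError(f"monogenic_fraction[{s}] must be in [0, 1], got {pi}")
        for name in ("background_or_rate", "hb_background_rate", "sex_leak_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dominant_mean", "secondary_ratio", "mean_depth", "contamination_hb_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_or_genes < 2:
            raise ValueError("need at least 2 OR genes")
        if self.donors_per_stage < 1:
            raise ValueError("donors_per_stage must be >= 1")


@dataclass
class GroundTruth:
    """Generative truth emitted alongside a simulated cohort."""

    per_cell: pd.DataFrame  # cell_id, chosen_or, contaminated, true_sex
    expected_single_or_fraction: float
    realized_single_or_fraction: float

    def write(self, path) -> None:
        self.per_cell.to_csv(path, sep="\t", index=False)


def _zt_poisson(rng: np.random.Generator, mu: float) -> int:
    """Zero-truncated Poisson draw (rejection; mu > 0)."""
    for _ in range(10_000):
        k = rng.poisson(mu)
        if k > 0:
            return int(k)
    return 1


def _build_gene_panel(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    # OR loci cluster on a handful of chromosomes; class I receptors sit on chr11
    or_chroms = np.array(["chr1", "chr7", "chr11", "chr12", "chr19", "chr6", "chr14", "chr17"])
    or_weights = np.array([0.18, 0.12, 0.25, 0.10, 0.15, 0.07, 0.07, 0.06])
    chroms = rng.choice(or_chroms, size=cfg.n_or_genes, p=or_weights)
    for i in range(cfg.n_or_genes):
        on_chr11 = chroms[i] == "chr11"
        cls = "I" if (on_chr11 and rng.random() < 0.5) else "II"
        rows.append((f"OR{i + 1:04d}", f"OR{i + 1:04d}", True, cls, chroms[i], "none"))
    rows.append(("XIST", "XIST", False, "none", "chrX", "xist"))
    for g in Y_PANEL_GENES:
        rows.append((g, g, False, "none", "chrY", "y_linked"))
    for g in HEMOGLOBIN_GENES:
        rows.append((g, g, False, "none", "chr11" if g == "HBB" else "chr16", "hemoglobin"))
    for i in range(cfg.n_mito_genes):
        rows.append((f"MT-G{i + 1}", f"MT-G{i + 1}", False, "none", "chrM", "mitochondrial"))
    bg_chroms = rng.choice([f"chr{c}" for c in range(1, 23)], size=cfg.n_background_genes)
    for i in range(cfg.n_background_genes):
        rows.append((f"BG{i + 1:05d}", f"BG{i + 1:05d}", False, "none", bg_chroms[i], "none"))
    return pd.DataFrame(
        rows, columns=["gene_id", "symbol", "is_or", "or_class", "chromosome", "marker_role"]
    )


def _draw_or_counts(
    rng: np.random.Generator,
    n_or: int,
    choose_prob: float,
    dominant_mean: float,
    co_rate: float,
    secondary_mean: float,
    background_rate: float,
) -> tuple[dict[int, int], int | None]:
    """OR counts for one cell; returns {or_index: count} and the chosen OR."""
    counts: dict[int, int] = {}
    chosen = None
    if choose_prob > 0 and rng.random() < choose_prob:
        chosen = int(rng.integers(n_or))
        counts[chosen] = _zt_poisson(rng, dominant_mean)
        if co_rate > 0 and rng.random() < co_rate:
            second = int(rng.integers(n_or - 1))
            if second >= chosen:
                second += 1
            counts[second] = counts.get(second, 0) + _zt_poisson(rng, secondary_mean)
    if background_rate > 0:
        n_bg = rng.poisson(background_rate)
        for g in rng.integers(n_or, size=n_bg):
            counts[int(g)] = counts.get(int(g), 0) + 1
    return counts, chosen


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a cohort triple plus ground truth, deterministic under seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _build_gene_panel(config, rng)
    gene_ids = genes["gene_id"].to_numpy(object)
    idx_of = {g: i for i, g in enumerate(gene_ids)}
    or_offset = 0  # OR genes occupy the first n_or_genes columns
    xist_idx = idx_of["XIST"]
    y_idx = np.array([idx_of[g] for g in Y_PANEL_GENES])
    hb_idx = np.array([idx_of[g] for g in HEMOGLOBIN_GENES])
    mito_idx = np.array([idx_of[f"MT-G{i + 1}"] for i in range(config.n_mito_genes)])
    bg_idx = np.array([idx_of[f"BG{i + 1:05d}"] for i in range(config.n_background_genes)])

    # fixed relative abundances for the housekeeping panel
    bg_weights = rng.dirichlet(np.full(config.n_background_genes, 2.0))

    pis = config.monogenic_by_stage()
    secondary_mean = config.dominant_mean / config.secondary_ratio

    rows, cols, vals = [], [], []
    cell_rows = []
    truth_rows = []
    donor_counter = 0
    cell_counter = 0
    n_sex = len(config.donor_sexes)
    for stage in config.stages:
        stage_donors = []
        for _ in range(config.donors_per_stage):
            donor_counter += 1
            stage_donors.append(
                (f"D{donor_counter:02d}", config.donor_sexes[(donor_counter - 1) % n_sex])
            )
        for cell_type, n_cells in config.stage_cells()[stage].items():
            for j in range(n_cells):
                donor, sex = stage_donors[j % len(stage_donors)]
                cell_counter += 1
                cid = f"C{cell_counter:06d}"
                r = len(cell_rows)
                cell_rows.append((cid, donor, stage, cell_type, "snrna"))

                gcounts: dict[int, int] = {}
                # 1. housekeeping depth, spread over background genes
                depth = rng.poisson(
                    rng.lognormal(math.log(config.mean_depth), config.depth_sigma)
                )
                if depth > 0:
                    n_mito = rng.binomial(depth, config.mito_fraction)
                    mito_counts = rng.multinomial(
                        n_mito, np.full(config.n_mito_genes, 1 / config.n_mito_genes)
                    )
                    for k, c in zip(mito_idx, mito_counts):
                        if c:
                            gcounts[k] = gcounts.get(k, 0) + int(c)
                    bg_counts = rng.multinomial(depth - n_mito, bg_weights)
                    nz = np.flatnonzero(bg_counts)
                    for k in nz:
                        gcounts[bg_idx[k]] = gcounts.get(bg_idx[k], 0) + int(bg_counts[k])
                # 2. sex signature
                if sex == "female":
                    x = rng.poisson(config.xist_mean)
                    y_tot = rng.poisson(config.sex_leak_mean)
                else:
                    x = rng.poisson(config.sex_leak_mean)
                    y_tot = rng.poisson(config.y_total_mean)
                if x:
                    gcounts[xist_idx] = gcounts.get(xist_idx, 0) + int(x)
                if y_tot:
                    spread = rng.multinomial(y_tot, np.full(len(y_idx), 1 / len(y_idx)))
                    for k, c in zip(y_idx, spread):
                        if c:
                            gcounts[k] = gcounts.get(k, 0) + int(c)
                # 3. ambient hemoglobin
                hb_tot = rng.poisson(config.hb_background_rate)
                if hb_tot:
                    spread = rng.multinomial(hb_tot, np.full(len(hb_idx), 1 / len(hb_idx)))
                    for k, c in zip(hb_idx, spread):
                        if c:
                            gcounts[k] = gcounts.get(k, 0) + int(c)
                # 4. OR program
                if cell_type == "iOSN":
                    choose_p, dom_mean = pis[stage], config.dominant_mean
                elif cell_type == "INP":
                    choose_p, dom_mean = config.inp_or_positive_rate, config.inp_dominant_mean
                else:
                    choose_p, dom_mean = 0.0, config.dominant_mean
                or_counts, chosen = _draw_or_counts(
                    rng,
                    config.n_or_genes,
                    choose_p,
                    dom_mean,
                    config.co_expression_rate,
                    secondary_mean,
                    config.background_or_rate,
                )
                for k, c in or_counts.items():
                    gk = or_offset + k
                    gcounts[gk] = gcounts.get(gk, 0) + c

                for k, c in gcounts.items():
                    rows.append(r)
                    cols.append(k)
                    vals.append(c)
                truth_rows.append(
                    (cid, gene_ids[chosen] if chosen is not None else "", False, sex)
                )

    cells = pd.DataFrame(cell_rows, columns=["cell_id", "donor", "stage", "cell_type", "modality"])
    n_total = len(cells)
    counts = sp.coo_matrix(
        (vals, (rows, cols)), shape=(n_total, len(gene_ids)), dtype=np.int64
    ).tocsr()
    cm = CountMatrix(cells["cell_id"].to_numpy(object), gene_ids, counts)
    truth = pd.DataFrame(truth_rows, columns=["cell_id", "chosen_or", "contaminated", "true_sex"])

    if config.contamination_fraction > 0:
        cm, flags = plant_contamination(
            cm,
            cells,
            genes,
            config.contamination_fraction,
            rng,
            hb_mean=config.contamination_hb_mean,
        )
        truth["contaminated"] = flags

    # realized single-OR fraction among OR-positive iOSN
    or_block = cm.counts[:, :config.n_or_genes]
    n_expressed = np.asarray((or_block > 0).sum(axis=1)).ravel()
    is_iosn = (cells["cell_type"] == "iOSN").to_numpy()
    pos = is_iosn & (n_expressed > 0)
    realized = float((n_expressed[pos] == 1).mean()) if pos.any() else float("nan")
    expected = expected_single_or_fraction(config)
    gt = GroundTruth(truth, expected, realized)
    return cm, validate_gene_annotation(genes), validate_cell_annotation(cells), gt


def plant_contamination(
    cm: CountMatrix,
    cells: pd.DataFrame,
    genes: pd.DataFrame,
    fraction: float,
    rng: np.random.Generator,
    hb_mean: float = 20.0,
) -> tuple[CountMatrix, np.ndarray]:
    """Overlay a maternal-blood signature on a random subset of cells.

    Selected cells gain zero-truncated Poisson hemoglobin counts and a
    flipped sex signature: the XIST count and the Y-panel total are
    exchanged (the old XIST count lands on the first Y-panel gene).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = cm.n_cells
    n_pick = int(round(fraction * n))
    flags = np.zeros(n, dtype=bool)
    if n_pick == 0:
        return cm, flags
    picked = rng.choice(n, size=n_pick, replace=False)
    flags[picked] = True

    gene_ids = list(cm.gene_ids)
    xist_idx = gene_ids.index("XIST")
    y_idx = [gene_ids.index(g) for g in Y_PANEL_GENES if g in gene_ids]
    hb_idx = [gene_ids.index(g) for g in HEMOGLOBIN_GENES if g in gene_ids]
    if not hb_idx:
        raise ValueError("no hemoglobin genes in panel")

    mat = cm.counts.tolil(copy=True)
    for r in sorted(picked):
        hb_tot = _zt_poisson(rng, hb_mean)
        spread = rng.multinomial(hb_tot, np.full(len(hb_idx), 1 / len(hb_idx)))
        for k, c in zip(hb_idx, spread):
            if c:
                mat[r, k] = mat[r, k] + int(c)
        old_x = int(mat[r, xist_idx])
        old_y = int(sum(mat[r, k] for k in y_idx))
        mat[r, xist_idx] = old_y
        for k in y_idx:
            mat[r, k] = 0
        if old_x:
            mat[r, y_idx[0]] = old_x
    out = CountMatrix(cm.cell_ids, cm.gene_ids, mat.tocsr())
    return out, flags


def expected_single_or_fraction(config: SimulationConfig) -> float:
    """Closed-form P(exactly one expressed OR | OR-positive) for iOSN.

    Background OR transcripts have total count Poisson(lambda_bg) with each
    transcript assigned to a uniformly random OR gene, which is equivalent
    to independent per-gene Poisson(lambda_bg / n) counts; the formula uses
    that thinning identity.  Stage-specific monogenic fractions are weighted
    by the configured iOSN counts per stage.
    """
    config.validate()
    n = config.n_or_genes
    lam = config.background_or_rate
    rho = config.co_expression_rate
    p_gene = -math.expm1(-lam / n)  # P(a given OR gets >=1 background transcript)
    p_no_new = math.exp(-lam * (n - 1) / n)

    pis = config.monogenic_by_stage()
    stage_cells = config.stage_cells()
    num = 0.0
    den = 0.0
    for stage in config.stages:
        w = stage_cells[stage].get("iOSN", 0)
        if w == 0:
            continue
        pi = pis[stage]
        # chooser, no second OR, background confined to the chosen gene
        one = pi * (1 - rho) * p_no_new
        # non-chooser with exactly one background-expressed gene
        one += (1 - pi) * n * p_gene * (1 - p_gene) ** (n - 1)
        pos = pi + (1 - pi) * (1 - (1 - p_gene) ** n)
        num += w * one
        den += w * pos
    if den == 0:
        raise ValueError("no iOSN configured; fraction undefined")
    return num / den


# ---------------------------------------------------------------------------
# spatial strip
# ---------------------------------------------------------------------------

_DEFAULT_STRIP_TYPES = {"RHBC": 200, "MV": 150, "INP": 200, "iOSN": 250, "SUS": 150}


def _default_density(cell_type: str, grid: np.ndarray) -> np.ndarray:
    # respiratory types pile up at low s, olfactory types at high s
    if cell_type in ("RHBC", "MV"):
        return 2.0 * (1.0 - grid)
    return 2.0 * grid


@dataclass(frozen=True)
class SpatialStripConfig:
    """A 1-D respiratory-to-olfactory epithelial band.

    ``total_floor`` sets a hard minimum on per-cell transcript totals so
    the expected number of cells removed by a minimum-transcript filter is
    a known Poisson tail probability.
    """

    seed: int = 0
    length: float = 1000.0  # µm
    width: float = 60.0  # µm
    cells_per_type: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_STRIP_TYPES)
    )
    #: per-type density over [0,1]; arrays are evaluated on a uniform grid
    density_profiles: Mapping[str, np.ndarray] | None = None
    density_grid_size: int = 512
    n_or_genes: int = 57
    n_marker_genes: int = 24
    total_floor: int = 0
    total_mean: float = 89.0
    monogenic_fraction: float = 0.7
    co_expression_rate: float = 0.05
    dominant_mean: float = 8.0
    background_or_rate: float = 0.05

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError("strip length must be positive")
        if self.width <= 0:
            raise ValueError("strip width must be positive")
        if not self.cells_per_type or sum(self.cells_per_type.values()) <= 0:
            raise ValueError("configuration requests zero cells")
        if self.density_profiles is not None:
            for t, prof in self.density_profiles.items():
                prof = np.asarray(prof, dtype=float)
                if prof.size == 0:
                    raise ValueError(f"empty density profile for {t}")
                if prof.sum() <= 0:
                    raise ValueError(f"density profile for {t} has no mass")


def _sample_axis_positions(
    rng: np.random.Generator, density: np.ndarray, n: int
) -> np.ndarray:
    """Inverse-CDF sampling of s in [0,1] from a gridded density."""
    density = np.asarray(density, dtype=float)
    m = density.size
    probs = density / density.sum()
    bins = rng.choice(m, size=n, p=probs)
    return (bins + rng.random(n)) / m


def simulate_spatial_strip(
    config: SpatialStripConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Place cells on a [0, L] x width band with typed axial densities.

    Returns the count matrix, gene annotation, cell annotation (with x/y
    positions in µm) and a per-cell truth table with the chosen OR.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = (np.arange(config.density_grid_size) + 0.5) / config.density_grid_size

    # gene panel: ORs + one marker gene block shared by all types
    rows = []
    for i in range(config.n_or_genes):
        rows.append((f"OR{i + 1:04d}", f"OR{i + 1:04d}", True, "II", "chr11", "none"))
    for i in range(config.n_marker_genes):
        rows.append((f"MK{i + 1:04d}", f"MK{i + 1:04d}", False, "none", "chr1", "none"))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "symbol", "is_or", "or_class", "chromosome", "marker_role"]
    )
    marker_weights = rng.dirichlet(np.full(config.n_marker_genes, 2.0))

    cell_rows, truth_rows = [], []
    srows, scols, svals = [], [], []
    cid = 0
    secondary_mean = config.dominant_mean / 4.0
    for cell_type, n_cells in config.cells_per_type.items():
        if n_cells == 0:
            continue
        if config.density_profiles is not None:
            if cell_type not in config.density_profiles:
                raise ValueError(f"no density profile for {cell_type}")
            density = np.asarray(config.density_profiles[cell_type], dtype=float)
            if density.size != config.density_grid_size:
                # resample onto the sampling grid
                src = np.linspace(0, 1, density.size)
                density = np.interp(grid, src, density)
        else:
            density = _default_density(cell_type, grid)
        s = _sample_axis_positions(rng, density, n_cells)
        x = s * config.length
        y = rng.random(n_cells) * config.width
        for j in range(n_cells):
            cid += 1
            r = len(cell_rows)
            cell_rows.append(
                (f"S{cid:06d}", "SP1", "PCW9", cell_type, "spatial", x[j], y[j])
            )
            gcounts: dict[int, int] = {}
            extra = max(config.total_mean - config.total_floor, 0.0)
            total = config.total_floor + (rng.poisson(extra) if extra > 0 else 0)
            if total > 0:
                mk = rng.multinomial(total, marker_weights)
                for k in np.flatnonzero(mk):
                    gi = config.n_or_genes + k
                    gcounts[gi] = gcounts.get(gi, 0) + int(mk[k])
            choose_p = config.monogenic_fraction if cell_type == "iOSN" else 0.0
            or_counts, chosen = _draw_or_counts(
                rng,
                config.n_or_genes,
                choose_p,
                config.dominant_mean,
                config.co_expression_rate,
                secondary_mean,
                config.background_or_rate,
            )
            for k, c in or_counts.items():
                gcounts[k] = gcounts.get(k, 0) + c
            for k, c in gcounts.items():
                srows.append(r)
                scols.append(k)
                svals.append(c)
            truth_rows.append(
                (f"S{cid:06d}", genes["gene_id"].iloc[chosen] if chosen is not None else "")
            )

    cells = pd.DataFrame(
        cell_rows, columns=["cell_id", "donor", "stage", "cell_type", "modality", "x", "y"]
    )
    counts = sp.coo_matrix(
        (svals, (srows, scols)), shape=(len(cells), len(genes)), dtype=np.int64
    ).tocsr()
    cm = CountMatrix(cells["cell_id"].to_numpy(object), genes["gene_id"].to_numpy(object), counts)
    truth = pd.DataFrame(truth_rows, columns=["cell_id", "chosen_or"])
    return cm, validate_gene_annotation(genes), validate_cell_annotation(cells), truth
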