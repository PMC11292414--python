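"""Copy-number × expression integration for ecDNA prediction.

Works on paired gene × cell-line matrices: copy number as log2 relative to
ploidy and expression as log2(TPM + 1). A gene amplified extrachromosomally
in a minority of cell lines produces the "island" motif — a few lines jointly
high on both axes while the population clusters near the origin. This module
provides:

* quadrant assignment at fixed thresholds (default CNV > 3, RNA > 7);
* the Q^CNV statistic, contrasting a copy-number value against a high
  population percentile (P_k = 99.9 by default), normalised by the number of
  entities at or above that percentile — computed per gene (across cell
  lines) and per cell line (across genes);
* an integrative predictor that combines both Q statistics, quadrant-I
  membership and external circular-DNA caller flags;
* confusion-matrix evaluation of calls against karyotype-derived labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .karyotype import AmplificationLabel

QUADRANTS = ("I", "II", "III", "IV")

DEFAULT_CNV_THRESHOLD = 3.0
DEFAULT_RNA_THRESHOLD = 7.0
DEFAULT_PERCENTILE = 99.9


@dataclass
class OmicsMatrices:
    """Aligned gene × cell-line CNV (log2 rel. ploidy) and RNA (log2(TPM+1))."""

    cnv: pd.DataFrame
    rna: pd.DataFrame

    def __post_init__(self) -> None:
        if self.cnv.empty or self.rna.empty:
            raise ValueError("omics matrices must be non-empty")
        if not self.cnv.index.equals(self.rna.index) or not self.cnv.columns.equals(self.rna.columns):
            raise ValueError("cnv and rna matrices must share gene index and cell columns")
        if not np.isfinite(self.cnv.to_numpy()).all() or not np.isfinite(self.rna.to_numpy()).all():
            raise ValueError("matrices must be finite")
        if (self.rna.to_numpy() < 0).any():
            raise ValueError("rna values (log2(TPM+1)) must be >= 0")

    @property
    def genes(self) -> pd.Index:
        return self.cnv.index

    @property
    def cells(self) -> pd.Index:
        return self.cnv.columns


def assign_quadrant(
    cnv_value: float,
    rna_value: float,
    cnv_t: float = DEFAULT_CNV_THRESHOLD,
    rna_t: float = DEFAULT_RNA_THRESHOLD,
) -> str:
    """Quadrant of one (CNV, RNA) point; strict ">" on both thresholds, so
    boundary points fall to the lower quadrant. I = high/high, II = low/high,
    III = low/low, IV = high/low."""
    if not np.isfinite(cnv_value) or not np.isfinite(rna_value):
        raise ValueError("quadrant assignment requires finite inputs")
    high_cnv = cnv_value > cnv_t
    high_rna = rna_value > rna_t
    if high_cnv:
        return "I" if high_rna else "IV"
    return "II" if high_rna else "III"


def quadrant_matrix(
    matrices: OmicsMatrices,
    cnv_t: float = DEFAULT_CNV_THRESHOLD,
    rna_t: float = DEFAULT_RNA_THRESHOLD,
) -> pd.DataFrame:
    """Vectorised quadrant call for every (gene, cell) point."""
    high_cnv = matrices.cnv.to_numpy() > cnv_t
    high_rna = matrices.rna.to_numpy() > rna_t
    out = np.where(high_cnv, np.where(high_rna, "I", "IV"), np.where(high_rna, "II", "III"))
    return pd.DataFrame(out, index=matrices.genes, columns=matrices.cells)


def find_island_genes(
    matrices: OmicsMatrices,
    min_cells: int = 3,
    cnv_t: float = DEFAULT_CNV_THRESHOLD,
    rna_t: float = DEFAULT_RNA_THRESHOLD,
) -> list[tuple[str, list[str]]]:
    """Genes showing the island motif: >= ``min_cells`` cell lines in
    quadrant I while the population median of both axes sits in quadrant III
    (near the origin). Returns (gene, quadrant-I cell lines) pairs."""
    quad = quadrant_matrix(matrices, cnv_t, rna_t)
    out: list[tuple[str, list[str]]] = []
    med_cnv = matrices.cnv.median(axis=1)
    med_rna = matrices.rna.median(axis=1)
    for gene in matrices.genes:
        island_cells = [c for c in matrices.cells if quad.at[gene, c] == "I"]
        if len(island_cells) >= min_cells and med_cnv[gene] <= cnv_t and med_rna[gene] <= rna_t:
            out.append((gene, island_cells))
    return out


@dataclass
class QScores:
    """Per-(gene, cell) Q^CNV values; NaN flags an undefined score."""

    q_gene: pd.DataFrame | None = None
    q_cell: pd.DataFrame | None = None
    p_k: float = DEFAULT_PERCENTILE


def _q_along_axis(values: np.ndarray, p_k: float) -> np.ndarray:
    """Q scores computed row-wise: (v − P_k(row)) / #{entries >= P_k(row)}."""
    pk = np.percentile(values, p_k, axis=1, keepdims=True)  # linear interpolation
    n_at_or_above = (values >= pk).sum(axis=1, keepdims=True).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (values - pk) / n_at_or_above
    q[np.broadcast_to(n_at_or_above == 0, q.shape)] = np.nan
    return q


def q_cnv_gene(matrices: OmicsMatrices, p_k: float = DEFAULT_PERCENTILE) -> QScores:
    """Q^CNV(gene): for each gene, CNV minus that gene's P_k-th percentile
    across cell lines, divided by the number of cell lines at/above it."""
    if matrices.cnv.shape[1] < 2:
        raise ValueError("Q^CNV(gene) needs at least 2 cell lines")
    q = _q_along_axis(matrices.cnv.to_numpy(dtype=float), p_k)
    return QScores(q_gene=pd.DataFrame(q, index=matrices.genes, columns=matrices.cells), p_k=p_k)


def q_cnv_cell(matrices: OmicsMatrices, p_k: float = DEFAULT_PERCENTILE) -> QScores:
    """Q^CNV(cell): mirror of :func:`q_cnv_gene` with genes and cell lines
    exchanged — percentile and denominator taken across the genes within
    each cell line."""
    q = _q_along_axis(matrices.cnv.to_numpy(dtype=float).T, p_k).T
    return QScores(q_cell=pd.DataFrame(q, index=matrices.genes, columns=matrices.cells), p_k=p_k)


@dataclass(frozen=True)
class IntegrativeCall:
    """Per-cell integrative verdict with its evidence breakdown."""

    cell_id: str
    status: str  # positive | negative | not-evaluable
    q_gene_max: float = float("nan")
    q_cell_max: float = float("nan")
    q_gene_pass: bool = False
    q_cell_pass: bool = False
    quadrant_one: bool = False
    external: bool = False


def integrative_predict(
    qscores: QScores,
    quadrants: pd.DataFrame,
    external_flags: Mapping[str, bool],
    sigma_mult: float = 1.0,
    stat_scope: str = "cell_max",
) -> dict[str, IntegrativeCall]:
    """Combine the four evidence layers into a per-cell ecDNA call.

    A cell is positive iff its best Q^CNV(gene) and Q^CNV(cell) both exceed
    the population mean + ``sigma_mult``·sd, it has at least one gene in
    quadrant I, and at least one external caller (AmpliconArchitect /
    CircleHunter, OR-combined upstream) flags it. Cells with no external
    flag entry are reported as not-evaluable, never silently negative.

    ``stat_scope`` controls the population over which μ and σ are computed:
    ``"cell_max"`` (default) uses per-cell maxima; ``"pairs"`` uses all
    defined (gene, cell) scores.
    """
    if qscores.q_gene is None or qscores.q_cell is None:
        raise ValueError("both q_gene and q_cell must be present")
    if stat_scope not in ("cell_max", "pairs"):
        raise ValueError("stat_scope must be 'cell_max' or 'pairs'")

    gene_max = qscores.q_gene.max(axis=0, skipna=True)  # per-cell best gene score
    cell_max = qscores.q_cell.max(axis=0, skipna=True)
    if stat_scope == "cell_max":
        g_pop, c_pop = gene_max.dropna(), cell_max.dropna()
    else:
        g_pop = qscores.q_gene.stack().dropna()
        c_pop = qscores.q_cell.stack().dropna()
    g_thresh = g_pop.mean() + sigma_mult * g_pop.std(ddof=1)
    c_thresh = c_pop.mean() + sigma_mult * c_pop.std(ddof=1)

    quad_one = (quadrants == "I").any(axis=0)

    calls: dict[str, IntegrativeCall] = {}
    for cell in qscores.q_gene.columns:
        if cell not in external_flags:
            calls[cell] = IntegrativeCall(cell_id=cell, status="not-evaluable")
            continue
        gp = bool(gene_max[cell] > g_thresh)
        cp = bool(cell_max[cell] > c_thresh)
        q1 = bool(quad_one.get(cell, False))
        ext = bool(external_flags[cell])
        calls[cell] = IntegrativeCall(
            cell_id=cell,
            status="positive" if (gp and cp and q1 and ext) else "negative",
            q_gene_max=float(gene_max[cell]),
            q_cell_max=float(cell_max[cell]),
            q_gene_pass=gp,
            q_cell_pass=cp,
            quadrant_one=q1,
            external=ext,
        )
    return calls


@dataclass(frozen=True)
class ConfusionReport:
    """Confusion counts with the derived metrics (MCC = 0 on a zero marginal)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0

    @property
    def mcc(self) -> float:
        denom = (
            (self.tp + self.fp)
            * (self.tp + self.fn)
            * (self.tn + self.fp)
            * (self.tn + self.fn)
        )
        if denom == 0:
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / denom**0.5


def evaluate_confusion(
    calls: Mapping[str, bool],
    labels: Mapping[str, AmplificationLabel | str],
) -> ConfusionReport:
    """Score boolean calls against karyotype labels.

    Cells with unknown labels (or without a call) are excluded before
    counting; raises if nothing evaluable remains.
    """
    tp = fp = tn = fn = 0
    for cell, label in labels.items():
        truth = label.ecdna if isinstance(label, AmplificationLabel) else label
        if truth == "unknown" or cell not in calls:
            continue
        call = bool(calls[cell])
        if truth == "positive":
            tp, fn = (tp + 1, fn) if call else (tp, fn + 1)
        elif truth == "negative":
            fp, tn = (fp + 1, tn) if call else (fp, tn + 1)
        else:
            raise ValueError(f"bad label for {cell}: {truth!r}")
    if tp + fp + tn + fn == 0:
        raise ValueError("no evaluable cells (all labels unknown?)")
    return ConfusionReport(tp=tp, fp=fp, tn=tn, fn=fn)


def aberration_overlap(predicted_chroms: Iterable[str], aberrant_chroms: Iterable[str]) -> float:
    """Percentage of predicted chromosomes also seen aberrant in karyotypes:
    100·|predicted ∩ aberrant| / |predicted|."""
    pred = set(predicted_chroms)
    if not pred:
        raise ValueError("predicted chromosome set is empty")
    return 100.0 * len(pred & set(aberrant_chroms)) / len(pred)


# --- model/results surface ---------------------------------------------------


class IntegrativeEcdnaModel:
    """Integrative ecDNA predictor over paired CNV/RNA matrices.

    Parameters mirror the analysis defaults: quadrant thresholds (CNV > 3,
    RNA > 7 on the log2 scales), percentile P_k = 99.9 for both Q^CNV
    variants, and a μ+1σ rule on the per-cell maxima.
    """

    def __init__(
        self,
        matrices: OmicsMatrices,
        external_flags: Mapping[str, bool],
        cnv_threshold: float = DEFAULT_CNV_THRESHOLD,
        rna_threshold: float = DEFAULT_RNA_THRESHOLD,
        percentile: float = DEFAULT_PERCENTILE,
        sigma_mult: float = 1.0,
    ) -> None:
        self.matrices = matrices
        self.external_flags = dict(external_flags)
        self.cnv_threshold = cnv_threshold
        self.rna_threshold = rna_threshold
        self.percentile = percentile
        self.sigma_mult = sigma_mult

    @classmethod
    def from_dataframes(cls, cnv: pd.DataFrame, rna: pd.DataFrame, external_flags: Mapping[str, bool], **kw):
        return cls(OmicsMatrices(cnv=cnv, rna=rna), external_flags, **kw)

    def fit(self) -> "IntegrativeResults":
        qs = QScores(
            q_gene=q_cnv_gene(self.matrices, self.percentile).q_gene,
            q_cell=q_cnv_cell(self.matrices, self.percentile).q_cell,
            p_k=self.percentile,
        )
        quad = quadrant_matrix(self.matrices, self.cnv_threshold, self.rna_threshold)
        calls = integrative_predict(qs, quad, self.external_flags, self.sigma_mult)
        return IntegrativeResults(model=self, qscores=qs, quadrants=quad, calls=calls)


@dataclass
class IntegrativeResults:
    """Fitted integrative predictions with their evidence layers."""

    model: IntegrativeEcdnaModel
    qscores: QScores
    quadrants: pd.DataFrame
    calls: dict[str, IntegrativeCall]

    @property
    def positive_cells(self) -> list[str]:
        return [c for c, call in self.calls.items() if call.status == "positive"]

    def evaluate(self, labels: Mapping[str, AmplificationLabel | str]) -> ConfusionReport:
        bool_calls = {c: k.status == "positive" for c, k in self.calls.items() if k.status != "not-evaluable"}
        return evaluate_confusion(bool_calls, labels)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": c.cell_id,
                "status": c.status,
                "q_gene_max": c.q_gene_max,
                "q_cell_max": c.q_cell_max,
                "q_gene_pass": c.q_gene_pass,
                "q_cell_pass": c.q_cell_pass,
                "quadrant_I": c.quadrant_one,
                "external": c.external,
            }
            for c in self.calls.values()
        ]
        return pd.DataFrame(rows).set_index("cell_id")

    def summary(self) -> str:
        df = self.to_frame()
        n_pos = int((df["status"] == "positive").sum())
        n_ne = int((df["status"] == "not-evaluable").sum())
        lines = [
            "Integrative ecDNA prediction",
            "============================",
            f"cells evaluated:        {len(df) - n_ne}",
            f"not evaluable:          {n_ne}",
            f"predicted ecDNA+:       {n_pos}",
            f"CNV/RNA thresholds:     >{self.model.cnv_threshold} / >{self.model.rna_threshold}",
            f"Q percentile P_k:       {self.model.percentile}",
            f"sigma multiplier:       {self.model.sigma_mult}",
        ]
        return "\n".join(lines)

    def plot_quadrants(self, gene: str, ax=None):
        """Scatter one gene's CNV vs RNA across cell lines with the quadrant
        thresholds; quadrant-I cells highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        cnv = self.model.matrices.cnv.loc[gene]
        rna = self.model.matrices.rna.loc[gene]
        in_q1 = (cnv > self.model.cnv_threshold) & (rna > self.model.rna_threshold)
        ax.scatter(cnv[~in_q1], rna[~in_q1], s=12, c="grey", label="background")
        if in_q1.any():
            ax.scatter(cnv[in_q1], rna[in_q1], s=20, c="crimson", label="quadrant I")
        ax.axvline(self.model.cnv_threshold, ls="--", lw=0.8, c="k")
        ax.axhline(self.model.rna_threshold, ls="--", lw=0.8, c="k")
        ax.set_xlabel("CNV (log2 rel. ploidy)")
        ax.set_ylabel("RNA (log2(TPM+1))")
        ax.set_title(gene)
        ax.legend(frameon=False, fontsize=8)
        return ax
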