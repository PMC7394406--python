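"""Expression-level summaries: DEG direction tallies, set overlaps,
qPCR relative quantification and the integer EMT score.

The differential-expression table is consumed, never computed, here: rows
are (gene_id, log2 fold change, adjusted p). Relative qPCR quantification
follows the comparative-cycle (2^-ddCt) method with a stable endogenous
reference gene and a calibrator sample. The EMT score summarizes marker
panels into one integer per sample group: negative = epithelial-like,
positive = mesenchymal-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .controls import ExpressionTable
from .events import intersect_genes

logger = logging.getLogger(__name__)

__all__ = [
    "DegSummary",
    "QuantCycleRecord",
    "EmtPanel",
    "read_deg_table",
    "deg_direction_summary",
    "overlap_summary",
    "ddct_fold_change",
    "read_qpcr",
    "emt_score",
]


class DegSummary(NamedTuple):
    n_total: int
    n_up: int
    n_down: int
    pct_up: int
    pct_down: int


def read_deg_table(path) -> pd.DataFrame:
    """DEG TSV with columns gene_id, log2FoldChange, padj."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "log2FoldChange", "padj"):
        if col not in df.columns:
            raise ValueError(f"missing column {col} in {path}")
    return df


def deg_direction_summary(degs: pd.DataFrame, alpha: float = 0.05,
                          use_raw_p: bool = False) -> DegSummary:
    """Counts and integer percentages of significant up/down DEGs.

    Significance is adjusted p < alpha (``use_raw_p`` switches to a raw
    ``pvalue`` column). Rows with log2 fold change exactly zero count in
    neither direction (logged). Percentages are of the significant total,
    rounded to the nearest integer.
    """
    pcol = "pvalue" if use_raw_p else "padj"
    sig = degs[degs[pcol] < alpha]
    n_up = int((sig["log2FoldChange"] > 0).sum())
    n_down = int((sig["log2FoldChange"] < 0).sum())
    n_zero = len(sig) - n_up - n_down
    if n_zero:
        logger.info("%d significant genes with zero log2FC counted in neither direction", n_zero)
    n_total = len(sig)
    if n_total == 0:
        logger.warning("no significant genes at alpha=%g", alpha)
        return DegSummary(0, 0, 0, 0, 0)
    pct_up = int(round(100 * n_up / n_total))
    pct_down = int(round(100 * n_down / n_total))
    return DegSummary(n_total, n_up, n_down, pct_up, pct_down)


def overlap_summary(genes_a, genes_b) -> tuple[int, int, int]:
    """Venn counts (only_a, shared, only_b); see events.intersect_genes."""
    return intersect_genes(genes_a, genes_b)


@dataclass(frozen=True)
class QuantCycleRecord:
    """Quantification cycles for one target/reference x test/calibrator set."""

    ct_target_test: float
    ct_reference_test: float
    ct_target_calibrator: float
    ct_reference_calibrator: float

    def __post_init__(self) -> None:
        for f in (
            self.ct_target_test,
            self.ct_reference_test,
            self.ct_target_calibrator,
            self.ct_reference_calibrator,
        ):
            if not np.isfinite(f):
                raise ValueError("quantification cycles must be finite")


def ddct_fold_change(rec: QuantCycleRecord) -> float:
    """Relative expression 2^-ddCt of test vs calibrator.

    dCt = Ct(target) - Ct(reference) within each sample; ddCt is the test
    dCt minus the calibrator dCt. A ddCt of +1 is one cycle later, i.e. a
    halving of relative expression.
    """
    dct_test = rec.ct_target_test - rec.ct_reference_test
    dct_cal = rec.ct_target_calibrator - rec.ct_reference_calibrator
    return float(2.0 ** -(dct_test - dct_cal))


def read_qpcr(path) -> pd.DataFrame:
    """qPCR CSV: sample, target_gene, reference_gene, ct_target, ct_reference,
    is_calibrator (0/1)."""
    df = pd.read_csv(path)
    required = ("sample", "target_gene", "reference_gene", "ct_target",
                "ct_reference", "is_calibrator")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing column {col} in {path}")
    return df


def qpcr_fold_changes(qpcr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample 2^-ddCt fold changes vs the calibrator, per target gene."""
    rows = []
    for target, group in qpcr.groupby("target_gene"):
        cal = group[group["is_calibrator"] == 1]
        if len(cal) == 0:
            raise ValueError(f"no calibrator sample for target {target}")
        cal_row = cal.iloc[0]
        for _, row in group.iterrows():
            rec = QuantCycleRecord(
                ct_target_test=row["ct_target"],
                ct_reference_test=row["ct_reference"],
                ct_target_calibrator=cal_row["ct_target"],
                ct_reference_calibrator=cal_row["ct_reference"],
            )
            rows.append(
                {
                    "target_gene": target,
                    "sample": row["sample"],
                    "fold_change": ddct_fold_change(rec),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class EmtPanel:
    """Marker panels; DSP denotes desmoplakin."""

    epithelial_genes: frozenset[str] = frozenset({"CDH1", "DSP", "OCLN", "ESRP1"})
    mesenchymal_genes: frozenset[str] = frozenset({"CDH2", "VIM", "FOXC2", "ZEB1", "SOX10"})

    def __post_init__(self) -> None:
        self.epithelial_genes = frozenset(self.epithelial_genes)
        self.mesenchymal_genes = frozenset(self.mesenchymal_genes)
        if not self.epithelial_genes or not self.mesenchymal_genes:
            raise ValueError("both panels must be non-empty")
        if self.epithelial_genes & self.mesenchymal_genes:
            raise ValueError("panels must be disjoint")


ScoreScheme = Callable[[pd.DataFrame, dict[str, str], EmtPanel], dict[str, int]]


def _signed_marker_count(
    abundance: pd.DataFrame, groups: dict[str, str], panel: EmtPanel
) -> dict[str, int]:
    """Default scheme: per group, (# mesenchymal markers whose group mean
    exceeds the gene's all-sample median) - (# epithelial markers doing so).
    Ties (group mean exactly at the median) count as not exceeding."""
    scores: dict[str, int] = {}
    medians = abundance.median(axis=1)
    group_names = sorted(set(groups.values()))
    for g in group_names:
        samples = [s for s, grp in groups.items() if grp == g]
        if not samples:
            raise ValueError(f"group {g} has no samples")
        means = abundance[samples].mean(axis=1)
        mes = sum(
            1 for gene in panel.mesenchymal_genes
            if gene in abundance.index and means[gene] > medians[gene]
        )
        epi = sum(
            1 for gene in panel.epithelial_genes
            if gene in abundance.index and means[gene] > medians[gene]
        )
        scores[g] = int(mes - epi)
    return scores


def emt_score(
    expr: ExpressionTable,
    groups: dict[str, str],
    panel: EmtPanel | None = None,
    reference_group: str | None = None,
    scheme: ScoreScheme | None = None,
) -> dict[str, int]:
    """Integer EMT score per sample group.

    Bounded in [-|epithelial panel|, +|mesenchymal panel|] under the default
    signed-marker-count scheme; more negative = more epithelial. Panel genes
    missing from the expression table are dropped with a warning. The scheme
    is pluggable; ``reference_group`` is passed through to schemes that
    normalize against a baseline (unused by the default).
    """
    panel = panel or EmtPanel()
    missing = (panel.epithelial_genes | panel.mesenchymal_genes) - set(expr.gene_ids)
    if missing:
        logger.warning("panel genes missing from expression table: %s",
                       ",".join(sorted(missing)))
    unknown = set(groups) - set(expr.sample_labels)
    if unknown:
        raise ValueError(f"samples not in expression table: {sorted(unknown)}")
    scheme = scheme or _signed_marker_count
    return scheme(expr.abundance, groups, panel)
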