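"""Event constructs and internal/external control construct sampling.

Internal controls are E-I-E-I-E windows drawn from the reference transcript
of a gene carrying a skipped-exon event, constrained not to overlap any of
that gene's event constructs. External controls come from the most highly
expressed genes that are not mitochondrial, not differentially spliced in
any of the five event classes, and have a MANE-matched transcript.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import (
    EIEIEConstruct,
    Gene,
    GenomeAnnotation,
    Transcript,
    enumerate_constructs,
    intervals_intersect,
    select_reference_transcript,
)
from .events import EventSet, SpliceEvent, strip_version

logger = logging.getLogger(__name__)

__all__ = [
    "ControlConfig",
    "ExpressionTable",
    "ManeSet",
    "build_event_construct",
    "internal_control_pool",
    "sample_internal_control",
    "select_external_control_genes",
    "sample_external_controls",
    "gene_rng",
]


@dataclass
class ControlConfig:
    n_external: int = 2000
    mito_contigs: frozenset[str] = frozenset({"chrM", "MT"})
    seed: int = 0
    allow_fewer_external: bool = False
    rank_statistic: str = "mean"  # mean | median | max across samples

    def __post_init__(self) -> None:
        if self.n_external < 1:
            raise ValueError("n_external must be >= 1")
        self.mito_contigs = frozenset(self.mito_contigs)


class ExpressionTable:
    """Gene x sample abundance matrix (TPM-like, non-negative)."""

    def __init__(self, abundance: pd.DataFrame):
        if abundance.index.has_duplicates:
            raise ValueError("duplicate gene_ids in expression table")
        if (abundance.values < 0).any():
            raise ValueError("negative abundance values")
        self.abundance = abundance.astype(float)

    @property
    def sample_labels(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.abundance.index)

    @classmethod
    def read_tsv(cls, path) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        self.abundance.to_csv(path, sep="\t", float_format="%.6g")

    def summarize(self, statistic: str = "mean") -> pd.Series:
        if statistic == "mean":
            return self.abundance.mean(axis=1)
        if statistic == "median":
            return self.abundance.median(axis=1)
        if statistic == "max":
            return self.abundance.max(axis=1)
        raise ValueError(f"unknown rank statistic {statistic!r}")


class ManeSet:
    """Curated transcript set keyed by (transcript_id, version)."""

    def __init__(self, entries):
        self.entries: set[tuple[str, int]] = {(str(t), int(v)) for t, v in entries}

    def __contains__(self, item) -> bool:
        t, v = item
        return (str(t), int(v)) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def read_tsv(cls, path) -> "ManeSet":
        df = pd.read_csv(path, sep="\t")
        return cls(zip(df["transcript_id"], df["version"]))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("transcript_id\tversion\n")
            for t, v in sorted(self.entries):
                fh.write(f"{t}\t{v}\n")

    def match(self, transcript: Transcript) -> bool:
        if transcript.version is None:
            return False
        base = transcript.transcript_id.rpartition(".")[0]
        return (base, transcript.version) in self.entries


def gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    """Per-gene random stream: global seed mixed with a stable gene hash.

    CRC32 (not Python's salted ``hash``) keeps streams identical across
    processes and platforms, and independent of gene processing order.
    """
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(gene_id.encode())])
    )


def build_event_construct(event: SpliceEvent) -> EIEIEConstruct:
    """E-I-E-I-E for one SE row; introns are the intervening gaps.

    rMATS flanking-exon columns are genomic (upstream = leftmost); the 5'
    exon of the construct is therefore the downstream column on the minus
    strand.
    """
    if event.event_class != "SE":
        raise ValueError("event constructs are defined for SE events only")
    left, mid, right = event.upstream_exon, event.central, event.downstream_exon
    if not (left[1] < mid[0] and mid[1] < right[0]):
        raise ValueError(
            "SE exons must be separated by introns of length >= 1 "
            f"(got {left}, {mid}, {right})"
        )
    exons_5to3 = [left, mid, right] if event.strand == "+" else [right, mid, left]
    c = EIEIEConstruct.from_exon_triplet(
        gene_id=event.gene_id,
        contig=event.contig,
        strand=event.strand,
        exons_5to3=exons_5to3,
        origin="event",
    )
    return c


def internal_control_pool(
    gene: Gene,
    event_constructs: list[EIEIEConstruct],
    max_tsl: int | None = None,
    overlap: str = "span",
) -> list[EIEIEConstruct] | None:
    """Candidate internal-control windows for a gene.

    Every 3-exon window of the reference transcript whose genomic span does
    not intersect the span of any event construct of the gene
    (``overlap="exon"`` restricts the test to exon parts). ``None`` when the
    gene has no reference transcript; an empty list when every window
    clashes.
    """
    ref = select_reference_transcript(gene, max_tsl=max_tsl)
    if ref is None:
        logger.info("gene %s has no reference transcript", gene.gene_id)
        return None
    pool = []
    for cand in enumerate_constructs(ref, gene_id=gene.gene_id, origin="internal_control"):
        clash = False
        for ev in event_constructs:
            if overlap == "exon":
                ivs = [ev.parts[p] for p in ("exon_up", "central_exon", "exon_down")]
                clash = any(
                    intervals_intersect(cand.parts[p], iv)
                    for p in ("exon_up", "central_exon", "exon_down")
                    for iv in ivs
                )
            else:
                clash = intervals_intersect(cand.span, ev.span)
            if clash:
                break
        if not clash:
            pool.append(cand)
    return pool


def sample_internal_control(
    gene: Gene,
    event_constructs: list[EIEIEConstruct],
    seed: int,
    max_tsl: int | None = None,
    overlap: str = "span",
) -> EIEIEConstruct | None:
    """One uniformly-random member of :func:`internal_control_pool`.

    Returns ``None`` when the gene has no reference transcript (logged) or
    the pool is empty — the latter is expected for transcripts with few
    exons. Deterministic given the seed (per-gene stream).
    """
    pool = internal_control_pool(gene, event_constructs, max_tsl=max_tsl, overlap=overlap)
    if not pool:
        return None
    rng = gene_rng(seed, gene.gene_id)
    return pool[int(rng.integers(len(pool)))]


def select_external_control_genes(
    expr: ExpressionTable,
    filtered_events: list[EventSet],
    annotation: GenomeAnnotation,
    mane: ManeSet,
    cfg: ControlConfig,
) -> list[str]:
    """Top-expressed genes passing the mito / event / MANE filters.

    Genes are ranked by the configured across-sample summary of abundance
    (descending; ties break to the lexicographically smaller gene id);
    excluded are genes on mitochondrial contigs, genes present in any of the
    filtered event sets, and genes without a transcript whose (id, version)
    is in the MANE set. Returns the top ``cfg.n_external`` gene ids.
    """
    event_genes: set[str] = set()
    for es in filtered_events:
        event_genes |= es.gene_ids()

    ranked = expr.summarize(cfg.rank_statistic)
    order = sorted(ranked.index, key=lambda g: (-ranked[g], g))

    selected: list[str] = []
    n_mito = n_event = n_no_mane = n_unknown = 0
    for gid in order:
        gene = annotation.genes.get(gid)
        if gene is None:
            n_unknown += 1
            continue
        if gene.contig in cfg.mito_contigs:
            n_mito += 1
            continue
        if strip_version(gid) in event_genes:
            n_event += 1
            continue
        if not any(mane.match(t) for t in gene.transcripts):
            n_no_mane += 1
            continue
        selected.append(gid)
        if len(selected) == cfg.n_external:
            break
    logger.info(
        "external-control selection: %d kept; excluded %d mito, %d in events, "
        "%d without MANE match, %d absent from annotation",
        len(selected), n_mito, n_event, n_no_mane, n_unknown,
    )
    if len(selected) < cfg.n_external:
        msg = (
            f"only {len(selected)} eligible external-control genes "
            f"(requested {cfg.n_external})"
        )
        if not cfg.allow_fewer_external:
            raise ValueError(msg)
        logger.warning(msg)
    return selected


def sample_external_controls(
    gene_ids: list[str],
    annotation: GenomeAnnotation,
    mane: ManeSet,
    seed: int,
) -> list[EIEIEConstruct]:
    """One random window from each gene's MANE transcript.

    Genes whose MANE transcript has fewer than 3 exons are skipped with a
    logged count. Deterministic given the seed and independent of gene
    order (per-gene streams).
    """
    out: list[EIEIEConstruct] = []
    n_skipped = 0
    for gid in gene_ids:
        gene = annotation.genes[gid]
        mane_tx = [t for t in gene.transcripts if mane.match(t)]
        if not mane_tx:
            raise ValueError(f"gene {gid} has no MANE-matched transcript")
        tx = min(mane_tx, key=lambda t: t.transcript_id)
        windows = enumerate_constructs(tx, gene_id=gid, origin="external_control")
        if not windows:
            n_skipped += 1
            continue
        rng = gene_rng(seed, gid)
        out.append(windows[int(rng.integers(len(windows)))])
    if n_skipped:
        logger.info("%d external-control genes skipped (<3 exons)", n_skipped)
    return out
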