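"""Reading and filtering rMATS-style differential-splicing tables.

Five event classes are supported: skipped exon (SE), alternative 3'/5'
splice site (A3SS/A5SS), mutually exclusive exons (MXE) and retained intron
(RI). Coordinates in rMATS tables are 0-based half-open and are taken
verbatim. The significance filter retains events with p < 0.05 AND
FDR < 0.05 (strict inequalities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_CLASSES = ("SE", "A3SS", "A5SS", "MXE", "RI")

#: Columns common to every rMATS table.
COMMON_COLUMNS = ("GeneID", "geneSymbol", "chr", "strand", "PValue", "FDR", "IncLevelDifference")

#: Class-specific coordinate columns; the first pair is the central anchor.
CLASS_COORD_COLUMNS = {
    "SE": (
        "exonStart_0base", "exonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ),
    "A3SS": ("longExonStart_0base", "longExonEnd", "shortES", "shortEE", "flankingES", "flankingEE"),
    "A5SS": ("longExonStart_0base", "longExonEnd", "shortES", "shortEE", "flankingES", "flankingEE"),
    "MXE": (
        "1stExonStart_0base", "1stExonEnd",
        "2ndExonStart_0base", "2ndExonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ),
    "RI": ("riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE", "downstreamES", "downstreamEE"),
}


def strip_version(gene_id: str) -> str:
    """Gene identity for tallies/overlaps: drop any trailing .version."""
    base, _, tail = gene_id.partition(".")
    return base if tail else gene_id


@dataclass(frozen=True)
class SpliceEvent:
    event_class: str
    gene_id: str
    gene_symbol: str
    contig: str
    strand: str
    central: tuple[int, int]
    p_value: float
    fdr: float
    inc_level_diff: float
    upstream_exon: tuple[int, int] | None = None   # genomically leftmost (SE)
    downstream_exon: tuple[int, int] | None = None  # genomically rightmost (SE)

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class}")
        if not (np.isfinite(self.p_value) and np.isfinite(self.fdr)):
            raise ValueError("p_value and fdr must be finite")
        if self.event_class == "SE":
            if self.upstream_exon is None or self.downstream_exon is None:
                raise ValueError("SE event needs flanking exon coordinates")
            if not (
                self.upstream_exon[1] <= self.central[0]
                < self.central[1] <= self.downstream_exon[0]
            ):
                raise ValueError(
                    "SE exons must be ordered upstream <= central <= downstream "
                    "(genomic coordinates)"
                )


@dataclass
class EventSet:
    events: list[SpliceEvent] = field(default_factory=list)
    provenance: str = ""
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def gene_ids(self) -> set[str]:
        return {strip_version(e.gene_id) for e in self.events}


@dataclass
class ClassTally:
    events_per_class: dict[str, int]
    genes_per_class: dict[str, int]
    multi_class_genes: dict[int, int]


def _read_one(path: str | Path, event_class: str) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = list(COMMON_COLUMNS) + list(CLASS_COORD_COLUMNS[event_class])
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing column {col} in {path}")
    return df


def events_from_frame(
    df: pd.DataFrame, event_class: str, provenance: str = ""
) -> EventSet:
    """Build an EventSet from an rMATS-style DataFrame.

    Rows whose numeric fields fail to parse (e.g. "NA" inclusion-level
    differences) are dropped; the drop count is recorded on the EventSet
    and logged.
    """
    if event_class not in EVENT_CLASSES:
        raise ValueError(f"unknown event class {event_class}")
    required = list(COMMON_COLUMNS) + list(CLASS_COORD_COLUMNS[event_class])
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    coord_cols = CLASS_COORD_COLUMNS[event_class]
    numeric_cols = ["PValue", "FDR", "IncLevelDifference", *coord_cols]
    parsed = df[numeric_cols].apply(pd.to_numeric, errors="coerce")
    good = parsed.notna().all(axis=1)
    n_dropped = int((~good).sum())
    if n_dropped:
        logger.info("dropped %d unparseable %s rows", n_dropped, event_class)
    events = []
    for idx in df.index[good]:
        row = df.loc[idx]
        num = parsed.loc[idx]
        kwargs = {}
        if event_class == "SE":
            kwargs["upstream_exon"] = (int(num["upstreamES"]), int(num["upstreamEE"]))
            kwargs["downstream_exon"] = (int(num["downstreamES"]), int(num["downstreamEE"]))
        events.append(
            SpliceEvent(
                event_class=event_class,
                gene_id=str(row["GeneID"]),
                gene_symbol=str(row["geneSymbol"]),
                contig=str(row["chr"]),
                strand=str(row["strand"]),
                central=(int(num[coord_cols[0]]), int(num[coord_cols[1]])),
                p_value=float(num["PValue"]),
                fdr=float(num["FDR"]),
                inc_level_diff=float(num["IncLevelDifference"]),
                **kwargs,
            )
        )
    return EventSet(events=events, provenance=provenance, n_dropped=n_dropped)


def read_rmats(paths: dict[str, str | Path], provenance: str = "") -> dict[str, EventSet]:
    """Read one table per event class; returns a per-class EventSet map.

    Files are tab-separated with the rMATS JC column set (JCEC tables have
    the same columns and read identically). A missing mandatory column is a
    hard error naming the column and file.
    """
    out: dict[str, EventSet] = {}
    for event_class, path in paths.items():
        if event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {event_class}")
        df = _read_one(path, event_class)
        out[event_class] = events_from_frame(df, event_class, provenance)
    return out


def filter_events(events: EventSet, p_max: float = 0.05, fdr_max: float = 0.05) -> EventSet:
    """Retain events with p_value < p_max AND fdr < fdr_max (strict)."""
    kept = [e for e in events if e.p_value < p_max and e.fdr < fdr_max]
    return EventSet(events=kept, provenance=events.provenance)


def split_by_direction(
    events: EventSet, patient_is_sample1: bool = True
) -> tuple[EventSet, EventSet]:
    """Split SE events into (more_skipped, less_skipped) in the patient.

    With the patient as rMATS sample 1, a negative inclusion-level
    difference means lower inclusion (more skipping) in the patient. Events
    with an exactly zero difference belong to neither set and are logged.
    """
    for e in events:
        if e.event_class != "SE":
            raise ValueError(f"split_by_direction requires SE events, got {e.event_class}")
    sign = 1.0 if patient_is_sample1 else -1.0
    more = [e for e in events if sign * e.inc_level_diff < 0]
    less = [e for e in events if sign * e.inc_level_diff > 0]
    n_zero = len(events) - len(more) - len(less)
    if n_zero:
        logger.info("%d SE events with zero inclusion difference excluded", n_zero)
    return (
        EventSet(events=more, provenance=events.provenance),
        EventSet(events=less, provenance=events.provenance),
    )


def tally_event_classes(event_sets: dict[str, EventSet] | EventSet) -> ClassTally:
    """Per-class event and distinct-gene counts plus multi-class gene counts."""
    if isinstance(event_sets, EventSet):
        pooled = list(event_sets)
    else:
        pooled = [e for s in event_sets.values() for e in s]
    events_per_class = {c: 0 for c in EVENT_CLASSES}
    genes_by_class: dict[str, set[str]] = {c: set() for c in EVENT_CLASSES}
    classes_by_gene: dict[str, set[str]] = {}
    for e in pooled:
        gid = strip_version(e.gene_id)
        events_per_class[e.event_class] += 1
        genes_by_class[e.event_class].add(gid)
        classes_by_gene.setdefault(gid, set()).add(e.event_class)
    multi: dict[int, int] = {}
    for classes in classes_by_gene.values():
        multi[len(classes)] = multi.get(len(classes), 0) + 1
    return ClassTally(
        events_per_class=events_per_class,
        genes_per_class={c: len(s) for c, s in genes_by_class.items()},
        multi_class_genes=multi,
    )


def intersect_genes(set_a, set_b) -> tuple[int, int, int]:
    """Venn counts (only_a, shared, only_b) on de-duplicated inputs."""
    a, b = set(set_a), set(set_b)
    return (len(a - b), len(a & b), len(b - a))
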