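"""The 14 per-construct sequence features.

For an E-I-E-I-E construct the features are: five part lengths, GC content
of the central exon and both introns, branch-point-to-3'SS distance of both
introns, and four splice-site strengths (donor and acceptor of the central
exon, donor of the upstream exon, acceptor of the downstream exon).

Splice-site strength is an additive position-specific log-odds score over
the 9-mer donor window (last 3 exonic nt + first 6 intronic nt) or the
23-mer acceptor window (last 20 intronic nt + first 3 exonic nt). The
default model is a first-order position-weight table trained from all
annotated junction windows of a loaded annotation (pseudocount 1); any
table with the same shape — e.g. one exported from a maximum-entropy
scorer — can be dropped in, and all downstream statistics depend only on
the rank ordering of scores.

Branch points are called with a heptamer position-weight model centred on
the branch adenosine (heptamer position 6 of 7): every A whose distance d
from the intron's 3' end lies in [search_min, search_max] is scored and the
argmax returned, ties resolved toward the 3'SS. The reported BPS-3'SS
distance is the 1-based offset of the branch A from the intron's 3' end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import EIEIEConstruct, GenomeAnnotation, PART_NAMES

__all__ = [
    "DONOR_WINDOW_LEN",
    "ACCEPTOR_WINDOW_LEN",
    "FeatureVector",
    "FEATURE_NAMES",
    "FEATURE_KINDS",
    "SpliceSiteModel",
    "BranchPointModel",
    "gc_content",
    "donor_window",
    "acceptor_window",
    "score_site",
    "find_branch_point",
    "train_splice_site_model",
    "default_branch_point_model",
    "compute_features",
    "features_to_frame",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DONOR_EXONIC, DONOR_INTRONIC = 3, 6
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3
DONOR_WINDOW_LEN = DONOR_EXONIC + DONOR_INTRONIC      # 9
ACCEPTOR_WINDOW_LEN = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC  # 23

BRANCH_HEPTAMER_LEN = 7
BRANCH_A_POS = 5  # 0-based index of the branch adenosine in the heptamer


@dataclass
class FeatureVector:
    """The 14 features for one construct; ``None`` marks an absent value."""

    construct_id: str = ""
    origin: str = ""
    central_exon_len: float | None = None
    upstream_exon_len: float | None = None
    downstream_exon_len: float | None = None
    upstream_intron_len: float | None = None
    downstream_intron_len: float | None = None
    central_exon_gc: float | None = None
    upstream_intron_gc: float | None = None
    downstream_intron_gc: float | None = None
    upstream_bps_3ss_dist: float | None = None
    downstream_bps_3ss_dist: float | None = None
    central_donor_score: float | None = None
    central_acceptor_score: float | None = None
    upstream_donor_score: float | None = None
    downstream_acceptor_score: float | None = None


FEATURE_NAMES = tuple(
    f.name for f in dc_fields(FeatureVector) if f.name not in ("construct_id", "origin")
)

#: Feature kind drives the direction vocabulary in comparison tables:
#: length/dist -> Shorter/Longer, gc -> Lower/Higher, score -> Weaker/Stronger.
FEATURE_KINDS = {
    "central_exon_len": "length",
    "upstream_exon_len": "length",
    "downstream_exon_len": "length",
    "upstream_intron_len": "length",
    "downstream_intron_len": "length",
    "central_exon_gc": "gc",
    "upstream_intron_gc": "gc",
    "downstream_intron_gc": "gc",
    "upstream_bps_3ss_dist": "length",
    "downstream_bps_3ss_dist": "length",
    "central_donor_score": "score",
    "central_acceptor_score": "score",
    "upstream_donor_score": "score",
    "downstream_acceptor_score": "score",
}


def _weights_frame(weights: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(weights, columns=list(BASES)).rename_axis("position")


@dataclass
class SpliceSiteModel:
    """Additive per-position log-odds tables for donor and acceptor sites."""

    donor_weights: np.ndarray   # (9, 4), columns A C G T
    acceptor_weights: np.ndarray  # (23, 4)
    label: str = "pwm"

    def __post_init__(self) -> None:
        self.donor_weights = np.asarray(self.donor_weights, dtype=float)
        self.acceptor_weights = np.asarray(self.acceptor_weights, dtype=float)
        if self.donor_weights.shape != (DONOR_WINDOW_LEN, 4):
            raise ValueError("donor_weights must be (9, 4)")
        if self.acceptor_weights.shape != (ACCEPTOR_WINDOW_LEN, 4):
            raise ValueError("acceptor_weights must be (23, 4)")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# splice-site model: {self.label}\n")
            fh.write("site\tposition\tA\tC\tG\tT\n")
            for site, w in (("donor", self.donor_weights), ("acceptor", self.acceptor_weights)):
                for i, row in enumerate(w):
                    vals = "\t".join(f"{x:.6f}" for x in row)
                    fh.write(f"{site}\t{i}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpliceSiteModel":
        df = pd.read_csv(path, sep="\t", comment="#")
        donor = df[df["site"] == "donor"].sort_values("position")[list(BASES)].to_numpy()
        acceptor = df[df["site"] == "acceptor"].sort_values("position")[list(BASES)].to_numpy()
        return cls(donor, acceptor, label=str(path))


@dataclass
class BranchPointModel:
    """Heptamer log-odds table centred on the branch adenosine."""

    heptamer_weights: np.ndarray  # (7, 4)
    search_min: int = 15
    search_max: int = 500
    label: str = "bp-pwm"

    def __post_init__(self) -> None:
        self.heptamer_weights = np.asarray(self.heptamer_weights, dtype=float)
        if self.heptamer_weights.shape != (BRANCH_HEPTAMER_LEN, 4):
            raise ValueError("heptamer_weights must be (7, 4)")
        if not 1 <= self.search_min <= self.search_max:
            raise ValueError("need 1 <= search_min <= search_max")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# branch-point model: {self.label} "
                     f"search={self.search_min}-{self.search_max}\n")
            fh.write("position\tA\tC\tG\tT\n")
            for i, row in enumerate(self.heptamer_weights):
                vals = "\t".join(f"{x:.6f}" for x in row)
                fh.write(f"{i}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, search_min: int = 15, search_max: int = 500):
        df = pd.read_csv(path, sep="\t", comment="#").sort_values("position")
        return cls(df[list(BASES)].to_numpy(), search_min, search_max, label=str(path))


# ---------------------------------------------------------------------------
# Atomic feature operations


def gc_content(seq: str) -> float | None:
    """(#G + #C) / (#A + #C + #G + #T); ambiguity codes are ignored entirely.

    Returns ``None`` for an all-ambiguous sequence; raises on an empty one.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    if gc + at == 0:
        return None
    return gc / (gc + at)


def donor_window(construct: EIEIEConstruct, exon: str) -> str | None:
    """9-mer at an exon's 3' boundary: last 3 exonic + first 6 intronic nt."""
    if construct.sequences is None:
        raise ValueError("construct sequences not extracted")
    if exon == "upstream":
        exon_seq, intron_seq = construct.sequences["exon_up"], construct.sequences["intron_up"]
    elif exon == "central":
        exon_seq, intron_seq = construct.sequences["central_exon"], construct.sequences["intron_down"]
    else:
        raise ValueError(f"no donor window for exon {exon!r}")
    if len(exon_seq) < DONOR_EXONIC or len(intron_seq) < DONOR_INTRONIC:
        return None
    return exon_seq[-DONOR_EXONIC:] + intron_seq[:DONOR_INTRONIC]


def acceptor_window(construct: EIEIEConstruct, exon: str) -> str | None:
    """23-mer at an exon's 5' boundary: last 20 intronic + first 3 exonic nt."""
    if construct.sequences is None:
        raise ValueError("construct sequences not extracted")
    if exon == "central":
        intron_seq, exon_seq = construct.sequences["intron_up"], construct.sequences["central_exon"]
    elif exon == "downstream":
        intron_seq, exon_seq = construct.sequences["intron_down"], construct.sequences["exon_down"]
    else:
        raise ValueError(f"no acceptor window for exon {exon!r}")
    if len(intron_seq) < ACCEPTOR_INTRONIC or len(exon_seq) < ACCEPTOR_EXONIC:
        return None
    return intron_seq[-ACCEPTOR_INTRONIC:] + exon_seq[:ACCEPTOR_EXONIC]


def score_site(window: str, model: SpliceSiteModel, kind: str) -> float | None:
    """Sum of per-position weights; ``None`` for windows with ambiguity codes."""
    if kind == "donor":
        weights = model.donor_weights
    elif kind == "acceptor":
        weights = model.acceptor_weights
    else:
        raise ValueError(f"kind must be donor or acceptor, got {kind!r}")
    window = window.upper()
    if len(window) != weights.shape[0]:
        raise ValueError(
            f"{kind} window length {len(window)} does not match model "
            f"({weights.shape[0]})"
        )
    total = 0.0
    for i, base in enumerate(window):
        j = BASE_INDEX.get(base)
        if j is None:
            return None
        total += weights[i, j]
    return total


def score_heptamer(heptamer: str, model: BranchPointModel) -> float | None:
    if len(heptamer) != BRANCH_HEPTAMER_LEN:
        raise ValueError("heptamer must have length 7")
    total = 0.0
    for i, base in enumerate(heptamer.upper()):
        j = BASE_INDEX.get(base)
        if j is None:
            return None
        total += model.heptamer_weights[i, j]
    return total


def find_branch_point(
    intron_seq: str, model: BranchPointModel
) -> tuple[int, float] | None:
    """Best-scoring candidate branch adenosine in the 3' search window.

    Candidates are As whose 1-based distance d from the intron 3' end lies
    in [search_min, search_max] and whose heptamer (5 nt upstream of the A,
    the A, 1 nt downstream) fits inside the intron. Ties go to the smallest
    d; returns ``None`` when no candidate exists.
    """
    seq = intron_seq.upper()
    L = len(seq)
    best: tuple[int, float] | None = None
    d_hi = min(model.search_max, L - BRANCH_A_POS)
    for d in range(model.search_min, d_hi + 1):
        i = L - d  # 0-based index of the candidate A
        if i + (BRANCH_HEPTAMER_LEN - 1 - BRANCH_A_POS) > L - 1:
            continue
        if seq[i] != "A":
            continue
        hept = seq[i - BRANCH_A_POS : i - BRANCH_A_POS + BRANCH_HEPTAMER_LEN]
        score = score_heptamer(hept, model)
        if score is None:
            continue
        if best is None or score > best[1]:
            best = (d, score)
    return best


# ---------------------------------------------------------------------------
# Default models


def _log_odds(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=1, keepdims=True)
    return np.log2(probs / 0.25)


def train_splice_site_model(
    annotation: GenomeAnnotation, pseudocount: float = 1.0
) -> SpliceSiteModel:
    """First-order PWM trained on every annotated junction of the annotation.

    For each transcript, each exon/intron boundary contributes its donor
    9-mer and each intron/exon boundary its acceptor 23-mer (windows that
    run past a short part, or contain ambiguity codes, are skipped).
    """
    donor_counts = np.zeros((DONOR_WINDOW_LEN, 4))
    acceptor_counts = np.zeros((ACCEPTOR_WINDOW_LEN, 4))

    def tally(window: str | None, counts: np.ndarray) -> None:
        if window is None:
            return
        idx = [BASE_INDEX.get(b) for b in window]
        if any(j is None for j in idx):
            return
        for i, j in enumerate(idx):
            counts[i, j] += 1

    for gene, tx in annotation.transcripts():
        exon_seqs = [
            annotation.fetch(gene.contig, s, e, gene.strand) for s, e in tx.exons
        ]
        intron_seqs = [
            annotation.fetch(gene.contig, iv[0], iv[1], gene.strand)
            for iv in tx.introns()
        ]
        for k, intron in enumerate(intron_seqs):
            ex5, ex3 = exon_seqs[k], exon_seqs[k + 1]
            if len(ex5) >= DONOR_EXONIC and len(intron) >= DONOR_INTRONIC:
                tally(ex5[-DONOR_EXONIC:] + intron[:DONOR_INTRONIC], donor_counts)
            if len(intron) >= ACCEPTOR_INTRONIC and len(ex3) >= ACCEPTOR_EXONIC:
                tally(intron[-ACCEPTOR_INTRONIC:] + ex3[:ACCEPTOR_EXONIC], acceptor_counts)

    return SpliceSiteModel(
        donor_weights=_log_odds(donor_counts, pseudocount),
        acceptor_weights=_log_odds(acceptor_counts, pseudocount),
        label="trained-on-annotation",
    )


#: Branch-point consensus used by the default caller: a TACTAAC-like box
#: with the branch A at heptamer position 6.
BRANCH_CONSENSUS = "TACTAAC"


def default_branch_point_model(
    consensus_prob: float = 0.85, search_min: int = 15, search_max: int = 500
) -> BranchPointModel:
    weights = np.zeros((BRANCH_HEPTAMER_LEN, 4))
    for i, base in enumerate(BRANCH_CONSENSUS):
        p = np.full(4, (1 - consensus_prob) / 3)
        p[BASE_INDEX[base]] = consensus_prob
        weights[i] = np.log2(p / 0.25)
    return BranchPointModel(weights, search_min, search_max, label="consensus-heptamer")


# ---------------------------------------------------------------------------
# Composition


def compute_features(
    construct: EIEIEConstruct,
    ss_model: SpliceSiteModel,
    bp_model: BranchPointModel,
) -> FeatureVector:
    """All 14 features for one sequence-extracted construct.

    Absent values (short parts, ambiguity codes, no branch-point candidate)
    propagate as ``None``; valid constructs never raise.
    """
    if construct.sequences is None:
        raise ValueError("construct sequences not extracted")
    seqs = construct.sequences
    fv = FeatureVector(construct_id=construct.construct_id, origin=construct.origin)
    fv.central_exon_len = construct.part_length("central_exon")
    fv.upstream_exon_len = construct.part_length("exon_up")
    fv.downstream_exon_len = construct.part_length("exon_down")
    fv.upstream_intron_len = construct.part_length("intron_up")
    fv.downstream_intron_len = construct.part_length("intron_down")
    fv.central_exon_gc = gc_content(seqs["central_exon"])
    fv.upstream_intron_gc = gc_content(seqs["intron_up"])
    fv.downstream_intron_gc = gc_content(seqs["intron_down"])

    for attr, intron in (
        ("upstream_bps_3ss_dist", "intron_up"),
        ("downstream_bps_3ss_dist", "intron_down"),
    ):
        hit = find_branch_point(seqs[intron], bp_model)
        setattr(fv, attr, float(hit[0]) if hit is not None else None)

    for attr, window, kind in (
        ("central_donor_score", donor_window(construct, "central"), "donor"),
        ("central_acceptor_score", acceptor_window(construct, "central"), "acceptor"),
        ("upstream_donor_score", donor_window(construct, "upstream"), "donor"),
        ("downstream_acceptor_score", acceptor_window(construct, "downstream"), "acceptor"),
    ):
        setattr(fv, attr, score_site(window, ss_model, kind) if window else None)
    return fv


def features_to_frame(fvs: list[FeatureVector]) -> pd.DataFrame:
    """One row per construct; absent values become NA."""
    rows = []
    for fv in fvs:
        row = {"construct_id": fv.construct_id, "origin": fv.origin}
        for name in FEATURE_NAMES:
            v = getattr(fv, name)
            row[name] = np.nan if v is None else v
        rows.append(row)
    return pd.DataFrame(rows, columns=["construct_id", "origin", *FEATURE_NAMES])
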