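"""Self-contained synthetic inputs with planted ground truth.

Generates a genome FASTA, Gencode-style GTF, MANE-style transcript list,
five rMATS-style event tables, a gene x sample expression matrix, a DEG
table and qPCR records, together with a truth manifest recording every
planted effect, so each pipeline stage can be tested against known truth.

Planted structure:

* every splice junction carries a donor/acceptor motif sampled from a
  consensus-sharp ("strong") or flattened ("weak") per-position
  distribution — weak motifs are planted at the central exon boundaries of
  event windows;
* every intron carries the exact branch-point consensus heptamer at a
  planted 3'SS offset (other exact occurrences inside the search window are
  scrubbed, so the planted adenosine is the unique top-scoring candidate);
* event windows get a shortened central exon, lengthened flanking introns,
  doubled branch-point offsets and optionally GC-shifted central exons;
* decoy genes (mitochondrial, MANE-less, differentially spliced) sit at the
  top of the expression ranking so the external-control filters are
  genuinely exercised;
* the DEG table realizes a configured (n_up, n_down, n_null) plan and the
  expression matrix carries matching group shifts, epithelial/mesenchymal
  marker profiles per group, and highly expressed mitochondrial genes.

Everything is driven by integer-seeded per-gene substreams, so outputs are
byte-identical across runs and platforms and independent of iteration
order.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Gene, GenomeAnnotation, Transcript, write_gtf
from .controls import ExpressionTable, ManeSet
from .features import (
    ACCEPTOR_INTRONIC,
    BRANCH_A_POS,
    BRANCH_CONSENSUS,
    DONOR_INTRONIC,
)

__all__ = [
    "SimConfig",
    "GeneTruth",
    "TruthManifest",
    "SimBundle",
    "generate_reference",
    "generate_event_tables",
    "generate_expression_and_degs",
    "generate_bundle",
    "null_config",
    "external_contract_config",
]

BASE_ARRAY = np.array(list("ACGT"))

#: Donor 9-mer consensus: 3 exonic + 6 intronic nt; GT is invariant.
DONOR_CONSENSUS = "CAGGTAAGT"
DONOR_FORCED = (3, 4)  # the intronic GT
#: Acceptor 23-mer consensus: 20 intronic (polypyrimidine + AG) + 3 exonic.
ACCEPTOR_CONSENSUS = "TTTTTTTTTTCTTTTTTCAGGTT"
ACCEPTOR_FORCED = (18, 19)  # the intronic AG

STRONG_CONSENSUS_PROB = 0.85

EPITHELIAL_PANEL = ("CDH1", "DSP", "OCLN", "ESRP1")
MESENCHYMAL_PANEL = ("CDH2", "VIM", "FOXC2", "ZEB1", "SOX10")

NUCLEAR_CONTIGS = ("chr1", "chr2", "chr3", "chr4")
MITO_CONTIG = "chrM"


@dataclass
class SimConfig:
    """Study conditions for the synthetic bundle.

    The effect multipliers describe how event windows differ from
    background: default values plant a halved central exon, tripled flanking
    introns, doubled branch-point offsets and flattened (weakened) splice
    sites at the central exon boundaries, with no GC shift.
    """

    seed: int = 0
    n_genes: int = 340            # nuclear genes
    n_event_genes: int = 200
    include_chrM_genes: int = 5   # extra genes on the mitochondrial contig
    n_no_mane_genes: int = 10     # highly expressed decoys without MANE match
    exons_per_gene: tuple[int, int] = (5, 9)
    exon_len_median: float = 150.0
    exon_len_sigma: float = 0.35
    intron_len_median: float = 1000.0
    intron_len_sigma: float = 0.5
    min_exon_len: int = 30
    min_intron_len: int = 120
    exon_gc: float = 0.48
    intron_gc: float = 0.42
    central_exon_len_factor: float = 0.5
    intron_len_factor: float = 3.0
    bp_dist_factor: float = 2.0
    splice_site_strength_shift: float = -2.0  # <0 plants weak central junctions
    exon_gc_shift: float = 0.0
    bp_offset_range: tuple[int, int] = (22, 45)
    n_samples_per_group: int = 3
    groups: tuple[str, ...] = ("patient", "mother", "control")
    deg_plan: tuple[int, int, int] = (346, 835, 2000)  # (n_up, n_down, n_null)

    def __post_init__(self) -> None:
        if self.n_event_genes > self.n_genes:
            raise ValueError("n_event_genes must be <= n_genes")
        if self.exons_per_gene[0] < 3:
            raise ValueError("event windows need at least 3 exons per gene")
        if self.exons_per_gene[0] > self.exons_per_gene[1]:
            raise ValueError("exons_per_gene range is degenerate")
        min_event_intron = int(self.min_intron_len * min(1.0, self.intron_len_factor))
        needed = ACCEPTOR_INTRONIC + DONOR_INTRONIC + len(BRANCH_CONSENSUS) + 2
        if min_event_intron < needed:
            raise ValueError(
                f"introns of length {min_event_intron} cannot hold the embedded "
                f"motifs (need >= {needed})"
            )
        for factor in (self.central_exon_len_factor, self.intron_len_factor, self.bp_dist_factor):
            if factor <= 0:
                raise ValueError("effect factors must be positive")
        if any(n < 0 for n in self.deg_plan):
            raise ValueError("deg_plan counts must be non-negative")


@dataclass
class GeneTruth:
    gene_id: str
    role: str                      # event-more-skipped | event-less-skipped | background | chrM
    contig: str
    strand: str
    n_exons: int
    event_window: int | None = None   # first exon index of the planted window
    bp_offsets: list[int] = field(default_factory=list)     # per intron, transcript order
    weak_junctions: list[list] = field(default_factory=list)  # [site, intron_index]
    deg_direction: str = "none"    # up | down | null | none
    has_mane: bool = True
    splice_classes: list[str] = field(default_factory=list)  # significant rMATS classes


@dataclass
class TruthManifest:
    genes: dict[str, GeneTruth] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {gid: asdict(t) for gid, t in sorted(self.genes.items())}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(genes={gid: GeneTruth(**rec) for gid, rec in payload.items()})

    def by_role(self, role: str) -> list[str]:
        return sorted(g for g, t in self.genes.items() if t.role == role)


@dataclass
class SimBundle:
    cfg: SimConfig
    genome: dict[str, str]
    annotation: GenomeAnnotation
    mane: ManeSet
    truth: TruthManifest
    event_tables: dict[str, pd.DataFrame] | None = None
    expression: ExpressionTable | None = None
    degs: pd.DataFrame | None = None
    qpcr: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every generated artifact as plain text files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        fasta = outdir / "genome.fa"
        with open(fasta, "w") as fh:
            for contig in sorted(self.genome):
                fh.write(f">{contig}\n")
                seq = self.genome[contig]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        paths["genome"] = fasta
        write_gtf(self.annotation, outdir / "annotation.gtf")
        paths["gtf"] = outdir / "annotation.gtf"
        self.mane.write_tsv(outdir / "mane.tsv")
        paths["mane"] = outdir / "mane.tsv"
        self.truth.to_json(outdir / "truth.json")
        paths["truth"] = outdir / "truth.json"
        if self.event_tables is not None:
            for cls_name, df in self.event_tables.items():
                p = outdir / f"{cls_name}.MATS.JC.txt"
                df.to_csv(p, sep="\t", index=False)
                paths[cls_name] = p
        if self.expression is not None:
            self.expression.write_tsv(outdir / "expression.tsv")
            paths["expression"] = outdir / "expression.tsv"
        if self.degs is not None:
            self.degs.to_csv(outdir / "degs.tsv", sep="\t", index=False)
            paths["degs"] = outdir / "degs.tsv"
        if self.qpcr is not None:
            self.qpcr.to_csv(outdir / "qpcr.csv", index=False)
            paths["qpcr"] = outdir / "qpcr.csv"
        return paths

    def sample_labels(self) -> list[str]:
        return [
            f"{g}_{i + 1}"
            for g in self.cfg.groups
            for i in range(self.cfg.n_samples_per_group)
        ]

    def sample_groups(self) -> dict[str, str]:
        return {
            f"{g}_{i + 1}": g
            for g in self.cfg.groups
            for i in range(self.cfg.n_samples_per_group)
        }


# ---------------------------------------------------------------------------
# Sequence-level helpers


def _gene_stream(cfg: SimConfig, tag: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, tag, index])
    )


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _sample_motif(
    rng: np.random.Generator,
    consensus: str,
    forced: tuple[int, ...],
    p_consensus: float,
) -> np.ndarray:
    """Draw a motif around a consensus; forced positions are invariant."""
    idx = np.empty(len(consensus), dtype=int)
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, base in enumerate(consensus):
        b = base_index[base]
        if i in forced or rng.random() < p_consensus:
            idx[i] = b
        else:
            others = [x for x in range(4) if x != b]
            idx[i] = others[int(rng.integers(3))]
    return idx


def _weak_prob(cfg: SimConfig) -> float:
    """Consensus probability of the weak motif class.

    The strength shift (in score table units, negative = weaker) flattens
    the sampling distribution: each unit shift multiplies the consensus
    probability by 2^-0.25, floored at the uniform 0.25.
    """
    return max(0.25, STRONG_CONSENSUS_PROB * 2.0 ** (0.25 * cfg.splice_site_strength_shift))


def _scrub_branch_duplicates(intron: np.ndarray, planted_a: int, search_min: int,
                             search_max: int) -> None:
    """Mutate the branch A of non-planted exact consensus occurrences."""
    seq = "".join(BASE_ARRAY[intron])
    L = len(seq)
    start = 0
    while True:
        hit = seq.find(BRANCH_CONSENSUS, start)
        if hit < 0:
            break
        a_idx = hit + BRANCH_A_POS
        d = L - a_idx
        if a_idx != planted_a and search_min <= d <= search_max + 10:
            intron[a_idx] = 2  # A -> G kills the candidate
        start = hit + 1


# ---------------------------------------------------------------------------
# Reference generation


def _assign_roles(cfg: SimConfig) -> list[str]:
    roles = []
    for i in range(cfg.n_genes):
        if i < cfg.n_event_genes:
            roles.append("event-more-skipped" if i % 2 == 0 else "event-less-skipped")
        else:
            roles.append("background")
    roles.extend(["chrM"] * cfg.include_chrM_genes)
    return roles


def generate_reference(cfg: SimConfig) -> SimBundle:
    """Genome, annotation, MANE set and truth manifest.

    Each gene gets one protein-coding transcript with a TSL and a versioned
    id (designated MANE unless the gene is a MANE-less decoy); a subset of
    genes get extra transcripts (a shorter protein-coding one, or a
    non-coding one without TSL) to exercise reference-transcript selection.
    """
    roles = _assign_roles(cfg)
    weak_p = _weak_prob(cfg)
    plant_weak = cfg.splice_site_strength_shift < 0

    # MANE-less decoys are the last background genes.
    background_idx = [i for i, r in enumerate(roles) if r == "background"]
    no_mane = set(background_idx[-cfg.n_no_mane_genes:]) if cfg.n_no_mane_genes else set()

    contig_parts: dict[str, list[str]] = {c: [] for c in (*NUCLEAR_CONTIGS, MITO_CONTIG)}
    contig_cursor: dict[str, int] = {c: 0 for c in contig_parts}
    genes: list[Gene] = []
    mane_entries: list[tuple[str, int]] = []
    truth = TruthManifest()

    for idx, role in enumerate(roles):
        rng = _gene_stream(cfg, 10, idx)
        gene_id = f"SIMG{idx:05d}"
        contig = MITO_CONTIG if role == "chrM" else NUCLEAR_CONTIGS[idx % len(NUCLEAR_CONTIGS)]
        strand = "+" if idx % 2 == 0 else "-"
        lo, hi = cfg.exons_per_gene
        n_exons = int(rng.integers(lo, hi + 1))

        exon_lens = np.maximum(
            cfg.min_exon_len,
            np.round(rng.lognormal(math.log(cfg.exon_len_median), cfg.exon_len_sigma, n_exons)),
        ).astype(int)
        intron_lens = np.maximum(
            cfg.min_intron_len,
            np.round(rng.lognormal(math.log(cfg.intron_len_median), cfg.intron_len_sigma, n_exons - 1)),
        ).astype(int)
        exon_gcs = np.full(n_exons, cfg.exon_gc)

        event_window: int | None = None
        weak_junctions: list[list] = []
        is_event = role.startswith("event")
        if is_event:
            event_window = int(rng.integers(0, n_exons - 2))
            central = event_window + 1
            exon_lens[central] = max(
                12, int(round(exon_lens[central] * cfg.central_exon_len_factor))
            )
            for j in (event_window, event_window + 1):  # flanking introns
                intron_lens[j] = int(round(intron_lens[j] * cfg.intron_len_factor))
            exon_gcs[central] = min(0.95, max(0.05, cfg.exon_gc + cfg.exon_gc_shift))
            if plant_weak:
                # central exon's acceptor (end of intron_up) and donor
                # (start of intron_down)
                weak_junctions = [["acceptor", event_window], ["donor", event_window + 1]]

        bp_offsets: list[int] = []
        for j, intron_len in enumerate(intron_lens):
            d = int(rng.integers(cfg.bp_offset_range[0], cfg.bp_offset_range[1] + 1))
            if is_event and j in (event_window, event_window + 1):
                d = int(round(d * cfg.bp_dist_factor))
            d = min(d, 500, int(intron_len) - (len(BRANCH_CONSENSUS) - BRANCH_A_POS))
            bp_offsets.append(d)

        # --- assemble the gene in transcript orientation -------------------
        weak_set = {tuple(w) for w in weak_junctions}
        exon_arrs = [_random_seq(rng, int(n), float(g)) for n, g in zip(exon_lens, exon_gcs)]
        intron_arrs = [_random_seq(rng, int(n), cfg.intron_gc) for n in intron_lens]
        for j in range(n_exons - 1):
            donor_p = weak_p if ("donor", j) in weak_set else STRONG_CONSENSUS_PROB
            acceptor_p = weak_p if ("acceptor", j) in weak_set else STRONG_CONSENSUS_PROB
            donor = _sample_motif(rng, DONOR_CONSENSUS, DONOR_FORCED, donor_p)
            acceptor = _sample_motif(rng, ACCEPTOR_CONSENSUS, ACCEPTOR_FORCED, acceptor_p)
            exon_arrs[j][-3:] = donor[:3]
            intron_arrs[j][:DONOR_INTRONIC] = donor[3:]
            intron_arrs[j][-ACCEPTOR_INTRONIC:] = acceptor[:ACCEPTOR_INTRONIC]
            exon_arrs[j + 1][:3] = acceptor[ACCEPTOR_INTRONIC:]
            # branch-point heptamer at the planted offset
            L = len(intron_arrs[j])
            a_idx = L - bp_offsets[j]
            hept = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in BRANCH_CONSENSUS])
            intron_arrs[j][a_idx - BRANCH_A_POS : a_idx - BRANCH_A_POS + len(hept)] = hept
            _scrub_branch_duplicates(intron_arrs[j], a_idx, 15, 500)

        parts = []
        for j in range(n_exons):
            parts.append(exon_arrs[j])
            if j < n_exons - 1:
                parts.append(intron_arrs[j])
        gene_arr = np.concatenate(parts)
        gene_len = len(gene_arr)

        # transcript-orientation offsets of exons within the gene
        offsets = []
        pos = 0
        for j in range(n_exons):
            offsets.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])

        gene_seq = "".join(BASE_ARRAY[gene_arr])
        if strand == "-":
            comp = str.maketrans("ACGT", "TGCA")
            gene_seq = gene_seq.translate(comp)[::-1]

        origin = contig_cursor[contig]
        spacer = "".join(BASE_ARRAY[_random_seq(rng, 200, 0.40)])
        contig_parts[contig].append(gene_seq + spacer)
        contig_cursor[contig] += gene_len + 200

        if strand == "+":
            exons = [(origin + s, origin + e) for s, e in offsets]
        else:
            exons = [(origin + gene_len - e, origin + gene_len - s) for s, e in offsets]

        version = int(rng.integers(1, 10))
        tsl = int(rng.integers(1, 6))
        tx_base = f"SIMT{idx:05d}"
        primary = Transcript(
            transcript_id=f"{tx_base}.{version}",
            contig=contig,
            strand=strand,
            transcript_type="protein_coding",
            version=version,
            tsl=tsl,
            exons=tuple(sorted(exons)),
        )
        transcripts = [primary]
        if idx % 6 == 3 and n_exons >= 4:
            # shorter protein-coding alternative with TSL
            transcripts.append(
                Transcript(
                    transcript_id=f"{tx_base}B.1",
                    contig=contig,
                    strand=strand,
                    transcript_type="protein_coding",
                    version=1,
                    tsl=int(rng.integers(1, 6)),
                    exons=tuple(sorted(exons)[1:]),
                )
            )
        if idx % 7 == 2:
            # non-coding transcript without a TSL
            transcripts.append(
                Transcript(
                    transcript_id=f"{tx_base}N.1",
                    contig=contig,
                    strand=strand,
                    transcript_type="processed_transcript",
                    version=1,
                    tsl=None,
                    exons=tuple(sorted(exons)[:2]),
                )
            )
        gene = Gene(
            gene_id=gene_id,
            contig=contig,
            strand=strand,
            gene_type="protein_coding",
            gene_symbol=f"SYM{idx:05d}",
            transcripts=transcripts,
        )
        genes.append(gene)
        if idx not in no_mane:
            mane_entries.append((tx_base, version))

        truth.genes[gene_id] = GeneTruth(
            gene_id=gene_id,
            role=role,
            contig=contig,
            strand=strand,
            n_exons=n_exons,
            event_window=event_window,
            bp_offsets=bp_offsets,
            weak_junctions=weak_junctions,
            has_mane=idx not in no_mane,
        )

    genome = {c: "".join(parts) for c, parts in contig_parts.items() if parts}
    contig_lengths = {c: len(s) for c, s in genome.items()}

    def seq_source(contig: str, start: int, end: int) -> str:
        return genome[contig][start:end]

    annotation = GenomeAnnotation(
        genes, sequence_source=seq_source, contig_lengths=contig_lengths
    )
    return SimBundle(
        cfg=cfg,
        genome=genome,
        annotation=annotation,
        mane=ManeSet(mane_entries),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Event tables


def _format_p(rng: np.random.Generator, significant: bool) -> tuple[float, float]:
    if significant:
        p = 10.0 ** rng.uniform(-6, math.log10(0.035))
        fdr = min(0.049, p * (1.0 + rng.uniform(0.0, 2.0)))
    else:
        p = rng.uniform(0.05, 0.95)
        fdr = min(0.999, p * (1.0 + rng.uniform(0.0, 1.0)))
    return p, fdr


def _se_window_coords(tx: Transcript, window: int) -> dict[str, int]:
    """rMATS SE coordinate columns for a 3-exon window (genomic upstream =
    leftmost exon)."""
    trio = sorted(tx.exons[window : window + 3])
    up, mid, down = trio
    return {
        "exonStart_0base": mid[0],
        "exonEnd": mid[1],
        "upstreamES": up[0],
        "upstreamEE": up[1],
        "downstreamES": down[0],
        "downstreamEE": down[1],
    }


def generate_event_tables(cfg: SimConfig, bundle: SimBundle) -> dict[str, pd.DataFrame]:
    """rMATS-style tables for the five classes.

    Every event gene contributes one significant SE row at its planted
    window (inclusion difference negative for more-skipped genes, with the
    patient as sample 1); half of the background genes contribute
    non-significant SE rows, some failing only the FDR half of the filter.
    Small A3SS/A5SS/MXE/RI tables mark a few background genes significant
    (external-control decoys) and give the first event genes an extra RI
    event to exercise multi-class tallies. A couple of rows carry "NA"
    inclusion differences to exercise the reader's drop policy.
    """
    rng = _gene_stream(cfg, 20)
    rows: dict[str, list[dict]] = {c: [] for c in ("SE", "A3SS", "A5SS", "MXE", "RI")}

    def base_row(gene: Gene, p: float, fdr: float, ild) -> dict:
        return {
            "GeneID": gene.gene_id,
            "geneSymbol": gene.gene_symbol,
            "chr": gene.contig,
            "strand": gene.strand,
            "PValue": round(p, 10),
            "FDR": round(fdr, 10),
            "IncLevelDifference": ild,
        }

    background = bundle.truth.by_role("background")
    multi_class = bundle.truth.by_role("event-more-skipped")[:3]

    for gid in sorted(bundle.truth.genes):
        t = bundle.truth.genes[gid]
        gene = bundle.annotation.genes[gid]
        tx = gene.transcripts[0]
        if t.role.startswith("event"):
            p, fdr = _format_p(rng, True)
            mag = rng.uniform(0.1, 0.6)
            ild = -mag if t.role == "event-more-skipped" else mag
            row = base_row(gene, p, fdr, round(ild, 4))
            row.update(_se_window_coords(tx, t.event_window))
            rows["SE"].append(row)
            t.splice_classes.append("SE")

    # non-significant SE background rows (half the background genes)
    for k, gid in enumerate(background):
        if k % 2:
            continue
        gene = bundle.annotation.genes[gid]
        tx = gene.transcripts[0]
        window = int(rng.integers(0, max(1, tx.n_exons - 2)))
        if k % 6 == 0:
            p = rng.uniform(0.001, 0.049)  # passes p, fails FDR
            fdr = rng.uniform(0.05, 0.95)
        else:
            p, fdr = _format_p(rng, False)
        row = base_row(gene, p, fdr, round(rng.uniform(-0.05, 0.05), 4))
        row.update(_se_window_coords(tx, window))
        rows["SE"].append(row)

    # two unparseable SE rows (NA inclusion difference)
    for gid in background[1:3]:
        gene = bundle.annotation.genes[gid]
        tx = gene.transcripts[0]
        row = base_row(gene, 0.5, 0.6, "NA")
        row.update(_se_window_coords(tx, 0))
        rows["SE"].append(row)

    # decoy genes significant in the other four classes
    other_classes = ("A3SS", "A5SS", "MXE", "RI")
    decoy_pool = [g for k, g in enumerate(background) if k % 2 == 1]
    for ci, cls_name in enumerate(other_classes):
        decoys = decoy_pool[ci * 5 : ci * 5 + 5]
        extra = multi_class if cls_name == "RI" else []
        for gid in [*decoys, *extra]:
            t = bundle.truth.genes[gid]
            gene = bundle.annotation.genes[gid]
            tx = gene.transcripts[0]
            p, fdr = _format_p(rng, True)
            row = base_row(gene, p, fdr, round(rng.uniform(-0.5, 0.5), 4))
            exons = sorted(tx.exons)
            if cls_name in ("A3SS", "A5SS"):
                row.update({
                    "longExonStart_0base": exons[1][0], "longExonEnd": exons[1][1],
                    "shortES": exons[1][0] + 9, "shortEE": exons[1][1],
                    "flankingES": exons[0][0], "flankingEE": exons[0][1],
                })
            elif cls_name == "MXE":
                row.update({
                    "1stExonStart_0base": exons[1][0], "1stExonEnd": exons[1][1],
                    "2ndExonStart_0base": exons[2][0], "2ndExonEnd": exons[2][1],
                    "upstreamES": exons[0][0], "upstreamEE": exons[0][1],
                    "downstreamES": exons[3][0], "downstreamEE": exons[3][1],
                })
            else:  # RI: retained intron spans exon1..exon2
                row.update({
                    "riExonStart_0base": exons[0][0], "riExonEnd": exons[1][1],
                    "upstreamES": exons[0][0], "upstreamEE": exons[0][1],
                    "downstreamES": exons[1][0], "downstreamEE": exons[1][1],
                })
            rows[cls_name].append(row)
            t.splice_classes.append(cls_name)

    tables = {}
    for cls_name, cls_rows in rows.items():
        df = pd.DataFrame(cls_rows)
        df.insert(0, "ID", range(len(df)))
        tables[cls_name] = df
    bundle.event_tables = tables
    return tables


# ---------------------------------------------------------------------------
# Expression, DEGs, qPCR


def generate_expression_and_degs(
    cfg: SimConfig, bundle: SimBundle
) -> tuple[ExpressionTable, pd.DataFrame, pd.DataFrame]:
    """Expression matrix, DEG table and qPCR records with planted structure.

    Mitochondrial genes, MANE-less decoys and event genes are given the
    highest baseline abundances so every external-control exclusion filter
    removes at least one top-ranked gene. The DEG plan assigns the first
    plan genes up/down log2 fold changes with adjusted p < 0.05 (padding
    with synthetic filler ids when the plan exceeds the gene count); the
    expression matrix carries matching patient-vs-rest shifts. Marker-panel
    genes get epithelial-high profiles in the patient group and
    mesenchymal-high profiles in the control group.
    """
    rng = _gene_stream(cfg, 30)
    samples = bundle.sample_labels()
    groups = bundle.sample_groups()
    gene_ids = sorted(bundle.truth.genes)

    n_up, n_down, n_null = cfg.deg_plan
    nuclear = [g for g in gene_ids if bundle.truth.genes[g].role != "chrM"]
    deg_gene_ids = list(nuclear)
    n_pad = max(0, n_up + n_down + n_null - len(deg_gene_ids))
    deg_gene_ids += [f"SIMPAD{i:05d}" for i in range(n_pad)]

    deg_rows = []
    lfc_by_gene: dict[str, float] = {}
    for k, gid in enumerate(deg_gene_ids[: n_up + n_down + n_null]):
        if k < n_up:
            direction, lfc = "up", rng.uniform(0.5, 3.0)
            padj = 10.0 ** rng.uniform(-8, math.log10(0.049))
        elif k < n_up + n_down:
            direction, lfc = "down", -rng.uniform(0.5, 3.0)
            padj = 10.0 ** rng.uniform(-8, math.log10(0.049))
        else:
            direction, lfc = "null", rng.normal(0.0, 0.3)
            padj = rng.uniform(0.05, 1.0)
        deg_rows.append(
            {"gene_id": gid, "log2FoldChange": round(float(lfc), 4),
             "padj": round(float(padj), 10)}
        )
        if gid in bundle.truth.genes:
            bundle.truth.genes[gid].deg_direction = direction
        if direction in ("up", "down"):
            lfc_by_gene[gid] = float(lfc)
    degs = pd.DataFrame(deg_rows)

    # --- abundance matrix ------------------------------------------------
    n_samples = len(samples)
    data = {}
    for gid in gene_ids:
        t = bundle.truth.genes[gid]
        if t.role == "chrM":
            base = rng.uniform(30000, 60000)
        elif not t.has_mane:
            base = rng.uniform(15000, 25000)
        elif t.role.startswith("event"):
            base = rng.uniform(5000, 12000)
        else:
            base = rng.lognormal(math.log(200), 1.0)
        noise = rng.lognormal(0.0, 0.2, n_samples)
        vals = base * noise
        lfc = lfc_by_gene.get(gid)
        if lfc is not None:
            shift = 2.0 ** lfc
            vals = np.array([
                v * shift if groups[s] == "patient" else v
                for v, s in zip(vals, samples)
            ])
        data[gid] = np.round(vals, 3)

    # marker-panel profiles: patient epithelial, control mesenchymal
    panel_levels = {
        "patient": {"epi": 200.0, "mes": 10.0},
        "mother": {"epi": 25.0, "mes": 100.0},
        "control": {"epi": 20.0, "mes": 160.0},
    }
    for gene_set, key in ((EPITHELIAL_PANEL, "epi"), (MESENCHYMAL_PANEL, "mes")):
        for sym in gene_set:
            vals = [
                panel_levels.get(groups[s], {"epi": 50.0, "mes": 50.0})[key]
                * rng.lognormal(0.0, 0.1)
                for s in samples
            ]
            data[sym] = np.round(vals, 3)

    expr = ExpressionTable(pd.DataFrame(data, index=samples).T.astype(float))

    # --- qPCR records -----------------------------------------------------
    qpcr_rows = []
    calibrator = f"{cfg.groups[-1]}_1"
    planted_ddct = {"TARGET_DOWN": 2.0, "TARGET_UP": -1.0}
    for target, ddct in planted_ddct.items():
        ref_cal = 18.0 + rng.normal(0, 0.05)
        tgt_cal = 24.0 + rng.normal(0, 0.05)
        for s in samples:
            is_cal = int(s == calibrator)
            shift = 0.0 if groups[s] != "patient" else ddct
            qpcr_rows.append({
                "sample": s,
                "target_gene": target,
                "reference_gene": "ACTB",
                "ct_target": round(tgt_cal + shift + rng.normal(0, 0.03), 3),
                "ct_reference": round(ref_cal + rng.normal(0, 0.03), 3),
                "is_calibrator": is_cal,
            })
    qpcr = pd.DataFrame(qpcr_rows)

    bundle.expression = expr
    bundle.degs = degs
    bundle.qpcr = qpcr
    return expr, degs, qpcr


def generate_bundle(cfg: SimConfig, outdir: str | Path | None = None) -> SimBundle:
    """Full bundle: reference + event tables + expression/DEG/qPCR."""
    bundle = generate_reference(cfg)
    generate_event_tables(cfg, bundle)
    generate_expression_and_degs(cfg, bundle)
    if outdir is not None:
        bundle.write(outdir)
    return bundle


# ---------------------------------------------------------------------------
# Named study conditions


def null_config(seed: int = 0) -> SimConfig:
    """No planted effects; used for type-I-error calibration."""
    return SimConfig(
        seed=seed,
        n_genes=130,
        n_event_genes=50,
        central_exon_len_factor=1.0,
        intron_len_factor=1.0,
        bp_dist_factor=1.0,
        splice_site_strength_shift=0.0,
        exon_gc_shift=0.0,
        deg_plan=(20, 30, 50),
    )


def external_contract_config(seed: int = 0) -> SimConfig:
    """Enough eligible genes to select 2000 external controls, plus decoys."""
    return SimConfig(
        seed=seed,
        n_genes=2160,
        n_event_genes=50,
        include_chrM_genes=5,
        n_no_mane_genes=20,
        exons_per_gene=(4, 7),
        deg_plan=(50, 80, 200),
    )
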