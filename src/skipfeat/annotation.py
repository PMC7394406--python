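"""Genome annotation model and E-I-E-I-E construct geometry.

Internal coordinates are always 0-based half-open on the forward genomic
strand (the rMATS ``exonStart_0base`` convention). GTF input/output uses the
standard 1-based inclusive convention. Exon lists inside a
:class:`Transcript` are ordered 5'->3' in transcript orientation, i.e. by
descending genomic position on the minus strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import gffutils
import pyfaidx
from Bio.Seq import reverse_complement

__all__ = [
    "Interval",
    "Transcript",
    "Gene",
    "GenomeAnnotation",
    "EIEIEConstruct",
    "PART_NAMES",
    "load_annotation",
    "select_reference_transcript",
    "enumerate_constructs",
    "extract_sequences",
    "write_gtf",
    "write_constructs_tsv",
    "write_constructs_fasta",
]

Interval = tuple[int, int]  # 0-based half-open genomic interval

#: Construct part names, 5'->3' in transcript orientation.
PART_NAMES = ("exon_up", "intron_up", "central_exon", "intron_down", "exon_down")


def interval_length(iv: Interval) -> int:
    return iv[1] - iv[0]


def intervals_intersect(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


@dataclass(frozen=True)
class Transcript:
    """An exon chain on one strand of one contig.

    ``exons`` are 0-based half-open genomic intervals ordered 5'->3' in
    transcript orientation (descending genomic coordinate on the minus
    strand). ``version`` is the trailing ``.N`` of a versioned transcript id
    when present; ``tsl`` is the Gencode transcript support level (1-5) or
    ``None`` when the attribute is absent or "NA".
    """

    transcript_id: str
    contig: str
    strand: str
    transcript_type: str = "protein_coding"
    version: int | None = None
    tsl: int | None = None
    exons: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        genomic = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(genomic, genomic[1:]):
            if e0 > s1:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
            if s1 - e0 < 1:
                raise ValueError(
                    f"zero-length intron in transcript {self.transcript_id}"
                )
        expected = tuple(genomic) if self.strand == "+" else tuple(genomic[::-1])
        if tuple(self.exons) != expected:
            object.__setattr__(self, "exons", expected)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> Interval:
        genomic = sorted(self.exons)
        return (genomic[0][0], genomic[-1][1])

    def introns(self) -> list[Interval]:
        """Intron intervals, 5'->3' in transcript orientation."""
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e0, s1))
            else:
                out.append((e1, s0))
        return out


@dataclass
class Gene:
    gene_id: str
    contig: str
    strand: str
    gene_type: str = "protein_coding"
    gene_symbol: str = ""
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.contig != self.contig or t.strand != self.strand:
                raise ValueError(
                    f"transcript {t.transcript_id} disagrees with gene "
                    f"{self.gene_id} on contig/strand"
                )


SequenceSource = Callable[[str, int, int], str]
"""Resolves (contig, start, end) -> forward-strand nucleotide string."""


class GenomeAnnotation:
    """Genes plus a handle onto the genome sequence.

    ``sequence_source`` maps a forward-strand 0-based half-open interval to
    its nucleotide string; :meth:`fetch` adds strand handling on top.
    """

    def __init__(
        self,
        genes: Iterable[Gene],
        sequence_source: SequenceSource | None = None,
        contig_lengths: dict[str, int] | None = None,
    ):
        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self.sequence_source = sequence_source
        self.contig_lengths = contig_lengths or {}

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        if self.sequence_source is None:
            raise ValueError("annotation has no sequence source attached")
        if start < 0 or (
            contig in self.contig_lengths and end > self.contig_lengths[contig]
        ):
            raise ValueError(
                f"interval [{start},{end}) out of bounds on contig {contig}"
            )
        seq = self.sequence_source(contig, start, end).upper()
        if strand == "-":
            seq = reverse_complement(seq)
        return seq

    def transcripts(self) -> Iterator[tuple[Gene, Transcript]]:
        for g in self:
            for t in g.transcripts:
                yield g, t


@dataclass
class EIEIEConstruct:
    """Three consecutive exons plus the two intervening introns.

    ``parts`` maps :data:`PART_NAMES` (5'->3' in transcript orientation) to
    genomic intervals; on the minus strand ``exon_up`` is therefore the
    genomically rightmost part. ``sequences`` (filled by
    :func:`extract_sequences`) are uppercase and read 5'->3' in transcript
    orientation.
    """

    gene_id: str
    origin: str  # event | internal_control | external_control
    contig: str
    strand: str
    parts: dict[str, Interval]
    sequences: dict[str, str] | None = None
    construct_id: str = ""

    def __post_init__(self) -> None:
        missing = [p for p in PART_NAMES if p not in self.parts]
        if missing:
            raise ValueError(f"construct missing parts {missing}")
        ivs = sorted(self.parts.values())
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if e0 != s1:
                raise ValueError("construct parts are not contiguous")
        for intron in ("intron_up", "intron_down"):
            if interval_length(self.parts[intron]) < 1:
                raise ValueError(f"{intron} has length < 1")
        if not self.construct_id:
            s, e = self.span
            self.construct_id = f"{self.gene_id}|{self.origin}|{self.contig}:{s}-{e}"

    @property
    def span(self) -> Interval:
        ivs = sorted(self.parts.values())
        return (ivs[0][0], ivs[-1][1])

    def part_length(self, name: str) -> int:
        return interval_length(self.parts[name])

    @classmethod
    def from_exon_triplet(
        cls,
        gene_id: str,
        contig: str,
        strand: str,
        exons_5to3: Sequence[Interval],
        origin: str,
    ) -> "EIEIEConstruct":
        """Build from three exon intervals given 5'->3' in transcript order."""
        if len(exons_5to3) != 3:
            raise ValueError("need exactly three exons")
        e_up, e_mid, e_down = exons_5to3
        if strand == "+":
            i_up = (e_up[1], e_mid[0])
            i_down = (e_mid[1], e_down[0])
        else:
            i_up = (e_mid[1], e_up[0])
            i_down = (e_down[1], e_mid[0])
        parts = {
            "exon_up": tuple(e_up),
            "intron_up": i_up,
            "central_exon": tuple(e_mid),
            "intron_down": i_down,
            "exon_down": tuple(e_down),
        }
        return cls(gene_id=gene_id, origin=origin, contig=contig, strand=strand, parts=parts)


# ---------------------------------------------------------------------------
# GTF reading


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_version(transcript_id: str) -> tuple[str, int | None]:
    if "." in transcript_id:
        base, _, tail = transcript_id.rpartition(".")
        if tail.isdigit():
            return base, int(tail)
    return transcript_id, None


def _parse_tsl(raw: str | None) -> int | None:
    if raw is None:
        return None
    tok = raw.strip().split()[0] if raw.strip() else ""
    if tok.isdigit():
        level = int(tok)
        if 1 <= level <= 5:
            return level
    return None


def _validate_gtf(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
            if fields[2] in ("gene", "transcript", "exon") and not _ATTR_RE.search(
                fields[8]
            ):
                raise ValueError(
                    f"{path}:{lineno}: malformed attribute string {fields[8]!r}"
                )


def load_annotation(gtf_path: str | Path, fasta_path: str | Path | None = None) -> GenomeAnnotation:
    """Read a Gencode-dialect GTF (and optionally an indexed FASTA).

    Transcripts are reconstructed by grouping exon rows on ``transcript_id``,
    so a GTF with exon rows only is acceptable; gene/transcript rows, when
    present, contribute their attributes. GTF 1-based inclusive coordinates
    are converted to 0-based half-open. Raises if a GTF contig is absent from
    the FASTA, naming the contig.
    """
    gtf_path = Path(gtf_path)
    _validate_gtf(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=False,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )

    seq_source: SequenceSource | None = None
    contig_lengths: dict[str, int] = {}
    fasta = None
    if fasta_path is not None:
        fasta = pyfaidx.Fasta(str(fasta_path), sequence_always_upper=True)
        contig_lengths = {name: len(rec) for name, rec in fasta.items()}

        def seq_source(contig: str, start: int, end: int, _f=fasta) -> str:
            return str(_f[contig][start:end])

    tx_attrs: dict[str, dict] = {}
    for feat in db.features_of_type("transcript"):
        tid = feat.attributes["transcript_id"][0]
        tx_attrs[tid] = {k: v[0] for k, v in feat.attributes.items()}

    gene_attrs: dict[str, dict] = {}
    for feat in db.features_of_type("gene"):
        gid = feat.attributes["gene_id"][0]
        gene_attrs[gid] = {k: v[0] for k, v in feat.attributes.items()}

    # Group exon rows by transcript.
    tx_exons: dict[str, list[Interval]] = {}
    tx_meta: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        if fasta is not None and feat.seqid not in contig_lengths:
            raise ValueError(
                f"contig {feat.seqid!r} in GTF is not present in the FASTA"
            )
        tx_exons.setdefault(tid, []).append((feat.start - 1, feat.end))
        if tid not in tx_meta:
            attrs = {k: v[0] for k, v in feat.attributes.items()}
            attrs.update(tx_attrs.get(tid, {}))
            tx_meta[tid] = {
                "contig": feat.seqid,
                "strand": feat.strand,
                "attrs": attrs,
            }

    genes: dict[str, Gene] = {}
    for tid in sorted(tx_exons):
        meta = tx_meta[tid]
        attrs = meta["attrs"]
        gid = attrs["gene_id"]
        base, version = _parse_version(tid)
        transcript = Transcript(
            transcript_id=tid,
            contig=meta["contig"],
            strand=meta["strand"],
            transcript_type=attrs.get("transcript_type", ""),
            version=version,
            tsl=_parse_tsl(attrs.get("transcript_support_level")),
            exons=tuple(sorted(tx_exons[tid])),
        )
        if gid not in genes:
            gattrs = gene_attrs.get(gid, attrs)
            genes[gid] = Gene(
                gene_id=gid,
                contig=meta["contig"],
                strand=meta["strand"],
                gene_type=gattrs.get("gene_type", attrs.get("gene_type", "")),
                gene_symbol=gattrs.get("gene_name", attrs.get("gene_name", "")),
            )
        genes[gid].transcripts.append(transcript)

    ann = GenomeAnnotation(
        genes.values(), sequence_source=seq_source, contig_lengths=contig_lengths
    )
    if fasta is not None:
        for gene in ann:
            if gene.contig not in contig_lengths:
                raise ValueError(
                    f"contig {gene.contig!r} in GTF is not present in the FASTA"
                )
            for t in gene.transcripts:
                if t.span[1] > contig_lengths[gene.contig]:
                    raise ValueError(
                        f"transcript {t.transcript_id} exceeds contig "
                        f"{gene.contig} length"
                    )
    return ann


# ---------------------------------------------------------------------------
# Reference-transcript selection and construct enumeration


def select_reference_transcript(
    gene: Gene,
    max_tsl: int | None = None,
    length: str = "spliced",
) -> Transcript | None:
    """Longest protein-coding transcript that carries a support level.

    Candidates must have ``transcript_type == "protein_coding"`` and a
    non-missing TSL (optionally ``<= max_tsl``). "Longest" is spliced
    (exonic) length by default; ``length="genomic"`` uses the genomic span.
    Ties break to the lexicographically smallest transcript id. Returns
    ``None`` when no candidate exists.
    """
    def measure(t: Transcript) -> int:
        if length == "genomic":
            s, e = t.span
            return e - s
        return t.spliced_length

    candidates = [
        t
        for t in gene.transcripts
        if t.transcript_type == "protein_coding"
        and t.tsl is not None
        and (max_tsl is None or t.tsl <= max_tsl)
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda t: (-measure(t), t.transcript_id))


def enumerate_constructs(
    transcript: Transcript, gene_id: str | None = None, origin: str = "internal_control"
) -> list[EIEIEConstruct]:
    """All consecutive 3-exon windows of a transcript, 5'->3'.

    Returns ``max(0, n_exons - 2)`` constructs; window k's central exon is
    exon k+1 in transcript orientation.
    """
    gene_id = gene_id or transcript.transcript_id
    out = []
    for k in range(max(0, transcript.n_exons - 2)):
        out.append(
            EIEIEConstruct.from_exon_triplet(
                gene_id=gene_id,
                contig=transcript.contig,
                strand=transcript.strand,
                exons_5to3=transcript.exons[k : k + 3],
                origin=origin,
            )
        )
    return out


def extract_sequences(
    construct: EIEIEConstruct, annotation: GenomeAnnotation
) -> EIEIEConstruct:
    """Fill the five part sequences, oriented 5'->3' along the transcript.

    On the minus strand each part is reverse-complemented; the part order in
    ``sequences`` is always transcript order, so the concatenation over
    :data:`PART_NAMES` equals the (strand-corrected) genomic span substring.
    """
    seqs = {
        name: annotation.fetch(construct.contig, s, e, construct.strand)
        for name, (s, e) in construct.parts.items()
    }
    construct.sequences = seqs
    return construct


# ---------------------------------------------------------------------------
# Writers


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene/transcript/exon rows in Gencode-style GTF."""
    with open(Path(path), "w") as fh:
        for gene in sorted(annotation, key=lambda g: g.gene_id):
            gs, ge = None, None
            for t in gene.transcripts:
                s, e = t.span
                gs = s if gs is None else min(gs, s)
                ge = e if ge is None else max(ge, e)
            gattr = (
                f'gene_id "{gene.gene_id}"; gene_type "{gene.gene_type}"; '
                f'gene_name "{gene.gene_symbol or gene.gene_id}";'
            )
            fh.write(
                f"{gene.contig}\tskipfeat\tgene\t{gs + 1}\t{ge}\t.\t"
                f"{gene.strand}\t.\t{gattr}\n"
            )
            for t in sorted(gene.transcripts, key=lambda t: t.transcript_id):
                tsl = str(t.tsl) if t.tsl is not None else "NA"
                tattr = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_type "{gene.gene_type}"; transcript_type "{t.transcript_type}"; '
                    f'gene_name "{gene.gene_symbol or gene.gene_id}"; '
                    f'transcript_support_level "{tsl}";'
                )
                s, e = t.span
                fh.write(
                    f"{gene.contig}\tskipfeat\ttranscript\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t.\t{tattr}\n"
                )
                for (es, ee) in sorted(t.exons):
                    fh.write(
                        f"{gene.contig}\tskipfeat\texon\t{es + 1}\t{ee}\t.\t"
                        f"{gene.strand}\t.\t{tattr}\n"
                    )


def write_constructs_tsv(constructs: Sequence[EIEIEConstruct], path: str | Path) -> None:
    """BED12-like TSV: span plus five block sizes/starts (genomic order)."""
    with open(Path(path), "w") as fh:
        fh.write(
            "contig\tspan_start\tspan_end\tname\tstrand\t"
            "block_sizes\tblock_starts\n"
        )
        for c in constructs:
            s0, e0 = c.span
            blocks = sorted(c.parts.values())
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - s0) for s, _ in blocks)
            fh.write(
                f"{c.contig}\t{s0}\t{e0}\t{c.gene_id}|{c.origin}\t{c.strand}\t"
                f"{sizes}\t{starts}\n"
            )


def write_constructs_fasta(
    constructs: Sequence[EIEIEConstruct], path: str | Path
) -> None:
    """Five records per construct, one per part, transcript orientation."""
    with open(Path(path), "w") as fh:
        for c in constructs:
            if c.sequences is None:
                raise ValueError(f"construct {c.construct_id} has no sequences")
            for name in PART_NAMES:
                fh.write(f">{c.construct_id}|{name}\n{c.sequences[name]}\n")
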