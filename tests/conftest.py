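import numpy as np
import pytest

from skipfeat.annotation import Gene, GenomeAnnotation, Transcript
from skipfeat.pipeline import run_feature_comparison
from skipfeat.simulate import SimConfig, generate_bundle


def make_annotation(genes, genome: dict[str, str]) -> GenomeAnnotation:
    """In-memory annotation over explicit contig sequences."""
    return GenomeAnnotation(
        genes,
        sequence_source=lambda c, s, e: genome[c][s:e],
        contig_lengths={c: len(s) for c, s in genome.items()},
    )


def random_genome(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def simple_gene(
    gene_id: str,
    exons,
    strand: str = "+",
    contig: str = "chrT",
    transcript_type: str = "protein_coding",
    tsl: int | None = 1,
) -> Gene:
    tx = Transcript(
        transcript_id=f"{gene_id}T.1",
        contig=contig,
        strand=strand,
        transcript_type=transcript_type,
        version=1,
        tsl=tsl,
        exons=tuple(exons),
    )
    return Gene(gene_id=gene_id, contig=contig, strand=strand,
                gene_symbol=gene_id, transcripts=[tx])


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        seed=11,
        n_genes=64,
        n_event_genes=24,
        include_chrM_genes=3,
        n_no_mane_genes=4,
        deg_plan=(20, 30, 40),
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return generate_bundle(small_cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_cfg, small_bundle):
    return run_feature_comparison(small_cfg, n_external=8, bundle=small_bundle)
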