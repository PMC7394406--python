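import numpy as np
import pandas as pd
import pytest

from skipfeat.annotation import Gene, Transcript, enumerate_constructs
from skipfeat.controls import (
    ControlConfig,
    ExpressionTable,
    ManeSet,
    build_event_construct,
    sample_external_controls,
    sample_internal_control,
    select_external_control_genes,
)
from skipfeat.events import EventSet
from conftest import make_annotation, simple_gene
from test_events import make_se
from oracles import brute_force_internal_pool, random_exon_chain


def tx_with_exons(exons, strand="+", tid="T.1", contig="c"):
    return Transcript(transcript_id=tid, contig=contig, strand=strand,
                      transcript_type="protein_coding", version=1, tsl=1,
                      exons=tuple(exons))


def gene_with_exons(exons, strand="+", gid="G"):
    tx = tx_with_exons(exons, strand=strand, tid=f"{gid}T.1")
    return Gene(gene_id=gid, contig="c", strand=strand, transcripts=[tx])


class TestBuildEventConstruct:
    def test_intron_arithmetic(self):
        from skipfeat.events import SpliceEvent
        ev = SpliceEvent(
            event_class="SE", gene_id="G", gene_symbol="G", contig="c", strand="+",
            central=(200, 260), p_value=0.01, fdr=0.01, inc_level_diff=-0.2,
            upstream_exon=(0, 100), downstream_exon=(400, 500),
        )
        c = build_event_construct(ev)
        assert c.parts["intron_up"] == (100, 200)
        assert c.parts["intron_down"] == (260, 400)
        assert c.part_length("intron_up") == 100
        assert c.part_length("intron_down") == 140
        assert c.origin == "event"

    def test_zero_length_intron_is_error(self):
        from skipfeat.events import SpliceEvent
        ev = SpliceEvent(
            event_class="SE", gene_id="G", gene_symbol="G", contig="c", strand="+",
            central=(100, 160), p_value=0.01, fdr=0.01, inc_level_diff=-0.2,
            upstream_exon=(0, 100), downstream_exon=(400, 500),
        )
        with pytest.raises(ValueError):
            build_event_construct(ev)

    def test_minus_strand_role_assignment(self):
        from skipfeat.events import SpliceEvent
        ev = SpliceEvent(
            event_class="SE", gene_id="G", gene_symbol="G", contig="c", strand="-",
            central=(200, 260), p_value=0.01, fdr=0.01, inc_level_diff=-0.2,
            upstream_exon=(0, 100), downstream_exon=(400, 500),
        )
        c = build_event_construct(ev)
        # same genomic parts; 5' exon is the genomically rightmost
        assert c.parts["exon_up"] == (400, 500)
        assert c.parts["exon_down"] == (0, 100)
        assert c.parts["central_exon"] == (200, 260)


class TestSampleInternalControl:
    def test_single_window_overlapping_event_gives_none(self):
        gene = gene_with_exons([(0, 100), (200, 300), (400, 500)])
        (event,) = enumerate_constructs(gene.transcripts[0], gene_id="G")
        assert sample_internal_control(gene, [event], seed=1) is None

    def test_pool_matches_brute_force_enumeration(self):
        exons = [(i * 400, i * 400 + 100) for i in range(6)]
        gene = gene_with_exons(exons)
        windows = enumerate_constructs(gene.transcripts[0], gene_id="G")
        event = windows[0]  # spans exons 1-3
        valid_idx = brute_force_internal_pool(exons, "+", [event.span])
        sampled = sample_internal_control(gene, [event], seed=3)
        spans = [windows[k].span for k in valid_idx]
        assert sampled.span in spans

    def test_deterministic_given_seed(self):
        exons = [(i * 400, i * 400 + 100) for i in range(8)]
        gene = gene_with_exons(exons)
        windows = enumerate_constructs(gene.transcripts[0], gene_id="G")
        event = windows[0]
        a = sample_internal_control(gene, [event], seed=9)
        b = sample_internal_control(gene, [event], seed=9)
        assert a.parts == b.parts

    def test_gene_without_reference_transcript_gives_none(self):
        gene = simple_gene("G", [(0, 100), (200, 300), (400, 500)],
                           transcript_type="lncRNA")
        assert sample_internal_control(gene, [], seed=1) is None

    def test_randomized_geometries_match_brute_force(self):
        """Valid pools equal direct interval-intersection enumeration over
        random gene/event geometries on both strands."""
        rng = np.random.default_rng(2024)
        for trial in range(60):
            n = int(rng.integers(3, 10))
            exons = random_exon_chain(rng, n)
            strand = "+" if trial % 2 == 0 else "-"
            gene = gene_with_exons(exons if strand == "+" else exons[::-1],
                                   strand=strand, gid=f"G{trial}")
            windows = enumerate_constructs(gene.transcripts[0], gene_id=gene.gene_id)
            if not windows:
                continue
            k_ev = int(rng.integers(len(windows)))
            event = windows[k_ev]
            got = sample_internal_control(gene, [event], seed=trial)
            valid = brute_force_internal_pool(
                gene.transcripts[0].exons, strand, [event.span]
            )
            if not valid:
                assert got is None
            else:
                assert got.span in [windows[k].span for k in valid]


class TestSelectExternalControlGenes:
    def _fixture(self):
        genome = {"chr1": "A" * 4000, "chrM": "A" * 4000}
        exons = [(0, 100), (200, 300), (400, 500), (700, 800)]
        genes = []
        for gid, contig in [("g1", "chr1"), ("g2", "chrM"), ("g3", "chr1"),
                            ("g4", "chr1"), ("g5", "chr1")]:
            tx = Transcript(transcript_id=f"{gid}T.1", contig=contig, strand="+",
                            transcript_type="protein_coding", version=1, tsl=1,
                            exons=tuple(exons))
            genes.append(Gene(gene_id=gid, contig=contig, strand="+",
                              transcripts=[tx]))
        ann = make_annotation(genes, genome)
        expr = ExpressionTable(pd.DataFrame(
            {"s1": [100, 90, 80, 70, 60], "s2": [100, 90, 80, 70, 60]},
            index=["g1", "g2", "g3", "g4", "g5"], dtype=float))
        mane = ManeSet([(f"g{i}T", 1) for i in range(1, 6)])
        events = EventSet(events=[make_se(gene="g4")])
        return ann, expr, mane, [events]

    def test_worked_example_filters_and_ranks(self):
        ann, expr, mane, ev = self._fixture()
        cfg = ControlConfig(n_external=3, seed=0)
        assert select_external_control_genes(expr, ev, ann, mane, cfg) == \
            ["g1", "g3", "g5"]

    def test_too_few_eligible_is_error_unless_allowed(self):
        ann, expr, mane, ev = self._fixture()
        with pytest.raises(ValueError, match="eligible"):
            select_external_control_genes(
                expr, ev, ann, mane, ControlConfig(n_external=4, seed=0))
        got = select_external_control_genes(
            expr, ev, ann, mane,
            ControlConfig(n_external=4, seed=0, allow_fewer_external=True))
        assert got == ["g1", "g3", "g5"]

    def test_abundance_tie_breaks_lexicographically(self):
        ann, expr, mane, ev = self._fixture()
        expr.abundance.loc["g5"] = expr.abundance.loc["g3"]
        cfg = ControlConfig(n_external=2, seed=0)
        assert select_external_control_genes(expr, ev, ann, mane, cfg) == \
            ["g1", "g3"]

    def test_missing_mane_match_excludes_gene(self):
        ann, expr, mane, ev = self._fixture()
        mane.entries.discard(("g1T", 1))
        cfg = ControlConfig(n_external=3, seed=0, allow_fewer_external=True)
        got = select_external_control_genes(expr, ev, ann, mane, cfg)
        assert "g1" not in got


class TestSampleExternalControls:
    def _annotation(self, n_exons, gid="g1"):
        exons = [(i * 300, i * 300 + 100) for i in range(n_exons)]
        gene = gene_with_exons(exons, gid=gid)
        ann = make_annotation([gene], {"c": "A" * 5000})
        mane = ManeSet([(f"{gid}T", 1)])
        return ann, mane

    def test_three_exon_gene_returns_its_single_window(self):
        ann, mane = self._annotation(3)
        (c,) = sample_external_controls(["g1"], ann, mane, seed=1)
        assert c.parts["central_exon"] == (300, 400)
        assert c.origin == "external_control"

    def test_two_exon_gene_skipped(self):
        ann, mane = self._annotation(2)
        assert sample_external_controls(["g1"], ann, mane, seed=1) == []

    def test_fixed_seed_reproducible(self):
        ann, mane = self._annotation(9)
        a = sample_external_controls(["g1"], ann, mane, seed=4)
        b = sample_external_controls(["g1"], ann, mane, seed=4)
        assert [c.parts for c in a] == [c.parts for c in b]

    def test_sampling_exchangeable_over_seeds(self):
        """Each window of a 4-window pool is drawn with frequency ~1/4
        (99% binomial band) across 2000 seeded draws."""
        ann, mane = self._annotation(6)  # 4 windows
        counts = {}
        for seed in range(2000):
            (c,) = sample_external_controls(["g1"], ann, mane, seed=seed)
            counts[c.span] = counts.get(c.span, 0) + 1
        assert len(counts) == 4
        for n in counts.values():
            assert 0.2 <= n / 2000 <= 0.3

    def test_result_independent_of_gene_order(self):
        exons = [(i * 300, i * 300 + 100) for i in range(7)]
        g1 = gene_with_exons(exons, gid="g1")
        g2 = gene_with_exons([(s + 3000, e + 3000) for s, e in exons], gid="g2")
        ann = make_annotation([g1, g2], {"c": "A" * 9000})
        mane = ManeSet([("g1T", 1), ("g2T", 1)])
        fwd = sample_external_controls(["g1", "g2"], ann, mane, seed=5)
        rev = sample_external_controls(["g2", "g1"], ann, mane, seed=5)
        assert {c.gene_id: c.span for c in fwd} == {c.gene_id: c.span for c in rev}
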