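import numpy as np
import pytest

from skipfeat.annotation import enumerate_constructs, extract_sequences
from skipfeat.features import (
    ACCEPTOR_WINDOW_LEN,
    BranchPointModel,
    FEATURE_NAMES,
    SpliceSiteModel,
    acceptor_window,
    compute_features,
    default_branch_point_model,
    donor_window,
    features_to_frame,
    find_branch_point,
    gc_content,
    score_site,
    train_splice_site_model,
)
from conftest import make_annotation, random_genome, simple_gene
from oracles import exhaustive_branch_scan, revcomp


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 0.5), ("GGCC", 1.0), ("ANGC", 2 / 3), ("AT", 0.0),
        ("atgc", 0.5),
    ])
    def test_fraction_ignores_ambiguity_codes(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_ambiguous_is_absent(self):
        assert gc_content("NNNN") is None

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            gc_content("")


def _construct(exon_up="A" * 40, intron_up=None, central="C" * 30,
               intron_down=None, exon_down="G" * 40, strand="+"):
    """Assemble an in-memory construct directly from part sequences."""
    intron_up = intron_up or ("GTAAGT" + "T" * 60 + "TACTAAC" + "T" * 10 + "CAG")
    intron_down = intron_down or ("GTAAGT" + "A" * 60 + "TACTAAC" + "T" * 10 + "CAG")
    from skipfeat.annotation import EIEIEConstruct
    lens = [len(exon_up), len(intron_up), len(central), len(intron_down), len(exon_down)]
    bounds = np.cumsum([0] + lens)
    names = ["exon_up", "intron_up", "central_exon", "intron_down", "exon_down"]
    parts = {n: (int(bounds[i]), int(bounds[i + 1])) for i, n in enumerate(names)}
    c = EIEIEConstruct(gene_id="G", origin="event", contig="c", strand=strand, parts=parts)
    c.sequences = dict(zip(names, [exon_up, intron_up, central, intron_down, exon_down]))
    return c


class TestBoundaryWindows:
    def test_donor_window_concatenates_exon_tail_and_intron_head(self):
        c = _construct(central="T" * 27 + "ACG", intron_down="GTAAGT" + "C" * 94)
        assert donor_window(c, "central") == "ACGGTAAGT"

    def test_upstream_donor_uses_upstream_intron(self):
        c = _construct(exon_up="A" * 37 + "CCG", intron_up="GTATGT" + "T" * 94)
        assert donor_window(c, "upstream") == "CCGGTATGT"

    def test_acceptor_window_is_intron_tail_plus_exon_head(self):
        intron = "GTAAGT" + "C" * 74 + "T" * 17 + "CAG"
        c = _construct(intron_up=intron, central="GTT" + "A" * 27)
        got = acceptor_window(c, "central")
        assert got == "T" * 17 + "CAG" + "GTT"
        assert len(got) == ACCEPTOR_WINDOW_LEN

    def test_short_parts_give_absent_windows(self):
        c = _construct(exon_up="AC")
        assert donor_window(c, "upstream") is None
        c2 = _construct(intron_down="GTAAG")  # shorter than 6 nt
        assert donor_window(c2, "central") is None
        assert acceptor_window(c2, "downstream") is None


def toy_ss_model(fill=0.0):
    donor = np.full((9, 4), fill)
    acceptor = np.full((23, 4), fill)
    return SpliceSiteModel(donor, acceptor, label="toy")


class TestScoreSite:
    def test_zero_model_scores_zero(self):
        assert score_site("ACGGTAAGT", toy_ss_model(), "donor") == 0.0

    def test_hand_summed_toy_model(self):
        model = toy_ss_model()
        rng = np.random.default_rng(3)
        model.donor_weights[:] = rng.normal(size=(9, 4)).round(3)
        window = "ACGGTAAGT"
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        expected = sum(model.donor_weights[i, idx[b]] for i, b in enumerate(window))
        assert score_site(window, model, "donor") == pytest.approx(expected)

    def test_consensus_window_attains_row_maxima_sum(self):
        model = toy_ss_model()
        rng = np.random.default_rng(4)
        model.donor_weights[:] = rng.normal(size=(9, 4))
        best = "".join("ACGT"[int(j)] for j in model.donor_weights.argmax(axis=1))
        assert score_site(best, model, "donor") == pytest.approx(
            model.donor_weights.max(axis=1).sum()
        )

    def test_additivity_under_single_position_mutation(self):
        model = toy_ss_model()
        rng = np.random.default_rng(5)
        model.donor_weights[:] = rng.normal(size=(9, 4))
        window = list("ACGGTAAGT")
        base_score = score_site("".join(window), model, "donor")
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for pos in range(9):
            for b in "ACGT":
                mutated = window.copy()
                mutated[pos] = b
                delta = (model.donor_weights[pos, idx[b]]
                         - model.donor_weights[pos, idx[window[pos]]])
                assert score_site("".join(mutated), model, "donor") == \
                    pytest.approx(base_score + delta)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="length"):
            score_site("ACGT", toy_ss_model(), "donor")

    def test_ambiguity_code_gives_absent(self):
        assert score_site("ACGGTANGT", toy_ss_model(), "donor") is None

    def test_model_tsv_round_trip(self, tmp_path):
        model = toy_ss_model()
        model.donor_weights[:] = np.random.default_rng(6).normal(size=(9, 4))
        model.to_tsv(tmp_path / "m.tsv")
        back = SpliceSiteModel.from_tsv(tmp_path / "m.tsv")
        np.testing.assert_allclose(back.donor_weights, model.donor_weights, atol=1e-6)


class TestFindBranchPoint:
    def test_unique_candidate_reported_with_distance(self):
        model = default_branch_point_model()
        intron = "G" * 69 + "A" + "G" * 30  # single A at distance 31
        hit = find_branch_point(intron, model)
        assert hit is not None and hit[0] == 31

    def test_equal_scores_tie_to_smaller_distance(self):
        model = default_branch_point_model()
        intron = ["G"] * 100
        intron[35:42] = list("TACTAAC")  # branch A at index 40, d = 60
        intron[70:77] = list("TACTAAC")  # branch A at index 75, d = 25
        hit = find_branch_point("".join(intron), model)
        assert hit[0] == 25  # identical scores; nearer the 3'SS wins

    def test_short_intron_gives_absent(self):
        model = default_branch_point_model()
        assert find_branch_point("GTAAGTACG", model) is None

    def test_matches_exhaustive_scan_on_random_introns(self):
        model = default_branch_point_model()
        rng = np.random.default_rng(99)
        for _ in range(150):
            intron = random_genome(rng, int(rng.integers(40, 300)), gc=0.4)
            got = find_branch_point(intron, model)
            want = exhaustive_branch_scan(
                intron, model.heptamer_weights, model.search_min, model.search_max
            )
            if want is None:
                assert got is None
            else:
                assert got[0] == want[0]
                assert got[1] == pytest.approx(want[1])

    def test_result_invariant_outside_search_window(self):
        model = BranchPointModel(
            default_branch_point_model().heptamer_weights, search_min=15,
            search_max=80,
        )
        rng = np.random.default_rng(17)
        tail = random_genome(rng, 120, gc=0.4)
        for head in ("A" * 100, "T" * 100, random_genome(rng, 100)):
            hit = find_branch_point(head + tail, model)
            ref = find_branch_point("C" * 100 + tail, model)
            assert (hit is None) == (ref is None)
            if hit:
                assert hit == ref


class TestComputeFeatures:
    def _annotated_construct(self, seed=0, strand="+"):
        rng = np.random.default_rng(seed)
        genome = {"chrT": random_genome(rng, 2000)}
        exons = [(100, 200), (350, 410), (610, 700), (900, 1000)]
        gene = simple_gene("G", exons, strand=strand)
        ann = make_annotation([gene], genome)
        constructs = enumerate_constructs(gene.transcripts[0], gene_id="G")
        for c in constructs:
            extract_sequences(c, ann)
        return ann, constructs

    def test_length_feature_bookkeeping(self):
        c = _construct(exon_up="A" * 100, intron_up="G" * 144 + "TACTAAC" + "T" * 6,
                       central="C" * 60, intron_down="G" * 194 + "TACTAAC" + "T" * 6,
                       exon_down="T" * 90)
        fv = compute_features(c, toy_ss_model(), default_branch_point_model())
        assert (fv.upstream_exon_len, fv.downstream_exon_len, fv.central_exon_len,
                fv.upstream_intron_len, fv.downstream_intron_len) == \
            (100, 90, 60, 157, 207)

    def test_composition_equals_atomic_operations(self):
        ann, constructs = self._annotated_construct()
        ss = train_splice_site_model(ann)
        bp = default_branch_point_model()
        for c in constructs:
            fv = compute_features(c, ss, bp)
            assert fv.central_exon_gc == pytest.approx(gc_content(c.sequences["central_exon"]))
            assert fv.central_donor_score == pytest.approx(
                score_site(donor_window(c, "central"), ss, "donor"))
            assert fv.downstream_acceptor_score == pytest.approx(
                score_site(acceptor_window(c, "downstream"), ss, "acceptor"))
            up_bp = find_branch_point(c.sequences["intron_up"], bp)
            assert fv.upstream_bps_3ss_dist == (up_bp[0] if up_bp else None)

    def test_frame_equals_per_construct_loop(self):
        ann, constructs = self._annotated_construct(seed=8)
        ss = train_splice_site_model(ann)
        bp = default_branch_point_model()
        fvs = [compute_features(c, ss, bp) for c in constructs]
        df = features_to_frame(fvs)
        assert list(df.columns) == ["construct_id", "origin", *FEATURE_NAMES]
        for fv, (_, row) in zip(fvs, df.iterrows()):
            for name in FEATURE_NAMES:
                v = getattr(fv, name)
                if v is None:
                    assert np.isnan(row[name])
                else:
                    assert row[name] == pytest.approx(v)

    def test_strand_symmetry_on_mirrored_genome(self):
        """Features are identical for the mirrored construct on the
        reverse-complemented genome."""
        rng = np.random.default_rng(21)
        genome = {"chrT": random_genome(rng, 2000)}
        exons = [(100, 200), (350, 410), (610, 700)]
        L = len(genome["chrT"])
        g_plus = simple_gene("G", exons, strand="+")
        g_minus = simple_gene("G", [(L - e, L - s) for s, e in exons], strand="-")
        ann_p = make_annotation([g_plus], genome)
        ann_m = make_annotation([g_minus], {"chrT": revcomp(genome["chrT"])})
        (cp,) = enumerate_constructs(g_plus.transcripts[0], gene_id="G")
        (cm,) = enumerate_constructs(g_minus.transcripts[0], gene_id="G")
        extract_sequences(cp, ann_p)
        extract_sequences(cm, ann_m)
        bp = default_branch_point_model()
        ss = toy_ss_model()
        ss.donor_weights[:] = np.random.default_rng(5).normal(size=(9, 4))
        ss.acceptor_weights[:] = np.random.default_rng(6).normal(size=(23, 4))
        fp = compute_features(cp, ss, bp)
        fm = compute_features(cm, ss, bp)
        for name in FEATURE_NAMES:
            assert getattr(fp, name) == getattr(fm, name)


class TestTrainedModel:
    def test_trained_model_ranks_consensus_above_flattened(self, small_bundle):
        """A PWM trained on the generated annotation scores consensus-sharp
        windows higher than flattened random windows on average."""
        from skipfeat.simulate import ACCEPTOR_CONSENSUS, DONOR_CONSENSUS
        ss = train_splice_site_model(small_bundle.annotation)
        rng = np.random.default_rng(0)
        rand_donor = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(200)]
        cons = score_site(DONOR_CONSENSUS, ss, "donor")
        rand_mean = np.mean([score_site(w, ss, "donor") for w in rand_donor])
        assert cons > rand_mean + 3
        cons_a = score_site(ACCEPTOR_CONSENSUS, ss, "acceptor")
        rand_acceptor = ["".join(rng.choice(list("ACGT"), 23)) for _ in range(200)]
        assert cons_a > np.mean([score_site(w, ss, "acceptor") for w in rand_acceptor]) + 3
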