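"""CpG islands, 25 bp windows, training sets and window classification."""

from __future__ import annotations

import numpy as np
import pytest

from methylage import genome_annotation as ga


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_islands(seq: str, window=100, min_gc=0.5, min_oe=0.6, min_len=200):
    """Enumerate every qualifying window, merge spans, filter by length."""
    s = seq.upper()
    spans = []
    for i in range(len(s) - window + 1):
        chunk = s[i : i + window]
        nc, ng = chunk.count("C"), chunk.count("G")
        ncg = chunk.count("CG")
        if nc + ng < min_gc * window:
            continue
        if nc == 0 or ng == 0:
            continue
        if ncg * window / (nc * ng) < min_oe:
            continue
        spans.append((i, i + window))
    merged = []
    for start, end in spans:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s0, e0) for s0, e0 in merged if e0 - s0 >= min_len]


def brute_force_windows(seq: str, size=25):
    """Bins anchored at 0 holding >= 1 CG whose C lies inside the bin."""
    s = seq.upper()
    out = []
    for start in range(0, (len(s) // size) * size, size):
        n_cg = sum(
            1
            for i in range(start, start + size)
            if s[i : i + 2] == "CG"
        )
        if n_cg >= 1:
            out.append((start, start + size, n_cg))
    return out


def random_dna(rng, length, gc=0.5):
    return "".join(
        rng.choice(list("ACGT"), p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        for _ in range(length)
    )


# ---------------------------------------------------------------------------
# CpG island detection
# ---------------------------------------------------------------------------

class TestCpGIslands:
    def test_no_gc_sequence_has_no_islands(self):
        assert ga.detect_cpg_islands("A" * 1000) == []

    def test_pure_cg_repeat_is_one_full_length_island(self):
        seq = "CG" * 150
        islands = ga.detect_cpg_islands(seq)
        assert len(islands) == 1
        isl = islands[0]
        assert (isl.start, isl.end) == (0, 300)
        assert isl.gc_fraction == 1.0
        # 150 CG starts (0, 2, ..., 298) all lie fully inside [0, 300)
        assert isl.obs_exp_ratio == pytest.approx((150 * 300) / (150 * 150))

    def test_too_short_sequence_yields_empty(self):
        assert ga.detect_cpg_islands("CG" * 40) == []

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_brute_force_oracle_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        # GC-rich background so qualifying windows actually occur
        seq = random_dna(rng, 5000, gc=0.62)
        got = [(i.start, i.end) for i in ga.detect_cpg_islands(seq)]
        assert got == brute_force_islands(seq)

    def test_detection_ignores_soft_masking_case(self, rng):
        seq = random_dna(rng, 3000, gc=0.65)
        upper = ga.detect_cpg_islands(seq)
        lower = ga.detect_cpg_islands(seq.lower())
        assert [(i.start, i.end) for i in upper] == [
            (i.start, i.end) for i in lower
        ]


# ---------------------------------------------------------------------------
# 25 bp windows
# ---------------------------------------------------------------------------

class TestWindows:
    def test_no_cg_no_windows(self):
        assert ga.make_windows("AT" * 50) == []

    def test_hand_enumerated_two_windows(self):
        seq = list("A" * 100)
        seq[3:5] = "CG"
        seq[60:62] = "CG"
        windows = ga.make_windows("".join(seq))
        assert [(w.start, w.end) for w in windows] == [(0, 25), (50, 75)]
        assert all(w.cpg_count == 1 for w in windows)

    def test_cg_straddling_boundary_counts_for_left_bin(self):
        seq = list("A" * 75)
        seq[24] = "C"
        seq[25] = "G"
        windows = ga.make_windows("".join(seq))
        assert [(w.start, w.end) for w in windows] == [(0, 25)]

    @pytest.mark.parametrize("seed", [21, 22])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 2000, gc=0.4)
        got = [(w.start, w.end, w.cpg_count) for w in ga.make_windows(seq)]
        assert got == brute_force_windows(seq)

    def test_fully_masked_bins_dropped_only_under_exclude_policy(self):
        seq = ("cg" * 13)[:25] + "ACGT" * 10
        kept = ga.make_windows(seq, mask_policy="include")
        dropped = ga.make_windows(seq, mask_policy="exclude")
        assert (0, 25) in [(w.start, w.end) for w in kept]
        assert (0, 25) not in [(w.start, w.end) for w in dropped]

    def test_trailing_partial_bin_is_dropped(self):
        windows = ga.make_windows("CG" * 20)  # 40 bp -> one full bin
        assert [(w.start, w.end) for w in windows] == [(0, 25)]


# ---------------------------------------------------------------------------
# gene models and training sets
# ---------------------------------------------------------------------------

def _gene(tid="t1", symbol="g1", strand="+", exons=((10_000, 10_300), (10_800, 11_100), (11_500, 11_800)), cds=None):
    if cds is None:
        cds = exons[0][0] + 20 if strand == "+" else exons[-1][1] - 21
    return ga.GeneModel(tid, symbol, "chr1", strand, tuple(exons), cds)


class TestGeneModel:
    def test_promoter_is_5kb_upstream_on_plus_strand(self):
        gm = _gene(cds=10_000, exons=((10_000, 10_300), (10_800, 11_100)))
        assert gm.promoter() == (5_000, 10_000)

    def test_promoter_clipped_at_chromosome_start(self):
        gm = _gene(exons=((2_000, 2_300), (2_800, 3_100)), cds=2_000)
        assert gm.promoter() == (0, 2_000)

    def test_promoter_downstream_of_start_codon_on_minus_strand(self):
        gm = _gene(strand="-")
        assert gm.promoter() == (gm.cds_start + 1, gm.cds_start + 1 + 5_000)

    def test_first_exon_and_intron_follow_transcript_orientation(self):
        plus = _gene(strand="+")
        minus = _gene(strand="-")
        assert plus.first_exon == (10_000, 10_300)
        assert plus.first_intron == (10_300, 10_800)
        assert minus.first_exon == (11_500, 11_800)
        assert minus.first_intron == (11_100, 11_500)

    def test_cds_outside_exons_rejected(self):
        with pytest.raises(ValueError, match="cds_start"):
            _gene(cds=10_500)

    def test_cds_outside_chromosome_rejected_by_training_sets(self):
        gm = _gene()
        with pytest.raises(ValueError, match="outside"):
            ga.build_training_sets([gm], chrom_lengths={"chr1": 9_000})


class TestTrainingSets:
    def test_island_overlapping_promoter_by_one_base_is_cgi_promoter(self):
        gm = _gene()  # promoter [5020, 10020)
        ps, pe = gm.promoter()
        isl = ga.CpGIsland("chr1", ps - 250, ps + 1, 0.6, 0.8)
        training = ga.build_training_sets([gm], [isl])
        assert len(training.cgi_promoter) == 1
        assert not training.cgi_intergenic

    def test_island_outside_promoters_is_intergenic(self):
        gm = _gene()
        isl = ga.CpGIsland("chr1", 100, 400, 0.6, 0.8)
        training = ga.build_training_sets([gm], [isl])
        assert len(training.cgi_intergenic) == 1

    def test_exon_and_intron_sets_cover_gene_structure(self):
        gm = _gene()
        training = ga.build_training_sets([gm])
        assert len(training.exon) == 3
        assert [(s, e) for _, s, e, _ in training.intron] == [
            (10_300, 10_800), (11_100, 11_500)
        ]


class TestWindowClassification:
    def _classify(self, window_span, gene):
        w = ga.GenomicWindow("chr1", window_span[0], window_span[1], 1)
        training = ga.build_training_sets([gene])
        return ga.classify_windows([w], [gene], training)[0]

    def test_first_intron_of_minus_strand_gene_is_regulatory(self):
        gm = _gene(strand="-")
        w = self._classify((11_200, 11_225), gm)  # inside (11100, 11500)
        assert w.regulatory
        assert "intron" in w.labels
        assert w.linked_transcripts == ("t1",)

    def test_last_exon_of_three_exon_gene_is_not_regulatory(self):
        gm = _gene(strand="+")
        w = self._classify((11_600, 11_625), gm)
        assert not w.regulatory
        assert "exon" in w.labels

    def test_window_beyond_5kb_upstream_not_promoter_linked(self):
        gm = _gene(strand="+")  # promoter starts at 5020
        w = self._classify((4_000, 4_025), gm)
        assert "promoter" not in w.labels
        assert w.linked_transcripts == ()
        assert "intergenic" in w.labels

    def test_classification_independent_of_gene_model_order(self, dataset):
        subset = dataset.windows[:200]
        training = ga.build_training_sets(
            dataset.gene_models, chrom_lengths={
                c: len(s) for c, s in dataset.genome.items()
            },
        )
        bare = [
            ga.GenomicWindow(w.chromosome, w.start, w.end, w.cpg_count)
            for w in subset
        ]
        fwd = ga.classify_windows(bare, dataset.gene_models, training)
        rev = ga.classify_windows(bare, dataset.gene_models[::-1], training)
        assert [(w.labels, w.regulatory, w.linked_transcripts) for w in fwd] == [
            (w.labels, w.regulatory, w.linked_transcripts) for w in rev
        ]


class TestGFF3RoundTrip:
    def test_models_survive_write_read(self, tmp_path, dataset):
        path = tmp_path / "models.gff3"
        ga.write_gff3(dataset.gene_models, path)
        back = ga.read_gff3(path)
        orig = sorted(dataset.gene_models, key=lambda m: m.transcript_id)
        assert len(back) == len(orig)
        for a, b in zip(back, orig):
            assert (a.transcript_id, a.chromosome, a.strand) == (
                b.transcript_id, b.chromosome, b.strand
            )
            assert a.exons == b.exons
            assert a.cds_start == b.cds_start
            assert a.gene_symbol == b.gene_symbol
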