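"""Junction filtering, motif/strand inference, known/novel status and the
AS event detector (checked against a brute-force enumeration oracle)."""

import numpy as np
import pytest

from txome_atlas.core import GeneModel, GenomicInterval, SpliceJunction
from txome_atlas.classify import merge_transcripts
from txome_atlas.splicing import (
    classify_junctions,
    detect_as_events,
    filter_junctions,
    intron_size_stats,
    junction_motif,
    tissue_breadth,
)
from txome_atlas.synthetic import SimConfig, simulate_dataset
from conftest import brute_force_as_events, make_junction, make_transcript


class TestFilter:
    def test_threshold_met_in_one_tissue_retained(self):
        (j,) = filter_junctions([make_junction("c", 0, 100, {"root": 3})])
        assert j.tissues_detected == {"root"}

    def test_no_cross_tissue_pooling(self):
        # 2 + 2 reads across tissues never reach the per-tissue minimum
        assert filter_junctions([make_junction("c", 0, 100, {"root": 2, "leaf": 2})]) == []

    def test_detection_is_per_tissue(self):
        (j,) = filter_junctions([make_junction("c", 0, 100, {"root": 5, "leaf": 1})])
        assert j.tissues_detected == {"root"}


class TestMotif:
    def _junction(self, seq_parts):
        donor, acceptor = seq_parts
        genome = {"c": "AAAA" + donor + "TTTTTTTT" + acceptor + "AAAA"}
        return make_junction("c", 4, 16, {}), genome

    def test_forward_gt_ag(self):
        j, genome = self._junction(("GT", "AG"))
        assert junction_motif(j, genome) == ("GT-AG", "+")

    def test_reverse_complement_ct_ac(self):
        j, genome = self._junction(("CT", "AC"))
        assert junction_motif(j, genome) == ("GT-AG", "-")

    def test_gc_ag_canonical(self):
        j, genome = self._junction(("GC", "AG"))
        assert junction_motif(j, genome) == ("GC-AG", "+")

    def test_at_ac_minor_spliceosome(self):
        j, genome = self._junction(("AT", "AC"))
        assert junction_motif(j, genome) == ("AT-AC", "+")

    def test_noncanonical_takes_gene_strand(self):
        j, genome = self._junction(("CC", "GG"))
        assert junction_motif(j, genome, gene_strand="-") == ("CC-GG", "-")

    def test_intron_under_four_bases_rejected(self):
        with pytest.raises(ValueError, match="4 bp"):
            SpliceJunction(GenomicInterval("c", 10, 13))


class TestKnownNovel:
    def test_exact_intron_is_known(self, toy_locus):
        gene, _ = toy_locus
        j = make_junction("c", 100, 200, {"root": 5})
        assert classify_junctions([j], [gene]) == {("c", 100, 200): "known"}

    def test_shifted_acceptor_is_novel(self, toy_locus):
        gene, _ = toy_locus
        j = make_junction("c", 100, 220, {"root": 5})
        assert classify_junctions([j], [gene])[("c", 100, 220)] == "novel"

    def test_empty_annotation_all_novel(self):
        j = make_junction("c", 100, 200, {"root": 5})
        assert classify_junctions([j], [])[("c", 100, 200)] == "novel"


class TestDetector:
    """Toy plus-strand locus: exons [0,100),[200,300),[400,500);
    annotated introns I1=[100,200), I2=[300,400)."""

    def _base_junctions(self):
        return [
            make_junction("c", 100, 200, {"root": 9, "leaf": 9}),
            make_junction("c", 300, 400, {"root": 9, "leaf": 9}),
        ]

    def test_exon_skip(self, toy_locus):
        gene, _ = toy_locus
        jx = self._base_junctions() + [make_junction("c", 100, 400, {"root": 6})]
        events, _ = detect_as_events(jx, [], [gene])
        (e,) = events
        assert (e.event_type, e.coords, e.tissues_detected) == (
            "ES", (200, 300), {"root"}
        )

    def test_alt_acceptor(self, toy_locus):
        gene, _ = toy_locus
        jx = self._base_junctions() + [make_junction("c", 100, 220, {"leaf": 6})]
        events, _ = detect_as_events(jx, [], [gene])
        (e,) = events
        assert (e.event_type, e.coords) == ("A3SS", (100, 220))
        assert e.partner == (100, 200)
        assert e.tissues_detected == {"leaf"}

    def test_alt_donor(self, toy_locus):
        gene, _ = toy_locus
        jx = self._base_junctions() + [make_junction("c", 120, 200, {"leaf": 6})]
        events, _ = detect_as_events(jx, [], [gene])
        (e,) = events
        assert (e.event_type, e.coords) == ("A5SS", (120, 200))

    def test_minus_strand_types_swap(self):
        gene = GeneModel(
            "gm", "-",
            (GenomicInterval("c", 0, 100, "-"), GenomicInterval("c", 200, 300, "-")),
        )
        jx = [
            make_junction("c", 100, 200, {"root": 9}, "-"),
            make_junction("c", 100, 180, {"root": 9}, "-"),  # shared start
        ]
        events, _ = detect_as_events(jx, [], [gene])
        (e,) = events
        # on minus strand the genomic start is the acceptor side
        assert e.event_type == "A5SS"

    def test_intron_retention_needs_both_isoforms(self, toy_locus):
        gene, _ = toy_locus
        spanning = make_transcript("t", "+", [(0, 300), (400, 500)], {"root", "stem"})
        # junction present + spanning exon -> IR; tissues intersect evidence
        events, _ = detect_as_events(self._base_junctions(), [spanning], [gene])
        (e,) = events
        assert (e.event_type, e.coords) == ("IR", (100, 200))
        assert e.tissues_detected == {"root"}  # junction: root/leaf; transcript: root/stem

    def test_spanning_exon_without_junction_is_not_ir(self, toy_locus):
        gene, _ = toy_locus
        spanning = make_transcript("t", "+", [(0, 300), (400, 500)], {"root"})
        jx = [make_junction("c", 300, 400, {"root": 9})]  # only I2 detected
        events, _ = detect_as_events(jx, [spanning], [gene])
        assert events == []

    def test_null_case(self, toy_locus):
        gene, _ = toy_locus
        events, orphans = detect_as_events(self._base_junctions(), [], [gene])
        assert events == [] and orphans == []

    def test_orphan_junctions_reported(self, toy_locus):
        gene, _ = toy_locus
        jx = self._base_junctions() + [make_junction("c", 5000, 5200, {"root": 8})]
        events, orphans = detect_as_events(jx, [], [gene])
        assert events == []
        assert [o.key for o in orphans] == [("c", 5000, 5200)]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        """Random loci with <= 6 junctions: detector equals exhaustive
        enumeration of all junction pairs and containments."""
        rng = np.random.default_rng(seed)
        n_exons = int(rng.integers(2, 6))
        bounds = np.cumsum(rng.integers(50, 200, size=2 * n_exons - 1))
        exons = [(0, int(bounds[0]))] + [
            (int(bounds[2 * i - 1]), int(bounds[2 * i])) for i in range(1, n_exons)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneModel(
            "g", strand,
            tuple(GenomicInterval("c", s, e, strand) for s, e in exons),
        )
        introns = [(i.start, i.end) for i in gene.introns]
        tissues = ["root", "leaf", "flower"]
        candidates = [tuple(iv) for iv in introns]
        for s, e in introns:  # shifted variants inside the intron
            if e - s > 30:
                candidates.append((s + int(rng.integers(5, 15)), e))
                candidates.append((s, e - int(rng.integers(5, 15))))
        for i in range(len(introns) - 1):  # skip junctions
            candidates.append((introns[i][0], introns[i + 1][1]))
        rng.shuffle(candidates)
        jx = []
        for s, e in candidates[: int(rng.integers(1, 7))]:
            support = {
                t: int(rng.choice([0, 2, 5, 11])) for t in tissues
            }
            jx.append(make_junction("c", s, e, support, strand))
        transcripts = []
        if introns and rng.random() < 0.8:
            s, e = introns[int(rng.integers(0, len(introns)))]
            transcripts.append(
                make_transcript("tr", strand, [(max(0, s - 20), e + 20)], {"root"})
            )
        filtered = filter_junctions(jx)
        got, _ = detect_as_events(filtered, transcripts, [gene])
        got_set = {(e.event_type, e.coords, e.tissues_detected) for e in got}
        expected = brute_force_as_events(filtered, transcripts, gene)
        assert got_set == expected

    def test_planted_events_recovered_with_tissues(self, small_dataset, small_pipeline):
        got = {
            (e.gene_id, e.event_type, e.coords, e.tissues_detected)
            for e in small_pipeline.events
        }
        expected = {
            (e.gene_id, e.event_type, e.coords, e.tissues)
            for e in small_dataset.truth.as_events
        }
        assert got == expected


def test_noisy_recall_seed_averaged():
    """5% junction support noise: seed-averaged recall stays >= 0.9."""
    recalls = []
    for seed in range(3):
        cfg = SimConfig(
            seed=seed, junction_noise_rate=0.05,
            n_genes=60, n_ntrs=0, n_utr_genes=0, n_uorfs=0,
            as_events={"IR": 12, "ES": 6, "A5SS": 6, "A3SS": 6},
        )
        ds = simulate_dataset(cfg)
        merged = merge_transcripts(ds.per_tissue_transcripts().values())
        events, _ = detect_as_events(ds.junctions, merged, ds.annotation.genes)
        detected = {(e.gene_id, e.event_type, e.coords) for e in events}
        planted = ds.truth.event_set()
        recalls.append(len(detected & planted) / len(planted))
        assert detected <= planted  # no spurious events
    assert np.mean(recalls) >= 0.9


class TestBreadth:
    def test_breadth_counts_tissues(self, small_pipeline):
        breadths, summary = tissue_breadth(small_pipeline.events, k=2)
        assert summary["total"] == len(small_pipeline.events)
        # histogram conservation
        assert breadths.value_counts().sum() == summary["total"]
        assert summary["breadth_ge_2"] >= summary["breadth_gt_2"]

    def test_single_tissue_event_breadth_one(self, small_dataset, small_pipeline):
        singles = [e for e in small_pipeline.events if len(e.tissues_detected) == 1]
        for e in singles:
            assert e.breadth == 1


class TestIntronSizeStats:
    def test_identical_samples_p_one(self, toy_locus):
        gene, _ = toy_locus
        from txome_atlas.core import ASEvent

        events = [
            ASEvent("IR", "GX", "c", (i.start, i.end), frozenset({"root"}))
            for i in gene.introns
        ]
        stats = intron_size_stats(events, [gene])
        assert stats.mean_retained == stats.mean_all
        assert stats.p_value == 1.0

    def test_means_arithmetic(self):
        g1 = GeneModel(
            "a", "+",
            (GenomicInterval("c", 0, 50, "+"), GenomicInterval("c", 150, 200, "+"),
             GenomicInterval("c", 500, 550, "+")),
        )  # introns 100 bp and 300 bp
        from txome_atlas.core import ASEvent

        ir = [ASEvent("IR", "a", "c", (50, 150), frozenset({"root"}))]
        stats = intron_size_stats(ir, [g1])
        assert stats.mean_retained == 100.0
        assert stats.mean_all == 200.0

    def test_short_intron_preference_detected(self):
        """IR planted preferentially in short introns: retained mean is
        below the global mean with a significant rank-sum test."""
        cfg = SimConfig(
            seed=5, n_genes=200, n_ntrs=0, n_utr_genes=0, n_uorfs=0,
            as_events={"IR": 200}, ir_prefer_short_introns=True,
        )
        ds = simulate_dataset(cfg)
        merged = merge_transcripts(ds.per_tissue_transcripts().values())
        events, _ = detect_as_events(ds.junctions, merged, ds.annotation.genes)
        ir = [e for e in events if e.event_type == "IR"]
        stats = intron_size_stats(ir, ds.annotation.genes)
        assert stats.mean_retained < stats.mean_all
        assert stats.p_value < 0.05

    def test_empty_inputs_rejected(self, toy_locus):
        gene, _ = toy_locus
        with pytest.raises(ValueError):
            intron_size_stats([], [gene])
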