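"""rDNA unit annotation, IGS delineation, linkage and configuration."""

import numpy as np
import pytest

from satscout import simrep
from satscout.aligncore import HSP
from satscout.rdnalink import (
    IgsRegion,
    RdnaUnit,
    annotate_rdna,
    classify_config,
    classify_copies,
    compare_igs_variants,
    delineate_igs,
    pair_multiplicity,
)


def _unit(chrom, start, orientation="+", gene_len=(100, 50, 150), gaps=(30, 30)):
    g18 = (start, start + gene_len[0] - 1)
    g58 = (g18[1] + gaps[0] + 1, g18[1] + gaps[0] + gene_len[1])
    g26 = (g58[1] + gaps[1] + 1, g58[1] + gaps[1] + gene_len[2])
    if orientation == "-":
        # forward coordinates but transcription right-to-left
        names = ("26S", "5.8S", "18S")
    else:
        names = ("18S", "5.8S", "26S")
    return RdnaUnit(chrom, dict(zip(names, (g18, g58, g26))), orientation)


class TestAnnotateRdna:
    def test_simulated_cluster_recovers_all_units(self, rdna_scenario):
        units = rdna_scenario["units"]
        manifest = rdna_scenario["manifest"]
        truth = manifest.by_kind("rdna_unit")
        found = [u for u in units if not u.partial]
        assert len(found) == len(truth)
        for u, t in zip(sorted(found, key=lambda u: u.start),
                        sorted(truth, key=lambda r: r["start"])):
            assert u.orientation == t["strand"]
            # unit extent covers the transcribed block within the planted unit
            assert t["start"] <= u.start < u.end <= t["end"]
        assert all(u.orientation == "+" for u in found)

    def test_no_rdna_genome_gives_empty(self):
        chroms = {"chr1": simrep.random_seq(20_000, np.random.default_rng(3))}
        refs = simrep.surrogate_rrna_refs()
        assert annotate_rdna(chroms, {k: refs[k] for k in ("18S", "5.8S", "26S")}) == []

    def test_minus_strand_unit(self):
        genes = simrep.surrogate_rrna_refs()
        rng = np.random.default_rng(4)
        template = simrep.random_seq(1500, rng)
        unit, _ = simrep.make_rdna_unit(genes, template, None, 0,
                                        unit_orientation="-")
        chrom = (simrep.random_seq(2000, rng) + unit
                 + simrep.random_seq(2000, rng))
        units = annotate_rdna({"c": chrom},
                              {k: genes[k] for k in ("18S", "5.8S", "26S")})
        assert len(units) == 1
        assert units[0].orientation == "-"


class TestDelineateIgs:
    def test_igs_length_between_planted_units(self, rdna_scenario):
        igs = [r for r in rdna_scenario["igs"] if r.complete]
        assert len(igs) == 5
        for r in igs:
            assert r.length == 3595
            # bounded by upstream 26S 3' end and downstream 18S 5' end
            assert r.start == r.upstream.genes["26S"][1] + 1
            assert r.end == r.downstream.genes["18S"][0] - 1

    def test_single_unit_gives_flagged_partial(self):
        u = _unit("c", 1000)
        (r,) = delineate_igs([u])
        assert not r.complete
        assert classify_config(r).config == "undetermined"

    def test_overlapping_units_rejected(self):
        a, b = _unit("c", 1000), _unit("c", 1100)
        with pytest.raises(ValueError, match="overlapping"):
            delineate_igs([a, b])


class TestClassifyCopies:
    def test_copy_inside_igs_is_linked(self):
        igs = [IgsRegion("c", 1000, 2000, _unit("c", 1), _unit("c", 2100))]
        hits = [HSP(1, 200, 1200, 1399, "-", 97.0, 180.0, 100.0, "c")]
        labeled = classify_copies(hits, igs)
        assert labeled[0]["label"] == "igs_linked"
        assert len(igs[0].embedded) == 1

    def test_distant_copy_is_independent(self):
        igs = [IgsRegion("c", 1000, 2000, _unit("c", 1), _unit("c", 2100))]
        hits = [HSP(1, 200, 12_000, 12_199, "+", 97.0, 180.0, 100.0, "c")]
        assert classify_copies(hits, igs)[0]["label"] == "independent"

    def test_every_hit_gets_exactly_one_label(self, rdna_scenario):
        labeled = rdna_scenario["labeled"]
        assert all(r["label"] in ("independent", "igs_linked") for r in labeled)

    def test_cluster_scenario_counts_match_truth(self, rdna_scenario):
        """Complete IGSs carry exactly two linked copies each; independent
        array copies stay independent."""
        igs = rdna_scenario["igs"]
        labeled = rdna_scenario["labeled"]
        complete = [r for r in igs if r.complete]
        linked = [r for r in labeled if r["label"] == "igs_linked"]
        assert len(linked) == 2 * len(complete)


class TestPairMultiplicity:
    def test_modal_pair_count_on_cluster(self, rdna_scenario):
        hist, mode = pair_multiplicity(rdna_scenario["igs"])
        assert mode == 2
        assert hist == {2: 5}

    def test_no_embedded_copies_mode_zero(self):
        igs = [IgsRegion("c", 1000, 2000, _unit("c", 1), _unit("c", 2100))]
        hist, mode = pair_multiplicity(igs)
        assert mode == 0 and hist == {0: 1}

    def test_minority_singleton_does_not_move_mode(self):
        regions = []
        for i in range(11):
            r = IgsRegion("c", 1, 10, _unit("c", 1), _unit("c", 2100))
            n = 1 if i == 0 else 2
            r.embedded = [("f", 1, 2, "-")] * n
            regions.append(r)
        hist, mode = pair_multiplicity(regions)
        assert hist == {1: 1, 2: 10}
        assert mode == 2


class TestClassifyConfig:
    @pytest.mark.parametrize("o1,o2,expected", [
        ("+", "+", "N"), ("-", "-", "N"), ("+", "-", "P"), ("-", "+", "P")])
    def test_orientation_combinations(self, o1, o2, expected):
        igs = IgsRegion("c", 1000, 2000, _unit("c", 1, o1), _unit("c", 2100, o2))
        assert classify_config(igs).config == expected

    def test_orientation_flip_preserves_classes(self):
        flip = {"+": "-", "-": "+"}
        for o1, o2 in (("+", "+"), ("+", "-")):
            a = IgsRegion("c", 1, 2, _unit("c", 1, o1), _unit("c", 2100, o2))
            b = IgsRegion("c", 1, 2, _unit("c", 1, flip[o1]),
                          _unit("c", 2100, flip[o2]))
            assert classify_config(a).config == classify_config(b).config


class TestCompareIgsVariants:
    def test_identical_variants_no_deletion(self):
        seq = simrep.random_seq(800, np.random.default_rng(5))
        diff = compare_igs_variants(seq, seq)
        assert diff.deletion_length == 0

    def test_planted_deletion_sized_like_published_variants(self):
        """3595 bp spacer minus positions 932-3542: a 2611 bp deletion at
        breakpoint 931/932 is recovered from the alignment."""
        long_igs = simrep.random_seq(3595, np.random.default_rng(6))
        short_igs = long_igs[:931] + long_igs[3542:]
        assert len(short_igs) == 984
        diff = compare_igs_variants(long_igs, short_igs)
        assert diff.deletion_length == 2611
        # gap placement is ambiguous when flanking bases repeat; the
        # breakpoint may legitimately slide within that repeat
        assert abs(diff.breakpoint - 931) <= 2
        # applying the deletion reconstructs the short variant exactly
        from satscout.horstruct import apply_deletion
        dels = [e for e in diff.events if e.direction == "deletion-in-query"]
        assert apply_deletion(long_igs, dels[0]) == short_igs

    def test_lengths_only_single_deletion_model(self):
        diff = compare_igs_variants(3595, 984)
        assert diff.deletion_length == 2611
        assert diff.breakpoint is None

    def test_short_longer_than_long_rejected(self):
        with pytest.raises(ValueError):
            compare_igs_variants(984, 3595)
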