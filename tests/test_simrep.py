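"""Simulator: mutation model, array tiling, rDNA units, manifests."""

import numpy as np
import pytest

from satscout import simrep
from satscout.aligncore import global_align, revcomp
from satscout.simrep import (
    ArraySpec,
    ChromSpec,
    MonomerFamilySpec,
    RdnaClusterSpec,
    SimError,
    SimSpec,
)


class TestMutate:
    def test_zero_rate_is_identity(self):
        assert simrep.mutate("ACGT", 0.0, 7) == "ACGT"

    def test_rate_one_changes_every_site(self):
        seq = simrep.random_seq(500, np.random.default_rng(0))
        out = simrep.mutate(seq, 1.0, 3)
        assert all(a != b for a, b in zip(seq, out))

    def test_expected_divergence_at_ten_percent(self):
        """Global-alignment identity of a 10%-mutated 1000-mer is 90 +/- 2."""
        seq = simrep.random_seq(1000, np.random.default_rng(11))
        out = simrep.mutate(seq, 0.10, 1)
        assert len(out) == len(seq)
        mism = sum(1 for a, b in zip(seq, out) if a != b)
        # binomial: 100 +/- ~2.8 sd of 9.5 around n*p
        assert abs(mism - 100) <= 30
        assert global_align(seq, out).identity_pct == pytest.approx(90.0, abs=2.0)

    def test_deterministic_given_seed(self):
        seq = simrep.random_seq(300, np.random.default_rng(5))
        assert simrep.mutate(seq, 0.2, 9) == simrep.mutate(seq, 0.2, 9)
        assert simrep.mutate(seq, 0.2, 9) != simrep.mutate(seq, 0.2, 10)

    def test_non_acgt_rejected(self):
        with pytest.raises(SimError, match="non-ACGT"):
            simrep.mutate("ACGN", 0.1, 1)

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(SimError):
            simrep.mutate("ACGT", 1.5, 1)


class TestMakeArray:
    def test_pure_tiling_without_mutation(self, monomer237):
        arr, coords = simrep.make_array(monomer237, 4, 0.0)
        assert len(arr) == 948
        assert coords == [(1, 237), (238, 474), (475, 711), (712, 948)]
        assert arr == monomer237 * 4

    def test_every_copy_stays_close_to_monomer(self, monomer237):
        arr, coords = simrep.make_array(monomer237, 20, 0.03, seed=1)
        assert len(arr) == 4740
        for s, e in coords:
            ident = global_align(arr[s - 1 : e], monomer237).identity_pct
            assert ident >= 90.0

    def test_insertion_shifts_downstream_copies(self, monomer237):
        ins = simrep.random_seq(50, np.random.default_rng(2))
        arr, coords = simrep.make_array(monomer237, 3, 0.0, [(2, ins)])
        assert len(arr) == 3 * 237 + 50
        assert coords[2] == (2 * 237 + 50 + 1, len(arr))

    def test_insertion_index_beyond_copies_rejected(self, monomer237):
        with pytest.raises(SimError, match="beyond copy count"):
            simrep.make_array(monomer237, 3, 0.0, [(4, "ACGT" * 5)])


class TestRdnaUnit:
    def _genes(self):
        return simrep.surrogate_rrna_refs()

    def test_two_embedded_copies_annotated_in_igs(self, monomer237):
        genes = self._genes()
        rng = np.random.default_rng(1)
        template = simrep.random_seq(3595, rng)
        unit, ann = simrep.make_rdna_unit(genes, template, monomer237, 2)
        copies = [a for a in ann if a["kind"] == "igs_copy"]
        igs = [a for a in ann if a["kind"] == "igs"][0]
        assert len(copies) == 2
        for c in copies:
            assert igs["start"] <= c["start"] <= c["end"] <= igs["end"]
            assert c["strand"] == "-"  # reverse-oriented embedding
        # copies sit adjacent to the unit end (next unit's 18S side)
        assert igs["end"] - copies[-1]["end"] == 100

    def test_zero_copies_leaves_template_verbatim(self):
        genes = self._genes()
        template = simrep.random_seq(1000, np.random.default_rng(3))
        unit, ann = simrep.make_rdna_unit(genes, template, None, 0)
        assert unit.endswith(template)

    def test_reverse_embedding_is_reverse_complement(self, monomer237):
        genes = self._genes()
        template = simrep.random_seq(1000, np.random.default_rng(4))
        unit, ann = simrep.make_rdna_unit(genes, template, monomer237, 1,
                                          embedded_orientation="reverse")
        c = [a for a in ann if a["kind"] == "igs_copy"][0]
        assert unit[c["start"] - 1 : c["end"]] == revcomp(monomer237)

    def test_template_too_short_rejected(self, monomer237):
        genes = self._genes()
        with pytest.raises(SimError, match="shorter than"):
            simrep.make_rdna_unit(genes, "ACGT" * 50, monomer237, 2)

    def test_minus_orientation_maps_coordinates(self, monomer237):
        genes = self._genes()
        template = simrep.random_seq(1000, np.random.default_rng(6))
        fwd, ann_f = simrep.make_rdna_unit(genes, template, monomer237, 2)
        rev, ann_r = simrep.make_rdna_unit(genes, template, monomer237, 2,
                                           unit_orientation="-")
        assert rev == revcomp(fwd)
        for a in ann_r:
            seg = rev[a["start"] - 1 : a["end"]]
            name = a["name"]
            match_f = [b for b in ann_f if b["name"] == name]
            if len(match_f) == 1 and name in ("18S", "5.8S", "26S"):
                assert seg == revcomp(genes[name])


class TestGenome:
    def test_counts_and_determinism(self, tmp_path, monomer237):
        spec = SimSpec(
            seed=3,
            monomer_families=[MonomerFamilySpec("fam", (111, 126))],
            chrom_specs=[ChromSpec("chr1", 100_000,
                                   [(10_001, ArraySpec("fam", copies=20))])])
        p1 = simrep.write_genome(spec, tmp_path / "a")
        p2 = simrep.write_genome(spec, tmp_path / "b")
        for key in p1:
            assert simrep.checksum(p1[key]) == simrep.checksum(p2[key])
        import json
        man = json.loads((tmp_path / "a" / "manifest.json").read_text())
        arrays = [r for r in man["records"] if r["kind"] == "array"]
        assert len(arrays) == 1
        assert len(arrays[0]["copies"]) == 20
        fasta = (tmp_path / "a" / "genome.fa").read_text()
        assert fasta.startswith(">chr1\n")
        assert max(len(l) for l in fasta.splitlines()) <= 60

    def test_overlapping_features_rejected(self):
        spec = SimSpec(
            seed=1,
            monomer_families=[MonomerFamilySpec("fam", (111, 126))],
            chrom_specs=[ChromSpec("chr1", 50_000,
                                   [(1_000, ArraySpec("fam", copies=10)),
                                    (1_500, ArraySpec("fam", copies=10))])])
        with pytest.raises(SimError, match="overlapping"):
            simrep.build_genome(spec)

    def test_feature_beyond_chromosome_rejected(self):
        spec = SimSpec(
            seed=1,
            monomer_families=[MonomerFamilySpec("fam", (111, 126))],
            chrom_specs=[ChromSpec("chr1", 2_000,
                                   [(1_000, ArraySpec("fam", copies=10))])])
        with pytest.raises(SimError, match="exceeds"):
            simrep.build_genome(spec)

    def test_manifest_fidelity(self, demo_genome):
        """Re-aligning every planted copy to its family monomer meets the
        identity implied by the substitution rate (1 - rate - 3 SE)."""
        chroms, manifest, spec = demo_genome
        monomers = manifest.by_kind("monomer_refs")[0]["sequences"]
        for arr in manifest.by_kind("array"):
            mono = monomers[arr["family"]]
            if arr["strand"] == "-":
                mono = revcomp(mono)
            rate = 0.03
            se = np.sqrt(rate * (1 - rate) / len(mono))
            floor = 100 * (1 - rate - 3 * se)
            for s, e in arr["copies"]:
                seq = chroms[arr["chrom"]][s - 1 : e]
                assert global_align(seq, mono).identity_pct >= floor

    def test_array_copies_tile_interval_without_insertions(self, demo_genome):
        chroms, manifest, spec = demo_genome
        for arr in manifest.by_kind("array"):
            copies = arr["copies"]
            assert copies[0][0] == arr["start"]
            assert copies[-1][1] == arr["end"]
            for (s1, e1), (s2, e2) in zip(copies, copies[1:]):
                assert s2 == e1 + 1

    def test_manifest_distinguishes_array_and_igs_copies(self, demo_genome):
        chroms, manifest, spec = demo_genome
        kinds = {r["kind"] for r in manifest.records}
        assert {"array", "rdna_unit", "igs_copy"} <= kinds
        # igs copies nest inside the igs interval of their unit
        igs_by_unit = {(r["chrom"], r["unit_index"]): r
                       for r in manifest.by_kind("igs")}
        for c in manifest.by_kind("igs_copy"):
            igs = igs_by_unit[(c["chrom"], c["unit_index"])]
            assert igs["start"] <= c["start"] <= c["end"] <= igs["end"]
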