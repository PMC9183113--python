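"""Synthetic genomes with planted satellite arrays and 45S rDNA units.

The generator emulates the genomic structures the rest of the pipeline
is built to detect: tandem arrays of a ~237 bp two-subunit monomer
whose copies diverge to the 85-94% inter-copy identity band, occasional
non-repeat insertions inside arrays, and 45S rDNA units
(18S-ITS1-5.8S-ITS2-26S-IGS) whose intergenic spacer carries a fixed
number of reverse-oriented copies of a shorter monomer variant, in
co-oriented (N) or inverted (P) unit neighbourhoods.  Everything
planted is recorded in a truth manifest (JSON plus GFF3/BED views) so
tests can score recovery against exact coordinates.

All coordinates are 1-based inclusive internally; BED exports are
0-based half-open.  A fixed seed regenerates byte-identical output.

The substitution model is deliberately simple — uniform site choice
with a forced change to one of the three other bases, and no indels
inside copies except via explicit insertion lists — so the planted
identity of every copy is analytically predictable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from satscout.aligncore import revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SimError(ValueError):
    """Invalid simulation specification or parameters."""


# ---------------------------------------------------------------------------
# primitive sequence operations


def random_seq(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT sequence of the given length."""
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate_rng(seq: str, sub_rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(arr.size) < sub_rate
    idx = np.flatnonzero(mask)
    if idx.size:
        # forced change: shift each hit base by 1..3 in ACGT order
        code = np.searchsorted(_BASES, arr[idx])
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(code + shift) % 4]
    return arr.tobytes().decode()


def mutate(seq: str, sub_rate: float, seed: int) -> str:
    """Substitute a ``sub_rate`` fraction of sites, deterministically.

    Every chosen site is forced to a different base, so the expected
    identity of the result to the input is exactly ``1 - sub_rate``.
    """
    if not 0.0 <= sub_rate <= 1.0:
        raise SimError("sub_rate must lie in [0, 1]")
    if set(seq) - set("ACGT"):
        raise SimError("mutate: sequence contains non-ACGT characters")
    return _mutate_rng(seq, sub_rate, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class MonomerFamilySpec:
    """A monomer family: subunit structure and an optional derived indel.

    ``subunit_lengths`` of [111, 126] gives the classic 237 bp dimeric
    satellite monomer; a ``planted_indel`` of (position, length, seq)
    applied inside one subunit models a derived family such as the
    208 bp IGS-linked variant (a 27 bp deletion of the long monomer).
    """

    name: str
    subunit_lengths: tuple[int, ...] = (111, 126)
    planted_indel: tuple[int, int, str] | None = None
    orientation: str = "forward"

    @property
    def monomer_length(self) -> int:
        return sum(self.subunit_lengths)


@dataclass
class ArraySpec:
    """A tandem array to plant: family, copy count, divergence, insertions."""

    family: str
    copies: int = 20
    sub_rate: float = 0.03
    insertions: tuple[tuple[int, str], ...] = ()
    strand: str = "+"


@dataclass
class RdnaClusterSpec:
    """A tandem run of 45S rDNA units with IGS-embedded monomer copies.

    ``unit_orientations`` is one strand symbol per unit; co-oriented
    neighbours produce N-configuration spacers, inverted ones P.
    ``embedded_copies`` monomers of ``embedded_family`` are planted in
    every IGS, in reverse orientation relative to the independent
    satellite by default, adjacent to the downstream 18S end.
    """

    embedded_family: str
    n_units: int = 6
    unit_orientations: tuple[str, ...] | None = None
    embedded_copies: int = 2
    embedded_sub_rate: float = 0.03
    igs_length: int = 3595

    def orientations(self) -> tuple[str, ...]:
        if self.unit_orientations is not None:
            if len(self.unit_orientations) != self.n_units:
                raise SimError("unit_orientations length != n_units")
            return self.unit_orientations
        return ("+",) * self.n_units


@dataclass
class ChromSpec:
    name: str
    length: int
    features: list[tuple[int, object]] = field(default_factory=list)
    # features: (1-based start, ArraySpec | RdnaClusterSpec)


@dataclass
class SimSpec:
    """Full simulation specification; (spec, seed) fixes every byte."""

    seed: int = 1
    chrom_specs: list[ChromSpec] = field(default_factory=list)
    monomer_families: list[MonomerFamilySpec] = field(default_factory=list)

    def family(self, name: str) -> MonomerFamilySpec:
        for fam in self.monomer_families:
            if fam.name == name:
                return fam
        raise SimError(f"unknown monomer family {name!r}")


# ---------------------------------------------------------------------------
# monomer construction


def make_family_monomer(
    spec: MonomerFamilySpec, rng: np.random.Generator,
    subunit_identity: float = 0.70,
) -> str:
    """Build a dimeric monomer whose subunits share a common ancestor.

    The first subunit is random; each further subunit is a mutated,
    length-adjusted derivative so that inter-subunit identity sits near
    ``subunit_identity`` — the internal structure a self-comparison
    decomposition should recover.
    """
    subs: list[str] = []
    base = random_seq(max(spec.subunit_lengths), rng)
    for i, ln in enumerate(spec.subunit_lengths):
        # first subunit is the ancestor; later ones diverge from it so
        # the pairwise identity lands near subunit_identity
        deriv = base[:ln] if i == 0 else _mutate_rng(base[:ln], 1.0 - subunit_identity, rng)
        subs.append(deriv)
    monomer = "".join(subs)
    if spec.planted_indel is not None:
        pos, ln, seq = spec.planted_indel
        if seq:  # insertion
            monomer = monomer[:pos] + seq + monomer[pos:]
        else:  # deletion of ln bases at pos (0-based)
            monomer = monomer[:pos] + monomer[pos + ln:]
    if spec.orientation == "reverse":
        monomer = revcomp(monomer)
    return monomer


def make_array(
    monomer: str,
    copies: int,
    sub_rate: float = 0.0,
    insertions: list[tuple[int, str]] | None = None,
    seed: int = 1,
) -> tuple[str, list[tuple[int, int]]]:
    """Tandem array of independently mutated monomer copies.

    ``insertions`` is a list of (after_copy, sequence): the sequence is
    inserted after that copy number (0 = before the first copy).
    Returns the array string and exact 1-based per-copy coordinates.
    """
    if copies < 1:
        raise SimError("copies must be >= 1")
    insertions = list(insertions or [])
    for after, _ in insertions:
        if not 0 <= after <= copies:
            raise SimError(f"insertion index {after} beyond copy count {copies}")
    rng = np.random.default_rng(seed)
    by_pos: dict[int, list[str]] = {}
    for after, ins in insertions:
        by_pos.setdefault(after, []).append(ins)

    parts: list[str] = []
    coords: list[tuple[int, int]] = []
    pos = 0
    for ins in by_pos.get(0, []):
        parts.append(ins)
        pos += len(ins)
    for c in range(1, copies + 1):
        cp = _mutate_rng(monomer, sub_rate, rng)
        parts.append(cp)
        coords.append((pos + 1, pos + len(cp)))
        pos += len(cp)
        for ins in by_pos.get(c, []):
            parts.append(ins)
            pos += len(ins)
    return "".join(parts), coords


# ---------------------------------------------------------------------------
# rDNA units

#: realistic surrogate lengths for the 45S cistron parts (bp)
RRNA_LENGTHS = {"18S": 1800, "ITS1": 300, "5.8S": 160, "ITS2": 250, "26S": 3400}

_SURROGATE_SEED = 20220237  # fixed: surrogate references never change


def surrogate_rrna_refs() -> dict[str, str]:
    """Bundled random-but-fixed rRNA gene surrogates of realistic lengths.

    Stand-ins for real 18S/5.8S/26S references; generated from a frozen
    seed so they are identical in every installation.
    """
    rng = np.random.default_rng(_SURROGATE_SEED)
    return {name: random_seq(ln, rng) for name, ln in RRNA_LENGTHS.items()}


def make_rdna_unit(
    genes: dict[str, str],
    igs_template: str,
    embedded_monomer: str | None = None,
    n_copies: int = 0,
    unit_orientation: str = "+",
    embedded_orientation: str = "reverse",
    gap_to_18s: int = 100,
    sub_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[str, list[dict]]:
    """One 45S rDNA unit: 18S-ITS1-5.8S-ITS2-26S-IGS with embedded copies.

    ``n_copies`` copies of ``embedded_monomer`` replace a slice of the
    IGS template ending ``gap_to_18s`` bp before the spacer's end, i.e.
    adjacent to the next unit's 18S side.  Reverse embedding plants the
    reverse complement.  Returns the unit sequence and annotation
    records with unit-relative 1-based coordinates.
    """
    if n_copies < 0:
        raise SimError("n_copies must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(0)

    igs = igs_template
    copy_rel: list[tuple[int, int]] = []
    if n_copies and embedded_monomer:
        block_parts = []
        for _ in range(n_copies):
            cp = _mutate_rng(embedded_monomer, sub_rate, rng)
            if embedded_orientation == "reverse":
                cp = revcomp(cp)
            block_parts.append(cp)
        block = "".join(block_parts)
        if len(block) + gap_to_18s > len(igs_template):
            raise SimError("igs_template shorter than total embedded length")
        bstart = len(igs_template) - gap_to_18s - len(block)  # 0-based
        igs = igs_template[:bstart] + block + igs_template[bstart + len(block):]
        off = bstart
        for cp in block_parts:
            copy_rel.append((off + 1, off + len(cp)))
            off += len(cp)

    order = ["18S", "ITS1", "5.8S", "ITS2", "26S"]
    parts = [genes[k] for k in order] + [igs]
    unit = "".join(parts)

    ann: list[dict] = []
    pos = 0
    for name, part in zip(order + ["IGS"], parts):
        ann.append({"kind": "rrna_gene" if name in ("18S", "5.8S", "26S") else
                    ("igs" if name == "IGS" else "its"),
                    "name": name, "start": pos + 1, "end": pos + len(part),
                    "strand": "+"})
        pos += len(part)
    igs_start = ann[-1]["start"]
    emb_strand = "-" if embedded_orientation == "reverse" else "+"
    for cs, ce in copy_rel:
        ann.append({"kind": "igs_copy", "name": "embedded",
                    "start": igs_start + cs - 1, "end": igs_start + ce - 1,
                    "strand": emb_strand})

    if unit_orientation == "-":
        n = len(unit)
        unit = revcomp(unit)
        flip = {"+": "-", "-": "+"}
        for a in ann:
            a["start"], a["end"] = n - a["end"] + 1, n - a["start"] + 1
            a["strand"] = flip[a["strand"]]
        ann.sort(key=lambda a: a["start"])
    return unit, ann


# ---------------------------------------------------------------------------
# genome assembly


@dataclass
class TruthManifest:
    """Everything the simulator planted, with exact coordinates."""

    seed: int
    records: list[dict] = field(default_factory=list)

    def by_kind(self, kind: str) -> list[dict]:
        return [r for r in self.records if r["kind"] == kind]

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "records": self.records},
            indent=1, sort_keys=True)


def _render_cluster(
    spec: RdnaClusterSpec,
    monomer: str,
    genes: dict[str, str],
    rng: np.random.Generator,
) -> tuple[str, list[dict]]:
    """Concatenate rDNA units; coordinates relative to cluster start."""
    igs_template = random_seq(spec.igs_length, rng)
    parts: list[str] = []
    records: list[dict] = []
    pos = 0
    orientations = spec.orientations()
    for i, ori in enumerate(orientations):
        unit, ann = make_rdna_unit(
            genes, igs_template, monomer, spec.embedded_copies,
            unit_orientation=ori, sub_rate=spec.embedded_sub_rate, rng=rng)
        records.append({"kind": "rdna_unit", "start": pos + 1,
                        "end": pos + len(unit), "strand": ori,
                        "unit_index": i})
        for a in ann:
            rec = dict(a)
            rec["start"] += pos
            rec["end"] += pos
            rec["unit_index"] = i
            if rec["kind"] == "igs_copy":
                rec["family"] = spec.embedded_family
            records.append(rec)
        parts.append(unit)
        pos += len(unit)
    # planted spacer configuration between consecutive co/inverted units
    for i in range(len(orientations) - 1):
        records.append({
            "kind": "spacer_config", "unit_index": i,
            "config": "N" if orientations[i] == orientations[i + 1] else "P"})
    return "".join(parts), records


def build_genome(spec: SimSpec) -> tuple[dict[str, str], TruthManifest]:
    """Render a SimSpec into chromosome sequences plus a truth manifest."""
    rng = np.random.default_rng(spec.seed)
    genes = surrogate_rrna_refs()
    monomers: dict[str, str] = {}
    for fam in spec.monomer_families:
        monomers[fam.name] = make_family_monomer(fam, rng)

    chroms: dict[str, str] = {}
    manifest = TruthManifest(seed=spec.seed)
    manifest.records.append({"kind": "monomer_refs", "sequences": dict(monomers)})

    for cs in spec.chrom_specs:
        seq = list(random_seq(cs.length, rng))
        placed: list[tuple[int, int]] = []
        for start, feat in sorted(cs.features, key=lambda f: f[0]):
            if isinstance(feat, ArraySpec):
                fam = spec.family(feat.family)
                mono = monomers[fam.name]
                if feat.strand == "-":
                    mono = revcomp(mono)
                arr, coords = make_array(
                    mono, feat.copies, feat.sub_rate,
                    list(feat.insertions),
                    seed=int(rng.integers(0, 2**31 - 1)))
                block, records = arr, [
                    {"kind": "array", "chrom": cs.name, "start": start,
                     "end": start + len(arr) - 1, "strand": feat.strand,
                     "family": fam.name, "copy_number": feat.copies,
                     "copies": [[start + a - 1, start + b - 1] for a, b in coords]}]
            elif isinstance(feat, RdnaClusterSpec):
                mono = monomers[spec.family(feat.embedded_family).name]
                block, recs = _render_cluster(feat, mono, genes, rng)
                records = []
                for r in recs:
                    r = dict(r)
                    r["chrom"] = cs.name
                    if "start" in r:
                        r["start"] += start - 1
                        r["end"] += start - 1
                    records.append(r)
            else:
                raise SimError(f"unknown feature type {type(feat).__name__}")

            end = start + len(block) - 1
            if end > cs.length:
                raise SimError(
                    f"feature at {cs.name}:{start} exceeds chromosome length")
            for a, b in placed:
                if start <= b and end >= a:
                    raise SimError(
                        f"overlapping planted features on {cs.name}: "
                        f"[{a},{b}] vs [{start},{end}]")
            placed.append((start, end))
            seq[start - 1 : end] = block
            manifest.records.extend(records)
        chroms[cs.name] = "".join(seq)
    return chroms, manifest


# ---------------------------------------------------------------------------
# file output


def _wrap_fasta(name: str, seq: str, width: int = 60) -> str:
    body = "\n".join(seq[i : i + width] for i in range(0, len(seq), width))
    return f">{name}\n{body}\n"


def write_genome(spec: SimSpec, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + manifest (JSON, GFF3, BED) for a SimSpec.

    Byte-identical for identical (spec, seed).  Returns output paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chroms, manifest = build_genome(spec)

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for name in chroms:
            fh.write(_wrap_fasta(name, chroms[name]))

    mpath = outdir / "manifest.json"
    mpath.write_text(manifest.to_json() + "\n")

    gff = outdir / "manifest.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        typemap = {"array": "tandem_array", "rdna_unit": "rdna_unit",
                   "igs_copy": "igs_copy", "igs": "intergenic_spacer",
                   "rrna_gene": "rRNA_gene"}
        for i, r in enumerate(manifest.records):
            if r["kind"] not in typemap or "chrom" not in r:
                continue
            attrs = f"ID=feat{i}"
            if "family" in r:
                attrs += f";family={r['family']}"
            if "name" in r:
                attrs += f";Name={r['name']}"
            fh.write("\t".join([
                r["chrom"], "satscout-sim", typemap[r["kind"]],
                str(r["start"]), str(r["end"]), ".", r.get("strand", "."),
                ".", attrs]) + "\n")

    bed = outdir / "manifest.bed"
    with open(bed, "w") as fh:
        for r in manifest.records:
            if "chrom" not in r or "start" not in r:
                continue
            fh.write("\t".join([
                r["chrom"], str(r["start"] - 1), str(r["end"]),
                r["kind"], "0", r.get("strand", ".")]) + "\n")
    return {"fasta": fasta, "manifest": mpath, "gff3": gff, "bed": bed}


def checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# canned study-scale scenarios


def demo_spec(seed: int = 1) -> SimSpec:
    """Desk-scale two-chromosome scenario.

    chrA carries one independent 20-copy array of the 237 bp family;
    chrB emulates the NOR neighbourhood: an independent array plus a
    cluster of six co-oriented rDNA units whose spacers each embed the
    derived family in pairs, reverse-oriented.
    """
    fam_long = MonomerFamilySpec("CS237like", (111, 126))
    # derived family: 27 bp deleted from within the second subunit,
    # leaving a ~210 bp monomer (the shortened IGS-linked variant)
    fam_del = MonomerFamilySpec("delCS237like", (111, 126),
                                planted_indel=(150, 27, ""),
                                orientation="forward")
    cluster = RdnaClusterSpec(embedded_family="delCS237like", n_units=6,
                              embedded_copies=2, igs_length=3595)
    cluster_len = cluster.n_units * (sum(RRNA_LENGTHS.values()) + cluster.igs_length)
    return SimSpec(
        seed=seed,
        monomer_families=[fam_long, fam_del],
        chrom_specs=[
            ChromSpec("chrA", 30_000,
                      [(5_001, ArraySpec("CS237like", copies=20, sub_rate=0.03))]),
            ChromSpec("chrB", cluster_len + 40_000,
                      [(2_001, ArraySpec("CS237like", copies=12, sub_rate=0.03)),
                       (10_001, cluster)]),
        ],
    )
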