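"""Stage orchestration: simulate, scan, and PCR runs over files.

Each run writes its outputs plus a ``run_report.json`` echoing every
parameter needed to reproduce it byte-identically.  Logs go to
standard error; results only to files.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

from Bio import SeqIO

from satscout import __version__
from satscout.aligncore import (
    HSP,
    PRESETS,
    hsps_to_tsv,
    local_search,
    revcomp,
)
from satscout.horstruct import classify_family, decompose_subunits
from satscout.profilemap import genome_fraction, insilico_pcr, profile
from satscout.rdnalink import (
    annotate_rdna,
    classify_config,
    classify_copies,
    delineate_igs,
    pair_multiplicity,
)
from satscout.simrep import (
    ArraySpec,
    ChromSpec,
    MonomerFamilySpec,
    RdnaClusterSpec,
    SimSpec,
    demo_spec,
    surrogate_rrna_refs,
    write_genome,
)
from satscout.tandemscan import build_consensus, delineate_arrays, segment_monomers

log = logging.getLogger("satscout")


def setup_logging() -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s [%(name)s:%(levelname)s] %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2)."""


@dataclass
class RunReport:
    command: str
    version: str = __version__
    parameters: dict = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, **counts) -> None:
        self.stages.append({"stage": name, **counts})

    def write(self, outdir: Path) -> Path:
        p = Path(outdir) / "run_report.json"
        p.write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")
        return p


# ---------------------------------------------------------------------------
# configuration


def spec_from_config(cfg: dict) -> SimSpec:
    """Build a SimSpec from a parsed (YAML) config mapping."""
    try:
        families = [
            MonomerFamilySpec(
                name=f["name"],
                subunit_lengths=tuple(f.get("subunit_lengths", (111, 126))),
                planted_indel=tuple(f["planted_indel"]) if f.get("planted_indel") else None,
                orientation=f.get("orientation", "forward"),
            )
            for f in cfg.get("monomer_families", [])
        ]
        chroms = []
        for c in cfg.get("chromosomes", []):
            feats = []
            for feat in c.get("features", []):
                kind = feat.get("kind", "array")
                start = int(feat["start"])
                if kind == "array":
                    feats.append((start, ArraySpec(
                        family=feat["family"],
                        copies=int(feat.get("copies", 20)),
                        sub_rate=float(feat.get("sub_rate", 0.03)),
                        insertions=tuple(
                            (int(a), s) for a, s in feat.get("insertions", [])),
                        strand=feat.get("strand", "+"))))
                elif kind == "rdna_cluster":
                    feats.append((start, RdnaClusterSpec(
                        embedded_family=feat["embedded_family"],
                        n_units=int(feat.get("n_units", 6)),
                        unit_orientations=tuple(feat["unit_orientations"])
                        if feat.get("unit_orientations") else None,
                        embedded_copies=int(feat.get("embedded_copies", 2)),
                        embedded_sub_rate=float(feat.get("embedded_sub_rate", 0.03)),
                        igs_length=int(feat.get("igs_length", 3595)))))
                else:
                    raise ConfigError(f"unknown feature kind {kind!r}")
            chroms.append(ChromSpec(c["name"], int(c["length"]), feats))
    except KeyError as exc:
        raise ConfigError(f"missing required config field: {exc}") from exc
    return SimSpec(seed=int(cfg.get("seed", 1)), chrom_specs=chroms,
                   monomer_families=families)


def _read_fasta(path: str | Path) -> dict[str, str]:
    recs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not recs:
        raise ConfigError(f"no FASTA records in {path}")
    return recs


# ---------------------------------------------------------------------------
# runs


def run_simulate(outdir: str | Path, config: dict | None = None,
                 seed: int | None = None) -> RunReport:
    """Generate a synthetic genome (demo spec unless configured)."""
    outdir = Path(outdir)
    spec = spec_from_config(config) if config else demo_spec()
    if seed is not None:
        spec.seed = seed
    log.info("simulate: %d chromosomes, seed %d", len(spec.chrom_specs), spec.seed)
    paths = write_genome(spec, outdir)
    report = RunReport("simulate", parameters={"seed": spec.seed})
    report.add_stage("simulate", chromosomes=len(spec.chrom_specs),
                     manifest=str(paths["manifest"]))
    report.write(outdir)
    return report


def run_scan(
    genome_fa: str | Path,
    monomers_fa: str | Path,
    outdir: str | Path,
    rrna_refs_fa: str | Path | None = None,
    preset: str = "relaxed",
    genome_size: int | None = None,
    bin_size: int = 10_000,
) -> RunReport:
    """Full stage chain on a genome: search, arrays, HOR, rDNA, profile."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}")
    chroms = _read_fasta(genome_fa)
    monomers = _read_fasta(monomers_fa)
    total_len = sum(len(s) for s in chroms.values())
    gsize = genome_size or total_len

    report = RunReport("scan", parameters={
        "genome": str(genome_fa), "monomers": str(monomers_fa),
        "preset": preset, "genome_size": gsize, "bin_size": bin_size})

    hsps_by_family: dict[str, list[HSP]] = {}
    strict_by_family: dict[str, list[HSP]] = {}
    for fam, mono in monomers.items():
        for label, params, store in (
                (preset, PRESETS[preset], hsps_by_family),
                ("strict", PRESETS["strict"], strict_by_family)):
            hits: list[HSP] = []
            for chrom, seq in chroms.items():
                hits.extend(local_search(mono, seq, params, subject_id=chrom))
            store[fam] = hits
        log.info("search: family %s -> %d HSPs (%s)", fam,
                 len(hsps_by_family[fam]), preset)
    report.add_stage("local_search", **{
        f"hsps_{f}": len(h) for f, h in hsps_by_family.items()})

    with open(outdir / "hsps.tsv", "w") as fh:
        for fam, hits in hsps_by_family.items():
            fh.write(hsps_to_tsv(hits, query_id=fam))

    # arrays + consensus + decomposition per family
    arrays_all = []
    gff_lines = ["##gff-version 3"]
    decomp_report: dict[str, dict] = {}
    for fam, mono in monomers.items():
        arrays = delineate_arrays(hsps_by_family[fam], len(mono))
        arrays_all.extend((fam, a) for a in arrays)
        report.add_stage(f"delineate_arrays[{fam}]", arrays=len(arrays))
        if arrays:
            big = max(arrays, key=lambda a: a.span)
            seq = chroms[big.chrom][big.start - 1 : big.end]
            if big.strand == "-":
                seq = revcomp(seq)
            segs = segment_monomers(seq, consensus=mono)
            cons = build_consensus(
                [seq[s - 1 : e] for s, e, ln in segs if ln >= 0.8 * len(mono)]
                or [mono])
            dec = decompose_subunits(cons, monomer_id=fam)
            call = classify_family(cons, monomers)
            decomp_report[fam] = {
                "consensus": cons,
                "consensus_length": len(cons),
                "segments": segs,
                "subunit_lengths": list(dec.lengths),
                "inter_subunit_identity_pct": dec.inter_subunit_identity_pct,
                "family_call": asdict(call),
            }
            report.add_stage(f"decompose[{fam}]",
                             subunits=len(dec.subunits),
                             consensus_length=len(cons))
    for fam, a in arrays_all:
        gff_lines.append("\t".join([
            a.chrom, "satscout", "tandem_array", str(a.start), str(a.end),
            ".", a.strand, ".",
            f"family={fam};copy_number={a.copy_number};"
            f"insertion_proportion={a.insertion_proportion};short={a.short}"]))
    (outdir / "arrays.gff3").write_text("\n".join(gff_lines) + "\n")
    (outdir / "decomposition.json").write_text(
        json.dumps(decomp_report, indent=1, sort_keys=True) + "\n")

    # rDNA / IGS stages
    if rrna_refs_fa is not None:
        rrna_refs = _read_fasta(rrna_refs_fa)
    else:
        rrna_refs = surrogate_rrna_refs()
        report.warnings.append(
            "no rRNA references supplied; using bundled surrogates "
            "(only meaningful on simulated genomes)")
    units = annotate_rdna(chroms, rrna_refs)
    igs = delineate_igs(units)
    labeled = []
    for fam in monomers:
        labeled.extend(classify_copies(hsps_by_family[fam], igs, family=fam))
    hist, mode = pair_multiplicity(igs)
    configs = [classify_config(r) for r in igs]
    report.add_stage("rdna", units=len(units), igs=len(igs),
                     igs_linked=sum(1 for r in labeled if r["label"] == "igs_linked"),
                     independent=sum(1 for r in labeled if r["label"] == "independent"),
                     multiplicity_mode=mode,
                     multiplicity_histogram=hist,
                     n_config=sum(1 for c in configs if c.config == "N"),
                     p_config=sum(1 for c in configs if c.config == "P"))
    rdna_lines = ["##gff-version 3"]
    for u in units:
        for g, (s, e) in sorted(u.genes.items(), key=lambda kv: kv[1]):
            rdna_lines.append("\t".join([
                u.chrom, "satscout", "rRNA_gene", str(s), str(e), ".",
                u.orientation, ".", f"Name={g}"]))
        rdna_lines.append("\t".join([
            u.chrom, "satscout", "rdna_unit", str(u.start), str(u.end), ".",
            u.orientation, ".", f"partial={u.partial}"]))
    for r, c in zip(igs, configs):
        rdna_lines.append("\t".join([
            r.chrom, "satscout", "igs", str(r.start), str(r.end), ".", ".", ".",
            f"config={c.config};embedded={len(r.embedded)};complete={r.complete}"]))
        for fam, s, e, strand in r.embedded:
            rdna_lines.append("\t".join([
                r.chrom, "satscout", "igs_copy", str(s), str(e), ".",
                strand, ".", f"family={fam}"]))
    (outdir / "rdna.gff3").write_text("\n".join(rdna_lines) + "\n")

    # profile + fractions
    chrom_lengths = {c: len(s) for c, s in chroms.items()}
    prof_lines = []
    fracs = []
    for fam, mono in monomers.items():
        prof = profile(hsps_by_family[fam], bin_size, chrom_lengths, len(mono))
        prof_lines.append(f"# family={fam}")
        prof_lines.append(prof.to_bedgraph())
        fracs.extend(genome_fraction(
            {preset: hsps_by_family[fam], "strict": strict_by_family[fam]},
            gsize, family=fam))
    (outdir / "profile.bedgraph").write_text("\n".join(prof_lines))
    with open(outdir / "fractions.tsv", "w") as fh:
        fh.write("family\tpreset\tcovered_bp\tgenome_size_bp\tfraction_pct\n")
        for fr in fracs:
            fh.write(f"{fr.family}\t{fr.preset}\t{fr.covered_bp}\t"
                     f"{fr.genome_size_bp}\t{fr.fraction_pct}\n")
    report.add_stage("profile", families=len(monomers))
    report.add_stage("genome_fraction", estimates=len(fracs))
    report.write(outdir)
    log.info("scan complete: %d arrays, %d rDNA units", len(arrays_all), len(units))
    return report


def run_pcr(
    template_fa: str | Path,
    fwd_primer: str,
    rev_primer: str,
    outdir: str | Path,
    max_len: int = 3000,
    max_mismatch: int = 2,
) -> RunReport:
    """In-silico PCR on every template record; ladder TSV per record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    templates = _read_fasta(template_fa)
    report = RunReport("pcr", parameters={
        "fwd": fwd_primer, "rev": rev_primer, "max_len": max_len,
        "max_mismatch": max_mismatch})
    rows = ["template\tamplicon\tlength_bp"]
    for name, seq in templates.items():
        ladder = insilico_pcr(seq, fwd_primer, rev_primer, max_len, max_mismatch)
        if not ladder.lengths:
            log.warning("pcr: no amplicons on template %s", name)
            report.warnings.append(f"no amplicons on template {name}")
        for i, ln in enumerate(ladder.lengths):
            rows.append(f"{name}\t{i + 1}\t{ln}")
        report.add_stage(f"pcr[{name}]", amplicons=len(ladder.lengths),
                         ladder_step=ladder.step)
    (outdir / "ladder.tsv").write_text("\n".join(rows) + "\n")
    report.write(outdir)
    return report
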