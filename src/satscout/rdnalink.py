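"""45S rDNA unit annotation, IGS delineation and repeat-linkage calling.

A 45S rDNA unit is the tandem 18S-ITS1-5.8S-ITS2-26S block; the
intergenic spacer (IGS) runs from the 26S 3' end of one unit to the
18S 5' end of the next.  This module assembles gene-level alignment
hits into oriented units, cuts out the spacers between adjacent units,
classifies satellite-repeat hits as independent-array copies versus
IGS-linked copies, reports the per-spacer embedded-copy multiplicity
(the diagnostic "always in pairs" signature of the IGS-linked variant),
labels each spacer N (between co-oriented units) or P (between
inverted units), and infers the deletion separating two IGS length
variants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from satscout.aligncore import (
    DEFAULT_SCORING,
    HSP,
    Scoring,
    SearchParams,
    global_align,
    local_search,
)
from satscout.horstruct import IndelCall, _scan_indels

_GENE_ORDER = ("18S", "5.8S", "26S")


@dataclass
class RdnaUnit:
    """One annotated 45S rDNA unit (transcribed block, IGS excluded)."""

    chrom: str
    genes: dict[str, tuple[int, int]]  # gene -> 1-based inclusive interval
    orientation: str  # "+" | "-"
    partial: bool = False

    @property
    def start(self) -> int:
        return min(s for s, _ in self.genes.values())

    @property
    def end(self) -> int:
        return max(e for _, e in self.genes.values())


@dataclass
class IgsRegion:
    """An intergenic spacer between two adjacent rDNA units."""

    chrom: str
    start: int
    end: int
    upstream: RdnaUnit | None
    downstream: RdnaUnit | None
    embedded: list[tuple[str, int, int, str]] = field(default_factory=list)
    # embedded: (family, start, end, orientation)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def complete(self) -> bool:
        return (self.upstream is not None and self.downstream is not None
                and not self.upstream.partial and not self.downstream.partial)


@dataclass
class SpacerConfig:
    """N/P orientation class of a spacer between rDNA units."""

    config: str  # "N" | "P" | "undetermined"
    flank_orientations: tuple[str | None, str | None]
    evidence: str = ""


# ---------------------------------------------------------------------------


def annotate_rdna(
    chroms: dict[str, str],
    rrna_refs: dict[str, str],
    params: SearchParams | None = None,
    scoring: Scoring = DEFAULT_SCORING,
    max_intergene_gap: int = 5000,
) -> list[RdnaUnit]:
    """Locate 45S rDNA units by aligning rRNA gene references.

    Gene hits on each chromosome are grouped into units when they occur
    in transcription order (18S < 5.8S < 26S along the strand) on a
    consistent strand with gaps below ``max_intergene_gap`` (the ITS
    scale).  Units missing a gene are flagged partial.
    """
    if params is None:
        params = SearchParams(word_size=12, min_identity_pct=90.0,
                              min_qcov_pct=90.0)
    units: list[RdnaUnit] = []
    for chrom in chroms:
        hits: list[tuple[int, int, str, str]] = []  # start, end, strand, gene
        for gene in _GENE_ORDER:
            if gene not in rrna_refs:
                continue
            for h in local_search(rrna_refs[gene], chroms[chrom], params,
                                  scoring, subject_id=chrom):
                hits.append((h.subject_start, h.subject_end, h.strand, gene))
        hits.sort()
        i = 0
        while i < len(hits):
            strand = hits[i][2]
            # expected gene order along forward coordinates
            expected = _GENE_ORDER if strand == "+" else _GENE_ORDER[::-1]
            genes: dict[str, tuple[int, int]] = {}
            j = i
            k = 0
            while j < len(hits) and k < 3:
                s, e, st, g = hits[j]
                if st != strand:
                    break
                if genes and s - max(v[1] for v in genes.values()) > max_intergene_gap:
                    break
                if g == expected[k]:
                    genes[g] = (s, e)
                    j += 1
                    k += 1
                else:
                    break
            if genes:
                units.append(RdnaUnit(chrom, genes, strand,
                                      partial=len(genes) < 3))
                i = j
            else:
                i += 1
    units.sort(key=lambda u: (u.chrom, u.start))
    return units


def delineate_igs(units: list[RdnaUnit]) -> list[IgsRegion]:
    """One IGS per adjacent unit pair, plus flagged partials at ends.

    For co-oriented forward units the spacer runs from the upstream
    26S 3' end + 1 to the downstream 18S 5' end - 1; between inverted
    units it is simply the gap between the flanking genes, whatever
    they are — its N/P class is decided by ``classify_config``.
    Overlapping units are rejected.
    """
    out: list[IgsRegion] = []
    by_chrom: dict[str, list[RdnaUnit]] = {}
    for u in units:
        by_chrom.setdefault(u.chrom, []).append(u)
    for chrom, us in by_chrom.items():
        us = sorted(us, key=lambda u: u.start)
        for a, b in zip(us, us[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping rDNA units on {chrom}")
            out.append(IgsRegion(chrom, a.end + 1, b.start - 1, a, b))
        if len(us) == 1:
            u = us[0]
            out.append(IgsRegion(chrom, u.end + 1, u.end, u, None))
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


# ---------------------------------------------------------------------------


def classify_copies(
    hits: list[HSP],
    igs_regions: list[IgsRegion],
    family: str = "repeat",
    min_overlap_frac: float = 0.90,
) -> list[dict]:
    """Label every repeat hit independent or igs_linked (exhaustively).

    A hit is igs_linked iff at least ``min_overlap_frac`` of its span
    lies inside one IGS; linked copies are also appended to that
    region's ``embedded`` list.  Returns one record per hit.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, r in enumerate(igs_regions):
        if r.end >= r.start:
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, idx)
    labeled: list[dict] = []
    for h in hits:
        label, igs_idx = "independent", None
        tree = trees.get(h.subject_id)
        if tree is not None:
            for iv in tree.overlap(h.subject_start, h.subject_end + 1):
                ov = min(h.subject_end, iv.end - 1) - max(h.subject_start, iv.begin) + 1
                if ov >= min_overlap_frac * h.subject_span:
                    label, igs_idx = "igs_linked", iv.data
                    break
        rec = {"chrom": h.subject_id, "start": h.subject_start,
               "end": h.subject_end, "strand": h.strand, "family": family,
               "label": label, "igs_index": igs_idx}
        labeled.append(rec)
        if igs_idx is not None:
            igs_regions[igs_idx].embedded.append(
                (family, h.subject_start, h.subject_end, h.strand))
    return labeled


def pair_multiplicity(igs_regions: list[IgsRegion]) -> tuple[dict[int, int], int]:
    """Histogram of embedded-copy counts per complete IGS, and its mode.

    Ties on the mode break to the smaller count.  The canonical
    IGS-linked satellite signature is a mode of 2: copies always in
    pairs next to the downstream 18S.
    """
    counts = Counter(len(r.embedded) for r in igs_regions if r.complete)
    if not counts:
        return {}, 0
    mode = max(sorted(counts), key=lambda c: counts[c])
    return dict(sorted(counts.items())), mode


def classify_config(igs: IgsRegion) -> SpacerConfig:
    """N when the flanking units are co-oriented, P when inverted."""
    up = igs.upstream.orientation if igs.upstream is not None else None
    down = igs.downstream.orientation if igs.downstream is not None else None
    if up is None or down is None:
        return SpacerConfig("undetermined", (up, down), "partial IGS at contig end")
    if up == down:
        return SpacerConfig("N", (up, down), "co-oriented flanking units")
    return SpacerConfig("P", (up, down), "inverted flanking units")


# ---------------------------------------------------------------------------


@dataclass
class IgsVariantDiff:
    """Difference between two IGS length variants under a deletion model."""

    deletion_length: int
    breakpoint: int | None  # last aligned long-variant position before the gap
    events: list[IndelCall] = field(default_factory=list)


def compare_igs_variants(
    long_igs: str | int,
    short_igs: str | int,
    scoring: Scoring = DEFAULT_SCORING,
    min_event: int = 30,
) -> IgsVariantDiff:
    """Infer the internal deletion separating two IGS variants.

    With two sequences, a global alignment is scanned for large gap
    runs; a single contiguous internal deletion is the expected outcome
    and the breakpoint is the last aligned long-variant position before
    it.  More than one large gap yields a multi-event report, not an
    error.  With two integer lengths (the collinear single-deletion
    model), the deletion is simply their difference and the breakpoint
    is undetermined.
    """
    if isinstance(long_igs, int) and isinstance(short_igs, int):
        if short_igs > long_igs:
            raise ValueError("long variant must not be shorter than short variant")
        return IgsVariantDiff(long_igs - short_igs, None)
    if isinstance(long_igs, int) or isinstance(short_igs, int):
        raise TypeError("pass two sequences or two integer lengths")

    aln = global_align(short_igs, long_igs, scoring)
    events = _scan_indels(aln.aligned_subject, aln.aligned_query, min_event)
    dels = [e for e in events if e.direction == "deletion-in-query"]
    if not dels:
        return IgsVariantDiff(0, None, events)
    main = max(dels, key=lambda e: e.length)
    return IgsVariantDiff(
        deletion_length=sum(e.length for e in dels),
        breakpoint=main.position - 1,
        events=events,
    )
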