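"""Chromosome-scale repeat profiles, genome fractions, in-silico PCR.

Binned HSP-coverage profiles summarise where a satellite family lives
on each chromosome and delimit its array regions; genome-fraction
estimates divide the merged HSP footprint by the genome size at each
search stringency (a strict search can only lose coverage, so the
strict fraction bounds the relaxed one from below).  The in-silico PCR
predictor turns primer sites on a tandem template into the ladder of
amplicon lengths that array PCR produces on a gel, with the ladder
step recovering the monomer length.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import numpy as np

from satscout.aligncore import HSP, revcomp


@dataclass
class GenomeProfile:
    """Binned HSP coverage per chromosome plus merged array regions."""

    bin_size: int
    coverage: dict[str, np.ndarray]  # chrom -> covered bases per bin
    regions: list[tuple[str, int, int]]  # merged array regions, 1-based

    def to_bedgraph(self) -> str:
        lines = []
        for chrom in sorted(self.coverage):
            cov = self.coverage[chrom]
            for i, c in enumerate(cov):
                if c > 0:
                    lines.append(
                        f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t{int(c)}")
        return "\n".join(lines) + ("\n" if lines else "")


@dataclass
class FractionEstimate:
    family: str
    preset: str
    covered_bp: int
    genome_size_bp: int
    fraction_pct: float


@dataclass
class AmpliconLadder:
    """Predicted amplicon lengths for one primer pair on one template."""

    primer_pair: tuple[str, str]
    lengths: list[int]
    step: int | None  # median of consecutive differences; None if < 2 bands

    @property
    def n_amplicons(self) -> int:
        return len(self.lengths)

    def to_tsv(self) -> str:
        head = "amplicon\tlength_bp\n"
        rows = "".join(f"{i + 1}\t{ln}\n" for i, ln in enumerate(self.lengths))
        return head + rows


# ---------------------------------------------------------------------------


def _merge_intervals(ivs: list[tuple[int, int]], max_gap: int = 0) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s - merged[-1][1] - 1 <= max_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def profile(
    hsps: list[HSP],
    bin_size: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
    monomer_len: int = 237,
    region_gap: int | None = None,
) -> GenomeProfile:
    """Binned coverage of HSPs plus merged array regions.

    Each bin counts the HSP bases falling inside it, so summed bin
    coverage equals summed (clipped) HSP length.  HSP intervals closer
    than ``region_gap`` (default two monomer lengths) merge into one
    array region.
    """
    if region_gap is None:
        region_gap = 2 * monomer_len
    coverage: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for h in hsps:
        by_chrom.setdefault(h.subject_id, []).append((h.subject_start, h.subject_end))

    for chrom, ivs in by_chrom.items():
        length = (chrom_lengths or {}).get(chrom, max(e for _, e in ivs))
        nbins = (length + bin_size - 1) // bin_size
        cov = np.zeros(nbins, dtype=np.int64)
        for s, e in ivs:
            s0, e0 = s - 1, min(e, length)  # 0-based half-open clip
            b0, b1 = s0 // bin_size, (e0 - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo = max(s0, b * bin_size)
                hi = min(e0, (b + 1) * bin_size)
                cov[b] += hi - lo
        coverage[chrom] = cov

    regions = []
    for chrom in sorted(by_chrom):
        for s, e in _merge_intervals(by_chrom[chrom], region_gap):
            regions.append((chrom, s, e))
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            if chrom not in coverage:
                coverage[chrom] = np.zeros((length + bin_size - 1) // bin_size,
                                           dtype=np.int64)
    return GenomeProfile(bin_size, coverage, regions)


def genome_fraction(
    hsps_by_preset: dict[str, list[HSP]],
    genome_size: int,
    family: str = "repeat",
) -> list[FractionEstimate]:
    """Merged-HSP genome fraction per stringency preset.

    Overlapping HSP intervals are merged before summing, so nested or
    duplicated hits never inflate the estimate.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    out = []
    for preset, hsps in hsps_by_preset.items():
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for h in hsps:
            by_chrom.setdefault(h.subject_id, []).append(
                (h.subject_start, h.subject_end))
        covered = sum(
            e - s + 1
            for ivs in by_chrom.values()
            for s, e in _merge_intervals(ivs))
        out.append(FractionEstimate(
            family, preset, covered, genome_size,
            round(100.0 * covered / genome_size, 6)))
    return out


# ---------------------------------------------------------------------------
# in-silico PCR


def _site_matches(window: str, primer: str, max_mismatch: int,
                  exact_three_prime: str) -> bool:
    if len(window) != len(primer):
        return False
    if exact_three_prime == "end":
        if window[-3:] != primer[-3:]:
            return False
    else:  # the primer's 3' trio maps to the window start (minus strand site)
        if window[:3] != primer[:3]:
            return False
    mism = sum(1 for a, b in zip(window, primer) if a != b)
    return mism <= max_mismatch


def _find_sites(template: str, primer: str, max_mismatch: int) -> tuple[list[int], list[int]]:
    """Plus-strand and minus-strand binding sites (0-based start positions).

    A plus site is a template window matching the primer with an exact
    3'-terminal trio; a minus site matches the primer's reverse
    complement (whose first three template bases carry the primer's 3'
    end, so those must be exact).
    """
    L = len(primer)
    rc = revcomp(primer)
    plus, minus = [], []
    for i in range(len(template) - L + 1):
        w = template[i : i + L]
        if _site_matches(w, primer, max_mismatch, "end"):
            plus.append(i)
        if _site_matches(w, rc, max_mismatch, "start"):
            minus.append(i)
    return plus, minus


def insilico_pcr(
    template: str,
    fwd_primer: str,
    rev_primer: str,
    max_len: int = 3000,
    max_mismatch: int = 2,
    min_len: int = 40,
) -> AmpliconLadder:
    """Predict the amplicon ladder for a primer pair on a template.

    Both primers are searched on both strands; every convergent site
    pair (a plus-strand site left of a minus-strand site) within
    ``max_len`` yields an amplicon spanning both primer footprints.
    Sites require at most ``max_mismatch`` mismatches and an exact
    3'-terminal trio.  The ladder step is the median difference of
    consecutive distinct amplicon lengths.
    """
    template = template.upper()
    fwd, rev = fwd_primer.upper(), rev_primer.upper()
    for p in (fwd, rev):
        if len(p) < 15:
            raise ValueError("primers must be >= 15 bp")

    plus_sites: list[int] = []
    minus_ends: list[int] = []  # 0-based inclusive end of minus-strand site
    for p in (fwd, rev):
        plus, minus = _find_sites(template, p, max_mismatch)
        plus_sites.extend(plus)
        minus_ends.extend(m + len(p) - 1 for m in minus)

    lengths = []
    for s in plus_sites:
        for e in minus_ends:
            ln = e - s + 1
            if min_len <= ln <= max_len:
                lengths.append(ln)
    lengths = sorted(set(lengths))
    step = None
    if len(lengths) >= 2:
        diffs = [b - a for a, b in zip(lengths, lengths[1:])]
        step = int(median(diffs))
    return AmpliconLadder((fwd_primer, rev_primer), lengths, step)
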