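"""De novo tandem-period detection, monomer segmentation and consensus.

The detector finds candidate periods from the recurrence distances of
exact k-mers (the distance between two occurrences of the same word in
a tandem array equals the array period), ranks them by the fraction of
the sequence covered by recurring words, and refines each candidate by
aligning adjacent putative copies.  Segmentation then tiles an array
with a consensus monomer by repeated prefix alignment, reporting
terminal partial copies at their true shorter lengths, and the
consensus builder takes a per-column majority vote over a progressive
alignment of all copies against the longest one.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from satscout.aligncore import (
    DEFAULT_SCORING,
    HSP,
    Scoring,
    global_align,
)


@dataclass
class PeriodCall:
    """A candidate tandem period with its support and phase.

    ``support`` is the fraction of the sequence covered by k-mer
    recurrences at this period; ``phase`` the first supporting offset.
    """

    period: int
    support: float
    phase: int = 0


@dataclass
class TandemArray:
    """A delineated tandem array with segmented monomer copies.

    ``copy_number`` is fractional: total copy length over consensus (or
    monomer) length.  ``insertion_proportion`` is the fraction of the
    array span not assigned to monomer copies.  Arrays under 2.5 copies
    are flagged ``short`` — real but below the scale cytogenetic
    methods resolve.
    """

    chrom: str
    start: int
    end: int
    strand: str
    consensus: str
    copies: list[tuple[int, int, float]]
    copy_number: float
    insertion_proportion: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def short(self) -> bool:
        return self.copy_number < 2.5


# ---------------------------------------------------------------------------
# period detection


def _adjacent_copy_identity(seq: str, period: int) -> float:
    """Mean identity between adjacent period-sized windows (up to 3 probes)."""
    n = len(seq)
    if 2 * period > n:
        return 0.0
    probes = []
    for frac in (0.0, 0.4, 0.8):
        a = int(frac * (n - 2 * period))
        probes.append((seq[a : a + period], seq[a + period : a + 2 * period]))
    idents = [global_align(x, y).identity_pct for x, y in probes if x and y]
    return sum(idents) / len(idents) if idents else 0.0


def detect_period(
    seq: str,
    k: int = 12,
    max_period: int = 2000,
    min_support: float = 0.05,
    max_calls: int = 5,
) -> list[PeriodCall]:
    """Candidate tandem periods ranked by k-mer recurrence support.

    For every exact k-mer occurring more than once, the distances
    between consecutive occurrences vote for a period; the sequence
    coverage of the voting word pairs gives the support.  Candidates
    are refined by aligning adjacent putative copies and dropped when
    the adjacent-copy identity falls below 60%.  Returns an empty list
    when nothing periodic is present.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 2 * k:
        return []

    positions: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        positions.setdefault(seq[i : i + k], []).append(i)

    votes: dict[int, list[int]] = {}  # distance -> supporting start positions
    for pos in positions.values():
        for a, b in zip(pos, pos[1:]):
            d = b - a
            if 2 <= d <= max_period:
                votes.setdefault(d, []).append(a)

    calls: list[PeriodCall] = []
    seen: set[int] = set()
    for d, starts in sorted(votes.items(), key=lambda kv: (-len(kv[1]), kv[0])):
        if len(calls) >= max_calls:
            break
        if any(abs(d - s) <= 2 for s in seen):
            continue
        covered = _coverage(starts, d, k, n)
        support = covered / n
        if support < min_support:
            continue
        if d > k and _adjacent_copy_identity(seq, d) < 60.0:
            continue
        calls.append(PeriodCall(period=d, support=round(support, 4),
                                phase=min(starts) % d))
        seen.add(d)
    calls.sort(key=lambda c: (-c.support, c.period))
    return calls


def _coverage(starts: list[int], d: int, k: int, n: int) -> int:
    """Bases covered by the word footprints of recurrences at distance d."""
    ivs = []
    for a in sorted(starts):
        ivs.append((a, a + k))
        ivs.append((a + d, a + d + k))
    ivs.sort()
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    total += cur_e - cur_s
    return min(total, n)


# ---------------------------------------------------------------------------
# segmentation


def segment_monomers(
    seq: str,
    consensus: str | None = None,
    period: int | None = None,
    min_tail_frac: float = 0.25,
) -> list[tuple[int, int, int]]:
    """Tile a periodic region with monomer copies; 1-based (start, end, length).

    Phasing is against ``consensus`` when given; otherwise a consensus
    is derived from naive period-sized tiles.  Each copy boundary is
    the best prefix alignment of the consensus onto the remaining
    sequence, so copies absorb small indels (lengths may deviate from
    the consensus length).  A terminal remnant of at least
    ``min_tail_frac`` of a monomer is reported as a partial copy with
    its true shorter length.
    """
    seq = seq.upper()
    if consensus is None:
        if period is None:
            raise ValueError("segment_monomers needs a consensus or a period")
        tiles = [seq[i : i + period] for i in range(0, len(seq) - period + 1, period)]
        if not tiles:
            raise ValueError("sequence shorter than one period")
        consensus = build_consensus(tiles)
    L = len(consensus)
    out: list[tuple[int, int, int]] = []
    pos = 0
    n = len(seq)
    while n - pos >= L * (1 - min_tail_frac):
        window = seq[pos : pos + int(1.6 * L)]
        res = edlib.align(consensus, window, mode="SHW", task="locations")
        end = res["locations"][0][1]  # 0-based inclusive end in window
        if end is None or end < 0:
            break
        out.append((pos + 1, pos + end + 1, end + 1))
        pos += end + 1
    tail = n - pos
    if tail >= min_tail_frac * L:
        out.append((pos + 1, n, tail))
    return out


# ---------------------------------------------------------------------------
# consensus


def build_consensus(copies: list[str], scoring: Scoring = DEFAULT_SCORING) -> str:
    """Column-majority consensus of monomer copies.

    Copies are progressively aligned against the longest copy (ties:
    first occurrence); each anchor column takes the majority character
    with a deterministic tie-break (a real base beats a gap; bases tie
    in A<C<G<T order).  Majority-gap columns are dropped, so the
    consensus can be shorter than the anchor.
    """
    if not copies:
        raise ValueError("build_consensus requires at least one copy")
    copies = [c.upper() for c in copies]
    if len(copies) == 1:
        return copies[0]
    anchor = max(copies, key=len)
    counts: list[dict[str, int]] = [dict() for _ in range(len(anchor))]

    for cp in copies:
        if cp == anchor:
            cols = anchor
            gapped_anchor = anchor
        else:
            aln = global_align(anchor, cp, scoring)
            gapped_anchor, cols = aln.aligned_query, aln.aligned_subject
        ai = 0
        for a_ch, c_ch in zip(gapped_anchor, cols):
            if a_ch == "-":
                continue  # insertion relative to anchor: no column
            counts[ai][c_ch] = counts[ai].get(c_ch, 0) + 1
            ai += 1

    order = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
    out = []
    for col in counts:
        best = max(col.items(), key=lambda kv: (kv[1], -order.get(kv[0], 9)))
        if best[0] != "-":
            out.append(best[0])
    return "".join(out)


# ---------------------------------------------------------------------------
# array delineation from HSPs


def delineate_arrays(
    hsps: list[HSP],
    monomer_len: int,
    max_gap: int | None = None,
    chrom: str = "",
    consensus: str = "",
) -> list[TandemArray]:
    """Chain monomer HSPs into tandem arrays.

    Same-strand neighbours separated by at most ``max_gap`` (default
    two monomer lengths, tolerating non-repeat insertions without
    fusing distinct loci) belong to one array.  Fractional copy number
    is total HSP length over the monomer length, reported to 1 decimal.
    """
    if max_gap is None:
        max_gap = 2 * monomer_len
    arrays: list[TandemArray] = []
    for strand in ("+", "-"):
        hs = sorted(
            (h for h in hsps if h.strand == strand),
            key=lambda h: (h.subject_id, h.subject_start))
        chain: list[HSP] = []
        for h in hs:
            if chain and (h.subject_id != chain[-1].subject_id
                          or h.subject_start - chain[-1].subject_end - 1 > max_gap):
                arrays.append(_chain_to_array(chain, monomer_len, chrom, consensus))
                chain = []
            chain.append(h)
        if chain:
            arrays.append(_chain_to_array(chain, monomer_len, chrom, consensus))
    arrays.sort(key=lambda a: (a.chrom, a.start))
    return arrays


def _chain_to_array(
    chain: list[HSP], monomer_len: int, chrom: str, consensus: str
) -> TandemArray:
    start = min(h.subject_start for h in chain)
    end = max(h.subject_end for h in chain)
    copies = [(h.subject_start, h.subject_end, h.identity_pct) for h in chain]
    assigned = sum(h.subject_span for h in chain)
    span = end - start + 1
    return TandemArray(
        chrom=chain[0].subject_id or chrom,
        start=start, end=end, strand=chain[0].strand,
        consensus=consensus,
        copies=copies,
        copy_number=round(assigned / monomer_len, 1),
        insertion_proportion=round(max(0.0, 1.0 - assigned / span), 4),
    )
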