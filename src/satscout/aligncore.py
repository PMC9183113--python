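"""Pairwise alignment primitives and a seed-and-extend homology search.

The module provides the alignment currency used throughout the pipeline:
affine-gap global alignment with a percent-identity statistic, and a
BLAST-like local search returning high-scoring pairs (HSPs) on both
strands.  Default scoring is blastn-flavoured (match +1, mismatch -2,
gap open -5, gap extend -2) so that satellite monomers diverged to the
85-94% identity range typical of young plant satDNA remain well inside
the search thresholds.

Percent identity counts matches over all alignment columns, internal
gap columns included, with terminal (end-gap) columns trimmed — the
convention of interactive alignment editors, which keeps identities of
length-mismatched subunits comparable across families.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = frozenset("ACGTN")


class AlignError(ValueError):
    """Invalid input to an alignment primitive."""


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring scheme.

    ``gap_open`` is the cost charged once per gap, ``gap_extend`` per
    gapped column (BLAST convention: a gap of length k scores
    ``gap_open + k * gap_extend``).
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


DEFAULT_SCORING = Scoring()


@dataclass
class Alignment:
    """A gapped pairwise alignment with its score and percent identity."""

    aligned_query: str
    aligned_subject: str
    score: float
    identity_pct: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise AlignError("aligned strings must have equal length")


@dataclass
class HSP:
    """A local high-scoring pair, 1-based inclusive on both axes.

    Strand '-' means the query matches the reverse complement of the
    subject; subject coordinates always refer to the forward strand.
    """

    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    identity_pct: float
    score: float
    query_coverage_pct: float
    subject_id: str = ""

    @property
    def subject_span(self) -> int:
        return self.subject_end - self.subject_start + 1


@dataclass(frozen=True)
class SearchParams:
    """Thresholds for the local homology search.

    ``score_floor`` plays the role of an e-value cutoff: extension stops
    once no local alignment in a seeded window reaches it.  ``None``
    derives a floor from the query length (half of the perfect score).
    """

    word_size: int = 10
    min_identity_pct: float = 85.0
    min_qcov_pct: float = 95.0
    score_floor: float | None = None

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise AlignError("word_size must be >= 4")
        for p in (self.min_identity_pct, self.min_qcov_pct):
            if not 0.0 <= p <= 100.0:
                raise AlignError("percent thresholds must lie in [0, 100]")


#: The two stringencies used for chromosome profiling: the standard
#: screen (85% identity, 95% query coverage) and the high-stringency
#: variant (90%+ identity) used to delimit the youngest array copies.
PRESETS: dict[str, SearchParams] = {
    "relaxed": SearchParams(word_size=10, min_identity_pct=85.0, min_qcov_pct=95.0),
    "strict": SearchParams(word_size=10, min_identity_pct=90.0, min_qcov_pct=95.0),
}


def _check_seq(seq: str, allow_n: bool = True) -> str:
    s = seq.upper()
    allowed = _VALID if allow_n else frozenset("ACGT")
    bad = set(s) - allowed
    if bad:
        raise AlignError(f"invalid nucleotide characters: {sorted(bad)!r}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide sequence (ACGTN, case kept)."""
    if set(seq.upper()) - _VALID:
        raise AlignError("revcomp: sequence contains non-ACGTN characters")
    return seq.translate(_COMPLEMENT)[::-1]


def _make_aligner(scoring: Scoring, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # biopython charges open_gap_score on the first gapped column
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _identity_from_strings(aq: str, asub: str) -> float:
    # trim end-gap columns
    n = len(aq)
    lo = 0
    while lo < n and (aq[lo] == "-" or asub[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (aq[hi - 1] == "-" or asub[hi - 1] == "-"):
        hi -= 1
    if hi <= lo:
        return 0.0
    matches = sum(1 for a, b in zip(aq[lo:hi], asub[lo:hi]) if a == b and a != "-")
    return 100.0 * matches / (hi - lo)


def identity_pct(alignment: Alignment) -> float:
    """Percent identity: matches / alignment columns, end gaps trimmed."""
    return _identity_from_strings(alignment.aligned_query, alignment.aligned_subject)


def global_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> Alignment:
    """Optimal affine-gap global alignment of two sequences.

    Traceback is deterministic (the aligner's first optimal path), so
    repeated calls give byte-identical alignments.
    """
    a = _check_seq(a)
    b = _check_seq(b)
    if not a or not b:
        raise AlignError("global_align requires non-empty sequences")
    aligner = _make_aligner(scoring, "global")
    aln = aligner.align(a, b)[0]
    aq, asub = str(aln[0]), str(aln[1])
    return Alignment(aq, asub, float(aln.score), _identity_from_strings(aq, asub))


def _local_best(
    aligner: Align.PairwiseAligner, query: str, window: str
) -> tuple[float, int, int, int, int, float] | None:
    """Best local alignment of query vs window.

    Returns (score, q_start, q_end, w_start, w_end, identity) with
    0-based half-open coordinates, or None for an empty alignment.
    """
    alns = aligner.align(query, window)
    if len(alns) == 0:
        return None
    aln = alns[0]
    qblocks, wblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    aq, aw = str(aln[0]), str(aln[1])
    ident = _identity_from_strings(aq, aw)
    return (
        float(aln.score),
        int(qblocks[0][0]),
        int(qblocks[-1][1]),
        int(wblocks[0][0]),
        int(wblocks[-1][1]),
        ident,
    )


def _search_forward(
    query: str,
    subject: str,
    params: SearchParams,
    scoring: Scoring,
) -> list[tuple[int, int, int, int, float, float]]:
    """Seed-and-extend on the given subject orientation.

    Returns tuples (qs, qe, ss, se, score, identity) 0-based half-open.
    """
    k = params.word_size
    n, m = len(query), len(subject)
    words: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        words.setdefault(query[i : i + k], []).append(i)

    # seed subject positions carrying an exact query word
    seed_pos: list[int] = []
    for j in range(m - k + 1):
        if subject[j : j + k] in words:
            seed_pos.append(j)
    if not seed_pos:
        return []

    # cluster seeds into windows; pad by one query length on each side
    windows: list[tuple[int, int]] = []
    start = prev = seed_pos[0]
    for j in seed_pos[1:]:
        if j - prev > n:
            windows.append((max(0, start - n), min(m, prev + k + n)))
            start = j
        prev = j
    windows.append((max(0, start - n), min(m, prev + k + n)))

    floor = params.score_floor
    if floor is None:
        floor = 0.5 * n * scoring.match

    aligner = _make_aligner(scoring, "local")
    hits: list[tuple[int, int, int, int, float, float]] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < k:
            return
        best = _local_best(aligner, query, subject[lo:hi])
        if best is None:
            return
        score, qs, qe, ws, we, ident = best
        if score < floor or we <= ws:
            return
        hits.append((qs, qe, lo + ws, lo + we, score, ident))
        recurse(lo, lo + ws)
        recurse(lo + we, hi)

    for lo, hi in windows:
        recurse(lo, hi)
    return hits


def local_search(
    query: str,
    subject: str,
    params: SearchParams = PRESETS["relaxed"],
    scoring: Scoring = DEFAULT_SCORING,
    subject_id: str = "",
) -> list[HSP]:
    """Seed-and-extend local search of a query on both subject strands.

    Exact ``word_size``-mers seed candidate windows; each window is
    exhaustively decomposed into maximal-scoring, mutually disjoint
    local alignments (per strand) by recursive splitting.  HSPs passing
    the identity and query-coverage thresholds are returned sorted by
    subject position; overlapping cross-strand HSPs are reduced to the
    higher-scoring one.
    """
    query = _check_seq(query)
    subject = _check_seq(subject)
    if len(query) < params.word_size:
        raise AlignError("query shorter than word_size")
    n = len(query)
    m = len(subject)

    raw: list[HSP] = []
    for strand, subj in (("+", subject), ("-", revcomp(subject))):
        for qs, qe, ss, se, score, ident in _search_forward(query, subj, params, scoring):
            if strand == "+":
                s1, s2 = ss + 1, se
            else:  # map back to forward coordinates
                s1, s2 = m - se + 1, m - ss
            qcov = 100.0 * (qe - qs) / n
            if ident >= params.min_identity_pct and qcov >= params.min_qcov_pct:
                raw.append(
                    HSP(qs + 1, qe, s1, s2, strand, round(ident, 2), score,
                        round(qcov, 2), subject_id)
                )

    # non-redundancy across strands: drop an HSP whose subject interval
    # overlaps a higher-scoring kept HSP by more than half its length
    raw.sort(key=lambda h: (-h.score, h.subject_start))
    kept: list[HSP] = []
    for h in raw:
        redundant = False
        for g in kept:
            ov = min(h.subject_end, g.subject_end) - max(h.subject_start, g.subject_start) + 1
            if ov > 0.5 * h.subject_span:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.subject_start, h.subject_end))
    return kept


def hsps_to_tsv(hsps: list[HSP], query_id: str = "query") -> str:
    """Render HSPs in BLAST outfmt-6 column order.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send score qcovhsp (the last two replace evalue/bitscore with
    the raw score and query coverage).
    """
    lines = []
    for h in hsps:
        length = h.subject_span
        mism = max(0, round(length * (1 - h.identity_pct / 100.0)))
        ss, se = (h.subject_start, h.subject_end) if h.strand == "+" else (
            h.subject_end, h.subject_start)
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    query_id, h.subject_id or "subject", f"{h.identity_pct:.2f}",
                    length, mism, 0, h.query_start, h.query_end, ss, se,
                    f"{h.score:.1f}", f"{h.query_coverage_pct:.2f}",
                )
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
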