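"""Subunit decomposition of satellite monomers and cross-family indels.

Satellite monomers of the CS-237 type are higher-order repeats: the
monomer is a head-to-tail fusion of two diverged subunits (111 and
126 bp in the canonical family).  ``decompose_subunits`` recovers that
internal structure from the monomer alone by scoring every split point
for inter-half similarity.  ``compare_subunit_families`` aligns
subunits across families and reports the large indels that distinguish
a derived family (such as the single 27 bp deletion separating the
IGS-linked variant's short subunit from its progenitor), and
``classify_family`` assigns monomers to a reference family with the
orientation of the best-scoring strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from satscout.aligncore import (
    DEFAULT_SCORING,
    Scoring,
    global_align,
    revcomp,
    _local_best,
    _make_aligner,
)


@dataclass
class SubunitDecomposition:
    """The internal repeat structure of one monomer."""

    monomer_id: str
    subunits: list[tuple[int, int, int]]  # 1-based (start, end, length)
    inter_subunit_identity_pct: float

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(s[2] for s in self.subunits)


@dataclass
class IndelCall:
    """One indel separating a query subunit from its reference.

    ``position`` is 1-based in the reference: for a deletion-in-query
    it is the first deleted reference base; for an insertion-in-query
    the reference base after which the insertion sits.  ``sequence``
    is taken from the ungapped side.
    """

    position: int
    length: int
    sequence: str
    direction: str  # "deletion-in-query" | "insertion-in-query"

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError("IndelCall length must equal |sequence|")


@dataclass
class FamilyCall:
    family: str
    orientation: str  # "same" | "reverse"
    identity_pct: float


# ---------------------------------------------------------------------------


def _has_internal_similarity(
    a: str, b: str, scoring: Scoring,
    min_len: int = 20, min_ident: float = 55.0,
) -> bool:
    """Local match of >= min_len aligned columns at >= min_ident between halves."""
    aligner = _make_aligner(scoring, "local")
    best = _local_best(aligner, a, b)
    if best is None:
        return False
    _score, qs, qe, _ws, _we, ident = best
    return (qe - qs) >= min_len and ident >= min_ident


def decompose_subunits(
    monomer: str,
    monomer_id: str = "monomer",
    scoring: Scoring = DEFAULT_SCORING,
    min_subunit: int = 20,
    identity_floor: float = 45.0,
) -> SubunitDecomposition:
    """Split a monomer into its two internal subunits by self-comparison.

    Every split point from ``min_subunit`` to L - ``min_subunit`` is
    scored by the affine-gap global alignment of the two halves; the
    best-scoring split defines the subunits (ties break to the smaller
    first subunit).  When the best split's inter-half identity falls
    below ``identity_floor`` or no local off-diagonal match of >= 20
    aligned bases at >= 55% identity exists, the monomer is reported as
    a single subunit.
    """
    monomer = monomer.upper()
    L = len(monomer)
    if L < 2 * min_subunit:
        raise ValueError(f"monomer must be >= {2 * min_subunit} bp")

    best_s, best_score, best_ident = None, None, 0.0
    for s in range(min_subunit, L - min_subunit + 1):
        aln = global_align(monomer[:s], monomer[s:], scoring)
        if best_score is None or aln.score > best_score:
            best_s, best_score, best_ident = s, aln.score, aln.identity_pct

    assert best_s is not None
    dimeric = (
        best_ident >= identity_floor
        and _has_internal_similarity(monomer[:best_s], monomer[best_s:], scoring)
    )
    if not dimeric:
        return SubunitDecomposition(monomer_id, [(1, L, L)], 0.0)
    return SubunitDecomposition(
        monomer_id,
        [(1, best_s, best_s), (best_s + 1, L, L - best_s)],
        round(best_ident, 2),
    )


# ---------------------------------------------------------------------------


def _scan_indels(
    gapped_ref: str, gapped_query: str, min_indel: int
) -> list[IndelCall]:
    """Maximal gap runs in a global alignment, as indel calls.

    End gaps are ignored (length-difference overhangs, not internal
    indels).  Runs shorter than ``min_indel`` are folded into identity.
    """
    n = len(gapped_ref)
    lo = 0
    while lo < n and (gapped_ref[lo] == "-" or gapped_query[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (gapped_ref[hi - 1] == "-" or gapped_query[hi - 1] == "-"):
        hi -= 1

    calls: list[IndelCall] = []
    ref_pos = gapped_ref[:lo].replace("-", "")
    rp = len(ref_pos)  # 1-based ref coordinate of last consumed ref base
    i = lo
    while i < hi:
        if gapped_query[i] == "-" and gapped_ref[i] != "-":
            j = i
            while j < hi and gapped_query[j] == "-" and gapped_ref[j] != "-":
                j += 1
            seq = gapped_ref[i:j]
            if len(seq) >= min_indel:
                calls.append(IndelCall(rp + 1, len(seq), seq, "deletion-in-query"))
            rp += j - i
            i = j
        elif gapped_ref[i] == "-" and gapped_query[i] != "-":
            j = i
            while j < hi and gapped_ref[j] == "-" and gapped_query[j] != "-":
                j += 1
            seq = gapped_query[i:j]
            if len(seq) >= min_indel:
                calls.append(IndelCall(rp, len(seq), seq, "insertion-in-query"))
            i = j
        else:
            rp += 1
            i += 1
    return calls


def compare_subunit_families(
    query_subunit: str,
    reference_subunit: str,
    scoring: Scoring = DEFAULT_SCORING,
    min_indel: int = 5,
) -> tuple[float, list[IndelCall]]:
    """Global alignment of subunits across families, with indel calls.

    Returns (identity_pct, indels).  Only indels of >= ``min_indel`` bp
    are called; shorter gaps count against identity but are not
    reported, separating family-defining events from alignment jitter.
    """
    aln = global_align(query_subunit, reference_subunit, scoring)
    # alignment is query-vs-reference: reference is the second string
    indels = _scan_indels(aln.aligned_subject, aln.aligned_query, min_indel)
    return aln.identity_pct, indels


def apply_deletion(reference: str, call: IndelCall) -> str:
    """Apply a deletion-in-query call to the reference (round-trip check)."""
    if call.direction != "deletion-in-query":
        raise ValueError("apply_deletion expects a deletion-in-query call")
    p = call.position - 1
    return reference[:p] + reference[p + call.length:]


# ---------------------------------------------------------------------------


def classify_family(
    monomer: str,
    references: dict[str, str],
    scoring: Scoring = DEFAULT_SCORING,
    identity_floor: float = 70.0,
) -> FamilyCall:
    """Assign a monomer to the best-matching reference family and strand.

    The winner is the (reference, strand) pair with the highest global
    alignment score; below ``identity_floor`` percent identity the call
    is "unassigned".
    """
    if not references:
        raise ValueError("classify_family requires at least one reference")
    best: tuple[float, float, str, str] | None = None
    for name in references:
        ref = references[name]
        for orient, q in (("same", monomer), ("reverse", revcomp(monomer))):
            aln = global_align(q, ref, scoring)
            key = (aln.score, aln.identity_pct, orient, name)
            if best is None or key > best:
                best = key
    score, ident, orient, name = best
    if ident < identity_floor:
        return FamilyCall("unassigned", orient, round(ident, 2))
    return FamilyCall(name, orient, round(ident, 2))
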