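"""Global pairwise protein alignment, percent identity, and novelty filtering.

Alignment is classic Needleman-Wunsch with affine gaps (BLOSUM62, gap open
-11, gap extend -1 under the convention that a gap of length L costs
``open + (L-1) * extend``; terminal gaps are penalised).  ``X`` scores zero
against everything.

Percent identity uses matched columns over *all* aligned columns (dual-gap
columns cannot occur in a pairwise alignment), so a "100% query coverage"
comparison of two globally aligned full-length proteins is directly
interpretable.  The novelty filter discards a query when its best identity
against the reference panel strictly exceeds the threshold (default 45%).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import ProteinRecord, SeqIOError

GAP_OPEN = -11.0
GAP_EXTEND = -1.0


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    coverage_pct: float

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)


@lru_cache(maxsize=1)
def _aligner() -> PairwiseAligner:
    matrix = substitution_matrices.load("BLOSUM62")
    arr = matrix.copy()
    # X is permitted in queries and scores 0 against every residue
    if "X" in arr.alphabet:
        xi = arr.alphabet.index("X")
        for j in range(len(arr.alphabet)):
            arr[xi, j] = 0.0
            arr[j, xi] = 0.0
    aln = PairwiseAligner(mode="global", substitution_matrix=arr,
                          open_gap_score=GAP_OPEN, extend_gap_score=GAP_EXTEND)
    return aln


def _stats(ga: str, gb: str) -> tuple[float, float]:
    cols = len(ga)
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    aligned_query = sum(1 for x, y in zip(ga, gb) if x != "-" and y != "-")
    qlen = sum(1 for x in ga if x != "-")
    identity = 100.0 * matches / cols if cols else 0.0
    coverage = 100.0 * aligned_query / qlen if qlen else 0.0
    return identity, coverage


def global_align(a: str | ProteinRecord, b: str | ProteinRecord) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    Traceback follows Biopython's deterministic first-alignment rule, which
    prefers residue pairing over gaps; identical calls always return the
    identical alignment.
    """
    sa = a.seq if isinstance(a, ProteinRecord) else a
    sb = b.seq if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise SeqIOError("global_align requires non-empty sequences")
    res = _aligner().align(sa, sb)
    best = res[0]
    ga, gb = best[0], best[1]
    identity, coverage = _stats(ga, gb)
    return PairwiseAlignment(aligned_a=ga, aligned_b=gb, score=float(best.score),
                             identity_pct=identity, coverage_pct=coverage)


def percent_identity(a: str | ProteinRecord, b: str | ProteinRecord) -> tuple[float, float]:
    """Percent identity and query coverage, rounded to 0.1%."""
    aln = global_align(a, b)
    return round(aln.identity_pct, 1), round(aln.coverage_pct, 1)


@dataclass(frozen=True)
class NoveltyDecision:
    keep: bool
    best_ref: str
    best_identity_pct: float


def novelty_filter(query: ProteinRecord, references: list[ProteinRecord],
                   threshold_pct: float = 45.0) -> NoveltyDecision:
    """Discard queries sharing > ``threshold_pct`` identity with any reference.

    The inequality is strict: a hit at exactly the threshold is kept.  The
    best-matching reference and its identity are reported either way.
    """
    if not references:
        raise SeqIOError("novelty_filter requires a non-empty reference set")
    best_id = -1.0
    best_ref = ""
    for ref in references:
        ident, _cov = percent_identity(query, ref)
        if ident > best_id:
            best_id, best_ref = ident, ref.id
    return NoveltyDecision(keep=not best_id > threshold_pct,
                           best_ref=best_ref, best_identity_pct=best_id)
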