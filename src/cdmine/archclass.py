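"""Domain-architecture classification of CGTase candidates.

Known CGTase architectures differ only in what follows the catalytic core:

* ``ABC`` — the minimal functional core: catalytic A/B domains plus the
  C beta-sandwich, with essentially no C-terminal tail;
* ``ABCE_CBM20`` — core plus a starch-binding CBM20 (E) domain fused
  almost directly (the D domain absent);
* ``ABCDE_CBM20`` — the conventional five-domain form, with a ~90-residue
  D domain spacing the core from the CBM20;
* ``ABCDE_ARCH`` — the archaeal form, where the CBM20 is replaced by an
  unrelated E_arch domain.

The core is located by coordinate transfer from the anchored reference
(the mapped end of the reference C domain); the tail after the core is
scanned with CBM20 / E_arch log-odds profiles.  Because no reliable
D-domain motif exists, D is detected by spacer length: a CBM20 hit
starting >= 60 residues after the core implies an intervening D domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from .csrscan import (AnchorResult, ReferenceSeed, _log_odds, _ref_to_query_map,
                      domain_instances, score_window)
from .seqio import ProteinRecord

TAIL_MIN = 40          # residues; shorter tails mean "no appended domain"
D_SPACER_MIN = 60      # residues between core end and CBM20 start implying a D domain
DOMAIN_HIT_MIN_SCORE = 30.0   # log-odds sum over the 100-column profile


@dataclass(frozen=True)
class DomainHit:
    domain_id: str     # CBM20 | E_ARCH
    start: int
    end: int
    score: float


@dataclass(frozen=True)
class ArchitectureCall:
    label: str         # ABC | ABCE_CBM20 | ABCDE_CBM20 | ABCDE_ARCH | OTHER
    core_span: tuple[int, int] | None
    tail_len: int
    tail_hits: tuple[DomainHit, ...]
    warning: str | None = None


@lru_cache(maxsize=1)
def _domain_profiles() -> dict[str, list[dict[str, float]]]:
    return {d: _log_odds(domain_instances(d)) for d in ("CBM20", "E_ARCH")}


def locate_catalytic_core(query: ProteinRecord, anchor: AnchorResult) -> tuple[int, int] | None:
    """Query span of the catalytic ABC core, via the anchored alignment.

    The core runs from the mapped start of the reference A domain (or
    residue 1 when the query keeps its signal peptide / the A start does
    not map) to the mapped end of the reference C domain.  Returns ``None``
    when the C-domain end cannot be mapped (e.g. truncated queries).
    """
    if anchor is None:
        raise ValueError("locate_catalytic_core requires an anchor")
    ref = anchor.ref
    mapping = _ref_to_query_map(anchor.alignment)
    c_start, c_end = ref.domain_spans["C"]
    # require that most of the C domain actually maps, then place the core
    # end by the median alignment offset over the domain: robust against
    # co-optimal tracebacks that strand single residues across a gap
    pairs = [(p, mapping[p]) for p in range(c_start, c_end + 1) if p in mapping]
    if len(pairs) < 0.6 * (c_end - c_start + 1):
        return None
    offsets = sorted(q - p for p, q in pairs)
    median_off = offsets[len(offsets) // 2]
    end = min(c_end + median_off, len(query.seq))
    a_start_ref = ref.domain_spans["A"][0]
    start = mapping.get(a_start_ref, 1)
    return (start, end)


def scan_cterm(query: ProteinRecord, core_span: tuple[int, int]) -> list[DomainHit]:
    """Best CBM20 and E_arch profile hits in the tail after the core."""
    tail_start = core_span[1] + 1
    tail = query.seq[tail_start - 1:]
    hits: list[DomainHit] = []
    for dom, profile in _domain_profiles().items():
        w = len(profile)
        best: DomainHit | None = None
        for s in range(len(tail) - w + 1):
            sc = score_window(profile, tail[s:s + w])
            if best is None or sc > best.score:
                best = DomainHit(domain_id=dom, start=tail_start + s,
                                 end=tail_start + s + w - 1, score=round(sc, 2))
        if best is not None and best.score >= DOMAIN_HIT_MIN_SCORE:
            hits.append(best)
    return hits


def classify_architecture(query: ProteinRecord, anchor: AnchorResult | None) -> ArchitectureCall:
    """Decision table over core location and tail domain content."""
    if anchor is None:
        return ArchitectureCall("OTHER", None, 0, (), warning="no anchor")
    core = locate_catalytic_core(query, anchor)
    if core is None:
        return ArchitectureCall("OTHER", None, 0, (), warning="catalytic core incomplete")
    tail_len = len(query.seq) - core[1]
    if tail_len < TAIL_MIN:
        return ArchitectureCall("ABC", core, tail_len, ())
    hits = scan_cterm(query, core)
    cbm = next((h for h in hits if h.domain_id == "CBM20"), None)
    earch = next((h for h in hits if h.domain_id == "E_ARCH"), None)
    if cbm and earch:
        if cbm.score == earch.score:
            return ArchitectureCall("OTHER", core, tail_len, tuple(hits),
                                    warning="CBM20/E_arch tie")
        if earch.score > cbm.score:
            cbm = None
        else:
            earch = None
    if cbm is not None:
        gap = cbm.start - (core[1] + 1)
        label = "ABCDE_CBM20" if gap >= D_SPACER_MIN else "ABCE_CBM20"
        return ArchitectureCall(label, core, tail_len, (cbm,))
    if earch is not None:
        return ArchitectureCall("ABCDE_ARCH", core, tail_len, (earch,))
    return ArchitectureCall("OTHER", core, tail_len, ())
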