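"""Detection of carbohydrate-metabolism-via-cyclodextrins (CM-CD) gene
clusters in annotated genomes.

The CM-CD pathway couples four steps: extracellular cyclodextrin synthesis
(a CGTase), translocation/internalisation (a type I ATP-dependent ABC
importer, MdxEFG, energised by a shared MsmX ATPase), intracellular
degradation (cyclodextrinase, glucoamylase, glucan phosphorylase) and
glycolytic assimilation (Pgi, PfkA, PykF).  In genomes that encode the
pathway, these genes co-occur in one cluster, with the mdxEFG cassette
typically immediately downstream of the CGTase gene and a sigma-dependent
promoter (-35/-10 boxes, ~17 bp spacer) upstream of the CGTase.

Role calling is exemplar-based: each protein is globally aligned against a
panel of role exemplars and accepts the best role when identity and
coverage clear the thresholds.  The packaged exemplars are synthetic
stand-ins with realistic lengths (the real pathway proteins cannot be
redistributed); the MdxE exemplar carries the printed CldE lipoprotein
signal peptide, and MdxE calls additionally require a lipobox Cys, since
substrate-binding proteins of Gram-positive ABC importers are membrane
lipoproteins.

A cluster call requires the CORE role set {CGTASE, MDXE, MDXF, MDXG,
CDASE, GP} inside a window of at most 40 consecutive genes — the minimal
synthesis -> transport -> degradation chain.  Glycolytic/glucoamylase
roles only upgrade the tier to EXTENDED (some clusters genuinely lack
single assimilation genes).  MsmX is reported genome-wide and flagged
"distal" when outside every cluster, which is its usual location.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import sigpep
from .csrscan import AA20, builtin_refset, _rand_protein
from .pairid import global_align
from .seqio import GeneModel, ProteinRecord

CORE_ROLES = frozenset({"CGTASE", "MDXE", "MDXF", "MDXG", "CDASE", "GP"})
EXTENDED_ROLES = frozenset({"GA", "PGI", "PFKA", "PYKF"})
PATHWAY_ROLES = CORE_ROLES | EXTENDED_ROLES | {"MSMX"}

ROLE_IDENTITY_MIN = 30.0
ROLE_COVERAGE_MIN = 70.0
WINDOW_GENES = 40
CASSETTE_MAX_INTERVENING = 1

# printed CldE-type lipoprotein signal carried by the MdxE exemplar
SIGNAL_MDXE = "MKKYSKILALLTAMVFVLSIALTGCG"

# exemplar lengths chosen to match typical sizes of each protein family
_ROLE_LENGTHS = {
    "MDXE": 420, "MDXF": 300, "MDXG": 280, "CDASE": 570, "GA": 600,
    "GP": 680, "PGI": 450, "PFKA": 320, "PYKF": 470, "MSMX": 365,
}
_ACCESSORY = {  # co-encoded context genes; annotated but never gate a call
    "ACC_HPR": 88, "ACC_MURB": 300, "ACC_RAPZ": 284, "ACC_RODZ": 260,
    "ACC_WHIA": 310, "ACC_POL3A": 640, "ACC_PEPT": 410, "ACC_MATE": 450,
}


@dataclass(frozen=True)
class RoleAssignment:
    gene_id: str
    role: str
    identity_pct: float
    coverage_pct: float
    best_exemplar: str
    lipobox_ok: bool | None = None   # only meaningful for MDXE candidates


@dataclass(frozen=True)
class ClusterCall:
    contig: str
    first_index: int            # indices into the contig's sorted gene list
    last_index: int
    gene_ids: tuple[str, ...]
    n_genes: int
    roles_present: frozenset[str]
    cassette_adjacent: bool
    cgt_upstream: bool
    tier: str                   # CORE | EXTENDED


@dataclass(frozen=True)
class PromoterHit:
    pos_35: int
    pos_10: int
    spacer: int
    score: float

    def __post_init__(self) -> None:
        assert self.spacer == self.pos_10 - (self.pos_35 + 6)


@lru_cache(maxsize=1)
def builtin_exemplars() -> dict[str, list[ProteinRecord]]:
    """Synthetic role exemplars, one or more per role, deterministic."""
    out: dict[str, list[ProteinRecord]] = {"CGTASE": []}
    for seed in builtin_refset():
        out["CGTASE"].append(seed.record)
    rng_base = 400
    for i, (role, length) in enumerate(_ROLE_LENGTHS.items()):
        rng = np.random.default_rng(rng_base + i)
        seq = _rand_protein(rng, length)
        if role == "MDXE":
            seq = SIGNAL_MDXE + seq[len(SIGNAL_MDXE):]
        out[role] = [ProteinRecord(id=f"EX_{role}", seq=seq,
                                   description=f"synthetic {role} exemplar")]
    out["ACCESSORY"] = []
    for i, (name, length) in enumerate(_ACCESSORY.items()):
        rng = np.random.default_rng(500 + i)
        out["ACCESSORY"].append(ProteinRecord(
            id=f"EX_{name}", seq=_rand_protein(rng, length),
            description="synthetic accessory exemplar"))
    return out


def assign_roles(proteins: list[ProteinRecord],
                 exemplars: dict[str, list[ProteinRecord]] | None = None,
                 identity_min: float = ROLE_IDENTITY_MIN,
                 coverage_min: float = ROLE_COVERAGE_MIN) -> dict[str, RoleAssignment]:
    """Best-exemplar role call for every protein, keyed by protein id.

    A role is accepted iff identity >= ``identity_min`` and coverage >=
    ``coverage_min`` against the best-scoring exemplar; otherwise NONE.
    MDXE calls additionally require an SPII lipobox (membrane anchoring of
    the substrate-binding protein).  Exemplars whose length differs from
    the query by more than 2x are skipped: they cannot reach the coverage
    threshold.
    """
    exemplars = exemplars if exemplars is not None else builtin_exemplars()
    if not exemplars:
        raise ValueError("empty exemplar set")
    out: dict[str, RoleAssignment] = {}
    for prot in proteins:
        best = None  # (score, role, exemplar_id, identity, coverage)
        for role, exes in exemplars.items():
            for ex in exes:
                ratio = len(ex.seq) / len(prot.seq)
                if ratio < 0.5 or ratio > 2.0:
                    continue
                aln = global_align(prot.seq, ex.seq)
                if best is None or aln.score > best[0]:
                    best = (aln.score, role, ex.id,
                            round(aln.identity_pct, 1), round(aln.coverage_pct, 1))
        role, lipo = "NONE", None
        ident = cov = 0.0
        ex_id = ""
        if best is not None:
            _, cand_role, ex_id, ident, cov = best
            if ident >= identity_min and cov >= coverage_min:
                role = cand_role
                if role == "MDXE":
                    lipo = sigpep.detect_spII(prot) is not None
                    if not lipo:
                        role = "NONE"
        out[prot.id] = RoleAssignment(gene_id=prot.id, role=role,
                                      identity_pct=ident, coverage_pct=cov,
                                      best_exemplar=ex_id, lipobox_ok=lipo)
    return out


def _cassette_flags(genes: list[GeneModel], roles: list[str],
                    lo: int, hi: int) -> tuple[bool, bool]:
    """mdxEFG adjacency and CGTase-upstream flags for window [lo, hi]."""
    def first_idx(role: str) -> int | None:
        for i in range(lo, hi + 1):
            if roles[i] == role:
                return i
        return None

    e, f, g = first_idx("MDXE"), first_idx("MDXF"), first_idx("MDXG")
    c = first_idx("CGTASE")
    cassette = False
    cgt_up = False
    if e is not None and f is not None and g is not None:
        strands = {genes[e].strand, genes[f].strand, genes[g].strand}
        if len(strands) == 1:
            step = 1 if genes[e].strand == "+" else -1
            ordered = (np.sign(f - e) == step and np.sign(g - f) == step)
            close = (abs(f - e) <= CASSETTE_MAX_INTERVENING + 1
                     and abs(g - f) <= CASSETTE_MAX_INTERVENING + 1)
            cassette = bool(ordered and close)
        if c is not None and genes[c].strand == genes[e].strand:
            step = 1 if genes[c].strand == "+" else -1
            cgt_up = (e - c) * step > 0 and abs(e - c) <= CASSETTE_MAX_INTERVENING + 1
    return cassette, cgt_up


def find_cmcd_clusters(genes: list[GeneModel],
                       roles: dict[str, RoleAssignment],
                       window_genes: int = WINDOW_GENES) -> list[ClusterCall]:
    """Emit merged windows of <= ``window_genes`` genes containing all CORE
    roles, extended over flanking role-bearing genes."""
    calls: list[ClusterCall] = []
    by_contig: dict[str, list[GeneModel]] = {}
    for gm in genes:
        by_contig.setdefault(gm.contig, []).append(gm)
    for contig, glist in by_contig.items():
        glist = sorted(glist, key=lambda g: g.start)
        rlist = [roles[g.product_id].role if g.product_id in roles else "NONE"
                 for g in glist]
        n = len(glist)
        windows: list[tuple[int, int]] = []
        # minimal windows containing all CORE roles (two-pointer)
        need = {r: 0 for r in CORE_ROLES}
        have = 0
        lo = 0
        for hi in range(n):
            r = rlist[hi]
            if r in need:
                need[r] += 1
                if need[r] == 1:
                    have += 1
            while have == len(CORE_ROLES):
                r0 = rlist[lo]
                if r0 in need and need[r0] == 1:
                    # window is minimal at this right edge
                    if hi - lo + 1 <= window_genes:
                        windows.append((lo, hi))
                    need[r0] -= 1
                    have -= 1
                else:
                    if r0 in need:
                        need[r0] -= 1
                lo += 1
        if not windows:
            continue
        # merge overlapping/adjacent windows
        windows.sort()
        merged = [list(windows[0])]
        for s, e in windows[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            # extend across flanking genes that carry any annotated role
            while s > 0 and rlist[s - 1] != "NONE" and (e - s + 2) <= window_genes:
                s -= 1
            while e < n - 1 and rlist[e + 1] != "NONE" and (e - s + 2) <= window_genes:
                e += 1
            present = frozenset(r for r in rlist[s:e + 1] if r != "NONE")
            cassette, cgt_up = _cassette_flags(glist, rlist, s, e)
            tier = "EXTENDED" if len(present & EXTENDED_ROLES) >= 2 else "CORE"
            calls.append(ClusterCall(
                contig=contig, first_index=s, last_index=e,
                gene_ids=tuple(g.gene_id for g in glist[s:e + 1]),
                n_genes=e - s + 1, roles_present=present,
                cassette_adjacent=cassette, cgt_upstream=cgt_up, tier=tier))
    return calls


def msmx_assignments(genes: list[GeneModel], roles: dict[str, RoleAssignment],
                     clusters: list[ClusterCall]) -> list[tuple[str, bool]]:
    """(gene_id, distal) for every MSMX call; distal = outside every cluster."""
    in_cluster: set[str] = set()
    for c in clusters:
        in_cluster.update(c.gene_ids)
    out = []
    for g in genes:
        ra = roles.get(g.product_id)
        if ra is not None and ra.role == "MSMX":
            out.append((g.gene_id, g.gene_id not in in_cluster))
    return out


# ---------------------------------------------------------------------------
# sigma-promoter scanning
# ---------------------------------------------------------------------------

# Training boxes: the two deduced CGTase-gene promoters plus the sigma-A
# consensus.  Position weight matrices use 0.5 pseudocounts against a
# uniform 0.25 background.
BOX35_INSTANCES = ["TGCACT", "TTTCGA", "TTGACA"]
BOX10_INSTANCES = ["TAATAT", "CATATT", "TATAAT"]
SPACER_RANGE = (15, 19)
BOX35_MIN_SCORE = 2.9
BOX10_MIN_SCORE = 3.7
UPSTREAM_WINDOW_NT = 200


def _pwm(instances: list[str]) -> list[dict[str, float]]:
    n = len(instances)
    cols = []
    for j in range(len(instances[0])):
        counts: dict[str, int] = {}
        for inst in instances:
            counts[inst[j]] = counts.get(inst[j], 0) + 1
        cols.append({b: math.log(((counts.get(b, 0) + 0.5) / (n + 2.0)) / 0.25)
                     for b in "ACGT"})
    return cols


@lru_cache(maxsize=1)
def _pwms() -> tuple[list[dict[str, float]], list[dict[str, float]]]:
    return _pwm(BOX35_INSTANCES), _pwm(BOX10_INSTANCES)


def _pwm_score(pwm: list[dict[str, float]], window: str) -> float:
    if len(window) != len(pwm) or any(b not in "ACGT" for b in window):
        return -math.inf
    return sum(col[b] for col, b in zip(pwm, window))


def scan_promoter(dna_window: str,
                  spacer_range: tuple[int, int] = SPACER_RANGE) -> list[PromoterHit]:
    """All -35/-10 box pairs with a plausible spacer, best pair first.

    The window should be the strand-oriented upstream region of a gene
    (default 200 nt).  Windows shorter than 30 nt cannot hold a promoter
    and return no hits.
    """
    dna = dna_window.upper()
    if len(dna) < 30:
        return []
    pwm35, pwm10 = _pwms()
    hits: list[PromoterHit] = []
    for p35 in range(1, len(dna) - 6 + 2):
        s35 = _pwm_score(pwm35, dna[p35 - 1:p35 + 5])
        if s35 < BOX35_MIN_SCORE:
            continue
        for spacer in range(spacer_range[0], spacer_range[1] + 1):
            p10 = p35 + 6 + spacer
            if p10 + 5 > len(dna):
                continue
            s10 = _pwm_score(pwm10, dna[p10 - 1:p10 + 5])
            if s10 < BOX10_MIN_SCORE:
                continue
            hits.append(PromoterHit(pos_35=p35, pos_10=p10, spacer=spacer,
                                    score=round(s35 + s10, 3)))
    hits.sort(key=lambda h: (-h.score, h.pos_35))
    return hits


def upstream_window(contig_seq: str, gene: GeneModel,
                    window_nt: int = UPSTREAM_WINDOW_NT) -> str:
    """Strand-oriented upstream region of a gene (promoter search space)."""
    from Bio.Seq import Seq
    if gene.strand == "+":
        lo = max(0, gene.start - 1 - window_nt)
        return contig_seq[lo:gene.start - 1]
    hi = min(len(contig_seq), gene.end + window_nt)
    return str(Seq(contig_seq[gene.end:hi]).reverse_complement())
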