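"""Rule-based signal-peptidase-II (lipoprotein) signal-peptide detection.

Bacterial lipoproteins carry a short N-terminal signal peptide that is
cleaved by signal peptidase II immediately before an invariant cysteine,
which is subsequently lipid-modified and anchors the mature protein to the
membrane.  The classical tripartite organisation is a positively charged
n-region, a hydrophobic h-region, and a "lipobox" of three small/apolar
residues directly preceding the Cys.

This detector is a transparent rule system, not a trained model: every
decision can be traced to the charge, hydropathy and lipobox rules below,
and identical input always yields the identical call.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import ProteinRecord, SeqIOError

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

# Permissive lipobox residue classes for the three positions preceding the
# Cys.  The textbook box [LVI][ASTVIG][GAS]C is too strict for some real
# lipoproteins whose -3 position carries F or A; the -3 class is therefore
# widened to {L,V,I,F,A} while -1 stays small ({G,A,S}).
LIPOBOX_MINUS3 = frozenset("LVIFA")
LIPOBOX_MINUS2 = frozenset("ASTVIGF")
LIPOBOX_MINUS1 = frozenset("GAS")


@dataclass(frozen=True)
class SigPepParams:
    """Tunable thresholds of the SPII rule detector."""

    min_pos: int = 15          # earliest allowed lipobox Cys position
    max_pos: int = 35          # latest allowed lipobox Cys position
    min_n_charge: int = 1      # net charge of residues 2..6 (K/R +1, D/E -1)
    min_h_score: float = 1.0   # mean Kyte-Doolittle hydropathy of the h-region


@dataclass(frozen=True)
class SignalPeptideCall:
    signal_len: int     # residues cleaved off (Cys position - 1)
    cys_pos: int        # 1-based position of the lipobox Cys
    n_charge: int
    h_score: float
    lipobox: str        # 4-residue box ending in C

    def __post_init__(self) -> None:
        assert self.cys_pos == self.signal_len + 1
        assert self.lipobox.endswith("C") and len(self.lipobox) == 4


def _n_region_charge(seq: str) -> int:
    charge = 0
    for aa in seq[1:6]:  # residues 2..6
        if aa in "KR":
            charge += 1
        elif aa in "DE":
            charge -= 1
    return charge


def detect_spII(record: ProteinRecord, params: SigPepParams | None = None) -> SignalPeptideCall | None:
    """Scan for an SPII lipoprotein signal peptide; ``None`` means no call.

    Candidate lipobox cysteines within ``[min_pos, max_pos]`` are tested in
    order of position; the first Cys satisfying the n-region charge rule,
    the h-region hydropathy rule and the lipobox residue classes wins
    (SPII cleaves at the first lipobox).  The cleaved signal spans residues
    ``1..cys_pos-1``.
    """
    params = params or SigPepParams()
    seq = record.seq
    if not seq:
        raise SeqIOError("empty sequence")
    if len(seq) < params.min_pos:
        return None
    n_charge = _n_region_charge(seq)
    for cys_pos in range(params.min_pos, min(params.max_pos, len(seq)) + 1):
        if seq[cys_pos - 1] != "C":
            continue
        # lipobox residues at -3..-1 relative to the Cys
        m3, m2, m1 = seq[cys_pos - 4], seq[cys_pos - 3], seq[cys_pos - 2]
        if m3 not in LIPOBOX_MINUS3 or m2 not in LIPOBOX_MINUS2 or m1 not in LIPOBOX_MINUS1:
            continue
        if n_charge < params.min_n_charge:
            continue
        # h-region: after the n-region (residue 7) up to the lipobox
        h_region = seq[6:cys_pos - 4]
        if not h_region:
            continue
        h_score = sum(KYTE_DOOLITTLE[aa] for aa in h_region) / len(h_region)
        if h_score < params.min_h_score:
            continue
        return SignalPeptideCall(
            signal_len=cys_pos - 1,
            cys_pos=cys_pos,
            n_charge=n_charge,
            h_score=round(h_score, 3),
            lipobox=seq[cys_pos - 4:cys_pos],
        )
    return None
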