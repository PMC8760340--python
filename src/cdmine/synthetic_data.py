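"""Synthetic proteomes and annotated genomes with known ground truth.

Every pipeline stage in this package is testable without downloads because
this module can fabricate its inputs with the truth recorded at
construction time: proteomes containing CGTases of each architecture at
controlled identity to the packaged seeds, alpha-amylase-like and broken
decoys, and genomes carrying a CM-CD gene cluster (synthesis, mdxEFG
transport cassette, degradation and assimilation genes plus accessory
context, 30 genes in the default layout) alongside a decoy cluster that
lacks core roles.

Evolution is substitution-only by default so that every planted coordinate
(catalytic triad, CSR spans, signal peptides, promoter boxes) stays exact
in the mutated copies; identity targets are realised by drawing the exact
number of substitutions implied by the target and verified by recount.
All randomness flows from the single ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import seqio
from .csrscan import (AA20, CORE_LAYOUT, CSR_INSTANCES, SLOT_POSITIONS,
                      ReferenceSeed, builtin_refset, _rand_protein)
from .clusterfind import SIGNAL_MDXE, builtin_exemplars
from .seqio import AlignedRecord, GeneModel, ProteinRecord

DECOY_KINDS = ("AMYLASE_FLIP", "TRIAD_KO", "TRUNCATE", "SHUFFLE")

# truth labels the pipeline is expected to recover for each decoy kind:
# (enzyme class, architecture, SPII signal length).  Point-mutation and
# truncation decoys of the lipoprotein seed keep its 21-residue signal;
# shuffling destroys it.
DECOY_TRUTH = {
    "AMYLASE_FLIP": ("ALPHA_AMYLASE_LIKE", "ABC", 21),
    "TRIAD_KO": ("GH13_OTHER", "ABC", 21),
    "TRUNCATE": ("NOT_GH13", "OTHER", 21),
    "SHUFFLE": ("NOT_GH13", "OTHER", None),
}

TRUNCATE_AT = 200  # inside domain B (161-245): leaves an incomplete core


def mutate_to_identity(seq: str, target_pct: float, seed: int,
                       protect_positions: frozenset[int] | set[int] = frozenset()) -> str:
    """Substitution-only mutation to a target percent identity.

    Exactly ``round((1 - target/100) * len)`` positions outside the
    protected set are substituted to a different residue, so the recounted
    identity is within rounding (<= 0.5 points) of the target.
    Deterministic per seed.
    """
    if not 20.0 <= target_pct <= 100.0:
        raise ValueError("target identity must be within [20, 100]")
    rng = np.random.default_rng(seed)
    n = len(seq)
    k = int(round((1.0 - target_pct / 100.0) * n))
    mutable = [i for i in range(n) if (i + 1) not in protect_positions]
    if k > len(mutable):
        raise ValueError(f"target {target_pct}% unreachable: needs {k} substitutions "
                         f"but only {len(mutable)} unprotected positions")
    s = list(seq)
    for i in rng.choice(len(mutable), size=k, replace=False):
        pos = mutable[i]
        choices = [a for a in AA20 if a != s[pos]]
        s[pos] = choices[rng.integers(len(choices))]
    return "".join(s)


def realized_identity(a: str, b: str) -> float:
    """Column-recount identity of two equal-length sequences (the oracle
    for substitution-only mutation)."""
    if len(a) != len(b):
        raise ValueError("recount requires equal lengths")
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def evolve_family(root_seq: str, tree: TreeNode, rate: float, seed: int) -> list[AlignedRecord]:
    """Substitution-only evolution of ``root_seq`` down a branch-length tree.

    Each branch applies Poisson(length * rate * L) substitutions at uniform
    positions.  Leaves are returned already aligned (no indels are ever
    introduced).  ``rate`` scales branch lengths; at rate 0 all leaves equal
    the root.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(root_seq)
    leaves: list[AlignedRecord] = []

    def descend(node: TreeNode, seq: list[str]) -> None:
        for child in node.children:
            s = list(seq)
            bl = child.length or 0.0
            nsub = rng.poisson(bl * rate * n)
            for _ in range(nsub):
                pos = int(rng.integers(n))
                choices = [a for a in AA20 if a != s[pos]]
                s[pos] = choices[rng.integers(len(choices))]
            if child.is_tip():
                leaves.append(AlignedRecord(id=child.name, seq="".join(s)))
            else:
                descend(child, s)

    descend(tree, list(root_seq))
    return leaves


def make_decoy(seed_ref: ReferenceSeed, kind: str, seed: int) -> ProteinRecord:
    """Apply one truth-labelled breaking edit to a CGTase seed."""
    if kind not in DECOY_KINDS:
        raise ValueError(f"unknown decoy kind {kind!r}")
    rng = np.random.default_rng(seed)
    s = list(seed_ref.seq)
    slots = seed_ref.diagnostic_slots
    if kind == "AMYLASE_FLIP":
        pos = slots.get("CSRV_CENTER")
        if pos is None:
            raise ValueError("seed lacks a CSR V centre slot")
        s[pos - 1] = "L"
    elif kind == "TRIAD_KO":
        pos = slots.get("NUCLEOPHILE")
        if pos is None:
            raise ValueError("seed lacks a nucleophile slot")
        s[pos - 1] = "A"
    elif kind == "TRUNCATE":
        s = s[:TRUNCATE_AT]
    elif kind == "SHUFFLE":
        rng.shuffle(s)
    return ProteinRecord(id=f"DECOY_{kind}_{seed}", seq="".join(s),
                         description=f"synthetic decoy ({kind})")


# ---------------------------------------------------------------------------
# proteome fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the package's study conditions."""

    seed: int = 0
    n_per_architecture: int = 3          # CGTase variants per architecture
    identity_target: float = 65.0        # % identity of variants to their seed
    n_decoys_per_kind: int = 2
    # genome settings
    role_identity: float = 60.0          # % identity of planted role genes
    n_background_genes: int = 10         # flanking decoy genes on the main contig
    intergenic_nt: int = 150
    promoter_spacer: int = 17
    include_cluster: bool = True
    include_decoy_cluster: bool = True


def _protected_positions(ref: ReferenceSeed) -> frozenset[int]:
    """CSR spans, diagnostic slots and the N-terminal region of a seed.

    Protecting the first 35 residues keeps the signal-peptide truth of each
    variant identical to its seed (present for the lipoprotein seed,
    impossible for the Cys-free others).
    """
    prot: set[int] = set(range(1, 36))
    for start, end in ref.csr_spans.values():
        prot.update(range(start, end + 1))
    prot.update(ref.diagnostic_slots.values())
    return frozenset(prot)


def build_synthetic_proteome(config: SimConfig) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """CGTase variants of every architecture plus labelled decoys.

    Returns the protein list and a truth table with one row per protein:
    architecture, enzyme class and signal-peptide length (None when no
    SPII signal exists).
    """
    seeds = {s.architecture: s for s in builtin_refset()}
    rng = np.random.default_rng(config.seed)
    proteins: list[ProteinRecord] = []
    rows: list[dict] = []
    for arch, ref in seeds.items():
        prot_pos = _protected_positions(ref)
        for i in range(config.n_per_architecture):
            sub_seed = int(rng.integers(2**31 - 1))
            seq = mutate_to_identity(ref.seq, config.identity_target, sub_seed, prot_pos)
            pid = f"SYN_{arch}_{i}"
            proteins.append(ProteinRecord(id=pid, seq=seq,
                                          description=f"synthetic {arch} CGTase variant"))
            rows.append({"id": pid, "architecture": arch, "enzyme_class": "CGTASE_LIKE",
                         "signal_len": 21 if arch == "ABC" else None})
    abc = seeds["ABC"]
    for kind in DECOY_KINDS:
        for i in range(config.n_decoys_per_kind):
            sub_seed = int(rng.integers(2**31 - 1))
            rec = make_decoy(abc, kind, sub_seed)
            rec = ProteinRecord(id=f"{rec.id}_{i}", seq=rec.seq, description=rec.description)
            cls, arch_label, sig_len = DECOY_TRUTH[kind]
            proteins.append(rec)
            rows.append({"id": rec.id, "architecture": arch_label,
                         "enzyme_class": cls, "signal_len": sig_len})
    truth = pd.DataFrame(rows)
    return proteins, truth


# ---------------------------------------------------------------------------
# genome fixture
# ---------------------------------------------------------------------------

# one fixed codon per residue for reverse translation (plus TAA stop)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCG", "Q": "CAG", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

# default 30-gene cld-style cluster layout: synthesis gene, mdxEFG cassette
# immediately downstream, degradation and assimilation genes, accessory
# context genes and unknown-function filler; the phosphorylase closes the
# cluster so the core roles delimit the full 30-gene span.
DEFAULT_CLUSTER_ROSTER: tuple[str, ...] = (
    "CGTASE", "MDXE", "MDXF", "MDXG", "CDASE", "GA", "NONE", "ACC_HPR",
    "ACC_MURB", "NONE", "PGI", "PFKA", "PYKF", "ACC_RAPZ", "NONE",
    "ACC_RODZ", "ACC_WHIA", "NONE", "ACC_POL3A", "NONE", "ACC_PEPT",
    "NONE", "ACC_MATE", "NONE", "NONE", "NONE", "NONE", "NONE", "NONE",
    "GP",
)
# decoy cluster: same neighbourhood but missing MDXF and CDASE (core roles)
DECOY_CLUSTER_ROSTER: tuple[str, ...] = tuple(
    r for r in DEFAULT_CLUSTER_ROSTER if r not in ("MDXF", "CDASE"))

# accessory/unknown genes may sit on either strand; cassette and synthesis
# genes stay on the forward strand in the default layout
_MINUS_STRAND_ROLES = {"ACC_MURB", "ACC_RODZ", "ACC_MATE"}


@dataclass
class SyntheticTruth:
    proteins: pd.DataFrame
    genes: pd.DataFrame
    clusters: pd.DataFrame
    promoters: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("proteins", "genes", "clusters", "promoters"):
            df = getattr(self, name)
            df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)
            df.to_json(outdir / f"truth_{name}.json", orient="records", indent=1)


@dataclass
class GenomeFixture:
    contigs: dict[str, str]
    genes: list[GeneModel]
    proteins: list[ProteinRecord]
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"genome": outdir / "genome.fna", "gff": outdir / "genome.gff3",
                 "proteins": outdir / "proteins.faa"}
        seqio.write_dna_fasta(self.contigs, paths["genome"])
        seqio.write_gff3(self.genes, paths["gff"],
                         {c: len(s) for c, s in self.contigs.items()})
        seqio.write_fasta(self.proteins, paths["proteins"])
        self.truth.write(outdir)
        return paths


def _role_protein(role: str, config: SimConfig, rng: np.random.Generator,
                  tag: str) -> ProteinRecord:
    """A planted gene product: a role exemplar diverged to the configured
    identity (signal region protected for MDXE), or a random protein for
    unknown-function filler."""
    if role == "NONE":
        length = int(rng.integers(150, 400))
        return ProteinRecord(id=tag, seq=_rand_protein(rng, length),
                             description="synthetic unknown-function protein")
    exemplars = builtin_exemplars()
    if role == "CGTASE":
        ref = builtin_refset()[0]  # the three-domain lipoprotein seed
        prot = _protected_positions(ref)
        seq = mutate_to_identity(ref.seq, config.role_identity,
                                 int(rng.integers(2**31 - 1)), prot)
    elif role.startswith("ACC_"):
        ex = next(e for e in exemplars["ACCESSORY"] if e.id == f"EX_{role}")
        seq = mutate_to_identity(ex.seq, config.role_identity,
                                 int(rng.integers(2**31 - 1)))
    else:
        ex = exemplars[role][0]
        protect = frozenset(range(1, 36)) if role == "MDXE" else frozenset()
        seq = mutate_to_identity(ex.seq, config.role_identity,
                                 int(rng.integers(2**31 - 1)), protect)
    return ProteinRecord(id=tag, seq=seq, description=f"synthetic {role} gene product")


def build_synthetic_genome(config: SimConfig) -> GenomeFixture:
    """Assemble contigs carrying the planted cluster(s) with full truth.

    The main contig holds background genes, the default 30-gene cluster,
    a distal MsmX gene, and a promoter (configured -35/-10 boxes and
    spacer) upstream of the cluster's CGTase gene.  A second contig holds
    the decoy cluster missing two core roles.  Gene placement is strictly
    sequential, so placements can never overlap.
    """
    rng = np.random.default_rng(config.seed + 1)
    gene_rows, prot_rows, cluster_rows, promoter_rows = [], [], [], []
    genes: list[GeneModel] = []
    proteins: list[ProteinRecord] = []
    contigs: dict[str, str] = {}

    def lay_contig(contig: str, roster: list[tuple[str, str]],
                   cluster_span: tuple[int, int] | None) -> None:
        """roster: list of (gene_tag, role); cluster_span: roster indices."""
        parts: list[str] = []
        cursor = 0
        last_end = 0
        for idx, (tag, role) in enumerate(roster):
            prot = _role_protein(role, config, rng, f"{tag}_prot")
            gap = config.intergenic_nt
            inter = _rand_dna(rng, gap)
            if role == "CGTASE":
                # plant the sigma promoter ending 30 nt before the CDS start
                box = ("TGCACT" + _rand_dna(rng, config.promoter_spacer) + "TAATAT")
                insert_at = gap - 30 - len(box)
                inter = inter[:insert_at] + box + inter[insert_at + len(box):]
            parts.append(inter)
            cursor += len(inter)
            cds = "".join(_CODON[a] for a in prot.seq) + "TAA"
            strand = "-" if role in _MINUS_STRAND_ROLES else "+"
            if strand == "-":
                from Bio.Seq import Seq
                cds = str(Seq(cds).reverse_complement())
            start = cursor + 1
            end = cursor + len(cds)
            if start <= last_end:
                raise ValueError("overlapping gene placement")
            last_end = end
            parts.append(cds)
            cursor = end
            gm = GeneModel(gene_id=tag, contig=contig, start=start, end=end,
                           strand=strand, product_id=prot.id)
            genes.append(gm)
            proteins.append(prot)
            gene_rows.append({"gene_id": tag, "contig": contig, "start": start,
                              "end": end, "strand": strand, "role": role})
            if role == "CGTASE":
                p35_abs = start - 30 - len(box)
                promoter_rows.append({
                    "gene_id": tag, "contig": contig,
                    "pos_35": p35_abs, "pos_10": p35_abs + 6 + config.promoter_spacer,
                    "spacer": config.promoter_spacer})
        parts.append(_rand_dna(rng, config.intergenic_nt))
        contigs[contig] = "".join(parts)
        if cluster_span is not None:
            cluster_rows.append({
                "contig": contig,
                "first_gene": roster[cluster_span[0]][0],
                "last_gene": roster[cluster_span[1]][0],
                "n_genes": cluster_span[1] - cluster_span[0] + 1})

    # main contig
    roster1: list[tuple[str, str]] = [("msmx_distal", "MSMX")]
    nbg = config.n_background_genes
    for i in range(nbg // 2):
        roster1.append((f"bg1_{i}", "NONE"))
    cluster_start = len(roster1)
    if config.include_cluster:
        for j, role in enumerate(DEFAULT_CLUSTER_ROSTER):
            roster1.append((f"cld_{j + 1:02d}", role))
    cluster_end = len(roster1) - 1
    for i in range(nbg - nbg // 2):
        roster1.append((f"bg2_{i}", "NONE"))
    lay_contig("ctg_main", roster1,
               (cluster_start, cluster_end) if config.include_cluster else None)

    # decoy contig
    if config.include_decoy_cluster:
        roster2 = [(f"dbg_{i}", "NONE") for i in range(3)]
        roster2 += [(f"dcl_{j + 1:02d}", role)
                    for j, role in enumerate(DECOY_CLUSTER_ROSTER)]
        roster2 += [(f"dbg2_{i}", "NONE") for i in range(3)]
        lay_contig("ctg_decoy", roster2, None)

    # per-protein truth (role only; enzyme/architecture truth lives in the
    # proteome fixture)
    prot_rows = [{"id": g.product_id, "role": r["role"]}
                 for g, r in zip(genes, gene_rows)]
    truth = SyntheticTruth(
        proteins=pd.DataFrame(prot_rows),
        genes=pd.DataFrame(gene_rows),
        clusters=pd.DataFrame(cluster_rows,
                              columns=["contig", "first_gene", "last_gene", "n_genes"]),
        promoters=pd.DataFrame(promoter_rows,
                               columns=["gene_id", "contig", "pos_35", "pos_10", "spacer"]))
    return GenomeFixture(contigs=contigs, genes=genes, proteins=proteins, truth=truth)


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
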