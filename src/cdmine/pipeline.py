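"""End-to-end mining runs: screen -> classify -> signal peptide -> novelty
-> clusters -> (optional) phylogeny, with TSV/JSON reports.

A run takes a proteome (FASTA) and/or an annotated genome (FASTA + GFF3),
applies every per-protein analysis, detects CM-CD clusters and promoters
on the genome side, and writes machine-readable reports that embed the
resolved configuration and package version.  Runs are deterministic:
the same config and seed produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import archclass, clusterfind, csrscan, pairid, phylo, sigpep
from .seqio import read_fasta, read_gff3


@dataclass
class RunConfig:
    """Resolved settings of one mining run."""

    proteome: str | None = None
    genome: str | None = None
    gff: str | None = None
    alignment: str | None = None          # aligned FASTA for the phylo stage
    outdir: str = "cdmine_out"
    novelty_threshold: float = 45.0
    anchor_threshold: float = csrscan.ANCHOR_THRESHOLD
    role_identity_min: float = clusterfind.ROLE_IDENTITY_MIN
    role_coverage_min: float = clusterfind.ROLE_COVERAGE_MIN
    spacer_min: int = clusterfind.SPACER_RANGE[0]
    spacer_max: int = clusterfind.SPACER_RANGE[1]
    bootstrap_reps: int = 100
    seed: int = 0
    run_phylo: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.novelty_threshold <= 100:
            raise ValueError("novelty_threshold must be in (0, 100]")
        if not 0 < self.role_identity_min <= 100 or not 0 < self.role_coverage_min <= 100:
            raise ValueError("role thresholds must be in (0, 100]")
        if self.spacer_min > self.spacer_max:
            raise ValueError("invalid spacer range")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MiningReport:
    proteins: pd.DataFrame
    clusters: pd.DataFrame
    promoters: pd.DataFrame
    msmx: pd.DataFrame
    config: dict
    version: str
    complete: bool = True

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.proteins.to_csv(outdir / "mining_report.tsv", sep="\t", index=False)
        self.clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        self.promoters.to_csv(outdir / "promoters.tsv", sep="\t", index=False)
        self.msmx.to_csv(outdir / "msmx.tsv", sep="\t", index=False)
        payload = {
            "version": self.version,
            "config": self.config,
            "complete": self.complete,
            "proteins": self.proteins.to_dict(orient="records"),
            "clusters": self.clusters.to_dict(orient="records"),
            "promoters": self.promoters.to_dict(orient="records"),
            "msmx": self.msmx.to_dict(orient="records"),
        }
        (outdir / "report.json").write_text(json.dumps(payload, indent=1, default=str))
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(self.summary())

    def summary(self) -> str:
        lines = [f"cdmine {self.version} mining summary", ""]
        if len(self.proteins):
            counts = self.proteins["enzyme_class"].value_counts().to_dict()
            lines.append(f"proteins analysed: {len(self.proteins)} {counts}")
            kept = int((self.proteins["novelty"] == "keep").sum())
            lines.append(f"novelty filter: kept {kept}/{len(self.proteins)}")
        else:
            lines.append("proteins analysed: 0")
        lines.append(f"CM-CD clusters: {len(self.clusters)}")
        lines.append(f"promoter hits: {len(self.promoters)}")
        return "\n".join(lines) + "\n"


PROTEIN_COLUMNS = ["id", "anchor_ref", "anchor_score", "enzyme_class",
                   "architecture", "nucleophile_pos", "glu_pos", "asp2_pos",
                   "csrV_center", "h1", "h2", "signal_len", "cys_pos",
                   "novelty", "novelty_best_ref", "novelty_identity_pct"]


def _novelty_references() -> list:
    """Conventional-architecture seeds stand in for the characterized
    reference panel of the novelty screen."""
    return [s.record for s in csrscan.builtin_refset() if s.architecture != "ABC"]


def mine_proteome(records, config: RunConfig) -> pd.DataFrame:
    refs = _novelty_references()
    rows = []
    for rec in records:
        anchor, report, cls = csrscan.scan_protein(rec, anchor_threshold=config.anchor_threshold)
        arch = archclass.classify_architecture(rec, anchor)
        sp = sigpep.detect_spII(rec)
        nov = pairid.novelty_filter(rec, refs, threshold_pct=config.novelty_threshold)
        fmt = lambda slot: f"{slot[0]}{slot[1]}" if slot else None
        rows.append({
            "id": rec.id,
            "anchor_ref": anchor.ref.id if anchor else None,
            "anchor_score": round(anchor.normalized_score, 3) if anchor else None,
            "enzyme_class": cls.label,
            "architecture": arch.label,
            "nucleophile_pos": report.nucleophile_pos if report else None,
            "glu_pos": report.glu_pos if report else None,
            "asp2_pos": report.asp2_pos if report else None,
            "csrV_center": fmt(report.csrV_center) if report else None,
            "h1": fmt(report.h1) if report else None,
            "h2": fmt(report.h2) if report else None,
            "signal_len": sp.signal_len if sp else None,
            "cys_pos": sp.cys_pos if sp else None,
            "novelty": "keep" if nov.keep else "discard",
            "novelty_best_ref": nov.best_ref,
            "novelty_identity_pct": nov.best_identity_pct,
        })
    return pd.DataFrame(rows, columns=PROTEIN_COLUMNS)


def mine_genome(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    from .seqio import read_dna_fasta

    genes, proteins = read_gff3(config.gff, config.genome)
    contigs = read_dna_fasta(config.genome)
    roles = clusterfind.assign_roles(
        proteins, identity_min=config.role_identity_min,
        coverage_min=config.role_coverage_min)
    clusters = clusterfind.find_cmcd_clusters(genes, roles)
    cluster_df = pd.DataFrame([{
        "contig": c.contig, "first_gene": c.gene_ids[0], "last_gene": c.gene_ids[-1],
        "n_genes": c.n_genes, "tier": c.tier,
        "cassette_adjacent": c.cassette_adjacent, "cgt_upstream": c.cgt_upstream,
        "roles_present": ",".join(sorted(c.roles_present)),
    } for c in clusters], columns=["contig", "first_gene", "last_gene", "n_genes",
                                   "tier", "cassette_adjacent", "cgt_upstream",
                                   "roles_present"])
    prom_rows = []
    spacer_range = (config.spacer_min, config.spacer_max)
    for g in genes:
        if roles[g.product_id].role != "CGTASE":
            continue
        window = clusterfind.upstream_window(contigs[g.contig], g)
        hits = clusterfind.scan_promoter(window, spacer_range=spacer_range)
        if hits:
            best = hits[0]
            prom_rows.append({"gene_id": g.gene_id, "contig": g.contig,
                              "pos_35": best.pos_35, "pos_10": best.pos_10,
                              "spacer": best.spacer, "score": best.score})
    promoter_df = pd.DataFrame(prom_rows, columns=["gene_id", "contig", "pos_35",
                                                   "pos_10", "spacer", "score"])
    msmx_df = pd.DataFrame(
        [{"gene_id": gid, "distal": distal}
         for gid, distal in clusterfind.msmx_assignments(genes, roles, clusters)],
        columns=["gene_id", "distal"])
    return cluster_df, promoter_df, msmx_df


def run_mine(config: RunConfig) -> MiningReport:
    """Execute every configured stage and assemble the mining report."""
    empty = pd.DataFrame()
    proteins_df = pd.DataFrame(columns=PROTEIN_COLUMNS)
    clusters_df = promoters_df = msmx_df = None
    complete = True
    if config.proteome:
        records = read_fasta(config.proteome)
        proteins_df = mine_proteome(records, config)
    if config.genome and config.gff:
        clusters_df, promoters_df, msmx_df = mine_genome(config)
    if config.run_phylo and config.alignment:
        aln = read_fasta(config.alignment, allow_gaps=True)
        phy = phylo.bootstrap_support(aln, config.bootstrap_reps, config.seed)
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        phy.write_newick(outdir / "tree.nwk")
    report = MiningReport(
        proteins=proteins_df,
        clusters=clusters_df if clusters_df is not None else pd.DataFrame(
            columns=["contig", "first_gene", "last_gene", "n_genes", "tier",
                     "cassette_adjacent", "cgt_upstream", "roles_present"]),
        promoters=promoters_df if promoters_df is not None else pd.DataFrame(
            columns=["gene_id", "contig", "pos_35", "pos_10", "spacer", "score"]),
        msmx=msmx_df if msmx_df is not None else pd.DataFrame(columns=["gene_id", "distal"]),
        config=config.to_dict(), version=__version__, complete=complete)
    report.write(config.outdir)
    return report
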