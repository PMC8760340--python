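"""Role assignment, CM-CD cluster detection and promoter scanning."""

import numpy as np
import pytest

from cdmine import clusterfind as cf
from cdmine.seqio import GeneModel, ProteinRecord


def _roles_truth(fixture):
    tg = fixture.truth.genes.set_index("gene_id")["role"]
    return {gid: ("ACCESSORY" if r.startswith("ACC_") else r) for gid, r in tg.items()}


class TestRoleAssignment:
    def test_planted_roles_recovered_exactly(self, genome_fixture, genome_roles):
        want = _roles_truth(genome_fixture)
        for g in genome_fixture.genes:
            assert genome_roles[g.product_id].role == want[g.gene_id], g.gene_id

    def test_exemplar_itself_gets_its_role_at_full_identity(self):
        ex = cf.builtin_exemplars()["CDASE"][0]
        ra = cf.assign_roles([ex])[ex.id]
        assert ra.role == "CDASE"
        assert ra.identity_pct == 100.0 and ra.coverage_pct == 100.0

    def test_shuffled_protein_gets_no_role(self):
        ex = cf.builtin_exemplars()["GP"][0]
        rng = np.random.default_rng(3)
        s = list(ex.seq)
        rng.shuffle(s)
        rec = ProteinRecord(id="shuf", seq="".join(s))
        assert cf.assign_roles([rec])["shuf"].role == "NONE"

    def test_mdxe_requires_lipobox(self):
        ex = cf.builtin_exemplars()["MDXE"][0]
        # destroy the lipobox Cys but keep near-full identity
        seq = ex.seq.replace("C", "S", 1)
        rec = ProteinRecord(id="nolipo", seq=seq)
        ra = cf.assign_roles([rec])["nolipo"]
        assert ra.role == "NONE" and ra.lipobox_ok is False

    def test_empty_exemplar_set_rejected(self):
        with pytest.raises(ValueError):
            cf.assign_roles([ProteinRecord(id="p", seq="MKV")], exemplars={})


class TestClusterDetection:
    def test_default_fixture_yields_one_30_gene_extended_call(self, genome_fixture, genome_roles):
        calls = cf.find_cmcd_clusters(genome_fixture.genes, genome_roles)
        assert len(calls) == 1
        call = calls[0]
        truth = genome_fixture.truth.clusters.iloc[0]
        assert call.contig == truth.contig
        assert call.gene_ids[0] == truth.first_gene
        assert call.gene_ids[-1] == truth.last_gene
        assert call.n_genes == truth.n_genes == 30
        assert call.tier == "EXTENDED"
        assert call.cassette_adjacent and call.cgt_upstream
        assert cf.CORE_ROLES <= call.roles_present

    def test_decoy_cluster_without_core_roles_is_not_called(self, genome_fixture, genome_roles):
        calls = cf.find_cmcd_clusters(genome_fixture.genes, genome_roles)
        assert all(c.contig != "ctg_decoy" for c in calls)

    @pytest.mark.parametrize("dropped_role", sorted(cf.CORE_ROLES))
    def test_removing_any_core_role_abolishes_the_call(self, genome_fixture, genome_roles, dropped_role):
        keep = [g for g in genome_fixture.genes
                if not (g.contig == "ctg_main"
                        and genome_roles[g.product_id].role == dropped_role)]
        calls = cf.find_cmcd_clusters(keep, genome_roles)
        assert all(c.contig != "ctg_main" for c in calls)

    def test_removing_assimilation_roles_downgrades_tier_but_keeps_call(self, genome_fixture, genome_roles):
        drop = {"PGI", "PFKA", "PYKF"}
        keep = [g for g in genome_fixture.genes
                if genome_roles[g.product_id].role not in drop]
        calls = [c for c in cf.find_cmcd_clusters(keep, genome_roles) if c.contig == "ctg_main"]
        assert len(calls) == 1
        assert calls[0].tier == "CORE"

    def test_distant_genes_do_not_affect_the_call(self, genome_fixture, genome_roles):
        """Removing genes far from the cluster (keeping the unannotated
        buffer next to it) leaves the call untouched."""
        full = cf.find_cmcd_clusters(genome_fixture.genes, genome_roles)
        trimmed_genes = [g for g in genome_fixture.genes
                         if g.gene_id not in {"msmx_distal", "bg1_0", "bg2_1"}]
        trimmed = cf.find_cmcd_clusters(trimmed_genes, genome_roles)
        assert [c.gene_ids for c in full if c.contig == "ctg_main"] == \
               [c.gene_ids for c in trimmed if c.contig == "ctg_main"]

    def test_reverse_complementing_contig_preserves_calls(self, genome_fixture, genome_roles):
        flipped = []
        for g in genome_fixture.genes:
            length = len(genome_fixture.contigs[g.contig])
            flipped.append(GeneModel(
                gene_id=g.gene_id, contig=g.contig,
                start=length - g.end + 1, end=length - g.start + 1,
                strand="-" if g.strand == "+" else "+", product_id=g.product_id))
        orig = cf.find_cmcd_clusters(genome_fixture.genes, genome_roles)
        flip = cf.find_cmcd_clusters(flipped, genome_roles)
        assert len(orig) == len(flip) == 1
        assert set(orig[0].gene_ids) == set(flip[0].gene_ids)
        assert (orig[0].cassette_adjacent, orig[0].cgt_upstream) == \
               (flip[0].cassette_adjacent, flip[0].cgt_upstream)
        assert orig[0].tier == flip[0].tier

    def test_msmx_reported_distal(self, genome_fixture, genome_roles):
        calls = cf.find_cmcd_clusters(genome_fixture.genes, genome_roles)
        msmx = cf.msmx_assignments(genome_fixture.genes, genome_roles, calls)
        assert msmx == [("msmx_distal", True)]


class TestPromoterScan:
    def _rand_dna(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_printed_boxes_with_17bp_spacer_are_top_hit(self):
        win = self._rand_dna(100, 1) + "TGCACT" + self._rand_dna(17, 2) + "TAATAT" + self._rand_dna(50, 3)
        hits = cf.scan_promoter(win)
        assert hits and hits[0].spacer == 17
        assert hits[0].pos_35 == 101 and hits[0].pos_10 == 124

    def test_second_printed_promoter_detected(self):
        win = self._rand_dna(60, 4) + "TTTCGA" + self._rand_dna(17, 5) + "CATATT" + self._rand_dna(40, 6)
        hits = cf.scan_promoter(win)
        assert hits and hits[0].spacer == 17

    def test_boxes_too_far_apart_are_not_paired(self):
        win = self._rand_dna(60, 7) + "TGCACT" + self._rand_dna(25, 8) + "TAATAT" + self._rand_dna(40, 9)
        assert all(not (h.pos_35 == 61 and h.spacer == 25) for h in cf.scan_promoter(win))

    def test_random_window_has_no_hit(self):
        assert cf.scan_promoter(self._rand_dna(200, 10)) == []

    def test_short_window_returns_empty(self):
        assert cf.scan_promoter("ACGT" * 7) == []

    def test_planted_genome_promoters_recovered(self, genome_fixture):
        gmap = {g.gene_id: g for g in genome_fixture.genes}
        for _, row in genome_fixture.truth.promoters.iterrows():
            g = gmap[row.gene_id]
            win = cf.upstream_window(genome_fixture.contigs[g.contig], g)
            hits = cf.scan_promoter(win)
            assert hits and hits[0].spacer == row.spacer
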