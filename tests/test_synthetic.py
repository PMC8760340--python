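"""Generator guarantees: identity targeting, evolution, decoys, genomes."""

from io import StringIO

import numpy as np
import pytest
from skbio import TreeNode

from cdmine import synthetic_data as sd
from cdmine.csrscan import builtin_refset, _rand_protein
from cdmine.seqio import read_gff3


class TestMutateToIdentity:
    def test_target_100_returns_sequence_unchanged(self):
        seq = _rand_protein(np.random.default_rng(0), 200)
        assert sd.mutate_to_identity(seq, 100.0, seed=1) == seq

    def test_realized_identity_hits_target_by_recount(self):
        seq = _rand_protein(np.random.default_rng(1), 500)
        mut = sd.mutate_to_identity(seq, 80.0, seed=7)
        assert 78.0 <= sd.realized_identity(seq, mut) <= 82.0

    def test_mean_absolute_error_below_one_point(self):
        seq = _rand_protein(np.random.default_rng(2), 400)
        errs = []
        rng = np.random.default_rng(3)
        for i in range(100):
            target = float(rng.uniform(30, 95))
            mut = sd.mutate_to_identity(seq, target, seed=1000 + i)
            errs.append(abs(sd.realized_identity(seq, mut) - target))
        assert float(np.mean(errs)) <= 1.0

    def test_protected_positions_untouched(self):
        seq = _rand_protein(np.random.default_rng(4), 100)
        protect = frozenset(range(1, 21))
        mut = sd.mutate_to_identity(seq, 50.0, seed=5, protect_positions=protect)
        assert mut[:20] == seq[:20]

    def test_unreachable_target_rejected(self):
        seq = _rand_protein(np.random.default_rng(5), 50)
        with pytest.raises(ValueError, match="unreachable"):
            sd.mutate_to_identity(seq, 20.0, seed=6,
                                  protect_positions=frozenset(range(1, 45)))

    def test_deterministic_per_seed(self):
        seq = _rand_protein(np.random.default_rng(6), 120)
        assert sd.mutate_to_identity(seq, 60.0, seed=9) == sd.mutate_to_identity(seq, 60.0, seed=9)
        assert sd.mutate_to_identity(seq, 60.0, seed=9) != sd.mutate_to_identity(seq, 60.0, seed=10)


class TestEvolveFamily:
    def _tree(self):
        return TreeNode.read(StringIO("((a:0.1,b:0.1):0.2,(c:0.1,d:0.1):0.2);"))

    def test_rate_zero_leaves_equal_root(self):
        root = _rand_protein(np.random.default_rng(7), 150)
        fam = sd.evolve_family(root, self._tree(), rate=0.0, seed=1)
        assert all(r.seq == root for r in fam)

    def test_same_seed_reproduces_family(self):
        root = _rand_protein(np.random.default_rng(8), 150)
        f1 = sd.evolve_family(root, self._tree(), rate=1.0, seed=2)
        f2 = sd.evolve_family(root, self._tree(), rate=1.0, seed=2)
        assert [(r.id, r.seq) for r in f1] == [(r.id, r.seq) for r in f2]

    def test_leaves_stay_aligned_without_indels(self):
        root = _rand_protein(np.random.default_rng(9), 150)
        fam = sd.evolve_family(root, self._tree(), rate=1.0, seed=3)
        assert {len(r.seq) for r in fam} == {150}
        assert {r.id for r in fam} == {"a", "b", "c", "d"}


class TestMakeDecoy:
    def test_amylase_flip_changes_only_the_center(self, abc_seed):
        dec = sd.make_decoy(abc_seed, "AMYLASE_FLIP", seed=1)
        pos = abc_seed.diagnostic_slots["CSRV_CENTER"]
        diffs = [i for i, (x, y) in enumerate(zip(abc_seed.seq, dec.seq), start=1) if x != y]
        assert diffs == [pos] and dec.seq[pos - 1] == "L"

    def test_triad_ko_changes_only_the_nucleophile(self, abc_seed):
        dec = sd.make_decoy(abc_seed, "TRIAD_KO", seed=1)
        pos = abc_seed.diagnostic_slots["NUCLEOPHILE"]
        diffs = [i for i, (x, y) in enumerate(zip(abc_seed.seq, dec.seq), start=1) if x != y]
        assert diffs == [pos] and dec.seq[pos - 1] == "A"

    def test_truncation_cuts_inside_domain_b(self, abc_seed):
        dec = sd.make_decoy(abc_seed, "TRUNCATE", seed=1)
        b_start, b_end = abc_seed.domain_spans["B"]
        assert b_start < len(dec.seq) < b_end

    def test_shuffle_preserves_composition(self, abc_seed):
        dec = sd.make_decoy(abc_seed, "SHUFFLE", seed=1)
        assert sorted(dec.seq) == sorted(abc_seed.seq)
        assert dec.seq != abc_seed.seq

    def test_unknown_kind_rejected(self, abc_seed):
        with pytest.raises(ValueError):
            sd.make_decoy(abc_seed, "NONSENSE", seed=1)


class TestGenomeFixture:
    def test_deterministic_for_fixed_seed(self, sim_config, genome_fixture):
        again = sd.build_synthetic_genome(sim_config)
        assert again.contigs == genome_fixture.contigs
        assert again.genes == genome_fixture.genes
        assert again.truth.genes.equals(genome_fixture.truth.genes)

    def test_gene_count_matches_truth_and_gff(self, genome_fixture, tmp_path):
        paths = genome_fixture.write(tmp_path)
        genes, proteins = read_gff3(paths["gff"], paths["genome"])
        assert len(genes) == len(genome_fixture.genes) == len(genome_fixture.truth.genes)
        # GFF round trip reproduces each planted protein exactly
        planted = {p.id: p.seq for p in genome_fixture.proteins}
        assert all(planted[g.gene_id + "_prot"] == p.seq for g, p in zip(genes, proteins))

    def test_truth_tables_serialize_losslessly(self, genome_fixture, tmp_path):
        import pandas as pd
        genome_fixture.truth.write(tmp_path)
        back = pd.read_csv(tmp_path / "truth_genes.tsv", sep="\t")
        assert back.equals(genome_fixture.truth.genes)

    def test_no_cluster_config_plants_no_cluster(self):
        fx = sd.build_synthetic_genome(sd.SimConfig(include_cluster=False,
                                                    include_decoy_cluster=False))
        assert len(fx.truth.clusters) == 0
        assert not any(g.gene_id.startswith("cld_") for g in fx.genes)


def test_proteome_truth_covers_every_protein(proteome_fixture):
    proteins, truth = proteome_fixture
    assert len(proteins) == len(truth)
    assert {p.id for p in proteins} == set(truth["id"])
    assert set(truth["enzyme_class"]) == {"CGTASE_LIKE", "ALPHA_AMYLASE_LIKE",
                                          "GH13_OTHER", "NOT_GH13"}
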