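# Methods

This note records the models behind each stage, the tunable parameters and
their defaults, the numerical choices, and what the synthetic fixtures can
and cannot demonstrate.

## Coordinate conventions

Protein residues are numbered 1-based on the sequence *as provided*
(precursor numbering: a cleaved signal peptide occupies residues 1..n, so
a catalytic residue keeps the same number whether or not the mature form
is considered).  Genome coordinates are 1-based inclusive in the GFF3
dialect.  `X` is accepted by scanning and alignment, where it scores 0,
and rejected by physicochemistry, which needs real masses.

## SPII signal peptides (sigpep)

Bacterial lipoprotein signals are modelled as n-region + h-region +
lipobox-Cys.  Rules and defaults:

| rule | default | unit |
|---|---|---|
| lipobox Cys window | 15–35 | residue position |
| n-region net charge (residues 2–6; K/R +1, D/E −1) | ≥ +1 | charges |
| h-region mean Kyte–Doolittle hydropathy | ≥ 1.0 | scale units |
| lipobox classes | −3 ∈ {L,V,I,F,A}, −2 ∈ {A,S,T,V,I,G,F}, −1 ∈ {G,A,S} | — |

The −3 class is deliberately wider than the textbook `[LVI][ASTVIG][GAS]C`
box: documented SPII substrates exist whose −3 position carries Phe, and
the canonical box would reject them.  The first (lowest-position) Cys
satisfying all rules wins, mirroring cleavage at the first lipobox; this
also makes the detector order-deterministic.  No probabilistic model is
used — every call is traceable to these four rules.

## Pairwise alignment and identity (pairid)

Needleman–Wunsch global alignment with BLOSUM62, gap open −11 and extend
−1 under the convention that a gap of length L costs `open + (L−1)·extend`;
terminal gaps are penalised.  Traceback ties follow the aligner's fixed
first-alignment rule (residue pairing preferred over gaps), so results are
deterministic.  Percent identity is matches over all aligned columns —
not over the shorter sequence — so an "identity at 100 % query coverage"
statement is directly interpretable; coverage is the fraction of query
residues aligned against residues.  The novelty filter discards a query
whose best identity against the reference panel strictly exceeds the
threshold (default 45 %); a hit at exactly the threshold is kept.

A remote-database screen would use E-values; no database statistics exist
at desk scale, so candidate screening instead relies on the normalised
anchor score below.

## CSR scanning (csrscan)

Coordinate transfer uses one global alignment to the best-scoring
reference seed rather than per-motif local search: the CSRs are short
(6–9 columns) and anchoring prevents spurious off-domain matches while
yielding precursor-consistent numbering.  The anchor score is normalised
by the longer sequence length; the default threshold (0.5 per residue)
was placed an order of magnitude above the maximum reached by shuffled
full-length sequences (≈ −0.08, n = 50 shuffles) and far below the ≈ 4–6
reached by genuine homologues, which corresponds to roughly the 20 %
identity / 80 % coverage twilight-zone floor below which transfer is
meaningless.

Diagnostic slots (triad, CSR V centre, H1, H2) are mapped strictly
through alignment columns; a slot falling on a gap is reported absent.
CSR hits are re-scored with per-column add-one-smoothed log-odds profiles
(background 1/20) within ±5 residues of the mapped start — slack that
absorbs alignment wander near gaps without ever moving a diagnostic slot.
A CSR hit requires ≥ 60 % of its span to map and a non-negative log-odds
sum.

Classification decision table, applied in order: complete triad (Asp,
Glu, Asp at the mapped slots) + aromatic CSR V centre (Y/F) + H1 ∈
{F,W,Y} + H2 ∈ {F,Y,M} + ≥ 4 CSR hits → `CGTASE_LIKE`; complete triad
with a non-aromatic centre → `ALPHA_AMYLASE_LIKE`; ≥ 4 CSR hits otherwise
→ `GH13_OTHER`; else `NOT_GH13`.  Maltogenic starch-acting enzymes get no
label of their own: no single-residue rule separates them from CGTases,
so that distinction is left to phylogeny.

### Packaged reference seeds

The four seeds (one per architecture) are synthetic consensus proteins:
deterministic pseudo-random backgrounds carrying the CSR/H1 motif
instances and landmark coordinates of the canonical three-domain CGTase
precursor frame — nucleophile 250, acid/base 279, second Asp 351, CSR V
centre 216, H1 Trp 204 in a GSISNWN motif at 199–205, core 23–434, C
domain 434–524, and (for the lipoprotein seed) the printed 21-residue
SPII signal.  Real database accessions cannot be redistributed inside the
package; the synthetic seeds make every coordinate test runnable offline.
Anything one concludes from them concerns the *machinery* (anchoring,
transfer, decision tables), not the biology of any particular accession.

## Architecture classification (archclass)

The catalytic core is the mapped span from the reference A-domain start
to the reference C-domain end; the end is placed using the **median**
alignment offset over the C domain, which is robust to co-optimal
tracebacks that strand single residues across a long terminal gap.
Tails shorter than 40 residues mean `ABC` (the smallest real appended
domain, CBM20 at ≈ 100 residues, is far larger).  CBM20 and E_arch are
scored with 100-column profiles over sliding tail windows; a hit needs a
log-odds sum ≥ 30 (self-score ≈ 115, random tails ≈ −14, so the margin is
wide in both directions).  The D domain has no reliable motif of its own
and is instead inferred from spacer length: a CBM20 hit starting ≥ 60
residues after the core implies an intervening D (≈ 90 residues in
five-domain proteins).  If both domain kinds somehow hit, the higher
score wins and an exact tie yields `OTHER` with a warning.

## Phylogenetics (phylo)

Distances are Poisson-corrected p-distances, d = −ln(1−p), with p counted
over columns where both sequences carry residues; p ≥ 0.95 is clamped
(with a warning) because the correction diverges.  Trees are
neighbor-joining (Saitou–Nei agglomeration via scikit-bio) with negative
branch lengths clamped to zero.  NJ + Poisson substitutes for
maximum-likelihood WAG+Γ inference: it is self-contained, fast, and the
package's acceptance surface (exact monophyly recovery on families with
clean splits) does not require ML; `bootstrap_support` accepts any
`tree_builder` callable as a plug-in point.  Bootstrap resamples columns
with replacement, rebuilds the tree per replicate, and reports for each
original internal bipartition the percentage of replicates containing it;
everything is reproducible from the seed.  Monophyly is exact: a label
set forms a clade iff some edge bipartition equals it (or its
complement).  Trees are unrooted; rooting on an outgroup is display-only.
No alignment trimming is applied by default — no principled trimming rule
presented itself, and the tests use untrimmed synthetic alignments.

## CM-CD clusters and promoters (clusterfind)

Role calling is exemplar-based best-hit assignment with identity ≥ 30 %
and coverage ≥ 70 % (defaults); exemplars differing more than two-fold in
length are skipped since they cannot reach the coverage bound.  MdxE
calls additionally require an SPII lipobox, because the substrate-binding
subunit of the Gram-positive importer is a membrane lipoprotein.  The
packaged exemplars are synthetic stand-ins at realistic lengths.

The cluster definition is this package's operationalisation — no formal
minimal gene set for a CM-CD cluster exists in the literature.  CORE =
{CGTASE, MDXE, MDXF, MDXG, CDASE, GP}: the minimal synthesis → transport
→ degradation chain.  Glucoamylase and the glycolytic trio (Pgi, PfkA,
PykF) are EXTENDED-tier only (≥ 2 of them upgrade the tier), because real
clusters genuinely lack single assimilation genes.  Windows span at most
40 consecutive genes (known clusters reach 30; 40 tolerates insertions
without merging unrelated loci); minimal windows containing CORE are
merged and then extended across contiguous role-bearing flanking genes.
Cassette adjacency requires mdxE→F→G in transcription order on one
strand with ≤ 1 intervening gene per step; the CGTase-upstream flag uses
the same tolerance.  Accessory context genes (HPr, MurB, RapZ, RodZ,
WhiA, …) are annotated for reporting and never gate a call.  MsmX — the
shared ATPase that energises the importer — is reported genome-wide and
flagged distal when outside every cluster, its usual location.

Promoter scanning uses 6-column PWMs (pseudocount 0.5, background 0.25)
trained on the two deduced CGTase-gene promoter box pairs plus the σA
consensus (−35: TGCACT, TTTCGA, TTGACA; −10: TAATAT, CATATT, TATAAT),
box thresholds 2.9 / 3.7 (just below the weakest training instance,
≈ 2.96 / 3.81) and spacers of 15–19 nt.  On uniform-random 200-nt windows
the pair-hit rate is ≈ 2 % — chance σ-like boxes do occur, which is
biologically unsurprising — so promoter hits support, but never gate,
a cluster call.

## Synthetic data (synthetic_data)

The generator's defaults are the package's study conditions: three
CGTase variants per architecture at 65 % identity to their seed (CSR
spans, diagnostic slots and the first 35 residues protected), two decoys
per kind (CSR V flip, triad knockout, truncation inside domain B,
shuffle), a 30-gene cld-style cluster (synthesis gene, mdxEFG cassette
immediately downstream, degradation/assimilation genes, accessory
context, unknown-function filler, phosphorylase closing the span), role
genes at 60 % identity to their exemplars, a decoy cluster missing two
core roles, a distal MsmX gene, and TGCACT/TAATAT boxes with a 17-nt
spacer ending 30 nt upstream of each planted CGTase gene.

Identity targets are realised exactly: the implied number of
substitutions is drawn outside the protected set and verified by column
recount (error bounded by rounding).  Family evolution is
substitution-only Poisson(branch × rate × length) mutation down a given
tree, so leaves stay aligned and every planted coordinate remains exact.
Protecting the first 35 residues keeps signal-peptide truth constructed
rather than accidental: the lipoprotein seed's variants keep their
signal, and the other seeds are built Cys-free over that region so "no
SPII call" is guaranteed by construction.

What the fixtures do **not** emulate: insertions/deletions (an
indel-free family keeps coordinate truths exact; consequently the tests
say nothing about alignment quality under indels), realistic codon
usage or GC structure, regulatory realism beyond the planted boxes, and
real GH13 sequence diversity — the seeds are consensus constructions, so
passing round-trips demonstrates the machinery, not performance on real
proteomes.

## Problem sizes and runtime choices

The default test fixtures use 20 proteins (≈ 520–715 residues), a
two-contig genome of ≈ 88 kb with 75 genes, bootstrap runs of 100
replicates on ≈ 30-taxon families, 200 random additive matrices of up to
8 taxa for the NJ oracle, and 40–50 random pairs of length ≤ 8 for the
exhaustive alignment oracle — sizes at which the independent oracles
(alignment-path enumeration, tree-path distances, column recounts) are
exact and the whole suite runs in well under a minute of alignment time.

## Known limitations

* The scanner transfers coordinates only from its packaged seeds; real
  proteomes would benefit from user-supplied annotated references (the
  `refset` argument accepts them).
* Percent identities from global alignment need not match heuristic
  database-search identities to the integer.
* The mature-protein physchem values cannot be validated against a
  published construct whose exact linker is unstated; the calculator is
  instead pinned to its documented mass/pKa tables.
* GH13_2 maltogenic enzymes classify through the same decision table as
  CGTases; separating them is a phylogenetic, not residue-level, task.
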