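# Methods

This note documents the models, estimators, defaults and design
decisions behind `pocketevo`, in the order data flows through the
pipeline.

## Inputs and coordinate conventions

The pipeline consumes (a) a receptor–ligand complex in PDB format,
(b) an in-frame codon multiple sequence alignment of receptor orthologs
(FASTA) with a designated mammalian reference record, (c) a rooted or
unrooted newick phylogeny over the same species, and (d) a YAML branch
scheme listing the ordered taxonomic groups ("main branches", most
ancestral first), the species in each, and the group in which the
receptor's first ligand appeared.

Pocket positions are 1-based residue ordinals on the ungapped reference
protein (biologist convention); alignment columns are 0-based
half-open internally; all serialised output is 1-based.  Frame
integrity is enforced at load: unequal record lengths, lengths not
divisible by three, mid-codon gaps, or an internal stop in the
reference are hard errors — an upstream codon-aware alignment step is
assumed to guarantee these properties.

## Interface extraction

A receptor residue belongs to the binding pocket iff at least one of
its heavy atoms lies within a cutoff (default 5.0 Å, configurable) of
any heavy atom of the ligand chain.  Only standard amino-acid residues
of the receptor chain are eligible; the ligand chain may be peptide or
small molecule and all its heavy atoms count; waters and hydrogens are
excluded; altlocs resolve to the highest-occupancy conformer (ties:
first listed).  The 5 Å heavy-atom criterion is a geometric substitute
for unavailable curated contact annotations and is flagged as such in
the provenance block.  Positions are reported as ordinals along the
receptor chain's residues in file order, ordered by (residue number,
insertion code); the ordinal → author-number map is emitted for
traceability.  An empty interface is a warning, not an error.

## Branch model

Tree edges are assigned to taxonomic groups by the
most-ancestral-descendant rule: an edge belongs to the most ancestral
group found among the leaves below it.  Edges inside a group's clade
therefore carry that group's label, and each backbone stem carries the
label of the group diverging at that depth, so every edge is labelled
exactly once.  Unrooted input trees are rooted on the edge separating
the most ancestral group from the rest (per-branch slicing needs
directionality).  The ligand-appearance group and every more derived
group are "ligand-present"; the appearance branch itself counts as
present.

## Conservation indexes

Per-species percent identity to the reference is computed over pocket
columns (%ID BP) and over all columns (%ID Mol); the branch value is
the unweighted mean over the group's species, with the reference
excluded from its own group to avoid self-match inflation.  Columns
where the reference is gapped are dropped from the denominator; a gap
in a species at a counted column is a mismatch (a deleted pocket
residue is non-conservation; configurable).  Whether to average over
species or sites first is a genuine free choice; averaging per-species
values keeps them usable for the branch-level test.

The pocket-vs-molecule comparison is an unpaired Welch (unequal
variance) two-sided *t*-test on the per-species value lists, the robust
default when the variance structure is unknown.  Direction
(pocket-higher / whole-higher) is only assigned when p < α (default
0.05).  Groups with fewer than two usable species yield an undefined
sentinel.

The within-branch non-synonymous count N is, per pocket column, the
number of distinct amino acids observed among the group's species
(gaps ignored) minus one, floored at zero, summed over columns — a
minimum count of amino-acid-changing events inside the branch,
deliberately independent of the tree.  It is compared against the
"low" threshold 20 in the classifier.

## Selection estimators

All selection statistics are counting-based; no likelihood machinery
and no external binaries.  Branch lengths play no role in the
estimators (counts are per-edge sums); they matter only to the
simulator.

**Site counts.**  `count_sites` implements the classic Nei–Gojobori
fractions: per codon position, the fraction of the three possible
changes that are synonymous contributes to s-sites; stop neighbours
count as non-synonymous; n + s = 3 for every sense codon (TTT → s =
1/3, ATG → s = 0).

**Pathway averaging.**  A codon pair differing at k positions is
scored by averaging synonymous/non-synonymous step counts over all k!
shortest mutational pathways, excluding pathways that traverse a stop
codon; if every pathway is stop-blocked the difference counts as
entirely non-synonymous.

**Pairwise dN/dS** skips codon pairs with gaps, ambiguity or stops,
averages site totals over the two sequences, and corrects the
proportions with the Jukes–Cantor-style transform
d = −(3/4)·ln(1 − (4/3)p), undefined once p ≥ 3/4.  ω is undefined
(NaN) when ds = 0; the classifier treats an undefined ω as satisfying
neither "ω > x" nor "ω < x".

**Ancestral reconstruction** uses a unit-cost Sankoff dynamic program
per nucleotide column — exact minimum-change parsimony that also
handles polytomies (on bifurcating trees it coincides with Fitch).
Resolution is deterministic: the root takes the lexicographically
smallest minimum-cost state; below the root, a node keeps its parent's
state whenever that is globally optimal, with lexicographic
tie-breaks.  Leaves with gaps or missing states act as wildcards.

**Per-branch ω** sums pathway-averaged substitution counts over the
group's edges from the reconstructed parent → child codon pairs
(columns with a reconstructed stop are skipped for that edge and
logged).  Site totals come from the reference pocket codons, weighted
by mutational opportunity: each single-nucleotide change is weighted by
κ (default 2.0, a typical vertebrate transition/transversion rate
ratio) when it is a transition, with stop neighbours excluded.  Without
this weighting the estimator inherits the well-known NG86 bias —
synonymous changes are transition-enriched, so plain site counts
overestimate dS and a neutral sequence reads ω ≈ 0.84 under κ = 2.
dn = Nd/N and ds = Sd/S are uncorrected per-edge-sum rates (a
distance-style correction is not meaningful for sums over many short
edges), and ω = dn/ds.

Known limitation: at per-edge divergences approaching one substitution
per codon, multi-hit codons collapse into single parent–child pairs
whose pathway average leaks fractional synonymous counts; a true ω of
1.5 is estimated at ≈ 1.3–1.36 (measured by single-edge simulation).
Position relative to 1 is preserved, but positive-selection calls near
the boundary are conservative, and with ~25 synonymous counts per
branch the estimate carries a standard deviation near 0.3.

**Per-site scan.**  Per protein column, Nd and Sd are summed over all
edges and the non-synonymous fraction is tested against the column's
opportunity-weighted expectation with a two-sided exact binomial test
(fractional pathway counts rounded to the nearest integer).  Because
several hundred columns are tested, p-values are Holm-adjusted before
any site is declared positive or purifying (raw p-values are also
reported; `correction="none"` disables the adjustment).  Family-wise
control is what makes the classifier's "no positively selected site in
the pocket" criteria meaningful: with ~50 pocket columns, an
uncorrected per-site α = 0.05 would flag at least one pocket site by
chance in most runs.  Columns with no substitutions are uninformative.

## Scenario classifier

Thresholds (all configurable): ω-positive 1.0, ω-low 1.0, pre-ligand
%ID ceiling 30, S1 %ID floor 40 (the divergent-branch floor is
ambiguous between 40 and 50; 40 is the permissive default), N ceiling
20, α 0.05, N-contrast α 0.05, trend tolerance 5 %ID points, S3
terminal %ID minimum 90.

Criteria are evaluated in order S1 → S2 → S3 with first-match-wins
(the scenarios are conceptually disjoint but no tie-break is implied by
their definitions); all criterion outcomes are retained so borderline
cases are auditable.  "%ID increases toward mammals" is tested as a
noise-robust trend — the terminal (mammalian-side) value must lie
within the tolerance of the series maximum and above the first
ligand-present value — rather than exact monotonicity, which sampling
noise of a ~25–50-residue pocket violates in a large fraction of
genuinely increasing series.  The S3 ω-criteria split the
ligand-present groups: purifying selection is required strictly after
the appearance branch, ω > 1 at the appearance branch itself; elevated
pre-ligand ω is reported but not mandatory.  The S3 N-contrast is a
one-sided Welch test of per-group N, pre-ligand vs ligand-present.
Fewer than two sampled pre-ligand groups or no sampled post-ligand
group yields UNCLASSIFIED with a note (the "phylogeny failed" case).

## Synthetic data generator

Sequences evolve by a continuous-time codon process with
single-nucleotide changes only: rate(i → j) ∝ κ^[transition] · π_j ·
{1 synonymous, ω non-synonymous, 0 stop}, ω looked up by the edge's
branch class (pre-ligand / appearance / post-ligand via the edge
partition) and site class (pocket / background).  Rates are scaled so
one unit of branch length equals one expected substitution per codon
under neutrality at the stationary frequencies (the standard codon
model normalisation; branch lengths are in substitutions per codon
site).  Simulation is exact per codon along each edge (Gillespie);
waiting times and jumps come from one RNG stream per edge, spawned
deterministically from the master seed in preorder edge order, so
results are byte-reproducible.  No indels and no stop codons are ever
produced.  Codon frequencies default to equal over the 61 sense
codons; κ defaults to 2.0.

The scenario regimes are fixed ω schedules:

| regime | pocket pre | pocket appearance | pocket post | background |
|--------|-----------:|------------------:|------------:|-----------:|
| S1     | 0.02       | 0.02              | 0.02        | 0.4        |
| S2     | 1.0        | 1.5               | 1.5         | 0.2        |
| S3     | 1.5        | 1.5               | 0.02        | 0.3        |

The default family emulates a receptor present since the first
metazoans, on a clade ladder over ten taxonomic groups (opisthokonts …
mammals) with the ligand appearing in vertebrates.  Geometry
(substitutions per codon): each group is a star clade — three species
at pendant 0.07, except mammals with five species plus the reference at
pendant 0.04 (mammals are by far the densest-sampled taxon in real
ortholog resources, and the reference group needs enough close
conspecifics for the within-group Welch test to have power) — on stems
of 2.0 for the four pre-vertebrate groups (invertebrate orthologs are
several hundred My apart) and 1.2 for the vertebrate radiation, with
backbone internals of 0.8.  Sequences are 500 codons with a 50-codon
pocket (10% of the protein, at the large end of real receptor–peptide
interfaces), evenly spaced.

These defaults were set by an explicit power calibration, run before
the validation experiments were frozen: the per-branch synonymous
counts must stay well away from zero (an Sd = 0 branch yields an
undefined ω and vetoes scenario 1), the within-branch N must stay
below 20 under the neutral-to-positive pocket regimes (which caps
pocket size × within-group divergence), the pre-ligand pocket %ID must
sit clearly below the 30% ceiling (which demands deep pre-vertebrate
stems), and the appearance-branch ω > 1 signature must be detectable
against the estimator's ≈ 0.3 standard deviation (which demands a large
pocket × appearance-branch-length product).  These constraints pull in
opposing directions; the defaults are the compromise that satisfies
all margins simultaneously.  The residual weakness is the
appearance-branch ω check under scenario 3: with true ω = 1.5
estimated at ≈ 1.3 ± 0.3, roughly 15–20% of S3 families read ω ≤ 1 at
the appearance branch and fall to UNCLASSIFIED, capping scenario-3
recovery near 80–85% and overall recovery near 92%.

What the generator does *not* emulate: indels and alignment error,
among-site rate variation beyond the two site classes, non-uniform
codon usage, lineage-specific κ, gene loss/duplication, and any
structure for the ligand.  Passing the recovery benchmark therefore
shows the pipeline recovers the scenario signatures from clean codon
alignments of realistic depth — not that it is robust to alignment or
orthology error in real data.

## Validation experiments

The acceptance script and `tests/test_acceptance.py` rerun, from
scratch: exact (1e-9) agreement of the pairwise counter with an
independent brute-force pathway enumeration on 200 random 100-codon
pairs; the site-count identities over all 61 sense codons; parsimony
scores vs exhaustive enumeration over all ancestral labelings on
hundreds of random ≤ 6-leaf trees; recovery of simulated ω on a
balanced 8-taxon tree (edge length 0.2, 500 codons, κ = 2) — neutral
median within [0.8, 1.2] over 20 replicates and median ordering across
ω ∈ {0.05, 0.5, 1.0}; the site scan's positive rate under neutrality
(≤ 10% of informative sites at α = 0.05); scenario recovery over 50
families per regime with the S1/S3 schedule-swap negative control
(labels must follow the regime, not the metadata); interface extraction
vs an all-pairs distance oracle with cutoff-monotonicity and
rigid-motion invariance on 100 random structures; and byte-identical
reruns of the end-to-end pipeline.  Problem sizes were chosen so the
whole suite runs in a few minutes on a laptop-class single core.
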