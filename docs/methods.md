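# Methods

This note documents the models and procedures implemented in `cobashare`,
the parameters that matter, the design choices made where conventions
diverge, and what the synthetic-data generators do and do not emulate.

## Read-level functional profiling

Translated metagenomic reads (six-frame, standard genetic code, stops as
`*`, N-containing codons as `X`, trailing partial codons dropped) are
searched against per-gene profile HMMs; the pipeline consumes the
per-domain tabular output. Filtering proceeds in a fixed order:

1. **E-value cutoff** — hits with independent E-value > 10⁻⁶ are removed.
   The threshold is inclusive (a hit at exactly 10⁻⁶ survives).
2. **Best-hit resolution** — a read aligning to several HMMs (in any
   frame; the `_frameK` suffix is stripped first) keeps exactly one hit:
   minimal E-value, ties broken by maximal bit score, residual ties by
   lexicographically smallest HMM name. The last tie-break is a
   determinism choice; E-value/bit-score ordering leaves it open.
3. **Coverage gate** — per (sample, gene), the union of hit envelopes in
   HMM coordinates must cover ≥ 20% of the HMM length (inclusive
   boundary) for the gene to count as present in that sample. The union
   is computed across all taxa jointly: presence is a property of the
   sample's read pool, not of any single species. Genes failing the gate
   contribute no table entries for that sample.
4. **Normalization** — each (sample, gene, taxon) entry carries the raw
   retained-read count, the count divided by HMM length (for
   within-sample comparisons), and additionally divided by the sample's
   post-QC read count and scaled to hits per million reads (for
   cross-sample comparisons). Per-million is a convention choice; the
   scale cancels in every ratio the package reports.
5. **Rare-pair filter** — a (gene, taxon) pairing is kept only if it
   appears (≥ 1 retained read) in ≥ 5 samples spanning ≥ 2 studies.
   "Appears" means one read suffices; the filter is idempotent.
6. **Contaminant removal** — entries whose taxon is on a supplied
   contaminant list are dropped (the list is an input, not learned here).

Taxon contributions (per sample, over a gene subset) and gene frequency
profiles (per gene, across samples) are ratios of length-normalized and
length+depth-normalized counts respectively; both are probability vectors
by construction. A species is called a metagenomic de novo producer when
it retains entries for ≥ 5 distinct genes of a 10-marker panel.

**Marker panel.** The package registers an 11-gene marker default spanning
the pathway — cobA; cbiL, cbiH, cbiF, cbiC, cbiA (corrin ring, anaerobic
nomenclature, with aerobic orthologues recognized); cobQ, cobD, cobP, cobS
(nucleotide loop); bluB (lower ligand) — and uses the 10 non-bluB markers
for producer calls, because documented producers of non-benzimidazolyl
cobamides lack bluB. Both the panel and the ≥ 5 threshold are
configurable (`ProfilingParams`); the specific gene choice is a documented
assumption, not a claim about any external curation.

Mock-community false-positive accounting divides hits assigned to taxa
outside the known mock roster by all classified hits; reads the classifier
left unclassified count in neither numerator nor denominator.

## Genome classification

`PathwayModel` fixes the gene vocabulary by subsection: tetrapyrrole
precursor synthesis (hemA/hemL/hemB/hemC/hemD/cobA), aerobic corrin ring
(cobG/cobJ/cobM/cobF/cobK/cobL/cobH/cobB/cobN), anaerobic corrin ring
(cbiK/cbiL/cbiH/cbiF/cbiD/cbiJ/cbiG/cbiE/cbiT/cbiC/cbiA), nucleotide loop
(cobO/cobQ/cobD/cobP/cobS/cobT/cobC), lower ligand (bluB). Aerobic and
anaerobic orthologue pairs (e.g. cbiH↔cobJ, cbiP↔cobQ, cobU↔cobP) satisfy
a requirement in either series; corrin-ring completeness is the max of the
two series after orthologue expansion.

Categories are assigned by ordered rules with a recorded decision trace:
**producer** when corrin-ring and nucleotide-loop completeness are both
≥ 0.5; otherwise **salvager** when ≥ 3 of the four salvage genes
(cobQ/cbiP, cobD/cbiB, cobP/cobU, cobS) are present; otherwise
**nonproducer**. The 0.5/0.5/3 thresholds are this package's documented
defaults (`CategoryRules`) — the semantics ("producer / precursor salvager
/ nonproducer") are standard, the exact cutoffs are configurable because
published category scorings differ in detail. bluB is tracked as a
benzimidazolyl-capability flag and never required for producer status.
cbiZ (cobamide remodeling) is registered as an HMM but excluded from
category scoring.

Dependence is a separate axis: a genome is cobamide-dependent iff it
encodes ≥ 1 of seven cobamide-dependent enzyme families (B12-dependent
ribonucleotide reductase, metH, methylmalonyl-CoA mutase family,
ethanolamine ammonia lyase, B12-dependent glycerol/diol dehydratase,
D-ornithine 4,5-aminomutase, epoxyqueuosine reductase; stored under
gene-symbol stand-ins nrdJ/metH/mcmA/eutB/pduC/oraS/queG).

Group contrasts (e.g. genome length by host vs environment association)
use a two-sided Mann–Whitney U test: exact null when both groups have
n ≤ 8, tie-corrected normal approximation otherwise.

## Association networks

Counts are compositional, so inference runs on the centered log-ratio
transform: per sample, add a pseudocount (default 1), close to
proportions, take logs, subtract the row mean. With pseudocount 0 the
transform is scale-invariant; with a pseudocount it requires no zero
handling.

The graph estimator is neighborhood selection: each species' standardized
CLR column is regressed on all others with an L1 penalty (coordinate
descent, objective (1/2n)‖y − Xβ‖² + λ‖β‖₁, tolerance 10⁻⁶, ≤ 10⁴
sweeps), over a 20-point log-spaced penalty path from λ_max (the largest
absolute off-diagonal entry of the standardized CLR covariance, which
zeroes every regression) down to λ_max/100. An edge exists when either
directed coefficient is nonzero ("or" symmetrization, the default; "and"
is available); its sign and weight come from the symmetrized coefficient
mean, and pairs whose mean is exactly zero are dropped.

The penalty is chosen by StARS: 50 subsamples without replacement of size
min(⌊10√n⌋, ⌊0.8n⌋), per-edge selection frequency ξ at each λ, per-λ
instability = mean of 2ξ(1−ξ) over all pairs, monotonized by a cumulative
max from the sparse end; the selected λ is the smallest (densest graph)
whose monotonized instability is ≤ 0.05, refit on the full data. If no λ
qualifies the sparsest is returned with a warning — on truly null data the
subsample-level noise can keep instability above threshold at every λ,
and the sparsest penalty then correctly yields an (almost) empty graph.
Subsample count/size and the 0.05 threshold follow the reference defaults
of the stability-selection literature and are exposed in `NetworkParams`.

Species enter network inference only if, over the pooled samples of all
studies, mean relative abundance > 0.015% and prevalence ≥ 55% — a single
roster for all studies, with networks then inferred per study (or per
study × microenvironment group). Consensus networks keep edges appearing
with identical sign in ≥ 2 input networks (weight = mean of contributing
weights); isolated nodes are dropped, a choice recorded in the output
rather than hidden.

Topology metrics: density 2|E|/(|V|(|V|−1)); global transitivity
3 × triangles / connected triples; modularity by greedy agglomerative
maximization starting from singletons, merging the connected pair with the
largest gain and breaking ties by the lexicographically smallest community
pair (deterministic by construction; like all greedy modularity methods
the value is a lower bound and the partition can depend on labels when
gains tie); phylum assortativity is Newman's nominal assortativity.

Edge categories count unordered producer/salvager/nonproducer endpoint
pairs, plus the share of edges joining a producer to a cobamide-dependent
salvager or nonproducer — the edges where sharing is mechanistically
plausible.

## Community statistics

Rarefaction is a multivariate hypergeometric draw to exactly the target
depth (default 1,500,000 reads); samples below depth raise an explicit
discard signal. Shannon diversity uses the natural log by default (the
base is configurable; conventions differ and the choice only rescales).
Bray–Curtis runs on square-root transformed abundances by default, which
up-weights rare taxa; the transform commutes with pre-square-rooted input.
Producer cumulative abundance (CPC) is a subset sum of relative
abundances. Quartile grouping uses strict inequalities against the first
and third quartiles (type-7 linear-interpolation quantiles when computed
from data): values exactly at a bound are Mid. Rank tests are Spearman,
two-sided Mann–Whitney, and Kruskal–Wallis followed by Dunn's z-tests on
pooled tie-corrected ranks with Bonferroni multiplication capped at 1.
Batch-effect adjustment and ordination are out of scope; Bray–Curtis
matrices are exported for external ordination.

## Riboswitch context

Riboswitch covariance-model hits are filtered at E ≤ 10⁻⁶ and counted raw
— read and model lengths are comparable, so length normalization would add
nothing. For loci mapped onto genomes, genes overlapping or within a
5,000 bp window (a parameter; regulatory neighborhoods have no canonical
width) are listed upstream/downstream *relative to the riboswitch's
strand*, because a cobalamin riboswitch acts in the 5′ UTR of the
transcript it controls. The locus category is that of the nearest
same-strand downstream gene under a user-supplied function map, falling
back to `hypothetical` for product-less genes and `other` for unmapped
ones. Flanking distance is the coordinate difference between facing ends
(a gene starting at 200 after a riboswitch ending at 150 is 50 bp away);
overlap is distance 0.

## Synthetic data: what it emulates, what it does not

`make_community` plants categories by construction: producers carry the
complete pathway gene complement (hence all markers), salvagers exactly
the salvage set, nonproducers neither; a configurable fraction carries
1–3 dependent enzyme families; phyla rotate over four labels.

`simulate_hit_table` draws per-sample species abundances log-normal
(σ = 1.0, a standard heavy-tailed abundance model) and allocates hit reads
to (species, gene) cells with probability ∝ abundance × HMM length.
Envelope lengths are max(20% of the model, 40 aa) with tiled starts, so
any truly detected gene passes the coverage gate — the generator isolates
counting, normalization, and taxonomy behavior from coverage noise, which
is instead exercised by planted "trace" genes (2 reads pinned to the
first 15% of a model no roster species carries, guaranteed to fail the
gate). False positives are a flat per-read Bernoulli reassignment to
out-of-roster taxa; real classifier errors are structured (near-neighbor
confusions), so passing the false-positive tests shows correct rate
accounting, not robustness to realistic misclassification. Metadata depth
is reads-per-sample × 100, standing in for the fact that cobamide-gene
hits are a small fraction of a metagenome.

`simulate_count_matrices` builds a precision matrix from the planted edge
list (unit diagonal, off-diagonal −sign × 0.3 by default, ridge-inflated
to a minimum eigenvalue of 0.01), inverts and normalizes it to a
correlation matrix, and maps latent Gaussian draws through the normal CDF
into negative-binomial (species means log-normal around 50, size 5) or
Poisson marginals — a Gaussian copula, chosen over direct multivariate
count construction because it preserves the planted graph's rank
correlations, which CLR-based inference consumes. Studies share graph and
marginals but draw independently. The generator does not emulate
zero-inflation beyond what the NB produces, sequencing-depth variation
across samples, or compositional closure of real pipelines.

Because the generators are constructions, the recovery tests demonstrate
internal correctness (rules implemented as stated, estimators recovering
planted structure under their own assumptions), not performance on real
metagenomes.

## Problem sizes and numerical choices

The validation suite and `scripts/acceptance.py` use desk-scale problem
sizes chosen to make the statistics decisive while keeping runs fast:
planted-truth recovery at 50 species × 60 samples × 3 studies × 3,000
hit-reads/sample; false-positive estimation at 10⁵ hits × 5 seeds
(binomial SE ≈ 10⁻⁴ against a planted 10⁻³); network recovery at p = 30,
n = 800 (comfortably above the n ≈ p detectability regime for partial
correlations of 0.3 after copula attenuation); rank-test calibration at
2,000 null replicates (rejection-rate SE ≈ 0.5 percentage points at
α = 0.05). Lasso coordinate descent tolerance is 10⁻⁶; probability-vector
identities are asserted to 10⁻¹²; exact-zero symmetrized coefficients are
dropped rather than thresholded. All randomness flows through
per-call-seeded generators; there is no global random state anywhere in
the package.

## Known limitations

- The category-rule thresholds and marker panel are documented defaults,
  not a reproduction of any specific published scoring table; real
  analyses should supply their curated `PathwayModel`/`CategoryRules`.
- Greedy modularity is a heuristic lower bound; partitions on graphs with
  tied merge gains depend on node labels.
- The rare-pair filter and producer calls operate on presence (≥ 1 read),
  so extremely deep samples can promote spurious pairings that a
  rate-based filter would not; mirroring the published rule was preferred.
- Consensus merging requires exact species-name agreement across studies;
  no taxonomy harmonization is attempted.
- Per-sample independence is assumed when reconciling reads that align to
  multiple HMMs; no cross-sample reconciliation is performed.
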