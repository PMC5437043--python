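# Methods

This note records the models, conventions and design choices behind
`plastohotspot`, in the spirit of a methods supplement: what each stage
computes, which knobs matter, and what the synthetic data do and do not
establish about real plastomes.

## Coordinates, formats and the quadripartite contract

All internal coordinates are 0-based half-open on the forward strand;
GFF3 I/O converts to and from the standard 1-based closed convention.
Each genome must carry four `region` features — LSC, IRb, SSC, IRa, in
that order — which must tile the sequence exactly, with the two IRs of
equal length. Region boundaries are taken as given annotation rather
than re-detected by repeat finding: boundary detection is a separate
problem (usually settled by junction PCR or assembly inspection) and
treating it as input keeps the accounting exact. Minus-strand features
are extracted as reverse complements; locus sequences are normalized to
the orientation of the reference taxon's left flanking gene.

## Pairwise alignment

All pairwise alignments are global (Needleman–Wunsch) with affine gap
penalties: match +1, mismatch −1, gap open −4, gap extend −0.5 (a gap
of length L costs 4 + 0.5·L). The engine is Biopython's
`PairwiseAligner`; the first optimal path it reports is used, which
makes results deterministic for fixed inputs. Because the choice among
co-optimal paths can depend on argument order, the SV computation puts
its two sequences into lexicographic order first, making the statistic
exactly symmetric. The penalty ratio (gap open ≫ extend) keeps a
multi-base indel as one gap run, matching the "one event per maximal
gap run" convention below.

## InDel events

One event = one maximal run of gap characters in either row of a
pairwise alignment. Terminal runs at either end are never events (they
reflect boundary drift, not internal mutation). Alignment is performed
region by region — LSC/LSC, SSC/SSC, one IR copy against one IR copy —
which prevents spurious gaps from bridging region boundaries; IR counts
therefore refer to a single copy. An event is NDH-related when its
reference interval (insertions use the flanking base) lies within 50 bp
of an annotated *ndh* feature; the window is a judgement call — it is
meant to capture the deletion scars left at the boundaries of truncated
genes, and no principled value exists because "related" is not a
published operational definition.

## The SV statistic

SV = (mutations + InDel events) / (conserved sites + mutations + InDel
events) × 100, computed per taxon pair after trimming terminal gap
runs, then averaged over all unordered distinct pairs in which both
sequences are present. Self-pairs are excluded (they would only dilute
the mean with zeros) and the pair count is exposed in the output for
audit. Per-locus GC content is computed on the reference taxon's
sequence — a single deterministic representative — since an
alignment-wide GC would vary with taxon sampling. Ranks are dense
(1…L), ties broken lexicographically by locus name so reruns are
bit-stable. Loci shorter than 150 bp in the reference are discarded
before any SV computation; short spacers carry too little alignment
context for the event counts to be meaningful.

## SSR detection

Perfect tandem repeats of primitive 1–6 bp motifs, reported at ≥8 units
(mononucleotide) or ≥5 units (multinucleotide); motifs are
canonicalized to their lexicographically smallest rotation on the given
strand (a poly-T run is reported as T, not folded onto A — both
conventions exist in the literature and the strand-explicit one matches
how published tables list types). Overlapping reports are collapsed to
the longest span, so a homopolymer inside a longer dinucleotide tract
is not double-reported. Cross-taxon homology of an SSR site uses the
locus identity plus 20 bp of flanking context with ≤2 mismatches per
flank — cheaper and more robust to repeat-length change than whole-locus
alignment; a site is retained when present in a minimum number of taxa
(default 15, scaled down in tests) and called polymorphic when at least
two distinct unit counts occur.

## Statistical kernels

Spearman's correlation uses midranks for ties and a two-sided p from
the t approximation with n−2 df (the default behaviour of mainstream
statistics packages at these sample sizes). The two-sided Mann–Whitney
U test is exact by full enumeration of group assignments when
n₁+n₂ ≤ 12 — two-sidedness defined as P(|U − mn/2| ≥ |U_obs − mn/2|)
under the permutation null — and otherwise uses the normal
approximation with tie-corrected variance and a 0.5 continuity
correction. OLS is textbook least squares with R² = 1 − SSE/SST.
These are deliberately self-contained implementations; the test suite
cross-checks them against scipy on random data.

## Tree engine

The combination analysis needs thousands of trees, so the default
engine is neighbor joining on Jukes–Cantor distances with pairwise
deletion of gap/ambiguous sites, and classical nonparametric bootstrap:
columns resampled with replacement, supports = percentage of replicate
trees containing each internal bipartition of the point tree. A
saturated pair (mismatch fraction ≥ 0.75, where the JC correction
diverges) is capped at distance 5.0 with a warning; a pair sharing no
non-gap columns is an error naming the pair. Mean bootstrap support
averages over ingroup internal edges only — the root edge, the
outgroup side and edges inside the outgroup clade are excluded
(configurable to `all`); the published procedures do not state which
nodes enter such means, and the ingroup scope makes scores comparable
across combinations in which outgroup placement varies. The scoring
procedure is engine-agnostic: any program that emits newick with
support values could be substituted where ML inference (e.g. GTR+Γ) is
required, at a large cost in runtime.

The per-size summary fits an OLS line to mean support against
combination size over all combinations (not per-size means — the
scatter at small sizes is informative), and the plateau is the smallest
size whose per-size mean is within 2 support points (configurable) of
the best.

## The synthetic generator

The generator emulates the statistical structure the analysis consumes,
not plastome biology per se. A genome is an ordered list of segments
(genes, exons, introns, spacers, SSR tracts) spanning LSC, IRb and SSC;
IRa is emitted as the exact mirror of IRb, so IR mirror symmetry is
preserved through evolution by construction and every IR edit exists
once. All edits operate on segments, so annotations lift through
insertions and deletions exactly, and every planted event is recorded
in a replayable ground truth (verified by an exact length-bookkeeping
test: each region's length change equals the signed sum of its planted
events).

Default study conditions mirror a *Dendrobium*-like design: 25 ingroup
taxa plus 3 outgroups and an unevolved reference genome, ~150 kb
genomes, ~92 syntenic loci, ten hotspot loci with a 5× substitution
multiplier. `SimConfig.desk()` scales this to 15 kb / 12 loci / 10 taxa
/ 4 hotspots; the test suite and the acceptance script run at desk
scale so the full suite stays within a few minutes on one CPU.
Parameter defaults, per unit root-to-tip path (trees are Yule with
exponential branch lengths, rescaled to mean depth 1):

* substitution rate 0.02/site (Jukes–Cantor), ×5 in hotspot loci —
  chosen so background locus SV sits near 4 % and hotspot SV near 20 %,
  the order of magnitude seen in congeneric plastome comparisons;
* InDel rates per site: LSC 1.2×10⁻³, SSC 6×10⁻⁴, IR 1.5×10⁻⁴ —
  reproducing the strong LSC bias of observed InDel distributions, with
  geometric(0.3) lengths capped at 30 bp, confined to non-coding
  segments, never straddling segment boundaries, and kept ≥20 bp apart
  within a segment so planted events remain individually identifiable;
* SSR tracts seeded mostly as A/T mononucleotides (8–14 units) plus one
  AT dinucleotide and one G tract in the IR, slipping ±1 unit with
  probability 0.25 per branch; tracts carry non-motif guard bases so
  the realized unit count always equals the recorded ground truth;
* hotspot loci drawn AT-rich (GC 26 % vs 37 % background), encoding the
  empirical association between mutational hotspots and AT bias, which
  is what makes the SV–GC correlation testable;
* about half the ingroup lineages truncate (or with probability 0.15
  delete) 1–3 SSC *ndh* genes on their terminal branches, with the
  removed extent recorded as an NDH-related deletion.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: IR expansion/contraction (region
boundaries move only through indels), rate heterogeneity beyond the
hotspot multiplier (no Γ, no codon structure), rearrangements and
micro-inversions, recombination, base-compositional evolution, and
sequencing/assembly error. One desk-scale artifact deserves note: with
a 15 kb genome the NDH truncations dominate total size variation, so
the changed-length correlations come out SSC-led rather than LSC-led,
and retained-NDH length correlates with genome size — both patterns
opposite to what a full-size plastome set shows. The acceptance outputs
report these numbers as honest properties of the simulated conditions,
not as reproductions of published correlations.

## Known limitations

* NJ + bootstrap is a stand-in for ML inference; absolute support
  values differ from GTR+Γ bootstraps, though the ranking of
  combinations — the quantity of interest — is far less sensitive.
* Center-star progressive alignment ("once a gap, always a gap") is
  exact for the low-divergence, indel-sparse loci it is applied to but
  is not an optimal multiple aligner.
* At desk scale the bootstrap saturates quickly (many combinations at
  100 % support), which compresses the SV–support correlation.
* The SSR flank-matching heuristic can merge distinct tracts closer
  than one flank length, and interrupted/compound repeats are split at
  every interruption (perfect repeats only).
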