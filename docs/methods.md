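# Methods

This note documents the statistical conventions, algorithmic choices and
generator design behind `mitocensus`, in the order the pipeline runs.

## Coordinates and the junction census

Annotations use 1-based, inclusive coordinates on both ends, so
`length = stop − start + 1`; this is the arithmetic under which a
printed mitogenome annotation table is internally consistent, and the
parser cross-checks both the declared Length and the declared Interval
column against the coordinates, failing loudly on disagreement.
Thousands separators and typographic minus signs are normalized on
input.

The junction census is **linear over printed row order**: the
wrap-around junction from the control region back to the first gene is
excluded. Rationale: annotation tables leave the control region's
interval blank, and only under the linear convention do the census
categories partition the n−1 printed junctions. Wrap-around (origin-
spanning) features are rejected by the GenBank parser rather than
silently split.

Strand labels are taken verbatim from the annotation and reported as
plus/minus. No attempt is made to reinterpret them as heavy/light:
published tables are not consistent about which strand they call heavy,
and the census is well-defined without deciding.

Gene symbols are normalized through an editable alias table shipped as
package data (`COB`→`cytb`, `ND4L`→`nad4L`, `tRNA-Ser`→`trnS1`, ...);
unknown labels pass through untouched so exotic annotations fail
comparisons visibly instead of silently.

## Composition and skew

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C). N bases are excluded from
every denominator (content and skew) and reported as a separate count,
keeping both statistics pure four-letter quantities; a zero denominator
yields a missing value, never 0, because 0 is a meaningful (balanced)
skew. Per-feature composition is computed on the annotated plus-strand
span — the convention of whole-table statistics in mitogenome papers —
and minus-strand features additionally get a reverse-complement row
(labelled `(RC)`), since both skews flip sign between strands and the
strand basis of published per-gene skews is often ambiguous. TSV output
rounds percentages to 2 decimals; JSON keeps full precision.

## Codon usage

The genetic code is fixed to the vertebrate mitochondrial code
(translation table 2), taken from Biopython's table registry: AGA/AGG
are stops, ATA encodes Met, TGA encodes Trp. CDS extraction
reverse-complements minus-strand features, trims and flags a trailing
partial codon (the incomplete-stop convention, completed in vivo by
polyadenylation), and exposes the first codon and terminal triplet
separately.

Annotated terminal triplets are tallied verbatim even when they are not
valid table-2 stops — they are incomplete or abutted annotations, and
"repairing" them would manufacture data. RSCU counts include start
codons (a one-codon-per-gene effect) and exclude terminal triplets by
default; both are switches on `CodonUsageTable.from_codon_lists`. A
synonymous family never observed yields missing RSCU for all members
rather than zeros.

## NG86 dN/dS

The Nei–Gojobori (1986) counting method, proportion-based, with
Jukes–Cantor correction — the estimator family desktop tools report.
Choices:

* Site counting: per codon position, the fraction of the three possible
  changes that preserve the amino acid; changes creating a stop count as
  nonsynonymous. S + N = 3 × codons, an invariant the tests enforce.
* Multi-hit codons: observed differences are averaged over all minimal
  substitution pathways; pathways through stop codons are excluded, and
  if every pathway is blocked all are used (the conventional fallback).
  `exclude_stop_paths=False` switches to unconditional all-pathway
  averaging, which reproduces Biopython's NG86 exactly (used as an
  independent cross-check in the tests, never as the implementation).
* p ≥ 3/4 makes the Jukes–Cantor distance undefined; undefined dS/dN and
  ω = dN/dS with dS = 0 propagate as missing values with exclusion
  counts, never as zeros.
* Codons containing ambiguity characters are dropped pairwise; an
  internal stop codon aborts with a frame error rather than being
  skipped. A shared terminal stop is trimmed.
* Gene-level summaries are unweighted means over all unordered species
  pairs (how the averaging scheme of desktop tools is usually read);
  pairs with undefined values are excluded and counted.

The counting classification is exact only when each differing codon
differs by a single nucleotide. The sequence evolver therefore offers a
`single_hit` mode (at most one substitution per codon over the whole
tree) under which synonymous-only simulation gives dN = 0 and
nonsynonymous-only simulation gives dS = 0 *by construction*; without
it, pathway averaging on multi-hit codons can attribute fractional
counts across categories, which is a property of the estimator, not a
bug.

## tRNA cloverleaf folding

Template-constrained exhaustive search instead of free-energy folding:
the claims this pipeline supports are arm-level (presence/absence,
wobble pairs), and a constrained combinatorial search is deterministic,
parameter-free and testable without thermodynamic tables. The template
enumerates acceptor stem 6–8 bp, D stem 0 or 3–4 bp with loop 4–12 nt
(0 = structurally absent, spanning 4–16 nt unpaired), anticodon stem
4–5 bp with a fixed 7 nt loop, variable loop 3–23 nt, T stem 4–5 bp
with loop 5–9 nt, short connectors, and a 0–3 nt 3' tail; all windows
are a config block (`FoldConfig`) whose defaults cover published
vertebrate mitochondrial tRNA dimensions (55–95 nt). Allowed pairs are
Watson–Crick plus G·T (the DNA-alphabet rendering of the G·U wobble; T
is used throughout, never U).

The fold maximizing total paired bases wins; ties break toward
canonical arm dimensions (acceptor 7, D 4, anticodon 5, T 5, T-loop 7),
then by leftmost placement, making folding a total deterministic
function. An arm is absent when its stem pairs < 2 bases in the optimum
(`arm_min_pairs`, configurable) — a single spurious pair cannot
manufacture an arm. A supplied anticodon that is not found in the chosen
anticodon loop sets a warning flag rather than failing, since annotation
and fold can legitimately disagree.

Scoring uses an anti-diagonal cumulative pair matrix, making each of the
~67k template geometries O(1) to score (~0.1 s per tRNA).

Published wobble-pair censuses come from other structure predictors, so
cross-species wobble counts are report-level output here, never
assertions.

## Gene order

Orders are signed symbol sequences; circular orders are canonicalized to
start at trnF (the conventional vertebrate first gene) else the
lexicographically smallest symbol, making outputs rotation-invariant.
The default breakpoint comparison is unsigned — a strand flip alone is
not a breakpoint — because the rearrangements this pipeline targets are
translocations; signed mode is a flag. `diff_blocks` decomposes one
order into maximal runs contiguous in the other and reports every block
except the longest (the conserved backbone) as displaced; for a
reciprocal translocation of two blocks this isolates exactly those two.
This is a reporting heuristic, not a rearrangement-scenario inference
(inversion/DCJ sorting is out of scope).

## Synthetic data generator

The generator's defaults are the study conditions the pipeline is tested
under: a circular 16,712 bp genome laid out from a published teleost
annotation template (37 genes + control region with its exact junction
structure — 15 seamless / 10 overlaps / 12 gaps — lengths, strands and
start codons, including the GTG start of cox1), genome-wide AT target
0.5253 with the control region at 0.6333, a D-armless trnS1, and a
13-carrier wobble plan distributing designed G·T pairs as acceptor 8 /
T 7 / anticodon 7 / D 6 across the first 13 template tRNAs.

* PCGs are valid table-2 ORFs: start codon, sense codons drawn from a
  codon-bias vector (default: independent-base weights matching the AT
  target, renormalized over sense codons — no in-frame stop can occur),
  and a complete (TAA/TAG) or incomplete (T/TA) stop matching the
  template length.
* tRNAs instantiate designed cloverleaves: stems are random with exact
  complements (G·T at designed wobble positions, kept away from stem
  ends), drawn at the genome AT target so pairing preserves composition;
  loops and connectors come from {C, A}, which cannot pair with each
  other. Candidates are rejection-sampled until the template folder
  recovers the designed arm presence and wobble counts, so the sidecar
  is ground truth by construction, not by expectation (acceptance is
  ~99% per draw; sampling stays deterministic under the seed).
* Annotated overlaps are resolved "first writer wins": the later feature
  adopts bases already laid down. Under the default layout this corrupts
  only stop-codon tails and tRNA termini — never start codons or D
  arms — and affected features carry an `overlap_affected` sidecar flag;
  realized start/terminal triplets are re-extracted from the assembled
  genome.
* rRNAs and spacers are i.i.d. bases at the AT target; the control
  region at its elevated target. Residual composition bias: {C,A} loops
  sit at 50% AT and stop-codon exclusion trims AT-rich codons, leaving
  the realized genome ~0.5–1 point below an extreme AT target — well
  inside the ±2-point binomial recovery band asserted at 16 kb.

Sequence evolution along a Newick tree applies Poisson numbers of
synonymous (within-family single-nucleotide) and nonsynonymous
(across-family, never creating a stop) events per branch, with an event
log as ground truth; `single_hit` is described above. The generator does
not emulate: real codon autocorrelation, rate heterogeneity across
sites, transition/transversion bias, indels or alignment error,
heteroplasmy, or NUMT contamination — passing tests therefore certify
the statistics' bookkeeping and invariances, not robustness to
real-data artifacts upstream of this package's scope.

## Scale of the shipped checks

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path with stable statistics: 100-tRNA structure-recovery samples,
120–300-codon alignments, 4–5-taxon trees, single 16.7 kb genomes. The
published 23-species analyses (per-gene dN/dS ranking, cross-species
amino-acid heatmaps, ML/BI phylogenies) require external accessions and
inference tools that are deliberately out of scope; the machinery they
would run on is covered by the property suites and a purifying-selection
emulation (mean ω ≪ 1 on a synthetic clade).

## Known limitations

* The cloverleaf folder reports the template optimum; genuinely
  non-cloverleaf tRNAs are described as "arms absent", not rejected.
* NG86 is a counting estimator: no rate-ratio weighting, no codon-model
  ML; saturated pairs (p ≥ 3/4) are missing, not extrapolated.
* Neighbor joining (via scikit-bio) is shipped as a topology sanity
  check on p-distances, not a substitute for model-based inference.
* The census trusts its annotation; gene finding and boundary curation
  are upstream.
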