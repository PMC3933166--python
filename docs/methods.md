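# Methods

## Gene architecture model

A spidroin-like gene is modeled as a single uninterrupted reading frame
partitioned into three regions: an N-terminal coding region, an ordered
array of tandem repeat units (all of one period, the final unit possibly
truncated), and a C-terminal coding region. Coordinates are 0-based
half-open everywhere in the API; serialized reports use 1-based
inclusive coordinates. The reported ORF length includes the stop codon,
so protein length = ORF/3 − 1.

### Period detection

The repeat period is the codon-multiple shift `p` maximizing the mean
identity between the sequence and itself shifted by `p` (computed over
the overlap). Every multiple of the true period scores equally well, so
the smallest `p` within a tolerance (default 0.01) of the maximum is
reported, with the best non-adjacent runner-up for diagnostics. A best
score below a floor (default 0.60) means no usable tandem structure.

### Segmentation

For a near-perfect array the decomposition into units is ambiguous up to
rotation — interior windows cannot distinguish a unit boundary from any
codon-aligned offset of it; only the junctions with the non-repetitive
terminals carry that information. Segmentation therefore proceeds in two
steps:

1. **Span location.** Every codon-aligned phase of the period is scanned;
   full-length blocks with identity ≥ 50% (`terminal_threshold`) to the
   block consensus form candidate runs, and the phase with the largest
   summed in-run identity wins (ties: longer run, then smaller phase).
2. **Boundary refinement and tiling.** From the run's outermost interior
   unit boundaries, change-point scans extend the array outward: each
   codon-aligned prefix length `L` is scored by (matched positions) −
   0.75·L (`boundary_threshold`), and among lengths within 1.0 score
   point of the maximum (`boundary_slack`) the longest wins, so a single
   mutated codon at a true boundary does not shorten the array, while
   terminal sequence (≈25% expected identity) cannot extend it.
   Full-period windows continue the scan; a shorter window closes the
   array. Units are then tiled from the refined start — full periods
   followed by a possibly truncated final unit, matching how these
   arrays grow head-to-tail. Flanks become the terminals; an empty
   terminal is represented as `None`.

The truncated final unit is kept as a repeat (not fused into the
C-terminal region) whenever its prefix still out-scores the boundary
threshold, which reproduces the expected short final unit of real
aciniform genes.

## Alignment and identity

Pairwise alignment is global Needleman–Wunsch with affine gaps
(Bio.Align.PairwiseAligner): nucleotides at match +1 / mismatch −1 /
gap −2, proteins at BLOSUM62 with −10/−1 gaps. Multiple alignment is a
center-star progressive scheme — every sequence is aligned to the
longest sequence and merged on its coordinates — which is deterministic
and accurate for the near-identical sets this package targets (repeat
units, amplicon clones, congeneric consensus repeats). Coding sequences
can be aligned in protein space and back-threaded to codons, so gaps
never break the reading frame.

Percent identity defaults to **pairwise deletion** (identical columns /
columns where neither row is gapped); a gap-as-mismatch policy is
available by flag, and the two bracket the plausible readings of
"percent identical sites" (e.g. whether a truncated final unit's missing
columns count). `N` never matches anything, including another `N`.
Majority-rule consensus counts the gap as a residue, drops columns where
the gap is the unique majority, and breaks residue ties alphabetically
(flagged); a residue tied with the gap wins.

## Variant diagnosis

Within one clone set (one individual, one region):

1. **Singleton masking.** A column where exactly one clone differs from a
   single shared state in all others is attributed to polymerase error;
   the cell is replaced by the majority residue and logged. Residues
   carried by ≥2 clones are never altered. For 2-clone sets every
   difference is a reciprocal singleton, so masking is skipped with a
   warning rather than guessing.
2. **Unsupported-clone discard.** A clone is retained iff its
   post-masking residue pattern over the polymorphic columns matches at
   least one other clone (this removes PCR chimeras and clones with
   residual unmasked errors).
3. **Clustering.** Single-linkage agglomeration at >95% identical sites
   (pairwise deletion). Single-clone clusters emit nothing; each cluster
   of ≥2 clones emits its majority-rule consensus as a variant. Under
   this metric, templates differing only by indels fall in one cluster —
   a documented consequence of the identical-sites definition.
4. **Minimum locus count** = ⌈variants / ploidy⌉, ploidy defaulting to 2.

The mask→discard order is the default; a flag flips it for sensitivity
analysis. Recovery guarantees hold only when true templates are pairwise
*below* the clustering threshold; templates nearer than that merge by
design (the parameter-recovery experiments condition on separable
templates for exactly this reason).

## Selection (NG86 dN/dS)

Synonymous site fractions per codon count, over all nine single-base
changes, the fraction that preserve the amino acid; changes into stop
codons are never synonymous, so synonymous + nonsynonymous fractions sum
to 3 per codon. Substitutions between codons differing at several
positions are averaged over all orderings of the changes, excluding
orderings that pass through a stop codon unless none avoids one. Codons
containing a gap or `N` in either sequence, and stop codons, are excluded
pairwise. The proportions pS, pN are Jukes–Cantor corrected
(d = −¾·ln(1 − 4p/3), undefined at p ≥ ¾ and flagged). Zero
nonsynonymous divergence with nonzero synonymous divergence yields a
ratio of exactly 0 even when the correction of pS saturates (single-codon
toy cases). Region summaries report both the ratio of mean dN to mean dS
(headline, robust to dS = 0 pairs) and the mean of per-pair ratios,
because "average across codons" admits either reading. Classification:
<1 purifying, within 0.05 of 1 neutral, >1 positive.

## Trees

Neighbor joining (scikit-bio) on p-distances (1 − identity/100), with
negative branch estimates clamped to zero. Midpoint rooting places the
root halfway along the longest leaf-to-leaf path (a 2-leaf tree is
handled directly; scikit-bio degenerates there). Monophyly is an edge
bipartition test. Bootstrap support resamples alignment columns with
replacement, rebuilds NJ per replicate, and reports the fraction of
replicates containing each original bipartition; the generator is seeded
and replicate-order deterministic. Maximum-likelihood inference is out of
scope: every grouping claim here is distance-based.

## Synthetic-data generator

The generator emulates the study regime end to end and is the ground
truth for every recovery test:

| parameter | default | meaning |
| --- | --- | --- |
| `repeat_len_nt` | 612 | repeat unit (204 aa) |
| `n_repeats` | 20 | units in the array |
| `n_term_len`, `c_term_len` | 510, 330 | terminal coding spans (nt) |
| `last_repeat_len_nt` | none | optional truncated final unit (558 for the study-scale replay) |
| `n_loci`, `ploidy` | 4, 2 | gene copies per diploid genome |
| `mutation_rate` | 1e-4 | per base per generation (repeat region) |
| `terminal_rate_multiplier` | 5 | terminals diverge faster than conversion-homogenized repeats |
| `conversion_rate` | 1 | whole-unit conversion events per sequence per generation |
| `n_generations` | 200 | evolution span |
| `synonymous_bias` | 0 | fraction of mutations redirected to synonymous changes |
| `pcr_error_rate` | 5e-4 | per base per clone |
| `clones_per_template` | 6 | amplicons sequenced per true template |

Genes are built as ATG + random sense codons (repeat codons skewed
toward serine/alanine/glycine) + tandem-duplicated unit + stop. Gene
conversion is whole-unit copy-paste between random repeat pairs within
one sequence — the simplest mechanism producing intragenic
homogenization; terminals never convert (they have no repeat partner).
Mutation rates are not inferred from data: they are set to reproduce the
qualitative identity regimes (>98% within a gene, terminals several-fold
more divergent) and are documented as illustrative. All randomness flows
through seeded numpy generators; identical parameters give identical
output.

**Junction identifiability.** The two terminal codons flanking the array
are constrained to share ≤1 position with the codon that would continue
the repeat consensus. Without this, a terminal codon can mimic the
array's continuation by chance (~1/61 per codon) and the true boundary
becomes unknowable from the sequence itself, making exact
boundary-recovery checks ill-posed. This is consistent with the
terminals being unique, non-repetitive sequence.

**What the generator does not model** — and hence what passing tests do
not certify on real data: indels and microsatellite slippage inside
repeats, tract-length (partial-unit) gene conversion, selection beyond
the synonymous-bias knob, PCR chimera formation (only a fixed toy
chimera is tested), base-calling error structure, and between-locus
recombination. Real amplicon surveys also sample templates unevenly;
clone counts here are uniform per template.

## Scale of the shipped experiments

The test suite and the acceptance script run entirely on generated data
at the sizes stated in each experiment: 1,000 random pairs for the
aligner oracle, 100 random additive trees for NJ, 400 two-codon pairs
for the NG86 oracle, 50 seeded simulations for variant
precision/recall, 30 matched pairs for the conversion sign test, 100
clone sets for masking soundness, and a single study-scale gene replay
(20 × 612 nt). These sizes give stable statistics in seconds on one CPU.
The checks that replay the published numbers on the deposited GenBank
records run only after `scripts/fetch_reference_data.py` has populated
`data/reference/` (network required once); the per-region variant
grouping and the four-species consensus-repeat file additionally need
manual curation from the published supplementary tables, since region
assignments are not encoded in the sequence records.

## Known limitations

- The center-star aligner is tuned for high-identity sets; for deeply
  diverged proteins a dedicated MSA tool would be preferable, and the
  cross-species conservation numbers carry an aligner-dependent
  tolerance.
- NG86 is a counting estimator; model-based codon methods will differ
  slightly, which is why region dN/dS targets carry an explicit
  tolerance and the regime ordering is the robust claim.
- Clustering merges indel-only variants (identical-sites metric) and any
  templates above the 95% threshold; the minimum-locus count is thereby
  conservative, never inflated.
- Boundary recovery is exact only when junctions are identifiable; on
  real data a terminal codon that happens to extend the repeat consensus
  is indistinguishable from one more repeat codon.
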