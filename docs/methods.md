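# Methods

## The model

L1 amplification is modelled as a *master lineage*: a chain of families
F_0 (oldest) ... F_{n-1} (youngest) in which each progenitor derives from
its parent by neutral substitutions accumulated over the inter-family time
gap.  Neutral evolution is Jukes-Cantor with per-lineage rate *r*
(substitutions/site/MY): a branch of duration t substitutes each site with
probability 3/4·(1 − e^(−4rt/3)), the new base uniform over the other
three.  Two copies deposited at family age t therefore show an expected
model-corrected divergence of 2·r·t.

Superimposed on the chain are the processes that diversify real L1:

* **Promoter replacement** — the 5'UTR of a family is spliced out and
  replaced by another library promoter.  Promoters are fixed-length
  (600 bp: two tandem 200 bp monomers plus a tail) so element coordinates
  are shared across families.
* **Recombination** — a recipient family's progenitor becomes
  donor[0:b) + recipient[b:), i.e. a chronologically young element
  retains its own 3' end and recruits an older 5' terminus.  If the
  breakpoint lies 3' of the promoter the recipient also acquires the
  donor's promoter type, which is how promoter transfer between families
  happens mechanistically.
* **Lateral introduction** — a family flagged lateral receives extra stem
  divergence *after* the chain is built, i.e. it becomes a side branch
  whose descendants on the chain are unaffected; this is the signature of
  a family acquired by inter-specific hybridisation (a long stem with no
  intermediate sequences), as opposed to drift inherited by the whole
  subsequent lineage.
* **Copy deposition** — each family deposits copies at its activity time;
  each copy evolves independently for its age and is 5'-truncated with
  probability `truncation_prob` at a uniform offset (the field reports no
  truncation-length law; uniform is the simplest falsifiable choice).
  Copies overwrite background sequence (i.i.d. with configurable GC) at
  non-overlapping loci.

Element layout (bp): 600 promoter, 1,218 ORF1 (LPR at offset 300: two
66 bp units encoding ideal heptads), 43 spacer, 3,834 ORF2 (endonuclease
codons 10-240, reverse transcriptase codons 500-731), 652 3'UTR containing
a 30 bp polypurine tract.  ORF1 therefore spans alignment positions 1-1218
and ORF2 starts at 1262 when alignments are anchored at ORF1, matching the
coordinate frame used for mouse L1 consensus alignments.

Under `preserve_orfs` (default), substitutions that would create a
premature stop are redirected and the start/stop codons are immutable:
progenitors are replication-competent by definition, and keeping copy ORFs
open makes the simulator's full-length flag match an ORF-intactness
definition of full length.  This is a deliberate idealisation — real old
copies accumulate stops — appropriate because the mining stage is scored
on 5'-truncation status, not on decay.

### Default study conditions

Six families at activity times (9.2, 6.4, 4.6, 2.2, 1.2, 0.25) MY echoing
the span of the recently active mouse families; promoter chain
Lx → Fanc → F → F → A → A; r = 0.009093/site/MY so that pairwise
divergence/age = 1.8186 %/MY, the constant implied by the published family
table (see *Ages*); 25 copies per family in a 3 Mb genome; truncation
probability 0.4.  These defaults are the conditions under which the
package's recovery statistics (mining ≥ 0.95 recall/precision, family ARI
≥ 0.95) are asserted.

## Mining

The RT protein is searched against all six reading frames with exact 5-aa
seeds, seeds clustered along the target, and the modal diagonal of each
cluster extended as an ungapped BLOSUM62 maximal-scoring segment (Kadane
scan).  Matches above score/coverage thresholds are merged within 500 bp
and a 14 kb window is cut around the RT midpoint (reverse-strand hits are
reverse-complemented so windows are element-oriented).  Window annotation
is anchored: RT is located near the window centre, the endonuclease domain
upstream of it, the ORF2 span by in-frame expansion to the nearest ATG and
stop, ORF1 immediately upstream of ORF2 (gap ≤ 300 bp), the 3'UTR
immediately downstream of ORF2, and up to 3,000 bp upstream of ORF1 is the
5' region.  Anchoring matters: a 14 kb window can contain a second planted
element, and unanchored best-hit matching stitches chimeric annotations.

Full length requires intact ORF1 (ATG, no internal stop, ≥ 1,100 bp) and
ORF2 (≥ 3,700 bp), a 3'UTR match, and — when a promoter library is
supplied — a promoter match ending at ORF1 whose own first 100 bp align at
the match start (without the head check, the missing prefix of a
promoter-truncated copy aligns cheaply to genomic background and inflates
identity).  Intactness thresholds allow ~10% slack below the canonical
1,218/3,835 bp lengths.

## Family classification

5' regions are typed by local alignment (match +1, mismatch −1, gap
−4/−1) against the promoter library: assignment needs ≥ 80% identity over
≥ 200 aligned bases; an edlib prescreen ranks candidates so the exact
aligner runs only on the top two.  Unassigned regions are clustered by
single linkage on edlib edit distance at 85% identity; clusters of ≥ 10
become novel types.

Families are defined per promoter group on the 3' terminus (last 500 bp of
ORF2 + 3'UTR): NJ + bootstrap, cut every internal edge with support ≥ 70%
whose smaller side has ≥ 4 leaves, and star-validate each component.  The
star statistic is Σ(internal branch lengths)/Σ(all branch lengths); a
component passes when the statistic ≤ 0.10 and no internal edge with ≥ 4
leaves a side has support ≥ 70%.  The minimum-clade rule exists because
two copies sharing a couple of coincident substitutions form
chance-supported cherries in star families; clusters that small were also
below the copy-number floor used for consensus building.  Validated
families are re-checked on ORF1 and split if supported structure appears
there.  Consensus is per-column plurality (gap-majority columns dropped,
ties broken A<C<G<T), and names are promoter type + Roman numeral in
increasing age order, ties broken toward larger families.

## Phylogenetics

Distances use pairwise deletion and the standard closed forms (JC, K2P,
TN93 with empirical base frequencies); saturated pairs are flagged, not
silently clamped.  Neighbor joining is Saitou-Nei with the Q criterion,
deterministic tie-breaking on label pairs, and negative branch lengths
clamped to zero.  Bootstrap support is the percentage of column-resampled
replicate trees containing each bipartition.  Promoter-replacement counts
use Hartigan's generalisation of Fitch parsimony, exact on the basal
trifurcation.  The test suite cross-checks NJ against scikit-bio and
against exhaustive minimum-evolution (OLS branch lengths over all 945
seven-taxon topologies).

## Recombination

MaxChi slides a split point along the comparable columns of a pair and
scores the 2x2 match/mismatch table of 50 bp flanking windows (windows
truncate, never below 10 sites, near alignment edges so terminal
breakpoints remain detectable); significance of the maximum is assessed by
permuting column order (1,000 draws by default, vectorised) *and* by the
analytic chi-square tail Bonferroni-corrected over split positions.  The
Chimaera-like variant restricts to informative sites where a candidate
recombinant matches exactly one of two putative parents; run over all
(recombinant, parent-pair) triplets — with a further Bonferroni over
triplets — it is the primary event caller.  An event also needs flank
dominance by different parents (≥ 0.7 / ≤ 0.3) and both transferred
segments ≥ 300 bp (the stringent large-segment rule).  Bootscan (windowed
bootstrap NJ sister-tracking) corroborates events when enabled.

Verification compares bootstrap NJ trees of the two flanks: verified
means the recipient's smallest supported (≥ 70%) containing clade differs
between flanks.  Full flanks are used even though they can span other
breakpoints in multi-event histories: restricting to the segments
delimited by neighbouring breakpoints leaves too few informative sites for
supported placements, and the criterion only inspects the recipient's own
placement, which tolerates heterogeneity elsewhere (`verify_breakpoint`
accepts explicit bounds for callers who want segment-local trees).  The informative-site
pattern cannot orient recombinant vs parent, so events are oriented by
family age when ages are available (the younger family is the recipient)
and re-verified in the swapped orientation otherwise.  One recombination
surfaces in several triplets and in descendants of the recipient;
`consolidate_events` clusters verified breakpoints (gap 150 bp) to report
the minimum number of distinct events.  Verified breakpoints split the
alignment into recombination-free segments for the tree and selection
stages.

## Selection

Nei-Gojobori counting over all consensus pairs: per-codon opportunity
excludes mutations to stops from the denominator (so S + N = 3 per
countable codon), differences average over stop-avoiding shortest
pathways with equal weights, proportions are Jukes-Cantor corrected, and
the SE is a delete-one-codon jackknife.  A dataset with no synonymous
signal is flagged undefined rather than infinite.  Per-site classes come
from a two-sided binomial test of each codon's nonsynonymous difference
fraction against its opportunity fraction, Benjamini-Hochberg controlled
at 0.05.  Regions follow the ORF1 partition (5' terminus / coiled coil /
3' terminus, the coiled-coil bounds taken from the median predicted span)
and the ORF2 split at codon 1,171, each intersected with the
recombination-free segments; intersections under 30 codons are skipped.

Limitations: pooled pair counts share ancestry, so site tests are mildly
pseudo-replicated and a few false-positive sites can appear even on
neutral data — the analogous single-method site hits in likelihood
analyses of real L1 are treated as false positives too.  The counting
estimator reproduces the qualitative selection pattern, not
likelihood-method dN/dS values.

## ORF1 structure

The LPR is located by aligning conserved ORF1 flanks, then decomposed
left-to-right: each canonical unit (the ancestral 66 bp and 42 bp units)
is prefix-aligned to the remainder, the best unit above 60% identity is
consumed, and the unit is labelled by the length it occupies — so internal
deletions surface as 45 (= 66 − 21) or 56 bp units without being
pre-declared; consumed lengths within 2 bp of the canonical length snap to
it (a boundary substitution can shift the alignment end by a base or two,
whereas real deletion variants differ by ≥ 10 bp).  Unit-structure
histories are reconstructed by Sankoff parsimony over the observed
structures with unit-level edit cost (insertion/deletion/length change
each 1), verified exhaustive on small trees.

Coiled coils are scored by heptad periodicity: each window (21 aa) is
scored under all 7 register phases as mean normalised Kyte-Doolittle
hydropathy at registers a/d minus the mean elsewhere, rescaled to [0,1];
a residue takes the best score of any covering window, the longest run
≥ 0.70 is the span, and heptads = span//7.  This reproduces ideal-heptad
constructions exactly; on real proteins a ±1 heptad tolerance is
appropriate since the propensity table is a single hydropathy scale, not
a full coiled-coil profile matrix.

## Ages

The 3'UTR alignment is masked at consensus CpG dinucleotides (both
columns) and at every maximal consensus purine run ≥ 9 bp (the polypurine
tract); divergence is the mean pairwise model distance in percent with a
1,000-replicate column-bootstrap SE.  Age = divergence × 0.55 MY/%, the
conversion that reproduces all 29 printed (divergence → age) pairs of the
published mouse family table to 2 decimals with half-up rounding; the
naive reading of the stated neutral rate ("1.1%/MY", i.e. divide by
2 × 1.1 → 0.4545) contradicts every printed age, so the calibrated factor
is the default and the discrepancy is logged when a non-default factor is
supplied.  The interval is ±1 SE mapped through the same factor — one
standard error, not a 95% CI, hence the ~2/3 expected coverage.

Lateral transfer: on the K2P NJ tree of genomic copies, each family's stem
is the branch above its largest member-only clade; a family is flagged
when its stem exceeds the 99th percentile of stems simulated under pure
vertical descent with matched activity times, rate and copy number.  Nulls
are matched by age rank because basal families legitimately carry longer
stems than nested young ones.

## Numerical and reproducibility choices

All randomness flows from explicit seeds (numpy Generator); simulation
output is byte-identical under a fixed seed, and the pipeline's TSV
outputs are byte-identical across reruns.  NJ ties, consensus ties and
naming ties all have deterministic rules, so results are invariant to
input order.  Problem sizes in the test suite and acceptance script (3 Mb
default genome, progenitor-level recombination scans, 60-100 replicate
calibrations, 100-replicate breakpoint trials) were chosen to exercise
each claim at meaningful statistical resolution on a single CPU.

What passing on simulations does not show: the simulator has no indels,
no target-site duplications or poly-A tails, no CpG hypermutation (the
real analysis masks CpG instead), rigid element coordinates, and
ORF-preserving neutral evolution.  Mining and classification accuracy on
real genomes — with nested/fragmented repeats, indel-riddled old copies
and RepeatMasker-style library ambiguity — will be lower than the
simulated recovery statistics.
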