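# Methods

This note documents the models and procedures `teeco` implements, the
parameters that matter, the design choices made where conventions diverge,
and what the synthetic-data tests do and do not demonstrate.

## Coordinates and input handling

Internally every genomic interval is 0-based half-open. RepeatMasker `.out`
and GFF3 coordinates (1-based inclusive) are converted once, on read.
Consensus coordinates stay 1-based inclusive as in the `.out` format, but the
minus-strand column order ("(left) end begin") is normalised on read so that
`cons_start <= cons_end` always holds; downstream conjoining logic relies on
this.

Overlapping repeat annotations are resolved in favour of the longer element;
the loser is removed whole, never truncated, because truncation would
fabricate coordinates that no aligner produced. Ties go to the lower
divergence (the better-supported copy), then the smaller start. The procedure
is greedy from longest to shortest, which makes it idempotent and
order-independent.

## Divergence

`kimura_cpg_divergence` implements the Kimura two-parameter distance
K = −½·ln((1−2p−q)·√(1−2q)) over comparable sites (both bases in A/C/G/T;
gaps and ambiguities excluded). The CpG adjustment follows the standard
repeat-annotation convention: consensus CpG dinucleotides are hypermutable,
so a transition at either CpG position counts 1/10 of a transition, and
transitions at both positions of one CpG count as a single full transition.
Transversions are never down-weighted. The correction is a flag
(`cpg_correction=False` gives textbook K2P). Saturated alignments
(1−2p−q ≤ 0 or 1−2q ≤ 0) raise rather than return a number.

Landscape profiles bin each element's genomic length by the divergence value
carried in its annotation (recomputation from sequence is available but not
required), into half-open bins of 1% width over [0, 60] plus an overflow
bin, so per-class occupancy is conserved exactly.

## DNA loss

k = ln(A/E)/t from E = A·e^(−kt). A and t are plain arguments (the
murid/cricetid comparison conventionally uses A = 2.8 Gb, t = 100 My). Two
readings of "extant ancestral DNA" are implemented: *conventional*
(assembly size minus lineage-specific TE bp) and *literal* (ancient-TE bp
minus lineage-specific TE bp). The literal difference can be negative in
TE-expansive lineages, so the conventional reading is the default and both
are logged. Which subtraction a given published k used cannot generally be
recovered from the printed value alone; the switch makes the choice explicit.

## ERV structure

LTR pairs are sought by local alignment (match +1, mismatch −1, gap −2)
between the element's first and last `min(2 kb, len/3)` windows; a pair is
reported when the alignment spans ≥ 100 columns at ≥ 80% identity. Identity
of the aligned columns estimates insertion age (LTRs are identical at
insertion). On constructed elements with a planted substitution rate d ≤ 10%
the recovered identity is within 1 percentage point of 100−d; above ~12%
the optimal local alignment starts trimming and gapping around mismatch runs
and the estimate acquires a small upward bias — users dating very old
elements should treat identities near the 80% floor as qualitative.

Autonomy calls are deliberately conservative in the nonautonomous direction:
a subfamily is *nonautonomous* only when at least five full-length, gap-free
copies exist and none carries a qualifying ORF (an annotation label, or an
ORF of ≥ 200 codons found in its sequence); *autonomous* requires a
full-length copy with both gag and pro/pol labels; everything else is
*ambiguous*. Full length means the copy's span is within ±10% of the
consensus length and both consensus ends are reached to within 20 bp; these
tolerances are configurable because "full length" has no universal cutoff.
ORF-based machinery screening is restricted to LINEs > 2,700 bp and LTR
elements > 5,000 bp — shorter elements cannot encode complete machinery.
Whether both LTRs must be present for "full length" is left optional
(`--require-ltrs` semantics at call sites); the default uses the consensus
coverage criteria only.

## Interruption detection

The detector scans each chromosome for ordered runs
`LINE fragment A … (only ERV annotations) … LINE fragment B` where A and B
share subfamily and strand, the consensus gap
`cons_start(B) − cons_end(A) − 1` (mirrored on the minus strand) is within
`cons_gap_tol`, and the genomic interval between A and B is covered by the
intervening ERV annotations up to `genomic_gap_tol` unannotated bp per
junction run. Defaults are 100 bp of consensus tolerance and 50 bp per
junction: exact conjoining is too strict for real annotations, which carry
indels and boundary fuzz, while looser values begin to admit coincidental
same-subfamily neighbours. Both are exposed on the CLI. The ERV's own strand
is unconstrained (either orientation interrupts equally); the flanking
fragments must match each other.

Strict mode reproduces a conservative census: exactly two fragments, nothing
but ERV sequence between them, and a united consensus span > 5,000 bp (a
full-length reconstruction). Chains of more than two fragments are excluded
outright in strict mode and reported as single multi-fragment calls (possibly
`fragmented`, i.e. short) in relaxed mode, so relaxed counts are a superset.

The per-subfamily enrichment statistic drops the full-length requirement: an
ERV element counts when it lies wholly within a gap flanked by same-subfamily
same-strand LINE fragments with nothing but ERVs between them (consensus
conjoining of the flanks is optional and off by default; both variants are
exposed because a census question and an insertion-bias question need not
share the stricter filter). The null re-places the focal subfamily's
elements uniformly per chromosome, lengths preserved, all other annotations
fixed. Shuffled elements may overlap fixed annotations — the null models
unconstrained insertion, and masking is available via assembly-gap intervals
when a layout carries them.

## Permutation machinery

One randomizer serves every permutation test: uniform per-chromosome
re-placement preserving element lengths and counts. p = (r+1)/(n_perm+1)
with r the number of null statistics ≥ observed, so finite runs never report
p = 0; Bonferroni converts p to q across subfamilies. Child RNG streams are
derived by hashing (seed, unit name), making per-subfamily results
independent of input order and of which other subfamilies are present.
Fisher's exact test (two-sided, probability-mass rule) and Mann–Whitney U
(enumeration over pooled-midrank splits for n ≤ 20, tie-corrected normal
approximation above) come from scipy except for the small-sample MWU branch,
which is enumerated in-package because scipy's exact method refuses ties.

## Distribution analyses

Upstream regions are the 5-kb window on the 5' (transcription-start) side of
each gene, clipped at chromosome edges and deliberately not merged across
genes; the enrichment count is the number of subfamily elements on the
gene's strand intersecting at least one such region. The Fisher variant
compares observed vs rounded expected counts in/out of regions (the
permutation p is always reported alongside, since rounding a small expected
count is crude). The segmental-duplication confound check measures SD
coverage inside the upstream regions of genes that actually harbor an
element of the enriched subfamily, against per-chromosome re-placement of
the SD intervals; a flagged subfamily's upstream signal may be
duplication-driven.

Hotspots: non-overlapping 100-kb windows (the trailing partial window is
normalised by its true length); density = ERV-covered bp / window length;
a window is a hotspot when its density reaches the linear-interpolated 95th
percentile of all window densities and is positive. Ties at the threshold
are all flagged; on an all-equal (degenerate) density vector every non-empty
window is therefore a hotspot, which is documented behaviour rather than a
target of inference. Whether "ERV density" means all ERVs or
lineage-specific ERVs only differs between uses in the field, so the element
filter is a parameter rather than fixed.

Neighbor delta-divergence compares |div(i) − div(i+1)| of consecutive ERVs
between pairs lying wholly inside hotspot windows and pairs wholly outside
(mixed pairs dropped): duplication-formed hotspots give near-zero deltas,
independent insertion gives deltas comparable to the genome background.

The gene-density/ERV-density association is fitted by ordinary least squares
on the window densities by default (a binomial-logit GLM is available); the
contract is the coefficient's sign and p-value, not the link function.

## KZNF ages

Nearest-duplicate divergence takes a symmetric pairwise divergence matrix as
input (computing the matrix, i.e. aligning paralogs, is out of scope); per
gene the minimal off-diagonal entry defines the nearest duplicate, with ties
broken toward the lexicographically smaller partner. Ages are compared per
gene by default; `dedupe_pairs` collapses mutual pairs to one record for the
pair-level view. "In hotspot" means the gene interval intersects a hotspot
window by ≥ 1 bp. KDE peaks use a Gaussian kernel with Scott's bandwidth on
a 0.1-grid over [0, max + 3·bandwidth]; near-equal maxima resolve to the
lower location, and degenerate (zero-variance) groups peak at their value.

## Synthetic data

The generator plants, on a configurable multi-chromosome layout: background
TE copies per subfamily (uniform placement, divergence drawn once per copy
from a per-subfamily normal, consensus coordinates consistent with copy
length); ERV-interrupted LINEs whose fragments conjoin exactly (consensus
gap 0, united span = host consensus length > 5 kb); hotspot windows filled
to a target density by independent insertion or by segmental duplication
(shared divergence ± 0.05 jitter); a strand-aware upstream insertion bias
for one subfamily at a configured multiple of its uniform expectation
(capped at placing all copies, so the realised excess can sit below the
nominal factor — the truth manifest records both); KZNF clusters, alternating
into and out of hotspot windows, whose paired duplicate divergences come
from group-specific normals; ordinary genes that avoid hotspot windows
(hotspots largely devoid of genes, hence a negative gene–ERV density
dependence); and uniform SD intervals. Everything planted is recorded in a
truth manifest, and identical seeds give byte-identical files.

Two placement regimes exist by design. Structured genomes
(`rodentlike_config`, `planted_interruption_config`, `sd_hotspot_config`,
`kznf_shift_config`) rejection-sample TEs to be overlap-free, since the
detectors consume overlap-resolved annotations. Calibration genomes
(`calibration_config`) place TEs with overlaps allowed, which makes the
generating process *exactly* the uniform per-chromosome null the permutation
tests randomize against — the right regime for checking p-value uniformity.
Calibration uses 20 ERV subfamilies of 750 copies on a 3-Mb genome so the
null count statistics are wide; permutation p-values of discrete counts are
intrinsically slightly conservative (ties between observed and null inflate
p by roughly the statistic's maximum point mass, ~0.4/√λ for a count with
mean λ), and wide nulls keep that bias well inside the Kolmogorov–Smirnov
tolerance used by the calibration tests.

What the synthetic tests show: the detectors and tests recover exactly what
was planted, produce calibrated p-values under their own null, and are
deterministic. What they do not show: robustness to fragmented and nested
real-world annotations beyond the planted structure, to reference assembly
gaps, to divergence values estimated from noisy alignments, or to the
annotation-quality artefacts (chimeric models, boundary errors) that real
RepeatMasker output contains. Tolerances (`cons_gap_tol`, `genomic_gap_tol`,
full-length margins) are exposed precisely because real data will need them
re-examined.

## Problem sizes and numerical choices

The bundled study conditions are: planted-recovery genome 10 Mb / 5
chromosomes / ~5,000 annotations / 50 interruptions; calibration 10 replicate
3-Mb genomes × 20 subfamilies (200 subfamily-replicates) at 500 permutations;
planted upstream excess 10× at 1,000 permutations; hotspot and KZNF power
sweeps over 100 seeds of 10-Mb genomes. These sizes make the full test suite
and the acceptance script run in about a minute each on one CPU while keeping
every statistic comfortably powered. Floating-point contracts: the
loss-coefficient inversion holds to 1e-12; divergence agrees with a per-site
oracle to 1e-9; Fisher p-values agree with exact enumeration to 1e-11.
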