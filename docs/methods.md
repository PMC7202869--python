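# Methods

## Scope and coordinate conventions

The package implements the inference chain for one class of structural
event: a multi-kilobase genomic block amplified as direct head-to-tail
repeats on one chromosome, with downstream consequences — a
promoter-exchange fusion gene at the copy junctions, dosage changes in the
genes inside the block, pseudogenizing indels in some copies, nested
transposable-element (TE) insertions, and a later translocation of a
sub-amplicon to another scaffold.

All internal coordinates are 0-based half-open; every parsed or printed
coordinate (GFF3, SAM POS, breakpoint reports) is 1-based inclusive and is
converted exactly once at the I/O boundary. A tandem unit is stored as
[s, e); its two printed breakpoints are s+1 (first base of the unit) and
e+1 (first base after it), so the printed difference equals the unit length
— the convention that makes a printed pair like 445,716 / 770,265 imply a
324,549-bp unit with no off-by-one.

Only the SAM-text subset the evidence needs is supported: CIGAR ops
M/I/D/S, soft clips terminal only; N/H/P/X/= are rejected rather than
reinterpreted. BAM, compressed and indexed formats are out of scope.

## The simulator and what it does (not) emulate

`simgen` builds the diploid sample genome explicitly: one haplotype carries
`copies_per_genome − 1` unit copies head-to-tail (the other keeps the
baseline single copy), with TEs and indel variants placed per copy and an
optional amplicon copy inserted into a second scaffold. A liftover map
(blocks tiling the sample genome, each a reference image or novel sequence)
is the single source of truth for read projection.

Reads are drawn uniformly (fixed length, error-free by default) and
projected to reference coordinates through the liftover: maximal
reference-colinear runs are assembled (reference gaps ≤ 50 nt become D ops,
small bridged novel pieces become I ops), the run with the most matched
bases anchors the read, and everything outside it is soft-clipped — so
clipped bases always equal the partner-locus (or TE) sequence exactly.
`depth` is the expected coverage of a single-copy reference position summed
over both haplotypes; a position inside a c-copy unit therefore receives
about (c/2)·depth. RNA reads are drawn from transcripts defined as chains
of reference exon pieces; a backward jump in a chain (the tandem junction
in the chimeric transcript) projects to a soft clip, and a ≤ 50 nt gap (an
exonic micro-deletion) to a D op. Intron-sized gaps split the alignment
into an anchored part plus a clip because spliced (N) alignments are not
modelled.

Deliberately not emulated: sequencing errors (an option exists but the
default is 0), quality strings, insert-size/fragment models, GC and
mappability bias, mapping ambiguity (reads are emitted pre-aligned, never
passed through an external mapper). Passing tests therefore demonstrate
correctness of the inference logic under clean evidence, not robustness to
real-library noise; the statistical stages (binomial window test, ΔΔCT,
probit, ANOVA) do face simulated noise at realistic magnitudes.

qPCR Ct values follow Ct = base − log2(level) + N(0, sd) with base 20
(arbitrary; only differences matter) and sd 0.15 by default. Dose–mortality
counts are Binomial(n, p) with probit(p′) = slope·(log10 d − log10 LC50)
and p = c + (1 − c)p′. DE tables mark planned core genes significant with a
fixed sign in every pairwise comparison and background genes significant in
a random ~30% of tables, so the expected number of background genes
surviving a 36-way consistent intersection is ~N·0.3³⁶ ≈ 0.

## Copy-ratio scan

Windows default to 10 kb with 5 kb step (the ~325-kb scale unit is then
resolved by > 30 windows); reads count in the window containing their
leftmost mapped base. Significance is an exact two-sided binomial test of
the window's test-count share against the library-size share — exact at
these counts, rather than a Gaussian ratio approximation. BH adjustment is
computed across all windows of the scan before segment calling. Ratios are
re-centred on the scan's median window ratio (raw value retained): with an
amplified block that is a non-negligible fraction of one library,
total-count normalisation alone shifts every window, and the median window
is a copy-neutral anchor whenever most of the scaffold is copy-neutral.
Segments are maximal runs with log2 ratio ≥ 0.5 and q ≤ 0.05, with runs
separated by ≤ `max_gap` failing windows merged.

## Breakpoint clustering and linking

Terminal soft clips ≥ 10 nt cluster when their positions agree within 3 nt;
the consensus is a column-wise majority (ties → N, and N never counts as a
match). The junction-proximal 15-mer of the consensus seeds an exact search
over the reference; ungapped extension scores identity over the full
consensus and a junction is emitted only at identity ≥ 0.9 — a hard
guarantee, random 25-mers against a 100-kb reference essentially never link
(expected seed-hit rate ≈ L·4⁻¹⁵). Head-to-tail same-scaffold linkage
classifies as a tandem duplication, another scaffold as an interscaffold
insertion; inversions are deliberately unresolved (recorded limitation).

A cluster's `n_crossing` counts every read whose extent — aligned span plus
clipped tails — crosses the junction. Because the aligner-like projection
anchors each junction read at the breakpoint holding the *majority* of its
bases, the reads of one junction divide between the two reciprocal
clusters; the per-cluster clip fraction is therefore roughly half the naive
(c−2)/c one might expect from copy counting, and the tests validate cluster
counts against a truth-geometry oracle rather than that approximation. The
same geometry applies to the minority (translocated-copy) breakpoint: with
one translocated copy against eight natives the truthful copy share is 1/9
and the measured per-cluster clip fraction is ~4%.

Defaults (min_clip 10, cluster_tol 3, min_seed 15, min_identity 0.9,
minority min_fraction 0.03) are declared choices: no read-support or
clip-length thresholds are inherited from elsewhere; they are set so a
5–12%-class secondary breakpoint is detectable while random linkage stays
improbable.

## Fusion prediction and junction tally

A fusion is predicted only when exactly one gene straddles each breakpoint,
both on the same strand, in the orientation for which the promoter-donor
fragment is transcriptionally upstream across the junction. Since the
junction concatenates unit-end sequence upstream of unit-start sequence
(reading the forward strand), the containment pattern "promoter + leading
exons of the start-straddling gene inside the unit" is only
transcription-compatible on the minus strand; a plus-strand pair with exon
material inside on both sides raises `orientation-incompatible` instead of
mispredicting. "Inside the breakpoint" means strict containment of the
whole exon interval in the half-open unit, which makes boundary cases
deterministic. Protein consequences are summed from a coding-residue
annotation (residues of the body donor's excluded exons lost, residues of
the promoter donor's retained exons gained); nothing is translated and no
domain prediction is attempted.

The read tally counts a read as chimeric when it is anchored with ≥ 10
matched bases on one side of the junction and its clip matches the partner
side sequence, and as wild-type when it crosses a breakpoint position with
≥ 10 matched bases on both sides and no clip; everything else is ignored,
so ordinary splice-junction clips elsewhere in either gene cannot
contaminate the tally.

## ΔΔCT, fate classification and loss-of-function evidence

ΔCt = Ct(target) − mean(Ct of housekeepers) — the arithmetic mean of Cts is
the geometric mean of the corresponding relative quantities. Replicates are
paired by replicate id when target and housekeepers share ids (variance of
the paired differences); otherwise variances propagate across unpaired
means with a Welch–Satterthwaite df. fold = E^(−ΔΔCT) with amplification
efficiency fixed at 2.0 unless supplied; 95% limits are t-based on ΔΔCT
(bootstrap was the other candidate; t on ΔΔCT is the standard default and
reproduces the intended n = 4 error bars).

Fate verdicts depend only on ρ = expression fold / copy fold:
ρ ≤ 0.9 decayed, ρ ≥ 1.5 hyper-expressed, else dosage-proportional. The two
empirical groups the classifier must separate sit at ρ ≈ 0.6–0.8 and
ρ ≥ 3.7; 0.9 splits the low group from exact dosage (ρ = 1) with margin on
both sides, and both thresholds are exposed. The copy fold used for
concordance is the qPCR fold (read-depth fold is a cross-check only).

Variant read fractions demand the exact described indel in the CIGAR at the
site, with ≥ 5 aligned bases on each side to count as informative; the
Wilson 95% interval is attached (clamped to exactly 0/1 at the k = 0/k = n
boundaries where the analytic bounds are exact). The NMD test is one-sided
(H1: RNA fraction < DNA fraction): Fisher's exact test when any table cell
is < 10, the pooled two-proportion normal approximation otherwise.

## Event ordering

Five local rules (see the `teorder` module docstring) map per-copy element
presence/absence to precedence edges, each edge carrying its justification
code. The rules are sound but deliberately incomplete: ambiguous
configurations (e.g. an element in every native copy but absent from the
translocated one) produce no edge. Elements are never ordered directly
against each other — any inter-element order in the displayed linearization
is lexicographic tie-breaking only, and the exhaustive linear-extension
oracle in the tests confirms which orderings the constraints actually
force (e.g. an element constrained only to postdate the duplication may
legitimately linearize after later events). Presence calling from long
reads is reduced to interval containment upstream and is consumed here as
given labels; no mechanism (NAHR vs alternative transposition) is asserted.

## Endpoint statistics

The consistent-DE core set requires q ≤ 0.05 (fold filter 0 by default,
exposed) with an identical fold-change sign in every comparison; genes
missing from any table are excluded and counted, never imputed. The
intersection is monotone in the q threshold.

ANOVA is the one-way fixed-effects F; Tukey HSD uses the studentized-range
quantile on the pooled within-group mean square, and compact letters are
assigned by insert-and-absorb over groups ordered by descending mean (ties
by name), making the display deterministic. The all-zero-variance,
equal-means degenerate case returns p = 1 and a single shared letter.

Probit fits mortality ~ Φ(α + β log10 dose) by IRLS (GLM, binomial family,
probit link, vial sizes as variance weights) after Abbott correction
(p − c)/(1 − c), applied only when pooled control mortality c > 0.
LC50 = 10^(−α/β); the 95% interval is the Fieller construction on the
fitted covariance and becomes infinite (flagged) when g = z²·var(β)/β² ≥ 1
or under complete separation; β ≤ 0 raises as a non-monotone response.

## The standard synthetic study and problem sizes

`scenario.run_end_to_end` wires everything to one configuration: a 1-Mb
focal scaffold with a 30-kb unit (the ~325-kb amplicon scaled ~10× so the
full study simulates in tens of seconds), 8 copies per diploid genome, 60×
DNA at 150-nt reads (~1M reads across test and comparator), RNA at 40
reads per unit expression level, a gene straddling each breakpoint (minus
strand, so the junction fuses them), four TEs downstream of the focal P450
(hAT in all copies; TTAA3 in a subset and the translocated copy; MULE in a
native subset only; Tc1 only in the translocated copy), a 6-bp start-codon
deletion on 2 of 8 kinase-gene copies with its transcript at ~1/8 of
wild-type level, a 5-kb amplicon around the P450 translocated into a second
scaffold, expression folds of 2.7/3.2/2.4 (dosage-decayed group) and
14.7/19.9/36.8 (hyper-expressed group) against a 4-fold copy gain, a
symbiont-titer design with a ~0.4-fold crash in the susceptible lineage
under nicotine and none in the adapted one, and a probit bioassay at
LC50 10, slope 2, five doses × five vials of 20. CNV calling in this
scenario uses 10-kb non-overlapping windows (unit boundaries are
grid-aligned by construction, so segment bounds are exact; with the 5-kb
default step, partial boundary windows can extend a called segment by one
window and dilute its mean ratio).

## Known limitations

- No spliced (N) alignments; RNA splice junctions appear as soft clips.
- Only head-to-tail and interscaffold junction classes; inversions and
  general breakend pairs are out of scope.
- Copies are unphased: which physical copy carries a variant is not called.
- The simulator's clean-evidence regime means error tolerance of consensus
  building and seeding is untested beyond the N-tie rule.
- The per-cluster clip fraction understates copy share by the anchoring
  split described above; consumers wanting copy share should use depth or
  qPCR folds.
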