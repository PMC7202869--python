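# hostshift

Inference chain for detecting and characterising a large direct tandem
segmental duplication from short-read evidence, built around the scenario of
a tobacco-adapted aphid lineage in which a ~325-kb block of a scaffold was
amplified head-to-tail, creating a chimeric fusion gene at the copy
junctions, amplifying a cluster of detoxification genes, and accumulating
loss-of-function mutations in gene copies that confer no benefit at elevated
dosage.

It is written for bioinformaticians who want a tested, self-contained
implementation of each step of that inference — plus a ground-truth
simulator, so every stage can be exercised on data with a known answer.

## What it computes

**Copy-ratio scan (`cnvscan`).** Reads are binned by leftmost mapped base
into sliding windows; each window's test/reference pair (x, y) with library
totals (X, Y) is scored by an exact two-sided binomial test of
x ~ Bin(x+y, X/(X+Y)) and the ratio log2((x/X)/(y/Y)), re-centred on the
scan's median window. Benjamini–Hochberg adjustment runs over the whole scan
and maximal passing runs merge into amplified segments.

**Breakpoint linking (`svlink`).** Reads with terminal soft clips ≥ 10 nt
cluster by clip position; each cluster's column-majority consensus is
located on the reference by exact 15-mer seeding plus ungapped extension
(identity ≥ 0.9). A reciprocally linked same-scaffold pair in head-to-tail
orientation is a direct tandem duplication; the unit is
[left cluster, right cluster) half-open, so the printed 1-based breakpoint
difference *is* the unit length. A minority-breakpoint scan reports
sub-majority clusters (default ≥ 3% of crossing reads) around a gene,
e.g. a translocated extra copy linking to another scaffold.

**Fusion transcripts (`fusion`).** At a tandem junction, unit-end sequence
is transcriptionally upstream of unit-start sequence. Junction-spanning RNA
reads tally as chimeric (anchored one side, clip matching the partner side)
or wild-type (contiguous match across the breakpoint); the fused gene model
is predicted from the annotation: promoter donor = gene straddling the unit
start with promoter and leading exons inside the unit, body donor = gene
straddling the unit end with trailing exons inside.

**Gene fate (`genefate`).** Relative quantities by the ΔΔCT method,
fold = E^(−ΔΔCT) with E = 2, normalised to the mean of two housekeeping
genes, t-based 95% limits. Each amplicon gene is classified by the
concordance ratio ρ = expression fold / copy fold: `decayed` (ρ ≤ 0.9),
`dosage_proportional`, or `hyper_expressed` (ρ ≥ 1.5). Exact indel read
fractions (Wilson 95% CI) in DNA vs RNA feed a one-sided depletion test for
nonsense-mediated decay.

**Event ordering (`teorder`).** Per-copy transposable-element
presence/absence (from long-read co-occurrence) is turned into precedence
constraints by five sound local rules (element in all copies → predates the
duplication; in a proper native subset → postdates it; …), transitively
reduced into an event DAG with a deterministic linearization.

**Endpoint statistics (`phenostats`).** k-way consistent differential
expression intersection; relative symbiont titer (symbiont gene vs two host
single-copy genes via ΔΔCT); one-way ANOVA with Tukey HSD compact letter
display; probit dose–response LC50 = 10^(−α/β) with Abbott control
correction and Fieller 95% limits.

**Simulator (`simgen`).** Builds reference + rearranged diploid genomes
from an explicit truth configuration (tandem copies, TE insertions,
per-copy indels, a translocated amplicon) and emits pre-aligned reads
through an exact liftover — a read crossing a novel junction is soft-clipped
with the clipped bases equal to the partner-locus sequence — plus Ct tables,
DE tables and binomial dose–mortality tables. Fully deterministic per seed.

## Worked example

```python
from hostshift import svlink

# printed 1-based breakpoints of the amplified block
junctions = svlink.junction_pair_from_breakpoints("16", 445_716, 770_265)
call = svlink.call_tandem_duplication(junctions)
print(call.unit_length)          # 324549  (= 770265 - 445716)
print(call.printed_breakpoints)  # (445716, 770265)
```

Running the full synthetic study (1-Mb focal scaffold, 30-kb unit, 8 copies
per diploid genome, 60× DNA):

```python
from hostshift import scenario
res = scenario.run_end_to_end(seed=1)
print(res.dup_call.printed_breakpoints)   # (300001, 330001) — exact recovery
print(res.dup_call.copy_fold)             # 4.17  (truth: 8 copies / 2 = 4)
print(res.tally.chimeric_fraction)        # 0.985 (fusion >> wild-type)
print(res.nmd_p)                          # 2.0e-4 (variant depleted in RNA)
print(res.event_dag.linearization)
# ('hAT', 'dup', 'MULE', 'TTAA3', 'transloc', 'Tc1')
```

The breakpoints come back at the exact simulated positions; the read-depth
segment implies a ~4-fold amplification matching the configured 8 copies
against a diploid baseline; ~98% of junction-informative RNA reads are
chimeric because the fusion transcript dominates the wild-type body donor;
the 6-bp deletion planted on 2 of 8 gene copies shows ~24% of DNA reads but
only ~8% of RNA reads, a significant depletion consistent with
nonsense-mediated decay; and the element-ordering DAG places the hAT
insertion before the duplication and Tc1/mariner after the translocation.

## Command line

`hostshift io validate`, `cnvscan`, `svlink`, `fusion`, `genefate`,
`teorder`, `core-de`, `titer`, `probit` — thin wrappers over the library
reading plain-text SAM/FASTA/GFF3/TSV and writing TSV/JSON, with all
printed coordinates 1-based inclusive.

See `docs/methods.md` for the model, parameter defaults and limitations.
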