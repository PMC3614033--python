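# Methods

## The problem and the method

When a mutator strain of budding yeast is evolved to grow in a
challenging condition, the clone that emerges carries far more
mutations than the handful that actually drive its phenotype.  Bulk
segregant analysis (BSA) separates the two classes with sex: the
evolved clone is backcrossed to its ancestor, the diploid is
sporulated, and the haploid spores are grown under the selective
condition.  An allele required for the selected phenotype ends up in
nearly every surviving spore, while a neutral allele is inherited by
about half of them.  Sequencing DNA pooled from the selected spores
turns this into a per-variant read fraction: causal alleles approach
fixation, hitchhikers hover near 50%.

`bsakit` implements the computational side of this design — variant-set
comparison, effect annotation, the pool-fraction classifier,
linked-pair hitchhiker screening, copy-number causality logic, and
Sanger-trace frequency estimation — together with a forward simulator
of the entire experiment so that every stage can be tested against
known ground truth.

## The classifier

A clone variant is called *putatively causal* when all three criteria
hold:

1. **de novo** — present in the evolved clone, absent from the
   ancestor reference set, and not already carried by the time-zero
   founder of the evolution (founder variants can segregate above
   threshold through linkage or background effects but are not
   products of the selection);
2. **functional** — a nonsynonymous coding change (missense, nonsense,
   frameshift, or in-frame indel) or a substitution within the
   promoter window, defined as ≤ 500 bp upstream of the coding start;
3. **enriched** — its mutant-read fraction in the selected pool is
   *strictly* greater than the threshold (default 0.9).

Pool fractions are held as exact rationals (`fractions.Fraction`), so a
variant at exactly 90% is reproducibly non-causal regardless of read
depth; a float comparison could flip such boundary cases.  Variants
covered by fewer than `min_depth` reads (default 10) are reported
uncallable rather than classified — a 9/10 fraction should not clear a
strict 90% rule on the strength of ten reads.

Two putative-causal calls on the same chromosome within a configurable
genetic-map radius (default 25 cM) are unlikely to both be causal; the
lower-fraction member of such a pair is flagged as a probable
hitchhiker carried by its neighbor, keeps its classification, and is
excluded from gene-level counts.  Exact fraction ties flag neither and
log a warning.  The radius is an artifact choice: the underlying
observation is qualitative (linked allele at lower frequency), and
25 cM keeps the flag conservative on a yeast-density map.

Gene-level summaries collapse multiple causal nucleotide changes in
one gene of one clone to a single mutation, so a clone with nine
causal rows across eight genes reports eight gene-level mutations.

## Variant annotation and nomenclature

Gene models are single-exon CDS intervals — adequate for budding
yeast, where the genes relevant to this analysis are intronless.  CDS
coordinates are 1-based in coding orientation; promoter coordinates
are negative with no zero (−1 is the base immediately upstream), and
the window is inclusive at −500.  Minus-strand variants are annotated
in coding orientation with complemented alleles, and annotation of a
minus-strand gene is tested to agree exactly with annotating the
reverse-complemented construct on the plus strand.

Names follow the compact convention of classical yeast genetics
reports: `703 G->T` (CDS substitution), `-379 G->A` (promoter),
`100_100delT` / `2494_2495insT` (indels), and `E235*`, `T2996S`,
`G227Vfs249` at the protein level.  For frameshifts the reported codon
is the *first amino acid actually changed* by the shifted frame (which
can be downstream of the indel when the shifted frame initially
re-encodes the same residues), and the terminal number is the codon at
which the new frame hits a stop.  The stop-scan translates the mutated
CDS plus up to 300 bp of downstream genomic sequence; if no stop
appears in that range the name ends `fs?` and the class remains
frameshift.  A parser inverts the nucleotide-level names exactly,
which is verified by a 1,000-case round-trip test.

Choices where the convention is silent: a variant inside one gene's
CDS and another gene's promoter belongs to the CDS gene (ties broken
by nearest coding start); stop-loss substitutions are classed as
missense; in-frame indels get their own class (`inframe_indel`) and
count as protein-altering for the classifier.

## The simulator

The generator emulates the experiment end to end, with defaults set to
the study conditions the pipeline targets:

| parameter | default | why |
|---|---|---|
| chromosomes | 16 × 100 kb | yeast chromosome count; lengths scaled down ~8× so full runs take milliseconds.  Variant counts, not genome size, drive the statistics. |
| map density | 0.4 cM/kb | yeast-like recombination density |
| causal mutations | 5, s = 0.1 each | the scale of the most parsimonious evolved clone; s is not measurable from the published data, and 0.1 over 34 generations drives a heterozygous allele to ~96%, matching the observed >90% segregation |
| hitchhikers | 110 | typical evolved-clone mutation count at mutator rates |
| time-zero variants | 5 | founder-private background variants |
| spore selection | 34 generations | one 100:1 plus three 500:1 dilutions, Σ log₂ ≈ 33.5 |
| pool coverage | 90× Poisson | the floor of the pooled-sequencing depth |
| sequencing error | 10⁻³/read/site | Illumina-scale substitution error |

**Meiosis.**  Crossovers follow the no-interference model: under a
Poisson crossover process the haplotype along a chromosome is Markov,
so the simulator draws the first locus as a fair coin and switches
between adjacent loci `d` cM apart with probability
`r(d) = (1 − e^(−2d/100))/2`.  Because Haldane's function is closed
under the two-locus composition rule, this reproduces the Haldane
recombination fraction between *every* pair of loci — which makes the
closed form an independent oracle for the simulator (tested at five
map distances against 3σ binomial bands).  Chiasma interference and
gene conversion are not modeled; the pipeline's statistics depend only
on pairwise recombination fractions, for which Haldane is the standard
testable choice.

**Selection.**  Default mode is deterministic exponential weighting: a
spore carrying causal alleles with coefficients `s_i` has final weight
`Π(1 + s_i)^g`.  This is the expectation of serial batch growth and
gives the closed-form check `p' = p(1+s)^g / (p(1+s)^g + 1 − p)`
(= 0.962 at p = 0.5, s = 0.1, g = 34).  A stochastic mode resamples the
population multinomially through explicit passage bottlenecks
(5×10⁵ cells; dilutions 100:1 + 3×500:1) for users who want drift; the
two agree in expectation and are tested to agree within Monte-Carlo
error.  Mating-type/marker selection of spores is not modeled
genetically — "spores" are already the selectable haploid set, which
is orthogonal to allele-frequency structure.

**Sequencing.**  Per-variant read totals are Poisson around the target
coverage (the conventional model; any overdispersion in real data
widens the binomial bands but does not move their centers), and each
read reports the mutant allele with probability
`f(1−e) + (1−f)e`.

**Depth tracks.**  Windowed depths (1 kb default) are Poisson around
coverage × copy number.  A heterozygous-origin duplication that is not
under selection is carried by half the selected spores, so its
expected pool copy ratio is (2+1)/2 = 1.5; a causal event keeps the
clone's ratio.  CNV segmentation merges runs of ≥ 3 consecutive
windows beyond ratio 1.5 (gain) or 0.75 (loss); all three numbers are
artifact choices — the published events are 20 kb-scale and
unambiguous at these defaults, and segmentation is tested to be stable
under window noise at 10% of the ratio gap.  No HMM or circular binary
segmentation: the target events are single large steps.

**Sanger traces.**  Peak-height pairs whose ratio is the true
frequency plus truncated Gaussian noise (σ = 0.02 default).  The
estimator is `h_mut/(h_mut + h_anc)` with the 5%/95% background clamp
in time-course mode and raw values in segregation mode; exact 5%/95%
values are left unclamped (the clamp bounds are described as strict
inequalities).

**What the simulator does not emulate**, and hence what passing tests
do not show about real data: alignment and variant-calling artifacts
(the pipeline consumes variant tables, not reads), mapping bias near
indels, overdispersed coverage, chiasma interference, aneuploidy
beyond simple segmental copy changes, and de novo mutation during the
backcross itself.  Parameter-recovery results are statements about the
model's own study conditions, not about any particular wet-lab
dataset.

## Reference dataset

The package ships a transcription of the published mutation table for
the twelve evolved clones (81 nucleotide-change rows across 12 clones,
with footnote lists of linked hitchhikers, time-zero founder alleles,
and alleles below 5% final frequency).  Effects are reconstructed from
the printed nucleotide/protein names; the files are checksum-guarded
and re-classified at load time rather than carrying any stored
classification.  Running the classifier over this table reproduces the
published tallies (80 gene-level causal mutations, 53 distinct genes,
39 genes mutated once, recurrence counts per gene and pathway) —
these are computed, not asserted, in both the test suite and
`scripts/acceptance.py`.

## Numerical and degenerate-input choices

- Thresholds on fractions use exact rational arithmetic; simulation
  tolerances in tests are derived from binomial standard errors at the
  stated sample sizes (typically 3σ), not tuned constants.
- Zero total reads → `MissingDataError`, reported uncallable.
- Both Sanger peaks zero → uncallable; negative heights rejected.
- Dilution factors ≤ 1 rejected (a cycle must return to saturation).
- Competition scoring rounds the mean elimination cycle half-up before
  banding; replicates eliminating in both directions warn and apply
  majority rule.  A replicate needs an explicit winner with its
  elimination cycle — cycle count alone does not determine direction.
- Overlapping CNV events are rejected by the depth simulator; NaN
  ratio windows (zero reference depth) break segmentation runs.
- All simulator randomness flows from one seed; identical configs give
  bit-identical outputs.

## Problem sizes

Default test and acceptance runs use 10,000 spores per meiosis, 20
simulator seeds for parameter recovery (100 causal and ~1,500 unlinked
hitchhiker classifications), 1,000 nomenclature round-trips, and
200-window depth tracks.  At these sizes the binomial error bands in
the tests are a few tenths of a percent wide and the full suite runs
in seconds.

## Known limitations

- Single-exon gene models only; no splice forms.
- Substitution-only hitchhikers in the generator (planted causal
  alleles may be promoter or coding substitutions; indel planting is
  exercised through the annotation tests rather than the generator).
- The hitchhiker flag considers pairs, not longer linked chains; a
  chain of three linked causal calls is resolved pairwise.
- No statistical test on pool fractions — the method is a hard
  threshold by design, and the package deliberately mirrors that.
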