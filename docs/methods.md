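# Methods

This note documents the models and procedures implemented in smrnapipe,
the defaults that matter, what the synthetic-data generator does and does
not emulate, and the design choices made where the design was genuinely
open.

## Small-RNA cluster analysis

Reads are placed by exact matching only (0 mismatches), both strands,
with every hit of a multi-mapping read reported and counted in full at
each location. Exactness keeps the mapper checkable against an
exhaustive substring scan; fractional multi-map weighting is a common
alternative but full counting is the simplest defensible rule and is
recorded in the output metadata. A read equal to its own reverse
complement is reported once, canonicalized to the + strand.

"Sliding 100 bp windows" are implemented as non-overlapping 100 bp
tiling windows (step = width, configurable). A 1 bp slide would count
each read ~100 times and make windows non-independent; the per-window
fold formula and the per-chromosome difference tracks both treat windows
as disjoint clusters, which the tiling realizes directly. A hit belongs
to the single window containing its 5′-most genomic coordinate (for a
minus-strand hit, its highest coordinate), so a boundary-spanning read
is never double-assigned.

RPM uses the library's total clean reads as denominator, not the mapped
subtotal, matching how "reads per million" totals are usually quoted for
clean libraries; this is configurable. X and Y are per-window medians of
RPM across each genotype's libraries — with the single library per
genotype of the emulated design the median is the identity, but the same
code path serves replicated designs. The fold value is
log2((X + c)/(Y + c)) with c = 0.5 RPM, because windows with zero counts
in one genotype are common and otherwise undefined; windows with
X = Y = 0 are never called. The 4-fold cut-off is inclusive
(|fold| ≥ 2 in log2 units): a "cut-off threshold" reads most naturally
as attained at the boundary. Both c and the cut-off are parameters.

Properties guaranteed by construction and enforced by tests: windows
tile each chromosome exactly; swapping genotypes negates every fold
value; with c = 0 fold values are invariant to rescaling both libraries;
at the reference depth a null simulation passes well under 1% of
windows.

## miRNA analysis

Counting toward a catalogue entry accepts the exact mature sequence or a
3′-trimmed/extended variant of at most 2 nt with an identical 5′ end —
the dominant isomiR mode; 5′ variation changes the seed and is not
accepted. Entries sharing a mature sequence each receive the full count
and are flagged. Classification requires both a ≥2-fold RPM ratio
(pseudocount 0.5 RPM) and significance at α = 0.05. With one library
per genotype a replicate t-test is impossible, so significance comes
from a two-sided binomial test of the mutant count against the
expectation under equal abundance given both library totals, labelled
"count-test" in outputs; when ≥2 libraries per genotype are supplied, a
Welch t-test on per-library RPMs activates instead.

### Folding model

`fold_rna` maximizes a simple additive pair score — GC 3, AU 2, GU 1
model units, Watson–Crick plus wobble, minimum hairpin loop 3 — by
Nussinov-style dynamic programming with a deterministic traceback
(pairing (i, j) preferred, then an unpaired end, then the smallest
bifurcation point). The negated optimum is reported as the fold score,
so lower is more stable; the report column is labelled "mfe" but the
units are those of this model, not kcal/mol. The model is deliberately
not a nearest-neighbour thermodynamic model: it is self-contained,
parameter-free beyond the three pair scores, and exactly verifiable
against exhaustive enumeration of all legal structures (the test suite
does this for all lengths ≤ 14). Ensemble/partition-function folding is
out of scope.

### Novel hairpin discovery

Seeds are read stacks (reads sharing a 5′ position and strand) of ≥5
summed copies and 20–24 nt, lying outside every annotated feature class
except genes. Around each seed, 160 nt windows at 9 offsets are folded
on the seed's strand; a window is accepted if its fold score is ≤ −15
model units and the mature sits cleanly on one arm: at most 4 mature
bases unpaired, no mature base paired within the mature, partners
forming one compact block (≤ mature length + 8) separated from the
mature by at least the minimum loop. Among accepted offsets the best
fold score wins. The star sequence is the partner block with the
canonical 2 nt 3′ offset; the guide arm is the arm with the majority of
read counts in the precursor (ties to 5p). Seeds within 160 bp of an
already-processed seed are merged into one locus, and candidates with
identical mature sequences at different loci are grouped into one
family. The window size, offset count, score threshold and stack
minimum are explicit parameters: they are stand-ins for the loosely
specified practice of folding "sequences surrounding" a read stack, and
sensible alternatives exist. Expressed siRNA hotspots in unannotated
sequence can satisfy these criteria and appear as additional candidates;
this mirrors real discovery pipelines, where candidate lists require
downstream curation.

## Bisulfite methylation

Only the top (converted) strand of each amplicon is analyzed; a clone
arriving reversed is detected by aligning both orientations and keeping
the better conversion-aware identity. Alignment is global with
reference-C : clone-T substitutions free (conversion), other mismatches
costing 1 and gaps 2; clones below 90% identity (excluding conversions)
or outside 50–110% of the reference length are rejected and tallied.
Context is classified from the reference top strand: CG if the next base
is G, else CHG if the base after is G, else CHH; cytosines whose context
runs off the locus end are excluded. Per-context percentages pool all
clone×site calls, carry Wilson 95% intervals, and genotype differences
are absolute percentage points (a "decrease by 30%" is reported as
−30 points, the unambiguous reading) with a two-proportion z-test
attached as a descriptive aid. Incomplete conversion is reported as a QC
estimate when control positions are configured but never corrected for;
identical clones are not deduplicated.

## Expression analysis

The pipeline starts from a normalized genes × samples log2 intensity
matrix; probe-level processing is out of scope. The default per-gene
test is a moderated t: per-gene pooled variances are shrunk toward a
prior fitted by matching the moments of log sample variances under a
scaled-inverse-chi-square hierarchy (trigamma-inverse Newton iteration),
with the posterior degrees of freedom added to the residual ones. With
three replicates and typical array noise, per-gene variance estimates
on 4 degrees of freedom are too unstable for a plain t-test to reach
useful power under multiple-testing control; variance moderation is the
standard remedy for exactly this design, so it is the default, with
`method="welch"` available. A gene is called up/down when its BH
q-value passes α = 0.05 and |log2FC| ≥ 1; the fold filter is a
*reporting* threshold — power statements about an effect equal to the
filter boundary are made on the significance call, since an estimator
centred exactly on the boundary clears it only half the time regardless
of the test.

The chromosomal chi-square uses expected counts proportional to the
number of expressed genes per chromosome (not chromosome length): the
question is whether DEGs fall where expressed genes are.
Length-weighting is available by passing a different expected
composition. "Expressed" means present in the input matrix after any
upstream detection filter. GO proportions are descriptive
(DE-in-category / expressed-in-category, ordered by category size); no
enrichment p-values are computed, deliberately.

## Cross-layer association

A differential cluster associates with a methylation locus or DEG when
their intervals overlap or lie within 1 kb (configurable); the nearest
passing cluster is reported, ties broken by effect size. The
concordance flag records whether the small-RNA fold value and the CHH
delta share a sign — the expectation if the locus is under small-RNA
directed de novo methylation. The 1 kb rule is a stand-in for a
qualitative notion of "regional association" and is surfaced as a
parameter for exactly that reason. miRNA–target pairs are typed
I (miRNA down, target up), II (up, down), III (both up), IV (both
down), or none when either side is unchanged or missing; the five types
partition all pairs.

## Synthetic-data generator

The generator emulates the study design, not its sequences: two
genotypes; one small-RNA library each (200,000 clean reads by default,
scaled down from the ~10⁷ of deep sequencing — all detection rules are
ratio/RPM-based, hence depth-scale-invariant); three expression
replicates per genotype; ten bisulfite loci (four from a
retrotransposon-like family, three from a DNA-transposon-like family,
three genic) of 300 bp × 30 clones with planted per-context methylation
levels; a catalogue of 32 known miRNA loci with designed hairpins
(mature + 12 nt loop + near-reverse-complement star with ≤2 planted
mismatches); one novel hairpin whose identical mature sequence sits at
three unannotated loci, expressed ~30:1 in the mutant with 5p-dominant
reads; 20 planted differential clusters of 400 reads at 8-fold bias
(up and down), two of them placed adjacent to the differentially
methylated TE loci so the cross-layer association has a planted positive
control; and ~5% of genes planted as DEGs at |log2| 1–2.5, concentrated
on chromosome 1 to echo a non-random chromosomal distribution.
Background reads are drawn uniformly from the genome with lengths
bimodal at 21 and 24 nt (the canonical plant classes); planted reads are
drawn *from* the library budget, so each library totals exactly its
configured clean-read count. Expression noise is Normal with σ = 0.25
per replicate on the log2 scale — a configurable stand-in, since array
noise models vary. Bisulfite clones methylate each reference C with the
planted context probability and convert unmethylated Cs with rate 0.995.

What it does not emulate — and what passing tests therefore do not show
about real data: sequencing error and adapter artifacts in reads,
compositional genome structure (the background is i.i.d. uniform, so
mapping ambiguity is limited to the planted TE families), probe-level
microarray effects, PCR duplicates and bisulfite clone biases, and any
biological coupling between layers beyond the explicitly planted
associations.

Problem sizes used in the shipped checks: 4 chromosomes × 200 kb with
2 × 200k reads for recovery and calibration runs; 100-seed replicate
simulations for the statistical calibration of DEG calling and
methylation intervals; genomes of 10–50 kb with 200 reads for oracle
equivalence; sequences ≤ 14 nt for exhaustive folding enumeration.
These sizes keep the full validation suite desk-scale while leaving
every rule identical to what larger inputs would use.

## Numerical and degenerate-input conventions

Pseudocounts: 0.5 RPM in cluster and miRNA ratios. Zero-variance genes:
p = 1 when means are equal, 0 otherwise (Welch path); the moderated path
is immune once any gene has positive variance. Empty windows, empty
catalogues, loci without cytosines, and empty candidate lists all yield
empty-but-valid outputs (a locus with no cytosines warns). Chi-square
cells with zero expectation are excluded with degrees of freedom
reduced. All randomness flows from a single integer seed through
per-stage generators, making every output byte-reproducible; table
floats are written with 6 significant digits.

## Known limitations

Exact matching understates signal from polymorphic or edited reads; the
folding model ranks structures by pair count/strength only, so its
"mfe" values are not comparable to thermodynamic energies; the binomial
count-test treats reads as independent draws, which understates
overdispersion between true biological replicates; bisulfite summaries
pool clones, so within-clone correlation is not modelled in the Wilson
intervals; and the association layer is proximity-based, not causal —
concordance is a screen, not an inference.
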