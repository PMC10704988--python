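# Methods

This note documents the models and procedures rbpflow implements, the
parameter choices that matter, what the synthetic data generator does and
does not emulate, and the numerical conventions used throughout.

## Coordinates and formats

All internal coordinates are 0-based half-open `[start, end)`. GTF input
(1-based closed) is converted on read; BED is read and written natively in
the internal convention. Interval overlap ignores strand — the
coding-gene-overlap filter for lncRNAs is therefore conservative — and the
gap between intervals is 0 for overlapping or book-ended features.
FPKM is `count × 10⁹ / (transcript length × library size)` with the
per-gene length taken from the longest annotated transcript (a common,
deterministic convention; a union-exon length would differ only for genes
with widely divergent isoforms and is easy to supply instead, since the
length map is an explicit argument).

## Peak calling

Coverage is computed per gene from deduplicated read placements
(duplicates share chromosome, start, end and strand; the first occurrence
is kept; strands are pooled in the track). The track is scanned with
5 bp windows in 5 bp steps (trailing partial window included at its
actual length). The automaton:

- **opens** a peak at the first window of a run of 8 consecutive windows
  each ≥ 2.5 × *baseline*, or of a run of 8 windows whose median depth
  exceeds 50;
- **extends** it window by window, tracking the running maximum window
  depth;
- **terminates** immediately before the first run of 8 consecutive
  windows each below 4% of the running maximum, or at the track end
  (an open peak closes at the last window).

*Baseline* is the mean per-base depth of the enclosing gene, floored at 1.
Two readings in this rule set are genuinely ambiguous and were fixed as
follows: the "median" start rule is applied to the median of the
candidate run (not to single windows), and both the start and end rules
use the same run length of 8. Peak boundaries snap to window edges;
maximum and median depth are recomputed at base resolution for reporting.
Note an important structural property of the 4%-termination rule: over a
uniformly covered gene whose background never falls below 4% of the peak
maximum, the rule cannot fire and the peak runs to the end of the gene
track. Termination in practice comes from coverage gaps or the gene
boundary; peak-versus-background contrast alone does not close a peak.

## Permutation significance

The null model redistributes each gene's reads uniformly and
independently within the gene 500 times, preserving read lengths (a read
longer than its gene is pinned to the gene start). The null statistic is
the **maximum per-base depth of the gene** in each permutation, and a
peak's empirical p-value is the add-one estimator
`(1 + #{null maxima ≥ observed peak max}) / (1 + n)`, which can never be
zero and equals 1/501 at n = 500 when the observation beats every
permutation.

Using the gene-wide maximum (rather than the maximum within the peak's
own interval) is deliberate: candidate intervals are *selected* by the
window scan for being locally deep, so a null restricted to the selected
interval is anti-conservative — essentially every called candidate would
appear significant. The gene-wide maximum is exchangeable with the
observed maximum under the null, so the unconditional probability of a
spurious `p < 0.05` call per gene is at most 5%, which the null-gene
calibration test verifies empirically (the acceptance suite requires
≤ 7% over 500 simulated null genes, with the depth disjunct disabled).
Per-gene permutation streams are seeded by mixing the base seed with a
CRC of the gene id, so results are reproducible and independent of gene
processing order.

A peak is **significant** when `p < 0.05` or its maximum depth is ≥ 10,
and becomes a **final** peak when additionally the IP/input abundance
fold exceeds 4. Abundance is `(mean per-base depth within the peak + 1)
× 10⁶ / library size` for each library; the pseudocount keeps the ratio
defined and damps folds at very low coverage, and the per-million scaling
prevents library-depth differences from masquerading as enrichment.
With no input library the fold is undefined and the screen passes with a
logged warning (input is a control, used when available). No
multiple-testing correction is applied across peaks at this stage.
Intergenic reads are not assigned to genes; peaks are called per
annotated gene.

## Differential splicing

The per-sample splicing ratio of an event is `alt / (alt + model)` over
junction reads, masked (treated as missing) when the total is below 10 —
low-depth ratios are too noisy to compare. Events with at least two
unmasked samples per group are tested with the classical equal-variance
two-tailed t-test on the ratios (Welch is available behind a flag),
with t oriented knockdown − control so a positive value means more
alternative-isoform usage after knockdown. Zero-variance degenerate
inputs resolve by the limit (equal means → t = 0, p = 1). BH adjustment
runs across all testable events and significance is declared at adjusted
p ≤ 0.05; the largest raw p among significant events is reported as the
implied fixed-p cutoff, which makes the "p cutoff corresponding to 5%
FDR" formulation and direct BH thresholding numerically identical.

## DEG filtering, overlaps, enrichment

The DEG screen is applied exactly as printed, with strict inequalities:
`p < 0.05` **and** (`FC > 2` or `FC < 0.5`) on linear fold changes — a
fold change of exactly 2.0 is excluded. A flag converts log2 inputs; an
optional flag BH-adjusts the p column first (DESeq2-style tables already
carry `padj`, and the count-based path reports both). When only counts
are available, the result table is produced by pydeseq2's NB Wald test
(knockdown vs control), with the log2 fold change converted to linear.

Set integration reports exact region cardinalities and memberships for
2–3 named gene sets. Term enrichment is the upper-tail hypergeometric
probability `P[X ≥ overlap]` with population = background, successes =
term ∩ background, draws = query ∩ background, BH-corrected across
terms. The background defaults to all genes expressed in the experiment;
it is an explicit argument. BH itself is implemented directly (sorted
`p·n/rank`, suffix minimum, clip at 1, input order restored): the test
suite requires bit-exact agreement with an independently coded step-up
oracle, which is easiest to guarantee by owning the arithmetic.

## lncRNA cis targets

A candidate transcript is a credible lncRNA iff all four coding-potential
votes are "noncoding" **and** length ≥ 200 bp **and** it overlaps no
coding gene **and** it lies ≥ 1,000 bp from the nearest gene; boundaries
are strict as printed (199 bp removed, 200 kept; incomplete votes reject
the transcript). Co-location pairs a lncRNA with every gene whose
boundary gap is ≤ 100 kb (inclusive; measured between interval
boundaries, strand-agnostic, 0 for overlap). Co-expression uses Pearson
correlation across samples with the exact t-transform p-value (n − 2 df,
two-sided); a pair passes at `|r| > 0.6` and `p ≤ 0.01`, and the final
cis-target set is the intersection of the two screens. Zero-variance
profiles fail with a logged reason; an optional BH flag corrects the
correlation p-values (off by default).

Power note: with n samples the `p ≤ 0.01` cut corresponds to a minimum
attainable |r| of `t₀.₉₉₅,ₙ₋₂ / √(t² + n − 2)` — 0.917 at n = 6, 0.71 at
n = 12, 0.56 at n = 20. A 3 + 3 replicate design therefore has little
power to certify even strongly co-expressed pairs (true r = 0.9 passes
only ~43% of the time at n = 6); the recovery demonstrations use a
10 + 10 design, where the screen is well powered, while the default
end-to-end run keeps the 3 + 3 design and simply reports what passes.

## Synthetic data generator

The generator emulates the study design the pipeline targets and emits
every input plus a truth manifest. Defaults (all configurable):

- **Annotation**: 60 non-overlapping genes of 8–12 kb on 2 chromosomes,
  1–2 transcripts each; inter-gene gaps drawn from a mixture spanning
  both sides of the 1 kb and 100 kb positional thresholds.
- **iRIP reads**: 150 bp reads (with a 0–10 bp trimming spread) on random
  strands, uniform within genes at 80 reads/kb (≈ 12× per-base depth) in
  both IP and input; IP adds (8 − 1)-fold concentrated reads inside each
  planted 1 kb binding site, so the expected in-site IP/input depth ratio
  is 8. Sites are window-aligned and placed in the distal (3′) portion of
  the gene (right margin 0.15–0.3 site lengths) — typical of many RBPs'
  3′-UTR binding, and consistent with the termination rule's reliance on
  the gene boundary (see above). 5% planted exact-duplicate reads
  emulate PCR duplication; duplicate ids are listed in the manifest.
  The background depth is chosen so that the permutation and abundance
  screens operate away from their pseudocount-dominated regime, as in a
  realistically sequenced IP library.
- **Expression**: NB counts (dispersion 0.05) over log-normal baseline
  means for 3 + 3 replicates; planted DEGs have the knockdown mean
  multiplied/divided by 4; each planted cis pair shares a mean-one
  log-normal per-sample latent factor whose variance is solved in closed
  form so the linear-scale pair correlation is ≈ 0.9.
- **Splicing**: per event and sample, `alt ~ Binomial(100, ratio)` with
  `model = 100 − alt`; base ratios uniform in [0.1, 0.6]; shifted events
  move the knockdown ratio by ±0.3. Event types are drawn from the
  nine-type vocabulary (cassetteExon, ES, MXE, A5SS, A3SS, A5SS&ES,
  A3SS&ES, 5pMXE, 3pMXE).
- **lncRNAs**: credible candidates are placed ≥ 1 kb from every gene
  (cis-pair members within 100 kb of their partner, the rest far outside
  the window); four decoys exercise each removal rule (short, coding
  vote, gene overlap, proximity).

Everything is deterministic given (config, seed) — emitted files are
byte-identical across runs — and a self-check validates that every
manifest id exists in the emitted data.

**What the generator does not emulate**: nucleotide sequence and motif
content, exon-aware read placement (reads are uniform over the genomic
gene span), strand-specific libraries, mapping ambiguity/bias, GC and
length biases, batch effects, and isoform-level expression structure.
Passing the planted-truth tests therefore demonstrates that the
statistics and screens behave as specified under their own model
assumptions — calibration under the stated null, recovery at the stated
effect sizes — not that they are robust to the full messiness of real
sequencing data.

## Problem sizes and runtime conventions

The standard demonstrations use 60 genes / 20 sites for peak recovery,
500 genes × 500 permutations for null calibration, 1,000 events
(900 null + 100 shifted) for the splicing panel, and 20 simulated studies
for DEG recovery — sizes at which every planted effect is comfortably
detectable and a full end-to-end run takes seconds on one core. The
permutation engine is vectorised (one difference-array per permutation
batch), so 250,000 gene permutations run in well under a minute.

## Known limitations

- The termination rule's dependence on coverage gaps (not contrast)
  means peaks in continuously covered genes extend to the gene boundary;
  boundary precision is then set by the annotation, not the signal.
- The equal-variance t-test on 3 + 3 ratio vectors is exact only under
  normality; at junction depth ~100 the binomial ratios are close enough
  to normal that the FDR target holds in simulation, but very low-depth
  designs should raise the masking threshold instead of trusting p.
- Peaks are gene-scoped: intergenic enrichment is not called or assigned
  to a nearest gene.
- The hypergeometric enrichment treats terms as flat sets (no ontology
  propagation), and fold-change conventions assume knockdown/control
  orientation throughout.
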