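# Methods

This note documents the models and procedures implemented in `ecfscan`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate about real data.

## Background and scope

Heterologous extracytoplasmic function (ECF) sigma factors are attractive
orthogonal regulators for synthetic circuits, but an ECF imported into a
new host may recognise host-genome sequences resembling its cognate
promoter and drive unintended ("off-target") transcription.  `ecfscan`
quantifies that risk from sequence and expression data in four steps:

1. call transcription start sites (TSS) from enriched 5'-end read counts
   and extract the TSS specific to an ECF-overexpression strain;
2. scan the sequence upstream of each specific TSS for the ECF's
   bipartite -35/-10 promoter motif and keep statistically supported
   matches;
3. calibrate score cutoffs from promoters upstream of operons known (from
   RNA-seq differential expression) to respond to the ECF;
4. apply the cutoffs to windows around every annotated feature, yielding
   the genome-wide set of candidate off-target promoters.

Read mapping, read counting and differential-expression fitting are
upstream of this package: it consumes per-base 5'-end count tracks
(bedGraph or TSV) and a DE table (unit, members, log2 fold change,
adjusted p).  Operon structure is likewise an input; the package does not
infer operons.

## TSS calling

The first base of an enriched primary-transcript read marks a candidate
TSS; per-base tallies Rns are normalised to a relative read score

    RRS = (Rns / Rt) * 1e6,

with Rt the sample-wide total of mapped TSS reads (all replicons, both
strands).  Neighbouring positions are merged into a cluster whenever the
positional difference between neighbours is at most `max_gap` = 3 nt
(a difference of 3 clusters, 4 splits).  Each cluster is represented by
its dominant member (maximal Rns; ties break to the 5'-most member on
the strand — the tie rule is a package choice and is documented rather
than data-derived).  Dominant TSS with RRS >= `min_rrs` are retained;
1.5, 3.0 and 7.5 are conventional working points and 3.0 is the default
used downstream.

A TSS is *strain specific* to sample A when no retained TSS of sample B
lies within ±3 nt on the same contig and strand.  The ±3 tolerance
mirrors the cluster gap; presence/absence matching has no standard
definition, so the tolerance is exposed as a parameter.

RRS is strictly per-position; a cluster is represented by its dominant
member's RRS and member counts are never aggregated.  This keeps the
score interpretable as a per-base quantity and makes selection invariant
to how a cluster is subdivided.

## Promoter model and scanning

Each ECF group's promoter preference is a pair of position-specific
scoring matrices (PSSMs): 4 × L base-2 log-probability matrices for the
-35 and -10 boxes.  A box score is the sum over columns of the
log-probability of the observed base, so scores are ≤ 0 and closer to 0
means closer to the motif.  Log base 2 is fixed by convention here: any
base is monotone-equivalent for ranking, Pareto fronts and empirical
E-values, but fixing it makes printed scores comparable across runs.
Matrices given as counts or frequencies are converted with a per-base
pseudocount ε (default 0.01): p = (f + ε)/(1 + 4ε), which avoids -∞ on
sparse columns; a zero frequency with ε = 0 is a hard error.

A placement puts the -35 box, a spacer of 15–17 nt, and the -10 box in a
window held in transcription orientation (minus-strand windows are
reverse complemented, so box order is always -35 → -10 → TSS).  When a
window is anchored on a TSS, the placement must additionally leave 3–6
bases strictly between the last base of the -10 box and the TSS base;
"distance" counts intervening bases, a convention documented here
because the counting origin is otherwise ambiguous.  The total score is
s35 + s10.  The best match per window is the maximal-total placement;
exact ties break to the smaller spacer, then to the placement closest to
the 3' end.  Scanning is vectorised: box scores for all offsets of all
sequences are computed in one pass, so nulls with thousands of shuffles
are cheap.

### Empirical E-values

Significance is conditional on composition: the window is shuffled
n = 1,000 times (uniform random permutations, preserving mononucleotide
counts exactly — a strict reading of "same mononucleotide distribution"
that also conditions on the realised composition rather than an i.i.d.
approximation of it), each shuffle is scanned in the same mode (anchored
nulls stay anchored), and

    E = #(null best total >= observed total) / n.

The plain k/n estimator is the default so that E = 0 is attainable for
sites that no shuffle reaches; the (k+1)/(n+1) add-one variant is
available for callers that need strictly positive estimates.  Anchored
hits with E ≤ 0.05 are retained.  Each window's null is generated from a
seed derived from the run seed and the window id, computed once and
cached; calibration and genome-wide filtering therefore see identical
E-values regardless of evaluation order, which guarantees that every
calibration hit passes the cutoffs derived from it.

## Cutoff calibration

Units passing the DE filter (log2 fold change > 2 and adjusted p < 0.05,
both strict) anchor the calibration.  For each such unit, all placements
in its feature window (500 nt upstream to 100 nt downstream of the
strand-aware feature start) are collected and reduced to the Pareto
front with respect to (s35, s10): a placement survives unless another
placement is at least as good in both coordinates and strictly better in
one; duplicates of identical score pairs are all retained.  Over the
union of fronts, the worst values — minimal s35, s10 and total, maximal
E-value — become cutoffs, each relaxed by 5%: scores (negative) are
multiplied by 1.05, moving them away from 0, and the E-value cutoff is
multiplied by 1.05 and capped at 1.  All four cutoffs are applied as a
conjunction with inclusive boundaries.  A regulated unit with no
placements is excluded with a warning and recorded in the cutoff
provenance.  The E-value cutoff can alternatively be pinned (e.g. at
0.05) via `fixed_max_evalue`; the front-derived value is the default.

## Genome-wide prediction

Windows are extracted around every annotated feature (500 up / 100 down
of the strand-aware start; the anchor choice is configurable since
annotations differ in whether the feature start is a transcriptional or
translational coordinate).  Windows clipped at contig edges are flagged.
With calibrated cutoffs, E-values are computed only for placements that
already pass the three score cutoffs — the filter is a conjunction, so
this is exact and keeps hundred-run experiments within minutes.  With
calibration disabled, the best placement per window is tested against
the E ≤ 0.05 filter alone (per-region best-match semantics).  Because
neighbouring feature windows overlap, the same genomic promoter can be
attributed to two features; the report lists both attributions and a
deduplicated promoter set keyed by genomic box coordinates.

The background distribution of promoter-likeness is summarised by
scanning overlapping genome tiles (601 nt, step 300 — matched to the
feature-window length; the tiling is a package choice) on both strands
and recording each tile's best total.

DNA duplex-stability prediction is not reimplemented; a BED file of
externally produced low-stability intervals can be supplied and retained
hits are intersected with it.

Pipeline runs are deterministic: identical config and seed produce
byte-identical reports.  Stage artifacts are written per run; reruns
recompute rather than resume (a known limitation).

## Synthetic data generator

The generator produces the full input set with known ground truth:

- **Genome**: one contig of i.i.d. bases at fixed GC (default 0.60,
  matching a high-GC alphaproteobacterial host).  No dinucleotide
  structure is modelled; this is sufficient because the E-value null
  conditions on realised mononucleotide composition.
- **Features**: `n_features` (default 200) evenly spaced 300-bp features
  on alternating strands of a 100-kb contig; packing is validated and
  infeasible requests fail loudly.
- **Planted promoters**: for `n_regulated` (default 10) randomly chosen
  features, a site drawn from the PSSM pair (consensus bases, or
  column-wise sampled) with spacer 15–17 nt is written into the genome so
  that its TSS lies 3–6 nt downstream of the -10 box and 20–60 nt
  upstream of the feature start (a typical bacterial 5' UTR), inside the
  feature's 500-up/100-down window.
- **Count tracks**: the treatment sample assigns `depth ×
  signal_fraction` reads (default 10^6 × 0.1) multinomially to the
  planted TSS with ±1 nt positional jitter (10/80/10) to exercise the
  clustering rule; both samples additionally receive sparse background
  read starts, independently per strand-base, at Poisson rate
  `noise_rate × depth / 1e6` (default noise_rate 1e-4).  The default
  reproduces the background density seen in real enriched 5'-end data,
  where control-specific TSS occur at roughly one per 5–10 kb of strand.
  The background is deliberately sparse: dense per-base noise would fuse
  the ≤3-nt-gap clusters into contiguous strand-wide runs, which
  enriched 5'-end libraries do not show.  Rt is set to each sample's
  emitted total.
- **DE table**: one monocistronic unit per feature; planted units get
  log2fc = 4 and padj = 1e-6, all others small Gaussian log2fc noise
  (σ = 0.3) and padj uniform on [0.2, 1], so the DE filter recovers
  exactly the planted set.

What passing tests on this generator demonstrate: correctness of the
scoring, clustering, calibration and filtering machinery, end-to-end
recovery of strong planted signals, and control of the false-positive
rate under the package's own null.  What they do not demonstrate:
robustness to real-library artifacts (processed-RNA contamination,
capture efficiency, mapping bias), to promoters much weaker than
consensus, to operonic read-through, or to genomes with repeat structure
and composition heterogeneity.

## Numerical choices

- Scores are floats in bits; placement ties are resolved with a 1e-12
  tolerance; cutoff boundaries are inclusive with the same tolerance.
- E-value comparison uses `null >= total - 1e-9` so that exact re-creation
  of the observed arrangement in a shuffle counts as "at least as
  extreme".
- Consensus ties break alphabetically (A < C < G < T), documented.
- Coordinates are 0-based half-open internally and within window
  sequences; all emitted files are 1-based inclusive except BED/bedGraph,
  which follow their standards.
- Degenerate inputs: ambiguity codes are rejected, not skipped; an empty
  sample (Rt = 0) is an error at RRS computation; windows too short for
  any placement yield empty results (logged in the anchored scan).

## Problem sizes used in validation

The bundled validation suite runs the complete pipeline on 100-kb
genomes with 200 features, 10 planted consensus promoters and 10^6-read
samples, across 100 independent seeds, alongside a 2,000-window null
calibration of the E-value at n = 1,000 shuffles; oracle-equivalence
checks use 500–1,000 random instances per operation.  The acceptance
script repeats the pipeline experiment over 50 seeds and the null
calibration over 1,000 windows.

## Known limitations

- The bundled PSSMs are synthetic toys shaped like group-specific ECF
  preferences (7/6-column boxes, one strongly preferred base per
  column); real group matrices are drop-in replacements via
  `load_pssm_pair`.
- Score magnitudes depend on the log base and pseudocount; published
  scores from other implementations are comparable only after matching
  those constants.
- Extended -10 elements, UP elements and discriminator sequences are not
  modelled.
- RRS is per-position; if a consumer expects cluster-aggregated scores
  the selection threshold must be reinterpreted.
- Operon structure and duplex-stability intervals must be supplied;
  neither is inferred.
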