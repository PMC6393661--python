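# Methods

## Scope and model

`lnctrans` infers *trans*-regulatory lncRNA–TF–target relations from
case/control expression matrices. The inference chain is correlational:
it asserts co-variation consistent with a lncRNA acting through a TF on
that TF's regulon, not causal direction. The pipeline starts at gene-level
FPKM; read mapping, transcript assembly and coding-potential
classification are upstream of this package, and regulons and functional
gene sets are user-supplied GMT files.

## Statistical components

**Differential expression.** The selection rule is threshold-based:
raw *p* < 0.05 and |log2FC| > 1. The test statistic is Welch's two-sample
*t* on log2(FPKM + 1). FPKM is continuous and roughly log-normal, so a
*t*-test on the log scale is the transparent default; count-model
alternatives (negative-binomial shrinkage estimators) need raw counts the
pipeline does not assume. Genes with zero variance in both groups get
*p* = 1 when means agree, *p* = 0 otherwise. The log2 fold change uses a
pseudocount of 1 FPKM in both numerator and denominator, which keeps
unexpressed genes finite and makes the all-zero gene exactly 0. A
`signed_fc` flag restricts calls to up-regulation for users who want the
literal one-sided reading of the fold-change rule; the default treats it
two-sided because down-regulated genes are part of the analysis. BH
*q*-values are computed and reported but never drive selection.

**Co-expression.** All lncRNA × mRNA Pearson correlations on
log2(FPKM + 1) (raw-FPKM mode available). Significance uses the exact
transform *t* = *r*√(n−2)/√(1−r²) against t(n−2) rather than permutation:
at n = 6, permutation *p*-values have granularity 1/720-scale and cannot
resolve the 0.05 threshold cleanly. For n = 6 the two-sided *p* has the
closed form 1 − 1.5|r| + 0.5|r|³, used as an independent oracle; at
r = 0.84 it gives p = 0.0364. Edges require |r| > 0.7 and *p* < 0.05 and
retain signed r; downstream set operations ignore the sign. Zero-variance
genes are excluded with a logged warning instead of raising, since a
constant row is a data property, not a caller error.

**Over-representation.** Upper-tail hypergeometric P(X ≥ k) (the standard
convention, including the observed overlap) via `scipy.stats.hypergeom.sf`,
with fold enrichment (k/n)/(K/N) and the significance rule *p* < 0.05 and
FE > 2. The background universe is the intersection of the expression
matrix's genes with the collection's universe — an expression-aware
background, since testing genes that could never be observed inflates
enrichment; the collection-as-is universe is available by option. The
test is discrete and therefore conservative: under a random query the
realized type-I rate sits below the nominal 5% (observed ≈ 1–2% in the
null simulation), which the tests assert as an upper bound rather than a
two-sided calibration band.

**Pair ranking and triads.** Every lncRNA with ≥ 1 co-expression edge is
scored against every TF regulon with the same hypergeometric core (one
implementation; the network module calls the enrichment functions). Pairs
rank by (*p* asc, FE desc, lncrna_id, tf_id); the lexicographic tail makes
ties deterministic. The first 100 pairs form the pair tier and the first
10 the triad tier — selection is global across lncRNAs, with the per-lncRNA
reading available as an option since the "first hits" rule can be read
either way. Triad targets are regulon(TF) ∩ coexpressed(lncRNA),
intersected with DE mRNAs in the default mode (toggleable); triads left
empty are dropped with a log entry. Exported networks type nodes as
lncRNA/TF/target (a gene that is both TF and target stays TF) and carry
the pair *p* on lncRNA–TF edges, co-expression *r* on lncRNA–target edges
and a `regulates` label on TF–target edges; an audit pass re-derives every
exported edge from a co-expression record or regulon membership on every
run.

**Motif scan.** The binding-evidence step is an IUPAC consensus scan with
a mismatch budget: every window of the lncRNA within `max_mismatch` of the
consensus is a hit, with N in the sequence never matching and U read as T.
Hits annotate pairs (`motif_support`) and never gate or re-rank them,
because no principled score threshold exists for consensus matching at
this scale. Coordinates are 0-based half-open on the sense strand;
minus-strand scanning is off by default since lncRNA transcripts are
single-stranded.

**qPCR.** ΔCt = Ct(target) − Ct(reference) per sample; ΔΔCt subtracts the
control-group mean ΔCt (per-pair calibration available); relative
expression is 2^−ΔΔCt with efficiency fixed at 2. The group comparison is
a two-sided Student *t* on ΔCt values.

## Synthetic data generator

The generator emulates a small case/control FPKM experiment with planted
trans-regulation. Per TF *t*, a latent activity a_{t,s} ~ N(δ·1[case], 1)
with δ = `de_log2fc` for planted-triad TFs, else 0. Regulon targets, the
TF's own transcript and the planted lncRNA all load on a_{t,s} with weight
`activity_weight` on top of `baseline_log2fpkm`, plus N(0, `noise_sd`)
residuals; background genes are baseline plus residual. FPKM = 2^log2
value. The TF transcript loading on its own activity is a modelling
choice: without it there is no lncRNA–TF co-expression signal and no DE
TF, i.e. nothing for the pair-scoring stage to recover.

Defaults (3 + 3 samples, 500 mRNAs, 50 lncRNAs, 10 TFs, regulon size 20,
5 planted triads, δ = 1.5, weight 1.0, noise 0.3 log2 units, baseline 5
log2-FPKM ≈ 32 FPKM) mirror a small embryonic-tissue sequencing design.
Recovery tests use 10 + 10 samples because Pearson r at n = 6 is too
variable for stable recovery assertions; both configurations are exercised
in the tests. What the generator does **not** model: gene-length and
library-size effects inside FPKM, count-level overdispersion, correlated
background modules, batch effects. Passing recovery tests therefore shows
the pipeline recovers the assumed structure from data that satisfies its
assumptions — not that real tissue data satisfies them.

The qPCR table generator inverts the ΔΔCt computation (control ΔCt fixed,
case ΔCt = base − log2(fold)), so zero-noise tables round-trip fold
changes exactly and noisy tables test tolerance (±15% at 0.1-cycle noise
over 20 replicates).

## Numerical and design notes

- All output files are sorted by key and written with fixed float
  formatting, so reruns are byte-identical; the run manifest records the
  config echo, input checksums and per-stage row counts.
- Hypergeometric tails come from scipy's stable implementation and are
  verified against exact integer enumeration (max |Δ| ≈ 3e-16 over all
  N ≤ 25) — the enumeration oracle stays independent of the scored path.
- Correlation *p* conventions: p(0, n) = 1, p(±1, n) = 0.
- Null calibration (50 seeds of the zero-coupling generator): lncRNA–TF
  correlation rejections and DE rejections both fall within binomial 99%
  bounds of the nominal 5% rate. The co-expression fraction runs ~0.3
  percentage points above 5% because the pseudocount log transform is not
  exactly affine in the simulated range; the deviation stays inside the
  bounds.
- Gene identifiers match exactly and case-sensitively; gene-set members
  absent from the declared universe are dropped with a logged warning.
  Missing values in expression input are an error, never imputed.
- Acceptance-scale problem sizes (N ≤ 25 enumeration, 50 null seeds, 20
  recovery seeds) were chosen to keep the whole verification under a
  minute while leaving the binomial bounds meaningful.

## Known limitations

- Inference is correlational; "regulates" edges encode regulon membership,
  not demonstrated binding or causality.
- With 3 + 3 designs the correlation threshold |r| > 0.7 has a high null
  pass rate (p ≈ 0.12 at n = 6); the printed p < 0.05 rule is the binding
  constraint, and results at that scale should be treated as candidate
  rankings.
- The motif scan is a consensus surrogate, far weaker than PWM or
  structure-aware binding models.
- No multiple-testing control is applied in the default selection rules
  (they follow the printed thresholds); q-values are provided for users
  who want FDR-controlled selections.
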