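# Methods

## Mutant-count model

A fluctuation assay grows many parallel cultures from tiny inocula and
counts resistant mutants after plating on selective medium.  Because a
mutation arising early founds a large resistant clone, the mutant count
is heavy-tailed.  We model it as compound Poisson: the number of
mutation events per culture is Poisson with mean m, and each event
contributes an independent clone whose final size K follows the
Lea–Coulson law with mutant relative fitness ρ,

    q_k = ρ Γ(k) Γ(ρ+1) / Γ(k+ρ+1),   k ≥ 1,

whose survival function telescopes to P(K ≥ k) = Γ(k)Γ(ρ+1)/Γ(k+ρ)
(= 1/k at ρ = 1).  The count pmf follows from the Panjer recursion for
compound-Poisson sums,

    p_0 = e^{-m},   p_n = (m/n) Σ_{k=1..n} k q_k p_{n-k},

which is exact and numerically stable for the n ranges used here.  The
simulator draws Poisson event numbers and inverts the survival function
per clone (closed form floor(1/U) at ρ = 1, vectorised bisection
otherwise), so the recursion and the simulator are genuinely independent
routes to the same distribution; their agreement is a standing property
test.

Assumptions inherited from the model family: no cell death or phenotypic
lag, full plating efficiency (the assay plates the whole culture), and
mutation count independent of final population size within a condition.

## Estimation

m is estimated by maximising Σ log p_{min(c_i, cap)} with counts
winsorised at cap = 1024.  Winsorisation bounds the recursion depth and
makes the likelihood insensitive to the exact magnitude of "jackpot"
cultures, whose sizes carry little information about m beyond being
large; estimates are invariant to inflating any count already above the
cap.  ρ is fixed at 1 by default; a joint (m, ρ) mode (Nelder–Mead on
log parameters) is available.  Standard errors come from the inverse
observed information, computed by central differences at the optimum
with relative step 1e-4.  All-zero datasets sit on the m = 0 boundary
and are returned flagged (`converged = False`, NaN standard error)
rather than raising.  The classical P0 estimator
m = −ln(n₀/n), se = sqrt((1−p̂₀)/(n p̂₀)), is provided as a cross-check.

The rate is μ = m/Nt with Nt the arithmetic mean of the replicate CFU
totals, treated as fixed: se_μ = se_m/Nt.  CFU noise is small relative
to estimator noise at the default design (CV 10% over 3 replicates vs
~8% relative error on m), so its propagation is omitted from the default
path.

## Ratio tests

The low-to-high ratio R = μ_low/μ_high summarises each strain's
response to glucose.  Its variance is first-order delta method for
independent numerator and denominator (separate cultures per condition):
var(R) = R²(se_a²/a² + se_b²/b²), CI = R ± 1.96√var(R).  The test of
R = 1 is two-sided by default.  The between-strain contrast
z = (R₁−R₂)/√(var₁+var₂) defaults to one-sided, the directional
hypothesis being that the wild-type ratio exceeds the deletant's; the
sidedness is recorded in every report and both are computable.  At 5%
relative errors the delta-method sd is within a few percent of the
exact sd of a Gaussian ratio, and the 95% CIs show near-nominal
coverage (both property-tested).

## Variant calling

Reads are tried on both strands and aligned to the CDS with semi-global
dynamic programming (read end-gaps free; match +2, mismatch −3, gap
open −5, gap extend −2 — parameters chosen to prefer substitutions over
spurious gaps at Sanger-scale divergence).  A read whose best alignment
identity falls below 80% of aligned columns is rejected as unalignable.
Each mismatched column yields one substitution call (read N columns are
uninformative and yield none); each gap run yields one indel call,
left-normalised to the smallest CDS position that preserves the edit.
Indels are flagged frame-preserving when their length is a multiple
of 3.

Annotation uses ceil(cds_pos/3) codon numbering, translation with the
bacterial code, and the RRDR cluster ranges cluster I nt 1520–1598
(aa 507–533), cluster II nt 1687–1715 (aa 563–572), cluster III
nt 2060–2062 (aa 687).  The cluster III nucleotide range overlaps codon
688 under ceil numbering (codon 687 spans nt 2059–2061); cluster
membership follows the nucleotide ranges as given, codon numbers follow
the arithmetic.  Isolates with no call in clusters I/II are reported as
`none_detected`; isolates with several RRDR calls keep all of them and
are flagged for review rather than silently resolved.  VCF output maps
CDS position 1 to genomic position 4181245 on NC_000913.3 (forward
strand) with standard padding-base representation for indels.

## Spectrum models

Substitutions collapse to the six strand-symmetric classes (AT>GC,
GC>AT, AT>CG, AT>TA, GC>CG, GC>TA); insertions and deletions are one
category each.  The joint model is a baseline-category multinomial
logit on the grouped condition × category counts, maximised by Newton
ascent with step halving (tolerance 1e-8 on the log-likelihood, at most
500 iterations; coefficients capped at ±30 to keep separated fits
finite, with a separation flag on any capped fit).  The baseline
category is AT>GC; likelihood-ratio statistics are invariant to that
choice.  Per-category models are binomial logistic fits via statsmodels
GLM.

Terms are tested Type-II, respecting marginality: each main effect is
dropped from the additive model, the interaction from the full model.
With 8 categories each binary term has 7 df in the multinomial model
and 1 df in the per-category models.  A single-predictor multinomial LR
equals the classical G-statistic of the corresponding contingency
table, which serves as a closed-form oracle; statsmodels MNLogit on the
expanded individual-level data is an independent cross-check of the
fitted likelihood.  No multiple-testing correction is applied across
the per-category tests (one planned comparison per model).

## Synthetic-data generator

The generator emulates the study design with known truth: per condition
182 parallel cultures of Luria–Delbrück counts, 3 CFU replicates
(lognormal around Nt = 1e8 cells/culture, CV 10%, mean-preserving), and
isolate reads of the CDS window 1400–1900 (covering RRDR clusters I
and II).  With probability 214/274 an isolate carries exactly one
planted mutation: a category drawn from its condition's 8-probability
vector, placed at a uniformly chosen compatible cluster I/II site
(in-frame codon duplications/deletions for indels).  Reads are emitted
in random orientation.  The default per-base error rate is 0 —
quality-trimmed Sanger consensus is effectively error-free at the call
level — with a uniform substitution-error model available for
robustness experiments.

Default scenario parameters: Nt = 1e8 and m ≈ 1–2 per culture, the
magnitude of a typical rifampicin fluctuation assay; true low-to-high
rate ratios 1.6 (wild type) and 1.06 (deletant); 274 isolates split
75/62/68/69 across conditions (uneven, as real isolate yields are);
spectrum probability vectors encoding AT>GC enrichment at low glucose
in both strains and GC>TA enrichment in the deletant, strongest at high
glucose.  These are plausible study-scale values, not measured ones.

What the generator does **not** emulate: chromatogram noise and
quality-dependent base calling, PCR artefacts, selection dynamics on
the plate, the real distribution of resistance sites within the RRDR
(sites are uniform over compatible positions), and real between-
replicate structure in CFU counts.  Passing tests therefore demonstrate
correctness of the inference machinery under the stated model, not
robustness to those real-data features.  The shipped reference CDS is
likewise synthetic — a deterministic random ORF with the real gene's
length and RRDR coordinates — so amino-acid identities in annotations
are internally consistent but not biologically meaningful; real analyses
should supply the genuine CDS FASTA.

## Numerical and design choices

- Optimiser bracket for m: (1e-8, max(10, 3·mean + 10)); bounded Brent
  with xatol 1e-8.  Verified against a brute-force likelihood grid.
- Problem sizes in the validation suite: 1e5 cultures for pmf/simulator
  agreement, 200 replicates of the 182-culture design for estimator
  calibration, 1e6 draws for delta-method checks, 2000 null tables for
  multinomial type-I error, 500 zero-error reads for caller recovery —
  sizes at which Monte-Carlo error is well below the tested tolerances.
- Reported p-values carry full precision plus a journal-style rounding
  (3 decimals; 2 when p ≥ 0.1).
- Every generator and pipeline run is a pure function of
  (configuration, seed); reports embed a config hash and seed.

## Known limitations

- No death/lag/phenotypic-delay extensions of the count model and no
  partial-plating correction; m and μ are biased if those effects are
  present in real data.
- The joint (m, ρ) mode is provided but ρ is weakly identified at
  typical culture numbers; its standard errors are approximate.
- Multi-base substitution runs are emitted as adjacent single-base
  calls, which double-counts a true MNV in category tallies (not
  produced by the generator; flagged via the multi-call review flag).
- The multinomial separation handling (coefficient cap) preserves
  likelihood-ratio statistics but makes capped coefficient values
  themselves meaningless; they are flagged.
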