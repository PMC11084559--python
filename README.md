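# fluctspec

Estimation and comparison of spontaneous mutation **rates** and
**spectra** in bacteria from rifampicin fluctuation assays, with a
synthetic-study generator for validation.

The package addresses a question from experimental evolution: when an
environmental variable (here, glucose concentration) or a gene deletion
(here, *luxS*) changes a strain's overall mutation rate, is the change
uniform across mutation types, or driven by specific classes of single
nucleotide variants (SNVs)?  It implements the full analysis path for a
two-strain, two-environment fluctuation-test design:

1. **Rate estimation** (`fluctspec.luria_delbruck`).  Mutant counts
   across parallel cultures follow the Luria–Delbrück distribution: a
   compound Poisson over resistant-clone sizes, with clone-size law
   q_k = ρ·Γ(k)Γ(ρ+1)/Γ(k+ρ+1) (Lea–Coulson, generalised with mutant
   relative fitness ρ) and count pmf from the Panjer recursion
   p₀ = e^(−m), p_n = (m/n)·Σ k·q_k·p_{n−k}.  The expected number of
   mutations per culture m is estimated by maximum likelihood (counts
   winsorised at 1024), with a P0 cross-check m = −ln p̂₀, and converted
   to a per-cell, per-generation rate μ = m/Nt using the mean of
   replicate CFU platings.
2. **Rate comparison** (`fluctspec.rate_comparison`).  Each strain's
   plastic response is the low-to-high glucose rate ratio R, with
   delta-method ("sigma method") variance
   var(R) = R²(se_a²/a² + se_b²/b²), a z-test of R = 1 and a z contrast
   between strains, z = (R₁−R₂)/√(var₁+var₂).
3. **Variant calling** (`fluctspec.rpob_calls`).  Sanger-style reads are
   oriented, aligned semi-globally to the *rpoB* CDS, and mutations in
   the rifampicin-resistance determining region (cluster I aa 507–533,
   cluster II aa 563–572, cluster III aa 687) are extracted, annotated
   and optionally exported as VCF in NC_000913.3 coordinates.
4. **Spectrum tests** (`fluctspec.spectrum_models`).  Calls collapse to
   8 categories (6 strand-symmetric SNV classes + insertions +
   deletions).  Glucose, strain and interaction effects are tested with
   Type-II likelihood-ratio χ² tests under a baseline-category
   multinomial logit (7 df per term) and per-category binomial logistic
   models (1 df).
5. **Synthetic studies** (`fluctspec.synthetic_data`).  Generates the
   whole study — counts, CFU replicates, reads with planted mutations —
   from known ground truth: 182 cultures and 3 CFU replicates per
   condition, 274 isolates of which ~78% carry one RRDR mutation.  The
   shipped reference CDS is synthetic (correct length and RRDR
   coordinates, not the real sequence).

## Worked example

```sh
python analysis/01_simulate_study.py --seed 0
python analysis/02_estimate_rates.py
python analysis/03_call_variants.py
python analysis/04_spectrum_tests.py
```

The first script writes a synthetic study under
`results/synthetic_study/`.  The second estimates per-condition rates
and prints:

```
strain glucose    m_hat     se_m       mu_hat        se_mu
MG1655     low 1.587138 0.119444 1.562045e-08 1.175558e-09
MG1655    high 1.063284 0.092080 1.026299e-08 8.887711e-10
  luxS     low 1.336559 0.107246 1.463557e-08 1.174362e-09
  luxS    high 1.079471 0.092611 1.172585e-08 1.005992e-09
MG1655: low-to-high ratio 1.522 (95% CI 1.180-1.864), z = 2.99, p = 0.0028
luxS: low-to-high ratio 1.248 (95% CI 0.961-1.536), z = 1.69, p = 0.0906
strain contrast: Z = 1.20, one-sided p = 0.1149
```

The wild-type configuration was generated with a true low-to-high ratio
of 1.6 and the deletant with 1.06: the estimated ratios (1.52 and 1.25)
recover those within sampling noise, the wild-type response is clearly
significant and the deletant's is not.  The third script then calls RRDR
mutations from the 274 reads (207 detected here, 75.5%), and the fourth
tests the spectrum; with this seed the generator's built-in AT>GC
enrichment at low glucose and GC>TA enrichment in the deletant surface
as significant glucose and strain terms.

The same pipeline runs on real data through the CLI: `fluctspec
estimate-rates`, `compare-rates`, `call-variants`, `spectrum` and
`test-spectrum` accept the CSV/FASTA formats described in their
`--help`, and `fluctspec run` executes the synthetic pipeline end to
end.

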