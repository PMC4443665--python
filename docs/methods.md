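# Methods

## Mutation classification and spectra

Somatic single-nucleotide substitutions are classified into the standard
96 channels: six pyrimidine-centred substitution classes (C>A, C>G, C>T,
T>A, T>C, T>G) by 16 flanking contexts, ordered 5' base then 3' base,
A<C<G<T. Purine-reference records are folded onto the opposite strand
(channel indexing is a 2-to-1 map from the 192 stranded representations
onto 96 channels; reverse-complement pairs always collide). The internal
representation is exclusively pyrimidine-centred; the adenine-centric
ordering of the A:T>T:A class — the order in which motifs like CAG>CTG are
quoted, and the order used for cosine comparison — is a re-indexed view,
never a second bookkeeping of counts.

A spectrum is adjusted for territory composition channel-wise:
`p_c = (n_c / o_c) / Σ_d (n_d / o_d)`, where the opportunity `o_c` is the
count of the channel's trinucleotide plus its reverse complement in the
analyzed territory. Opportunities are counted over merged intervals
(shared bases once), at every window offset; windows containing N are
invalid for both context lookup and opportunity counting, and soft-masked
lower-case bases are folded to upper case. Mutation coordinates are
1-based; BED intervals 0-based half-open; conversion happens only at the
catalog boundary.

## Strand attribution

For each A:T>T:A mutation inside transcript intervals of a single strand,
the mutated adenine is assigned to the non-transcribed (coding) strand
when the forward-strand record has ref A in a plus-strand transcript or
ref T in a minus-strand transcript, and to the transcribed strand in the
mirror cases. Positions covered by transcripts on both strands are
*ambiguous* and are excluded from strand counting only — they still
contribute to spectra. This exclusion is the conservative choice for
bidirectionally transcribed loci, where transcription-coupled repair acts
on both strands and the bias prediction is void.

## Exposure tests

* **A:T>T:A excess**: exact one-sided binomial upper tail
  `P(X ≥ k), X ~ Binomial(n_total, 0.125)`, with 0.125 the A:T>T:A
  proportion of Signature 5, the known background signature richest in
  A:T>T:A. Using all SNVs of the sample as `n_total` (not only
  strand-annotated ones) matches how per-tumor totals are tabulated. The
  null is conservative: every other common bladder-tumor signature has a
  lower A:T>T:A proportion, and the discrete test's achievable level is
  below nominal.
* **Strand bias**: exact upper tail at p₀ = 0.5 over the strand-annotated
  A>T count.
* Both tails are computed as a log-sum-exp over exact binomial log point
  masses. This keeps full relative accuracy (≈1e-12, verified against
  arbitrary-precision integer summation) and carries `log10 p` alongside
  the linear value, so p-values far below the 1e-300 underflow threshold
  survive into machine-readable output; display formatting renders one
  significant figure and prints `0` below 1e-300.
* **FDR**: Benjamini–Hochberg step-up, each family (excess, strand)
  adjusted separately across all samples of the run. Undefined tests
  (samples with no mutations, or no strand-annotated A>T) are excluded
  from the family and propagate NaN.
* **Call rule**: *AA-exposed* requires FDR < 0.05 in both families **and**
  cosine ≥ 0.90 between the sample's opportunity-adjusted adenine-centric
  A:T>T:A 16-vector and the reference AA profile. Samples passing both
  tests but failing the cosine are *AA-possible-dissimilar*: statistically
  A>T-loaded and strand-biased, but with a context pattern unlike AA's —
  possibly another adenine mutagen. The conjunction rule is this package's
  formalization; the two tests and the cosine comparison are standard, but
  no canonical combination rule exists, so the rule and both cutoffs are
  explicit, configurable parameters reported in the run manifest. The 0.90
  cosine cutoff separates observed AA-like tumors (≥ 0.92) from the known
  dissimilar case (≈ 0.53) with a wide margin on both sides. The reference
  AA 16-vector is an input; by default the bundled AA fixture's profile is
  used.

## Signature factorization

Model: `V_cg ~ Poisson(o_c · Σ_k S_ck E_kg)` with column-stochastic S.
This is the opportunity-weighted Poisson model family shared by
EMu-style probabilistic extraction and KL-divergence NMF; it is fitted
directly by multiplicative updates,

    S_ck ← S_ck · (Σ_g R_cg E_kg) / (Σ_g E_kg),
    E_kg ← E_kg · (Σ_c o_c S_ck R_cg) / (Σ_c o_c S_ck),   R = V / (diag(o) S E),

which monotonically non-decrease the Poisson log-likelihood (the trace is
asserted in tests). The full Bayesian machinery of probabilistic
extractors is deliberately not replicated: the shared likelihood with
deterministic multi-restart fitting and an explicit information criterion
is desk-scale, reproducible, and sufficient for the recovery properties
tested here.

Numerical choices: opportunities are rescaled to mean 1 (a pure
reparametrization of E) for conditioning; denominators and Poisson means
are floored at 1e-12; S entries below 1e-10 after convergence are zeroed
and columns renormalized; initial entries are uniform(0.1, 1) from a
seeded generator with independent spawned streams per restart (10 restarts
by default — same seed, bitwise-identical result); convergence is a
relative log-likelihood change below 1e-8, capped at 5,000 iterations with
a `converged` flag. Model selection minimizes
`BIC = −2·LL + (96K + KG − K)·ln(ΣV)` over K = 2…8 by default; all per-K
scores are reported. Columns are ordered by total attributed mutations,
descending, which fixes the permutation ambiguity of NMF; the scale
ambiguity is fixed by the column-stochastic constraint.

A caveat on recovery tests: exact NMF of a dense rank-K matrix is not
unique — the fitted factors can reach the likelihood optimum while mixing
the generating columns. Recovery assertions therefore use identifiable
ground truths (signatures with private channels and cohorts containing
near-pure samples, which the sparse bundled fixtures approximate); on
such instances noiseless recovery is exact and Poisson-noised recovery
reaches matched cosines ≥ 0.95.

Exposure attribution re-runs only the E update with S frozen and returns
per-signature proportions. Signature sets are compared by greedy
best-match pairing on 96-channel cosine, with the A:T>T:A 16-channel
cosine reported per pair.

## Synthetic data

The generator emulates exome-style SNV catalogs drawn from mixtures of
four bundled signatures: AA-like (0.88 A:T>T:A mass, CAG>CTG peak 0.30,
TAG>TTG 0.22), CpG>TpG deamination (0.70 on C>T at NCG), APOBEC (0.90 on
C>T/C>G at TCW), and a Signature-5-like background whose A:T>T:A mass is
exactly 0.125 — the null proportion of the excess test — spread uniformly
within the class, with the remaining 0.875 flat elsewhere. The fixture
signatures are stylized: real signatures have ragged context profiles, and
passing tests show correct inference machinery, not robustness to
real-spectrum noise.

Channel draws are multinomial with weights `o_c · (S w)_c` (signatures are
per-opportunity profiles, consistent with the factorization model). The
fixture reference is a 100 kb i.i.d. uniform random sequence, so every
trinucleotide is available at nearly equal opportunity; transcripts tile
80% of it in alternating plus/minus 1.6 kb blocks (non-overlapping, so no
ambiguous strands arise). Each A:T>T:A mutation is placed on the
non-transcribed strand with probability `strand_bias_q` *mechanically* —
by choosing a genomic site whose trinucleotide and transcript orientation
realize the intended strand — so context attachment and strand annotation
are exercised end to end rather than labels being stamped on. Sites are
drawn with replacement; at the default burdens (log-uniform on
[100, 2000], the realistic span of per-tumor exome totals) duplicate
positions are rare and harmless to every downstream statistic.

Replicated calibration and power studies use a count-level fast path that
draws the multinomial channel counts and the binomial strand split
directly. Placement changes neither distribution, so the fast path is
distributionally identical to full catalog generation for everything the
exposure tests consume, and it keeps 500-replicate studies in seconds.
What the synthetic data do **not** model: sequencing and calling error,
germline contamination, copy-number and clonality structure, regional
mutation-rate covariates, and selection — detection performance on real
tumors is bounded by those factors, not by the statistics tested here.

Study-condition defaults used by the replicated studies: type-I
calibration uses 500 pure-background catalogs of 500 mutations; the
detection study uses cohorts of 10 exposed samples (AA weight 0.7, burden
700, q = 0.75 — the regime of heavily mutagenized observed tumors) against
90 unexposed (pure background, q = 0.5), 50 replicate cohorts; signature
recovery uses 60 samples of three well-separated processes at 300–1,000
mutations each. These sizes keep every study within interactive runtimes
while leaving the statistical conclusions unambiguous.

## Degenerate inputs and edge cases

Empty catalogs parse with an explicit warning rather than silent success;
mutations at sequence edges, with reference-mismatching alleles, or with N
in their window are flagged invalid and excluded from spectra with a
logged count; zero opportunity on a channel with observed mutations is an
error naming the channel; all-zero A:T>T:A subvectors make the cosine
undefined and the call *not-detected*; undefined tests return NaN rather
than raising, so one empty sample cannot abort a cohort run.

## Known limitations

The exposure test conditions on total SNV count and ignores inter-sample
overdispersion; tumors with very few mutations have essentially no power
(the smallest callable burdens in practice are in the dozens-of-mutations
range). The cosine cutoff and the conjunction call rule are pragmatic
conventions, not fitted quantities. The factorization assumes independent
Poisson counts and a shared opportunity vector across samples; it does not
model per-sample territories, hierarchical signature priors, or comparison
against external signature databases.
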