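# Methods

## The measurement scheme the package models

A budding-yeast mother cell is dissected at every division. For maternal
division n the experimenter keeps four colonies — the daughter Dn, her
first and second daughters GDn.1 and GDn.2, and GDn.1's first daughter
GGDn.1 — a *sublineage*. A replication error made during division n is a
single-strand mismatch for exactly one cell cycle; the next S-phase turns
it into a double-stranded mutation on one of the two new duplexes, which
mitosis delivers whole to one cell. Tracing the two resolution steps gives
each of division n's errors a deterministic presence/absence pattern over
the colonies:

| group | resolved at            | present in                          |
|-------|------------------------|-------------------------------------|
| Da    | Dn's first division    | Dn, GDn.2                           |
| Db    | Dn's first division    | GDn.1, GGDn.1                       |
| Ma    | maternal division n+1  | every colony of sublineage n+1      |
| Mb    | maternal division n+1  | every colony of every sublineage ≥ n+2 |

Da+Db (= Dm) and Ma+Mb (= Mm) are the mismatches segregated to daughter
and mother; their sum is the division's full error count. Every true
mutation is seen in at least two colonies, so colony-private variants
(sequencing errors, sub-clonal mutations) are discarded outright.
Division n is scorable iff sublineages n..n+3 exist and are uncensored;
the last three divisions of any pedigree are therefore never scorable.

The caller works on exact presence patterns: variants are restricted to
the intersection of all colonies' callable intervals, singletons dropped,
then each variant's colony set is compared with the four expected patterns
per division. Variants implicating a division but matching no pattern are
returned in an `unassigned` residue, never silently dropped.

### Assignment-error detection

Three documented dissection mix-ups are recognised:

* **Dn+1 moved in place of GDn.1** (`ma_zero_recurring_db`): the corrupted
  sublineage's Ma group is empty while a substantial fraction of its
  putative Db variants (shared by the GD1 and GGD colonies, new to this
  sublineage) recur downstream. The threshold is 25% recurrence: a true
  swap sends ≈50% of putative Db downstream, stray noise ≈0%. The next
  sublineage additionally shows an empty Mb group (`mb_zero`), flagged when
  the lineage-wide load makes an empty group implausible (mean ≥10
  variants/sublineage).
* **GDn.1/GDn.2 reversed** (`da_matches_ma`): the strict Da group empties
  and >90% of the variants at the Da branch point (shared by D and GD2,
  absent from all other sublineages) follow the full-sublineage pattern of
  the previous division's Ma group.
* **GGDn.2 taken instead of GGDn.1**: the documented blind spot — no
  pattern distortion exists; the Db count silently absorbs a second
  division's worth of errors. The generator reproduces this, and the test
  suite asserts the *absence* of a flag plus the Db inflation.

Flagged sublineages are censored (their colonies leave pattern
evaluation); scoring then proceeds on the remainder.

## Count models

Full counts are modelled three ways: single Poisson; K-component Poisson
mixture (EM, 2K−1 parameters, rates initialised at evenly spaced sample
quantiles, 10 jittered restarts, convergence at relative log-likelihood
change < 1e-8 or 500 iterations, monotonicity asserted every iteration);
negative binomial in the (μ, θ) parameterisation with
pmf Γ(x+θ)/(x!Γ(θ)) · (θ/(θ+μ))^θ · (μ/(θ+μ))^x, fitted by profile
likelihood in θ (log-scale bounded search in [1e-3, 1e6]; μ̂ is the sample
mean, the intercept-only MLE; θ̂ at the upper bound signals effectively
Poisson data and warns). The negative binomial is the gamma-Poisson
compound: λ ~ Gamma(shape θ, scale μ/θ) then Poisson(λ); `nb_to_gamma`
exposes that mixing density.

Models are ranked by AIC = 2k − 2lnL and compared by Akaike weights
w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2). BIC is computed and reported but AIC
drives the ranking. The mixture ladder K = 1, 2, … stops at the first K
whose AIC exceeds K−1's. `k_max` defaults to 4; the end-to-end recovery
test compares {Poisson k=1, k=2, negbin}, the model set appropriate to
unimodal full counts — with K=3/4 mixtures competing at n≈50, mixture
overfitting takes the top AIC rank in a nontrivial fraction of replicates
even when the truth is negative binomial.

Sample variance uses the n−1 denominator throughout, including the index
of dispersion D̂ = s²/x̄.

## Simulators and their closed-form oracles

All simulator means and variances are pinned to independently derived
moments (law of total variance), which the tests evaluate before trusting
any Monte Carlo output:

* **Replicon-variant pairs**: Dm, Mm i.i.d. NB(μ, θ). Full counts have
  Var = 2(μ + μ²/θ), so D = 1 + μ/θ (≈3.28 at μ=138, θ=60.42) and the
  pair regression R² ≈ 0.
* **Division-variant pairs**: shared λ ~ Gamma(θ, μ/θ), conditionally
  independent Poisson sides. Var(full) = 2μ + 4μ²/θ, D = 1 + 2μ/θ (≈5.57),
  corr(Dm, Mm) = (μ/θ)/(1 + μ/θ) ≈ 0.70, so E[R²] ≈ 0.48.
* **Poisson-binomial division** on a karyotype: per chromosome copy c,
  count ~ Poisson(r·f_c) (r = mismatch rate per haploid genome, f_c the
  haploid genome fraction; a diploid contributes two copies per
  chromosome), each copy masked by an independent Bernoulli(1/2).
  Var(B·N) = ν/2 + ν²/4 per copy, so the inherited total has mean r·p/2
  and D = 1 + (r/4)·Σ_c f_c². With the embedded full-assembly lengths
  Σ_i f_i² = 0.0754 (yeast S288C) and 0.0497 (human GRCh38 chr1–22+X+Y),
  giving D ≈ 3.60 (yeast, r=69) and ≈ 48 (human, r=1900).
* **Gamma-Poisson-binomial**: one λ draw per division (shape θ, mean = the
  mismatch rate in use), then the per-copy Poisson and Bernoulli steps.
  Adds E[λ²]·Σf²/2-type and Var(λ) terms: D ≈ 4.79 (yeast), ≈ 81 (human).

The observed mutation rate is half the mismatch rate (each mismatch
survives segregation with probability 1/2): yeast 34.5 observed ↔ 69
mismatches/haploid genome; human 950 ↔ 1900 (the yeast rate scaled by
genome size, 3.03e9/1.1e8). The Poisson control accumulates at the
observed rate with no segregation step. Bernoulli masks are independent
across copies and divisions; no mother/daughter complementarity and no
sister-chromatid exchange is modelled. Cumulative-burden trajectories sum
independent per-division draws, so the across-cell variance grows linearly
with slope ratio between models equal to the single-division D ratio.

### Karyotypes

Embedded tables carry the full-assembly chromosome lengths (S288C 16
nuclear chromosomes, 12,071,326 bp; GRCh38 chr1–22, X, Y, 3,088,269,832
bp; no mitochondrion, no scaffolds). The original analysis used
repeat-masked lengths, which are not published; dispersion depends on the
karyotype only through Σf², and plausible masking (85–100% retained per
chromosome, checked in the acceptance suite) moves the yeast D by well
under 5%. Users with masked lengths can supply any fai-style TSV. The
human diploid simulation duplicates every chromosome including X and Y;
sex-chromosome ploidy handling in the original is unstated, and the ±10%
band on human quantities absorbs it.

## The pedigree generator

`generate_lineage` runs the full mechanism forward. Every division of
every cell draws its own per-side rate λ ~ Gamma(shape θ, mean μ) — μ is
the per-side (Dm/Mm marginal) mean, so full counts are NB(2μ, θ); the
defaults μ=138, θ=60.42 reproduce full counts with mean ≈276 and D̂ ≈5.5.
Mother-retained and daughter-bound mismatches are laid down per chromosome
copy at rate λ·f_c/ploidy with uniform unique positions, pending
mismatches resolve at the carrier's next division by an all-or-none
Bernoulli per copy, and double-stranded mutations propagate to all
offspring. A colony's variant list is its founder's double-stranded set at
the moment it is finally left to grow. Descendant cells are simulated two
to three divisions deep; their mutations reach at most one colony and are
removed by the two-colony filter, exactly like the colony-private Poisson
noise channel (`noise_rate` per colony, default 0) that stands in for
sequencing error and sub-clonality. A `masking_fraction` removes a random
window per chromosome per colony to exercise the shared-genome
intersection. Because the extra descendant divisions are simulated, the
three dissection mix-ups can be replayed on the same realised world:
`inject_assignment_error` re-emits the pedigree with the mis-dissected
cells in the wrong slots and all shared colonies byte-identical.

What the generator does *not* emulate: mutation spectra and hotspots
(positions are uniform, ref base fixed), read depth and allele-frequency
structure (abstracted into the noise channel), replicative aging, lethality
within sublineages, and sister-chromatid exchange. Passing tests therefore
validate the calling logic, the count models and the segregation
arithmetic — not robustness to alignment artefacts or calling-pipeline
noise in real sequencing data.

## Statistical choices in the tests

* Stochastic assertions use fixed seeds and tolerances derived from the
  oracles' sampling variance (typically ≥3σ margins).
* The Mendelian 1:2:1 test of per-chromosome none:partial:all classes runs
  at per-side μ=600, the saturating regime where every homolog pair
  carries mutations and the multinomial (¼, ½, ¼) is exact. At the study
  rate (μ=138) small chromosomes often carry zero mismatches on one
  homolog, inflating the all/none classes to the closed-form
  (0.273, 0.453, 0.273) computable from the gamma moment-generating
  function — the same partial-class deficit visible in the real tally
  (876:1490:834). A chi-square against exact 1:2:1 at that rate rejects
  with high probability for n ≳ 2000 chromosome-divisions, as it does for
  the real data.
* The printed Akaike-weight triple is checked at 5% relative tolerance:
  the published AIC values are integer-rounded, which perturbs ΔAIC by up
  to ±0.5 and hence the small weights by up to e^0.25.
* End-to-end recovery (100 pedigrees × 50 scored divisions) asserts the
  negative binomial ranks first in ≥95 replicates against the one- and
  two-component Poisson alternatives and that μ̂ recovers the full-count
  mean within 10%.
* Problem sizes (10,000 cohorts for pair models, 1000×200 for yeast
  cohorts, 20×10,000 cells for human single-division dispersion, 200
  regression replicates of n=1000 pairs) keep every Monte Carlo standard
  error at least several-fold below the assertion tolerance.

## Known limitations

* Interval arithmetic is plain sorted half-open lists — adequate for
  colony-scale callable maps, not engineered for millions of intervals.
* VCF support is deliberately minimal (single sample, SNVs, CHROM/POS/
  REF/ALT); indels are out of scope by design.
* `detect_assignment_errors` is tuned for high-rate mutator pedigrees; at
  a handful of mutations per division the Ma/Mb-zero signatures lose
  power and the guards suppress flags rather than risk false censoring.
* The gamma-Poisson-binomial human extrapolation inherits both the
  masked-length and the X/Y-ploidy ambiguity; its values should be read
  with the stated ±10% band.
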