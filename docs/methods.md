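# Methods

This note documents the models behind each `cheatkit` stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions.

## Structural-variant window scan (`svscan`)

A read is **alternate** when its CIGAR contains a soft clip (S), hard clip
(H), insertion (I) or deletion (D), **or** when its integer SAM flag is one
of {67, 131, 115, 179, 81, 161, 97, 145, 65, 129, 113, 177} — pair
configurations (mate-unmapped, same-strand, and improper pairs) that
indicate large indels or rearrangements. The two criteria are combined as a
union, and flag matching is exact membership of the full integer value, not
bit decomposition: the scan targets those twelve specific configurations.

Coverage is per-base depth summed within non-overlapping, 0-based half-open
windows (default 100 bp) tiled from position 0. A read contributes over its
contiguous reference span including D/N gaps; I/S/H segments consume no
reference. Windows with zero total coverage have an undefined alternate
fraction and are excluded from ranking, so no division by zero occurs. No
mapping-quality filter is applied at this stage by default (`min_mapq` is
exposed): the signal of interest lives partly in low-quality clipped reads.
Secondary and supplementary alignments are excluded by default,
configurable.

The pairwise comparison emits the **full** ranked table of
|fraction_A − fraction_B| with ties broken by (contig, window start) for
determinism — the method's endpoint is a ranked list for visual
inspection, deliberately without an a priori cut-off, and without
breakpoint assembly or genotyping.

## Variant difference filter (`variant_diff`)

Call sets are indexed by (contig, position, ref, alt) after decomposing
multi-allelic records. A site absent from one sample counts as frequency 0
there, inheriting the carrying sample's depth. Thresholds (defaults:
frequency difference ≥ 0.8, depth ≥ 10) are inclusive, the common
convention. `cov_mode` selects whether depth must clear the threshold in
both samples (default) or only in the sample(s) carrying a record.
Frequency defaults to alt-supporting depth / DP (FORMAT AD), with
VarScan's percentage FREQ field and INFO AF as fallbacks; a
heterokaryon-aware report surfaces intermediate-frequency calls (0.2–0.8)
separately instead of relaxing the main filter, since a nuclear mixture
shows its variants at intermediate frequency by construction.

## Parallel-mutation test (`parallelism`)

Each of the n·m accumulated mutations is modelled as an independent draw
hitting the gene class with probability g/G. The reported p-value follows
the minimum-likelihood two-sided convention — the sum of all point
probabilities not exceeding the observed one, with a 1e-7 relative slack
for ties (the convention of the standard exact-binomial implementations);
one-sided tails are exposed. For strong enrichment the two-sided and
upper-tail values coincide, because no lower-tail outcome has smaller
likelihood. The PMF is evaluated in log space and tail sums use
log-sum-exp, keeping results exact to ~1e-300; smaller values underflow
double precision and return 0. The per-line mutation count is a user
parameter, not a constant, since it is an order-of-magnitude estimate.

## qPCR ΔCt quantification (`qpcr`)

Technical replicates (typically six) are averaged per amplicon; replicate
standard deviation above 0.5 cycles triggers a warning, and no outlier
dropping is performed. The sign convention is
ΔCt = C̄t(so) − C̄t(hygB), so positive values mean more mutant template
(the hygB amplicon crosses threshold earlier). With per-cycle efficiency E
(default 2.0, perfect doubling, matching validated primer pairs), the
template ratio is r = E^ΔCt and f_mutant = r/(1+r); the map is strictly
increasing and satisfies f(−Δ) = 1 − f(Δ) exactly. Ct values are taken as
instrument output — no amplification-curve fitting. An amplicon whose
replicates all sit at the cycle ceiling (default 40) indicates absent
template: the frequency is censored to 0 or 1 with a flag rather than
computed from E^±40.

## Plate-count deconvolution (`platecount`)

Model: +inositol plates grow inl-deficient homokaryons and heterokaryons;
+pantothenate plates grow pan-deficient homokaryons and heterokaryons;
unsupplemented plates grow heterokaryons only, which are assumed to plate
with equal efficiency on all three media. Replicate plates (typically 4 per
medium) are pooled by summing counts and volumes, an exact identity for
equal dilutions. Concentrations follow count × dilution / volume; the
subtraction estimator is c_het = c_none, c_homo = c_medium − c_none,
normalised to frequencies. Sampling noise can push a homokaryon estimate
negative; it is then clipped to zero and flagged, never silently. For noisy
counts an alternative estimator maximises the Poisson likelihood of the
three counts over non-negative class concentrations (L-BFGS-B with bounds),
which cannot produce negative classes. How colonies would be reassigned if
heterokaryons were phenotype-scored on supplemented plates is not modelled;
the subtraction design is the implemented reading.

## Fitness and equilibrium (`fitness`)

Competitive success S = f_final / f_initial uses the *realized* initial
frequency estimated from phenotype counts, not the nominal mixing ratio.
S is undefined at f_initial = 0 (error, not NaN). The frequency-dependence
fit regresses log S on f_initial by least squares; log-linear is the
default because it guarantees S > 0 and makes the S = 1 crossing a linear
root, and a quadratic option is exposed since the data cannot identify the
true functional form. The equilibrium is defined as the smallest root of
S = 1 within the observed frequency range; a fit whose curve does not
cross 1 there reports the equilibrium as absent, and a numerically flat
fit is flagged as such. The 95% band comes from a nonparametric bootstrap
over replicates (default 1000 resamples). One-sample t-tests of frequency
ratios and OLS summaries are thin wrappers over scipy/statsmodels,
provided as pipeline glue.

## Synthetic generators (`synthetic`)

Each generator is the forward model of its analysis stage and is its exact
inverse in the noise-free limit; all output is reproducible from
(config, seed).

**Alignments.** Fragments are drawn uniformly from a donor genome — the
reference with the configured deletion excised — with Gaussian insert
sizes, error-free bases and uniform coverage. Reads crossing the excision
point are written with the longer segment matched and the shorter
soft-clipped; pairs straddling it keep correct positions but lose the
proper-pair flag (97/145 vs 99/147). Defaults: 5 kb reference, 100 bp
reads, 300 bp insert, 30× depth, a 300 bp deletion at position 1000, and a
1% background soft-clip rate standing in for alignment noise. Sequencing
errors, indel-containing CIGARs beyond clips, GC bias and mappability are
not emulated — the scanner consumes only CIGAR/flag structure, so passing
tests demonstrate the windowing and ranking logic, not robustness to real
alignment artefacts. The default deletion (300 bp) exceeds the read
length, so breakpoints necessarily produce clips.

**qPCR.** Each amplicon's Ct is base_ct − log_E(template share) plus
Gaussian replicate noise (default sd 0.1 cycles, six replicates), making
the noise-free ΔCt exactly log_E(f/(1−f)). Pipetting covariance between
amplicons and efficiency drift are not modelled.

**Plating.** Each plate receives a fixed number of spores (default 400)
whose genotypes are multinomial at the true frequencies (default
0.55/0.35/0.10); a spore forms a colony iff its class is viable on the
medium. An exact mode uses expected counts, giving the round-trip
identity with the deconvolution.

**Serial transfers.** Per cycle: deterministic selection with the cheater
class weighted by S(f) = exp(b·(f* − f)) at the current cheater nuclear
frequency (heterokaryons counted half); heterokaryon formation moving
rate·2·f_c·f_w of the population into the heterokaryon class; spore yield
Y_max·(1 − d·f); then a multinomial bottleneck of 1% of the yield
(defaults: f* = 0.30, b = 3.0, rate = 0.20, Y_max = 2e8, d = 0.5, four
transfers from a 10% start). The success function is an explicitly
phenomenological stand-in chosen to produce negative frequency dependence
with a root at a configurable equilibrium; it is not derived from any
mechanistic model of mycelial architecture, and heterokaryon kinetics are
parameterised, not emergent. The bottleneck preserves expected frequency
(unbiased), which the tests verify over 1,000 seeded draws.

**Competitions.** The realized initial frequency is a binomial phenotype
count (default 300 colonies), one growth cycle multiplies the cheater's
odds by S(f), and the final frequency is again a binomial count — so the
generated S(f_initial) crosses 1 exactly at the configured root even
though the generating curve is not log-linear in f, which is what makes
equilibrium recovery a fair test of the fitting stage.

## Numerical conventions and edge cases

- Zero-coverage windows: excluded, never divided.
- Ranking ties: broken by (contig, window start) ascending.
- Binomial p-values: clamped to [0, 1]; two-sided tie slack 1e-7 relative.
- Ct at the cycle ceiling: censored frequency with flag.
- Negative plate-class estimates: clipped and flagged (subtraction mode)
  or prevented by bounds (MLE mode).
- Equilibrium outside the observed frequency range: reported absent rather
  than extrapolated.
- Degenerate t-test inputs (zero variance): error, not a silent t = 0.

## Problem sizes

The test suite and examples run on deliberately small instances: 5–8 kb
references at 30× (a few thousand reads), 20-seed ranking replications,
200–500-draw recovery experiments, and 200-dataset equilibrium
recoveries. These sizes give the binomial success criteria enough
resolution (e.g. a 90% recovery bound estimated from 200 trials) while
keeping any single check in the seconds-to-a-minute range; the algorithms
themselves are linear in reads and windows and scale to full-genome input
unchanged.

## Known limitations

- The flag list targets one library layout (paired-end, FR); other
  protocols would need a different discordance set.
- The window scan localises breakpoints only to window resolution and
  does not distinguish deletions from other rearrangements.
- The ΔCt model assumes equal, constant amplification efficiencies; the
  generalised two-efficiency ratio is available but defaults are equal.
- The plating model ignores differential germination or colony-overlap
  undercounting at high density.
- The transfer simulator's S(f) is phenomenological; conclusions about
  mechanism cannot be read off its trajectories.
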