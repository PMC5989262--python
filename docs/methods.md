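# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and the
design decisions taken where the underlying procedures were genuinely open.

## Flow-cytometry model and peak calling

Events carry a fluorescence pulse integral (FL, linear 0–1023 channels),
pulse height, side/forward scatter (log-scale) and acquisition time. The
processing chain is:

1. **Gating** — a rectangular region of interest in FL × SSC retains intact
   nuclei. Gate coordinates are acquisition-dependent and therefore
   parameters, not inferences; the default FL floor of channel 20 removes the
   exponential low-channel debris tail.
2. **Doublet discrimination** — a doublet carries twice the pulse integral at
   an essentially unchanged pulse height, so events with
   `FL / pulse_height > max_ratio` are removed. The adaptive default is
   1.5 × the median ratio of the sample, which sits between the singlet ratio
   and its doubled value for any plausible doublet fraction.
3. **Peak calling** — nuclei subpopulations on FL are modelled as a 1-D
   Gaussian mixture, fitted for 1–6 components with BIC selection.
   Initialisation is fully explicit (means at data quantiles, uniform
   weights, a common within-component variance), so the fit is deterministic
   given the data; no random restarts are used. Components closer than a
   10% mean ratio are moment-matched merged; components under 2% of gated
   events or broader than 20% CV are dropped. A featureless signal is
   rejected by comparing the mixture BIC against a uniform-background BIC —
   without this check a uniform FL stream yields spurious narrow
   high-channel components.
4. **Standard identification** — the internal reference standard (tomato,
   2C = 1.96 pg) is acquired at channel 720; the peak nearest that channel
   within a 15% relative tolerance is the standard. Genome size is then the
   linear rescaling `sample_mean / standard_mean × 1.96 pg`.
5. **G2 labelling** — a peak at twice another peak's mean (7% relative
   tolerance) whose proportion is at most 25% of its partner's is a
   G2-phase population and is excluded from genome-size reporting. The
   proportion condition is what separates a G2 pair from a genuine mixoploid
   (e.g. 2x/4x) whose two populations are comparably abundant; the
   threshold is configurable because no quantitative rule exists in the
   literature for these blades. One practical extension proved necessary:
   in mixoploid samples BIC occasionally fuses the two *small* G2 companions
   of adjacent G1 peaks into a single component lying between their doubled
   channels; a minor peak inside `[2·m_i, 2·m_j]` for adjacent peaks i, j is
   therefore also labelled G2 (condition: proportion ≤ 25% of the smaller
   partner's). Without it, 3x/4x blades sporadically gain a phantom peak
   near 0.7 pg.
6. **QC** — peak CVs must stay below 5% and, when an isolate is measured
   repeatedly, the between-replicate CV of the genome-size estimate below
   6%. These cutoffs are configurable defaults in line with good
   plant-flow-cytometry practice, not published thresholds.

Input formats are CSV event tables and CSV histograms. FCS parsing is out of
scope: the package targets exported event tables.

## Ploidy grid and cytotype classification

Genome sizes form a near-arithmetic grid. `calibrate_base` pools all gamete
section sizes, takes the lowest single-linkage cluster (a new cluster starts
at a 1.25× gap between consecutive sorted sizes) and anchors its median at
ploidy 2x — gametes display two or more alleles per locus, ruling out
haploidy. `assign_ploidy` rounds `size / unit` to the nearest integer and
accepts the call when the deviation from the grid point is within
`rel_tol × size`. The default `rel_tol = 0.15` accommodates the observed
deviation of population means from the grid (up to about 10% in tetraploids)
while still rejecting half-grid sizes.

Cytotypes follow fixed decision rules on section ploidies: two vegetative G1
ploidies → mixoploid (2x/3x → C5, 3x/4x → C6, 2x/4x → C7, group 3);
vegetative 3x → C1 if all gametes are 3x else C3; vegetative 4x → C2 if all
gametes are 4x else C4 (groups 1 and 2 respectively). A purely 2x vegetative
blade is left unclassified with an explicit reason — no such blade has been
observed and the call most likely indicates a miscalibration. Zygotospores
are always twice the highest vegetative ploidy (3x → 6x, 4x → 8x, mixoploids
double the higher line). Cell lines: {2,4,8,12}x → line 1, {3,6,9}x → line 2
(9x and 12x are triplicated 3x and 4x gametes). Multiploid (Mp) gametes are
called only when a gamete section contains a ploidy together with its triple
(e.g. 3x with 9x): a {p, 2p} pair alone is indistinguishable from a G1/G2
doublet, whereas the observed Mp sets always include the 3p multiple.
Blades whose only evidence is a gamete or zygotospore section are not forced
into C1–C7; they remain explicitly unclassified and join the heterogeneous
analysis groups via their ploidy signature.

Cytotype incidence is reported over classified blades, with percentages at
one decimal.

## Allele-frequency estimation under dosage ambiguity

A polyploid genotype exposes, per locus, only its allele *set*. Two
estimators are provided:

- **Naive (phenotype) frequencies** — each individual's distinct alleles
  receive equal weight summing to 1; the group frequency is the mean over
  scored individuals. Simple, assumption-free, biased toward rare alleles.
- **Maximum likelihood (EM dosage correction)** — assumes polysomic
  inheritance: an individual of ploidy *m* carries *m* independent draws
  from the group frequencies, and the observation is the exact set of
  distinct alleles. The E-step computes the expected dosage of each shown
  allele conditional on the observed set via inclusion–exclusion over missed
  subsets (sets have at most ~6 alleles, so the 2^|S| terms are trivial);
  the M-step renormalises expected counts. Initialisation is uniform over
  observed alleles, convergence is declared at max|Δp| < 1e-8 (default) or
  1000 iterations, and the log-likelihood is non-decreasing by construction
  of EM (asserted in tests). The tests also check the EM optimum against an
  independent brute-force grid search whose likelihood enumerates dosage
  compositions explicitly.

The exact internals of other dosage-correcting software are not published in
a reimplementable form; results may diverge in the third decimal on small
groups.

## Diversity and differentiation

Per locus: `Num` is the pooled allele count, `Eff_num = 1/Σp²` the effective
number of alleles. Gene diversities use Nei & Chesser-style small-sample
corrections with ñ the harmonic mean sample size across the k groups:

    Hs = ñ/(ñ−1) · (1 − mean_g Σ_a p²_ga)
    Ht = 1 − Σ_a p̄²_a + Hs/(ñ·k)        (p̄ the unweighted group mean; k ≥ 2)

**Choice of sampling unit.** The correction must match the sampling model of
the frequency estimator. For EM dosage-corrected frequencies the sampled
units are gene copies — each individual contributes ploidy-many draws — so ñ
counts gene copies (sum of ploidies of scored individuals). Using individuals
there inflates Hs by ~12% at group sizes of 7–15 and depresses pairwise G_ST
by ~0.04, which simulation at the survey group sizes confirms (estimates
0.226 vs a constructed 0.27 with individual-based ñ; 0.264 with gene-copy ñ).
For naive phenotype frequencies the individual *is* the sampled unit and ñ
counts individuals. Negative differentiation estimates, a normal consequence
of the unbiased corrections near zero differentiation, are reported as
computed, never truncated.

Multi-locus combination averages Hs and Ht over loci first and applies the
statistic to the means (per-locus values are retained in the output);
pairwise Jost's D uses k = 2. Groups with fewer than two members are flagged;
pairs with no shared scored locus are reported missing.

Missing loci are imputed per analysis group by drawing, with replacement,
from the group's observed allele pool at that locus; the number of draws is
the group's modal distinct-allele count there (the true dosage being
unknowable, the modal phenotype size is the least-informative reproducible
choice). Imputation is seeded and deterministic.

Individual-level structure uses the allele-sharing distance
`1 − |A∩B| / max(|A|,|B|)` averaged over co-scored loci (the literature does
not pin down a specific individual distance for polyploid phenotypes; the
interface accepts alternatives), neighbour joining (Saitou–Nei, via
scikit-bio; exact on additive matrices), and a PCA of mean-centred
allele-presence indicators with each axis oriented so its first non-zero
loading is positive.

## Synthetic cohorts and the survey stand-in

`SimConfig` defaults encode the study conditions: 0.1 pg per chromosome-set
equivalent (0.2 pg at 2x), tomato standard at channel 720, ~2,000 events per
sample, 4% peak CV, 10% debris, 8% G2 fraction, 20% standard fraction, 11
microsatellite loci (alternating di-/tri-nucleotide repeats, six alleles per
locus), 5% missing data. Mixoploid vegetative samples mix their two cell
lines 50/50 (the true mixing proportion is unreported); same-ploidy gametes
are the most frequent gamete pattern, and multiploid gamete sections carry
{p, 2p, 3p} at weights 0.5/0.3/0.2.

Lineage allele pools are mirrored two-allele mixtures with a shared tail:
alleles 1–2 carry mass 0.75 split (q, 1−q) / (1−q, q), the remaining four
alleles share 0.25 uniformly; q is solved (Brent) so the parametric
G_ST = (Ht−Hs)/Ht of the two pools equals the configured target, and the
mixoploid pool is the convex combination of the two lineage pools hitting its
own target against the 3x pool. Species receive disjoint allele ranges, which
yields the strong between-species structure visible in the PCA.

`study_cohort` fixes the composition to the published survey design — 122
blades (47/35/40 by species) whose sections sum to 217 flow analyses
(71/69/77), per-species cytotype counts consistent with the printed incidence
percentages (P. linearis 15/7/2/16 over 40 classified blades; P. umbilicalis
14/6/13/2 over 35; P. dioica 13/1/17 over 31 classified, its other 9 blades
being zygotospore-/gamete-only samples), and 121 genotypes in the 19
(species × ploidy-signature) groups, with P. linearis lineage pools at
G_ST 0.27 (3x vs 4x) and 0.17 (3x vs 3x/4x mixoploids). It is a synthetic
stand-in for the deposited raw datasets, not those data: composition is
deterministic, and the seed drives only allele draws, missing-data masks and
flow events.

What the generator does **not** emulate: S-phase nuclei between G1 and G2,
non-Gaussian peak asymmetries, spectral spillover, stutter and null alleles,
linkage between loci, mutation, and any spatial/sectorial structure of
mixoploid blades. Tests passing on synthetic cohorts therefore demonstrate
the correctness and calibration of the estimators under the stated model,
not robustness to every artefact of real acquisitions.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; per-sample event streams are
seeded from (cohort seed, stream index), so cohorts are bit-reproducible and
pipeline reruns byte-identical. The test suite runs the full 217-sample
stand-in once (shared fixture), averages the P. linearis differentiation over
six seeds, and checks G_ST recovery at targets {0.05, 0.15, 0.25} over 50
seeds with 20 loci and 30 tetraploids per group — sizes chosen to keep the
whole suite under a few minutes on one CPU while leaving Monte-Carlo error
well below the tolerances tested.

## Known limitations

- Peak calling assumes Gaussian G1 populations on a linear scale; heavily
  skewed or drifting acquisitions need upstream correction.
- The EM assumes fully polysomic inheritance and independent loci; partial
  preferential pairing in allopolyploids would bias dosage expectations.
- Diversity corrections treat groups as equal-weight populations; no
  hierarchical (region/population) partition is modelled.
- Bayesian ancestry/admixture inference and Hardy–Weinberg or linkage tests
  are out of scope (established external tools cover them).
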