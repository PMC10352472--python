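# Methods

## Problem setting

Couples carrying pathogenic alleles of a monogenic disease gene (autosomal
recessive, e.g. *GJB2*/*SLC26A4* hearing loss, or autosomal dominant) can
avoid transmitting the disorder by genetic testing of day-5 blastocyst
biopsies before transfer. The biopsy (3–5 trophectoderm cells) is
whole-genome amplified; amplification noise — strong allele imbalance and
occasional all-or-none allele dropout (ADO) — makes a genotype call at the
variant site alone unsafe. The pipeline therefore combines three readouts
per embryo: the direct variant-site genotype, linkage over a flanking SNP
scaffold, and a genome-wide read-count aneuploidy screen.

## Marker panel and phasing

Markers within `window_bp` (1 Mb, boundary-inclusive, distance to the
nearer gene edge) of the gene with minor-allele frequency above `maf_min`
(0.1) qualify; up to `panel_target` (90) are kept. The stated marker
criterion of the source procedure is a *major*-allele frequency above 0.1,
which is vacuous as printed (a major allele has frequency ≥ 0.5); we read
it as the standard MAF > 0.1 informativeness filter. When more than 90
markers qualify, the ±1 Mb window is divided into 90 equal positional
slots and the highest-MAF marker per slot is kept (topping up by global
MAF rank): the count is fixed but the choice rule is ours; positional
spreading protects against recombination blind spots.

Phasing is pure pedigree logic (no population/statistical phasing). With
an affected child: at each marker where the parent is heterozygous and the
trio genotypes uniquely identify the transmitted allele, that allele is
assigned to the parent's mutant-linked haplotype M, because the affected
child necessarily received M from every carrier parent. With grandparents
(couples without children): the grandparent carrying the parent's variant
identifies the M lineage, and a marker is phased when the grandparental
genotypes uniquely resolve which parental allele came from that lineage.
Mendelian-impossible markers are tolerated as genotyping error up to
`max_mendelian_error_rate` (2%) of assessed markers; beyond that the
family errors out as a suspected sample swap. At 90 markers with MAF
uniform on (0.1, 0.5), roughly 25–35 markers per parent are informative,
consistent with the 14–54 per family observed clinically (real panels
have linkage disequilibrium, which lowers the yield; the simulator draws
markers independently).

## Genotype calling

Sites under `low_depth_min` (100×) total coverage are *low depth* and
never genotyped. Above it, the allele fraction f = depth_b/total is cut
at `hom_af_max` (0.10) for homozygotes and [`het_af_low`, `het_af_high`]
= [0.20, 0.80] for heterozygotes; fractions between the bands give no
call. The wide het band and the gap are deliberate: amplified single-cell
material shows heavy allele imbalance, and a 0.10–0.20 fraction is as
likely a skewed heterozygote as a homozygote, so we abstain. The source
procedure fixes only the 100× rule; the cutpoints are this package's
convention.

## Linkage diagnosis and ADO

Each informative marker votes M or N by subtracting the other parent's
possible contribution from the embryo genotype; ambiguous or impossible
configurations vote indeterminate. The inheritance call requires
`min_informative_per_parent` (3) determinate votes and concordance at
least `vote_concordance_min` (0.8). A single discordant vote is site-level
error/ADO (logged, not fatal); a terminal run of ≥ 2 consecutive
discordant votes is a meiotic crossover — the block is excluded, the
breakpoint interval reported, and if it overlaps the gene the transmission
is indeterminate (the haplotype at the locus itself is then unknown). With
a tied vote and a single clean switch, the gene-side votes decide.

Reconciliation with the direct verdict: agreement confirms; a determinate
linkage call overrides a variant-site genotype whose mismatch is
explainable as one allele of an expected heterozygote dropping out,
recording an ADO event (`rescued_by_linkage` when the pathogenic allele
dropped, `non_mutant_allele_dropout` when the wild-type allele did — the
latter does not change the diagnosis); when linkage is uninformative an
unambiguous direct verdict stands alone; every other conflict is
indeterminate. The safety asymmetry is deliberate and absolute: errors
become abstentions, never transferable calls. A verdict driven into
indeterminacy by an unresolvable conflict carries `basis=None`, since none
of the four evidence bases applies.

The ADO *rate* uses the clinical denominator: one assay = one variant-site
PCR/sequencing per embryo; panel-SNP dropouts are handled by the voting
logic but excluded from the rate.

## Copy-number screen

1 Mb bins; the last bin of each chromosome is length-scaled; bins with GC
outside [0.2, 0.8] are masked. GC correction scales each bin by
(global median)/(1%-GC-bucket median), with buckets of fewer than 10 bins
left unscaled. Copy number is 2 × count/median(autosomal counts), making
the profile invariant to total depth. Calls per chromosome mean:
≥ `gain_cn_min` (2.65) gain, ≤ `loss_cn_max` (1.35) loss, (1.35, 1.7) and
(2.3, 2.65) mosaic. Segmentation is deterministic run-merging of
out-of-band bins (bridging single-bin gaps), reporting only segments ≥
`cnv_report_min_bp` (4 Mb) — matched to the visual-inspection resolution
of a 1 Mb binned profile; no CBS/HMM. The cn thresholds separate full,
mosaic and noise regimes at ~500 reads/bin Poisson noise (cn
σ ≈ 0.09/bin, ≈ 0.01/chromosome mean), giving effectively complete
whole-chromosome sensitivity and specificity at 1.5 M reads. QC:
< 200,000 total reads → amplification failure; ≥ 5 abnormal autosomes →
multi-chromosome abnormality (broken-cell signature); MAPD (median
absolute difference of consecutive bin cn) > 0.45 → contamination/noise.
Category precedence: amplification failure > contaminated >
multi-abnormal > aneuploid/mosaic > euploid. X is normalized against the
autosomal median and reported descriptively only; no sex inference.

## Final classification and cohort statistics

A monogenic *affected* finding is reported as affected regardless of
karyotype (it is the indication for testing); QC-failed screens and
indeterminate verdicts are inconclusive; chromosome abnormalities are
aneuploid; only euploid embryos with a determinate non-affected verdict
are transferable, wild type ranked before carrier. Heterozygous carriers
of a recessive allele are phenotypically unaffected and transferable once
wild-type embryos are exhausted.

Cohort rates use the clinical denominators: pregnancy and miscarriage per
transfer, live birth per started cycle, aneuploidy/inconclusive/
transferable per biopsied embryo, wild-type and carrier shares per
transferable embryo of recessive couples, ADO per assay. A zero
denominator yields an absent rate, not 0. The bundled cohort table is a
row-level transcription of a 47-couple clinical study; its column sums
are internally consistent with the printed totals (340 embryos, 54
cycles, 114 transferable, 59 transfers, 38 pregnancies), so all rates are
computed from the rows. One row records no clinical pregnancy alongside a
live-birth outcome; it is transcribed verbatim and flagged
(`pregnancy_outcome_inconsistent`), with the printed cells (no pregnancy)
used in totals.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the diagnosis relies
on: markers uniform over the ±1 Mb window with MAF ~ U(0.1, 0.5); parental
haplotypes drawn from allele frequencies with the pathogenic allele
anchored on M; transmission as a two-state walk with switch probability
`recomb_prob_per_mb` (0.01) per Mb (affected reference children are
conditioned to carry M at the variant site by anchoring the walk there);
per-site depth as a gamma-Poisson (negative-binomial) mixture with mean
300× and dispersion 0.15; heterozygote allele split Beta-binomial
(imbalance SD 0.08); ADO drawn per assay at `ado_prob` = 0.028, all or
none, logged as a truth event on variant sites regardless of zygosity and
altering the observed genotype only at heterozygotes (matching the
clinical assay-level accounting of 2.8%). Bin counts are multinomial over
1.5 M reads with expected weight ∝ bin length × copy number × a smooth
exponential GC-bias curve over a synthetic (deterministic, 0.30–0.60) GC
track; contamination is modeled as heavy per-bin lognormal weight noise
— foreign or degraded template — which the MAPD flag detects (a clean
50:50 mixture of two diploid genomes would be indistinguishable from
diploid in read counts alone). Cohorts draw aneuploidy at 0.382 and
amplification failure at 0.009 per embryo.

Not emulated: linkage disequilibrium between markers (informative yields
run slightly high), chimeric/partial ADO and preferential amplification
beyond the genotype cutpoints, real genome GC content, base-level
sequencing error, and embryo mosaicism as distinct cell populations
(mosaic events are simulated as intermediate copy number directly).
Passing simulation tests therefore demonstrates the logic and its noise
robustness under these assumptions, not performance on any particular
clinical dataset.

## Numerical and problem-size choices

Everything is seed-deterministic (`numpy.random.default_rng`). Ties in
panel-slot selection break toward the lower position; chromosome order is
natural (1–22, X); votes are position-ordered with insertion order as a
fallback when positions are absent. Simulation-based checks use 100
embryos per inheritance configuration at zero noise, 20 families × 25
embryos at clinical noise, 5,000 assays (50,000 in the acceptance script)
for dropout-rate recovery, and 100 seeds for trisomy detection — sizes at
which the binomial uncertainty of each estimate is comfortably below the
bands being checked.

## Known limitations

Same-variant recessive families cannot be origin-resolved by direct
testing (handled via linkage); double crossovers inside the window and
crossovers between the variant site and a terminal marker block are
beyond the ±1 Mb design's resolution; mosaicism percentages are not
estimated beyond the copy-number value; the Mendelian-error tolerance
(2%) is a heuristic for WGA noise, not a calibrated error model.
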