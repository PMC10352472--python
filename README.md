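# pgtdx

Linkage-based preimplantation genetic testing (PGT) for monogenic disease,
with simultaneous aneuploidy screening — the analysis pipeline used to
select unaffected, euploid embryos for couples at risk of transmitting a
recessive or dominant disorder (the motivating application is hereditary
hearing loss caused by *GJB2* and *SLC26A4* variants).

A single low-depth sequencing run of a whole-genome-amplified trophectoderm
biopsy yields two readouts per embryo, and `pgtdx` implements both arms plus
their combination:

- **PGT-M (monogenic).** A panel of up to 90 SNPs with minor-allele
  frequency > 0.1 within 1 Mb of the disease gene is phased onto each
  carrier parent's mutant-linked (M) versus normal (N) haplotype using an
  affected child or the grandparents. Each embryo's inherited haplotype is
  called by majority vote over the informative markers and reconciled with
  the direct genotype at the familial variant site(s). Allele dropout (ADO)
  — whole-genome amplification losing one allele of a heterozygote, at
  roughly 2.8% per assay — is detected as a direct/linkage mismatch and
  rescued when a single-allele loss explains it; any unexplained conflict
  yields an *indeterminate* verdict, never a transferable call.
- **PGT-A (aneuploidy).** Reads are counted in 1 Mb genomic bins
  (~1.5 M reads per embryo), GC-corrected per 1% GC bucket
  (count × median/bucket-median), converted to copy number
  cn = 2·count/median(autosomal counts), and thresholded into
  whole-chromosome gains/losses, mosaic calls, and segmental CNVs of at
  least 4 Mb, with QC categories for multi-chromosome abnormality,
  contamination (MAPD noise metric) and amplification failure.
- **Classification and cohort statistics.** Verdict × karyotype →
  transferable (wild type preferred over carrier), affected, aneuploid or
  inconclusive; cycle-level tables aggregate into the clinical outcome
  rates (pregnancy per transfer, live birth per cycle, …).
- **Synthetic data.** `pgtdx.simulate` generates SNP banks, families with
  known truth haplotypes, embryos with recombination/depth/ADO noise,
  binned read counts under arbitrary karyotypes, and whole cohorts — so
  every stage is testable end to end without any external data.

## Worked example

```sh
python examples/diagnose_family.py
```

```
family SIM09449: SLC26A4 (AR), maternal c.2168A>G / paternal c.697G>C
panel of 90 SNPs -> informative: father 30, mother 27
  E1: carrier_paternal       basis=ado_rescued, 1 ADO  (truth: carrier_paternal)
  E2: carrier_paternal       basis=concordant  (truth: carrier_paternal)
  E3: carrier_maternal       basis=concordant  (truth: carrier_maternal)
  E4: affected               basis=concordant  (truth: affected)
  ...
```

Of the 90-SNP panel, 30 paternal and 27 maternal markers are informative
(parent heterozygous, phase resolved by the affected child). Embryo E1's
variant-site genotype conflicted with the linkage vote in a way explainable
by one allele dropping out, so the diagnosis was rescued by linkage
(`basis=ado_rescued`); every verdict matches the generating truth.

Other examples: `ado_worked_case.py` (the classic hom-alt-at-one-site
dropout rescue), `aneuploidy_screen.py` (euploid / trisomy 16 / terminal 1q
mosaic profiles), `cohort_statistics.py` (the bundled 47-couple clinical
cohort: 340 embryos, 33.5% transferable, 38.2% aneuploid, 64.4% clinical
pregnancy per transfer, 61.1% live birth per cycle).

A thin CLI mirrors the pipeline stages
(`pgtdx simulate|phase|diagnose|cnv|classify|cohort-stats`); see
`pgtdx --help`.

## Layout

- `src/pgtdx/` — library (`model`, `io`, `panel`, `phasing`, `genotyping`,
  `linkage`, `cnv`, `classify`, `simulate`, `datasets`, `cli`)
- `docs/methods.md` — model assumptions, thresholds and design choices
- `examples/` — one narrative script per capability
- `tests/` — unit, property and end-to-end acceptance tests
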