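"""Copy-number screen of three simulated biopsies at 1.5 M reads.

Bin counts are GC-corrected in 1% buckets, normalized to copy number
against the autosomal median, and thresholded into whole-chromosome and
segmental (>= 4 Mb) calls.  Shown: a euploid embryo, a trisomy-16 embryo
and a terminal 1q mosaic deletion.
"""

from pgtdx import analyze_bins
from pgtdx.simulate import KaryotypeEvent, KaryotypeSpec, simulate_bin_counts

scenarios = {
    "euploid": KaryotypeSpec(),
    "trisomy 16": KaryotypeSpec(events=[KaryotypeEvent("gain", "16", cn=3.0)]),
    "del(1q) mosaic": KaryotypeSpec(events=[KaryotypeEvent(
        "segment", "1", cn=1.5, start=145_000_000, end=249_250_621)]),
}

for name, spec in scenarios.items():
    bins = simulate_bin_counts(spec, seed=5)
    res = analyze_bins(bins)
    print(f"{name}: category={res.category}, MAPD={res.mapd:.3f}")
    for chrom in res.abnormal_autosomes:
        print(f"   chr{chrom}: mean cn {res.chrom_cn[chrom]:.2f} "
              f"-> {res.chrom_calls[chrom]}")
    for seg in res.segmental_cnvs:
        print(f"   chr{seg.chrom}:{seg.start}-{seg.end} "
              f"({seg.size_bp / 1e6:.0f} Mb) cn {seg.cn:.2f} -> {seg.type}")
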