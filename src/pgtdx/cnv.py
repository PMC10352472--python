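"""Low-depth read-count aneuploidy screen (PGT-A).

Reads per 1 Mb genomic bin are GC-corrected in 1%-GC buckets, normalized
to copy number against the autosomal median, and thresholded into
whole-chromosome calls (gain / loss / mosaic), segmental CNVs of at least
4 Mb, and quality categories (multi-chromosome abnormality, contamination
by the MAPD noise metric, amplification failure).  Segmentation is simple
run-merging on thresholded bins -- deterministic and matched to the 1 Mb
visual-inspection resolution of the underlying clinical procedure.

X is normalized against the autosomal median and reported descriptively;
it never contributes to the multi-abnormal count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import AUTOSOMES, chrom_sort_key
from .model import BinRecord, Thresholds


@dataclass
class SegmentalCnv:
    chrom: str
    start: int
    end: int
    cn: float
    type: str  # gain | loss | mosaic_gain | mosaic_loss

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class ChromResult:
    """Chromosome screen result for one embryo biopsy."""

    chrom_cn: dict = field(default_factory=dict)       # chrom -> mean cn
    chrom_calls: dict = field(default_factory=dict)    # chrom -> call
    segmental_cnvs: list = field(default_factory=list)
    qc: dict = field(default_factory=lambda: {
        "amplification_failure": False, "multi_abnormal": False,
        "contaminated": False, "noisy": False,
    })
    mapd: float | None = None
    total_reads: float = 0.0
    category: str = "euploid"

    @property
    def abnormal_autosomes(self) -> list:
        return [c for c, call in self.chrom_calls.items()
                if call != "euploid" and c in AUTOSOMES]


def _copy(bins):
    return [BinRecord(b.chrom, b.start, b.end, b.gc_fraction, b.raw_count,
                      b.corrected_count, b.cn, b.masked) for b in bins]


def gc_correct(bins, thresholds: Thresholds | None = None) -> list:
    """Scale each bin's count by (global median) / (its 1%-GC-bucket median).

    The last, shorter bin of a chromosome is length-scaled first so all
    counts are per full bin width.  Bins with GC outside the reliable range
    are masked and excluded from all statistics.  Buckets with fewer than
    ``gc_bucket_min_bins`` members fall back to a factor of 1 (too few bins
    to estimate a bucket median).
    """
    thr = thresholds or Thresholds()
    out = _copy(bins)
    lo, hi = thr.gc_mask_range
    scaled = np.array([b.raw_count * (thr.bin_size_bp / b.length) for b in out])
    gc = np.array([b.gc_fraction for b in out])
    mask = (gc < lo) | (gc > hi)
    for b, m in zip(out, mask):
        b.masked = bool(m)
    usable = ~mask
    if not usable.any() or np.nanmedian(scaled[usable]) == 0:
        for b, s in zip(out, scaled):
            b.corrected_count = float(s)
        return out
    global_median = float(np.median(scaled[usable]))
    buckets = np.floor(gc * 100.0 / thr.gc_bucket_width).astype(int)
    factors = np.ones(len(out))
    for bucket in np.unique(buckets[usable]):
        sel = usable & (buckets == bucket)
        if sel.sum() < thr.gc_bucket_min_bins:
            continue
        med = float(np.median(scaled[sel]))
        if med > 0:
            factors[sel] = global_median / med
    for b, s, f in zip(out, scaled, factors):
        b.corrected_count = float(max(s * f, 0.0))
    return out


def copy_number(bins) -> list:
    """cn = 2 x corrected_count / median corrected autosomal count.

    The scaling makes the profile invariant to sequencing depth; the
    autosomal median anchors the diploid baseline at cn = 2.
    """
    out = _copy(bins)
    corrected = np.array([
        b.corrected_count if b.corrected_count is not None else np.nan for b in out
    ])
    autosomal = np.array([
        (not b.masked) and b.chrom.removeprefix("chr") in AUTOSOMES for b in out
    ])
    if not autosomal.any():
        raise ValueError("no usable autosomal bins")
    baseline = float(np.nanmedian(corrected[autosomal]))
    if baseline <= 0:
        raise AmplificationFailure("autosomal median corrected count is zero")
    for b, c in zip(out, corrected):
        b.cn = float(max(2.0 * c / baseline, 0.0)) if not b.masked else None
    return out


class AmplificationFailure(ValueError):
    """Too little usable signal to estimate copy number."""


def _classify_cn(cn: float, thr: Thresholds) -> str:
    (lo_lo, lo_hi), (hi_lo, hi_hi) = thr.mosaic_band
    if cn >= thr.gain_cn_min:
        return "gain"
    if cn <= thr.loss_cn_max:
        return "loss"
    if hi_lo < cn < hi_hi:
        return "mosaic_gain"
    if lo_lo < cn < lo_hi:
        return "mosaic_loss"
    return "euploid"


def call_chromosomes(bins, thresholds: Thresholds | None = None):
    """Whole-chromosome calls from per-chromosome mean copy number."""
    thr = thresholds or Thresholds()
    sums: dict = {}
    for b in bins:
        if b.masked or b.cn is None:
            continue
        chrom = b.chrom.removeprefix("chr")
        s, n = sums.get(chrom, (0.0, 0))
        sums[chrom] = (s + b.cn, n + 1)
    cn_means = {c: s / n for c, (s, n) in sums.items() if n > 0}
    calls = {c: _classify_cn(v, thr) for c, v in cn_means.items()}
    return cn_means, calls


def call_segments(bins, thresholds: Thresholds | None = None) -> list:
    """Segmental CNVs: merged runs of out-of-band bins of at least 4 Mb.

    A bin joins a run when its cn leaves the euploid band on the gain side
    (above the mosaic-gain floor) or the loss side (below the mosaic-loss
    ceiling); runs on the same side separated by a single in-band bin are
    merged.  Only segments of at least ``cnv_report_min_bp`` are reported.
    """
    thr = thresholds or Thresholds()
    (_, lo_hi), (hi_lo, _) = thr.mosaic_band
    segments = []
    by_chrom: dict = {}
    for b in bins:
        if b.masked or b.cn is None:
            continue
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        cbins = sorted(by_chrom[chrom], key=lambda b: b.start)
        sides = ["gain" if b.cn >= hi_lo else ("loss" if b.cn <= lo_hi else None)
                 for b in cbins]
        runs = _merge_runs(sides)
        for side, i0, i1 in runs:
            seg_bins = [cbins[i] for i in range(i0, i1 + 1)
                        if sides[i] == side]
            mean_cn = float(np.mean([b.cn for b in seg_bins]))
            seg = SegmentalCnv(chrom=chrom, start=cbins[i0].start,
                               end=cbins[i1].end, cn=mean_cn,
                               type=_segment_type(mean_cn, thr))
            if seg.size_bp >= thr.cnv_report_min_bp:
                segments.append(seg)
    return segments


def _segment_type(cn: float, thr: Thresholds) -> str:
    call = _classify_cn(cn, thr)
    if call == "euploid":
        # mean pulled toward 2 by merged gap bins; side decides
        return "mosaic_gain" if cn > 2.0 else "mosaic_loss"
    return call


def _merge_runs(sides):
    """Maximal same-side runs, bridging single None gaps."""
    runs = []
    i = 0
    n = len(sides)
    while i < n:
        if sides[i] is None:
            i += 1
            continue
        side = sides[i]
        j = i
        last_same = i
        while j + 1 < n:
            nxt = sides[j + 1]
            if nxt == side:
                j += 1
                last_same = j
            elif nxt is None and j + 2 < n and sides[j + 2] == side:
                j += 2
                last_same = j
            else:
                break
        runs.append((side, i, last_same))
        i = last_same + 1
    return runs


def qc_flags(bins, cn_means, calls, segments,
             thresholds: Thresholds | None = None) -> ChromResult:
    """Assemble QC flags and the final screen category.

    Category precedence: amplification failure > contamination (MAPD noise)
    > multi-chromosome abnormality > aneuploid / mosaic > euploid.
    """
    thr = thresholds or Thresholds()
    res = ChromResult(chrom_cn=cn_means, chrom_calls=calls,
                      segmental_cnvs=segments)
    res.total_reads = float(sum(b.raw_count for b in bins))
    res.mapd = mapd(bins)
    if res.total_reads < thr.min_total_mapped_reads:
        res.qc["amplification_failure"] = True
    if res.mapd is not None and res.mapd > thr.mapd_max:
        res.qc["noisy"] = True
        res.qc["contaminated"] = True
    if len(res.abnormal_autosomes) >= thr.multi_abnormal_chrom_min:
        res.qc["multi_abnormal"] = True

    if res.qc["amplification_failure"]:
        res.category = "amplification_failure"
    elif res.qc["contaminated"]:
        res.category = "contaminated"
    elif res.qc["multi_abnormal"]:
        res.category = "multi_abnormal"
    else:
        full = [c for c in res.abnormal_autosomes
                if res.chrom_calls[c] in ("gain", "loss")]
        mosaic_chrom = [c for c in res.abnormal_autosomes
                        if res.chrom_calls[c] in ("mosaic_gain", "mosaic_loss")]
        full_segs = [s for s in res.segmental_cnvs if s.type in ("gain", "loss")]
        mosaic_segs = [s for s in res.segmental_cnvs
                       if s.type in ("mosaic_gain", "mosaic_loss")]
        if full or full_segs:
            res.category = "aneuploid"
        elif mosaic_chrom or mosaic_segs:
            res.category = "mosaic"
        else:
            res.category = "euploid"
    return res


def mapd(bins) -> float | None:
    """Median absolute pairwise difference of consecutive bin cn values."""
    diffs = []
    prev = None
    for b in bins:
        if b.masked or b.cn is None:
            prev = None
            continue
        if prev is not None and prev.chrom == b.chrom:
            diffs.append(abs(b.cn - prev.cn))
        prev = b
    return float(np.median(diffs)) if diffs else None


def analyze_bins(raw_bins, thresholds: Thresholds | None = None) -> ChromResult:
    """Full screen: GC correction, copy number, calls, segments, QC."""
    thr = thresholds or Thresholds()
    total = float(sum(b.raw_count for b in raw_bins))
    if total < thr.min_total_mapped_reads:
        res = ChromResult()
        res.total_reads = total
        res.qc["amplification_failure"] = True
        res.category = "amplification_failure"
        return res
    corrected = gc_correct(raw_bins, thr)
    try:
        with_cn = copy_number(corrected)
    except (AmplificationFailure, ValueError):
        res = ChromResult()
        res.total_reads = total
        res.qc["amplification_failure"] = True
        res.category = "amplification_failure"
        return res
    cn_means, calls = call_chromosomes(with_cn, thr)
    # suppress redundant full-length segments on chromosomes already called
    # as whole-chromosome events
    whole = {c for c, call in calls.items() if call != "euploid"}
    segments = [s for s in call_segments(with_cn, thr)
                if s.chrom.removeprefix("chr") not in whole]
    return qc_flags(with_cn, cn_means, calls, segments, thr)


def plot_profile(bins, path, title: str = ""):
    """Genome-wide cn-per-bin scatter (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs, ys, ticks, labels = [], [], [], []
    offset = 0
    by_chrom: dict = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        cbins = [b for b in by_chrom[chrom] if not b.masked and b.cn is not None]
        for b in cbins:
            xs.append(offset + b.start)
            ys.append(b.cn)
        if cbins:
            ticks.append(offset + cbins[len(cbins) // 2].start)
            labels.append(chrom)
            offset += cbins[-1].end
    fig, ax = plt.subplots(figsize=(14, 3.5))
    ax.scatter(xs, ys, s=2)
    ax.axhline(2.0, color="grey", lw=0.5)
    ax.set_ylim(0, 4.5)
    ax.set_xticks(ticks, labels, fontsize=6)
    ax.set_ylabel("copy number")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
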