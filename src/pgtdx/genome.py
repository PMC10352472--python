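"""Static genome scaffold: GRCh37 chromosome lengths, gene regions and a
synthetic GC track.

The copy-number screen only needs chromosome extents and a per-bin GC
fraction.  Lengths are the GRCh37 primary-assembly values for the autosomes
and X.  The GC track is synthetic (a smooth deterministic curve spanning the
realistic 0.3-0.6 range) so that GC-bias correction is exercised without any
reference download; it is a stand-in for real genome GC content.
"""

from __future__ import annotations

import numpy as np

# GRCh37 primary assembly lengths (bp), autosomes then X.
CHROM_LENGTHS = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560,
}

AUTOSOMES = [str(i) for i in range(1, 23)]

# GRCh37 coordinates of the two genes dominating hereditary hearing loss in
# the study population; used as default linkage targets by the simulator.
GENE_REGIONS = {
    "GJB2": ("13", 20_761_609, 20_767_114),
    "SLC26A4": ("7", 107_301_080, 107_358_254),
}


def chrom_sort_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def synthetic_gc(chrom: str, positions) -> np.ndarray:
    """Deterministic synthetic GC fraction at bin-start positions.

    Smooth multi-scale sinusoids plus a position-hashed ripple; values span
    roughly 0.30-0.60 so that 1%-wide GC buckets are well populated.
    """
    pos = np.asarray(positions, dtype=float)
    idx = float(chrom_sort_key(chrom)[1]) if chrom.removeprefix("chr").isdigit() else 23.0
    gc = (
        0.45
        + 0.07 * np.sin(pos / 7.3e6 + idx)
        + 0.04 * np.sin(pos / 1.9e6 + 2.0 * idx)
        + 0.02 * np.sin(pos / 0.61e6)
    )
    return np.clip(gc, 0.25, 0.68)


def make_bins(bin_size: int = 1_000_000, chroms=None):
    """Tile the genome into 1-based inclusive non-overlapping windows.

    Returns a list of (chrom, start, end, gc_fraction); the last window of
    each chromosome may be shorter than ``bin_size``.
    """
    out = []
    for chrom in (chroms or list(CHROM_LENGTHS)):
        length = CHROM_LENGTHS[chrom]
        starts = np.arange(1, length + 1, bin_size)
        gcs = synthetic_gc(chrom, starts)
        for start, gc in zip(starts, gcs):
            end = min(int(start) + bin_size - 1, length)
            out.append((chrom, int(start), end, float(gc)))
    return out
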