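"""Domain types and thresholds for the PGT-M / PGT-A diagnosis pipeline.

The pipeline diagnoses trophectoderm biopsies of day-5 blastocysts from
couples at risk of transmitting a monogenic disease.  Two readouts are
combined per embryo: a direct genotype call at the familial variant site(s)
plus linkage over a panel of flanking SNPs (PGT-M), and a genome-wide
low-depth read-count copy-number screen (PGT-A).  The types here are the
shared vocabulary of every stage; thresholds collect every tunable constant
in one immutable object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class ValidationError(ValueError):
    """A record violates a type invariant; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class ParseError(ValueError):
    """A file could not be parsed; names the offending line."""

    def __init__(self, path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class PedigreeInconsistencyError(ValueError):
    """Too many Mendelian-impossible markers; likely sample swap."""


class InvalidReferenceError(ValueError):
    """The declared phasing reference does not carry the expected variant."""


class ReferenceAmbiguityError(ValueError):
    """Grandparental variant carriage does not identify the mutant origin."""


# Genotype codes are always relative to a site's (allele_a, allele_b) or
# (ref, alt) pair: "AA" = homozygous first allele, "BB" = homozygous second.
GENOTYPES = ("AA", "AB", "BB", "nocall")

GENO_ALLELES = {"AA": ("A", "A"), "AB": ("A", "B"), "BB": ("B", "B")}


def geno_from_alleles(a: str, b: str) -> str:
    """Combine two abstract alleles ('A'/'B') into a genotype code."""
    return "".join(sorted((a, b)))


@dataclass(frozen=True)
class Thresholds:
    """Every tunable constant of the pipeline, with clinical defaults.

    Defaults follow the published procedure where it states them (the
    1 Mb marker window, MAF > 0.1 marker criterion, 90-marker panel,
    100x low-depth cutoff, 1 Mb copy-number bins, 1% GC buckets, 4 Mb
    CNV reporting floor); the remaining cutpoints are this package's
    declared conventions, documented in docs/methods.md.
    """

    # marker panel
    window_bp: int = 1_000_000
    maf_min: float = 0.10
    panel_target: int = 90
    # genotype calling
    low_depth_min: int = 100
    hom_af_max: float = 0.10
    het_af_low: float = 0.20
    het_af_high: float = 0.80
    # linkage voting
    vote_concordance_min: float = 0.8
    min_informative_per_parent: int = 3
    max_mendelian_error_rate: float = 0.02
    # copy-number screen
    bin_size_bp: int = 1_000_000
    gc_bucket_width: float = 1.0  # percent GC per correction bucket
    gc_bucket_min_bins: int = 10
    gc_mask_range: tuple = (0.2, 0.8)
    cnv_report_min_bp: int = 4_000_000
    gain_cn_min: float = 2.65
    loss_cn_max: float = 1.35
    mosaic_band: tuple = ((1.35, 1.7), (2.3, 2.65))
    multi_abnormal_chrom_min: int = 5
    mapd_max: float = 0.45
    min_total_mapped_reads: int = 200_000

    def __post_init__(self):
        for name in ("window_bp", "maf_min", "panel_target", "low_depth_min",
                     "bin_size_bp", "gc_bucket_width", "cnv_report_min_bp",
                     "vote_concordance_min", "min_informative_per_parent",
                     "multi_abnormal_chrom_min", "mapd_max",
                     "min_total_mapped_reads"):
            if getattr(self, name) <= 0:
                raise ValidationError(name, "must be strictly positive")
        if not self.het_af_low < self.het_af_high:
            raise ValidationError("het_af_low", "must be < het_af_high")
        if not self.loss_cn_max < 2 < self.gain_cn_min:
            raise ValidationError("loss_cn_max", "need loss_cn_max < 2 < gain_cn_min")
        (lo_lo, lo_hi), (hi_lo, hi_hi) = self.mosaic_band
        if not (self.loss_cn_max <= lo_lo < lo_hi <= 2 <= hi_lo < hi_hi <= self.gain_cn_min):
            raise ValidationError(
                "mosaic_band",
                "mosaic bands must nest inside [loss_cn_max, gain_cn_min] around 2",
            )


@dataclass(frozen=True, order=True)
class SnpMarker:
    """A biallelic SNP usable as a linkage scaffold marker."""

    chrom: str = field(compare=True)
    pos: int = field(compare=True)
    marker_id: str = field(compare=False, default="")
    allele_a: str = field(compare=False, default="A")
    allele_b: str = field(compare=False, default="G")
    maf: float = field(compare=False, default=0.25)

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError("pos", f"1-based position required, got {self.pos}")
        if self.allele_a == self.allele_b:
            raise ValidationError("allele_b", "alleles must differ")
        if not 0.0 <= self.maf <= 0.5:
            raise ValidationError("maf", f"minor-allele frequency must be in [0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class VariantAllele:
    """A familial pathogenic variant, carried as opaque clinical annotation.

    ``origin`` records which parental side declares it; ``classification``
    (ACMG class etc.) is never interpreted by the pipeline.
    """

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    hgvs_label: str
    origin: str  # maternal | paternal | both
    classification: str = ""

    def __post_init__(self):
        if self.origin not in ("maternal", "paternal", "both"):
            raise ValidationError("origin", f"unknown origin {self.origin!r}")
        if self.pos < 1:
            raise ValidationError("pos", "1-based position required")

    @property
    def site_id(self) -> str:
        return self.hgvs_label

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FamilyDesign:
    """Pedigree design for one at-risk couple.

    For autosomal recessive (AR) families both parents carry a pathogenic
    allele (possibly the identical one); for autosomal dominant (AD)
    families exactly one parent carries the variant.  Phasing uses either
    an affected child or the carrier parents' own parents as reference.
    """

    family_id: str
    gene: str
    mode: str  # AR | AD
    maternal_variants: list
    paternal_variants: list
    reference_type: str = "affected_child"  # or "grandparents"
    members: dict = field(default_factory=dict)  # role -> sample_id

    def __post_init__(self):
        if self.mode not in ("AR", "AD"):
            raise ValidationError("mode", f"must be AR or AD, got {self.mode!r}")
        if self.reference_type not in ("affected_child", "grandparents"):
            raise ValidationError("reference_type", f"unknown {self.reference_type!r}")
        if self.mode == "AR":
            if not self.maternal_variants or not self.paternal_variants:
                raise ValidationError(
                    "maternal_variants" if not self.maternal_variants else "paternal_variants",
                    "AR design requires at least one variant on each parental side",
                )
        else:
            if bool(self.maternal_variants) == bool(self.paternal_variants):
                raise ValidationError(
                    "paternal_variants",
                    "AD design requires exactly one carrier parent",
                )
        if self.reference_type == "affected_child":
            if "child" not in self.members:
                raise ValidationError("members", "affected_child reference requires a 'child' member")
        else:
            for side in self.carrier_sides():
                parent = "father" if side == "paternal" else "mother"
                for role in (f"{side}_grandfather", f"{side}_grandmother"):
                    if role not in self.members:
                        raise ValidationError(
                            "members",
                            f"grandparent reference requires {role!r} for carrier {parent}",
                        )

    def carrier_sides(self):
        sides = []
        if self.paternal_variants:
            sides.append("paternal")
        if self.maternal_variants:
            sides.append("maternal")
        return sides

    @property
    def carrier_parent(self) -> Optional[str]:
        """For AD families, the single carrier parent; None for AR."""
        if self.mode != "AD":
            return None
        return "mother" if self.maternal_variants else "father"

    def variants_of(self, parent: str) -> list:
        return self.maternal_variants if parent == "mother" else self.paternal_variants

    def is_same_variant(self) -> bool:
        """AR family where both parents carry the identical allele."""
        return (
            self.mode == "AR"
            and self.maternal_variants[0].key == self.paternal_variants[0].key
        )

    def variant_site_sides(self) -> dict:
        """Map variant site_id -> set of carrying parents ('father'/'mother')."""
        sides: dict = {}
        for v in self.paternal_variants:
            sides.setdefault(v.site_id, set()).add("father")
        for v in self.maternal_variants:
            sides.setdefault(v.site_id, set()).add("mother")
        return sides


@dataclass(frozen=True)
class SiteCall:
    """Allele depths and the derived genotype at one assayed site.

    ``low_depth`` marks sites under the coverage floor (default 100x);
    such sites are never genotyped.
    """

    site_id: str
    depth_a: int
    depth_b: int
    genotype: str
    low_depth: bool

    def __post_init__(self):
        if self.depth_a < 0 or self.depth_b < 0:
            raise ValidationError("depth_a" if self.depth_a < 0 else "depth_b",
                                  "read depths must be non-negative")
        if self.genotype not in GENOTYPES:
            raise ValidationError("genotype", f"unknown genotype {self.genotype!r}")
        if self.low_depth and self.genotype != "nocall":
            raise ValidationError("genotype", "low-depth sites must be nocall")

    @property
    def total_depth(self) -> int:
        return self.depth_a + self.depth_b


@dataclass
class BinRecord:
    """One fixed-width genomic observation window of the copy-number screen."""

    chrom: str
    start: int
    end: int
    gc_fraction: float
    raw_count: float
    corrected_count: Optional[float] = None
    cn: Optional[float] = None
    masked: bool = False

    def __post_init__(self):
        if self.end < self.start:
            raise ValidationError("end", f"bin end {self.end} < start {self.start}")
        if self.start < 1:
            raise ValidationError("start", "1-based coordinates required")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValidationError("gc_fraction", f"must be in [0,1], got {self.gc_fraction}")
        if self.raw_count < 0:
            raise ValidationError("raw_count", "negative read count")
        if self.cn is not None and self.cn < 0:
            raise ValidationError("cn", "copy number must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CycleRecord:
    """One family's row of the clinical cycle/outcome table."""

    family_id: str
    female_age: float
    gene: str
    mode: str
    maternal_variants: str
    paternal_variants: str
    cycles: int
    total_embryos: int
    transferable: int
    implantation_times: int
    pregnancies: int
    miscarriages: int
    live_births: int
    outcome: str = ""
    note: str = ""

    def __post_init__(self):
        if self.transferable > self.total_embryos:
            raise ValidationError("transferable", "cannot exceed total_embryos")
        if self.pregnancies > self.implantation_times:
            raise ValidationError("pregnancies", "cannot exceed implantation_times")
        if self.miscarriages > self.pregnancies:
            raise ValidationError("miscarriages", "cannot exceed pregnancies")
        for f in ("cycles", "total_embryos", "transferable", "implantation_times",
                  "pregnancies", "miscarriages", "live_births"):
            if getattr(self, f) < 0:
                raise ValidationError(f, "count must be non-negative")
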