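"""Genotype calling from single-cell allele depths and the direct
(mutation-site) embryo verdict.

Whole-genome-amplified single-cell material shows strong allele imbalance,
so genotypes are called from the minor-allele fraction with deliberately
wide heterozygote bounds, and only at sites with at least 100x coverage.
The direct verdict classifies the embryo from the familial variant sites
alone; Mendelian impossibilities (an allele that neither parent could have
contributed at that site) are flagged as suspected allele dropout (ADO) and
resolved later against the linkage result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import FamilyDesign, SiteCall, Thresholds

DIRECT_STATUSES = (
    "unaffected_noncarrier", "carrier_maternal", "carrier_paternal",
    "carrier_origin_unknown", "affected_compound_het", "affected_homozygous",
    "variant_present", "variant_absent", "mendelian_impossible", "indeterminate",
)


def call_site_genotype(depth_a: int, depth_b: int,
                       thresholds: Thresholds | None = None,
                       site_id: str = "") -> SiteCall:
    """Call a genotype from the two allele depths at one site.

    Sites under ``low_depth_min`` total coverage are "low depth" and yield
    nocall.  Otherwise the fraction f = depth_b / total decides:
    f <= hom_af_max -> AA; f >= 1 - hom_af_max -> BB;
    het_af_low <= f <= het_af_high -> AB; anything between the bands is an
    uninterpretable imbalance and yields nocall.
    """
    thr = thresholds or Thresholds()
    if depth_a < 0 or depth_b < 0:
        raise ValueError("read depths must be non-negative")
    total = depth_a + depth_b
    if total < thr.low_depth_min:
        return SiteCall(site_id, depth_a, depth_b, "nocall", low_depth=True)
    f = depth_b / total
    if f <= thr.hom_af_max:
        genotype = "AA"
    elif f >= 1.0 - thr.hom_af_max:
        genotype = "BB"
    elif thr.het_af_low <= f <= thr.het_af_high:
        genotype = "AB"
    else:
        genotype = "nocall"
    return SiteCall(site_id, depth_a, depth_b, genotype, low_depth=False)


@dataclass
class DirectVerdict:
    """Preliminary embryo classification from the variant sites alone."""

    status: str
    calls: dict = field(default_factory=dict)  # site_id -> genotype code
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.status not in DIRECT_STATUSES:
            raise ValueError(f"unknown direct status {self.status!r}")


def _geno(call) -> str:
    return call.genotype if isinstance(call, SiteCall) else call


def direct_variant_verdict(embryo_calls: dict, family: FamilyDesign) -> DirectVerdict:
    """Classify an embryo from its genotype calls at the familial variant sites.

    ``embryo_calls`` maps site_id -> SiteCall (or genotype code) and must
    include every declared variant site; nocall is allowed and forces an
    indeterminate preliminary status rather than a guess.
    """
    sides = family.variant_site_sides()
    for site in sides:
        if site not in embryo_calls:
            raise ValueError(f"no call supplied for declared variant site {site!r}")
    calls = {site: _geno(embryo_calls[site]) for site in sides}

    if family.mode == "AD":
        site = family.variants_of(family.carrier_parent)[0].site_id
        g = calls[site]
        if g == "nocall":
            return DirectVerdict("indeterminate", calls)
        if g == "BB":
            # a het carrier parent cannot transmit two variant alleles
            return DirectVerdict("mendelian_impossible", calls, flags=["suspected_ADO"])
        return DirectVerdict("variant_present" if g == "AB" else "variant_absent", calls)

    if family.is_same_variant():
        site = family.maternal_variants[0].site_id
        g = calls[site]
        if g == "nocall":
            return DirectVerdict("indeterminate", calls)
        if g == "BB":
            return DirectVerdict("affected_homozygous", calls)
        if g == "AB":
            # direct testing cannot assign parental origin of an identical allele
            return DirectVerdict("carrier_origin_unknown", calls)
        return DirectVerdict("unaffected_noncarrier", calls)

    # AR, compound-heterozygous parents: one site per parental side.
    m_site = family.maternal_variants[0].site_id
    p_site = family.paternal_variants[0].site_id
    gm, gp = calls[m_site], calls[p_site]
    if "nocall" in (gm, gp):
        return DirectVerdict("indeterminate", calls)
    # hom-alt at a site only one parent carries requires an allele the other
    # parent does not have: classic signature of the other allele dropping out
    if gm == "BB" or gp == "BB":
        return DirectVerdict("mendelian_impossible", calls, flags=["suspected_ADO"])
    table = {
        ("AA", "AA"): "unaffected_noncarrier",
        ("AB", "AA"): "carrier_maternal",
        ("AA", "AB"): "carrier_paternal",
        ("AB", "AB"): "affected_compound_het",
    }
    return DirectVerdict(table[(gm, gp)], calls)
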