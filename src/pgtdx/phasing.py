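"""Pedigree haplotype phasing of each carrier parent's panel markers.

Each carrier parent has a mutant-linked haplotype M (the chromosome
carrying the pathogenic allele) and a normal homolog N.  An affected child
must have received M from every carrier parent, so at every marker where
the parent is heterozygous and Mendelian logic uniquely identifies the
transmitted allele, that allele is placed on M.  Couples without an
affected child are phased against the carrier parent's own parents: the
grandparent carrying the variant identifies the M-origin lineage.

Only pedigree logic is used -- no statistical (EM/HMM) phasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    GENO_ALLELES,
    FamilyDesign,
    InvalidReferenceError,
    PedigreeInconsistencyError,
    ReferenceAmbiguityError,
    SiteCall,
    Thresholds,
)


@dataclass
class ParentalHaplotypes:
    """Per-marker phase of one parent's alleles onto M vs N.

    ``phase`` maps marker_id -> (allele_on_M, allele_on_N) with abstract
    allele codes 'A'/'B'; a marker is informative iff it is phased.
    """

    parent: str  # father | mother
    phase: dict = field(default_factory=dict)
    positions: dict = field(default_factory=dict)  # marker_id -> bp position
    n_assessed: int = 0
    mendelian_impossible: list = field(default_factory=list)

    @property
    def n_informative(self) -> int:
        return len(self.phase)

    @property
    def informative_markers(self) -> list:
        if self.positions:
            return sorted(self.phase, key=lambda mid: self.positions.get(mid, 0))
        return list(self.phase)

    def is_informative(self, marker_id: str) -> bool:
        return marker_id in self.phase


def _geno(call) -> str:
    if call is None:
        return "nocall"
    return call.genotype if isinstance(call, SiteCall) else call


def transmitted_alleles(parent_geno: str, other_geno: str, child_geno: str) -> set:
    """Alleles the focal parent could have transmitted to the child.

    An unknown ('nocall') other-parent genotype is treated as unconstrained.
    An empty result means the trio is Mendelian-impossible at this site.
    """
    if parent_geno not in GENO_ALLELES or child_geno not in GENO_ALLELES:
        return set()
    other = GENO_ALLELES.get(other_geno, ("A", "B"))
    child = tuple(sorted(GENO_ALLELES[child_geno]))
    out = set()
    for a in set(GENO_ALLELES[parent_geno]):
        for b in set(other):
            if tuple(sorted((a, b))) == child:
                out.add(a)
    return out


def _marker_ids(family: FamilyDesign, panel, *call_dicts):
    if panel is not None:
        return panel.marker_ids
    variant_sites = set(family.variant_site_sides()) if family else set()
    common = set.intersection(*(set(d) for d in call_dicts)) if call_dicts else set()
    return sorted(common - variant_sites)


def _check_child_reference(family: FamilyDesign, parent: str, child_calls: dict):
    """The reference child must actually carry this parent's variant."""
    for v in family.variants_of(parent):
        g = _geno(child_calls.get(v.site_id))
        if g in ("AA",):
            raise InvalidReferenceError(
                f"reference child does not carry the {parent}'s variant {v.hgvs_label}; "
                "not a valid phasing reference"
            )


def phase_with_child(parent_calls: dict, other_parent_calls: dict,
                     child_calls: dict, family: FamilyDesign, parent: str,
                     panel=None, thresholds: Thresholds | None = None) -> ParentalHaplotypes:
    """Phase one carrier parent against an affected child.

    At each panel marker where the parent is heterozygous and the
    transmitted allele is uniquely determined by the trio genotypes, that
    allele goes on M (the affected child received the mutant-linked
    haplotype).  Ambiguous or homozygous markers stay unphased.  A fraction
    of Mendelian-impossible markers above ``max_mendelian_error_rate`` is
    treated as a pedigree inconsistency (sample swap) and raises.
    """
    thr = thresholds or Thresholds()
    _check_child_reference(family, parent, child_calls)
    haps = ParentalHaplotypes(parent=parent,
                              positions=panel.positions() if panel is not None else {})
    for mid in _marker_ids(family, panel, parent_calls, other_parent_calls, child_calls):
        gp = _geno(parent_calls.get(mid))
        go = _geno(other_parent_calls.get(mid))
        gc = _geno(child_calls.get(mid))
        if gp == "nocall" or gc == "nocall":
            continue
        haps.n_assessed += 1
        trans = transmitted_alleles(gp, go, gc)
        if not trans:
            haps.mendelian_impossible.append(mid)
            continue
        if gp == "AB" and len(trans) == 1:
            m = next(iter(trans))
            haps.phase[mid] = (m, "B" if m == "A" else "A")
    if haps.n_assessed:
        err = len(haps.mendelian_impossible) / haps.n_assessed
        if err > thr.max_mendelian_error_rate:
            raise PedigreeInconsistencyError(
                f"{len(haps.mendelian_impossible)}/{haps.n_assessed} markers are "
                f"Mendelian-impossible for {parent} (> {thr.max_mendelian_error_rate:.0%}); "
                "suspected sample swap"
            )
    return haps


def phase_with_grandparents(parent_calls: dict, grandfather_calls: dict,
                            grandmother_calls: dict, family: FamilyDesign,
                            parent: str, panel=None,
                            thresholds: Thresholds | None = None) -> ParentalHaplotypes:
    """Phase one carrier parent against their own parents.

    Exactly one grandparent must carry the parent's pathogenic allele; the
    allele the parent inherited from that grandparent sits on M.  Markers
    where grandparental genotypes do not uniquely resolve the origin, or
    where grandparental calls are missing, stay unphased.
    """
    thr = thresholds or Thresholds()
    vsite = family.variants_of(parent)[0].site_id
    gf_carries = _geno(grandfather_calls.get(vsite)) in ("AB", "BB")
    gm_carries = _geno(grandmother_calls.get(vsite)) in ("AB", "BB")
    if gf_carries == gm_carries:
        raise ReferenceAmbiguityError(
            "exactly one grandparent must carry the variant "
            f"{family.variants_of(parent)[0].hgvs_label} "
            f"(grandfather: {gf_carries}, grandmother: {gm_carries})"
        )
    origin_calls, other_calls = (
        (grandfather_calls, grandmother_calls) if gf_carries
        else (grandmother_calls, grandfather_calls)
    )
    haps = ParentalHaplotypes(parent=parent,
                              positions=panel.positions() if panel is not None else {})
    for mid in _marker_ids(family, panel, parent_calls):
        gp = _geno(parent_calls.get(mid))
        if gp == "nocall":
            continue
        g_origin = _geno(origin_calls.get(mid))
        g_other = _geno(other_calls.get(mid))
        if g_origin == "nocall" and g_other == "nocall":
            continue  # missing grandparental data: unphased, no error
        haps.n_assessed += 1
        origin_alleles = set(GENO_ALLELES.get(g_origin, ("A", "B")))
        other_alleles = set(GENO_ALLELES.get(g_other, ("A", "B")))
        assignments = [
            (m, n) for m, n in (("A", "B"), ("B", "A"))
            if m in origin_alleles and n in other_alleles
            and set((m, n)) <= set(GENO_ALLELES[gp])
        ]
        if gp != "AB":
            want = tuple(sorted(GENO_ALLELES[gp]))
            compatible = any(tuple(sorted((a, b))) == want
                             for a in origin_alleles for b in other_alleles)
            if not compatible:
                haps.mendelian_impossible.append(mid)
            continue
        if not assignments:
            haps.mendelian_impossible.append(mid)
            continue
        if len(assignments) == 1:
            haps.phase[mid] = assignments[0]
    if haps.n_assessed:
        err = len(haps.mendelian_impossible) / haps.n_assessed
        if err > thr.max_mendelian_error_rate:
            raise PedigreeInconsistencyError(
                f"{len(haps.mendelian_impossible)}/{haps.n_assessed} markers are "
                f"Mendelian-impossible for {parent}; suspected sample swap"
            )
    return haps


def phase_family(bank, family: FamilyDesign, calls_by_sample: dict,
                 thresholds: Thresholds | None = None, gene_region=None):
    """Select the panel and phase both parents for one family.

    ``calls_by_sample`` maps sample ids (as declared in the family's member
    roles) to per-site call dicts.  For AD families the non-carrier parent
    gets empty haplotypes.  Returns ``(panel, {"father": ..., "mother": ...})``.
    """
    from .genome import GENE_REGIONS
    from .panel import select_panel

    if gene_region is None:
        if family.gene in GENE_REGIONS:
            gene_region = GENE_REGIONS[family.gene]
        else:
            variants = family.maternal_variants + family.paternal_variants
            gene_region = (variants[0].chrom, min(v.pos for v in variants),
                           max(v.pos for v in variants))
    panel = select_panel(bank, gene_region, thresholds, gene=family.gene)
    haps = {}
    for parent in ("father", "mother"):
        if family.mode == "AD" and parent != family.carrier_parent:
            haps[parent] = ParentalHaplotypes(parent=parent)
            continue
        parent_calls = calls_by_sample[family.members[parent]]
        other = "mother" if parent == "father" else "father"
        if family.reference_type == "affected_child":
            haps[parent] = phase_with_child(
                parent_calls, calls_by_sample[family.members[other]],
                calls_by_sample[family.members["child"]], family, parent,
                panel, thresholds)
        else:
            side = "paternal" if parent == "father" else "maternal"
            haps[parent] = phase_with_grandparents(
                parent_calls,
                calls_by_sample[family.members[f"{side}_grandfather"]],
                calls_by_sample[family.members[f"{side}_grandmother"]],
                family, parent, panel, thresholds)
    return panel, haps


def informative_sites(haps_father: ParentalHaplotypes,
                      haps_mother: ParentalHaplotypes, panel=None) -> dict:
    """The phased-marker subsets and counts for both parents."""
    return {
        "father": haps_father.informative_markers,
        "mother": haps_mother.informative_markers,
        "n_father": haps_father.n_informative,
        "n_mother": haps_mother.n_informative,
        "n_total": haps_father.n_informative + haps_mother.n_informative,
    }
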