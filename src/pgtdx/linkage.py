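"""Linkage-based embryo diagnosis: haplotype transmission votes, meiotic
recombination detection, allele-dropout (ADO) reconciliation.

Every informative marker casts a vote on which parental haplotype (M,
mutant-linked, or N, normal) the embryo inherited; the inheritance call
requires a minimum number of determinate votes and a minimum concordance.
A contiguous terminal run of discordant votes is a meiotic crossover
within the marker window, not noise, and is excluded from the call; an
isolated discordant vote is treated as site-level error/ADO.

The linkage call is then reconciled with the direct variant-site verdict.
Mismatches explainable by one allele of an expected heterozygote dropping
out are recorded as ADO events and rescued; any unexplainable conflict
yields an indeterminate verdict -- the procedure never converts a conflict
into a transferable call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .genotyping import DirectVerdict
from .model import GENO_ALLELES, FamilyDesign, SiteCall, Thresholds
from .phasing import ParentalHaplotypes

VERDICT_STATUSES = (
    "unaffected_noncarrier", "carrier_maternal", "carrier_paternal",
    "carrier_origin_unknown", "affected", "ad_variant_present",
    "ad_variant_absent", "indeterminate",
)


@dataclass
class TransmissionResult:
    """Outcome of haplotype-vote counting for one parent."""

    parent: str
    votes_M: int = 0
    votes_N: int = 0
    votes_indeterminate: int = 0
    inherited: str = "indeterminate"  # M | N | indeterminate
    concordance: Optional[float] = None
    recombination_breakpoint: Optional[tuple] = None
    discordant_sites: list = field(default_factory=list)
    excluded_sites: list = field(default_factory=list)

    @property
    def n_assessed(self) -> int:
        return self.votes_M + self.votes_N + self.votes_indeterminate


@dataclass
class AdoEvent:
    """One suspected allele-dropout at a variant-site assay."""

    site_id: str
    parent: str
    expected_genotype: str
    observed_genotype: str
    resolution: str  # rescued_by_linkage | non_mutant_allele_dropout | unresolved


@dataclass
class MonogenicVerdict:
    """Final monogenic diagnosis for one embryo biopsy."""

    status: str
    ado_events: list = field(default_factory=list)
    basis: Optional[str] = None  # direct_only | linkage_only | concordant | ado_rescued

    def __post_init__(self):
        if self.status not in VERDICT_STATUSES:
            raise ValueError(f"unknown verdict status {self.status!r}")
        if any(e.resolution == "unresolved" for e in self.ado_events):
            # an unresolved dropout pattern can never support a diagnosis
            if self.status != "indeterminate":
                raise ValueError("unresolved ADO forces an indeterminate verdict")


def _geno(call) -> str:
    if call is None:
        return "nocall"
    return call.genotype if isinstance(call, SiteCall) else call


def _vote(m_allele: str, n_allele: str, other_geno: str, embryo_geno: str) -> Optional[str]:
    """Vote M/N for one marker, or None when ambiguous/impossible."""
    if embryo_geno not in GENO_ALLELES:
        return None
    other = set(GENO_ALLELES.get(other_geno, ("A", "B")))
    child = tuple(sorted(GENO_ALLELES[embryo_geno]))
    candidates = {
        a for a in (m_allele, n_allele)
        if any(tuple(sorted((a, b))) == child for b in other)
    }
    if candidates == {m_allele}:
        return "M"
    if candidates == {n_allele}:
        return "N"
    return None


def detect_recombination(vote_sequence, gene_region=None):
    """Locate a meiotic crossover in a position-ordered M/N vote sequence.

    ``vote_sequence`` is a list of ``(position, vote)`` with vote 'M'/'N'.
    A terminal run of >= 2 consecutive votes discordant with the majority
    is a recombination block; the breakpoint is the interval between the
    last concordant and the first discordant marker.  With a tied vote
    count and a single clean switch, the breakpoint is still reported and
    the block is the side away from the gene.  Returns
    ``(breakpoint_interval | None, excluded_indices)``.
    """
    n = len(vote_sequence)
    if n < 3:
        return None, set()
    votes = [v for _, v in vote_sequence]
    n_m, n_n = votes.count("M"), votes.count("N")
    majority = "M" if n_m > n_n else ("N" if n_n > n_m else None)

    if majority is not None:
        # longest terminal discordant run (prefix or suffix), length >= 2
        i = 0
        while i < n and votes[i] != majority:
            i += 1
        j = n
        while j > 0 and votes[j - 1] != majority:
            j -= 1
        prefix_len, suffix_len = i, n - j
        if max(prefix_len, suffix_len) < 2:
            return None, set()
        if prefix_len >= suffix_len:
            excluded = set(range(prefix_len))
            bp = (vote_sequence[prefix_len - 1][0], vote_sequence[prefix_len][0])
        else:
            excluded = set(range(j, n))
            bp = (vote_sequence[j - 1][0], vote_sequence[j][0])
        return (min(bp), max(bp)), excluded

    # tie: a single clean switch is still an unambiguous crossover
    switches = [k for k in range(n - 1) if votes[k] != votes[k + 1]]
    if len(switches) != 1:
        return None, set()
    k = switches[0]
    if min(k + 1, n - k - 1) < 2:
        return None, set()
    bp = (vote_sequence[k][0], vote_sequence[k + 1][0])
    excluded: set = set()
    if gene_region is not None:
        _, gstart, gend = gene_region
        gmid = (gstart + gend) / 2
        if gmid < bp[0]:
            excluded = set(range(k + 1, n))  # keep the gene-side (left) votes
        elif gmid > bp[1]:
            excluded = set(range(k + 1))
    return (min(bp), max(bp)), excluded


def _overlaps(interval, gene_region) -> bool:
    lo, hi = interval
    _, gstart, gend = gene_region
    return not (hi < gstart or lo > gend)


def infer_transmission(embryo_calls: dict, parental_haps: ParentalHaplotypes,
                       other_parent_calls: dict,
                       thresholds: Thresholds | None = None,
                       gene_region=None) -> TransmissionResult:
    """Infer which parental haplotype (M/N) the embryo inherited.

    Each informative marker votes by subtracting the other parent's
    possible contribution from the embryo genotype.  The call requires
    ``min_informative_per_parent`` determinate votes and
    ``vote_concordance_min`` concordance after excluding any recombination
    block; a crossover interval overlapping the gene makes the transmission
    indeterminate (the haplotype at the gene itself is then unknown).
    """
    thr = thresholds or Thresholds()
    res = TransmissionResult(parent=parental_haps.parent)
    seq = []  # (pos, vote, marker_id) for determinate votes, position-ordered
    for mid in parental_haps.informative_markers:
        m_allele, n_allele = parental_haps.phase[mid]
        vote = _vote(m_allele, n_allele, _geno(other_parent_calls.get(mid)),
                     _geno(embryo_calls.get(mid)))
        if vote is None:
            res.votes_indeterminate += 1
        else:
            if vote == "M":
                res.votes_M += 1
            else:
                res.votes_N += 1
            seq.append((parental_haps.positions.get(mid, len(seq)), vote, mid))
    seq.sort(key=lambda t: t[0])

    bp, excluded_idx = detect_recombination([(p, v) for p, v, _ in seq], gene_region)
    res.recombination_breakpoint = bp
    res.excluded_sites = [seq[i][2] for i in sorted(excluded_idx)]
    kept = [seq[i] for i in range(len(seq)) if i not in excluded_idx]
    n_m = sum(1 for _, v, _ in kept if v == "M")
    n_n = len(kept) - n_m
    if bp is not None and gene_region is not None and _overlaps(bp, gene_region):
        return res  # crossover over the gene: haplotype at the locus unknown
    det = n_m + n_n
    if det < thr.min_informative_per_parent or n_m == n_n:
        return res
    winner, agree = ("M", n_m) if n_m > n_n else ("N", n_n)
    concordance = agree / det
    if concordance < thr.vote_concordance_min:
        return res
    res.inherited = winner
    res.concordance = concordance
    res.discordant_sites = [mid for _, v, mid in kept if v != winner]
    return res


# ---------------------------------------------------------------------------
# reconciliation of direct and linkage results


def _needed_sides(family: FamilyDesign):
    if family.mode == "AD":
        return (family.carrier_parent,)
    return ("father", "mother")


def status_from_link(family: FamilyDesign, link: dict) -> Optional[str]:
    """Map inherited haplotypes {parent: M/N} to a verdict status."""
    if any(link.get(p) not in ("M", "N") for p in _needed_sides(family)):
        return None
    if family.mode == "AD":
        return "ad_variant_present" if link[family.carrier_parent] == "M" else "ad_variant_absent"
    f, m = link["father"], link["mother"]
    if f == "M" and m == "M":
        return "affected"
    if f == "M":
        return "carrier_paternal"
    if m == "M":
        return "carrier_maternal"
    return "unaffected_noncarrier"


def _expected_variant_genotypes(family: FamilyDesign, link: dict) -> dict:
    """Expected genotype at each variant site given inherited haplotypes."""
    out = {}
    for site, sides in family.variant_site_sides().items():
        alleles = []
        for parent in ("father", "mother"):
            carries = parent in sides
            alleles.append("B" if carries and link.get(parent) == "M" else "A")
        out[site] = "".join(sorted(alleles))
    return out


def _direct_status_to_verdict(status: str) -> Optional[str]:
    mapping = {
        "unaffected_noncarrier": "unaffected_noncarrier",
        "carrier_maternal": "carrier_maternal",
        "carrier_paternal": "carrier_paternal",
        "carrier_origin_unknown": "carrier_origin_unknown",
        "affected_compound_het": "affected",
        "affected_homozygous": "affected",
        "variant_present": "ad_variant_present",
        "variant_absent": "ad_variant_absent",
    }
    return mapping.get(status)


def _implied_link_from_direct(family: FamilyDesign, direct: DirectVerdict) -> dict:
    """Transmission each parent must have made if the direct calls are real."""
    implied: dict = {}
    verdict = _direct_status_to_verdict(direct.status)
    if verdict is None:
        return implied
    if family.mode == "AD":
        implied[family.carrier_parent] = "M" if verdict == "ad_variant_present" else "N"
        return implied
    if verdict == "carrier_origin_unknown":
        return implied  # one M, one N, but sides unknown
    implied["father"] = "M" if verdict in ("affected", "carrier_paternal") else "N"
    implied["mother"] = "M" if verdict in ("affected", "carrier_maternal") else "N"
    return implied


def _ado_event(family: FamilyDesign, site: str, expected: str, observed: str,
               link: dict) -> Optional[AdoEvent]:
    """Classify an expected-vs-observed mismatch at a variant site.

    A heterozygote observed as either homozygote lost one allele: if the
    lost allele is the pathogenic (alt) one the case is only recoverable by
    linkage; if the lost allele is wild-type the direct call exaggerated to
    hom-alt and the diagnosis is unaffected by the dropout.  Any other
    mismatch pattern is not a dropout and stays unresolved.
    """
    sides = family.variant_site_sides()[site]
    parent = sorted(sides)[0] if len(sides) == 1 else "both"
    if expected == "AB" and observed in ("AA", "BB"):
        dropped_mutant = observed == "AA"  # alt allele ('B') missing
        return AdoEvent(
            site_id=site, parent=parent, expected_genotype=expected,
            observed_genotype=observed,
            resolution="rescued_by_linkage" if dropped_mutant else "non_mutant_allele_dropout",
        )
    if expected == "BB" and observed == "AB":
        return None  # seeing both alleles where two alts expected: not a dropout
    return AdoEvent(site_id=site, parent=parent, expected_genotype=expected,
                    observed_genotype=observed, resolution="unresolved")


def reconcile(direct: DirectVerdict, transmission_father: TransmissionResult,
              transmission_mother: TransmissionResult,
              family: FamilyDesign) -> MonogenicVerdict:
    """Combine the direct verdict with both linkage calls into the diagnosis.

    Agreement confirms the direct result; a determinate linkage call
    overrides variant-site genotypes whose mismatch is explainable as a
    single-allele dropout (recorded as an :class:`AdoEvent`); any conflict
    without a dropout explanation, or missing information on both routes,
    yields an indeterminate verdict.
    """
    link = {"father": transmission_father.inherited,
            "mother": transmission_mother.inherited}
    link_status = status_from_link(family, link)
    direct_as_verdict = _direct_status_to_verdict(direct.status)

    if link_status is not None:
        expected = _expected_variant_genotypes(family, link)
        events = []
        unresolved = False
        for site, exp in expected.items():
            obs = direct.calls.get(site, "nocall")
            if obs == "nocall" or obs == exp:
                continue
            event = _ado_event(family, site, exp, obs, link)
            if event is None:
                unresolved = True
                continue
            events.append(event)
            if event.resolution == "unresolved":
                unresolved = True
        if unresolved:
            return MonogenicVerdict("indeterminate", ado_events=events, basis=None)
        if events:
            return MonogenicVerdict(link_status, ado_events=events, basis="ado_rescued")
        if direct_as_verdict is None:
            return MonogenicVerdict(link_status, basis="linkage_only")
        if direct_as_verdict == link_status or (
            direct_as_verdict == "carrier_origin_unknown"
            and link_status in ("carrier_maternal", "carrier_paternal")
        ):
            return MonogenicVerdict(link_status, basis="concordant")
        # statuses disagree though every site matched: conservative fallback
        return MonogenicVerdict("indeterminate", basis=None)

    # linkage indeterminate on at least one needed side
    if direct_as_verdict is not None:
        implied = _implied_link_from_direct(family, direct)
        for parent, needed in implied.items():
            actual = link.get(parent)
            if actual in ("M", "N") and actual != needed:
                # partial linkage contradicts the direct call: unsafe to diagnose
                return MonogenicVerdict("indeterminate", basis=None)
        return MonogenicVerdict(direct_as_verdict, basis="direct_only")

    events = []
    if direct.status == "mendelian_impossible":
        sides = family.variant_site_sides()
        for site, obs in direct.calls.items():
            if obs == "BB" and len(sides.get(site, ())) == 1:
                parent = sorted(sides[site])[0]
                events.append(AdoEvent(site_id=site, parent=parent,
                                       expected_genotype="AB", observed_genotype=obs,
                                       resolution="unresolved"))
    return MonogenicVerdict("indeterminate", ado_events=events, basis=None)


def ado_rate(n_ado_events: int, n_pcr_rounds: int) -> float:
    """Allele-dropout rate: events per variant-site PCR/sequencing assay."""
    if n_pcr_rounds < 1:
        raise ValueError("n_pcr_rounds must be >= 1")
    if n_ado_events < 0:
        raise ValueError("event count must be non-negative")
    return n_ado_events / n_pcr_rounds


def diagnose_embryo(family: FamilyDesign, panel, haps_father: ParentalHaplotypes,
                    haps_mother: ParentalHaplotypes, father_calls: dict,
                    mother_calls: dict, embryo_calls: dict,
                    thresholds: Thresholds | None = None):
    """Run the full monogenic diagnosis for one embryo.

    Returns ``(MonogenicVerdict, DirectVerdict, transmission_father,
    transmission_mother)``.
    """
    from .genotyping import direct_variant_verdict

    thr = thresholds or Thresholds()
    direct = direct_variant_verdict(embryo_calls, family)
    gene_region = panel.gene_region if panel is not None else None
    tf = infer_transmission(embryo_calls, haps_father, mother_calls, thr, gene_region)
    tm = infer_transmission(embryo_calls, haps_mother, father_calls, thr, gene_region)
    verdict = reconcile(direct, tf, tm, family)
    return verdict, direct, tf, tm
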