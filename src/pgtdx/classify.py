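"""Final embryo classification, transfer ranking and cohort statistics.

An embryo is transferable only when both readouts are clean: a determinate
monogenic verdict that is not affected, and a euploid chromosome screen.
Wild-type embryos are preferred over heterozygous carriers for transfer
(carriers of a recessive allele are phenotypically unaffected and are
transferred once wild-type embryos are used up).  Any indeterminate or
QC-failed component forces the inconclusive class -- never a transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .cnv import ChromResult
from .linkage import MonogenicVerdict
from .model import CycleRecord

FINAL_CLASSES = ("transferable_wildtype", "transferable_carrier", "affected",
                 "aneuploid", "inconclusive")

_QC_CATEGORIES = ("amplification_failure", "contaminated", "multi_abnormal")


@dataclass
class EmbryoReport:
    """Combined PGT-M + PGT-A report for one embryo biopsy."""

    embryo_id: str
    monogenic: MonogenicVerdict
    chromosomes: ChromResult
    final_class: str = "inconclusive"
    transfer_eligible: bool = False

    def __post_init__(self):
        if self.final_class not in FINAL_CLASSES:
            raise ValueError(f"unknown final class {self.final_class!r}")


def classify_embryo(monogenic_status: str, chrom_category: str, mode: str) -> str:
    """Combine the monogenic verdict and screen category into a final class.

    Precedence: a monogenic affected finding is reported as affected
    regardless of karyotype (it is the indication for testing); a QC-failed
    screen or an indeterminate verdict is inconclusive; chromosome
    abnormalities are aneuploid; only euploid embryos with a determinate
    non-affected verdict are transferable.
    """
    affected_statuses = {"affected", "ad_variant_present"}
    carrier_statuses = {"carrier_maternal", "carrier_paternal", "carrier_origin_unknown"}
    wildtype_statuses = {"unaffected_noncarrier", "ad_variant_absent"}

    if monogenic_status in affected_statuses:
        return "affected"
    if chrom_category in _QC_CATEGORIES:
        return "inconclusive"
    if chrom_category in ("aneuploid", "mosaic"):
        return "aneuploid"
    if monogenic_status in carrier_statuses and mode == "AR":
        return "transferable_carrier"
    if monogenic_status in wildtype_statuses:
        return "transferable_wildtype"
    # indeterminate monogenic result (or a carrier status under AD, which
    # cannot arise) on a euploid embryo
    return "inconclusive"


def build_report(embryo_id: str, monogenic: MonogenicVerdict,
                 chromosomes: ChromResult, mode: str) -> EmbryoReport:
    final = classify_embryo(monogenic.status, chromosomes.category, mode)
    return EmbryoReport(
        embryo_id=embryo_id, monogenic=monogenic, chromosomes=chromosomes,
        final_class=final,
        transfer_eligible=final in ("transferable_wildtype", "transferable_carrier"),
    )


def rank_transfer(reports) -> list:
    """Transfer-priority order: wild type first, then carriers; stable within
    a class, ties broken by embryo_id."""
    eligible = [r for r in reports if r.transfer_eligible]
    priority = {"transferable_wildtype": 0, "transferable_carrier": 1}
    return sorted(eligible, key=lambda r: (priority[r.final_class], r.embryo_id))


@dataclass
class CohortStats:
    """Cycle- and embryo-level totals plus the derived outcome rates.

    Each rate is 100 x numerator / denominator with the denominators of the
    clinical report: pregnancy and miscarriage per transfer, live birth per
    started cycle, aneuploidy / inconclusive / transferable per biopsied
    embryo, wild-type and carrier shares per transferable embryo of an
    autosomal recessive couple, ADO per variant-site assay.  A rate with a
    zero denominator is absent (None), not zero.
    """

    totals: dict = field(default_factory=dict)
    rates: dict = field(default_factory=dict)
    mean_female_age: Optional[float] = None


def _rate(numerator, denominator) -> Optional[float]:
    if not denominator:
        return None
    return 100.0 * numerator / denominator


def cohort_summary(cycle_records, tallies: dict | None = None) -> CohortStats:
    """Aggregate per-family cycle records and embryo-level tallies.

    ``tallies`` supplies the embryo-level counts that cannot be derived
    from cycle rows: ``inconclusive_embryos``, ``aneuploid_embryos``,
    ``malbac_failures``, ``ado_events``, ``pcr_rounds``,
    ``wildtype_transferable``, ``carrier_transferable``, ``ar_couples``,
    ``couples_without_wildtype``.  Missing keys leave the corresponding
    rates absent.
    """
    tallies = tallies or {}
    records = list(cycle_records)
    totals = {
        "couples": len(records),
        "cycles": sum(r.cycles for r in records),
        "embryos": sum(r.total_embryos for r in records),
        "transferable": sum(r.transferable for r in records),
        "transfers": sum(r.implantation_times for r in records),
        "pregnancies": sum(r.pregnancies for r in records),
        "miscarriages": sum(r.miscarriages for r in records),
        "live_births": sum(r.live_births for r in records),
    }
    for key in ("inconclusive_embryos", "aneuploid_embryos", "malbac_failures",
                "ado_events", "pcr_rounds", "wildtype_transferable",
                "carrier_transferable", "ar_couples", "couples_without_wildtype"):
        if key in tallies:
            totals[key] = tallies[key]

    embryos = totals["embryos"]
    inconclusive = tallies.get("inconclusive_embryos")
    ar_transferable = (
        tallies.get("wildtype_transferable", 0) + tallies.get("carrier_transferable", 0)
        if ("wildtype_transferable" in tallies or "carrier_transferable" in tallies)
        else None
    )
    rates = {
        "conclusive_pct": _rate(embryos - inconclusive, embryos) if inconclusive is not None else None,
        "inconclusive_pct": _rate(inconclusive, embryos) if inconclusive is not None else None,
        "aneuploid_pct": _rate(tallies.get("aneuploid_embryos"), embryos)
        if "aneuploid_embryos" in tallies else None,
        "transferable_pct": _rate(totals["transferable"], embryos),
        "wildtype_share_pct": _rate(tallies.get("wildtype_transferable"), ar_transferable)
        if ar_transferable else None,
        "carrier_share_pct": _rate(tallies.get("carrier_transferable"), ar_transferable)
        if ar_transferable else None,
        "couples_without_wildtype_pct": _rate(tallies.get("couples_without_wildtype"),
                                              tallies.get("ar_couples"))
        if "couples_without_wildtype" in tallies else None,
        "pregnancy_rate_pct": _rate(totals["pregnancies"], totals["transfers"]),
        "live_birth_rate_pct": _rate(totals["live_births"], totals["cycles"]),
        "miscarriage_pct": _rate(totals["miscarriages"], totals["transfers"]),
        "malbac_failure_pct": _rate(tallies.get("malbac_failures"), embryos)
        if "malbac_failures" in tallies else None,
        "ado_rate_pct": _rate(tallies.get("ado_events"), tallies.get("pcr_rounds"))
        if "pcr_rounds" in tallies else None,
    }
    mean_age = (sum(r.female_age for r in records) / len(records)) if records else None
    return CohortStats(totals=totals, rates=rates, mean_female_age=mean_age)
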