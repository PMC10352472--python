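"""Synthetic families, embryos, bin counts and cohorts with known truth.

The generator emulates the statistical structure the diagnosis relies on:
biallelic flanking SNPs with MAF above 0.1 within 1 Mb of the gene,
parental haplotypes with the pathogenic allele anchored on one homolog,
embryo inheritance with distance-dependent meiotic recombination,
overdispersed single-cell sequencing depth with beta-distributed allele
imbalance and an all-or-none allele-dropout (ADO) process at 2.8% per
assay, and 1.5 M-read multinomial bin counts with a smooth GC-bias curve
under arbitrary karyotypes (aneuploid fraction 38.2% at the cohort level).

Everything is driven by explicit seeds: the same seed reproduces the same
tables bit for bit, and every generated file parses cleanly through the
package readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .classify import classify_embryo
from .genome import GENE_REGIONS, make_bins
from .genotyping import call_site_genotype
from .linkage import status_from_link
from .model import FamilyDesign, SiteCall, SnpMarker, Thresholds, VariantAllele

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults are the study conditions being emulated."""

    seed: int = 0
    n_markers: int = 90
    maf_range: tuple = (0.1, 0.5)
    recomb_prob_per_mb: float = 0.01
    ado_prob: float = 0.028
    site_depth_mean: float = 300.0
    depth_dispersion: float = 0.15   # NB overdispersion: var = mu + disp*mu^2
    allele_imbalance_sd: float = 0.08
    cnv_total_reads: int = 1_500_000
    gc_bias_coefficients: tuple = (1.2, -3.0)
    aneuploid_fraction: float = 0.382
    malbac_failure_prob: float = 0.009
    embryos_per_cycle_mean: float = 6.3

    def __post_init__(self):
        for name in ("recomb_prob_per_mb", "ado_prob", "aneuploid_fraction",
                     "malbac_failure_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")


@dataclass
class KaryotypeEvent:
    kind: str            # "gain" | "loss" | "segment"
    chrom: str
    cn: float = 3.0      # absolute copy number of the event
    start: Optional[int] = None
    end: Optional[int] = None


@dataclass
class KaryotypeSpec:
    events: list = field(default_factory=list)
    contaminated: bool = False
    failed: bool = False

    @property
    def is_euploid(self) -> bool:
        return not self.events and not self.contaminated and not self.failed


@dataclass
class FamilyTruth:
    """A simulated family with its generating haplotypes exposed."""

    family: FamilyDesign
    bank: list                       # SnpMarker list (the family's panel bank)
    gene_region: tuple               # (chrom, start, end)
    # parent -> {"M": {site: allele}, "N": {site: allele}} over markers+variants
    haplotypes: dict = field(default_factory=dict)
    member_calls: dict = field(default_factory=dict)  # sample -> {site: SiteCall}
    positions: dict = field(default_factory=dict)     # site_id -> bp


@dataclass
class EmbryoSim:
    """One simulated biopsy with its generating truth."""

    embryo_id: str
    calls: dict                       # site_id -> SiteCall
    truth_transmission: dict          # parent -> "M" | "N" (at the gene)
    truth_status: str                 # verdict-space monogenic status
    ado_assay_sites: list = field(default_factory=list)  # sites where the dropout draw fired
    ado_het_sites: list = field(default_factory=list)    # draws that hit a heterozygote


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_snp_bank(region=None, n: int = 90, maf_range=(0.1, 0.5),
                      seed=0, window_bp: int = 1_000_000) -> list:
    """Markers uniformly positioned in the gene region +/- window.

    MAF is uniform over ``maf_range``; allele pairs are random distinct
    bases.  Positions are unique, so the bank sorts deterministically.
    """
    rng = _rng(seed)
    chrom, start, end = region or GENE_REGIONS["SLC26A4"]
    lo, hi = max(1, start - window_bp), end + window_bp
    positions = rng.choice(np.arange(lo, hi + 1), size=n, replace=False)
    positions.sort()
    markers = []
    for i, pos in enumerate(positions):
        a, b = rng.choice(4, size=2, replace=False)
        markers.append(SnpMarker(
            marker_id=f"rs{chrom}_{i:04d}", chrom=chrom, pos=int(pos),
            allele_a=_BASES[a], allele_b=_BASES[b],
            maf=float(rng.uniform(*maf_range)),
        ))
    return markers


def _default_variants(gene: str, region, mode: str, same_variant: bool):
    chrom, start, end = region
    span = end - start
    if mode == "AD":
        return [], [VariantAllele(gene, chrom, start + span // 3, "G", "A",
                                  "c.733G>A", "paternal")]
    if same_variant:
        v = VariantAllele(gene, chrom, start + span // 2, "C", "T",
                          "c.235delC", "both")
        return [v], [replace(v)]
    vm = VariantAllele(gene, chrom, start + (2 * span) // 3, "A", "G",
                       "c.2168A>G", "maternal")
    vp = VariantAllele(gene, chrom, start + span // 4, "G", "C",
                       "c.697G>C", "paternal")
    return [vm], [vp]


def _draw_haplotype(rng, bank) -> dict:
    """One population haplotype: allele 'B' with probability MAF per marker."""
    return {m.marker_id: ("B" if rng.random() < m.maf else "A") for m in bank}


def _member_call(genotype: str, site_id: str, depth: int = 400) -> SiteCall:
    if genotype == "AB":
        da = db = depth // 2
    elif genotype == "AA":
        da, db = depth, 0
    else:
        da, db = 0, depth
    return call_site_genotype(da, db, site_id=site_id)


def _genotype_of(hap1: dict, hap2: dict, site: str) -> str:
    return "".join(sorted((hap1[site], hap2[site])))


def _transmit(rng, positions_sorted, hap_m: dict, hap_n: dict,
              recomb_prob_per_mb: float, anchor_site=None, anchor_state=None):
    """Transmit one recombinant haplotype across ordered loci.

    The transmitted state ('M'/'N') performs a two-state walk along the
    chromosome with switch probability proportional to inter-locus distance.
    With an anchor, the walk is run outward from the anchor locus with the
    anchored state, which conditions on the transmission at that locus
    (used for affected reference children, who must carry M at the gene).
    """
    sites = [s for s, _ in positions_sorted]
    pos = np.array([p for _, p in positions_sorted], dtype=float)
    n = len(sites)
    states = np.empty(n, dtype="<U1")

    def step(prev_state, dist_bp):
        p_switch = min(recomb_prob_per_mb * dist_bp / 1e6, 0.5)
        if rng.random() < p_switch:
            return "N" if prev_state == "M" else "M"
        return prev_state

    if anchor_site is None:
        state = "M" if rng.random() < 0.5 else "N"
        k0 = 0
        states[0] = state
        for i in range(1, n):
            states[i] = step(states[i - 1], pos[i] - pos[i - 1])
    else:
        k0 = sites.index(anchor_site)
        states[k0] = anchor_state
        for i in range(k0 + 1, n):
            states[i] = step(states[i - 1], pos[i] - pos[i - 1])
        for i in range(k0 - 1, -1, -1):
            states[i] = step(states[i + 1], pos[i + 1] - pos[i])
    return {
        s: (hap_m[s] if states[i] == "M" else hap_n[s]) for i, s in enumerate(sites)
    }, {s: states[i] for i, s in enumerate(sites)}


def simulate_family(bank=None, mode: str = "AR", gene: str = "SLC26A4",
                    same_variant: bool = False,
                    reference_type: str = "affected_child",
                    seed=0, params: SimParams | None = None) -> FamilyTruth:
    """Build a family design with truth haplotypes and member site calls.

    Carrier parents get the pathogenic allele anchored on haplotype M.  The
    reference is either an affected child (inheriting M from every carrier
    parent, with recombination) or the carrier parents' own parents.
    Member calls are clean high-depth genotypes (germline DNA, not
    single-cell material).
    """
    rng = _rng(seed)
    params = params or SimParams()
    region = GENE_REGIONS[gene]
    if bank is None:
        bank = simulate_snp_bank(region, n=params.n_markers,
                                 maf_range=params.maf_range, seed=rng)
    maternal, paternal = _default_variants(gene, region, mode, same_variant)

    members = {"father": "FATHER", "mother": "MOTHER"}
    if reference_type == "affected_child":
        members["child"] = "CHILD"
    else:
        for side in (["paternal"] if paternal else []) + (["maternal"] if maternal else []):
            members[f"{side}_grandfather"] = f"{side.upper()}_GF"
            members[f"{side}_grandmother"] = f"{side.upper()}_GM"
    family = FamilyDesign(
        family_id=f"SIM{int(_rng(seed).integers(1, 10_000)):05d}", gene=gene,
        mode=mode, maternal_variants=maternal, paternal_variants=paternal,
        reference_type=reference_type, members=members,
    )

    positions = {m.marker_id: m.pos for m in bank}
    for v in maternal + paternal:
        positions[v.site_id] = v.pos
    variant_sites = {v.site_id for v in maternal + paternal}

    haplotypes = {}
    for parent, variants in (("father", paternal), ("mother", maternal)):
        hap_m = _draw_haplotype(rng, bank)
        hap_n = _draw_haplotype(rng, bank)
        for v in maternal + paternal:
            carries = v in variants
            hap_m[v.site_id] = "B" if carries else "A"
            hap_n[v.site_id] = "A"
        haplotypes[parent] = {"M": hap_m, "N": hap_n}

    truth = FamilyTruth(family=family, bank=bank, gene_region=region,
                        haplotypes=haplotypes, positions=positions)

    all_sites = sorted(positions, key=positions.get)
    ordered = [(s, positions[s]) for s in all_sites]
    gene_mid = (region[1] + region[2]) // 2

    def sample_calls(hap1, hap2):
        return {s: _member_call(_genotype_of(hap1, hap2, s), s) for s in all_sites}

    truth.member_calls["FATHER"] = sample_calls(haplotypes["father"]["M"],
                                                haplotypes["father"]["N"])
    truth.member_calls["MOTHER"] = sample_calls(haplotypes["mother"]["M"],
                                                haplotypes["mother"]["N"])

    if reference_type == "affected_child":
        carrier = {"AR": ("father", "mother"),
                   "AD": (family.carrier_parent,)}[mode]
        child_haps = {}
        for parent in ("father", "mother"):
            hm, hn = haplotypes[parent]["M"], haplotypes[parent]["N"]
            if parent in carrier:
                anchor = family.variants_of(parent)[0].site_id
                hap, _ = _transmit(rng, ordered, hm, hn, params.recomb_prob_per_mb,
                                   anchor_site=anchor, anchor_state="M")
            else:
                hap, _ = _transmit(rng, ordered, hm, hn, params.recomb_prob_per_mb)
            child_haps[parent] = hap
        truth.member_calls["CHILD"] = sample_calls(child_haps["father"],
                                                   child_haps["mother"])
    else:
        for parent, variants in (("father", paternal), ("mother", maternal)):
            if not variants:
                continue
            side = "paternal" if parent == "father" else "maternal"
            # the parent's M haplotype came from one grandparent (the
            # variant carrier), N from the other
            gp_other_m = _draw_haplotype(rng, bank)
            gp_other_n = _draw_haplotype(rng, bank)
            for v in maternal + paternal:
                gp_other_m[v.site_id] = "A"
                gp_other_n[v.site_id] = "A"
            origin_is_gf = rng.random() < 0.5
            hm, hn = haplotypes[parent]["M"], haplotypes[parent]["N"]
            origin_calls = sample_calls(hm, gp_other_m)
            other_calls = sample_calls(hn, gp_other_n)
            gf_id, gm_id = f"{side.upper()}_GF", f"{side.upper()}_GM"
            if origin_is_gf:
                truth.member_calls[gf_id] = origin_calls
                truth.member_calls[gm_id] = other_calls
            else:
                truth.member_calls[gm_id] = origin_calls
                truth.member_calls[gf_id] = other_calls
    return truth


def _noisy_depths(rng, genotype: str, params: SimParams):
    mu = params.site_depth_mean
    disp = params.depth_dispersion
    if disp > 0:
        # negative binomial via gamma-Poisson mixture
        shape = 1.0 / disp
        lam = rng.gamma(shape, mu / shape)
        total = int(rng.poisson(lam))
    else:
        total = int(rng.poisson(mu))
    if total == 0:
        return 0, 0
    if genotype == "AA":
        return total, 0
    if genotype == "BB":
        return 0, total
    sd = max(params.allele_imbalance_sd, 1e-6)
    conc = max(0.25 / (sd * sd) - 1.0, 2.0) / 2.0
    p = rng.beta(conc, conc)
    da = int(rng.binomial(total, p))
    return da, total - da


def simulate_embryo(truth: FamilyTruth, params: SimParams | None = None,
                    seed=0, embryo_id: str = "E1") -> EmbryoSim:
    """One biopsy: recombinant transmission, noisy depths, ADO.

    Each parent transmits a recombinant haplotype; the truth label is the
    M/N state at the gene itself.  Per-site total depth is overdispersed,
    heterozygous sites get beta-distributed allele imbalance, and each
    variant-site (and panel-site) assay suffers all-or-none dropout of one
    allele with probability ``ado_prob``; every dropout draw on a variant
    site is logged as a truth event.
    """
    params = params or SimParams()
    rng = _rng(seed)
    family = truth.family
    positions = truth.positions
    all_sites = sorted(positions, key=positions.get)
    ordered = [(s, positions[s]) for s in all_sites]
    _, gstart, gend = truth.gene_region
    gene_mid = (gstart + gend) / 2

    haps, states = {}, {}
    for parent in ("father", "mother"):
        hm, hn = truth.haplotypes[parent]["M"], truth.haplotypes[parent]["N"]
        haps[parent], states[parent] = _transmit(
            rng, ordered, hm, hn, params.recomb_prob_per_mb)

    # truth per parent = transmitted state at that parent's own variant
    # site (disease-allele carriage); non-carrier parents (AD) fall back to
    # the locus nearest the gene
    def truth_locus(parent):
        variants = family.variants_of(parent)
        if variants:
            return variants[0].site_id
        return min(all_sites, key=lambda s: abs(positions[s] - gene_mid))

    transmission = {p: states[p][truth_locus(p)] for p in ("father", "mother")}
    truth_status = status_from_link(family, transmission)

    variant_sites = set(family.variant_site_sides())
    calls = {}
    ado_assays, ado_hets = [], []
    for site in all_sites:
        genotype = _genotype_of(haps["father"], haps["mother"], site)
        da, db = _noisy_depths(rng, genotype, params)
        if rng.random() < params.ado_prob:
            if site in variant_sites:
                ado_assays.append(site)
            if genotype == "AB":
                if site in variant_sites:
                    ado_hets.append(site)
                if rng.random() < 0.5:
                    da = 0
                else:
                    db = 0
        calls[site] = call_site_genotype(da, db, site_id=site)
    return EmbryoSim(embryo_id=embryo_id, calls=calls,
                     truth_transmission=transmission, truth_status=truth_status,
                     ado_assay_sites=ado_assays, ado_het_sites=ado_hets)


def _gc_bias_factor(gc: np.ndarray, coefficients) -> np.ndarray:
    c1, c2 = coefficients
    x = gc - 0.45
    return np.exp(c1 * x + c2 * x * x)


def simulate_bin_counts(karyotype: KaryotypeSpec | None = None,
                        params: SimParams | None = None, seed=0,
                        bin_size: int = 1_000_000):
    """Multinomial bin counts for one biopsy under a karyotype.

    Expected bin weight is bin length x local copy number x GC-bias
    factor.  Contamination adds heavy per-bin lognormal weight noise
    (foreign or degraded template); amplification failure collapses the
    read total.  Returns a list of raw ``BinRecord``.
    """
    from .model import BinRecord

    params = params or SimParams()
    karyotype = karyotype or KaryotypeSpec()
    rng = _rng(seed)
    tiles = make_bins(bin_size)
    chroms = np.array([t[0] for t in tiles])
    starts = np.array([t[1] for t in tiles])
    ends = np.array([t[2] for t in tiles])
    gcs = np.array([t[3] for t in tiles])

    cn = np.full(len(tiles), 2.0)
    for ev in karyotype.events:
        on_chrom = chroms == ev.chrom
        if ev.kind in ("gain", "loss"):
            cn[on_chrom] = ev.cn
        elif ev.kind == "segment":
            sel = on_chrom & (starts <= ev.end) & (ends >= ev.start)
            cn[sel] = ev.cn
        else:
            raise ValueError(f"unknown karyotype event kind {ev.kind!r}")

    weights = (ends - starts + 1.0) * (cn / 2.0) * _gc_bias_factor(
        gcs, params.gc_bias_coefficients)
    if karyotype.contaminated:
        weights = weights * rng.lognormal(0.0, 0.7, size=len(weights))
    total = params.cnv_total_reads
    if karyotype.failed:
        total = int(rng.integers(5_000, 60_000))
        weights = weights * rng.lognormal(0.0, 1.5, size=len(weights))
    counts = rng.multinomial(total, weights / weights.sum())
    return [
        BinRecord(chrom=c, start=int(s), end=int(e), gc_fraction=float(g),
                  raw_count=float(k))
        for c, s, e, g, k in zip(chroms, starts, ends, gcs, counts)
    ]


def random_karyotype(rng, aneuploid: bool) -> KaryotypeSpec:
    """A plausible abnormal (or euploid) karyotype for cohort simulation."""
    if not aneuploid:
        return KaryotypeSpec()
    roll = rng.random()
    chrom = str(int(rng.integers(1, 23)))
    if roll < 0.45:
        return KaryotypeSpec(events=[KaryotypeEvent("gain", chrom, cn=3.0)])
    if roll < 0.8:
        return KaryotypeSpec(events=[KaryotypeEvent("loss", chrom, cn=1.0)])
    if roll < 0.95:
        start = int(rng.integers(1, 30_000_000))
        return KaryotypeSpec(events=[KaryotypeEvent(
            "segment", chrom, cn=float(rng.choice([1.0, 1.5, 2.5, 3.0])),
            start=start, end=start + int(rng.integers(6, 40)) * 1_000_000)])
    return KaryotypeSpec(events=[
        KaryotypeEvent(rng.choice(["gain", "loss"]), str(c),
                       cn=3.0 if i % 2 else 1.0)
        for i, c in enumerate(rng.choice(np.arange(1, 23), size=6, replace=False))
    ])


@dataclass
class CohortTruth:
    cycle_records: list
    embryos: list          # dicts with family_id, embryo_id, truth fields
    tallies: dict


def simulate_cohort(params: SimParams | None = None, n_couples: int = 47,
                    seed=0) -> CohortTruth:
    """A whole cohort: couples, cycles, embryo truth labels, outcome rows.

    Embryo-level truth (karyotype, monogenic status, amplification failure)
    is drawn from the generator's rates; clinical outcomes per transfer use
    the study-level pregnancy, miscarriage and live-birth frequencies.
    Feeds ``cohort_summary`` end to end.
    """
    from .model import CycleRecord

    params = params or SimParams()
    rng = _rng(seed)
    genes = ["GJB2", "SLC26A4"]
    records, embryo_rows = [], []
    tallies = {k: 0 for k in (
        "inconclusive_embryos", "aneuploid_embryos", "malbac_failures",
        "ado_events", "pcr_rounds", "wildtype_transferable",
        "carrier_transferable", "ar_couples", "couples_without_wildtype")}

    for i in range(n_couples):
        mode = "AD" if rng.random() < 3 / 47 else "AR"
        gene = genes[int(rng.integers(0, 2))] if mode == "AR" else "KCNQ4"
        family_id = f"SIMFAM{i:03d}"
        age = float(np.round(rng.uniform(25, 40), 0))
        cycles = 1 + int(rng.random() < 7 / 47)
        n_embryos = int(max(1, rng.poisson(params.embryos_per_cycle_mean * cycles)))
        if mode == "AR":
            tallies["ar_couples"] += 1
        n_transferable = n_wildtype = 0
        for e in range(n_embryos):
            failed = rng.random() < params.malbac_failure_prob
            aneuploid = rng.random() < params.aneuploid_fraction
            # Mendelian draw at a recessive (or dominant) locus
            if mode == "AR":
                n_mut = int(rng.random() < 0.5) + int(rng.random() < 0.5)
                status = {0: "unaffected_noncarrier", 2: "affected"}.get(
                    n_mut, "carrier_maternal" if rng.random() < 0.5 else "carrier_paternal")
            else:
                status = "ad_variant_present" if rng.random() < 0.5 else "ad_variant_absent"
            n_assays = 1 if mode == "AD" else 2
            tallies["pcr_rounds"] += 0 if failed else n_assays
            if not failed:
                tallies["ado_events"] += int(rng.binomial(n_assays, params.ado_prob))
            category = ("amplification_failure" if failed
                        else ("aneuploid" if aneuploid else "euploid"))
            final = ("inconclusive" if failed
                     else classify_embryo(status, category, mode))
            if failed:
                tallies["malbac_failures"] += 1
                tallies["inconclusive_embryos"] += 1
            elif aneuploid:
                tallies["aneuploid_embryos"] += 1
            if final == "transferable_wildtype":
                n_wildtype += 1
                n_transferable += 1
                if mode == "AR":  # shares are defined over AR couples only
                    tallies["wildtype_transferable"] += 1
            elif final == "transferable_carrier":
                n_transferable += 1
                if mode == "AR":
                    tallies["carrier_transferable"] += 1
            embryo_rows.append({
                "family_id": family_id, "embryo_id": f"{family_id}_E{e + 1}",
                "mode": mode, "gene": gene, "malbac_failed": failed,
                "aneuploid": aneuploid, "truth_status": status,
                "final_class": final,
            })
        if mode == "AR" and n_wildtype == 0:
            tallies["couples_without_wildtype"] += 1
        transfers = min(n_transferable, 1 + int(rng.random() < 0.25))
        pregnancies = int(rng.binomial(transfers, 38 / 59))
        miscarriages = int(rng.binomial(pregnancies, 4 / 38))
        live = pregnancies - miscarriages
        records.append(CycleRecord(
            family_id=family_id, female_age=age, gene=gene, mode=mode,
            maternal_variants="simulated", paternal_variants="simulated",
            cycles=cycles, total_embryos=n_embryos, transferable=n_transferable,
            implantation_times=transfers, pregnancies=pregnancies,
            miscarriages=miscarriages, live_births=live,
            outcome="simulated",
        ))
    return CohortTruth(cycle_records=records, embryos=embryo_rows, tallies=tallies)
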