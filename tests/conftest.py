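"""Shared fixtures: simulated families at zero noise and a constructed
compound-heterozygous scenario with a non-mutant allele dropout."""

from __future__ import annotations

import pytest

from pgtdx import SimParams, Thresholds
from pgtdx.model import FamilyDesign, VariantAllele
from pgtdx.panel import SnpPanel
from pgtdx.phasing import ParentalHaplotypes, phase_family
from pgtdx.simulate import simulate_family

SLC26A4_REGION = ("7", 107_301_080, 107_358_254)


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free generator settings: no dropout, no recombination."""
    return SimParams(ado_prob=0.0, recomb_prob_per_mb=0.0,
                     allele_imbalance_sd=0.02, depth_dispersion=0.0)


@pytest.fixture(scope="session")
def ar_family(clean_params):
    """A compound-het AR family phased at zero noise: (truth, panel, haps)."""
    truth = simulate_family(seed=11, params=clean_params)
    panel, haps = phase_family(truth.bank, truth.family, truth.member_calls,
                               gene_region=truth.gene_region)
    return truth, panel, haps


def make_compound_het_family():
    """An AR couple with distinct maternal/paternal alleles of one gene.

    Mirrors a pendrin-gene (SLC26A4) couple: mother carries c.2168A>G,
    father carries c.697G>C; the affected child is the phasing reference.
    """
    chrom, start, end = SLC26A4_REGION
    vm = VariantAllele("SLC26A4", chrom, 107_350_000, "A", "G", "c.2168A>G", "maternal")
    vp = VariantAllele("SLC26A4", chrom, 107_315_000, "G", "C", "c.697G>C", "paternal")
    return FamilyDesign(
        family_id="FCASE", gene="SLC26A4", mode="AR",
        maternal_variants=[vm], paternal_variants=[vp],
        members={"father": "F", "mother": "M", "child": "C"},
    )


@pytest.fixture
def dropout_case():
    """Worked non-mutant-allele-dropout scenario.

    The embryo reads homozygous-alt at the maternal variant site although
    the father does not carry that allele (his wild-type allele dropped
    out); linkage is determinate: paternal N, maternal M.  Returns
    (family, panel, haps, father_calls, mother_calls, embryo_calls).
    """
    family = make_compound_het_family()
    chrom, start, end = SLC26A4_REGION
    father_marks = [f"pf{i}" for i in range(5)]
    mother_marks = [f"pm{i}" for i in range(5)]
    positions = {}
    for i, mid in enumerate(father_marks):
        positions[mid] = start - 900_000 + i * 400_000
    for i, mid in enumerate(mother_marks):
        positions[mid] = start - 700_000 + i * 400_000
    panel = SnpPanel(gene="SLC26A4", chrom=chrom, start=start, end=end)
    haps_father = ParentalHaplotypes(
        parent="father",
        phase={mid: ("A", "B") for mid in father_marks},
        positions={mid: positions[mid] for mid in father_marks},
    )
    haps_mother = ParentalHaplotypes(
        parent="mother",
        phase={mid: ("A", "B") for mid in mother_marks},
        positions={mid: positions[mid] for mid in mother_marks},
    )
    father_calls = {mid: "AB" for mid in father_marks}
    father_calls.update({mid: "AA" for mid in mother_marks})
    mother_calls = {mid: "AB" for mid in mother_marks}
    mother_calls.update({mid: "AA" for mid in father_marks})
    embryo_calls = {}
    # father transmitted N (allele B): embryo AB at his informative markers
    for mid in father_marks:
        embryo_calls[mid] = "AB"
    # mother transmitted M (allele A): embryo AA at her informative markers
    for mid in mother_marks:
        embryo_calls[mid] = "AA"
    embryo_calls["c.2168A>G"] = "BB"  # paternal wild-type allele dropped out
    embryo_calls["c.697G>C"] = "AA"
    return family, panel, {"father": haps_father, "mother": haps_mother}, \
        father_calls, mother_calls, embryo_calls
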