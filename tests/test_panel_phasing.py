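"""Panel selection and pedigree phasing, checked against brute-force
Mendelian enumeration and the simulator's generating haplotypes."""

import itertools

import pytest

from pgtdx import SimParams, SnpMarker, Thresholds
from pgtdx.model import (
    GENO_ALLELES,
    InvalidReferenceError,
    PedigreeInconsistencyError,
    ReferenceAmbiguityError,
)
from pgtdx.panel import PanelSelectionError, select_panel
from pgtdx.phasing import (
    informative_sites,
    phase_family,
    phase_with_child,
    phase_with_grandparents,
)
from pgtdx.simulate import simulate_family, simulate_snp_bank

from conftest import SLC26A4_REGION, make_compound_het_family

GENOS = ("AA", "AB", "BB")


def brute_force_child_phase(gp, go, gc):
    """Enumerate haplotype assignments consistent with the affected child
    having received the parent's M haplotype; unique assignment -> phase."""
    if gp not in GENO_ALLELES or gc not in GENO_ALLELES:
        return None
    other = set(GENO_ALLELES.get(go, ("A", "B")))
    child = tuple(sorted(GENO_ALLELES[gc]))
    consistent = []
    pa, pb = GENO_ALLELES[gp]
    for m, n in {(pa, pb), (pb, pa)}:
        if any(tuple(sorted((m, b))) == child for b in other):
            consistent.append((m, n))
    if gp == "AB" and len(consistent) == 1:
        return consistent[0]
    return None


def _phase_markers(trios, tolerant=True):
    """Run phase_with_child on a constructed multi-marker panel."""
    family = make_compound_het_family()
    thr = Thresholds(max_mendelian_error_rate=1.0) if tolerant else Thresholds()
    parent = {f"m{i}": gp for i, (gp, _, _) in enumerate(trios)}
    other = {f"m{i}": go for i, (_, go, _) in enumerate(trios)}
    child = {f"m{i}": gc for i, (_, _, gc) in enumerate(trios)}
    child["c.2168A>G"] = "AB"
    child["c.697G>C"] = "AB"
    return phase_with_child(parent, other, child, family, "mother",
                            panel=None, thresholds=thr)


class TestSelectPanel:
    def _bank(self, n=200, seed=0, maf_range=(0.0, 0.5)):
        return simulate_snp_bank(SLC26A4_REGION, n=n, seed=seed,
                                 maf_range=maf_range, window_bp=2_000_000)

    def test_overflow_keeps_target_size_and_subset(self):
        bank = self._bank(n=300, maf_range=(0.05, 0.5))
        thr = Thresholds()
        panel = select_panel(bank, SLC26A4_REGION, thr)
        chrom, start, end = SLC26A4_REGION
        qualifying = {
            m.marker_id for m in bank
            if m.maf > thr.maf_min
            and (start - thr.window_bp) <= m.pos <= (end + thr.window_bp)
        }
        assert len(panel) == thr.panel_target
        assert set(panel.marker_ids) <= qualifying
        assert panel.markers == sorted(panel.markers)

    def test_underflow_returns_all_qualifying_with_warning(self):
        bank = self._bank(n=120, maf_range=(0.0, 0.5))
        thr = Thresholds()
        chrom, start, end = SLC26A4_REGION
        expected = {
            m.marker_id for m in bank
            if m.maf > thr.maf_min
            and (start - thr.window_bp) <= m.pos <= (end + thr.window_bp)
        }
        assert len(expected) < thr.panel_target
        with pytest.warns(UserWarning, match="qualifying"):
            panel = select_panel(bank, SLC26A4_REGION, thr)
        assert set(panel.marker_ids) == expected

    def test_window_boundary_inclusive(self):
        chrom, start, end = SLC26A4_REGION
        thr = Thresholds()
        at_edge = SnpMarker(chrom=chrom, pos=start - thr.window_bp,
                            marker_id="edge", maf=0.3)
        beyond = SnpMarker(chrom=chrom, pos=start - thr.window_bp - 1,
                           marker_id="beyond", maf=0.3)
        with pytest.warns(UserWarning):  # tiny panel, far below target
            panel = select_panel([at_edge, beyond], SLC26A4_REGION, thr)
        assert panel.marker_ids == ["edge"]

    def test_no_qualifying_markers_is_an_error(self):
        low = [SnpMarker(chrom="7", pos=107_301_080, marker_id="low", maf=0.05)]
        with pytest.raises(PanelSelectionError, match="no informative scaffold"):
            select_panel(low, SLC26A4_REGION)


class TestPhaseWithChild:
    def test_matches_brute_force_on_all_trio_combinations(self):
        """Exhaustive (27 combos): unique Mendelian transmission <-> phase."""
        trios = list(itertools.product(GENOS, repeat=3))
        haps = _phase_markers(trios)
        for i, (gp, go, gc) in enumerate(trios):
            expected = brute_force_child_phase(gp, go, gc)
            got = haps.phase.get(f"m{i}")
            assert got == expected, (gp, go, gc)

    def test_transmitted_allele_lands_on_mutant_haplotype(self):
        # father AB, mother AB, child BB: father must have transmitted B,
        # so B sits on his mutant-linked haplotype
        family = make_compound_het_family()
        child = {"m0": "BB", "c.2168A>G": "AB", "c.697G>C": "AB"}
        haps = phase_with_child({"m0": "AB"}, {"m0": "AB"}, child,
                                family, "father")
        assert haps.phase["m0"] == ("B", "A")

    def test_impossible_trio_is_unphased_not_misassigned(self):
        # father AB, mother AA, child BB: no Mendelian explanation exists
        haps = _phase_markers([("AB", "AA", "BB")])
        assert haps.phase == {}
        assert haps.mendelian_impossible == ["m0"]

    def test_homozygous_parent_uninformative(self):
        haps = _phase_markers([("AA", "AB", "AA")])
        assert haps.n_informative == 0

    def test_double_heterozygote_ambiguous(self):
        haps = _phase_markers([("AB", "AB", "AB")])
        assert haps.phase == {}

    def test_child_without_parental_variant_rejected(self):
        family = make_compound_het_family()
        child = {"m0": "AB", "c.2168A>G": "AA", "c.697G>C": "AB"}
        with pytest.raises(InvalidReferenceError, match="c.2168A>G"):
            phase_with_child({"m0": "AB"}, {"m0": "AA"}, child, family, "mother")

    def test_systematic_mendelian_errors_raise(self):
        # 100 markers, all impossible (parent AA, child BB) -> sample swap
        trios = [("AA", "AA", "BB")] * 100
        with pytest.raises(PedigreeInconsistencyError):
            _phase_markers(trios, tolerant=False)

    def test_zero_noise_simulation_recovers_generating_phase(self, ar_family):
        truth, panel, haps = ar_family
        for parent in ("father", "mother"):
            hap_m = truth.haplotypes[parent]["M"]
            assert haps[parent].n_informative > 0
            for mid, (m, _) in haps[parent].phase.items():
                assert hap_m[mid] == m

    def test_informative_count_monotone_under_marker_removal(self, ar_family):
        truth, panel, haps = ar_family
        full = haps["father"].n_informative
        reduced_calls = {
            s: {k: v for k, v in calls.items() if k not in panel.marker_ids[:30]}
            for s, calls in truth.member_calls.items()
        }
        hf = phase_with_child(reduced_calls["FATHER"], reduced_calls["MOTHER"],
                              reduced_calls["CHILD"], truth.family, "father")
        assert hf.n_informative <= full


class TestPhaseWithGrandparents:
    def _family(self, seed=21):
        return simulate_family(seed=seed, reference_type="grandparents")

    def test_unique_origin_assignment(self):
        family = make_compound_het_family()
        family.reference_type = "grandparents"
        family.members = {"father": "F", "mother": "M",
                          "maternal_grandfather": "GF", "maternal_grandmother": "GM"}
        gf = {"m0": "AA", "c.2168A>G": "AB"}  # variant carrier
        gm = {"m0": "BB", "c.2168A>G": "AA"}
        haps = phase_with_grandparents({"m0": "AB"}, gf, gm, family, "mother")
        assert haps.phase["m0"] == ("A", "B")

    def test_both_grandparents_het_ambiguous(self):
        family = make_compound_het_family()
        gf = {"m0": "AB", "c.2168A>G": "AB"}
        gm = {"m0": "AB", "c.2168A>G": "AA"}
        haps = phase_with_grandparents({"m0": "AB"}, gf, gm, family, "mother")
        assert haps.phase == {}

    def test_missing_grandparent_calls_tolerated(self):
        family = make_compound_het_family()
        gf = {"c.2168A>G": "AB"}
        gm = {"c.2168A>G": "AA"}
        haps = phase_with_grandparents({"m0": "AB"}, gf, gm, family, "mother")
        assert haps.phase == {} and haps.n_assessed == 0

    def test_ambiguous_variant_carriage_rejected(self):
        family = make_compound_het_family()
        gf = {"c.2168A>G": "AB"}
        gm = {"c.2168A>G": "AB"}
        with pytest.raises(ReferenceAmbiguityError):
            phase_with_grandparents({"m0": "AB"}, gf, gm, family, "mother")

    def test_simulated_grandparent_phasing_recovers_truth(self, clean_params):
        truth = simulate_family(seed=31, reference_type="grandparents",
                                params=clean_params)
        panel, haps = phase_family(truth.bank, truth.family, truth.member_calls,
                                   gene_region=truth.gene_region)
        for parent in ("father", "mother"):
            assert haps[parent].n_informative > 0
            for mid, (m, _) in haps[parent].phase.items():
                assert truth.haplotypes[parent]["M"][mid] == m


class TestInformativeSites:
    def test_counts_match_phased_subsets(self, ar_family):
        truth, panel, haps = ar_family
        info = informative_sites(haps["father"], haps["mother"], panel)
        assert info["n_father"] == len(info["father"]) == haps["father"].n_informative
        assert info["n_mother"] == len(info["mother"]) == haps["mother"].n_informative

    def test_fully_homozygous_parent_yields_zero(self):
        family = make_compound_het_family()
        parent = {f"m{i}": "AA" for i in range(10)}
        other = {f"m{i}": "AB" for i in range(10)}
        child = {f"m{i}": "AA" for i in range(10)}
        child.update({"c.2168A>G": "AB", "c.697G>C": "AB"})
        haps = phase_with_child(parent, other, child, family, "mother")
        assert haps.n_informative == 0

    def test_simulated_counts_in_clinical_band(self, clean_params):
        """Per-parent informative counts sit in the 14-54 range reported
        for real families at 90 markers with MAF uniform on (0.1, 0.5)."""
        counts = []
        for seed in range(1, 26):
            truth = simulate_family(seed=seed, params=clean_params)
            _, haps = phase_family(truth.bank, truth.family, truth.member_calls,
                                   gene_region=truth.gene_region)
            counts += [haps["father"].n_informative, haps["mother"].n_informative]
        mean = sum(counts) / len(counts)
        assert 14 <= mean <= 54
        assert sum(14 <= c <= 54 for c in counts) / len(counts) >= 0.9
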