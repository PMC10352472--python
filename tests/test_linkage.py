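"""Haplotype-vote transmission, recombination handling, ADO reconciliation
and the dropout-rate estimator."""

import pytest

from pgtdx import SimParams, Thresholds, ado_rate, detect_recombination
from pgtdx.genotyping import DirectVerdict
from pgtdx.linkage import (
    TransmissionResult,
    infer_transmission,
    reconcile,
    status_from_link,
)
from pgtdx.phasing import ParentalHaplotypes
from pgtdx.simulate import simulate_embryo

from conftest import SLC26A4_REGION, make_compound_het_family

GENE_REGION = SLC26A4_REGION


def make_haps(n=20, start=106_000_000, step=120_000, phase=("A", "B")):
    """A father phased at n markers upstream+downstream of the gene."""
    marks = [f"v{i}" for i in range(n)]
    return ParentalHaplotypes(
        parent="father",
        phase={m: phase for m in marks},
        positions={m: start + i * step for i, m in enumerate(marks)},
    )


def embryo_calls_for_votes(haps, votes, other="AA"):
    """Embryo genotypes realizing a desired vote string over haps' markers.

    The other parent is homozygous 'AA' everywhere, so the embryo genotype
    directly exposes the focal parent's transmitted allele.
    """
    calls = {}
    for mid, vote in zip(haps.informative_markers, votes):
        m, n = haps.phase[mid]
        allele = m if vote == "M" else n
        calls[mid] = "".join(sorted(allele + "A"))
    other_calls = {mid: other for mid in haps.phase}
    return calls, other_calls


class TestInferTransmission:
    def test_unanimous_votes(self):
        haps = make_haps(20)
        calls, other = embryo_calls_for_votes(haps, "M" * 20)
        res = infer_transmission(calls, haps, other, gene_region=GENE_REGION)
        assert (res.inherited, res.concordance) == ("M", 1.0)
        assert res.votes_M == 20 and res.votes_N == 0

    def test_isolated_discordant_vote_logged_not_fatal(self):
        haps = make_haps(20)
        votes = "M" * 10 + "N" + "M" * 9
        calls, other = embryo_calls_for_votes(haps, votes)
        res = infer_transmission(calls, haps, other, gene_region=GENE_REGION)
        assert res.inherited == "M"
        assert res.concordance == pytest.approx(19 / 20)
        assert res.discordant_sites == [haps.informative_markers[10]]
        assert res.recombination_breakpoint is None

    def test_no_determinate_votes_indeterminate(self):
        haps = make_haps(10)
        calls = {mid: "nocall" for mid in haps.phase}
        res = infer_transmission(calls, haps, {}, gene_region=GENE_REGION)
        assert res.inherited == "indeterminate"
        assert res.votes_indeterminate == 10

    def test_too_few_votes_indeterminate(self, thresholds):
        haps = make_haps(2)
        calls, other = embryo_calls_for_votes(haps, "MM")
        res = infer_transmission(calls, haps, other, thresholds, GENE_REGION)
        assert res.inherited == "indeterminate"

    def test_low_concordance_indeterminate(self):
        haps = make_haps(20)
        votes = "MNMNMNMNMN" + "M" * 10  # 15 M vs 5 N interleaved: 75% < 80%
        calls, other = embryo_calls_for_votes(haps, votes)
        res = infer_transmission(calls, haps, other, gene_region=GENE_REGION)
        assert res.inherited == "indeterminate"

    def test_vote_conservation(self):
        """votes_M + votes_N + votes_indeterminate == markers assessed."""
        haps = make_haps(30)
        votes = "M" * 18 + "N" * 12
        calls, other = embryo_calls_for_votes(haps, votes)
        for drop in (0, 5, 29):
            partial = dict(list(calls.items())[drop:])
            res = infer_transmission(partial, haps, other, gene_region=GENE_REGION)
            assert res.n_assessed == 30

    def test_matches_brute_force_on_small_panels(self):
        """Oracle equivalence: per-marker votes equal direct enumeration of
        both haplotype hypotheses on panels of up to 6 markers."""
        import itertools

        from pgtdx.model import GENO_ALLELES

        def brute_vote(phase, other_geno, embryo_geno):
            if embryo_geno not in GENO_ALLELES:
                return None
            other = set(GENO_ALLELES.get(other_geno, ("A", "B")))
            target = tuple(sorted(GENO_ALLELES[embryo_geno]))
            fits = {
                hyp for hyp, allele in zip(("M", "N"), phase)
                if any(tuple(sorted((allele, b))) == target for b in other)
            }
            return next(iter(fits)) if len(fits) == 1 else None

        genos = ("AA", "AB", "BB", "nocall")
        cases = list(itertools.product([("A", "B"), ("B", "A")], genos, genos))
        for chunk in range(0, len(cases), 6):
            batch = cases[chunk:chunk + 6]
            haps = ParentalHaplotypes(
                parent="father",
                phase={f"m{i}": phase for i, (phase, _, _) in enumerate(batch)},
                positions={f"m{i}": 1000 + i for i in range(len(batch))},
            )
            embryo = {f"m{i}": ge for i, (_, _, ge) in enumerate(batch)}
            other = {f"m{i}": go for i, (_, go, _) in enumerate(batch)}
            res = infer_transmission(embryo, haps, other,
                                     Thresholds(min_informative_per_parent=1))
            expected = [brute_vote(ph, go, ge) for ph, go, ge in batch]
            assert res.votes_M == sum(1 for v in expected if v == "M")
            assert res.votes_N == sum(1 for v in expected if v == "N")
            assert res.votes_indeterminate == sum(1 for v in expected if v is None)

    def test_raising_concordance_never_creates_a_call(self):
        """Monotonicity: a stricter concordance floor can only withdraw
        determinate calls, never add one."""
        haps = make_haps(20)
        votes = "M" * 17 + "N" * 3
        calls, other = embryo_calls_for_votes(haps, votes)
        previous = None
        for cmin in (0.55, 0.7, 0.85, 0.95):
            res = infer_transmission(
                calls, haps, other, Thresholds(vote_concordance_min=cmin),
                GENE_REGION)
            if previous == "indeterminate":
                assert res.inherited == "indeterminate"
            previous = res.inherited


class TestDetectRecombination:
    def test_distal_crossover_excluded_from_call(self):
        haps = make_haps(9, start=106_200_000, step=150_000)
        votes = "MMMMMM" + "NNN"
        calls, other = embryo_calls_for_votes(haps, votes)
        res = infer_transmission(calls, haps, other, gene_region=GENE_REGION)
        assert res.inherited == "M"
        assert res.concordance == 1.0
        assert res.recombination_breakpoint is not None
        assert len(res.excluded_sites) == 3

    def test_crossover_over_the_gene_is_indeterminate(self):
        # markers flank the gene; the switch interval spans it
        positions = [107_000_000 + i * 100_000 for i in range(3)] + \
            [107_400_000 + i * 100_000 for i in range(3)]
        haps = ParentalHaplotypes(
            parent="father",
            phase={f"v{i}": ("A", "B") for i in range(6)},
            positions={f"v{i}": p for i, p in enumerate(positions)},
        )
        calls, other = embryo_calls_for_votes(haps, "MMMNNN")
        res = infer_transmission(calls, haps, other, gene_region=GENE_REGION)
        assert res.inherited == "indeterminate"
        assert res.recombination_breakpoint is not None

    def test_no_discordant_run_no_breakpoint(self):
        bp, excluded = detect_recombination(
            [(i, "M") for i in range(10)], GENE_REGION)
        assert bp is None and excluded == set()

    def test_single_terminal_discordant_not_a_block(self):
        seq = [(i, "M") for i in range(9)] + [(9, "N")]
        bp, excluded = detect_recombination(seq, GENE_REGION)
        assert bp is None and excluded == set()


class TestReconcile:
    def _transmission(self, parent, inherited):
        return TransmissionResult(parent=parent, inherited=inherited,
                                  votes_M=10 if inherited == "M" else 0,
                                  votes_N=10 if inherited == "N" else 0,
                                  concordance=None if inherited == "indeterminate" else 1.0)

    def test_nonmutant_dropout_rescued(self, dropout_case):
        """Hom-alt at the maternal-only site plus determinate linkage
        (paternal N, maternal M) resolves to a maternal carrier with one
        non-mutant-allele-dropout event."""
        family, panel, haps, father_calls, mother_calls, embryo_calls = dropout_case
        from pgtdx import diagnose_embryo

        verdict, direct, tf, tm = diagnose_embryo(
            family, panel, haps["father"], haps["mother"],
            father_calls, mother_calls, embryo_calls)
        assert direct.status == "mendelian_impossible"
        assert (tf.inherited, tm.inherited) == ("N", "M")
        assert verdict.status == "carrier_maternal"
        assert verdict.basis == "ado_rescued"
        assert len(verdict.ado_events) == 1
        event = verdict.ado_events[0]
        assert event.site_id == "c.2168A>G"
        assert event.resolution == "non_mutant_allele_dropout"

    def test_mutant_dropout_rescued_by_linkage(self):
        """Truly compound-het embryo whose paternal alt allele dropped:
        direct looks carrier_maternal, linkage says affected."""
        family = make_compound_het_family()
        direct = DirectVerdict("carrier_maternal",
                               {"c.2168A>G": "AB", "c.697G>C": "AA"})
        verdict = reconcile(direct, self._transmission("father", "M"),
                            self._transmission("mother", "M"), family)
        assert verdict.status == "affected"
        assert verdict.basis == "ado_rescued"
        assert verdict.ado_events[0].resolution == "rescued_by_linkage"
        assert verdict.ado_events[0].site_id == "c.697G>C"

    def test_concordant_agreement(self):
        family = make_compound_het_family()
        direct = DirectVerdict("affected_compound_het",
                               {"c.2168A>G": "AB", "c.697G>C": "AB"})
        verdict = reconcile(direct, self._transmission("father", "M"),
                            self._transmission("mother", "M"), family)
        assert (verdict.status, verdict.basis) == ("affected", "concordant")
        assert verdict.ado_events == []

    def test_contradiction_without_dropout_pattern_indeterminate(self):
        """Direct het at the maternal site but maternal linkage N: a het
        cannot arise from allele dropout, so no diagnosis is safe."""
        family = make_compound_het_family()
        direct = DirectVerdict("carrier_maternal",
                               {"c.2168A>G": "AB", "c.697G>C": "AA"})
        verdict = reconcile(direct, self._transmission("father", "N"),
                            self._transmission("mother", "N"), family)
        assert verdict.status == "indeterminate"
        assert any(e.resolution == "unresolved" for e in verdict.ado_events)

    def test_direct_only_when_linkage_uninformative(self):
        family = make_compound_het_family()
        direct = DirectVerdict("carrier_paternal",
                               {"c.2168A>G": "AA", "c.697G>C": "AB"})
        verdict = reconcile(direct, self._transmission("father", "indeterminate"),
                            self._transmission("mother", "indeterminate"), family)
        assert (verdict.status, verdict.basis) == ("carrier_paternal", "direct_only")

    def test_linkage_only_when_direct_nocall(self):
        family = make_compound_het_family()
        direct = DirectVerdict("indeterminate",
                               {"c.2168A>G": "nocall", "c.697G>C": "nocall"})
        verdict = reconcile(direct, self._transmission("father", "N"),
                            self._transmission("mother", "N"), family)
        assert (verdict.status, verdict.basis) == ("unaffected_noncarrier", "linkage_only")

    def test_both_routes_uninformative_indeterminate(self):
        family = make_compound_het_family()
        direct = DirectVerdict("indeterminate",
                               {"c.2168A>G": "nocall", "c.697G>C": "nocall"})
        verdict = reconcile(direct, self._transmission("father", "indeterminate"),
                            self._transmission("mother", "indeterminate"), family)
        assert verdict.status == "indeterminate"

    def test_same_variant_carrier_origin_resolved_by_linkage(self):
        """Identical parental alleles: direct testing only says 'carrier',
        linkage attributes the origin."""
        from test_genotyping import make_same_variant_family

        family = make_same_variant_family()
        direct = DirectVerdict("carrier_origin_unknown", {"c.235delC": "AB"})
        verdict = reconcile(direct, self._transmission("father", "N"),
                            self._transmission("mother", "M"), family)
        assert (verdict.status, verdict.basis) == ("carrier_maternal", "concordant")


class TestAdoRate:
    def test_published_denominator(self):
        assert ado_rate(14, 501) == pytest.approx(0.02794, abs=1e-4)

    def test_zero_events(self):
        assert ado_rate(0, 400) == 0.0

    def test_zero_rounds_rejected(self):
        with pytest.raises(ValueError):
            ado_rate(1, 0)

    def test_simulated_rate_recovers_generator_probability(self, ar_family):
        """Truth dropout draws over 5000 assays fall inside the exact
        binomial 95% interval around p = 0.028."""
        from scipy.stats import binom

        truth, panel, haps = ar_family
        params = SimParams(ado_prob=0.028, recomb_prob_per_mb=0.0,
                           allele_imbalance_sd=0.02)
        n_assays = 0
        n_events = 0
        i = 0
        while n_assays < 5000:
            emb = simulate_embryo(truth, params, seed=9000 + i)
            n_assays += 2
            n_events += len(emb.ado_assay_sites)
            i += 1
        lo, hi = binom.interval(0.95, n_assays, 0.028)
        assert lo <= n_events <= hi
        assert ado_rate(n_events, n_assays) == n_events / n_assays
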