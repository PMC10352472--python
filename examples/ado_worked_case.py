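"""A worked allele-dropout rescue.

The embryo reads homozygous for the maternal pathogenic allele at a site
the father does not carry -- Mendelian-impossible at face value.  Linkage
shows the father transmitted his normal haplotype and the mother her
mutant-linked one, so the paternal wild-type allele must have dropped out
during whole-genome amplification: the embryo is a heterozygous maternal
carrier and the dropout does not affect the diagnosis.
"""

from pgtdx import diagnose_embryo
from pgtdx.model import FamilyDesign, VariantAllele
from pgtdx.panel import SnpPanel
from pgtdx.phasing import ParentalHaplotypes

REGION = ("7", 107_301_080, 107_358_254)  # the pendrin gene, GRCh37

family = FamilyDesign(
    family_id="DEMO", gene="SLC26A4", mode="AR",
    maternal_variants=[VariantAllele("SLC26A4", "7", 107_350_000, "A", "G",
                                     "c.2168A>G", "maternal")],
    paternal_variants=[VariantAllele("SLC26A4", "7", 107_315_000, "G", "C",
                                     "c.697G>C", "paternal")],
    members={"father": "F", "mother": "M", "child": "C"},
)
panel = SnpPanel(gene="SLC26A4", chrom=REGION[0], start=REGION[1], end=REGION[2])

# five informative markers per parent, already phased (allele A on M)
father_marks = {f"pf{i}": REGION[1] - 900_000 + i * 400_000 for i in range(5)}
mother_marks = {f"pm{i}": REGION[1] - 700_000 + i * 400_000 for i in range(5)}
haps_f = ParentalHaplotypes("father", {m: ("A", "B") for m in father_marks},
                            father_marks)
haps_m = ParentalHaplotypes("mother", {m: ("A", "B") for m in mother_marks},
                            mother_marks)
father_calls = {m: "AB" for m in father_marks} | {m: "AA" for m in mother_marks}
mother_calls = {m: "AB" for m in mother_marks} | {m: "AA" for m in father_marks}

embryo = {m: "AB" for m in father_marks}        # father gave N (allele B)
embryo |= {m: "AA" for m in mother_marks}       # mother gave M (allele A)
embryo["c.2168A>G"] = "BB"                      # impossible: father has no G here
embryo["c.697G>C"] = "AA"

verdict, direct, tf, tm = diagnose_embryo(
    family, panel, haps_f, haps_m, father_calls, mother_calls, embryo)

print(f"direct verdict:     {direct.status} (flags: {direct.flags})")
print(f"linkage:            father={tf.inherited}, mother={tm.inherited}")
print(f"final verdict:      {verdict.status}  basis={verdict.basis}")
for e in verdict.ado_events:
    print(f"ADO event:          {e.site_id}: expected {e.expected_genotype}, "
          f"saw {e.observed_genotype} -> {e.resolution}")
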