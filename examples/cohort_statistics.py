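"""Cohort outcome statistics from the bundled clinical cycle table.

Aggregates the 47-couple hereditary hearing-loss cohort (cycles, embryos,
transfers, outcomes) and prints every derived rate with its denominator:
e.g. pregnancy per transfer, live birth per started cycle, aneuploidy per
biopsied embryo, allele dropout per variant-site assay.
"""

from pgtdx import cohort_summary
from pgtdx.datasets import load_cohort_table, load_results_tallies

stats = cohort_summary(load_cohort_table(), load_results_tallies())

t = stats.totals
print(f"couples {t['couples']}, cycles {t['cycles']}, embryos {t['embryos']}, "
      f"transferable {t['transferable']}, transfers {t['transfers']}")
print(f"mean maternal age: {stats.mean_female_age:.1f} years\n")
for name, value in stats.rates.items():
    if value is not None:
        print(f"  {name:<30} {value:5.1f}%")
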