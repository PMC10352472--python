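"""Bundled clinical cohort tables (hereditary hearing-loss PGT study).

``load_cohort_table`` returns the per-family cycle/outcome records of the
47-couple cohort; ``load_results_tallies`` the embryo-level counts that the
cycle table does not carry (inconclusive, aneuploid, amplification-failure
and allele-dropout totals).  Both are transcriptions of published summary
tables; individual-level genetic data were never deposited and are not
shipped.
"""

from __future__ import annotations

from importlib import resources

from . import io as pgtio


def _data_path(name: str):
    return resources.files("pgtdx.data").joinpath(name)


def load_cohort_table() -> list:
    """Per-family cycle records of the clinical cohort (47 couples)."""
    with resources.as_file(_data_path("cohort_table.tsv")) as p:
        return pgtio.parse_cycle_table(p)


def load_results_tallies() -> dict:
    """Embryo-level outcome tallies of the clinical cohort."""
    with resources.as_file(_data_path("results_tallies.tsv")) as p:
        return pgtio.parse_tallies(p)
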