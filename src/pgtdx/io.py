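"""Readers and writers for every external table the pipeline touches.

All formats are plain text: tab-separated tables for SNP banks, pedigrees,
site calls and bin counts; JSON for reports and cohort statistics.  Every
reader validates against the domain-type invariants and reports the
offending line/field; writer/reader round trips are lossless.

Coordinates are 1-based inclusive throughout, matching clinical (HGVS-style)
usage.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .genotyping import call_site_genotype
from .model import (
    BinRecord,
    CycleRecord,
    FamilyDesign,
    ParseError,
    SnpMarker,
    Thresholds,
    ValidationError,
    VariantAllele,
)

SNP_BANK_COLUMNS = ["marker_id", "chrom", "pos", "allele_a", "allele_b", "maf"]
SITE_CALL_COLUMNS = ["sample_id", "site_id", "depth_a", "depth_b"]
BIN_COLUMNS = ["chrom", "start", "end", "gc_fraction", "count"]


def _read_rows(path):
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        yield i, line.rstrip("\n").split("\t")


def parse_snp_bank(path) -> list:
    """Read a SNP-bank TSV into validated markers, ordered by (chrom, pos)."""
    markers = []
    seen = set()
    header = None
    for line_no, fields in _read_rows(path):
        if header is None:
            header = fields
            if header != SNP_BANK_COLUMNS:
                raise ParseError(path, line_no, f"expected header {SNP_BANK_COLUMNS}, got {header}")
            continue
        if len(fields) != len(SNP_BANK_COLUMNS):
            raise ParseError(path, line_no, f"expected {len(SNP_BANK_COLUMNS)} columns, got {len(fields)}")
        row = dict(zip(SNP_BANK_COLUMNS, fields))
        try:
            marker = SnpMarker(
                marker_id=row["marker_id"], chrom=row["chrom"], pos=int(row["pos"]),
                allele_a=row["allele_a"], allele_b=row["allele_b"], maf=float(row["maf"]),
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(path, line_no, str(exc)) from exc
        if marker.marker_id in seen:
            raise ParseError(path, line_no, f"duplicate marker_id {marker.marker_id!r}")
        seen.add(marker.marker_id)
        markers.append(marker)
    markers.sort()
    return markers


def write_snp_bank(markers, path) -> None:
    lines = ["\t".join(SNP_BANK_COLUMNS)]
    for m in sorted(markers):
        lines.append(f"{m.marker_id}\t{m.chrom}\t{m.pos}\t{m.allele_a}\t{m.allele_b}\t{m.maf:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_pedigree(path) -> FamilyDesign:
    """Read the pedigree/family-design TSV dialect.

    Key-value lines declare family_id, gene, mode and reference_type;
    ``variant`` lines declare parental variants as
    ``variant  M|P|B  chrom  pos  ref  alt  hgvs``; ``member`` lines map
    pedigree roles to sample ids.
    """
    meta = {}
    maternal, paternal = [], []
    members = {}
    for line_no, fields in _read_rows(path):
        key = fields[0]
        if key == "variant":
            if len(fields) != 7:
                raise ParseError(path, line_no, "variant line needs: variant M|P|B chrom pos ref alt hgvs")
            side, chrom, pos, ref, alt, hgvs = fields[1:]
            origin = {"M": "maternal", "P": "paternal", "B": "both"}.get(side)
            if origin is None:
                raise ParseError(path, line_no, f"variant side must be M, P or B, got {side!r}")
            v = VariantAllele(gene=meta.get("gene", ""), chrom=chrom, pos=int(pos),
                              ref=ref, alt=alt, hgvs_label=hgvs, origin=origin)
            if origin in ("maternal", "both"):
                maternal.append(v)
            if origin in ("paternal", "both"):
                paternal.append(v)
        elif key == "member":
            if len(fields) != 3:
                raise ParseError(path, line_no, "member line needs: member role sample_id")
            members[fields[1]] = fields[2]
        elif key in ("family_id", "gene", "mode", "reference_type"):
            if len(fields) != 2:
                raise ParseError(path, line_no, f"{key} line needs a single value")
            meta[key] = fields[1]
        else:
            raise ParseError(path, line_no, f"unknown record type {key!r}")
    for required in ("family_id", "gene", "mode"):
        if required not in meta:
            raise ValidationError(required, "missing from pedigree file")
    return FamilyDesign(
        family_id=meta["family_id"], gene=meta["gene"], mode=meta["mode"],
        maternal_variants=maternal, paternal_variants=paternal,
        reference_type=meta.get("reference_type", "affected_child"),
        members=members,
    )


def write_pedigree(family: FamilyDesign, path) -> None:
    lines = [
        f"family_id\t{family.family_id}",
        f"gene\t{family.gene}",
        f"mode\t{family.mode}",
        f"reference_type\t{family.reference_type}",
    ]
    seen = set()
    for side, variants in (("M", family.maternal_variants), ("P", family.paternal_variants)):
        for v in variants:
            code = "B" if v.origin == "both" else side
            entry = (code, v.key)
            if entry in seen:
                continue
            seen.add(entry)
            lines.append(f"variant\t{code}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.hgvs_label}")
    for role, sample in family.members.items():
        lines.append(f"member\t{role}\t{sample}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_site_calls(path, thresholds: Thresholds | None = None) -> dict:
    """Read per-sample allele-depth rows into genotyped site calls.

    Returns ``{sample_id: {site_id: SiteCall}}``; genotypes are derived from
    the depths with the 100x low-depth rule and allele-fraction cutpoints.
    An empty file yields an empty table.
    """
    thresholds = thresholds or Thresholds()
    table: dict = {}
    header = None
    for line_no, fields in _read_rows(path):
        if header is None:
            header = fields
            if header != SITE_CALL_COLUMNS:
                raise ParseError(path, line_no, f"expected header {SITE_CALL_COLUMNS}, got {header}")
            continue
        if len(fields) != 4:
            raise ParseError(path, line_no, "expected 4 columns")
        sample, site, da, db = fields
        try:
            call = call_site_genotype(int(da), int(db), thresholds, site_id=site)
        except ValueError as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(path, line_no, str(exc)) from exc
        if site in table.setdefault(sample, {}):
            raise ParseError(path, line_no, f"duplicate call for {sample}/{site}")
        table[sample][site] = call
    return table


def write_site_calls(table: dict, path) -> None:
    lines = ["\t".join(SITE_CALL_COLUMNS)]
    for sample in sorted(table):
        for site, call in table[sample].items():
            lines.append(f"{sample}\t{site}\t{call.depth_a}\t{call.depth_b}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_bin_counts(path) -> list:
    """Read a BED-like bin-count TSV into ordered, non-overlapping bins."""
    bins = []
    header = None
    for line_no, fields in _read_rows(path):
        if header is None:
            header = fields
            if header != BIN_COLUMNS:
                raise ParseError(path, line_no, f"expected header {BIN_COLUMNS}, got {header}")
            continue
        if len(fields) != 5:
            raise ParseError(path, line_no, "expected 5 columns")
        chrom, start, end, gc, count = fields
        try:
            rec = BinRecord(chrom=chrom, start=int(start), end=int(end),
                            gc_fraction=float(gc), raw_count=float(count))
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(path, line_no, str(exc)) from exc
        if bins and bins[-1].chrom == rec.chrom:
            prev = bins[-1]
            if rec.start <= prev.end:
                raise ValidationError(
                    "start",
                    f"bins overlap or are unordered on chromosome {rec.chrom}: "
                    f"{prev.start}-{prev.end} then {rec.start}-{rec.end}",
                )
        bins.append(rec)
    return bins


def write_bin_counts(bins, path) -> None:
    lines = ["\t".join(BIN_COLUMNS)]
    for b in bins:
        lines.append(f"{b.chrom}\t{b.start}\t{b.end}\t{b.gc_fraction:.4f}\t{b.raw_count:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_to_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_report(report, path) -> None:
    """Serialize a report (any dataclass/dict tree) as stable-key JSON."""
    Path(path).write_text(json.dumps(_to_jsonable(report), indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


write_cohort_stats = write_report
read_cohort_stats = read_report


def parse_cycle_table(path) -> list:
    """Read the clinical cycle/outcome table (one row per family)."""
    columns = ["family_id", "female_age", "gene", "mode", "maternal_variants",
               "paternal_variants", "cycles", "total_embryos", "transferable",
               "implantation_times", "pregnancies", "miscarriages",
               "live_births", "outcome", "note"]
    rows = []
    header = None
    for line_no, fields in _read_rows(path):
        if header is None:
            header = fields
            if header != columns:
                raise ParseError(path, line_no, f"expected header {columns}")
            continue
        if len(fields) == len(columns) - 1:
            fields = fields + [""]  # trailing empty note
        if len(fields) != len(columns):
            raise ParseError(path, line_no, f"expected {len(columns)} columns, got {len(fields)}")
        row = dict(zip(columns, fields))
        rows.append(CycleRecord(
            family_id=row["family_id"], female_age=float(row["female_age"]),
            gene=row["gene"], mode=row["mode"],
            maternal_variants=row["maternal_variants"],
            paternal_variants=row["paternal_variants"],
            cycles=int(row["cycles"]), total_embryos=int(row["total_embryos"]),
            transferable=int(row["transferable"]),
            implantation_times=int(row["implantation_times"]),
            pregnancies=int(row["pregnancies"]),
            miscarriages=int(row["miscarriages"]),
            live_births=int(row["live_births"]),
            outcome=row["outcome"], note=row["note"],
        ))
    return rows


def write_cycle_table(rows, path) -> None:
    columns = ["family_id", "female_age", "gene", "mode", "maternal_variants",
               "paternal_variants", "cycles", "total_embryos", "transferable",
               "implantation_times", "pregnancies", "miscarriages",
               "live_births", "outcome", "note"]
    lines = ["\t".join(columns)]
    for r in rows:
        lines.append("\t".join(str(getattr(r, c)) for c in columns))
    Path(path).write_text("\n".join(lines) + "\n")


def parse_tallies(path) -> dict:
    """Read a two-column key/value tally table into an int-valued dict."""
    out = {}
    for line_no, fields in _read_rows(path):
        if len(fields) != 2:
            raise ParseError(path, line_no, "expected key<TAB>value")
        out[fields[0]] = int(fields[1])
    return out
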