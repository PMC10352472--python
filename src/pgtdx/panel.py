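"""Selection of the SNP linkage panel flanking the disease gene.

Markers within 1 Mb of the gene (boundary-inclusive, distance measured from
the nearer gene edge) with minor-allele frequency above 0.1 qualify; when
more than the 90-marker target qualify, the window is partitioned into
equal positional slots and the highest-MAF marker is kept per slot, which
spreads the panel across the window and protects against recombination
blind spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .model import SnpMarker, Thresholds


class PanelSelectionError(ValueError):
    """No marker qualifies: no informative scaffold possible."""


@dataclass
class SnpPanel:
    """The ordered marker scaffold around one gene region."""

    gene: str
    chrom: str
    start: int
    end: int
    markers: list = field(default_factory=list)

    def __post_init__(self):
        self.markers = sorted(self.markers)

    @property
    def marker_ids(self):
        return [m.marker_id for m in self.markers]

    def positions(self) -> dict:
        return {m.marker_id: m.pos for m in self.markers}

    def __len__(self):
        return len(self.markers)

    @property
    def gene_region(self):
        return (self.chrom, self.start, self.end)


def distance_to_region(marker: SnpMarker, start: int, end: int) -> int:
    """Distance from a marker to the nearer gene edge; 0 inside the gene."""
    if marker.pos < start:
        return start - marker.pos
    if marker.pos > end:
        return marker.pos - end
    return 0


def select_panel(bank, gene_region, thresholds: Thresholds | None = None,
                 gene: str = "") -> SnpPanel:
    """Select the linkage panel for ``gene_region = (chrom, start, end)``.

    Raises :class:`PanelSelectionError` when no marker qualifies; warns when
    fewer than the target qualify (the panel is then simply smaller).
    """
    thr = thresholds or Thresholds()
    chrom, start, end = gene_region
    qualifying = [
        m for m in bank
        if m.chrom == chrom
        and distance_to_region(m, start, end) <= thr.window_bp
        and m.maf > thr.maf_min
    ]
    if not qualifying:
        raise PanelSelectionError(
            f"no marker within {thr.window_bp} bp of {chrom}:{start}-{end} "
            f"with MAF > {thr.maf_min}: no informative scaffold possible"
        )
    if len(qualifying) <= thr.panel_target:
        if len(qualifying) < thr.panel_target:
            warnings.warn(
                f"only {len(qualifying)} qualifying markers for {chrom}:{start}-{end} "
                f"(target {thr.panel_target})", stacklevel=2,
            )
        chosen = qualifying
    else:
        chosen = _spread_select(qualifying, start - thr.window_bp,
                                end + thr.window_bp, thr.panel_target)
    return SnpPanel(gene=gene, chrom=chrom, start=start, end=end, markers=chosen)


def _spread_select(markers, span_start: int, span_end: int, target: int):
    """Keep the highest-MAF marker per positional slot, topping up by MAF rank."""
    span = max(span_end - span_start, 1)
    slots: dict = {}
    for m in markers:
        slot = min(int((m.pos - span_start) * target / span), target - 1)
        best = slots.get(slot)
        # highest MAF wins a slot; position breaks ties deterministically
        if best is None or (m.maf, -m.pos) > (best.maf, -best.pos):
            slots[slot] = m
    chosen = set(slots.values())
    if len(chosen) < target:
        rest = sorted((m for m in markers if m not in chosen),
                      key=lambda m: (-m.maf, m.pos))
        for m in rest[: target - len(chosen)]:
            chosen.add(m)
    return sorted(chosen)
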