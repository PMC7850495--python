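"""Microsatellite marker panels.

A marker is a genomic interval holding a tandem repeat of a short (1-6 bp)
DNA motif. Panels are stored as BED-compatible tab-separated files with six
columns: chrom, start, end, marker_id, repeat_unit, ref_length. Coordinates
are 0-based half-open throughout (BED convention); human-readable reports
elsewhere print 1-based inclusive positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Marker",
    "MarkerPanel",
    "PanelError",
    "read_marker_panel",
    "write_marker_panel",
    "subset_panel",
]

_MOTIF_RE = re.compile(r"^[ACGT]{1,6}$")


class PanelError(ValueError):
    """Raised when a panel file or panel construction is invalid."""


@dataclass(frozen=True)
class Marker:
    """One microsatellite locus.

    Parameters
    ----------
    marker_id : str
        Unique identifier within a panel.
    chrom : str
        Chromosome / contig name.
    start, end : int
        0-based half-open genomic interval of the repeat tract.
    repeat_unit : str
        Repeated DNA motif, 1-6 bp, uppercase ACGT.
    ref_length : int
        Reference tract length in bases; must equal ``end - start``.
    """

    marker_id: str
    chrom: str
    start: int
    end: int
    repeat_unit: str
    ref_length: int

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise PanelError("marker_id must be non-empty")
        if self.end <= self.start:
            raise PanelError(
                f"{self.marker_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.start < 0:
            raise PanelError(f"{self.marker_id}: negative start {self.start}")
        if not _MOTIF_RE.match(self.repeat_unit):
            raise PanelError(
                f"{self.marker_id}: repeat_unit {self.repeat_unit!r} must be 1-6 bp of ACGT"
            )
        if self.ref_length != self.end - self.start:
            raise PanelError(
                f"{self.marker_id}: ref_length {self.ref_length} != end - start "
                f"({self.end - self.start})"
            )

    @property
    def unit_length(self) -> int:
        return len(self.repeat_unit)


@dataclass
class MarkerPanel:
    """An ordered, validated collection of markers.

    Markers are kept sorted by (chrom, start). Duplicate ids, duplicate
    coordinates and overlapping intervals on the same chromosome are
    rejected: one locus, one statistic.
    """

    name: str
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.markers = sorted(self.markers, key=lambda m: (m.chrom, m.start))
        seen_ids: set[str] = set()
        prev: Marker | None = None
        for m in self.markers:
            if m.marker_id in seen_ids:
                raise PanelError(f"duplicate marker_id {m.marker_id!r}")
            seen_ids.add(m.marker_id)
            if prev is not None and prev.chrom == m.chrom and m.start < prev.end:
                raise PanelError(
                    f"markers {prev.marker_id!r} and {m.marker_id!r} overlap "
                    f"on {m.chrom}"
                )
            prev = m

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self) -> Iterator[Marker]:
        return iter(self.markers)

    def __getitem__(self, i: int) -> Marker:
        return self.markers[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerPanel):
            return NotImplemented
        return self.name == other.name and self.markers == other.markers

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def by_chrom(self) -> dict[str, list[Marker]]:
        out: dict[str, list[Marker]] = {}
        for m in self.markers:
            out.setdefault(m.chrom, []).append(m)
        return out


def read_marker_panel(path: str | Path) -> MarkerPanel:
    """Read a 6-column tab-separated marker panel file.

    Lines starting with ``#`` are comments; a ``# panel: NAME`` comment
    sets the panel name (default: the file stem).
    """
    path = Path(path)
    name = path.stem
    markers: list[Marker] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*panel:\s*(\S+)", line)
                if m:
                    name = m.group(1)
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise PanelError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
                )
            chrom, start_s, end_s, marker_id, unit, ref_len_s = fields
            try:
                start, end, ref_len = int(start_s), int(end_s), int(ref_len_s)
            except ValueError as exc:
                raise PanelError(f"{path}:{lineno}: non-integer coordinate: {exc}") from exc
            try:
                markers.append(
                    Marker(marker_id, chrom, start, end, unit.upper(), ref_len)
                )
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from exc
    return MarkerPanel(name=name, markers=markers)


def write_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    """Write a panel to a BED-compatible TSV; round-trips with read_marker_panel."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# panel: {panel.name}\n")
        fh.write("# columns: chrom\tstart\tend\tmarker_id\trepeat_unit\tref_length\n")
        for m in panel:
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.marker_id}\t"
                f"{m.repeat_unit}\t{m.ref_length}\n"
            )


def subset_panel(panel: MarkerPanel, n: int, seed: int) -> MarkerPanel:
    """Sample ``n`` distinct markers uniformly without replacement.

    Deterministic in (panel, n, seed); output sorted by coordinate. This is
    how the intermediate 230-marker panel is drawn from the 3,154 candidates.
    """
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    if n > len(panel):
        raise ValueError(f"cannot draw {n} markers from a panel of {len(panel)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(panel), size=n, replace=False)
    chosen = [panel[i] for i in sorted(idx)]
    return MarkerPanel(name=f"{panel.name}_subset{n}", markers=chosen)


def panel_from_records(name: str, records: Iterable[tuple]) -> MarkerPanel:
    """Build a panel from (chrom, start, end, marker_id, repeat_unit) tuples."""
    markers = [
        Marker(mid, chrom, start, end, unit, end - start)
        for chrom, start, end, mid, unit in records
    ]
    return MarkerPanel(name=name, markers=markers)
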