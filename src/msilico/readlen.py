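"""Per-marker microsatellite tract-length extraction from aligned reads.

For every marker the tract length observed in each spanning read is
measured by a single walk over the read's CIGAR, then normalized against
the reference tract length: a read whose tract matches the reference
contributes a delta of 0, a 2 bp deletion inside the tract contributes -2,
and so on. The multiset of deltas per marker (its length distribution) is
the input to the skewness statistic downstream.

A read is *spanning* when its aligned reference span covers the marker
plus ``flank`` anchor bases on both sides with aligned or deleted bases --
soft/hard clips or reference skips inside that window disqualify the read,
because an indel at the tract edge is only callable when flanking sequence
is anchored.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .markers import Marker, MarkerPanel

__all__ = [
    "LengthDistribution",
    "tract_length_from_read",
    "collect_length_distributions",
    "read_length_table",
    "write_length_table",
    "DEFAULT_FLANK",
    "DEFAULT_MAPQ_MIN",
]

logger = logging.getLogger("msilico")

DEFAULT_FLANK = 5
DEFAULT_MAPQ_MIN = 20

# CIGAR op codes (pysam numeric convention)
_MATCH_OPS = {0, 7, 8}  # M, =, X
_DEL = 2
_INS = 1
_REF_SKIP = 3
_CONSUMES_REF = {0, 2, 3, 7, 8}


@dataclass
class LengthDistribution:
    """Multiset of normalized tract-length deltas observed at one marker."""

    marker_id: str
    deltas: list[int] = field(default_factory=list)

    @property
    def coverage(self) -> int:
        return len(self.deltas)

    def sorted_deltas(self) -> list[int]:
        return sorted(self.deltas)


def _read_passes_filters(read: pysam.AlignedSegment, mapq_min: int) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.is_qcfail
        or read.mapping_quality < mapq_min
    )


def tract_length_from_read(
    read: pysam.AlignedSegment, marker: Marker, flank: int = DEFAULT_FLANK
) -> int | None:
    """Measure the microsatellite tract length in one aligned read.

    Returns ``None`` unless the read's aligned span covers
    ``[marker.start - flank, marker.end + flank)`` without clips or
    reference skips in that window. Otherwise returns::

        marker.ref_length
        + (query bases inserted strictly inside (start, end))
        - (reference bases deleted within [start, end))

    Insertions exactly at the tract boundaries are attributed to the flank
    (strict-interior rule); deletions use closed-open interval overlap.
    """
    cig = read.cigartuples
    if cig is None:
        logger.warning("read %s has no CIGAR; skipped", read.query_name)
        return None
    win_lo = marker.start - flank
    win_hi = marker.end + flank
    if read.reference_start > win_lo or read.reference_end < win_hi:
        return None

    ins = 0
    dele = 0
    r = read.reference_start
    for op, length in cig:
        if op == _INS:
            # insertion sits between reference positions r-1 and r
            if marker.start < r < marker.end:
                ins += length
        elif op == _DEL:
            lo = max(r, marker.start)
            hi = min(r + length, marker.end)
            if hi > lo:
                dele += hi - lo
        elif op == _REF_SKIP:
            if r < win_hi and r + length > win_lo:
                return None  # skip inside the anchor window: not spanning
        if op in _CONSUMES_REF:
            r += length
    return marker.ref_length + ins - dele


def _collect_streaming(
    af: pysam.AlignmentFile,
    panel: MarkerPanel,
    flank: int,
    mapq_min: int,
    dists: dict[str, LengthDistribution],
) -> None:
    by_chrom = panel.by_chrom()
    starts = {c: [m.start for m in ms] for c, ms in by_chrom.items()}
    for read in af.fetch(until_eof=True):
        if not _read_passes_filters(read, mapq_min):
            continue
        chrom = read.reference_name
        if chrom not in by_chrom:
            continue
        ms = by_chrom[chrom]
        # candidate markers: those starting before the read ends
        i = bisect_left(starts[chrom], read.reference_start)
        if i > 0:
            i -= 1  # marker starting just before the read may still be spanned
        while i < len(ms) and ms[i].start < read.reference_end:
            tract = tract_length_from_read(read, ms[i], flank=flank)
            if tract is not None:
                dists[ms[i].marker_id].deltas.append(tract - ms[i].ref_length)
            i += 1


def collect_length_distributions(
    alignments: str | Path | pysam.AlignmentFile,
    panel: MarkerPanel,
    flank: int = DEFAULT_FLANK,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> list[LengthDistribution]:
    """Build one normalized length distribution per panel marker.

    ``alignments`` may be a SAM/BAM path or an open AlignmentFile. Indexed
    BAMs are queried per marker region; plain SAM is streamed once.
    Duplicate, secondary, supplementary, QC-fail and low-MAPQ reads are
    excluded; each read contributes at most one delta per marker.
    """
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments))
        own = True
    try:
        dists = {m.marker_id: LengthDistribution(m.marker_id) for m in panel}
        header_refs = set(alignments.references)
        for chrom in panel.by_chrom():
            if chrom not in header_refs:
                logger.warning(
                    "chromosome %s in panel absent from alignment header; "
                    "its markers get coverage 0",
                    chrom,
                )
        if alignments.has_index():
            for m in panel:
                if m.chrom not in header_refs:
                    continue
                for read in alignments.fetch(
                    m.chrom, max(0, m.start - flank), m.end + flank
                ):
                    if not _read_passes_filters(read, mapq_min):
                        continue
                    tract = tract_length_from_read(read, m, flank=flank)
                    if tract is not None:
                        dists[m.marker_id].deltas.append(tract - m.ref_length)
        else:
            _collect_streaming(alignments, panel, flank, mapq_min, dists)
        return [dists[m.marker_id] for m in panel]
    finally:
        if own:
            alignments.close()


def write_length_table(dists: list[LengthDistribution], path: str | Path) -> None:
    """Write per-marker length distributions as TSV.

    Columns: marker_id, coverage, comma-separated sorted deltas (``.`` for
    an empty distribution). This table is also accepted as input anywhere
    a BAM is, so the statistical core runs without alignments.
    """
    with open(path, "w") as fh:
        fh.write("# columns: marker_id\tcoverage\tdeltas\n")
        for d in dists:
            deltas = ",".join(map(str, d.sorted_deltas())) if d.deltas else "."
            fh.write(f"{d.marker_id}\t{d.coverage}\t{deltas}\n")


def read_length_table(path: str | Path) -> list[LengthDistribution]:
    """Read a length table written by :func:`write_length_table`."""
    out: list[LengthDistribution] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            marker_id, cov_s, deltas_s = fields
            deltas = (
                [] if deltas_s == "." else [int(x) for x in deltas_s.split(",")]
            )
            if int(cov_s) != len(deltas):
                raise ValueError(
                    f"{path}:{lineno}: coverage {cov_s} != number of deltas "
                    f"{len(deltas)}"
                )
            out.append(LengthDistribution(marker_id, deltas))
    return out
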