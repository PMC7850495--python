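"""Per-marker instability scoring with Pearson's skewness coefficient.

The statistic is PSC = 3 * (mean - median) / sd over a marker's normalized
length deltas, with sd the sample (n-1 denominator) standard deviation.
An instability event -- a shifted tumor allele mixed with reference-length
reads -- pulls the mean away from the median and drives |PSC| above 1,
while symmetric stutter noise around the reference length leaves PSC near
0. Markers covered by 20 or fewer spanning reads are filtered out before
scoring. Because mean - median is bounded by one standard deviation, PSC
always lies in [-3, 3].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .readlen import LengthDistribution

__all__ = [
    "MarkerCall",
    "pearson_skewness",
    "call_marker",
    "call_markers",
    "write_marker_calls",
    "read_marker_calls",
    "DEFAULT_COVERAGE_MIN_EXCLUSIVE",
    "DEFAULT_PSC_THRESHOLD",
]

#: markers with coverage <= 20 are filtered out (strictly more than 20 required)
DEFAULT_COVERAGE_MIN_EXCLUSIVE = 20
#: a marker is unstable when PSC > 1 or PSC < -1 (strict)
DEFAULT_PSC_THRESHOLD = 1.0


@dataclass(frozen=True)
class MarkerCall:
    """Scored instability call for one marker in one sample.

    ``psc`` is ``None`` when the marker failed the coverage filter
    (``valid`` is False); an invalid marker is never unstable.
    """

    marker_id: str
    coverage: int
    psc: float | None
    valid: bool
    unstable: bool


def pearson_skewness(deltas: Sequence[int] | np.ndarray) -> float:
    """Pearson's second skewness coefficient, 3*(mean - median)/sd.

    sd uses the n-1 denominator; a zero-variance input (every read the
    same length -- the most stable possible observation) returns exactly 0.
    """
    arr = np.asarray(deltas, dtype=float)
    if arr.size == 0:
        raise ValueError("pearson_skewness requires a non-empty distribution")
    if arr.size == 1:
        return 0.0
    sd = arr.std(ddof=1)
    if sd == 0.0:
        return 0.0
    return float(3.0 * (arr.mean() - np.median(arr)) / sd)


def call_marker(
    dist: LengthDistribution,
    coverage_min_exclusive: int = DEFAULT_COVERAGE_MIN_EXCLUSIVE,
    psc_threshold: float = DEFAULT_PSC_THRESHOLD,
) -> MarkerCall:
    """Score one marker: coverage filter, PSC, strict instability threshold."""
    if dist.coverage <= coverage_min_exclusive:
        return MarkerCall(dist.marker_id, dist.coverage, None, False, False)
    psc = pearson_skewness(dist.deltas)
    return MarkerCall(
        dist.marker_id, dist.coverage, psc, True, abs(psc) > psc_threshold
    )


def call_markers(
    dists: Iterable[LengthDistribution],
    coverage_min_exclusive: int = DEFAULT_COVERAGE_MIN_EXCLUSIVE,
    psc_threshold: float = DEFAULT_PSC_THRESHOLD,
) -> list[MarkerCall]:
    return [
        call_marker(d, coverage_min_exclusive, psc_threshold) for d in dists
    ]


def write_marker_calls(calls: list[MarkerCall], path: str | Path) -> None:
    """Write per-marker calls as TSV (psc is NA for filtered markers)."""
    with open(path, "w") as fh:
        fh.write("marker_id\tcoverage\tpsc\tvalid\tunstable\n")
        for c in calls:
            psc = "NA" if c.psc is None else f"{c.psc:.6f}"
            fh.write(
                f"{c.marker_id}\t{c.coverage}\t{psc}\t"
                f"{str(c.valid).lower()}\t{str(c.unstable).lower()}\n"
            )


def read_marker_calls(path: str | Path) -> list[MarkerCall]:
    out: list[MarkerCall] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("marker_id\t"):
            raise ValueError(f"{path}: not a marker-call table")
        for line in fh:
            mid, cov, psc_s, valid_s, unstable_s = line.rstrip("\n").split("\t")
            psc = None if psc_s == "NA" else float(psc_s)
            if psc is not None and not math.isfinite(psc):
                raise ValueError(f"{path}: non-finite psc for {mid}")
            out.append(
                MarkerCall(
                    mid, int(cov), psc, valid_s == "true", unstable_s == "true"
                )
            )
    return out
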