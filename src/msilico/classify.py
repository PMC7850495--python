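"""Sample-level MSI classification.

A sample is called MSI-H when the fraction of unstable markers among
*valid* markers (those passing the coverage filter; filtered markers are
excluded from the denominator entirely) meets or exceeds a tissue-specific
cutoff: 0.4 for fresh tissue and cell lines, 0.25 for FFPE tissue, whose
degraded DNA depresses and widens the unstable fraction. The comparison is
inclusive: fraction == cutoff is MSI-H. A sample with no valid markers is
indeterminate rather than forced into either class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .psc import MarkerCall

__all__ = [
    "SampleResult",
    "SAMPLE_TYPES",
    "default_cutoff",
    "classify_sample",
    "write_sample_results",
    "read_sample_results",
]

logger = logging.getLogger("msilico")

SAMPLE_TYPES = ("fresh", "cell_line", "ffpe")

_CUTOFFS = {"fresh": 0.4, "cell_line": 0.4, "ffpe": 0.25}

MSI_H = "MSI-H"
MSS = "MSS"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class SampleResult:
    sample_id: str
    sample_type: str
    n_markers: int
    n_valid: int
    n_unstable: int
    unstable_fraction: float | None  # None when no valid markers
    cutoff: float
    status: str  # MSI-H | MSS | indeterminate


def default_cutoff(sample_type: str) -> float:
    """Tissue-specific unstable-fraction cutoff (fresh/cell_line 0.4, ffpe 0.25)."""
    try:
        return _CUTOFFS[sample_type]
    except KeyError:
        raise ValueError(
            f"unknown sample_type {sample_type!r}; expected one of {SAMPLE_TYPES}"
        ) from None


def classify_sample(
    calls: Sequence[MarkerCall] | Iterable[MarkerCall],
    sample_id: str,
    sample_type: str,
    cutoff: float | None = None,
) -> SampleResult:
    """Aggregate one sample's marker calls into an MSI status.

    The denominator is the number of valid markers only, never the panel
    size. ``cutoff`` defaults per sample type; fraction >= cutoff is MSI-H.
    """
    calls = list(calls)
    if not calls:
        raise ValueError(f"sample {sample_id}: empty marker-call collection")
    if cutoff is None:
        cutoff = default_cutoff(sample_type)
    elif sample_type not in SAMPLE_TYPES:
        raise ValueError(
            f"unknown sample_type {sample_type!r}; expected one of {SAMPLE_TYPES}"
        )
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    n_valid = sum(c.valid for c in calls)
    n_unstable = sum(c.unstable for c in calls)
    if n_valid == 0:
        logger.warning(
            "sample %s: no markers passed the coverage filter; status indeterminate",
            sample_id,
        )
        return SampleResult(
            sample_id, sample_type, len(calls), 0, 0, None, cutoff, INDETERMINATE
        )
    fraction = n_unstable / n_valid
    status = MSI_H if fraction >= cutoff else MSS
    return SampleResult(
        sample_id, sample_type, len(calls), n_valid, n_unstable, fraction,
        cutoff, status,
    )


def write_sample_results(results: list[SampleResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tsample_type\tn_markers\tn_valid\tn_unstable\t"
            "unstable_fraction\tcutoff\tstatus\n"
        )
        for r in results:
            frac = "NA" if r.unstable_fraction is None else f"{r.unstable_fraction:.6f}"
            fh.write(
                f"{r.sample_id}\t{r.sample_type}\t{r.n_markers}\t{r.n_valid}\t"
                f"{r.n_unstable}\t{frac}\t{r.cutoff}\t{r.status}\n"
            )


def read_sample_results(path: str | Path) -> list[SampleResult]:
    out: list[SampleResult] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample_id\t"):
            raise ValueError(f"{path}: not a sample-result table")
        for line in fh:
            (sid, stype, n_m, n_v, n_u, frac_s, cut, status) = line.rstrip(
                "\n"
            ).split("\t")
            frac = None if frac_s == "NA" else float(frac_s)
            out.append(
                SampleResult(
                    sid, stype, int(n_m), int(n_v), int(n_u), frac,
                    float(cut), status,
                )
            )
    return out
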