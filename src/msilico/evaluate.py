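"""Classifier evaluation: confusion metrics and McNemar's paired test.

MSI-H is the positive class throughout. Indeterminate calls (samples with
no valid markers) are excluded from the confusion counts and reported
separately; metrics whose denominator is zero are undefined (NA), never 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from scipy import stats

__all__ = ["EvalReport", "confusion", "mcnemar", "read_status_table"]

logger = logging.getLogger("msilico")

POSITIVE = "MSI-H"

#: below this many discordant pairs the exact binomial test is used
MCNEMAR_EXACT_MAX = 25


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    n_indeterminate: int

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def accuracy(self) -> float | None:
        d = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / d if d else None

    def to_dict(self) -> dict:
        def na(x):
            return "NA" if x is None else x

        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "n_indeterminate": self.n_indeterminate,
            "sensitivity": na(self.sensitivity),
            "specificity": na(self.specificity),
            "accuracy": na(self.accuracy),
        }


def confusion(
    truth: Mapping[str, str], called: Mapping[str, str]
) -> EvalReport:
    """Count TP/FP/TN/FN of sample-level calls against truth labels.

    Both mappings are sample_id -> status and must cover identical sample
    sets; indeterminate calls are dropped with a logged count.
    """
    if set(truth) != set(called):
        missing = set(truth) ^ set(called)
        raise ValueError(f"truth and calls cover different samples: {sorted(missing)[:5]}")
    tp = fp = tn = fn = n_ind = 0
    for sid, t in truth.items():
        c = called[sid]
        if c == "indeterminate":
            n_ind += 1
            continue
        if t == POSITIVE:
            tp, fn = (tp + 1, fn) if c == POSITIVE else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if c == POSITIVE else (fp, tn + 1)
    if n_ind:
        logger.warning("%d indeterminate calls excluded from metrics", n_ind)
    return EvalReport(tp, fp, tn, fn, n_ind)


def mcnemar(
    calls_a: Mapping[str, str],
    calls_b: Mapping[str, str],
    truth: Mapping[str, str],
) -> tuple[float, int, int]:
    """McNemar's test on paired classifier correctness.

    Each sample's call is scored correct/incorrect against truth; the test
    runs on the discordant pairs: ``b`` samples correct under A only,
    ``c`` correct under B only. Returns (p_value, b, c). With fewer than
    25 discordant pairs the exact two-sided binomial test on (b, b+c) at
    p=1/2 is used; otherwise the continuity-corrected chi-square
    (|b-c|-1)^2/(b+c) on 1 df. No discordance gives p = 1.

    To compare sensitivities, pass only truth-positive samples; for
    specificities, only truth-negative ones.
    """
    if not (set(calls_a) == set(calls_b) == set(truth)):
        raise ValueError("mcnemar requires paired calls on identical samples")
    b = c = 0
    for sid, t in truth.items():
        ok_a = calls_a[sid] == t
        ok_b = calls_b[sid] == t
        if ok_a and not ok_b:
            b += 1
        elif ok_b and not ok_a:
            c += 1
    n = b + c
    if n == 0:
        return 1.0, b, c
    if n < MCNEMAR_EXACT_MAX:
        p = stats.binomtest(b, n, 0.5).pvalue
    else:
        chi2 = (abs(b - c) - 1) ** 2 / n
        p = float(stats.chi2.sf(chi2, df=1))
    return min(1.0, float(p)), b, c


def read_status_table(path: str | Path) -> dict[str, str]:
    """Read sample statuses from a headered TSV.

    Accepts both truth tables (``truth_status`` column) and sample-result
    tables (``status`` column); keyed by ``sample_id``.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            id_col = header.index("sample_id")
        except ValueError:
            raise ValueError(f"{path}: no sample_id column") from None
        for name in ("truth_status", "status"):
            if name in header:
                status_col = header.index(name)
                break
        else:
            raise ValueError(f"{path}: no status/truth_status column")
        out: dict[str, str] = {}
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) <= max(id_col, status_col):
                continue
            sid = fields[id_col]
            if sid in out:
                raise ValueError(f"{path}: duplicate sample_id {sid!r}")
            out[sid] = fields[status_col]
    return out
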