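"""Synthetic MSI cohort generation with recorded ground truth.

The simulator emulates what targeted sequencing of microsatellite loci
looks like in the three sample regimes the caller supports:

* **Stable marker** -- reads pile up at the reference tract length with a
  small symmetric PCR-stutter probability of slipping one repeat unit in
  either direction.
* **Unstable marker** (in an MSI-H sample) -- a mixture of the stable law
  and a shifted tumor allele, by default a deletion of ``shift_units``
  repeat units carried by ``tumor_fraction`` of the reads, each allele
  with its own stutter. This produces the skewed, deletion-biased,
  multimodal distributions that drive |PSC| above 1.
* **FFPE regime** -- formalin-fixed tissue adds wider coverage dispersion
  across markers, a dropout probability that resamples a marker's coverage
  near or below the 20x filter, and extra per-read +/-1 bp artifact noise.

Coverage follows a negative binomial law parameterized by mean and
dispersion (smaller dispersion = wider spread). All randomness flows from
one seeded generator: identical parameters and seed give a bit-identical
cohort, and the optional SAM/FASTA emission encodes every simulated delta
as one spanning read so the extraction module can be checked end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .markers import Marker, MarkerPanel
from .readlen import LengthDistribution

__all__ = [
    "SimParams",
    "SimulatedSample",
    "SimulatedCohort",
    "simulate_marker",
    "simulate_cohort",
    "emit_sam",
    "build_toy_reference",
    "write_truth_table",
]

# per-regime coverage defaults: fresh tissue / cell lines sequence evenly,
# FFPE shows much wider variation in per-marker read counts
_REGIME_DISPERSION = {"fresh": 50.0, "cell_line": 50.0, "ffpe": 5.0}
_REGIME_DROPOUT = {"fresh": 0.0, "cell_line": 0.0, "ffpe": 0.15}
_REGIME_FFPE_NOISE = {"fresh": 0.0, "cell_line": 0.0, "ffpe": 0.05}

_READ_LENGTH = 150
_LEFT_ANCHOR = 40  # aligned bases left of the tract in every emitted read
_MIN_FLANK_CLEARANCE = 50


@dataclass(frozen=True)
class SimParams:
    """Cohort generation parameters.

    ``shift_units`` > 0 deletes repeat units from the tumor allele (the
    predominant mode of microsatellite instability); a negative value
    switches to insertion mode. ``coverage_dispersion``, ``dropout_rate``
    and ``ffpe_noise_rate`` default per regime when left as None.
    """

    seed: int = 0
    n_msih: int = 1
    n_mss: int = 1
    sample_type: str = "fresh"
    unstable_marker_rate: float = 0.6
    stutter_rate: float = 0.05
    shift_units: int = 3
    tumor_fraction: float = 0.5
    coverage_mean: float = 100.0
    coverage_dispersion: float | None = None
    dropout_rate: float | None = None
    ffpe_noise_rate: float | None = None

    def resolved(self) -> "SimParams":
        """Fill regime-dependent defaults and validate every range."""
        if self.sample_type not in _REGIME_DISPERSION:
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        p = replace(
            self,
            coverage_dispersion=(
                self.coverage_dispersion
                if self.coverage_dispersion is not None
                else _REGIME_DISPERSION[self.sample_type]
            ),
            dropout_rate=(
                self.dropout_rate
                if self.dropout_rate is not None
                else _REGIME_DROPOUT[self.sample_type]
            ),
            ffpe_noise_rate=(
                self.ffpe_noise_rate
                if self.ffpe_noise_rate is not None
                else _REGIME_FFPE_NOISE[self.sample_type]
            ),
        )
        if p.n_msih < 0 or p.n_mss < 0 or p.n_msih + p.n_mss == 0:
            raise ValueError("need a non-empty cohort (n_msih + n_mss > 0)")
        if not 0.0 < p.unstable_marker_rate <= 1.0:
            raise ValueError("unstable_marker_rate must be in (0, 1]")
        if not 0.0 <= p.stutter_rate <= 0.5:
            raise ValueError("stutter_rate must be in [0, 0.5]")
        if p.shift_units == 0:
            raise ValueError("shift_units must be non-zero")
        if not 0.0 < p.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in (0, 1]")
        if p.coverage_mean <= 0 or p.coverage_dispersion <= 0:
            raise ValueError("coverage_mean and coverage_dispersion must be positive")
        if not 0.0 <= p.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0.0 <= p.ffpe_noise_rate <= 0.5:
            raise ValueError("ffpe_noise_rate must be in [0, 0.5]")
        return p

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimParams":
        with open(path) as fh:
            data = json.load(fh)
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown SimParams keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SimulatedSample:
    sample_id: str
    truth_status: str  # MSI-H | MSS
    distributions: list[LengthDistribution]
    truth_unstable: dict[str, bool]  # marker_id -> truth flag


@dataclass
class SimulatedCohort:
    params: SimParams
    panel_name: str
    samples: list[SimulatedSample] = field(default_factory=list)


def _draw_coverage(params: SimParams, rng: np.random.Generator) -> int:
    m, d = params.coverage_mean, params.coverage_dispersion
    cov = int(rng.negative_binomial(d, d / (d + m)))
    if params.dropout_rate > 0 and rng.random() < params.dropout_rate:
        # FFPE dropout: resample uniformly on [0, 25], straddling the 20x filter
        cov = int(rng.integers(0, 26))
    return cov


def _stutter(
    n: int, unit_len: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric one-repeat-unit slippage: 0 w.p. 1-rate, else +/-unit_len."""
    out = np.zeros(n, dtype=np.int64)
    slip = rng.random(n) < rate
    k = int(slip.sum())
    if k:
        out[slip] = unit_len * rng.choice((-1, 1), size=k)
    return out


def simulate_marker(
    unstable: bool,
    marker: Marker,
    params: SimParams,
    rng: np.random.Generator,
) -> LengthDistribution:
    """Generate one marker's normalized length distribution.

    Stable law: delta 0 with probability 1 - stutter_rate, else one repeat
    unit up or down with equal probability. Unstable law: each read comes
    from the shifted tumor allele (at -shift_units * unit_length, with its
    own stutter) with probability tumor_fraction, else from the stable
    law. FFPE artifact noise then perturbs each read by +/-1 bp with
    probability ffpe_noise_rate. Deltas are floored at -ref_length (a
    tract cannot be shorter than zero bases).
    """
    params = params.resolved()
    cov = _draw_coverage(params, rng)
    unit = marker.unit_length
    deltas = _stutter(cov, unit, params.stutter_rate, rng)
    if unstable and cov:
        from_tumor = rng.random(cov) < params.tumor_fraction
        k = int(from_tumor.sum())
        if k:
            shifted = -params.shift_units * unit + _stutter(
                k, unit, params.stutter_rate, rng
            )
            deltas[from_tumor] = shifted
    if params.ffpe_noise_rate > 0 and cov:
        noisy = rng.random(cov) < params.ffpe_noise_rate
        k = int(noisy.sum())
        if k:
            deltas[noisy] += rng.choice((-1, 1), size=k)
    np.maximum(deltas, -marker.ref_length, out=deltas)
    return LengthDistribution(marker.marker_id, deltas.tolist())


def simulate_cohort(panel: MarkerPanel, params: SimParams) -> SimulatedCohort:
    """Generate a full cohort with truth labels, reproducible from the seed.

    Each MSI-H sample receives a random subset of
    ``round(unstable_marker_rate * |panel|)`` truth-unstable markers; MSS
    samples have none.
    """
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    params = params.resolved()
    rng = np.random.default_rng(params.seed)
    n_unstable = round(params.unstable_marker_rate * len(panel))
    cohort = SimulatedCohort(params=params, panel_name=panel.name)
    labels = ["MSI-H"] * params.n_msih + ["MSS"] * params.n_mss
    width = max(2, len(str(len(labels))))
    counters = {"MSI-H": 0, "MSS": 0}
    for status in labels:
        counters[status] += 1
        prefix = "MSIH" if status == "MSI-H" else "MSS"
        sample_id = f"{prefix}_{counters[status]:0{width}d}"
        if status == "MSI-H":
            idx = set(rng.choice(len(panel), size=n_unstable, replace=False).tolist())
        else:
            idx = set()
        truth = {m.marker_id: (i in idx) for i, m in enumerate(panel)}
        dists = [
            simulate_marker(truth[m.marker_id], m, params, rng) for m in panel
        ]
        cohort.samples.append(SimulatedSample(sample_id, status, dists, truth))
    return cohort


def write_truth_table(cohort: SimulatedCohort, path: str | Path) -> None:
    """Sample-level truth labels plus per-marker truth flags, one row per sample."""
    with open(path, "w") as fh:
        fh.write("sample_id\ttruth_status\tunstable_markers\n")
        for s in cohort.samples:
            unstable = ",".join(
                mid for mid, flag in s.truth_unstable.items() if flag
            )
            fh.write(f"{s.sample_id}\t{s.truth_status}\t{unstable or '.'}\n")


# ---------------------------------------------------------------------------
# toy reference + SAM emission


def build_toy_reference(
    panel: MarkerPanel, seed: int = 0
) -> dict[str, str]:
    """Random toy genome with each marker's repeat tract embedded.

    Flanks are random sequence; the bases immediately bordering each tract
    are forced to differ from the repeat's edge base so the reference
    tract has the stated length exactly. Markers must sit >= 50 bp from
    contig ends and from each other.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs: dict[str, list[str]] = {}
    for chrom, markers in panel.by_chrom().items():
        length = markers[-1].end + 200
        seq = bases[rng.integers(0, 4, size=length)].tolist()
        prev_end = 0
        for m in markers:
            if m.start - max(prev_end, 0) < _MIN_FLANK_CLEARANCE or m.start < _MIN_FLANK_CLEARANCE:
                raise ValueError(
                    f"marker {m.marker_id} lacks {_MIN_FLANK_CLEARANCE} bp clearance"
                )
            tract = (m.repeat_unit * math.ceil(m.ref_length / m.unit_length))[
                : m.ref_length
            ]
            seq[m.start : m.end] = list(tract)
            for pos, edge in ((m.start - 1, tract[0]), (m.end, tract[-1])):
                if seq[pos] == edge:
                    seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[edge]
            prev_end = m.end
        seqs[chrom] = "".join(seq)
    return seqs


def _read_for_delta(
    ref: str, marker: Marker, delta: int
) -> tuple[int, str, str]:
    """Build (pos, cigar, seq) for one spanning read encoding ``delta``."""
    s = marker.start - _LEFT_ANCHOR
    if delta == 0:
        return s, f"{_READ_LENGTH}M", ref[s : s + _READ_LENGTH]
    if delta < 0:
        d = -delta
        if d > marker.ref_length:
            raise ValueError(
                f"{marker.marker_id}: delta {delta} exceeds tract length"
            )
        p = marker.start + (marker.ref_length - d) // 2  # centered deletion
        m1 = p - s
        m2 = _READ_LENGTH - m1
        seq = ref[s:p] + ref[p + d : p + d + m2]
        return s, f"{m1}M{d}D{m2}M", seq
    # insertion strictly inside the tract
    r = marker.start + max(1, marker.ref_length // 2)
    m1 = r - s
    m2 = _READ_LENGTH - m1 - delta
    ins = (marker.repeat_unit * math.ceil(delta / marker.unit_length))[:delta]
    seq = ref[s:r] + ins + ref[r : r + m2]
    return s, f"{m1}M{delta}I{m2}M", seq


def emit_sam(
    cohort: SimulatedCohort, panel: MarkerPanel, out_dir: str | Path
) -> dict[str, Path]:
    """Materialize a cohort as toy-reference FASTA + one SAM per sample.

    Every simulated delta becomes one 150 bp spanning read whose CIGAR
    encodes the corresponding insertion or deletion inside the marker
    tract. Returns the paths written: ``reference``, ``reads_truth``,
    ``truth`` and one entry per sample id.
    """
    import pysam

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = build_toy_reference(panel, seed=cohort.params.seed)

    fasta_path = out_dir / "reference.fa"
    with open(fasta_path, "w") as fh:
        for chrom, seq in ref.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in ref.items()],
    }
    chrom_ids = {c: i for i, c in enumerate(ref)}
    markers_by_id = {m.marker_id: m for m in panel}

    paths: dict[str, Path] = {"reference": fasta_path}
    reads_truth_path = out_dir / "reads_truth.tsv"
    with open(reads_truth_path, "w") as truth_fh:
        truth_fh.write("sample_id\tread_name\tmarker_id\tdelta\n")
        for sample in cohort.samples:
            sam_path = out_dir / f"{sample.sample_id}.sam"
            with pysam.AlignmentFile(sam_path, "w", header=header) as sam:
                for dist in sample.distributions:
                    marker = markers_by_id[dist.marker_id]
                    for i, delta in enumerate(dist.deltas):
                        pos, cigar, seq = _read_for_delta(
                            ref[marker.chrom], marker, delta
                        )
                        a = pysam.AlignedSegment(sam.header)
                        a.query_name = f"{sample.sample_id}:{marker.marker_id}:{i}"
                        a.flag = 0
                        a.reference_id = chrom_ids[marker.chrom]
                        a.reference_start = pos
                        a.mapping_quality = 60
                        a.cigarstring = cigar
                        a.query_sequence = seq
                        a.query_qualities = pysam.qualitystring_to_array(
                            "I" * len(seq)
                        )
                        sam.write(a)
                        truth_fh.write(
                            f"{sample.sample_id}\t{a.query_name}\t"
                            f"{marker.marker_id}\t{delta}\n"
                        )
            paths[sample.sample_id] = sam_path
    truth_path = out_dir / "truth.tsv"
    write_truth_table(cohort, truth_path)
    paths["reads_truth"] = reads_truth_path
    paths["truth"] = truth_path
    return paths
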