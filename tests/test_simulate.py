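"""Cohort simulator: determinism, regime contrast, SAM round trip."""

import json
from collections import Counter

import numpy as np
import pytest

from msilico.markers import Marker
from msilico.psc import call_marker
from msilico.readlen import collect_length_distributions
from msilico.simulate import (
    SimParams,
    build_toy_reference,
    emit_sam,
    simulate_cohort,
    simulate_marker,
)


@pytest.fixture
def marker():
    return Marker("BAT26", "chr1", 600, 626, "A", 26)


def test_params_regime_defaults():
    fresh = SimParams(sample_type="fresh").resolved()
    ffpe = SimParams(sample_type="ffpe").resolved()
    assert fresh.dropout_rate == 0.0 and fresh.ffpe_noise_rate == 0.0
    assert ffpe.dropout_rate == 0.15 and ffpe.ffpe_noise_rate == 0.05
    assert ffpe.coverage_dispersion < fresh.coverage_dispersion


@pytest.mark.parametrize(
    "kwargs",
    [
        {"sample_type": "plasma"},
        {"n_msih": 0, "n_mss": 0},
        {"unstable_marker_rate": 0.0},
        {"stutter_rate": 0.6},
        {"shift_units": 0},
        {"tumor_fraction": 0.0},
        {"coverage_mean": -1},
        {"dropout_rate": 1.0},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        SimParams(**kwargs).resolved()


def test_params_json_roundtrip(tmp_path):
    p = SimParams(seed=9, n_msih=3, sample_type="ffpe", shift_units=-2)
    f = tmp_path / "sim.json"
    p.to_json(f)
    assert SimParams.from_json(f) == p
    (tmp_path / "bad.json").write_text(json.dumps({"seed": 1, "bogus": 2}))
    with pytest.raises(ValueError, match="bogus"):
        SimParams.from_json(tmp_path / "bad.json")


def test_noise_free_stable_marker_is_flat(marker):
    params = SimParams(stutter_rate=0.0)
    rng = np.random.default_rng(0)
    d = simulate_marker(False, marker, params, rng)
    assert set(d.deltas) == {0}
    assert call_marker(d).psc == 0.0


def test_pure_homozygous_shift_is_invisible_to_skewness(marker):
    # every read shifted by the same amount: zero variance, PSC 0
    params = SimParams(stutter_rate=0.0, tumor_fraction=1.0, shift_units=3)
    rng = np.random.default_rng(0)
    d = simulate_marker(True, marker, params, rng)
    assert set(d.deltas) == {-3}
    assert call_marker(d).psc == 0.0 and not call_marker(d).unstable


def test_insertion_mode_via_negative_shift(marker):
    params = SimParams(stutter_rate=0.0, tumor_fraction=1.0, shift_units=-2)
    rng = np.random.default_rng(0)
    d = simulate_marker(True, marker, params, rng)
    assert set(d.deltas) == {2}


def test_deltas_floored_at_tract_length():
    short = Marker("S", "chr1", 600, 602, "AC", 2)
    params = SimParams(shift_units=3, tumor_fraction=1.0, stutter_rate=0.0)
    rng = np.random.default_rng(0)
    d = simulate_marker(True, short, params, rng)
    assert min(d.deltas) >= -2


def test_unstable_marker_detection_rate(marker):
    """Monte-Carlo: most default-parameter unstable markers exceed |PSC| > 1.

    The rate is limited by near-50/50 allele splits that pin the median to
    the shifted cluster's stutter edge; the frozen band reflects the
    default mixture's true behaviour (about 0.84 +/- 3 binomial SE).
    """
    params = SimParams(sample_type="fresh")
    rng = np.random.default_rng(123)
    n = 500
    hits = sum(
        call_marker(simulate_marker(True, marker, params, rng)).unstable
        for _ in range(n)
    )
    se = np.sqrt(0.84 * 0.16 / n)
    assert abs(hits / n - 0.84) <= 3 * se


def test_stable_marker_false_call_rate_is_low(marker):
    params = SimParams(sample_type="fresh")
    rng = np.random.default_rng(123)
    calls = [
        call_marker(simulate_marker(False, marker, params, rng))
        for _ in range(300)
    ]
    assert sum(c.unstable for c in calls) <= 3


def test_cohort_determinism(panel23):
    params = SimParams(seed=5, n_msih=2, n_mss=2)
    a = simulate_cohort(panel23, params)
    b = simulate_cohort(panel23, params)
    for sa, sb in zip(a.samples, b.samples):
        assert sa.sample_id == sb.sample_id
        assert sa.truth_unstable == sb.truth_unstable
        assert [d.deltas for d in sa.distributions] == [
            d.deltas for d in sb.distributions
        ]


def test_mss_only_cohort_has_no_truth_unstable(panel23):
    cohort = simulate_cohort(panel23, SimParams(seed=1, n_msih=0, n_mss=5))
    assert len(cohort.samples) == 5
    for s in cohort.samples:
        assert s.truth_status == "MSS"
        assert not any(s.truth_unstable.values())


def test_msih_truth_unstable_count_matches_rate(panel23):
    cohort = simulate_cohort(panel23, SimParams(seed=2, n_msih=4, n_mss=0))
    for s in cohort.samples:
        assert sum(s.truth_unstable.values()) == round(0.6 * 23) == 14


def test_ffpe_coverage_disperses_more_than_fresh(panel23):
    """FFPE cohorts show wider across-marker coverage spread than fresh ones."""
    covs = {}
    for stype in ("fresh", "ffpe"):
        cohort = simulate_cohort(
            panel23, SimParams(seed=3, n_msih=0, n_mss=10, sample_type=stype)
        )
        covs[stype] = np.array(
            [[d.coverage for d in s.distributions] for s in cohort.samples]
        )
    assert covs["ffpe"].std() > covs["fresh"].std()
    # dropout pushes some FFPE markers below the 20x validity filter
    assert (covs["ffpe"] <= 20).sum() > (covs["fresh"] <= 20).sum()


# --- SAM emission -----------------------------------------------------------


def test_toy_reference_embeds_tracts(tiny_panel):
    ref = build_toy_reference(tiny_panel, seed=0)
    m = tiny_panel[0]  # 20 bp poly-A at chr1:200
    seq = ref["chr1"]
    assert seq[m.start : m.end] == "A" * 20
    assert seq[m.start - 1] != "A" and seq[m.end] != "A"


def test_emit_sam_cigar_shapes(tmp_path, tiny_panel):
    params = SimParams(seed=4, n_msih=1, n_mss=0, stutter_rate=0.0,
                       tumor_fraction=1.0, shift_units=3)
    cohort = simulate_cohort(tiny_panel, params)
    paths = emit_sam(cohort, tiny_panel, tmp_path)
    sam_text = paths[cohort.samples[0].sample_id].read_text()
    body = [l for l in sam_text.splitlines() if not l.startswith("@")]
    cigars = {line.split("\t")[5] for line in body}
    assert "150M" in cigars  # reference-length reads: pure match
    assert any("3D" in c for c in cigars)  # mononucleotide 3-unit deletion
    assert any("6D" in c for c in cigars)  # dinucleotide marker: 3 units = 6 bp


def test_sam_roundtrip_recovers_every_delta(tmp_path, tiny_panel):
    """End-to-end oracle: extraction reproduces the simulated multisets exactly."""
    params = SimParams(seed=7, n_msih=1, n_mss=1, coverage_mean=40,
                       sample_type="ffpe")
    cohort = simulate_cohort(tiny_panel, params)
    paths = emit_sam(cohort, tiny_panel, tmp_path)
    for sample in cohort.samples:
        dists = collect_length_distributions(paths[sample.sample_id], tiny_panel)
        got = {d.marker_id: Counter(d.deltas) for d in dists}
        want = {d.marker_id: Counter(d.deltas) for d in sample.distributions}
        assert got == want


def test_emit_sam_deterministic_bytes(tmp_path, tiny_panel):
    params = SimParams(seed=8, n_msih=1, n_mss=0, coverage_mean=30)
    out_a, out_b = tmp_path / "a", tmp_path / "b"
    for out in (out_a, out_b):
        emit_sam(simulate_cohort(tiny_panel, params), tiny_panel, out)
    name = "MSIH_01.sam"
    assert (out_a / name).read_bytes() == (out_b / name).read_bytes()
    assert (out_a / "reference.fa").read_bytes() == (out_b / "reference.fa").read_bytes()
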