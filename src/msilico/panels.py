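"""Fixture marker panels.

The published method was evaluated on three nested panels: 3,154 candidate
microsatellite markers, a random 230-marker subset, and a curated 23-marker
panel of Bethesda-style mononucleotide loci. The marker lists themselves are
not redistributable, so this module ships a synthetic but structurally
faithful stand-in for each size: a packaged hand-built 23-marker fixture on
a toy genome, and a deterministic generator for the 3,154-marker candidate
set (from which the 230-marker panel is drawn by uniform subsetting).
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .markers import Marker, MarkerPanel, read_marker_panel, subset_panel

__all__ = ["load_panel23", "candidate_panel", "panel230", "fixture_panel"]

#: fixed draw seeds so the fixture panels are identical across runs
CANDIDATE_PANEL_SEED = 3154
SUBSET_230_SEED = 230

# toy-genome layout knobs for the candidate generator
_N_CHROMS = 22
_FIRST_START = 200
_SPACING = 400  # distance between consecutive marker starts; >> read length


def load_panel23() -> MarkerPanel:
    """The packaged 23-marker mononucleotide fixture panel (synthetic, toy genome)."""
    with resources.as_file(
        resources.files("msilico.data").joinpath("panel23.tsv")
    ) as p:
        return read_marker_panel(p)


def candidate_panel(
    n_markers: int = 3154, seed: int = CANDIDATE_PANEL_SEED
) -> MarkerPanel:
    """Generate the synthetic candidate marker set on a toy genome.

    Markers are placed on ``chr1``..``chr22`` at fixed 400 bp spacing with
    randomly drawn repeat units (mononucleotide-biased, 1-4 bp motifs) and
    tract lengths of 10-27 repeat units for mononucleotides, fewer for
    longer motifs. Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    per_chrom = -(-n_markers // _N_CHROMS)  # ceil
    units_pool = ["A", "T", "C", "G", "AC", "AT", "AG", "CT", "AAT", "AAG", "AAAT"]
    weights = np.array([0.2, 0.2, 0.1, 0.1, 0.08, 0.08, 0.07, 0.07, 0.04, 0.03, 0.03])
    weights = weights / weights.sum()
    markers: list[Marker] = []
    for i in range(n_markers):
        chrom = f"chr{i // per_chrom + 1}"
        start = _FIRST_START + (i % per_chrom) * _SPACING
        unit = units_pool[rng.choice(len(units_pool), p=weights)]
        if len(unit) == 1:
            n_units = int(rng.integers(10, 28))
        elif len(unit) == 2:
            n_units = int(rng.integers(8, 16))
        else:
            n_units = int(rng.integers(6, 11))
        length = n_units * len(unit)
        markers.append(
            Marker(f"MS{i + 1:04d}", chrom, start, start + length, unit, length)
        )
    return MarkerPanel(name=f"panel{n_markers}", markers=markers)


def panel230(seed: int = SUBSET_230_SEED) -> MarkerPanel:
    """The 230-marker panel: a uniform random subset of the candidate set."""
    p = subset_panel(candidate_panel(), 230, seed=seed)
    p.name = "panel230"
    return p


def fixture_panel(name: str) -> MarkerPanel:
    """Look up one of the three fixture panels by name: panel23/panel230/panel3154."""
    if name == "panel23":
        return load_panel23()
    if name == "panel230":
        return panel230()
    if name == "panel3154":
        return candidate_panel()
    raise ValueError(f"unknown fixture panel {name!r}")
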