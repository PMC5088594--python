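"""Shared fixtures: small synthetic panels reused across test modules."""

import numpy as np
import pytest

from tilemeth import dmr as dmrm
from tilemeth import simulate as sim
from tilemeth import tiling


@pytest.fixture(scope="session")
def small_genome():
    """One-chromosome genome, small enough for fast unit tests."""
    spec = sim.GenomeSpec(n_chroms=1, chrom_length=120_000)
    return sim.generate_genome(spec, seed=7)


@pytest.fixture(scope="session")
def cg_panel():
    """Two-line panel with 40 injected CG differential segments (>=3 tiles).

    Returns (genome, truth, tiles_by_line); base methylation is shared
    between the lines except inside the injected segments, where the
    affected line is offset by 0.90.
    """
    spec = sim.GenomeSpec()
    genome = sim.generate_genome(spec, seed=101)
    truth = sim.make_truth(
        genome,
        ["ref", "alt"],
        "ref",
        seed=102,
        n_dmrs_per_context={"CG": 40, "CHG": 0, "CHH": 0},
        dmr_tile_counts=(3, 4, 5),
    )
    model = sim.MethylationModel()
    tiles = {}
    for line, seed in (("ref", 103), ("alt", 104)):
        df = sim.simulate_methylome(genome, model, line, truth, seed=seed)
        tiles[line] = tiling.aggregate_tiles(df)
    return genome, truth, tiles


@pytest.fixture(scope="session")
def cg_windows(cg_panel):
    """DM windows for the CG panel under default (results) parameters."""
    _, _, tiles = cg_panel
    params = dmrm.DMParams.for_context("CG")
    return dmrm.call_dm_windows(tiles["ref"], tiles["alt"], params), params
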