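"""Shared fixtures: tiny alignments, toy trees, and a small simulated
dataset with all three batteries run once (session-scoped, reused by the
battery-shape and pipeline tests)."""

import numpy as np
import pytest

from codonsel.inference import CladeSpec, FitOptions, run_model_battery
from codonsel.phylo import read_newick
from codonsel.seqdata import CodonAlignment
from codonsel.simulate import scenario_preset, simulate_alignment


def make_alignment(records: dict[str, str]) -> CodonAlignment:
    from codonsel.seqdata import _from_records
    from codonsel.genetics import STANDARD_CODE

    return _from_records(list(records.items()), STANDARD_CODE)


@pytest.fixture
def toy_tree():
    """Five tips: two 2-tip paralog clades plus an outgroup."""
    return read_newick("((a1:0.1,a2:0.2):0.05,(b1:0.1,b2:0.15):0.07,og:0.4);")


@pytest.fixture
def uniform_pi():
    return np.full(61, 1.0 / 61)


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-clade dataset simulated under a paralog-effect truth."""
    scen = scenario_preset(
        "pg_like_paralog", seed=11, n_a=3, n_b=3, n_sites=90
    )
    aln, classes, tree = simulate_alignment(scen)
    return scen, aln, tree


@pytest.fixture(scope="session")
def battery_reports(small_dataset):
    """All three batteries on the small dataset (expensive: run once)."""
    scen, aln, tree = small_dataset
    clades = scen.clades
    opts = FitOptions(seed=7)
    return {
        battery: run_model_battery(aln, tree, clades, battery, options=opts)
        for battery in ("branch", "site", "clade")
    }
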