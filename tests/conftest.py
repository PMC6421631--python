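"""Shared fixtures: one in-memory reference simulation (default settings,
seed 1) plus its on-disk form, both session-scoped since they are the
single most expensive thing the suite builds."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from isoformgrid import diffexpr as de
from isoformgrid import integration as integ
from isoformgrid import peak_classify as pc
from isoformgrid import synthetic_data as sd


@pytest.fixture(scope="session")
def sim_config() -> sd.SimulationConfig:
    return sd.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def simulation(sim_config):
    """(genome, models, truth, tracks, calls, counts) fully in memory."""
    genome, models, truth = sd.simulate_genome(sim_config)
    tracks, calls = sd.simulate_chip_tags(sim_config, truth)
    counts = sd.simulate_rnaseq_counts(sim_config, truth)
    return {
        "genome": genome,
        "models": models,
        "truth": truth,
        "tracks": tracks,
        "calls": calls,
        "counts": counts,
    }


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_config):
    out = tmp_path_factory.mktemp("fixture")
    sd.simulate_all(sim_config, out)
    return out


@pytest.fixture(scope="session")
def classified(simulation):
    summits = pc.merge_summits(
        simulation["calls"]["p42"], simulation["calls"]["p30"]
    )
    return pc.classify(
        summits,
        simulation["tracks"]["p30"],
        simulation["tracks"]["p42"],
        extra_tracks={
            "myb": simulation["tracks"]["myb"],
            "p300": simulation["tracks"]["p300"],
        },
    )


@pytest.fixture(scope="session")
def links(simulation, classified):
    return integ.nearest_gene(classified, simulation["models"])


@pytest.fixture(scope="session")
def de_results(simulation):
    """Per-cell-line DE tables plus the gene x line log2FC matrix."""
    tables = {
        line: de.nb_test_all(simulation["counts"], line)
        for line in sd.CELL_LINES
    }
    fcm = pd.DataFrame(
        {line: t.set_index("gene_id")["log2fc"] for line, t in tables.items()}
    )
    return tables, fcm


def truth_class_by_summit(truth: sd.GroundTruth) -> pd.Series:
    """Planted class keyed by summit coordinate (summits are unique)."""
    return truth.peaks.set_index("summit")["class"]


def class_accuracy(classified_peaks, truth: sd.GroundTruth) -> float:
    lookup = truth_class_by_summit(truth)
    hits = [
        p.peak_class == lookup.loc[p.summit.summit_pos]
        for p in classified_peaks
        if p.summit.summit_pos in lookup.index
    ]
    assert len(hits) == len(truth.peaks)
    return float(np.mean(hits))
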