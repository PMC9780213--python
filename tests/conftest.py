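"""Shared fixtures: one default simulated screen + pipeline run per session.

The heavy artifacts (a full desk-scale simulation and its pipeline result)
are computed once and shared across module and acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import hcsprofile as h
from hcsprofile.simulate import default_config, null_config

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_screen():
    """(config, cells, truth) for the default active screen."""
    cfg = default_config(seed=DEFAULT_SEED)
    cells, truth = h.simulate_screen(cfg)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def default_run(default_screen):
    """(config, cells, truth, PipelineResult) for the default active screen."""
    cfg, cells, truth = default_screen
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = h.run_pipeline(cells, cfg.layouts()[0], cfg.catalog())
    return cfg, cells, truth, result


@pytest.fixture(scope="session")
def null_screen():
    """A null screen (no artifacts, no effects) with its BZ table and layout."""
    cfg = null_config(seed=11)
    cells, truth = h.simulate_screen(cfg)
    layout = cfg.layouts()[0]
    wells = h.summarize_wells(cells)
    report = h.positional_report(wells, layout)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, adjustments = h.adjust_wells(wells, report, layout)
        bz, _ = h.standardize_cells(cells, adjustments)
    return cfg, cells, bz, report


def toy_cells(records, features=("f1", "f2")):
    """Build a minimal cell table from (plate, rep, row, col, trt, conc, *vals)."""
    rows = []
    for rec in records:
        plate, rep, row, col, trt, conc = rec[:6]
        vals = rec[6:]
        d = {"plate": plate, "replicate": rep, "row": row, "col": col,
             "treatment": trt, "concentration": conc}
        d.update(dict(zip(features, vals)))
        rows.append(d)
    return pd.DataFrame(rows)
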