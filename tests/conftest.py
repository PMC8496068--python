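import numpy as np
import pandas as pd
import pytest

from promid.datamodel import AnchorDefinition, LongTable
from promid.pipeline import RunConfig, run_pipeline
from promid.simulate import default_scenario

PS = AnchorDefinition(code="PS", categories=(0, 1, 2, 3, 4), worse_direction=1)


def make_table(rows, score_cols=("PF",), anchor_defs=None):
    """Build a LongTable from (patient, trial, timepoint, score..., anchor...) dicts."""
    if anchor_defs is None:
        anchor_defs = {"PS": PS}
    df = pd.DataFrame(rows)
    return LongTable.from_frame(
        df, score_columns=list(score_cols), anchor_defs=anchor_defs
    )


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the shipped default synthetic world.

    Session-scoped: the same artifacts back the pipeline-shape, recovery and
    report-format tests.
    """
    out = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig(scenario=default_scenario(seed=12345), out_dir=out)
    return run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
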