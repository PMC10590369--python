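"""Shared fixtures: small synthetic logs and hand-built processes."""

import numpy as np
import pytest

from traceclust.synthetic import example_config, generate_log
from traceclust.themes import ThemeProcess


@pytest.fixture(scope="session")
def small_config():
    return example_config(
        n_actors=12, n_weeks=10, n_clusters=3, n_topics_true=6, seed=11
    )


@pytest.fixture(scope="session")
def small_log(small_config):
    events, truth = generate_log(small_config)
    return events, truth


def make_process(actor_id, weeks, P, C):
    """Build a ThemeProcess from plain lists; NaN rows where C == 0."""
    P = np.asarray(P, dtype=float)
    C = np.asarray(C, dtype=int)
    P = P.copy()
    P[C == 0] = np.nan
    return ThemeProcess(actor_id=actor_id, weeks=list(weeks), P=P, C=C)


@pytest.fixture
def toy_window():
    return [(2019, w) for w in range(1, 5)]
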