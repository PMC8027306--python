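"""Shared fixtures: small synthetic datasets generated at session scope."""

import numpy as np
import pytest

from tempocode.events import EventStream
from tempocode.synth import (RateCodedGenConfig, TemporalGenConfig,
                             gen_rate_coded_dataset, gen_temporal_dataset,
                             make_templates, raised_cosine_envelope)
from tempocode.pipelines import prepare_dataset


@pytest.fixture(scope="session")
def envelope():
    return raised_cosine_envelope(105)


@pytest.fixture(scope="session")
def templates():
    return make_templates(4, 24, 24)


@pytest.fixture(scope="session")
def rate_dataset_small(templates, envelope):
    """A quick rate-coded dataset for unit-level checks (not the study scale)."""
    train = gen_rate_coded_dataset(
        templates, envelope, RateCodedGenConfig(n_per_class=15, seed=11))
    test = gen_rate_coded_dataset(
        templates, envelope, RateCodedGenConfig(n_per_class=8, seed=12))
    return train, test


@pytest.fixture(scope="session")
def temporal_dataset_small():
    train = gen_temporal_dataset(TemporalGenConfig(n_per_class=15, seed=11))
    test = gen_temporal_dataset(TemporalGenConfig(n_per_class=8, seed=12))
    return train, test


def random_stream(rng, width=16, height=16, n_events=200,
                  duration=105_000, label=None) -> EventStream:
    t = np.sort(rng.integers(0, duration, size=n_events))
    x = rng.integers(0, width, size=n_events)
    y = rng.integers(0, height, size=n_events)
    p = rng.integers(0, 2, size=n_events)
    return EventStream.from_arrays(t, x, y, p, width, height,
                                   duration=duration, label=label)
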