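import numpy as np
import pytest

from pbsample.records import CensoredDataset, SampleRecord


def make_dataset(detects, nondetects, grouping=""):
    """Build a dataset from detect values and (limit, count) pairs or a
    flat list of censoring limits."""
    recs = [SampleRecord(float(v), False, reporting_limit=1.0) for v in detects]
    for rl in nondetects:
        recs.append(SampleRecord(float(rl), True, reporting_limit=float(rl)))
    return CensoredDataset(recs, grouping=grouping)


@pytest.fixture
def single_limit_dataset():
    """Single reporting limit 1 ppb: detects {2, 5}, nondetects {<1, <1},
    in mixed input order."""
    recs = [
        SampleRecord(2.0, False, 1.0),
        SampleRecord(1.0, True, 1.0),
        SampleRecord(5.0, False, 1.0),
        SampleRecord(1.0, True, 1.0),
    ]
    return CensoredDataset(recs)


@pytest.fixture
def two_limit_dataset():
    """Two limits (1, 4 ppb): detects {0.5, 2, 3, 5}, nondetects
    {<1, <1, <4}."""
    recs = [
        SampleRecord(0.5, False, 1.0),
        SampleRecord(1.0, True, 1.0),
        SampleRecord(2.0, False, 1.0),
        SampleRecord(1.0, True, 1.0),
        SampleRecord(3.0, False, 1.0),
        SampleRecord(4.0, True, 4.0),
        SampleRecord(5.0, False, 4.0),
    ]
    return CensoredDataset(recs)


def random_censored_dataset(rng, n=60, limits=(1.0, 2.0, 4.0), mu=0.5, sigma=1.0):
    """Random multi-limit censored dataset for property tests."""
    true = np.exp(mu + sigma * rng.standard_normal(n))
    rl = rng.choice(limits, size=n)
    recs = []
    for t, r in zip(true, rl):
        cens = t < r
        recs.append(SampleRecord(float(r) if cens else float(t), bool(cens), float(r)))
    return CensoredDataset(recs)
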