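import numpy as np
import pytest

from bpdrisk import CensoredCount, ResidueDataset, ResidueRecord


@pytest.fixture
def toy_dataset() -> ResidueDataset:
    """Six records, two analytes, one food, one censored row per analyte."""
    recs = [
        ResidueRecord("s1", "rice_flour", "BP", lod=0.1, detected=True, value=10.0),
        ResidueRecord("s2", "rice_flour", "BP", lod=0.1, detected=True, value=20.0),
        ResidueRecord("s3", "rice_flour", "BP", lod=0.1, detected=False),
        ResidueRecord("s1", "rice_flour", "BP-3", lod=0.05, detected=True, value=1.0),
        ResidueRecord("s2", "rice_flour", "BP-3", lod=0.05, detected=True, value=2.0),
        ResidueRecord("s3", "rice_flour", "BP-3", lod=0.05, detected=False),
    ]
    return ResidueDataset(recs)


@pytest.fixture
def uncensored_counts() -> CensoredCount:
    """50 detected lognormal values, no non-detects."""
    rng = np.random.default_rng(314)
    vals = np.exp(rng.normal(2.0, 0.5, 50))
    return CensoredCount.from_values(vals, 0, 0.001)
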