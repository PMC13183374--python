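import numpy as np
import pytest

from parecall.scoring import CleavageSite, ScoredPosition
from parecall.tracks import EndCountTrack, GenomicPosition, NormalizedTrack, cpm_normalize


def make_site(
    position: int,
    strand: str = "+",
    reference: str = "chrI",
    wt_cpm=(50.0, 50.0),
    mut_cpm=(0.0, 0.0),
) -> CleavageSite:
    """A called site with per-replicate scores derived from the cpm values."""
    from parecall.scoring import compare_score

    pos = GenomicPosition(reference, position, strand)
    score = tuple(compare_score(w, m) for w, m in zip(wt_cpm, mut_cpm))
    scored = ScoredPosition(pos, tuple(wt_cpm), tuple(mut_cpm), score)
    return CleavageSite(position=pos, scored=scored)


def make_normalized(values_by_key, reference_lengths, sample_id="sample"):
    """NormalizedTrack with given cpm vectors; unlisted strands are zero."""
    values = {
        (ref, strand): np.zeros(n, dtype=float)
        for ref, n in reference_lengths.items()
        for strand in ("+", "-")
    }
    for key, vec in values_by_key.items():
        values[key] = np.asarray(vec, dtype=float)
    return NormalizedTrack(sample_id, dict(reference_lengths), values, source_total=1_000_000)


@pytest.fixture
def site_factory():
    return make_site


@pytest.fixture
def normalized_factory():
    return make_normalized


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at the standard study conditions."""
    from parecall.simulate import SyntheticConfig, simulate_dataset

    return simulate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_replicate_pairs(default_dataset):
    return [
        (cpm_normalize(wt), cpm_normalize(mut))
        for wt, mut in default_dataset.libraries.replicate_pairs
    ]
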