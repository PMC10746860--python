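import numpy as np
import pytest

from sigassign import SignatureSet, custom_schema
from sigassign.benchmark import pairwise_cosine


@pytest.fixture
def toy_signatures() -> SignatureSet:
    """Three 3-channel signatures: two axis-aligned, one flat."""
    profiles = np.array(
        [
            [1.0, 0.0, 1 / 3],
            [0.0, 1.0, 1 / 3],
            [0.0, 0.0, 1 / 3],
        ]
    )
    schema = custom_schema(["c1", "c2", "c3"])
    return SignatureSet(schema, ["s1", "s2", "s3"], profiles)


@pytest.fixture
def toy_sample() -> np.ndarray:
    return np.array([50, 50, 0])


def make_planted_samples(
    n_samples: int,
    seed: int,
    n_channels: int = 96,
    n_ref: int = 79,
    max_active: int = 3,
    min_exposure: float = 0.2,
    max_cosine: float = 0.6,
):
    """Noise-free samples lying exactly in the cone of their planted signatures.

    Reference profiles are built from integer channel masses summing to 1000
    (10 random channels each), so an activity that is a multiple of 1000
    yields exactly integral channel counts: the planted samples fit with zero
    residual and the test isolates the selection loop from sampling noise.
    Active sets (size <= max_active) are re-drawn until all pairwise profile
    cosines are below ``max_cosine`` and every planted signature carries at
    least ``min_exposure`` of the burden, so each component is individually
    detectable under the removal rule.

    Returns (SignatureSet, counts matrix, true activities, planted sets).
    """
    rng = np.random.default_rng(seed)
    unit = 1000
    masses = np.zeros((n_channels, n_ref), dtype=np.int64)
    for j in range(n_ref):
        channels = rng.choice(n_channels, size=10, replace=False)
        masses[channels, j] = rng.multinomial(unit, rng.dirichlet(np.ones(10)))
    refs = SignatureSet(
        custom_schema([f"ch{i + 1}" for i in range(n_channels)]),
        [f"SYN{j + 1}" for j in range(n_ref)],
        masses / unit,
    )
    cosines = pairwise_cosine(refs)
    counts = np.zeros((n_channels, n_samples), dtype=np.int64)
    true = np.zeros((n_ref, n_samples), dtype=np.int64)
    planted = []
    for s in range(n_samples):
        while True:
            k = int(rng.integers(1, max_active + 1))
            active = np.sort(rng.choice(n_ref, size=k, replace=False))
            sub = cosines[np.ix_(active, active)]
            if k > 1 and np.max(sub - np.eye(k)) >= max_cosine:
                continue
            multiples = rng.integers(1, 4, size=k)
            if k == 1 or multiples.min() / multiples.sum() >= min_exposure:
                break
        counts[:, s] = masses[:, active] @ multiples
        true[active, s] = multiples * unit
        planted.append(tuple(int(i) for i in active))
    return refs, counts, true, planted
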