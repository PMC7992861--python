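import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from m7gnet import (
    AssociationMatrix,
    MFConfig,
    NetworkData,
    SimilarityMatrix,
    SyntheticSpec,
    make_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted():
    """The planted low-rank study dataset: m=60 sites, n=20 diseases, rank 4,
    80 known associations, noise sd 0.1."""
    spec = SyntheticSpec(m=60, n=20, true_rank=4, n_known=80, noise_sd=0.1, seed=0)
    data, truth = make_dataset(spec)
    return data, truth


@pytest.fixture(scope="session")
def cv_config():
    """ALS configuration used for cross-validation on the planted dataset:
    rank matching the planted rank, the ridge penalty 2^-2."""
    return MFConfig(k=4, lambda1=0.25, lambda2=0.25, max_iter=200, tol=1e-4, seed=1)


@pytest.fixture
def tiny_data():
    """Minimal 3-site / 2-disease dataset with one known association."""
    sim = SimilarityMatrix(
        ["s1", "s2", "s3"],
        np.array([[1.0, 0.8, 0.2], [0.8, 1.0, 0.3], [0.2, 0.3, 1.0]]),
        "cnf",
    )
    dsim = SimilarityMatrix(["d1", "d2"], np.array([[1.0, 0.5], [0.5, 1.0]]), "disease")
    assoc = AssociationMatrix(["s1", "s2", "s3"], ["d1", "d2"], np.array([[1.0, 0], [0, 0], [0, 0]]))
    return NetworkData(sim, sim, assoc, dsim)


def random_network(rng, m=8, n=4, density=0.3):
    """A random valid heterogeneous network for solver stress tests."""
    from m7gnet import assemble, profile_similarity

    ss = profile_similarity([f"s{i}" for i in range(m)], seed=int(rng.integers(2**31)))
    dd = profile_similarity([f"d{j}" for j in range(n)], seed=int(rng.integers(2**31)))
    vals = (rng.random((m, n)) < density).astype(float)
    assoc = AssociationMatrix(list(ss.labels), list(dd.labels), vals)
    return assemble(ss, assoc, dd)
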