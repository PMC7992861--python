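"""Synthetic datasets with the statistical structure the method assumes.

The generator plants a low-rank association pattern: sites and diseases are
assigned to ``true_rank`` latent groups, latent factors are one-hot group
indicators plus Gaussian jitter, and the ``n_known`` site-disease pairs with
the highest (noisy) factor inner products become the known associations.
Site sequences are mutated copies of per-group archetype 41-mers (center
fixed to G, honouring the site-centered convention), so the sequence-derived
similarity networks genuinely carry the group signal; the disease similarity
network is built from group-correlated nonnegative profiles.  This makes the
method's core assumption true by construction, so parameter recovery is a
meaningful test.  A uniform-random association mode exists for null
calibration, where no fixture structure predicts the held-out pairs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .features import encode_all
from .evaluation import NetworkData
from .io import AssociationMatrix, SiteRecord
from .similarity import SimilarityMatrix, similarity_matrix

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    """Size and noise parameters of one synthetic dataset."""

    m: int = 60
    n: int = 20
    seq_length: int = 41
    true_rank: int = 4
    n_known: int = 80
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_known > self.m * self.n:
            raise ContractError("n_known cannot exceed m * n")
        if self.true_rank >= min(self.m, self.n):
            raise ContractError("true_rank must be < min(m, n)")
        if self.seq_length < 1 or self.seq_length % 2 == 0:
            raise ContractError("seq_length must be a positive odd integer")
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be nonnegative")


def _site_ids(m: int) -> list[str]:
    return [f"site{i:04d}" for i in range(m)]


def _disease_ids(n: int) -> list[str]:
    return [f"DOID:{j:04d}" for j in range(n)]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    seq = rng.choice(_BASES, size=length)
    seq[length // 2] = "G"
    return "".join(seq)


def random_sites(spec: SyntheticSpec) -> list[SiteRecord]:
    """Uniform-random site-centered sequences (center base fixed to G)."""
    rng = np.random.default_rng(spec.seed)
    return [
        SiteRecord(site_id=sid, ref_seq=_random_seq(rng, spec.seq_length), site_centered=True)
        for sid in _site_ids(spec.m)
    ]


def clustered_sites(
    spec: SyntheticSpec,
    clusters: np.ndarray,
    mutation_rate: float = 0.15,
    seed: int | None = None,
) -> list[SiteRecord]:
    """Sites drawn as mutated copies of one archetype sequence per group.

    Each position (except the fixed central G) is replaced by a uniform
    random base with probability ``mutation_rate``, so within-group sequences
    stay more alike than between-group ones.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_groups = int(np.max(clusters)) + 1 if len(clusters) else 0
    archetypes = [_random_seq(rng, spec.seq_length) for _ in range(n_groups)]
    records = []
    center = spec.seq_length // 2
    for sid, c in zip(_site_ids(spec.m), clusters):
        seq = np.array(list(archetypes[int(c)]))
        mutate = rng.random(spec.seq_length) < mutation_rate
        mutate[center] = False
        seq[mutate] = rng.choice(_BASES, size=int(mutate.sum()))
        records.append(SiteRecord(site_id=sid, ref_seq="".join(seq), site_centered=True))
    return records


def planted_association_matrix(
    spec: SyntheticSpec,
    site_clusters: np.ndarray | None = None,
    disease_clusters: np.ndarray | None = None,
    prevalence_sigma: float = 0.8,
) -> tuple[AssociationMatrix, np.ndarray, np.ndarray]:
    """Known associations planted from a noisy low-rank score matrix.

    Site factors P (m x r) and disease factors Q (n x r) are one-hot group
    indicators plus Gaussian jitter; scores = P Q^T + noise, and the top
    ``n_known`` scores become the known (1) associations.  Disease factor
    rows are additionally scaled by lognormal(0, ``prevalence_sigma``)
    prevalence weights, mimicking the strongly skewed per-disease annotation
    counts of real association databases (a few diseases carry most of the
    known links).  Returns the association matrix together with the
    generating factors for recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    r = spec.true_rank
    if site_clusters is None:
        site_clusters = rng.integers(r, size=spec.m)
    if disease_clusters is None:
        disease_clusters = rng.integers(r, size=spec.n)
    P = np.eye(r)[site_clusters] + 0.2 * rng.normal(size=(spec.m, r))
    Q = np.eye(r)[disease_clusters] + 0.2 * rng.normal(size=(spec.n, r))
    Q = Q * rng.lognormal(0.0, prevalence_sigma, size=spec.n)[:, None]
    scores = P @ Q.T + spec.noise_sd * rng.normal(size=(spec.m, spec.n))
    flat = np.argsort(scores, axis=None)[::-1][: spec.n_known]
    values = np.zeros(spec.m * spec.n)
    values[flat] = 1.0
    assoc = AssociationMatrix(
        _site_ids(spec.m), _disease_ids(spec.n), values.reshape(spec.m, spec.n)
    )
    return assoc, P, Q


def uniform_random_associations(
    m: int, n: int, n_known: int, seed: int = 0
) -> AssociationMatrix:
    """Known associations placed uniformly at random (null mode)."""
    rng = np.random.default_rng(seed)
    flat = rng.choice(m * n, size=n_known, replace=False)
    values = np.zeros(m * n)
    values[flat] = 1.0
    return AssociationMatrix(_site_ids(m), _disease_ids(n), values.reshape(m, n))


def profile_similarity(
    labels: list[str],
    seed: int = 0,
    clusters: np.ndarray | None = None,
    noise: float = 0.2,
    n_dims: int = 10,
) -> SimilarityMatrix:
    """Similarity from normalized inner products of nonnegative profiles.

    Without ``clusters`` the profiles are uniform random (a structureless but
    valid similarity network); with ``clusters`` each profile is its group's
    one-hot indicator plus nonnegative jitter, so within-group pairs are more
    similar.  Nonnegative profiles keep every entry in [0, 1].
    """
    rng = np.random.default_rng(seed)
    p = len(labels)
    if clusters is None:
        profiles = rng.random((p, n_dims))
    else:
        r = int(np.max(clusters)) + 1
        profiles = np.eye(r)[np.asarray(clusters)] + noise * rng.random((p, r))
    norms = np.linalg.norm(profiles, axis=1)
    values = (profiles / norms[:, None]) @ (profiles / norms[:, None]).T
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(labels), values, "disease")


def synthetic_disease_similarity(n: int, seed: int = 0) -> SimilarityMatrix:
    """A valid, structureless disease semantic similarity matrix."""
    return profile_similarity(_disease_ids(n), seed=seed)


def make_dataset(
    spec: SyntheticSpec,
    null: bool = False,
    mutation_rate: float = 0.15,
) -> tuple[NetworkData, dict]:
    """Full synthetic experiment inputs plus ground truth.

    Builds group-structured sequences, encodes them into both feature spaces,
    derives the two site similarity networks, plants the association matrix
    and a group-correlated disease similarity network.  With ``null=True``
    the associations are instead placed uniformly at random, leaving the
    similarity networks unrelated to the association pattern.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    site_clusters = rng.integers(spec.true_rank, size=spec.m)
    disease_clusters = rng.integers(spec.true_rank, size=spec.n)
    sites = clustered_sites(spec, site_clusters, mutation_rate=mutation_rate)
    csn = similarity_matrix(encode_all(sites, "chemical"), "jaccard")
    cnfsn = similarity_matrix(encode_all(sites, "cnf"), "cosine")
    assoc, P, Q = planted_association_matrix(spec, site_clusters, disease_clusters)
    if null:
        assoc = uniform_random_associations(spec.m, spec.n, spec.n_known, seed=spec.seed + 17)
    disease_sim = profile_similarity(
        _disease_ids(spec.n), seed=spec.seed + 3, clusters=disease_clusters
    )
    truth = {
        "sites": sites,
        "site_clusters": site_clusters,
        "disease_clusters": disease_clusters,
        "P": P,
        "Q": Q,
    }
    return NetworkData(csn, cnfsn, assoc, disease_sim), truth
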