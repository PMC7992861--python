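import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from m7gnet import (
    ContractError,
    MFConfig,
    NetworkData,
    grid_search,
    kfold_cv,
    loocv,
    planted_association_matrix,
    profile_similarity,
    roc_auc,
    synthetic_disease_similarity,
    SyntheticSpec,
)


def auc_bruteforce(pos, neg):
    """All-pairs comparison oracle (ties count one half)."""
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def small_data():
    """A small, quick dataset for harness-behaviour tests."""
    spec = SyntheticSpec(m=24, n=8, true_rank=3, n_known=30, noise_sd=0.1, seed=5)
    rng = np.random.default_rng(11)
    sc, dc = rng.integers(3, size=24), rng.integers(3, size=8)
    assoc, _, _ = planted_association_matrix(spec, sc, dc)
    sim = profile_similarity([f"site{i:04d}" for i in range(24)], seed=1, clusters=sc)
    dsim = profile_similarity([f"DOID:{j:04d}" for j in range(8)], seed=2, clusters=dc)
    return NetworkData(sim, sim, assoc, dsim)


fast = MFConfig(k=3, lambda1=0.25, lambda2=0.25, max_iter=60, tol=1e-3, seed=0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([3, 4], [1, 2]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1.0, 1.0], [1.0, 1.0, 1.0]) == 0.5

    def test_direct_count(self):
        assert roc_auc([0.9, 0.4], [0.6, 0.1]) == 0.75

    def test_empty_inputs_rejected(self):
        with pytest.raises(ContractError):
            roc_auc([], [1.0])
        with pytest.raises(ContractError):
            roc_auc([1.0], [])

    def test_matches_bruteforce_and_sklearn(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pos = rng.choice(np.linspace(0, 1, 9), size=rng.integers(1, 12))
            neg = rng.choice(np.linspace(0, 1, 9), size=rng.integers(1, 12))
            ours = roc_auc(pos, neg)
            assert ours == pytest.approx(auc_bruteforce(pos, neg))
            y = np.r_[np.ones(pos.size), np.zeros(neg.size)]
            assert ours == pytest.approx(roc_auc_score(y, np.r_[pos, neg]))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        pos, neg = rng.normal(size=20), rng.normal(size=30)
        base = roc_auc(pos, neg)
        for f in (np.exp, lambda x: 3 * x - 7, np.arctan):
            assert roc_auc(f(pos), f(neg)) == pytest.approx(base)

    def test_complementarity(self):
        rng = np.random.default_rng(2)
        pos, neg = rng.normal(size=15), rng.normal(size=25)
        assert roc_auc(pos, neg) + roc_auc(neg, pos) == pytest.approx(1.0)


class TestKFoldCV:
    def test_deterministic_given_master_seed(self, small_data):
        r1 = kfold_cv(small_data, fast, alpha=0.5, folds=5, repeats=2, seed=42)
        r2 = kfold_cv(small_data, fast, alpha=0.5, folds=5, repeats=2, seed=42)
        assert r1.auc_per_run == r2.auc_per_run and r1.mean == r2.mean

    def test_report_statistics_consistent(self, small_data):
        rep = kfold_cv(small_data, fast, alpha=0.5, folds=5, repeats=3, seed=1)
        assert rep.mean == pytest.approx(np.mean(rep.auc_per_run))
        assert rep.sd == pytest.approx(np.std(rep.auc_per_run, ddof=1))
        assert len(rep.auc_per_run) == 3
        assert 0.0 <= rep.mean <= 1.0

    def test_contract_errors(self, small_data):
        with pytest.raises(ContractError):
            kfold_cv(small_data, fast, folds=1)
        with pytest.raises(ContractError):
            kfold_cv(small_data, fast, folds=31)  # only 30 known pairs

    def test_report_serializes(self, small_data):
        rep = kfold_cv(small_data, fast, alpha=0.5, folds=5, seed=3)
        d = rep.to_dict()
        assert d["protocol"] == "kfold" and d["config"]["k"] == 3


class TestLOOCV:
    def test_scope_validation(self, small_data):
        with pytest.raises(ContractError):
            loocv(small_data, fast, scope="sideways")

    def test_global_runs_and_is_deterministic(self, small_data):
        r1 = loocv(small_data, fast, alpha=0.5, scope="global", seed=9)
        r2 = loocv(small_data, fast, alpha=0.5, scope="global", seed=9)
        assert r1.auc == r2.auc
        assert len(r1.auc_per_run) == small_data.associations.n_known

    def test_local_candidates_restricted_to_disease(self, small_data):
        rep = loocv(small_data, fast, alpha=0.5, scope="local", seed=9)
        assert rep.protocol == "loocv_local"
        assert 0.0 <= rep.auc <= 1.0
        assert len(rep.auc_per_run) + rep.n_skipped == small_data.associations.n_known


class TestGridSearch:
    def test_single_point_equals_direct_cv(self, small_data):
        table, best = grid_search(
            small_data, [3], [0.25], alpha_grid=[0.5],
            folds=5, repeats=1, seed=7, max_iter=60, tol=1e-3,
        )
        direct = kfold_cv(
            small_data, MFConfig(k=3, lambda1=0.25, lambda2=0.25, max_iter=60, tol=1e-3),
            alpha=0.5, folds=5, repeats=1, seed=7,
        )
        assert len(table) == 1
        assert best["mean_auc"] == pytest.approx(direct.mean)

    def test_alpha_sweep_isolates_informative_channel(self):
        # chemical network carries no signal, CNF network carries the group
        # structure behind the planted associations
        spec = SyntheticSpec(m=40, n=15, true_rank=3, n_known=60, seed=2)
        rng = np.random.default_rng(5)
        sc, dc = rng.integers(3, size=40), rng.integers(3, size=15)
        site_ids = [f"site{i:04d}" for i in range(40)]
        csn = profile_similarity(site_ids, seed=7)
        cnfsn = profile_similarity(site_ids, seed=8, clusters=sc, noise=0.15)
        assoc, _, _ = planted_association_matrix(spec, sc, dc)
        data = NetworkData(csn, cnfsn, assoc, synthetic_disease_similarity(15, seed=9))
        table, best = grid_search(
            data, [3], [0.25], alpha_grid=[0.0, 1.0],
            folds=5, repeats=1, seed=3, max_iter=100, tol=1e-4,
        )
        auc = table.set_index("alpha")["mean_auc"]
        assert auc[1.0] > auc[0.0]
        assert best["alpha"] == 1.0

    def test_published_scale_grids_accepted(self, small_data):
        # the full-scale grids are accepted verbatim; probe one corner cheaply
        table, _ = grid_search(
            small_data, [3], [2**-2, 2**2], alpha_grid=[0.0],
            folds=5, repeats=1, seed=0, max_iter=40, tol=1e-3,
        )
        assert sorted(table["lambda1"]) == [0.25, 4.0]

    def test_empty_grid_rejected(self, small_data):
        with pytest.raises(ContractError):
            grid_search(small_data, [], [0.25])


class TestLeakageIsolation:
    def test_masking_is_isolated_per_iteration(self, small_data):
        net0 = small_data.assemble(0.5)
        A0, W0 = net0.A.copy(), net0.W.copy()
        known = small_data.associations.known_pairs()
        for pair in known[:5]:
            net = net0.mask_out([pair])
            i, j = pair
            assert net.A[i, net.m + j] == 0.0 and net.W[i, net.m + j] == 0.0
            diff_a = np.argwhere(net.A != A0)
            assert {tuple(x) for x in diff_a} == {(i, net.m + j), (net.m + j, i)}
        np.testing.assert_array_equal(net0.A, A0)
        np.testing.assert_array_equal(net0.W, W0)
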