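"""Cross-validation protocols, ROC/AUC and hyperparameter grid search.

Three protocols are implemented:

* **repeated k-fold CV** — the known associations are shuffled and split into
  roughly equal folds; each fold in turn is hidden from the network, the
  model refitted, and the hidden fold's scores ranked against the scores of
  every never-known (candidate) pair, all taken from the same fit.  One AUC
  per fold, averaged per repeat; mean and sd are reported across repeats.
* **global LOOCV** — each known association is hidden alone and ranked
  against all never-known pairs.
* **local LOOCV** — as global, but the candidate set is restricted to the
  never-known pairs of the held-out association's disease; this is the
  stricter test, since the candidate pool per comparison is much smaller.

AUC is computed as the Mann-Whitney statistic (ties count 1/2), which equals
the area under the ROC curve traced by sweeping a rank threshold.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ContractError
from .heteronet import HeteroNetwork, assemble
from .io import AssociationMatrix
from .factorization import MFConfig, MaskedALS
from .similarity import SimilarityMatrix, integrate

logger = logging.getLogger(__name__)


@dataclass
class NetworkData:
    """The inputs of one experiment: two site networks, associations, disease network.

    ``csn``/``cnfsn`` are the chemical and CNF site similarity networks; they
    may be the same object when only a single precomputed site network is
    available (alpha then has no effect).
    """

    csn: SimilarityMatrix
    cnfsn: SimilarityMatrix
    associations: AssociationMatrix
    disease_sim: SimilarityMatrix

    def assemble(self, alpha: float = 1.0) -> HeteroNetwork:
        a_ss = self.csn if self.csn is self.cnfsn else integrate(self.csn, self.cnfsn, alpha)
        return assemble(a_ss, self.associations, self.disease_sim)


@dataclass
class CVReport:
    """Aggregated cross-validation result."""

    protocol: str
    auc: float
    auc_per_run: list[float]
    mean: float
    sd: float
    config: MFConfig
    alpha: float
    seed: int
    n_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "auc": self.auc,
            "auc_per_run": list(self.auc_per_run),
            "mean": self.mean,
            "sd": self.sd,
            "alpha": self.alpha,
            "seed": self.seed,
            "n_skipped": self.n_skipped,
            "config": vars(self.config).copy(),
        }


def roc_auc(positives, negatives) -> float:
    """Mann-Whitney AUC of positive scores against negative scores.

    Equals (number of (pos, neg) pairs with pos > neg, ties counting 1/2)
    divided by |pos| * |neg|; invariant under any strictly monotone transform
    of the pooled scores.
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ContractError("roc_auc requires nonempty positive and negative sets")
    ranks = rankdata(np.concatenate([pos, neg]))
    pos_rank_sum = ranks[: pos.size].sum()
    return float((pos_rank_sum - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def _fit_scores(net: HeteroNetwork, config: MFConfig, rng_seed) -> np.ndarray:
    est = MaskedALS(
        k=config.k,
        lambda1=config.lambda1,
        lambda2=config.lambda2,
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=np.random.default_rng(rng_seed),
    ).fit(net)
    return est.predict()


def _assert_hidden(net: HeteroNetwork, pairs) -> None:
    # leakage guard: the fold being tested must be invisible to the fit
    for i, j in pairs:
        assert net.A[i, net.m + j] == 0.0 and net.W[i, net.m + j] == 0.0


def kfold_cv(
    data: NetworkData,
    config: MFConfig,
    alpha: float = 1.0,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
) -> CVReport:
    """Repeated k-fold cross-validation over the known associations.

    Within each repeat, every fold's hidden positives are ranked against the
    scores of all never-known pairs from the same fold's fit; the repeat's
    AUC is the mean over its folds.
    """
    if folds < 2:
        raise ContractError("folds must be >= 2")
    known = np.argwhere(data.associations.values == 1.0)
    if known.shape[0] < folds:
        raise ContractError(
            f"{known.shape[0]} known associations cannot fill {folds} folds"
        )
    unknown = np.argwhere(data.associations.values == 0.0)
    net0 = data.assemble(alpha)
    per_repeat = []
    for rep in range(repeats):
        rng = np.random.default_rng([seed, rep])
        order = rng.permutation(known.shape[0])
        fold_aucs = []
        for f, chunk in enumerate(np.array_split(order, folds)):
            test_pairs = [tuple(known[t]) for t in chunk]
            net = net0.mask_out(test_pairs)
            _assert_hidden(net, test_pairs)
            scores = _fit_scores(net, config, [seed, rep, f])
            pos = np.array([scores[i, j] for i, j in test_pairs])
            neg = scores[unknown[:, 0], unknown[:, 1]]
            fold_aucs.append(roc_auc(pos, neg))
        per_repeat.append(float(np.mean(fold_aucs)))
    mean = float(np.mean(per_repeat))
    sd = float(np.std(per_repeat, ddof=1)) if repeats > 1 else 0.0
    return CVReport("kfold", mean, per_repeat, mean, sd, config, alpha, seed)


def loocv(
    data: NetworkData,
    config: MFConfig,
    alpha: float = 1.0,
    scope: str = "global",
    seed: int = 0,
) -> CVReport:
    """Leave-one-out cross-validation, global or local (per-disease) scope.

    Each known association is hidden alone, the model refitted, and the
    hidden pair's score compared with its candidate set (all never-known
    pairs globally, or only its disease's never-known pairs locally).  The
    per-pair Mann-Whitney statistics are averaged, which keeps diseases with
    differently sized candidate pools on an equal footing.
    """
    if scope not in ("global", "local"):
        raise ContractError(f"unknown LOOCV scope {scope!r}")
    values = data.associations.values
    known = np.argwhere(values == 1.0)
    if known.shape[0] < 2:
        raise ContractError("LOOCV needs at least two known associations")
    unknown = np.argwhere(values == 0.0)
    net0 = data.assemble(alpha)
    per_pair = []
    skipped = 0
    for t, (i, j) in enumerate(known):
        if scope == "local":
            cand = unknown[unknown[:, 1] == j]
            if cand.shape[0] == 0:
                logger.warning(
                    "disease %s has no unknown pairs; skipping local LOOCV test pair",
                    data.associations.diseases[j],
                )
                skipped += 1
                continue
        else:
            cand = unknown
        net = net0.mask_out([(i, j)])
        _assert_hidden(net, [(i, j)])
        scores = _fit_scores(net, config, [seed, t])
        per_pair.append(roc_auc([scores[i, j]], scores[cand[:, 0], cand[:, 1]]))
    auc = float(np.mean(per_pair))
    sd = float(np.std(per_pair, ddof=1)) if len(per_pair) > 1 else 0.0
    return CVReport(f"loocv_{scope}", auc, per_pair, auc, sd, config, alpha, seed, skipped)


def grid_search(
    data: NetworkData,
    k_grid,
    lambda_grid,
    alpha_grid=(1.0,),
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    tie_lambdas: bool = True,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[pd.DataFrame, dict]:
    """k-fold CV at every (k, lambda1, lambda2, alpha) grid point.

    With ``tie_lambdas`` the two penalties share one grid (lambda1 = lambda2);
    otherwise the full product of ``lambda_grid`` with itself is searched.
    Supports the two-stage procedure of fixing alpha while searching
    k/lambda, then sweeping alpha at the best k/lambda.  Returns the full
    result table and the argmax row as a dict.
    """
    k_grid = list(k_grid)
    lambda_grid = list(lambda_grid)
    alpha_grid = list(alpha_grid)
    if not k_grid or not lambda_grid or not alpha_grid:
        raise ContractError("grids must be nonempty")
    lam_pairs = (
        [(l, l) for l in lambda_grid]
        if tie_lambdas
        else list(itertools.product(lambda_grid, lambda_grid))
    )
    rows = []
    for k, (l1, l2), alpha in itertools.product(k_grid, lam_pairs, alpha_grid):
        config = MFConfig(k=k, lambda1=l1, lambda2=l2, max_iter=max_iter, tol=tol, seed=seed)
        report = kfold_cv(data, config, alpha=alpha, folds=folds, repeats=repeats, seed=seed)
        rows.append(
            {"k": k, "lambda1": l1, "lambda2": l2, "alpha": alpha,
             "mean_auc": report.mean, "sd_auc": report.sd}
        )
        logger.info(
            "grid point k=%d l1=%g l2=%g alpha=%.2f -> AUC %.4f", k, l1, l2, alpha, report.mean
        )
    table = pd.DataFrame(rows)
    best = table.iloc[int(table["mean_auc"].idxmax())].to_dict()
    return table, best
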