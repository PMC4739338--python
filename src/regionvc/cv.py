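"""Genomic prediction for held-out individuals and cross-validated accuracy.

Genetic values of test individuals are predicted by kernel regression:
``ghat_test = K_test,train (K_train,train)^-1 ghat_train``, the
conditional expectation of the test genetic values given the training
ones under the multivariate-normal kernel model.  Predictive ability is
measured by fourfold cross-validation replicated several times, scoring
Pearson correlation and mean-squared error between held-out phenotypes
and predictions (intercept plus the sum of predicted kernel effects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .data import KernelMatrix
from .gibbs import ChainSpec, ModelSpec, fit_multikernel
from .kernels import subset_kernel


@dataclass
class FoldAssignment:
    """One replicate's random partition of samples into folds."""

    replicate: int
    folds: pd.Series  # index: sample_id -> fold in {1..n_folds}
    seed: int

    @property
    def n_folds(self) -> int:
        return int(self.folds.max())

    def test_ids(self, fold: int) -> list[str]:
        return list(self.folds.index[self.folds == fold])

    def train_ids(self, fold: int) -> list[str]:
        return list(self.folds.index[self.folds != fold])


@dataclass
class CVResult:
    """Per-replicate predictive metrics and their aggregate."""

    metrics: pd.DataFrame  # replicate, model, correlation, mse

    def aggregate(self) -> pd.DataFrame:
        grouped = self.metrics.groupby("model")
        out = grouped.agg(
            mean_correlation=("correlation", "mean"),
            sd_correlation=("correlation", "std"),
            mean_mse=("mse", "mean"),
            sd_mse=("mse", "std"),
            n_replicates=("replicate", "count"),
        )
        return out.reset_index()


class SingularKernelError(np.linalg.LinAlgError):
    """Training-block kernel could not be factorized even with jitter."""


def predict_genetic_values(
    ghat_train: np.ndarray,
    K: KernelMatrix,
    train_ids: list[str],
    test_ids: list[str],
) -> np.ndarray:
    """Conditional-expectation prediction K_ts K_tt^-1 ghat_train.

    The training block is solved through a jittered Cholesky
    factorization (epsilon = 1e-8 * mean diagonal added) with a
    pseudo-inverse fallback for rank-deficient blocks.
    """
    ghat_train = np.asarray(ghat_train, dtype=float)
    if len(ghat_train) != len(train_ids):
        raise ValueError("ghat_train must align with train_ids")
    K_tt = subset_kernel(K, train_ids, train_ids)
    K_ts = subset_kernel(K, test_ids, train_ids)
    jitter = 1e-8 * float(np.mean(np.diag(K_tt)))
    A = K_tt + jitter * np.eye(len(train_ids))
    try:
        cho = linalg.cho_factor(A, lower=True)
        alpha = linalg.cho_solve(cho, ghat_train)
    except np.linalg.LinAlgError:
        alpha, *_ = np.linalg.lstsq(K_tt, ghat_train, rcond=1e-10)
        if not np.isfinite(alpha).all():
            cond = np.linalg.cond(K_tt)
            raise SingularKernelError(
                f"training kernel block singular (condition number {cond:.3g})"
            )
    return K_ts @ alpha


def make_folds(
    sample_ids: list[str], n_folds: int = 4, seed: int = 0, replicate: int = 0
) -> FoldAssignment:
    """Uniform random partition into folds whose sizes differ by <= 1."""
    n = len(sample_ids)
    if n < n_folds:
        raise ValueError(f"cannot split {n} samples into {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    # cycle fold labels over the permuted samples: balanced apportionment
    labels[perm] = np.arange(n) % n_folds + 1
    return FoldAssignment(
        replicate=replicate,
        folds=pd.Series(labels, index=list(sample_ids)),
        seed=seed,
    )


def _score(y_test: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    mse = float(np.mean((y_test - pred) ** 2))
    if np.std(pred) == 0.0 or np.std(y_test) == 0.0:
        warnings.warn(
            "degenerate predictions or responses: correlation undefined",
            stacklevel=2,
        )
        return np.nan, mse
    r = float(np.corrcoef(y_test, pred)[0, 1])
    return r, mse


@dataclass
class CVConfig:
    """Cross-validation layout and per-fold chain settings."""

    n_folds: int = 4
    n_reps: int = 15
    base_seed: int = 0
    chain: ChainSpec = field(
        default_factory=lambda: ChainSpec(n_iter=3000, burn_in=500, thin=5)
    )
    prior_df: float = 5.0
    prior_R2: float = 0.5


def run_cv(
    y: np.ndarray,
    kernels: list[KernelMatrix],
    config: CVConfig | None = None,
    model_label: str | None = None,
) -> CVResult:
    """Replicated k-fold cross-validation of a multi-kernel model.

    Kernels are built once from the full sample and subset per fold (one
    total kernel, train/test blocks extracted).  For each replicate
    (seed = base_seed + replicate index) and each fold, the model is
    refit on the training block, test individuals are predicted as
    ``mu + sum_t ghat_t,test``, and the four folds' test predictions are
    concatenated before scoring, giving one correlation and one MSE per
    replicate.
    """
    config = config or CVConfig()
    y = np.asarray(y, dtype=float)
    sample_ids = kernels[0].sample_ids
    if len(y) != len(sample_ids):
        raise ValueError("phenotype length does not match kernels")
    label = model_label or "+".join(K.name for K in kernels)
    y_by_id = dict(zip(sample_ids, y))

    rows = []
    for rep in range(config.n_reps):
        rep_seed = config.base_seed + rep
        assign = make_folds(sample_ids, config.n_folds, seed=rep_seed, replicate=rep)
        pred_all: list[np.ndarray] = []
        obs_all: list[np.ndarray] = []
        for fold in range(1, config.n_folds + 1):
            train_ids = assign.train_ids(fold)
            test_ids = assign.test_ids(fold)
            train_idx = kernels[0].sample_index(train_ids)
            sub_kernels = [
                KernelMatrix(
                    sample_ids=train_ids,
                    values=K.values[np.ix_(train_idx, train_idx)],
                    kind=K.kind,
                    region=K.region,
                    n_snps_used=K.n_snps_used,
                )
                for K in kernels
            ]
            spec = ModelSpec(
                kernels=sub_kernels,
                prior_df=config.prior_df,
                prior_R2=config.prior_R2,
                chain=config.chain,
                seed=rep_seed * config.n_folds + fold,
            )
            y_train = np.array([y_by_id[s] for s in train_ids])
            samples = fit_multikernel(y_train, spec)
            pred = np.full(len(test_ids), float(samples.mu.mean()))
            for K, name in zip(kernels, samples.kernel_names):
                ghat_train = samples.g_mean[name]
                pred = pred + predict_genetic_values(ghat_train, K, train_ids, test_ids)
            pred_all.append(pred)
            obs_all.append(np.array([y_by_id[s] for s in test_ids]))
        r, mse = _score(np.concatenate(obs_all), np.concatenate(pred_all))
        rows.append({"replicate": rep, "model": label, "correlation": r, "mse": mse})
    return CVResult(pd.DataFrame(rows))
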