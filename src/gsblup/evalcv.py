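"""Genotype-level train/test splitting, k-fold cross-validation, and the
accuracy metrics (Pearson r, MSE) used to evaluate genomic prediction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import FittedLMM, FixedSpec, RandomTermSpec, fit_lmm, fitted_values
from .predictnew import predict_phenotypes

__all__ = [
    "FoldPlan",
    "CVResult",
    "split_train_test",
    "kfold",
    "accuracy_metrics",
    "cross_validate",
]


@dataclass
class FoldPlan:
    """Partition of distinct genotype ids into k folds of near-equal size."""

    k: int
    seed: int
    assignments: dict[str, int]  # gid -> fold index in 1..k

    def fold(self, f: int) -> set[str]:
        return {g for g, ff in self.assignments.items() if ff == f}


@dataclass
class CVResult:
    """Per-fold training/testing accuracy with avg/sd summary rows."""

    folds: pd.DataFrame  # columns: fold, train_r, train_mse, test_r, test_mse
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self):
        vals = self.folds[["train_r", "train_mse", "test_r", "test_mse"]]
        self.summary = pd.DataFrame(
            [vals.mean(), vals.std(ddof=1)], index=["avg", "sd"]
        )

    def to_frame(self) -> pd.DataFrame:
        """Table-1 layout: fold rows followed by avg and sd rows."""
        s = self.summary.reset_index().rename(columns={"index": "fold"})
        return pd.concat([self.folds, s], ignore_index=True)


def split_train_test(
    gids, test_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Random disjoint train/test split of genotype ids.

    |test| = round(test_fraction * |gids|); deterministic given the seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    gids = sorted({str(g) for g in gids})
    if len(gids) < 2:
        raise ValueError("need at least 2 genotype ids to split")
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * len(gids)))
    n_test = min(max(n_test, 1), len(gids) - 1)
    perm = rng.permutation(len(gids))
    test = sorted(gids[i] for i in perm[:n_test])
    train = sorted(set(gids) - set(test))
    return train, test


def kfold(gids, k: int, seed: int) -> FoldPlan:
    """Random partition of genotype ids into k folds differing by <= 1 in size."""
    gids = sorted({str(g) for g in gids})
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(gids):
        raise ValueError(f"k={k} exceeds the number of distinct genotype ids ({len(gids)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(gids))
    assignments = {gids[i]: (pos % k) + 1 for pos, i in enumerate(perm)}
    return FoldPlan(k=k, seed=seed, assignments=assignments)


def accuracy_metrics(observed, predicted) -> tuple[float, float]:
    """Sample Pearson correlation and mean squared error (divisor n).

    Returns (r, mse); r is NaN (with a warning) when the observed values have
    zero variance.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-d vectors")
    if len(obs) < 2:
        raise ValueError("need at least 2 pairs")
    mse = float(np.mean((obs - pred) ** 2))
    if obs.std() == 0 or pred.std() == 0:
        warnings.warn("zero variance: Pearson r undefined", stacklevel=2)
        return float("nan"), mse
    r = float(np.corrcoef(obs, pred)[0, 1])
    return r, mse


def cross_validate(
    data: pd.DataFrame,
    response: str,
    random: list[RandomTermSpec],
    plan: FoldPlan,
    fixed: FixedSpec | None = None,
    gid_column: str | None = None,
) -> CVResult:
    """Genotype-level k-fold cross-validation of the mixed model.

    For each fold, the model is fitted on the complement, the held-out
    genotypes are predicted through the conditional-mean machinery (each
    term's full covariance from its RandomTermSpec), and training metrics
    (in-sample fitted values vs observed) and testing metrics are recorded.
    A fold whose fit fails is reported missing; the summary covers the folds
    that completed.
    """
    if gid_column is None:
        gid_column = random[0].factor
    gids = data[gid_column].astype(str)
    rows = []
    full_covs = {t.name: t.covariance for t in random}
    for f in range(1, plan.k + 1):
        test_gids = plan.fold(f)
        is_test = gids.isin(test_gids)
        train_df = data.loc[~is_test]
        test_df = data.loc[is_test]
        try:
            model = fit_lmm(train_df, response=response, fixed=fixed, random=random)
        except Exception as exc:  # noqa: BLE001 - fold-level resilience
            warnings.warn(f"fold {f}: fit failed ({exc}); reported missing", stacklevel=2)
            rows.append(
                {"fold": f, "train_r": np.nan, "train_mse": np.nan,
                 "test_r": np.nan, "test_mse": np.nan}
            )
            continue
        obs_tr = pd.to_numeric(train_df[response], errors="coerce")
        keep_tr = obs_tr.notna()
        yhat_tr = fitted_values(model)
        tr_r, tr_mse = accuracy_metrics(obs_tr[keep_tr].to_numpy(), yhat_tr)
        obs_te = pd.to_numeric(test_df[response], errors="coerce")
        keep_te = obs_te.notna()
        yhat_te = predict_phenotypes(model, full_covs, test_df.loc[keep_te])
        te_r, te_mse = accuracy_metrics(obs_te[keep_te].to_numpy(), yhat_te.to_numpy())
        rows.append(
            {"fold": f, "train_r": tr_r, "train_mse": tr_mse,
             "test_r": te_r, "test_mse": te_mse}
        )
    return CVResult(folds=pd.DataFrame(rows))


def evaluate_split(
    data: pd.DataFrame,
    response: str,
    random: list[RandomTermSpec],
    train_gids,
    test_gids,
    fixed: FixedSpec | None = None,
    gid_column: str | None = None,
) -> tuple[FittedLMM, pd.DataFrame]:
    """Single train/test evaluation: fit on the training genotypes, predict the rest.

    Returns the fitted model and a frame (gid, y, yHat, set) over all records,
    mirroring the observed-vs-predicted display of a single partition.
    """
    if gid_column is None:
        gid_column = random[0].factor
    gids = data[gid_column].astype(str)
    train_set, test_set = set(map(str, train_gids)), set(map(str, test_gids))
    model = fit_lmm(
        data.loc[gids.isin(train_set)], response=response, fixed=fixed, random=random
    )
    full_covs = {t.name: t.covariance for t in random}
    obs = pd.to_numeric(data[response], errors="coerce")
    keep = obs.notna()
    pred = predict_phenotypes(model, full_covs, data.loc[keep])
    out = pd.DataFrame(
        {
            "gid": gids[keep].to_numpy(),
            "y": obs[keep].to_numpy(),
            "yHat": pred.to_numpy(),
            "set": np.where(gids[keep].isin(test_set), "test", "train"),
        }
    )
    return model, out
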