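"""BLUPs and phenotype predictions for genotypes absent from the fitted data.

For each random term, partition the full covariance over fitted (1) and new
(2) levels,

    K = [[K11, K12], [K21, K22]],

and predict the new effects by the multivariate-normal conditional mean

    u2^ = K21 K11^-1 u1^.

Levels that were fitted pass through with their fitted BLUPs.  Predicted
phenotypes add the fixed part: y2^ = x2' beta^ + sum_j u2j^.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .lmm import FittedLMM, _build_X
from .relmat import PSD_RTOL, RelationshipMatrix

__all__ = ["predict_new_levels", "predict_phenotypes"]

#: relative tolerance for agreement between the fitted covariance block and
#: the K11 block of the user-supplied full covariance
K11_RTOL = 1e-8


def _solve_psd(K11: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve K11 X = B with the package's PSD clipping policy (jitter retry)."""
    try:
        c, low = sla.cho_factor(K11, lower=True, check_finite=False)
        return sla.cho_solve((c, low), B, check_finite=False)
    except sla.LinAlgError:
        w = np.linalg.eigvalsh(K11)
        lam_max = max(w.max(), 0.0)
        if w.min() < -PSD_RTOL * max(lam_max, 1e-300):
            raise np.linalg.LinAlgError(
                f"K11 indefinite beyond tolerance (min eigenvalue {w.min():.3e})"
            )
        jitter = max(PSD_RTOL * max(lam_max, 1.0), 1e-12)
        c, low = sla.cho_factor(
            K11 + jitter * np.eye(K11.shape[0]), lower=True, check_finite=False
        )
        return sla.cho_solve((c, low), B, check_finite=False)


def predict_new_levels(
    model: FittedLMM, full_covariances: dict[str, RelationshipMatrix]
) -> dict[str, pd.Series]:
    """Per-term BLUPs for every level of the supplied full covariances.

    ``full_covariances`` maps term name -> RelationshipMatrix whose labels
    include all fitted levels of that term (the K11 block must match the
    covariance used at fit time) plus any new levels to predict.  Only terms
    present in the mapping are predicted.
    """
    out: dict[str, pd.Series] = {}
    for name, K_full in full_covariances.items():
        if name not in model.u:
            raise KeyError(f"term {name!r} was not in the fitted model")
        u1 = model.u[name]
        fitted_levels = list(u1.index)
        try:
            idx1 = K_full.index_of(fitted_levels)
        except KeyError as exc:
            raise KeyError(
                f"term {name!r}: fitted level(s) missing from full covariance: {exc}"
            ) from None
        K11 = K_full.values[np.ix_(idx1, idx1)]
        K_fit = model.K_fitted[name].values
        scale = max(np.abs(K_fit).max(), 1e-300)
        if np.abs(K11 - K_fit).max() > K11_RTOL * scale:
            raise ValueError(
                f"term {name!r}: K11 block of the supplied covariance does not "
                f"match the covariance used at fit time (max abs diff "
                f"{np.abs(K11 - K_fit).max():.3e})"
            )
        new_levels = [lab for lab in K_full.labels if lab not in set(fitted_levels)]
        vals = pd.Series(index=pd.Index(K_full.labels, name="level"), dtype=float)
        vals.loc[fitted_levels] = u1.to_numpy()
        if new_levels:
            idx2 = K_full.index_of(new_levels)
            K21 = K_full.values[np.ix_(idx2, idx1)]
            u2 = K21 @ _solve_psd(K11, u1.to_numpy())
            vals.loc[new_levels] = u2
        out[name] = vals
    return out


def predict_phenotypes(
    model: FittedLMM,
    full_covariances: dict[str, RelationshipMatrix],
    new_data: pd.DataFrame,
) -> pd.Series:
    """Predicted responses y^ = x' beta^ + sum_j u_j^ for the rows of ``new_data``.

    ``new_data`` carries the grouping-factor column of every fitted term and
    any non-intercept fixed covariates (training factor levels are reused for
    the dummy coding; an unseen fixed level is an error).  Random-effect
    values come from :func:`predict_new_levels`, so rows may mix fitted and
    new genotype levels.
    """
    u_all = predict_new_levels(
        model, {name: full_covariances[name] for name in model.term_names
                if name in full_covariances}
    )
    missing_terms = [t for t in model.term_names if t not in u_all]
    if missing_terms:
        raise KeyError(f"no full covariance supplied for term(s): {missing_terms}")
    X, _, _ = _build_X(new_data, model.fixed, categories=model.fixed_categories)
    beta = model.beta.to_numpy()
    yhat = X @ beta
    for name in model.term_names:
        factor_col = model.term_factors[name]
        if factor_col not in new_data.columns:
            raise ValueError(
                f"column {factor_col!r} (factor of term {name!r}) absent from new data"
            )
        labels = new_data[factor_col].astype(str)
        unknown = sorted(set(labels) - set(u_all[name].index))
        if unknown:
            raise KeyError(
                f"term {name!r}: level(s) {unknown[:10]} absent from the "
                f"supplied full covariance"
            )
        yhat = yhat + u_all[name].loc[labels].to_numpy()
    return pd.Series(yhat, index=new_data.index, name="predicted")
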