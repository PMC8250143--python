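"""Readers/writers for phenotype, pedigree, marker and covariance tables,
and JSON persistence of fit artifacts.

All files are plain delimited text; the delimiter is auto-detected among
comma, tab and semicolon (comma default).  Decimal points only.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .lmm import FittedLMM, FixedSpec
from .relmat import MarkerMatrix, Pedigree, RelationshipMatrix

__all__ = [
    "read_phenotypes",
    "write_table",
    "read_pedigree",
    "read_markers",
    "read_covariance",
    "write_covariance",
    "save_fit",
    "load_fit",
]

log = logging.getLogger("gsblup")

NA_VALUES = ["", "NA", "na", "NaN", "nan"]


def _detect_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    for sep in ("\t", ";", ","):
        if sep in first:
            return sep
    return ","


def read_phenotypes(path, response: str | None = None) -> pd.DataFrame:
    """Read a delimited phenotype table (header row required).

    Missing-value markers ("NA", empty) become NaN.  When ``response`` is
    given, the column must exist and at least one record must be fittable.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), na_values=NA_VALUES, keep_default_na=True)
    if response is not None:
        if response not in df.columns:
            raise ValueError(f"response column {response!r} not found in {path.name}")
        n_missing = int(pd.to_numeric(df[response], errors="coerce").isna().sum())
        if n_missing == len(df):
            raise ValueError(f"no fittable records: all {response!r} values missing")
        log.info("read %d records (%d missing response) from %s", len(df), n_missing, path)
    return df


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_pedigree(path) -> Pedigree:
    """Three-column pedigree file: parent1, parent2, progeny (header row).

    "0", "NA" or empty denote an unknown parent.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    if df.shape[1] != 3:
        raise ValueError(f"pedigree file must have 3 columns, got {df.shape[1]}")
    p1, p2, prog = df.columns
    records = [(r[prog], r[p1], r[p2]) for _, r in df.iterrows()]
    return Pedigree(records)


def read_markers(path) -> MarkerMatrix:
    """Marker file: first column genotype id, remaining numeric marker codes."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), na_values=NA_VALUES)
    ids = df.iloc[:, 0].astype(str).tolist()
    vals = df.iloc[:, 1:]
    try:
        arr = vals.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric marker cells in {path.name}: {exc}") from None
    return MarkerMatrix(arr, ids, [str(c) for c in vals.columns])


def read_covariance(path, kind: str = "user") -> RelationshipMatrix:
    """Square labelled covariance file; row labels must equal column labels."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise ValueError(
            f"covariance file {path.name}: row labels differ from column labels"
        )
    return RelationshipMatrix(df.to_numpy(dtype=float), rows, kind=kind)


def write_covariance(K: RelationshipMatrix, path, sep: str = ",") -> None:
    """Round-trips values to 12 significant digits."""
    K.to_dataframe().to_csv(path, sep=sep, float_format="%.12g")


ARTIFACT_FORMAT_MAJOR = 1


def save_fit(model: FittedLMM, path) -> None:
    """Persist a fit as JSON: estimates, BLUPs, per-term fitted covariances,
    and the model specification needed to predict new levels later."""
    doc = {
        "format_major": ARTIFACT_FORMAT_MAJOR,
        "software_version": __version__,
        "response": model.response,
        "beta": {k: float(v) for k, v in model.beta.items()},
        "sigma2": model.sigma2,
        "lambdas": model.lambdas,
        "reml_loglik": model.reml_loglik,
        "converged": model.converged,
        "n_dropped": model.n_dropped,
        "fixed": {"intercept": model.fixed.intercept, "terms": list(model.fixed.terms)},
        "fixed_categories": model.fixed_categories,
        "terms": [
            {
                "name": name,
                "factor": model.term_factors[name],
                "u": model.u[name].to_dict(),
                "u_star": model.u_star[name].to_dict(),
                "K_levels": model.K_fitted[name].labels,
                "K_values": model.K_fitted[name].values.tolist(),
                "K_kind": model.K_fitted[name].kind,
            }
            for name in model.term_names
        ],
        "trace": model.trace,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_fit(path) -> FittedLMM:
    """Load a saved fit.  Prediction of new levels works on the loaded
    artifact; in-sample fitted values do not (design matrices are not stored)."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise ValueError(f"corrupt or unreadable fit artifact {path}: {exc}") from None
    if not isinstance(doc, dict) or "format_major" not in doc:
        raise ValueError(f"{path} is not a gsblup fit artifact")
    if doc["format_major"] != ARTIFACT_FORMAT_MAJOR:
        raise ValueError(
            f"fit artifact major version {doc['format_major']} is incompatible "
            f"with this software (expects {ARTIFACT_FORMAT_MAJOR})"
        )
    u, u_star, K_fitted, term_factors = {}, {}, {}, {}
    for t in doc["terms"]:
        name = t["name"]
        levels = [str(x) for x in t["K_levels"]]
        u[name] = pd.Series(
            [t["u"][lev] for lev in levels], index=pd.Index(levels, name="level")
        )
        u_star[name] = pd.Series(
            [t["u_star"][lev] for lev in levels], index=pd.Index(levels, name="level")
        )
        K_fitted[name] = RelationshipMatrix(
            np.array(t["K_values"], dtype=float), levels, kind=t.get("K_kind", "user")
        )
        term_factors[name] = t["factor"]
    fixed = FixedSpec(
        intercept=doc["fixed"]["intercept"],
        terms=[tuple(x) for x in doc["fixed"]["terms"]],
    )
    return FittedLMM(
        beta=pd.Series(doc["beta"]),
        sigma2={k: float(v) for k, v in doc["sigma2"].items()},
        reml_loglik=float(doc["reml_loglik"]),
        u_star=u_star,
        u=u,
        converged=bool(doc["converged"]),
        trace=doc.get("trace", []),
        design=None,
        fixed=fixed,
        random=None,
        response=doc["response"],
        n_dropped=int(doc.get("n_dropped", 0)),
        lambdas={k: float(v) for k, v in doc.get("lambdas", {}).items()},
        K_fitted=K_fitted,
        term_factors=term_factors,
        fixed_categories={k: list(v) for k, v in doc.get("fixed_categories", {}).items()},
    )
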