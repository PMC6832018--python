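"""Multivariate linear associations between microbes and clinical variables.

For each (feature, phenotype) pair, the arcsine-square-root transformed
relative abundance is regressed by ordinary least squares on the phenotype
plus confounder covariates (age, gender and BMI by default), and the
phenotype coefficient is tested with a two-sided t-test. p-values are BH
adjusted globally across all tested pairs in the run (a per-variable
family is available). Features are pre-filtered to a mean relative
abundance above 0.01% and presence in at least 10 samples.

Categorical covariates and phenotypes are dummy-coded (first level as
reference); ordinal phenotypes enter numerically. Pairs whose design is
collinear (constant phenotype, or phenotype aliased with the covariates)
are skipped with a reason rather than fitted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .diffabund import bh_adjust

DEFAULT_COVARIATES = ("age", "gender", "bmi")


def filter_features(
    matrix: pd.DataFrame,
    min_abundance: float = 1e-4,
    min_prevalence: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Keep features with mean abundance > min_abundance that are nonzero
    in >= min_prevalence samples; returns (filtered matrix, report)."""
    mean_ok = matrix.mean(axis=1) > min_abundance
    prev_ok = (matrix != 0).sum(axis=1) >= min_prevalence
    keep = mean_ok & prev_ok
    report = {"retained": int(keep.sum()), "removed": int((~keep).sum())}
    if not keep.any():
        warnings.warn("no features pass the abundance/prevalence filters", stacklevel=2)
    return matrix.loc[keep], report


def arcsine_sqrt(values):
    """Variance-stabilising transform y = arcsin(sqrt(p)) for proportions."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    return out


def _encode(column: pd.Series) -> pd.DataFrame:
    """Numeric passthrough or dummy coding (first level dropped)."""
    if column.dtype == object or str(column.dtype) == "category":
        dummies = pd.get_dummies(column, prefix=column.name, drop_first=True)
        return dummies.astype(float)
    return column.astype(float).to_frame()


def fit_associations(
    transformed: pd.DataFrame,
    metadata: pd.DataFrame,
    variables,
    covariates=DEFAULT_COVARIATES,
    q_max: float = 0.1,
    bh_family: str = "global",
) -> tuple[pd.DataFrame, list]:
    """OLS association of each transformed feature with each phenotype.

    ``transformed`` is the feature x sample matrix already on the
    arcsine-sqrt scale. Returns (records frame, skipped list); records
    carry coefficient, standard error, p, q and a significance flag at
    q < q_max. Samples with a missing tested variable are dropped for
    that variable's fits.
    """
    meta = metadata.loc[transformed.columns]
    skipped: list[tuple] = []
    rows = []
    cov_frames = [_encode(meta[c]) for c in covariates]
    cov = pd.concat(cov_frames, axis=1) if cov_frames else pd.DataFrame(index=meta.index)
    for variable in variables:
        v = meta[variable]
        ok = v.notna()
        v_enc = _encode(v[ok])
        if v_enc.shape[1] == 0 or (v_enc.nunique() <= 1).all():
            skipped.append((variable, "constant variable"))
            continue
        design = pd.concat([v_enc, cov.loc[ok.index[ok]]], axis=1)
        design.insert(0, "const", 1.0)
        X = design.to_numpy(dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            skipped.append((variable, "collinear design"))
            continue
        var_cols = list(range(1, 1 + v_enc.shape[1]))
        for feature in transformed.index:
            y = transformed.loc[feature, ok.index[ok]].to_numpy(dtype=float)
            fit = sm.OLS(y, X).fit()
            # report the (first) phenotype column's coefficient
            j = var_cols[0]
            p = float(fit.pvalues[j])
            if not np.isfinite(p):  # exact fit: zero residual variance
                p = 0.0
            rows.append(
                (feature, variable, float(fit.params[j]), float(fit.bse[j]), p, len(y))
            )
    records = pd.DataFrame(
        rows, columns=["feature_id", "variable", "coef", "se", "p", "n"]
    )
    if len(records):
        if bh_family == "global":
            records["q"] = bh_adjust(records["p"].to_numpy())
        elif bh_family == "per_variable":
            records["q"] = np.nan
            for variable in records["variable"].unique():
                mask = records["variable"] == variable
                records.loc[mask, "q"] = bh_adjust(records.loc[mask, "p"].to_numpy())
        else:
            raise ValueError(f"unknown bh_family {bh_family!r}")
        records["significant"] = records["q"] < q_max
    return records, skipped


def associate(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    variables,
    covariates=DEFAULT_COVARIATES,
    q_max: float = 0.1,
    min_abundance: float = 1e-4,
    min_prevalence: int = 10,
):
    """Filter -> transform -> fit, the full association stage."""
    filtered, report = filter_features(matrix, min_abundance, min_prevalence)
    transformed = arcsine_sqrt(filtered)
    records, skipped = fit_associations(
        transformed, metadata, variables, covariates=covariates, q_max=q_max
    )
    return records, {"filter": report, "skipped": skipped}
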