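"""Genotype x attribute trait matrices and descriptive statistics.

The per-leaf trait table is widened into one row per genotype and one
column per (phenotype, position, daylength, year) combination — the
"attributes" mapped downstream.  A full factorial of 16 phenotypes x 3
positions x 2 daylengths x 2 years yields 192 attributes.  The module
also hosts the descriptive statistics run on those matrices:
z-transformation, Kruskal-Wallis group tests, Pearson correlation,
PCA, and a factorial variance partition of PC scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .exceptions import (
    AliasingError,
    DuplicateRecordError,
    TooSparseError,
    ZeroVarianceError,
)
from .morphometrics import TRAIT_NAMES

__all__ = [
    "attribute_key",
    "parse_attribute_key",
    "assemble_matrix",
    "z_transform",
    "kruskal_wallis",
    "pearson_correlation",
    "pca",
    "variance_partition",
    "VariancePartition",
]


def attribute_key(phenotype: str, position: str, daylength_h: int, year: int) -> str:
    """Column name for one attribute: ``<phenotype>__<position>__<dl>h__<year>``."""
    return f"{phenotype}__{position}__{int(daylength_h)}h__{int(year)}"


def parse_attribute_key(key: str) -> tuple[str, str, int, int]:
    phenotype, position, dl, year = key.rsplit("__", 3)
    return phenotype, position, int(dl.rstrip("h")), int(year)


def assemble_matrix(
    traits: pd.DataFrame,
    presentation: str | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Widen a per-leaf trait table into a genotype x attribute matrix.

    ``traits`` is the output of :func:`ampelqtl.morphometrics.traits_table`
    (metadata columns + 16 trait columns).  Rows are genotypes, columns
    are attribute keys; replicate leaves sharing a design cell are
    averaged (rejected when ``strict``).  Missing cells stay NaN; the
    per-cell leaf counts are attached as ``result.attrs["counts"]``.
    """
    df = traits.copy()
    if presentation is not None:
        df = df[df["presentation"] == presentation]
    trait_cols = [c for c in TRAIT_NAMES if c in df.columns]
    if not trait_cols:
        raise ValueError("no phenotype columns found in trait table")

    long = df.melt(
        id_vars=["genotype_id", "position", "daylength_h", "year"],
        value_vars=trait_cols,
        var_name="phenotype",
        value_name="value",
    )
    long["attribute"] = [
        attribute_key(p, pos, dl, yr)
        for p, pos, dl, yr in zip(
            long["phenotype"], long["position"], long["daylength_h"], long["year"]
        )
    ]
    counts = long.pivot_table(
        index="genotype_id", columns="attribute", values="value", aggfunc="count"
    )
    if strict and (counts.to_numpy() > 1).any():
        where = np.argwhere(counts.to_numpy() > 1)[0]
        raise DuplicateRecordError(
            f"replicate leaves for genotype {counts.index[where[0]]!r}, "
            f"attribute {counts.columns[where[1]]!r} (strict mode)"
        )
    wide = long.pivot_table(
        index="genotype_id", columns="attribute", values="value", aggfunc="mean"
    )
    # column order: phenotype-major, then position, daylength, year
    ordered = sorted(
        wide.columns,
        key=lambda k: (
            trait_cols.index(parse_attribute_key(k)[0]),
            parse_attribute_key(k)[1],
            parse_attribute_key(k)[2],
            parse_attribute_key(k)[3],
        ),
    )
    wide = wide[ordered]
    wide.attrs["counts"] = counts.reindex(columns=ordered)
    return wide


def z_transform(matrix: pd.DataFrame, group_fields: tuple[str, ...] = ("phenotype", "position")) -> pd.DataFrame:
    """Z-transform attribute cells within (phenotype, position) groups.

    All cells whose columns share the grouping fields are pooled;
    within each pool the values get mean 0 and sample SD 1 (ddof=1).
    Missing cells stay missing.  Scale differences between leaf
    positions are thereby removed before pooled comparisons.
    """
    field_index = {"phenotype": 0, "position": 1, "daylength_h": 2, "year": 3}
    idx = [field_index[f] for f in group_fields]
    out = matrix.copy()
    groups: dict[tuple, list[str]] = {}
    for col in matrix.columns:
        parts = parse_attribute_key(col)
        groups.setdefault(tuple(parts[i] for i in idx), []).append(col)
    for key, cols in groups.items():
        values = matrix[cols].to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if len(finite) < 2:
            raise ZeroVarianceError(f"group {key} has <2 non-missing values")
        sd = finite.std(ddof=1)
        if sd == 0:
            raise ZeroVarianceError(f"group {key} has zero variance")
        out[cols] = (values - finite.mean()) / sd
    return out


def kruskal_wallis(values, groups) -> dict[str, float]:
    """Kruskal-Wallis rank test: H (tie-corrected), df, and chi-square p."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("kruskal_wallis needs >=2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("kruskal_wallis needs non-empty groups")
    df = len(labels) - 1
    if np.all(values == values[0]):
        return {"H": 0.0, "df": df, "p": 1.0}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        H, p = stats.kruskal(*samples)
    return {"H": float(H), "df": df, "p": float(p)}


def pearson_correlation(matrix: pd.DataFrame, min_periods: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between attributes.

    Constant columns yield NaN entries (reported with a warning rather
    than raising).
    """
    sds = matrix.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        warnings.warn(f"constant attributes give undefined correlations: {constant[:5]}")
    return matrix.corr(method="pearson", min_periods=min_periods)


def pca(
    matrix: pd.DataFrame,
    scale: bool = True,
    max_missing_fraction: float = 0.2,
) -> dict:
    """PCA of the attribute matrix via SVD of the (optionally scaled) data.

    Missing cells are mean-imputed (flagged in the result); more than
    ``max_missing_fraction`` missing raises.  Returns scores, loadings
    (columns = components) and variance fractions that sum to 1.
    """
    X = matrix.to_numpy(dtype=float)
    n_missing = int(np.isnan(X).sum())
    if n_missing > max_missing_fraction * X.size:
        raise TooSparseError(
            f"{n_missing}/{X.size} missing cells exceed fraction {max_missing_fraction}"
        )
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs >=2 rows and >=2 columns")
    col_means = np.nanmean(X, axis=0)
    imputed = n_missing > 0
    if imputed:
        X = np.where(np.isnan(X), col_means, X)
        col_means = X.mean(axis=0)
    Xc = X - col_means
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    fractions = var / var.sum()
    scores = pd.DataFrame(
        U * S,
        index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(len(S))],
    )
    loadings = pd.DataFrame(
        Vt.T, index=matrix.columns, columns=scores.columns
    )
    return {
        "scores": scores,
        "loadings": loadings,
        "variance_fractions": pd.Series(fractions, index=scores.columns),
        "imputed": imputed,
    }


@dataclass(frozen=True)
class VariancePartition:
    """Sequential sum-of-squares fractions per design term for one PC."""

    fractions: pd.Series  # per term, fraction of total SS
    residual: float

    def __post_init__(self) -> None:
        total = float(self.fractions.sum()) + self.residual
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"fractions + residual must sum to 1, got {total}")


#: fixed sequential order of design terms for the variance partition
PARTITION_TERMS = (
    "year",
    "daylength",
    "position",
    "genotype",
    "genotype:year",
    "genotype:position",
)


def variance_partition(scores, factors: pd.DataFrame) -> VariancePartition:
    """Partition PC-score variance across the factorial design terms.

    Sequential (type-I) sums of squares from an OLS fit with all
    factors categorical, in the fixed order year, daylength, position,
    genotype, genotype x year, genotype x position.  Rows with missing
    scores or factors are dropped.  Fractions are term SS / total SS;
    the residual fraction makes the total 1.
    """
    data = factors.copy()
    data["score"] = np.asarray(scores, dtype=float)
    data = data.dropna()
    for col in ("year", "daylength", "position", "genotype"):
        if col not in data.columns:
            raise ValueError(f"factors table needs a {col!r} column")
        if data[col].nunique() < 2:
            raise AliasingError(f"factor {col!r} has <2 levels after dropping missing rows")
    formula = (
        "score ~ C(year) + C(daylength) + C(position) + C(genotype) "
        "+ C(genotype):C(year) + C(genotype):C(position)"
    )
    model = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise AliasingError("singular factorial design (aliased terms)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anova = sm.stats.anova_lm(model, typ=1)
    ss = anova["sum_sq"]
    total = float(ss.sum())
    name_map = {
        "C(year)": "year",
        "C(daylength)": "daylength",
        "C(position)": "position",
        "C(genotype)": "genotype",
        "C(genotype):C(year)": "genotype:year",
        "C(genotype):C(position)": "genotype:position",
    }
    fractions = pd.Series(
        {name_map[k]: float(ss[k]) / total for k in name_map if k in ss.index}
    ).reindex(list(PARTITION_TERMS)).fillna(0.0)
    residual = float(ss.get("Residual", 0.0)) / total
    return VariancePartition(fractions=fractions, residual=residual)
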