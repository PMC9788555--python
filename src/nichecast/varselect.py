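"""Predictor screening: a-priori exclusions, Pearson correlation, PCA,
and stepwise VIF pruning.

The screening cascade mirrors common ecological-niche-modeling
practice: drop predictors known to carry spatial artifacts, inspect
pairwise Pearson correlations (|r| >= 0.8 flags a redundant set) and a
standardized PCA for structure, then prune automatically by iterated
variance-inflation factors until every survivor has VIF below the
threshold (default 10).

The correlation/PCA outputs are advisory — which member of a correlated
set is "biologically important" cannot be automated — while the VIF
pruning is the reproducible, deterministic step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .geo_io import EnvStack, OccurrenceSet, cell_indices

__all__ = [
    "DEFAULT_EXCLUDED",
    "SelectionReport",
    "extract_values",
    "pearson_matrix",
    "high_correlation_pairs",
    "pca",
    "vif",
    "vif_prune",
    "select_variables",
]

#: Bioclimatic layers excluded up front for known spatial artifacts
#: (odd discontinuities in the quarter-based temperature/precipitation
#: combinations).
DEFAULT_EXCLUDED = ("bio08", "bio09", "bio18", "bio19")


@dataclass
class SelectionReport:
    """Everything the screening cascade produced, for reporting."""

    excluded_a_priori: list[str]
    pearson: pd.DataFrame
    high_pairs: list[tuple[str, str, float]]
    pca_variance: pd.Series
    pca_loadings: pd.DataFrame
    vif_trace: list[tuple[str, float]]
    selected: list[str]


def extract_values(stack: EnvStack, occ: OccurrenceSet) -> pd.DataFrame:
    """Predictor values at occurrence locations, one row per record."""
    rows, cols, inside = cell_indices(stack.geometry, occ.lon, occ.lat)
    bad = ~inside.copy()
    ok = inside
    on_nodata = np.zeros(len(occ), dtype=bool)
    on_nodata[ok] = ~stack.valid_mask[rows[ok], cols[ok]]
    bad = bad | on_nodata
    if bad.any():
        pts = [
            (float(lo), float(la))
            for lo, la in zip(occ.lon[bad][:10], occ.lat[bad][:10])
        ]
        raise ValueError(
            f"{int(bad.sum())} occurrence(s) fall outside the grid or on "
            f"nodata cells, e.g. {pts}"
        )
    return stack.values_at(rows, cols)


def _check_table(table: pd.DataFrame, min_rows: int = 3) -> None:
    if len(table) < min_rows:
        raise ValueError(f"need at least {min_rows} rows, got {len(table)}")
    stds = table.std(ddof=0)
    constant = stds.index[stds == 0.0].tolist()
    if constant:
        raise ValueError(f"constant column(s): {constant}")


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Product-moment correlation matrix of the value table."""
    _check_table(table)
    return table.corr(method="pearson")


def high_correlation_pairs(
    pearson: pd.DataFrame, threshold: float = 0.8
) -> list[tuple[str, str, float]]:
    """All variable pairs with |r| >= threshold, strongest first."""
    pairs = []
    cols = list(pearson.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = float(pearson.loc[a, b])
            if abs(r) >= threshold:
                pairs.append((a, b, r))
    return sorted(pairs, key=lambda t: -abs(t[2]))


def pca(table: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """PCA on z-scored columns.

    Returns the per-component explained-variance fractions (summing to
    one, non-increasing) and the loading matrix (columns = components).
    Loading signs are fixed so each component's largest-magnitude
    loading is positive.
    """
    _check_table(table)
    if table.shape[1] < 2:
        raise ValueError("PCA needs at least 2 columns")
    z = (table - table.mean()) / table.std(ddof=1)
    model = PCA()
    model.fit(z.to_numpy())
    fractions = model.explained_variance_ratio_
    loadings = model.components_.T.copy()  # rows = variables
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
    comp_names = [f"PC{k + 1}" for k in range(loadings.shape[1])]
    return (
        pd.Series(fractions, index=comp_names, name="variance_fraction"),
        pd.DataFrame(loadings, index=table.columns, columns=comp_names),
    )


def vif(table: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column, intercept included.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing column j on the others;
    perfect collinearity yields ``inf``.
    """
    X = table.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    out = {}
    for j, name in enumerate(table.columns):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        sst = float(y @ y)
        if others.shape[1] == 0:
            out[name] = 1.0
            continue
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ssr = float(resid @ resid)
        r2 = 1.0 - ssr / sst if sst > 0 else 0.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def vif_prune(
    table: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], list[tuple[str, float]]]:
    """Iteratively drop the largest-VIF column while any VIF >= threshold.

    Ties on the maximum VIF (including several infinities under perfect
    collinearity) drop the *later* column in input order, keeping
    earlier — conventionally more interpretable — variables.  Survivors
    are returned in original column order, all with VIF < threshold.
    """
    if len(table) < table.shape[1] + 2:
        raise ValueError("need at least V + 2 rows for VIF pruning")
    current = list(table.columns)
    trace: list[tuple[str, float]] = []
    while len(current) > 1:
        v = vif(table[current])
        vmax = v.max()
        if not (vmax >= threshold):
            break
        tied = [name for name in current if v[name] == vmax]
        drop = tied[-1]  # later in input order
        trace.append((drop, float(vmax)))
        current.remove(drop)
    return current, trace


def select_variables(
    stack: EnvStack,
    occ: OccurrenceSet | None = None,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDED,
    vif_threshold: float = 10.0,
    correlation_flag: float = 0.8,
    mode: str = "occurrence",
) -> SelectionReport:
    """Run the full screening cascade and return a report.

    ``mode="occurrence"`` (default) computes the statistics on
    predictor values at occurrence locations; ``mode="background"``
    uses every valid landscape cell instead.
    """
    names = [n for n in stack.names if n not in exclude]
    sub = stack.subset(names)
    if mode == "occurrence":
        if occ is None:
            raise ValueError("occurrence mode requires an OccurrenceSet")
        table = extract_values(sub, occ)
    elif mode == "background":
        table = sub.table()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pearson = pearson_matrix(table)
    fractions, loadings = pca(table)
    selected, trace = vif_prune(table, threshold=vif_threshold)
    return SelectionReport(
        excluded_a_priori=[n for n in stack.names if n in exclude],
        pearson=pearson,
        high_pairs=high_correlation_pairs(pearson, correlation_flag),
        pca_variance=fractions,
        pca_loadings=loadings,
        vif_trace=trace,
        selected=selected,
    )
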