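"""Proxy-table assembly and PCA over microwear/DMTA variable tables.

PCA follows the conventions of R's ``prcomp`` with ``center = TRUE`` and
``scale = TRUE``: columns are centered, divided by their sample standard
deviation, and decomposed by SVD; component standard deviations are the
singular values over sqrt(n - 1) and proportions of variance their squares
over the total.  Loadings carry a fixed sign convention (the
largest-magnitude loading of each component is positive) so results are
reproducible across row orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Table-1-style variable order for the per-taxon comparison table.
PROXY_VARIABLES = [
    "tooth_count_per_jaw",
    "complete_crown_volume_mm3",
    "quadrant_abraded_volume_mm3",
    "percent_worn_crown",
    "max_formation_time_days",
    "mean_veib_width_um",
    "min_replacement_rate_days",
    "facet_coverage_percent",
    "pit_percent",
    "mean_asfc",
    "mean_eplsar",
    "opcr",
]


@dataclass
class PCAResult:
    sdev: np.ndarray
    proportion_of_variance: np.ndarray
    cumulative_proportion: np.ndarray
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # observations x components
    groups: pd.Series | None = None


def pca(
    table: pd.DataFrame,
    center: bool = True,
    scale: bool = True,
    group_col: str | None = None,
) -> PCAResult:
    """Principal component analysis of a numeric variable table.

    ``group_col``, if given, is removed from the variables and kept as a
    grouping label on the scores.  With ``scale`` every column must have
    nonzero variance; a constant column is reported by name.
    """
    groups = None
    if group_col is not None:
        groups = table[group_col].copy()
        table = table.drop(columns=[group_col])
    X = table.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("proxy table has missing cells; fill or drop before PCA")
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.where(sd == 0)[0]
        if len(zero):
            names = ", ".join(table.columns[zero])
            raise ValueError(f"zero-variance column(s) with scale=True: {names}")
        X = X / sd

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n - 1, p)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0

    sdev = S / np.sqrt(n - 1)
    var = sdev**2
    prop = var / var.sum()
    comp_names = [f"PC{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(Vt.T, index=table.columns, columns=comp_names)
    scores = pd.DataFrame(U * S, index=table.index, columns=comp_names)
    return PCAResult(
        sdev=sdev,
        proportion_of_variance=prop,
        cumulative_proportion=np.cumsum(prop),
        loadings=loadings,
        scores=scores,
        groups=groups,
    )


def pca_summary(result: PCAResult) -> pd.DataFrame:
    """`summary(prcomp)`-style table: sdev, proportion, cumulative."""
    return pd.DataFrame(
        {
            "sdev": result.sdev,
            "proportion_of_variance": result.proportion_of_variance,
            "cumulative_proportion": result.cumulative_proportion,
        },
        index=[f"PC{j + 1}" for j in range(len(result.sdev))],
    )


def group_ellipses(result: PCAResult, level: float = 0.68, n_points: int = 100) -> pd.DataFrame:
    """Normal-theory confidence ellipses of the first two score columns per
    group, returned as polyline rows (group, x, y)."""
    from scipy.stats import chi2

    if result.groups is None:
        raise ValueError("PCA was run without a grouping column")
    r = np.sqrt(chi2.ppf(level, df=2))
    t = np.linspace(0, 2 * np.pi, n_points)
    circle = np.column_stack([np.cos(t), np.sin(t)])
    rows = []
    xy = result.scores.iloc[:, :2].to_numpy()
    for g in pd.unique(result.groups):
        sel = (result.groups == g).to_numpy()
        if sel.sum() < 3:
            continue
        sub = xy[sel]
        mu = sub.mean(axis=0)
        cov = np.cov(sub, rowvar=False)
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
        pts = mu + r * circle @ L.T
        for x, y in pts:
            rows.append({"group": g, "x": x, "y": y})
    return pd.DataFrame(rows)


def assemble_proxy_table(per_taxon: dict[str, dict[str, float]]) -> pd.DataFrame:
    """One-row-per-taxon comparison table over the standard variable list.

    ``per_taxon`` maps taxon name to a dict of variable values.  Variables
    outside :data:`PROXY_VARIABLES` are appended after the standard block;
    missing cells are NaN (flagged, never dropped).
    """
    taxa = list(per_taxon)
    extra = []
    for vals in per_taxon.values():
        for k in vals:
            if k not in PROXY_VARIABLES and k not in extra:
                extra.append(k)
    cols = PROXY_VARIABLES + extra
    df = pd.DataFrame(index=pd.Index(taxa, name="taxon"), columns=cols, dtype=float)
    for taxon, vals in per_taxon.items():
        for k, v in vals.items():
            df.loc[taxon, k] = v
    return df
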