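"""Ordination of multilocus genotypes.

Genotypes are coded as an individuals x alleles indicator matrix (allele copy
counts per marker, mitochondrial haplotypes diploid-encoded), the standard
coding for factorial correspondence analysis of genotype data.  Two
ordinations are provided:

* correspondence analysis (CA) — eigendecomposition of the standardized
  residuals of the relative-frequency table under row/column independence;
  total inertia equals the Pearson chi-square statistic divided by the grand
  total;
* PCA — SVD of the column-centered matrix with a deterministic sign
  convention.

CA drops individuals with any missing marker; PCA imputes missing markers by
per-column means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import Dataset, DatasetError, encode_mito_as_diploid

__all__ = [
    "IndicatorMatrix",
    "OrdinationResult",
    "build_indicator_matrix",
    "correspondence_analysis",
    "pca",
    "inertia_ellipse",
]

_EPS = 1e-12


@dataclass
class IndicatorMatrix:
    """Individuals x allele-columns table plus a missing-marker mask."""

    values: pd.DataFrame  # index: individual ids; columns: "marker:allele"
    missing: pd.DataFrame  # boolean, index ids x marker names
    mode: str = "counts"


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # individuals x axes
    eigenvalues: np.ndarray
    proportion: np.ndarray  # inertia / variance share per retained axis
    loadings: pd.DataFrame | None = None


def build_indicator_matrix(
    dataset: Dataset, markers: Sequence[str], mode: str = "counts"
) -> IndicatorMatrix:
    """Code genotypes as allele copy counts (0/1/2) or frequencies (0/0.5/1).

    Columns are labelled ``marker:allele``; a scored nuclear genotype
    contributes 2 copies per marker (1.0 in frequency mode), a mitochondrial
    haplotype is diploid-encoded.  Markers missing in an individual leave
    zero entries and are flagged in the mask.
    """
    if mode not in ("counts", "frequencies"):
        raise DatasetError(f"mode must be 'counts' or 'frequencies', got {mode}")
    columns: list[str] = []
    for m in markers:
        columns.extend(f"{m}:{a}" for a in dataset.markers[m].alleles)
    ids = [ind.id for ind in dataset.individuals]
    values = pd.DataFrame(0.0, index=ids, columns=columns)
    missing = pd.DataFrame(False, index=ids, columns=list(markers))
    any_scored = False
    for ind in dataset.individuals:
        for m in markers:
            gt = ind.genotype(m)
            if gt is None:
                missing.loc[ind.id, m] = True
                continue
            any_scored = True
            if dataset.markers[m].inheritance == "mito":
                gt = encode_mito_as_diploid(gt)
            alleles = gt.alleles if len(gt.alleles) == 2 else gt.alleles * 2
            for a in alleles:
                values.loc[ind.id, f"{m}:{a}"] += 1.0
    if not any_scored:
        raise DatasetError("no scored markers in indicator matrix")
    if mode == "frequencies":
        values /= 2.0
    return IndicatorMatrix(values=values, missing=missing, mode=mode)


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, IndicatorMatrix):
        return matrix.values
    if isinstance(matrix, pd.DataFrame):
        return matrix
    return pd.DataFrame(np.asarray(matrix, dtype=float))


def correspondence_analysis(matrix, n_axes: int = 2, drop_missing: bool = True) -> OrdinationResult:
    """Correspondence analysis; row principal coordinates.

    Total inertia (sum of all eigenvalues) equals chi-square / grand total of
    the input table.  Requires a non-negative table with positive row sums;
    all-zero columns are dropped.  If the table has rank < ``n_axes`` fewer
    axes are returned, with a warning.
    """
    df = _as_frame(matrix)
    if drop_missing and isinstance(matrix, IndicatorMatrix):
        keep = ~matrix.missing.any(axis=1)
        df = df.loc[keep]
    X = df.to_numpy(dtype=float)
    if (X < 0).any():
        raise DatasetError("correspondence analysis requires a non-negative table")
    X = X[:, X.sum(axis=0) > 0]
    total = X.sum()
    if total <= 0 or (X.sum(axis=1) <= 0).any():
        raise DatasetError("correspondence analysis requires positive row margins")
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    rank = int((s > 1e-10).sum())
    if rank < n_axes:
        import warnings

        warnings.warn(f"table rank {rank} < requested {n_axes} axes", stacklevel=2)
    n_keep = min(n_axes, rank) if rank else 0
    eig = s**2
    coords = (U[:, :n_keep] * s[:n_keep]) / np.sqrt(r)[:, None]
    coordinates = pd.DataFrame(
        coords, index=df.index, columns=[f"CA{i + 1}" for i in range(n_keep)]
    )
    inertia = eig.sum()
    proportion = eig[:n_keep] / inertia if inertia > _EPS else np.zeros(n_keep)
    return OrdinationResult(
        coordinates=coordinates, eigenvalues=eig[:n_keep], proportion=proportion
    )


def _impute_missing(matrix: IndicatorMatrix, markers_by_column: dict[str, str]) -> pd.DataFrame:
    df = matrix.values.copy()
    for col in df.columns:
        m = markers_by_column[col]
        mask = matrix.missing[m]
        if mask.any():
            scored = df.loc[~mask, col]
            df.loc[mask, col] = scored.mean() if len(scored) else 0.0
    return df


def pca(matrix, n_axes: int = 2, center: bool = True, scale: bool = False) -> OrdinationResult:
    """PCA by SVD of the (optionally centered/scaled) matrix.

    Missing markers in an :class:`IndicatorMatrix` are imputed by per-column
    means before decomposition.  Sign convention: on each axis the
    largest-magnitude loading is positive, making results deterministic.
    """
    if isinstance(matrix, IndicatorMatrix):
        markers_by_column = {c: c.split(":", 1)[0] for c in matrix.values.columns}
        df = _impute_missing(matrix, markers_by_column)
    else:
        df = _as_frame(matrix)
    X = df.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise DatasetError("PCA requires at least two rows")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd < _EPS] = 1.0
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| positive per axis
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    n_keep = min(n_axes, s.size)
    var = s**2 / max(X.shape[0] - 1, 1)
    total_var = var.sum()
    proportion = var[:n_keep] / total_var if total_var > _EPS else np.zeros(n_keep)
    coords = U[:, :n_keep] * s[:n_keep]
    axes = [f"PC{i + 1}" for i in range(n_keep)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=df.index, columns=axes),
        eigenvalues=var[:n_keep],
        proportion=proportion,
        loadings=pd.DataFrame(Vt[:n_keep].T, index=df.columns, columns=axes),
    )


def plot_ordination(
    result: OrdinationResult,
    groups: dict[str, str] | None = None,
    path=None,
    ellipses: bool = True,
    title: str = "",
):
    """Scatter the first two axes with group colors and 95% inertia ellipses.

    ``groups`` maps individual id -> group label (e.g. population).  Returns
    the matplotlib figure; also writes it to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    coords = result.coordinates
    if coords.shape[1] < 2:
        raise DatasetError("plotting requires at least two ordination axes")
    fig, ax = plt.subplots(figsize=(6, 5))
    labels = [groups.get(i, "all") if groups else "all" for i in coords.index]
    for j, group in enumerate(sorted(set(labels))):
        mask = np.array([lab == group for lab in labels])
        pts = coords.to_numpy()[mask, :2]
        color = f"C{j % 10}"
        ax.scatter(pts[:, 0], pts[:, 1], s=14, color=color, label=group, alpha=0.7)
        if ellipses and pts.shape[0] > 2:
            center, half, angle = inertia_ellipse(pts)
            ax.add_patch(
                Ellipse(
                    center, 2 * half[0], 2 * half[1],
                    angle=np.degrees(angle),
                    fill=False, color=color, lw=1.2,
                )
            )
    x_lab, y_lab = coords.columns[:2]
    pct = 100 * result.proportion[:2]
    ax.set_xlabel(f"{x_lab} ({pct[0]:.1f}%)")
    ax.set_ylabel(f"{y_lab} ({pct[1]:.1f}%)")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def inertia_ellipse(points: np.ndarray, level_sigma: float = 2.4477) -> tuple[np.ndarray, np.ndarray, float]:
    """95% inertia ellipse of a 2-D point cloud.

    Returns (center, axis half-lengths, rotation angle in radians), computed
    from the coordinate covariance with a 2.45-sigma radius (the chi-square
    95% quantile on two degrees of freedom).
    """
    pts = np.asarray(points, dtype=float)
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    half = level_sigma * np.sqrt(np.maximum(eigval, 0.0))
    angle = float(np.arctan2(eigvec[1, 0], eigvec[0, 0]))
    return center, half, angle
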