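"""Linear discriminant analysis of origins on chromatin-mark distances.

Each origin is described by its linear distance (bp, 0 = overlap) to
the nearest peak of each chromatin mark; origins are grouped early /
mid / late by timing category. LDA finds the linear combinations of
these distances that best separate the timing groups; the analysis is
read through the per-origin axis coordinates and the Pearson
correlations between each distance variable and each axis.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .detection import Origin, origins_to_intervalset
from .intervals import IntervalSet, distance_to_nearest

GROUP_ORDER = ("early", "mid", "late")


@dataclasses.dataclass
class DistanceMatrix:
    """Origins x marks distances with a timing group per row."""

    X: pd.DataFrame  # rows: origin ids, columns: mark names, entries: bp
    groups: pd.Series  # "early" / "mid" / "late" per row
    n_dropped: int  # rows removed for undefined distances


@dataclasses.dataclass
class DiscriminantResult:
    coordinates: pd.DataFrame  # per-origin axis coordinates (DA1, DA2, ...)
    correlations: pd.DataFrame  # marks x axes Pearson correlations
    group_means: pd.DataFrame  # per-group mean coordinates
    groups: pd.Series


def build_distance_matrix(
    origins: Sequence[Origin], marks: Mapping[str, IntervalSet]
) -> DistanceMatrix:
    """Distance of every timing-labeled origin to its nearest peak of
    each mark; rows with any undefined distance (mark absent from the
    origin's chromosome) are dropped and counted."""
    for name, track in marks.items():
        if len(track) == 0:
            raise ValueError(f"mark track {name!r} is empty")
    labeled = [o for o in origins if "timing_group" in o.labels]
    oset = origins_to_intervalset(labeled)
    data = {}
    for name, track in marks.items():
        data[name] = distance_to_nearest(oset, track)
    X = pd.DataFrame(data)
    groups = pd.Series([o.labels["timing_group"] for o in labeled], name="group")
    ok = ~X.isna().any(axis=1)
    n_dropped = int((~ok).sum())
    X = X.loc[ok].reset_index(drop=True)
    groups = groups.loc[ok.to_numpy()].reset_index(drop=True)
    return DistanceMatrix(X=X, groups=groups, n_dropped=n_dropped)


def run_lda(
    matrix: DistanceMatrix,
    n_axes: int | None = None,
    log1p: bool = False,
    shrinkage: float | None = None,
) -> DiscriminantResult:
    """Fit multi-class LDA on the distance matrix.

    Distances are used raw in bp by default (``log1p`` compresses their
    heavy tail). Axes are ordered by discriminating power; at most
    ``n_groups - 1`` axes exist. The axis sign is fixed so that the
    variable with the largest-magnitude correlation on each axis
    correlates *negatively* with it, making outputs reproducible
    run-to-run.

    A singular within-group covariance raises with advice to pass a
    ``shrinkage`` value (uses the eigen solver with regularization).
    """
    X = matrix.X.to_numpy(dtype=float)
    if log1p:
        X = np.log1p(X)
    y = matrix.groups.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 groups")
    if np.any(counts <= X.shape[1]):
        raise ValueError("each group needs more rows than there are marks")
    max_axes = min(len(classes) - 1, X.shape[1])
    n_axes = max_axes if n_axes is None else min(n_axes, max_axes)
    if shrinkage is not None:
        lda = LinearDiscriminantAnalysis(
            solver="eigen", shrinkage=shrinkage, n_components=n_axes
        )
    else:
        lda = LinearDiscriminantAnalysis(solver="svd", n_components=n_axes)
    try:
        coords = lda.fit_transform(X, y)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular within-group covariance; rerun with a shrinkage value, "
            "e.g. shrinkage=0.1"
        ) from exc
    coords = coords[:, :n_axes]
    axes = [f"DA{i + 1}" for i in range(coords.shape[1])]
    # Pearson correlations of each (possibly transformed) variable with each axis
    corr = np.empty((X.shape[1], coords.shape[1]))
    for j in range(X.shape[1]):
        for a in range(coords.shape[1]):
            corr[j, a] = np.corrcoef(X[:, j], coords[:, a])[0, 1]
    # sign convention: top-|corr| variable of each axis is negative
    for a in range(coords.shape[1]):
        top = int(np.argmax(np.abs(corr[:, a])))
        if corr[top, a] > 0:
            coords[:, a] *= -1
            corr[:, a] *= -1
    coordinates = pd.DataFrame(coords, columns=axes)
    correlations = pd.DataFrame(corr, index=list(matrix.X.columns), columns=axes)
    gm = coordinates.groupby(matrix.groups.to_numpy()).mean()
    order = [g for g in GROUP_ORDER if g in gm.index] + [
        g for g in gm.index if g not in GROUP_ORDER
    ]
    return DiscriminantResult(
        coordinates=coordinates,
        correlations=correlations,
        group_means=gm.loc[order],
        groups=matrix.groups.copy(),
    )


def nearest_centroid_accuracy(result: DiscriminantResult) -> float:
    """Fraction of origins assigned to their own group by nearest group
    centroid in discriminant space (in-sample recovery measure)."""
    coords = result.coordinates.to_numpy()
    groups = result.groups.to_numpy()
    centroids = result.group_means
    d = np.stack(
        [np.linalg.norm(coords - centroids.loc[g].to_numpy(), axis=1) for g in centroids.index]
    )
    pred = np.asarray(centroids.index)[np.argmin(d, axis=0)]
    return float((pred == groups).mean())


def axis_separation(result: DiscriminantResult) -> float:
    """Between-group over total variance (eta^2) of DA1 coordinates."""
    x = result.coordinates["DA1"].to_numpy()
    g = result.groups.to_numpy()
    grand = x.mean()
    between = sum(
        (x[g == c].mean() - grand) ** 2 * (g == c).sum() for c in np.unique(g)
    )
    total = ((x - grand) ** 2).sum()
    return float(between / total) if total > 0 else 0.0


def permuted_separation(
    matrix: DistanceMatrix,
    n_shuffles: int = 100,
    seed: int | None = None,
    statistic=axis_separation,
    **lda_kwargs,
) -> np.ndarray:
    """Null distribution of a separation statistic under random group
    labels (refit per shuffle)."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = DistanceMatrix(
            X=matrix.X,
            groups=pd.Series(rng.permutation(matrix.groups.to_numpy())),
            n_dropped=0,
        )
        out[i] = statistic(run_lda(perm, **lda_kwargs))
    return out
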