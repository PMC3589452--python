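"""Bin sampling time points into experiment stages from geochemistry.

Samples are clustered on square-root transformed analyte concentrations
(Fe(II), sulfide, U(VI), acetate, sulfate) with Euclidean distances and
average (UPGMA) linkage; the tree is cut into k clusters (k = 3 by
default) and clusters are labelled early/middle/late by ascending mean
sampling day.  Analytes stay in their native units (µM / mM) — the square
root is the only transform by default; an optional standardisation flag
puts analytes on unit variance first for users who want scale-free
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin

ANALYTES = ("fe2", "sulfide", "u6", "acetate", "sulfate")
STAGE_NAMES_3 = ("early", "middle", "late")


def sqrt_transform(samples: pd.DataFrame) -> pd.DataFrame:
    """Element-wise square root of the analyte columns, indexed by day.

    ``samples`` must carry a ``day`` column plus the five analyte columns;
    negative concentrations are rejected.
    """
    missing = set(ANALYTES) - set(samples.columns)
    if missing:
        raise ValueError(f"geochemistry table missing analytes: {sorted(missing)}")
    if "day" not in samples.columns:
        raise ValueError("geochemistry table requires a 'day' column")
    feats = samples[list(ANALYTES)]
    if (feats.to_numpy() < 0).any():
        raise ValueError("negative concentrations are not allowed")
    out = np.sqrt(feats)
    out.index = pd.Index(samples["day"], name="day")
    return out


@dataclass
class StageAssignment:
    """Mapping of sample days to stage labels plus the linkage that made it."""

    mapping: dict[int, str]
    linkage: np.ndarray
    stage_order: tuple[str, ...]

    @property
    def stages(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {s: [] for s in self.stage_order}
        for day, stage in sorted(self.mapping.items()):
            out[stage].append(day)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": sorted(self.mapping), "stage": [self.mapping[d] for d in sorted(self.mapping)]}
        )

    def to_newick(self) -> str:
        """Newick rendering of the linkage tree with days as leaf names."""
        days = sorted(self.mapping)
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"d{days[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return render(tree, tree.dist) + ";"


def cluster_stages(features: pd.DataFrame, k: int = 3, standardize: bool = False) -> StageAssignment:
    """UPGMA clustering of feature rows, cut into k day-ordered stages."""
    n = len(features)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot cut {n} samples into {k} clusters")
    X = features.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    days = list(features.index)
    if n == 1:
        Z = np.empty((0, 4))
        labels = np.array([1])
    else:
        Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="average")
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # label clusters by ascending mean day
    order = sorted(set(labels), key=lambda c: np.mean([d for d, l in zip(days, labels) if l == c]))
    if k == 3:
        names = STAGE_NAMES_3
    else:
        names = tuple(f"stage{i + 1}" for i in range(len(order)))
    rename = {c: names[i] for i, c in enumerate(order)}
    mapping = {int(day): rename[lab] for day, lab in zip(days, labels)}
    return StageAssignment(mapping=mapping, linkage=Z, stage_order=names[: len(order)])


def validate_contiguity(assignment: StageAssignment) -> pd.DataFrame:
    """Report whether each stage's member days form a contiguous run.

    Contiguity is judged on the rank order of days, is independent of the
    input ordering, and is reported — never enforced: a non-contiguous
    stage is a diagnostic worth seeing, not an error.
    """
    days = sorted(assignment.mapping)
    ranks = {d: i for i, d in enumerate(days)}
    rows = []
    for stage in assignment.stage_order:
        members = sorted(d for d, s in assignment.mapping.items() if s == stage)
        r = [ranks[d] for d in members]
        contiguous = bool(members) and (max(r) - min(r) + 1 == len(r))
        rows.append({"stage": stage, "days": members, "contiguous": contiguous})
    return pd.DataFrame(rows)


class StageClusterer(BaseEstimator, ClusterMixin):
    """sklearn-style estimator around :func:`cluster_stages`.

    ``fit`` accepts either a raw geochemistry table (with ``day`` and the
    analyte columns, square-root transformed internally) or an
    already-transformed feature matrix indexed by day.

    Fitted attributes: ``labels_`` (stage label per sample),
    ``linkage_`` (scipy linkage matrix), ``stage_assignment_``.
    """

    def __init__(self, n_stages: int = 3, standardize: bool = False) -> None:
        self.n_stages = n_stages
        self.standardize = standardize

    def fit(self, X: pd.DataFrame, y=None) -> "StageClusterer":
        features = sqrt_transform(X) if "day" in X.columns else X
        assignment = cluster_stages(features, k=self.n_stages, standardize=self.standardize)
        self.stage_assignment_ = assignment
        self.linkage_ = assignment.linkage
        self.labels_ = np.array([assignment.mapping[int(d)] for d in features.index])
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_
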