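"""Hierarchical clustering of clones by growth variables.

Clones are clustered by agglomerative hierarchical clustering (Ward
linkage on Euclidean distance) after z-scoring every growth variable
across clones, then cut into flat classes. The two-stage procedure first
separates clones into superclasses (default k=2, mirroring two parental
cell lines) and then re-clusters within each superclass into subclasses
(default k=3). A UMAP embedding is available as a purely visual
verification aid; no quantitative result depends on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .progression import GrowthVariableVector


@dataclass
class ClusterResult:
    clone_ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix (merge heights non-decreasing)
    labels: np.ndarray  # flat labels, 1..k
    k: int
    variable_names: list[str]
    standardization: pd.DataFrame  # per-variable mean / sd used for z-scoring
    dropped_variables: list[str] = field(default_factory=list)

    def label_of(self, clone_id: str) -> int:
        return int(self.labels[self.clone_ids.index(clone_id)])


@dataclass
class TwoStageResult:
    superclass: ClusterResult
    subclass_by_group: dict[int, ClusterResult]
    super_agreement: float | None = None  # best-matching accuracy vs known line ids

    def flat_subclass_labels(self) -> dict[str, tuple[int, int]]:
        """clone_id -> (superclass label, within-superclass subclass label)."""
        out = {}
        for group, res in self.subclass_by_group.items():
            for cid, lab in zip(res.clone_ids, res.labels):
                out[cid] = (group, int(lab))
        return out


def _to_frame(vectors: list[GrowthVariableVector] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(vectors, pd.DataFrame):
        return vectors.copy()
    names = sorted(vectors[0].values)
    data = {v.clone_id: [v.values.get(n, np.nan) for n in names] for v in vectors}
    return pd.DataFrame.from_dict(data, orient="index", columns=names)


def _standardize(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """z-score columns; impute sparse missing values; drop constant columns."""
    df = df.copy()
    dropped = []
    for col in list(df.columns):
        missing = df[col].isna().mean()
        if missing > 0:
            if missing <= 0.10:
                df[col] = df[col].fillna(df[col].median())
            else:
                dropped.append(col)
                df = df.drop(columns=col)
                warnings.warn(f"variable {col!r} dropped: >10% missing", stacklevel=3)
                continue
        if df[col].std(ddof=0) == 0:
            dropped.append(col)
            df = df.drop(columns=col)
            warnings.warn(f"variable {col!r} dropped: constant across clones", stacklevel=3)
    if df.shape[1] == 0:
        raise ValueError("no usable (non-constant) growth variables remain")
    mean = df.mean()
    sd = df.std(ddof=0)
    z = (df - mean) / sd
    params = pd.DataFrame({"mean": mean, "sd": sd})
    return z, params, dropped


def cluster_clones(vectors: list[GrowthVariableVector] | pd.DataFrame, k: int,
                   method: str = "ward") -> ClusterResult:
    """Ward-linkage hierarchical clustering cut into exactly k clusters.

    Accepts growth-variable vectors or a clones × variables DataFrame.
    Variables are z-scored across clones; constant variables are dropped
    with a warning. Deterministic and invariant to clone input order up to
    label permutation.
    """
    df = _to_frame(vectors)
    if len(df) < 2:
        raise ValueError("clustering requires at least 2 clones")
    if k > len(df):
        raise ValueError(f"k={k} exceeds the number of clones ({len(df)})")
    z, params, dropped = _standardize(df)
    linkage = hierarchy.linkage(z.to_numpy(), method=method)
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    if np.unique(labels).size != k:
        raise ValueError(f"degenerate cut: could not produce {k} distinct clusters "
                         "(clones may be identical)")
    return ClusterResult(
        clone_ids=[str(i) for i in df.index],
        linkage=linkage,
        labels=labels,
        k=k,
        variable_names=list(z.columns),
        standardization=params,
        dropped_variables=dropped,
    )


def _best_matching_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Accuracy under the best label permutation (small k: exhaustive)."""
    from itertools import permutations
    pred_vals = np.unique(pred)
    truth_vals = np.unique(truth)
    best = 0.0
    for perm in permutations(truth_vals, len(pred_vals)):
        mapping = dict(zip(pred_vals, perm))
        acc = np.mean([mapping[p] == t for p, t in zip(pred, truth)])
        best = max(best, float(acc))
    return best


def two_stage_clustering(vectors: list[GrowthVariableVector] | pd.DataFrame,
                         superclass_labels: dict[str, object] | None = None,
                         k_super: int = 2, k_sub: int = 3,
                         method: str = "ward") -> TwoStageResult:
    """Superclass cut over all clones, then subclass cuts within each group.

    When known line identities are supplied (clone_id -> line), the
    agreement of the stage-1 labels with them is reported as the accuracy
    under the best label matching.
    """
    df = _to_frame(vectors)
    stage1 = cluster_clones(df, k=k_super, method=method)
    sub: dict[int, ClusterResult] = {}
    for group in np.unique(stage1.labels):
        members = [cid for cid, lab in zip(stage1.clone_ids, stage1.labels) if lab == group]
        group_df = df.loc[members]
        if len(group_df) < k_sub:
            raise ValueError(f"superclass {group} has {len(group_df)} clones, "
                             f"fewer than k_sub={k_sub}")
        sub[int(group)] = cluster_clones(group_df, k=k_sub, method=method)
    agreement = None
    if superclass_labels is not None:
        truth = np.array([superclass_labels[cid] for cid in stage1.clone_ids])
        agreement = _best_matching_accuracy(stage1.labels, truth)
    return TwoStageResult(superclass=stage1, subclass_by_group=sub,
                          super_agreement=agreement)


def embed_clones(vectors: list[GrowthVariableVector] | pd.DataFrame,
                 seed: int = 0, n_neighbors: int | None = None) -> pd.DataFrame:
    """2D UMAP embedding of z-scored growth variables (visual aid only).

    Deterministic given seed. Distances are preserved only approximately;
    no downstream inference uses these coordinates.
    """
    import umap  # deferred: slow import

    df = _to_frame(vectors)
    if len(df) < 4:
        raise ValueError("embedding requires at least 4 clones")
    z, _, _ = _standardize(df)
    nn = n_neighbors or min(15, len(df) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about exact reproducibility mode
        reducer = umap.UMAP(n_components=2, n_neighbors=nn, random_state=seed)
        coords = reducer.fit_transform(z.to_numpy())
    return pd.DataFrame(coords, index=df.index, columns=["umap1", "umap2"])
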