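"""Cell-type features and classification.

Three pieces:

* six output-connectivity features for inhibitory neurons and a linear
  discriminant over them (perisomatic- vs distal-targeting vs sparse vs
  inhibitory-targeting subclasses),
* dendritic/somatic morphometrics for excitatory neurons, including sparse
  and singular component loadings of depth and branch profiles, feeding a
  consensus (co-clustering) Leiden pipeline,
* the two-classifier agreement logic with a manual fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_model import Connectome, Skeleton, SUBCLASS_TO_CLASS

PROXIMAL_RADIUS = 50.0  # µm; "proximal dendrite" threshold
CLUMP_RADIUS = 15.0  # µm; same-target synapse clumping criterion


class FeatureUndefinedError(ValueError):
    """A feature's denominator is empty for this cell."""


# ---------------------------------------------------------------------------
# Inhibitory output features
# ---------------------------------------------------------------------------


@dataclass
class InhibOutputFeatures:
    frac_onto_inhibitory: float
    frac_exc_onto_soma: float
    frac_exc_onto_proximal_dendrite: float
    frac_exc_onto_distal_apical: float
    frac_in_multisynaptic_connections: float
    frac_multisyn_within_15um: float
    undefined: tuple = ()  # names of features with empty denominators (set to 0)

    FIELDS = (
        "frac_onto_inhibitory",
        "frac_exc_onto_soma",
        "frac_exc_onto_proximal_dendrite",
        "frac_exc_onto_distal_apical",
        "frac_in_multisynaptic_connections",
        "frac_multisyn_within_15um",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS], dtype=float)


def _target_distances(
    syn: pd.DataFrame, connectome: Connectome, target_id: int
) -> np.ndarray:
    """Distance of each synapse to its target's soma.

    Uses path distance along the target skeleton (synapses snapped to the
    nearest node) when one is present, otherwise the Euclidean distance from
    the cleft to the target soma.
    """
    pos = syn[["x", "y", "z"]].to_numpy(dtype=float)
    skel = connectome.skeletons.get(int(target_id))
    if skel is not None and (skel.compartment == 3).any():
        tree = cKDTree(skel.xyz)
        idx = tree.query(pos)[1]
        return skel.path_distances_to_root()[idx]
    soma = connectome.soma_xyz(int(target_id))
    return np.linalg.norm(pos - soma, axis=1)


def _pairwise_target_distance(
    a: pd.Series, b: pd.Series, connectome: Connectome, target_id: int
) -> float:
    """Distance between two synapses measured on the shared target."""
    skel = connectome.skeletons.get(int(target_id))
    pa = a[["x", "y", "z"]].to_numpy(dtype=float)
    pb = b[["x", "y", "z"]].to_numpy(dtype=float)
    if skel is not None and (skel.compartment == 3).any():
        tree = cKDTree(skel.xyz)
        na = int(skel.node_ids[int(tree.query(pa)[1])])
        nb = int(skel.node_ids[int(tree.query(pb)[1])])
        return skel.path_distance_between(na, nb)
    return float(np.linalg.norm(pa - pb))


def compute_inhibitory_output_features(
    cell: int, connectome: Connectome
) -> InhibOutputFeatures:
    """Six fractions describing how a cell distributes its output synapses."""
    out = connectome.outputs_of(cell)
    class_of = connectome.class_of()
    attached = out[out["post_id"].notna()].copy()
    attached["target_class"] = (
        attached["post_id"].astype(np.int64).map(class_of).fillna("unknown")
    )
    classified = attached[attached["target_class"] != "unknown"]
    if classified.empty:
        raise FeatureUndefinedError(f"cell {cell} has no classified output synapses")

    undefined = []
    n = len(classified)
    frac_inh = float((classified["target_class"] == "inhibitory").sum()) / n

    exc = classified[classified["target_class"] == "excitatory"]
    if exc.empty:
        undefined.extend(
            ["frac_exc_onto_soma", "frac_exc_onto_proximal_dendrite",
             "frac_exc_onto_distal_apical"]
        )
        frac_soma = frac_prox = frac_distal_apical = 0.0
    else:
        on_soma = exc["post_compartment"].isin(("soma", "soma_spine"))
        frac_soma = float(on_soma.sum()) / len(exc)
        dend = exc[~on_soma]
        prox = distal_apical = 0
        for tid, grp in dend.groupby("post_id"):
            d = _target_distances(grp, connectome, int(tid))
            soma_y = float(connectome.soma_xyz(int(tid))[1])
            above = grp["y"].to_numpy(dtype=float) < soma_y
            prox += int((d <= PROXIMAL_RADIUS).sum())
            distal_apical += int(((d > PROXIMAL_RADIUS) & above).sum())
        frac_prox = prox / len(exc)
        frac_distal_apical = distal_apical / len(exc)

    conn_sizes = classified.groupby(["post_id"]).size()
    multi_targets = set(conn_sizes[conn_sizes >= 2].index)
    in_multi = classified["post_id"].isin(multi_targets)
    frac_multi = float(in_multi.sum()) / n

    multi = classified[in_multi]
    if multi.empty:
        undefined.append("frac_multisyn_within_15um")
        frac_clumped = 0.0
    else:
        from scipy.spatial.distance import squareform, pdist

        clumped = 0
        for tid, grp in multi.groupby("post_id"):
            skel = connectome.skeletons.get(int(tid))
            if skel is not None and (skel.compartment == 3).any():
                dmat = np.zeros((len(grp), len(grp)))
                for i in range(len(grp)):
                    for j in range(i + 1, len(grp)):
                        dmat[i, j] = dmat[j, i] = _pairwise_target_distance(
                            grp.iloc[i], grp.iloc[j], connectome, int(tid)
                        )
            else:
                dmat = squareform(pdist(grp[["x", "y", "z"]].to_numpy(dtype=float)))
            np.fill_diagonal(dmat, np.inf)
            clumped += int((dmat.min(axis=1) <= CLUMP_RADIUS).sum())
        frac_clumped = clumped / len(multi)

    return InhibOutputFeatures(
        frac_onto_inhibitory=frac_inh,
        frac_exc_onto_soma=frac_soma,
        frac_exc_onto_proximal_dendrite=frac_prox,
        frac_exc_onto_distal_apical=frac_distal_apical,
        frac_in_multisynaptic_connections=frac_multi,
        frac_multisyn_within_15um=frac_clumped,
        undefined=tuple(undefined),
    )


class InhibitorySubclassClassifier:
    """Linear discriminant over the six output features."""

    def __init__(self) -> None:
        self._model = None

    def fit(self, features: np.ndarray, labels) -> "InhibitorySubclassClassifier":
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        self._model = LinearDiscriminantAnalysis()
        self._model.fit(np.asarray(features, dtype=float), np.asarray(labels))
        return self

    def predict(self, features) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("classifier has not been trained")
        X = np.atleast_2d(np.asarray(features, dtype=float))
        return self._model.predict(X)


def classify_inhibitory_subclass(
    features: InhibOutputFeatures | np.ndarray, model: InhibitorySubclassClassifier
) -> str:
    if isinstance(features, InhibOutputFeatures):
        features = features.as_array()
    return str(model.predict(features)[0])


# ---------------------------------------------------------------------------
# Excitatory morphometric features
# ---------------------------------------------------------------------------

N_DEPTH_BINS = 50
N_SOMA_BINS = 13
SOMA_BIN_SPAN = 100.0  # µm above and below the soma
BRANCH_DISTANCES = np.arange(30.0, 301.0, 30.0)  # 10 distances
ROTATION_DEG = 5.0

SCALAR_FEATURES = [
    "median_tip_distance",
    "median_tip_tortuosity",
    "n_dendritic_inputs",
    "n_somatic_inputs",
    "net_dendritic_path_length",
    "radial_extent_p97",
    "median_input_distance",
    "median_somatic_input_size",
    "median_dendritic_input_size",
    "input_size_dynamic_range",
    "shallowest_input_depth",
    "deepest_input_depth",
    "vertical_input_extent",
    "median_linear_synapse_density",
    "median_skeleton_radius",
]


def rotate_flatten(xyz: np.ndarray, angle_deg: float = ROTATION_DEG,
                   pia_y: float = 0.0) -> np.ndarray:
    """Rigid rotation in the (x, y) plane to flatten the pia, then shift pia to y=0."""
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th), 0.0],
                    [np.sin(th), np.cos(th), 0.0],
                    [0.0, 0.0, 1.0]])
    out = np.atleast_2d(xyz) @ rot.T
    out[:, 1] -= pia_y
    return out


def _dendrite_mask(skel: Skeleton) -> np.ndarray:
    return skel.compartment == 3


def depth_profile(depths: np.ndarray, depth_range: tuple[float, float],
                  n_bins: int) -> np.ndarray:
    """Histogram of synapse depths over fixed bins (brute-force countable)."""
    edges = np.linspace(depth_range[0], depth_range[1], n_bins + 1)
    counts, _ = np.histogram(depths, bins=edges)
    return counts.astype(float)


def _cell_raw_features(cell: int, connectome: Connectome,
                       depth_range: tuple[float, float]) -> dict:
    skel = connectome.skeletons.get(int(cell))
    if skel is None or not _dendrite_mask(skel).any():
        raise FeatureUndefinedError(f"cell {cell} has no dendrite skeleton")
    soma = connectome.soma_xyz(cell)
    xyz = rotate_flatten(skel.xyz)
    soma_rot = rotate_flatten(soma)[0]

    dist = skel.path_distances_to_root()
    dmask = _dendrite_mask(skel)
    tips = [skel.index_of(t) for t in skel.tips()]
    tips = [i for i in tips if dmask[i]]
    if not tips:
        raise FeatureUndefinedError(f"cell {cell} has no dendritic tips")
    tip_path = dist[tips]
    tip_euclid = np.linalg.norm(xyz[tips] - soma_rot, axis=1)
    tortuosity = tip_path / np.maximum(tip_euclid, 1e-9)

    lengths = skel.edge_lengths()
    net_path = float(lengths[dmask].sum())

    # radial distance to the vertical line through the soma (flattened pia)
    radial = np.hypot(xyz[:, 0] - soma_rot[0], xyz[:, 2] - soma_rot[2])
    radial_extent = float(np.percentile(radial, 97))

    inputs = connectome.synapses[connectome.synapses["post_id"] == cell]
    if inputs.empty:
        raise FeatureUndefinedError(f"cell {cell} has no input synapses")
    on_soma = inputs["post_compartment"].isin(("soma", "soma_spine"))
    som_in, den_in = inputs[on_soma], inputs[~on_soma]
    in_xyz = rotate_flatten(inputs[["x", "y", "z"]].to_numpy(dtype=float))
    in_depth = in_xyz[:, 1]
    in_dist = np.linalg.norm(in_xyz - soma_rot, axis=1)
    sizes = inputs["size_voxels"].to_numpy(dtype=float)
    den_sizes = den_in["size_voxels"].to_numpy(dtype=float)

    # linear density: synapses / cable per depth bin, median over occupied bins
    edges = np.linspace(depth_range[0], depth_range[1], N_DEPTH_BINS + 1)
    syn_counts, _ = np.histogram(in_depth, bins=edges)
    node_depth = xyz[:, 1]
    cable_per_bin, _ = np.histogram(
        node_depth[dmask], bins=edges, weights=lengths[dmask]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(cable_per_bin > 0, syn_counts / cable_per_bin, np.nan)
    med_density = float(np.nanmedian(density)) if np.isfinite(density).any() else 0.0

    far = dmask & (dist >= 30.0)
    med_radius = float(np.median(skel.radius[far])) if far.any() else float(
        np.median(skel.radius[dmask]))

    # branch count vs distance: connected components of the 10-µm shell graph
    branch_counts = []
    for dref in BRANCH_DISTANCES:
        shell = np.nonzero(dmask & (dist > dref - 10.0) & (dist <= dref))[0]
        if len(shell) == 0:
            branch_counts.append(0)
            continue
        shell_set = set(shell.tolist())
        seen: set[int] = set()
        n_comp = 0
        parent_idx = {
            i: (skel.index_of(int(skel.parent[i])) if skel.parent[i] != -1 else -1)
            for i in shell
        }
        # union by walking to parent within the shell
        comp: dict[int, int] = {}
        for i in shell:
            if i in seen:
                continue
            n_comp += 1
            stack = [int(i)]
            while stack:
                j = stack.pop()
                if j in seen:
                    continue
                seen.add(j)
                pj = parent_idx.get(j, -1)
                if pj in shell_set and pj not in seen:
                    stack.append(pj)
                # children inside shell
                for c in shell:
                    if parent_idx.get(int(c), -1) == j and int(c) not in seen:
                        stack.append(int(c))
        branch_counts.append(n_comp)

    soma_edges = np.linspace(-SOMA_BIN_SPAN, SOMA_BIN_SPAN, N_SOMA_BINS + 1)
    soma_rel = in_depth - soma_rot[1]
    soma_profile, _ = np.histogram(soma_rel, bins=soma_edges)

    pct = np.percentile(in_depth, [5, 95])
    scalars = {
        "median_tip_distance": float(np.median(tip_path)),
        "median_tip_tortuosity": float(np.median(tortuosity)),
        "n_dendritic_inputs": float(len(den_in)),
        "n_somatic_inputs": float(len(som_in)),
        "net_dendritic_path_length": net_path,
        "radial_extent_p97": radial_extent,
        "median_input_distance": float(np.median(in_dist)),
        "median_somatic_input_size": float(
            np.median(som_in["size_voxels"])) if len(som_in) else 0.0,
        "median_dendritic_input_size": float(np.median(den_sizes)) if len(den_sizes) else 0.0,
        "input_size_dynamic_range": float(
            np.percentile(sizes, 95) - np.percentile(sizes, 5)),
        "shallowest_input_depth": float(pct[0]),
        "deepest_input_depth": float(pct[1]),
        "vertical_input_extent": float(pct[1] - pct[0]),
        "median_linear_synapse_density": med_density,
        "median_skeleton_radius": med_radius,
    }
    return {
        "scalars": scalars,
        "depth_profile": depth_profile(in_depth, depth_range, N_DEPTH_BINS),
        "soma_profile": soma_profile.astype(float),
        "branch_profile": np.asarray(branch_counts, dtype=float),
    }


def _zscore_rows(mat: np.ndarray) -> np.ndarray:
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    return (mat - mu) / np.where(sd > 0, sd, 1.0)


@dataclass
class ExcitatoryFeaturePipeline:
    """Cohort-fitted morphometric features for excitatory cells.

    Scalar features are computed per cell; the depth, soma-adjusted and
    branch-count profiles are decomposed with cohort-fitted bases (SparsePCA
    x2 and truncated SVD) whose loadings become additional features.  The
    fitted bases are serialised with the result so loadings are reproducible.
    """

    depth_range: tuple = (0.0, 1000.0)
    random_state: int = 0
    _raw: dict = field(default_factory=dict, repr=False)
    _spca_depth=None
    _spca_soma=None
    _svd_branch=None

    def fit(self, cells, connectome: Connectome) -> "ExcitatoryFeaturePipeline":
        from sklearn.decomposition import SparsePCA, TruncatedSVD

        self._raw = {int(c): _cell_raw_features(int(c), connectome, self.depth_range)
                     for c in cells}
        depth = _zscore_rows(np.vstack([r["depth_profile"] for r in self._raw.values()]))
        soma = _zscore_rows(np.vstack([r["soma_profile"] for r in self._raw.values()]))
        branch = np.vstack([r["branch_profile"] for r in self._raw.values()])
        n = len(self._raw)
        self._spca_depth = SparsePCA(
            n_components=min(6, n), random_state=self.random_state).fit(depth)
        self._spca_soma = SparsePCA(
            n_components=min(5, n), random_state=self.random_state).fit(soma)
        self._svd_branch = TruncatedSVD(
            n_components=min(3, n, branch.shape[1] - 1),
            random_state=self.random_state).fit(branch)
        return self

    def transform(self, cells, connectome: Connectome) -> pd.DataFrame:
        if self._spca_depth is None:
            raise RuntimeError("pipeline has not been fitted")
        rows = []
        for c in cells:
            raw = self._raw.get(int(c))
            if raw is None:
                raw = _cell_raw_features(int(c), connectome, self.depth_range)
            rec = dict(raw["scalars"])
            d = _zscore_rows(raw["depth_profile"][None, :])
            s = _zscore_rows(raw["soma_profile"][None, :])
            for i, v in enumerate(np.atleast_1d(self._spca_depth.transform(d)[0])):
                rec[f"depth_spca_{i}"] = float(v)
            for i, v in enumerate(np.atleast_1d(self._spca_soma.transform(s)[0])):
                rec[f"soma_spca_{i}"] = float(v)
            for i, v in enumerate(
                np.atleast_1d(
                    self._svd_branch.transform(raw["branch_profile"][None, :])[0]
                )
            ):
                rec[f"branch_svd_{i}"] = float(v)
            rec["neuron_id"] = int(c)
            rows.append(rec)
        return pd.DataFrame(rows).set_index("neuron_id")


def compute_excitatory_features(
    cell: int, connectome: Connectome, cohort_stats: ExcitatoryFeaturePipeline
) -> pd.Series:
    """Feature vector for one cell against cohort-fitted decomposition bases."""
    return cohort_stats.transform([cell], connectome).iloc[0]


# ---------------------------------------------------------------------------
# Consensus clustering
# ---------------------------------------------------------------------------


@dataclass
class ConsensusClusterResult:
    labels: np.ndarray
    co_clustering: np.ndarray  # counts, 0..n_runs
    co_occurrence: np.ndarray  # runs containing both cells
    n_runs: int
    chosen_k: int
    davies_bouldin: dict
    silhouette: dict


def consensus_cluster(
    features: np.ndarray,
    n_runs: int = 100,
    keep_frac: float = 0.97,
    k_neighbors: int = 10,
    resolution: float = 1.3,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    linkage: str = "average",
) -> ConsensusClusterResult:
    """Repeated subsampled kNN-graph Leiden clustering with consensus labels.

    Each run clusters a random ``keep_frac`` subsample on a ``k_neighbors``
    nearest-neighbour graph with Leiden at the given resolution; co-clustering
    counts are accumulated; final labels come from agglomeration of the
    co-clustering dissimilarity with the cluster count chosen by minimum
    Davies-Bouldin score (ties: maximum silhouette).

    Average linkage is the default: Leiden at this resolution produces fine
    communities whose boundaries shuffle between subsample runs, so some
    same-cluster pairs never co-occur; complete linkage pins the merge height
    of a cluster to such extreme pairs, while the mean co-clustering
    frequency remains informative.  Pass ``linkage='complete'`` to agglomerate
    on the worst-pair dissimilarity instead.
    """
    import igraph
    import leidenalg
    from sklearn.cluster import AgglomerativeClustering
    from sklearn.metrics import davies_bouldin_score, silhouette_score
    from sklearn.neighbors import kneighbors_graph

    X = np.asarray(features, dtype=float)
    n = len(X)
    if n < k_neighbors + 1:
        raise ValueError(
            f"need at least {k_neighbors + 1} cells, got {n}"
        )
    rng = np.random.default_rng(seed)
    co = np.zeros((n, n), dtype=np.int32)
    occ = np.zeros((n, n), dtype=np.int32)
    keep_n = max(int(round(keep_frac * n)), k_neighbors + 1)
    for r in range(n_runs):
        sub = np.sort(rng.choice(n, size=keep_n, replace=False))
        A = kneighbors_graph(X[sub], n_neighbors=k_neighbors, mode="connectivity")
        src, dst = A.nonzero()
        g = igraph.Graph(n=keep_n, edges=list(zip(src.tolist(), dst.tolist())),
                         directed=False)
        g.simplify()
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed + r,
        )
        labels = np.asarray(part.membership)
        occ[np.ix_(sub, sub)] += 1
        for lab in np.unique(labels):
            members = sub[labels == lab]
            co[np.ix_(members, members)] += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(occ > 0, co / np.maximum(occ, 1), 0.0)
    dissim = 1.0 - sim
    np.fill_diagonal(dissim, 0.0)

    db_scores, sil_scores, candidates = {}, {}, {}
    lo, hi = k_range
    hi = min(hi, n - 1)
    for k in range(lo, hi + 1):
        model = AgglomerativeClustering(
            n_clusters=k, metric="precomputed", linkage=linkage
        )
        lab = model.fit_predict(dissim)
        if len(np.unique(lab)) < 2:
            continue
        candidates[k] = lab
        db_scores[k] = float(davies_bouldin_score(X, lab))
        sil_scores[k] = float(silhouette_score(X, lab))
    best_db = min(db_scores.values())
    tied = [k for k, v in db_scores.items() if np.isclose(v, best_db, rtol=1e-9)]
    chosen = max(tied, key=lambda k: sil_scores[k]) if len(tied) > 1 else tied[0]
    return ConsensusClusterResult(
        labels=candidates[chosen],
        co_clustering=co,
        co_occurrence=occ,
        n_runs=n_runs,
        chosen_k=chosen,
        davies_bouldin=db_scores,
        silhouette=sil_scores,
    )


# ---------------------------------------------------------------------------
# Two-classifier agreement
# ---------------------------------------------------------------------------


@dataclass
class ClassDecision:
    final_class: str | None
    provenance: str  # auto_agree | manual | unresolved


def resolve_cell_class(
    opinion_a: str | None, opinion_b: str | None, manual: str | None = None
) -> ClassDecision:
    """Consensus logic: two agreeing automated opinions, else manual, else unresolved."""
    if opinion_a is not None and opinion_b is not None and opinion_a == opinion_b:
        return ClassDecision(final_class=opinion_a, provenance="auto_agree")
    if manual is not None:
        return ClassDecision(final_class=manual, provenance="manual")
    return ClassDecision(final_class=None, provenance="unresolved")
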