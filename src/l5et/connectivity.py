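"""Descriptive output-connectivity analyses.

Per-cell excitatory/inhibitory output fractions, the 25% ET-targeting group
partition of interneurons, reciprocity rates, connection multiplicity and
compartment statistics, distance profiles of targeting (path and Euclidean),
local/interareal target-subclass matrices, and synapse-size tests
(Kruskal-Wallis with Conover post hoc, plus two-sample KS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import Connectome, SUBCLASSES

logger = logging.getLogger("l5et")

GROUP_THRESHOLD = 0.25
PROXIMAL_N = 100  # proximal-axon replication: the 100 closest outputs


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _classified_outputs(cell: int, connectome: Connectome) -> pd.DataFrame:
    out = connectome.outputs_of(cell).copy()
    class_of = connectome.class_of()
    tc = pd.Series("unknown", index=out.index, dtype=object)
    attached = out["post_id"].notna()
    tc.loc[attached] = (
        out.loc[attached, "post_id"].astype(np.int64).map(class_of).fillna("unknown")
    )
    out["target_class"] = tc
    return out


def synapse_path_distances(cell: int, connectome: Connectome) -> pd.Series:
    """Path distance (µm) from each output synapse's axon node to the soma."""
    skel = connectome.skeletons.get(int(cell))
    if skel is None:
        raise KeyError(f"cell {cell} has no skeleton")
    out = connectome.outputs_of(cell)
    dist = skel.path_distances_to_root()
    vals, keep = [], []
    for idx, node in zip(out.index, out["pre_node"]):
        if skel.has_node(int(node)):
            vals.append(dist[skel.index_of(int(node))])
            keep.append(idx)
        else:
            logger.warning("synapse at index %s: pre_node %s missing; excluded",
                           idx, node)
    return pd.Series(vals, index=keep, dtype=float)


# ---------------------------------------------------------------------------
# output class fractions
# ---------------------------------------------------------------------------


def output_class_fractions(cell: int, connectome: Connectome,
                           proximal_n: int | None = None):
    """(n_exc, n_inh, n_undetermined, inhibitory fraction) for one cell.

    With ``proximal_n`` set, only the n output synapses closest to the soma
    along the axon are counted (the proximal-axon replication).
    """
    out = _classified_outputs(cell, connectome)
    if out.empty:
        raise ValueError(f"cell {cell} has no outputs")
    if proximal_n is not None:
        d = synapse_path_distances(cell, connectome)
        keep = d.sort_values(kind="stable").index[:proximal_n]
        out = out.loc[out.index.intersection(keep)]
    n_exc = int((out["target_class"] == "excitatory").sum())
    n_inh = int((out["target_class"] == "inhibitory").sum())
    n_und = int((out["target_class"] == "unknown").sum())
    frac = n_inh / (n_inh + n_exc) if (n_inh + n_exc) else np.nan
    return n_exc, n_inh, n_und, frac


# ---------------------------------------------------------------------------
# group partition
# ---------------------------------------------------------------------------


@dataclass
class GroupPartition:
    fractions: pd.Series  # ET-targeting output fraction per interneuron
    labels: pd.Series  # "group1"/"group2"
    threshold: float
    excluded: list


def partition_groups(
    interneurons, connectome: Connectome, threshold: float = GROUP_THRESHOLD
) -> GroupPartition:
    """Partition interneurons by their fraction of outputs onto L5-ET cells.

    The boundary is inclusive: fraction exactly at the threshold -> group 2.
    """
    sub_of = connectome.subclass_of()
    fracs, labels, excluded = {}, {}, []
    for cell in interneurons:
        out = connectome.outputs_of(int(cell))
        if out.empty:
            logger.warning("interneuron %s has no outputs; excluded", cell)
            excluded.append(int(cell))
            continue
        attached = out[out["post_id"].notna()]
        n_et = int(
            (attached["post_id"].astype(np.int64).map(sub_of) == "L5-ET").sum()
        )
        frac = n_et / len(out)
        fracs[int(cell)] = frac
        labels[int(cell)] = "group2" if frac >= threshold else "group1"
    return GroupPartition(
        fractions=pd.Series(fracs, dtype=float),
        labels=pd.Series(labels, dtype=object),
        threshold=threshold,
        excluded=excluded,
    )


def group2_synapse_share(et_cells, partition: GroupPartition,
                         connectome: Connectome) -> float:
    """Share of ET->interneuron synapses that land on group-2 cells."""
    grouped = set(partition.labels.index)
    n2 = n = 0
    for cell in et_cells:
        out = connectome.outputs_of(int(cell))
        posts = out["post_id"].dropna().astype(np.int64)
        posts = posts[posts.isin(grouped)]
        n += len(posts)
        n2 += int((posts.map(partition.labels) == "group2").sum())
    return n2 / n if n else np.nan


# ---------------------------------------------------------------------------
# reciprocity
# ---------------------------------------------------------------------------


def reciprocity_rate(pre_cells, post_cells, connectome: Connectome) -> float:
    """Fraction of connected (pre -> post) pairs that also have >=1 post -> pre synapse."""
    syn = connectome.synapses
    pre_set, post_set = set(map(int, pre_cells)), set(map(int, post_cells))
    attached = syn[syn["post_id"].notna()]
    fwd = {
        (int(a), int(b))
        for a, b in zip(attached["pre_id"], attached["post_id"])
        if int(a) in pre_set and int(b) in post_set
    }
    if not fwd:
        return np.nan
    rev = {
        (int(b), int(a))
        for a, b in zip(attached["pre_id"], attached["post_id"])
    }
    n_recip = sum(1 for p in fwd if p in rev)
    return n_recip / len(fwd)


# ---------------------------------------------------------------------------
# connection statistics
# ---------------------------------------------------------------------------


def connection_stats(connectome: Connectome, pre_set) -> dict:
    """Multiplicity (mean, sd, range) per target class + compartment fractions."""
    if not len(list(pre_set)):
        raise ValueError("pre_set must be nonempty")
    syn = connectome.synapses[connectome.synapses["pre_id"].isin(list(pre_set))]
    class_of = connectome.class_of()
    attached = syn[syn["post_id"].notna()].copy()
    attached["target_class"] = (
        attached["post_id"].astype(np.int64).map(class_of).fillna("unknown")
    )
    result: dict = {"multiplicity": {}, "compartments": {}}
    for cls, grp in attached.groupby("target_class"):
        sizes = grp.groupby(["pre_id", "post_id"]).size().to_numpy()
        result["multiplicity"][cls] = {
            "mean": float(sizes.mean()),
            "sd": float(sizes.std(ddof=1)) if len(sizes) > 1 else 0.0,
            "min": int(sizes.min()),
            "max": int(sizes.max()),
            "n_connections": int(len(sizes)),
        }
        comp = grp["post_compartment"].value_counts(normalize=True)
        result["compartments"][cls] = comp.to_dict()
    return result


# ---------------------------------------------------------------------------
# distance profiles
# ---------------------------------------------------------------------------


@dataclass
class DistanceProfile:
    metric: str
    bin_edges: np.ndarray
    exc_counts: np.ndarray
    inh_counts: np.ndarray

    @property
    def inh_fraction(self) -> np.ndarray:
        tot = self.exc_counts + self.inh_counts
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(tot > 0, self.inh_counts / np.maximum(tot, 1), np.nan)


def distance_profiles(
    cells,
    connectome: Connectome,
    metric: str = "path",
    bin_width: float = 50.0,
    max_distance: float = 1000.0,
) -> DistanceProfile:
    """Class-resolved histogram of output-synapse distances to the soma.

    ``metric='path'`` measures along the axon skeleton from the synapse's
    node to the root; ``'euclidean'`` is the straight soma-to-cleft chord.
    """
    if metric not in ("path", "euclidean"):
        raise ValueError("metric must be 'path' or 'euclidean'")
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    exc = np.zeros(len(edges) - 1)
    inh = np.zeros(len(edges) - 1)
    for cell in np.atleast_1d(cells):
        out = _classified_outputs(int(cell), connectome)
        if metric == "path":
            d = synapse_path_distances(int(cell), connectome)
            out = out.loc[d.index]
            dist = d.to_numpy()
        else:
            soma = connectome.soma_xyz(int(cell))
            dist = np.linalg.norm(
                out[["x", "y", "z"]].to_numpy(dtype=float) - soma, axis=1
            )
        for cls, acc in (("excitatory", exc), ("inhibitory", inh)):
            mask = (out["target_class"] == cls).to_numpy()
            counts, _ = np.histogram(dist[mask], bins=edges)
            acc += counts
    return DistanceProfile(metric=metric, bin_edges=edges,
                           exc_counts=exc, inh_counts=inh)


# ---------------------------------------------------------------------------
# subclass matrix
# ---------------------------------------------------------------------------


@dataclass
class SubclassMatrix:
    table: pd.DataFrame  # rows: neuron ids + "all"; columns: subclasses + undetermined
    scope: str
    omitted: list  # interareal rows dropped for < min_synapses


def subclass_matrix(
    cells,
    connectome: Connectome,
    scope: str = "all",
    min_synapses: int = 20,
) -> SubclassMatrix:
    """Per-cell fractions of output synapses by target subclass.

    A synapse is *local* iff its position lies on the same side of the area
    border as the presynaptic soma, *interareal* otherwise.  Interareal rows
    with fewer than ``min_synapses`` synapses are omitted.  Rows sum to 1
    including the undetermined column.
    """
    if scope not in ("all", "local", "interareal"):
        raise ValueError("scope must be all/local/interareal")
    sub_of = connectome.subclass_of()
    border = connectome.geometry.border_x
    cols = list(SUBCLASSES[:-1]) + ["undetermined"]
    rows, omitted = {}, []
    for cell in np.atleast_1d(cells):
        out = connectome.outputs_of(int(cell))
        if scope != "all":
            soma_side = connectome.soma_xyz(int(cell))[0] >= border
            syn_side = out["x"].to_numpy(dtype=float) >= border
            mask = syn_side == soma_side if scope == "local" else syn_side != soma_side
            out = out[mask]
        if scope == "interareal" and len(out) < min_synapses:
            omitted.append(int(cell))
            continue
        counts = dict.fromkeys(cols, 0)
        for pid in out["post_id"]:
            if pd.isna(pid):
                counts["undetermined"] += 1
            else:
                sub = sub_of.get(int(pid), "unknown")
                counts["undetermined" if sub == "unknown" else sub] += 1
        total = sum(counts.values())
        rows[int(cell)] = (
            {k: v / total for k, v in counts.items()} if total else
            dict.fromkeys(cols, np.nan)
        )
    if rows:
        table = pd.DataFrame.from_dict(rows, orient="index")[cols]
    else:
        table = pd.DataFrame(columns=cols)
    # aggregate row over all synapses of included cells
    agg_counts = dict.fromkeys(cols, 0.0)
    for cell in rows:
        out = connectome.outputs_of(cell)
        if scope != "all":
            soma_side = connectome.soma_xyz(cell)[0] >= border
            syn_side = out["x"].to_numpy(dtype=float) >= border
            mask = syn_side == soma_side if scope == "local" else syn_side != soma_side
            out = out[mask]
        for pid in out["post_id"]:
            if pd.isna(pid):
                agg_counts["undetermined"] += 1
            else:
                sub = sub_of.get(int(pid), "unknown")
                agg_counts["undetermined" if sub == "unknown" else sub] += 1
    total = sum(agg_counts.values())
    if total:
        table.loc["all"] = {k: v / total for k, v in agg_counts.items()}
    return SubclassMatrix(table=table, scope=scope, omitted=omitted)


# ---------------------------------------------------------------------------
# synapse-size tests
# ---------------------------------------------------------------------------


def conover_pairwise(groups: dict, adjust: str = "holm") -> pd.DataFrame:
    """Conover's post hoc all-pairs test on ranks after Kruskal-Wallis.

    Statistic per pair (i, j): t = (R̄_i - R̄_j) / sqrt(S² ((N-1-H)/(N-k)) (1/n_i + 1/n_j))
    with S² the variance of all ranks and H the (tie-corrected) KW statistic;
    two-sided p from Student's t with N - k degrees of freedom, multiplicity
    adjusted (Holm by default).
    """
    from statsmodels.stats.multitest import multipletests

    names = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    sizes = np.array([len(s) for s in samples])
    N, k = int(sizes.sum()), len(samples)
    all_vals = np.concatenate(samples)
    ranks = stats.rankdata(all_vals)
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    rbar = np.array([r.mean() for r in split])
    H = stats.kruskal(*samples).statistic
    s2 = ranks.var(ddof=1)
    dof = N - k
    scale = s2 * (N - 1 - H) / dof
    recs = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(scale * (1 / sizes[i] + 1 / sizes[j]))
            t = (rbar[i] - rbar[j]) / se
            p = 2 * stats.t.sf(abs(t), dof)
            recs.append({"group_a": names[i], "group_b": names[j],
                         "statistic": float(t), "p_raw": float(p)})
    df = pd.DataFrame(recs)
    df["p_adjusted"] = multipletests(df["p_raw"], method=adjust)[1]
    return df


def synapse_size_tests(
    size_groups: dict,
    alpha: float = 0.05,
    adjust: str = "holm",
    pairwise_ks: bool = False,
) -> dict:
    """Kruskal-Wallis omnibus over subclass size samples, Conover post hoc.

    Groups with fewer than two samples are excluded with a warning.  Pairwise
    Conover results are reported only when the omnibus is significant.
    """
    groups = {}
    for name, vals in size_groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2:
            logger.warning("group %s has < 2 samples; excluded", name)
            continue
        groups[name] = vals
    if len(groups) < 2:
        raise ValueError("need at least two groups with >= 2 samples")
    kw = stats.kruskal(*groups.values())
    out = {
        "kruskal_H": float(kw.statistic),
        "kruskal_p": float(kw.pvalue),
        "pairwise_conover": None,
        "pairwise_ks": None,
    }
    if kw.pvalue < alpha:
        out["pairwise_conover"] = conover_pairwise(groups, adjust=adjust)
    if pairwise_ks:
        names = list(groups)
        recs = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                ks = stats.ks_2samp(groups[names[i]], groups[names[j]])
                recs.append({"group_a": names[i], "group_b": names[j],
                             "statistic": float(ks.statistic),
                             "p": float(ks.pvalue)})
        out["pairwise_ks"] = pd.DataFrame(recs)
    return out
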