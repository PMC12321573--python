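"""Domain types, coordinate conventions, file I/O and structural validation.

Conventions
-----------
* Right-handed coordinates in micrometres. ``y`` is depth below the pia
  (positive downward, pia at ``y = 0``); the plane ``x = border_x`` (default 0)
  separates the primary visual area (VISp, ``x < border_x``) from the higher
  visual area (HVA).
* All identifiers are 1-based integers.
* SWC files use the standard 7-column dialect with compartment codes
  1 = soma, 2 = axon, 3 = dendrite.
* Unknown or missing categorical values are preserved as ``"unknown"``; the
  bookkeeping of unresolved synapses requires an explicit undetermined bucket,
  so nothing is silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("l5et")

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

AREAS = ("VISp", "HVA")
LAYERS = ("L1", "L23", "L4", "L5", "L6", "WM")
CELL_CLASSES = ("excitatory", "inhibitory", "unknown")
EXC_SUBCLASSES = ("L23P", "L4P", "L5-IT", "L5-ET", "L5-NP", "L6P")
INH_SUBCLASSES = ("PeriTC", "DistTC", "SparTC", "InhTC")
SUBCLASSES = EXC_SUBCLASSES + INH_SUBCLASSES + ("unknown",)
PROOFREAD_STATUSES = (
    "none",
    "clean_dendrite",
    "clean_axon_extended",
    "clean_axon_comprehensive",
)
COMPARTMENTS = (
    "spine",
    "shaft",
    "soma",
    "soma_spine",
    "other",
    "orphan_spine",
    "unknown",
)

SUBCLASS_TO_CLASS = {
    **{s: "excitatory" for s in EXC_SUBCLASSES},
    **{s: "inhibitory" for s in INH_SUBCLASSES},
    "unknown": "unknown",
}

NEURON_COLUMNS = [
    "neuron_id",
    "x",
    "y",
    "z",
    "area",
    "layer",
    "cell_class",
    "subclass",
    "proofread_status",
]
SYNAPSE_COLUMNS = [
    "synapse_id",
    "pre_id",
    "post_id",
    "x",
    "y",
    "z",
    "size_voxels",
    "post_compartment",
    "pre_node",
]

SWC_COMPARTMENT_CODES = {1: "soma", 2: "axon", 3: "dendrite"}
SWC_CODE_OF = {v: k for k, v in SWC_COMPARTMENT_CODES.items()}


class ConnectomeLoadError(RuntimeError):
    """A required file is missing or unreadable."""


class SkeletonFormatError(ValueError):
    """An SWC file violates the rooted-tree contract."""


# ---------------------------------------------------------------------------
# Skeleton
# ---------------------------------------------------------------------------


@dataclass
class Skeleton:
    """A rooted tree skeleton of one neuron.

    ``node_ids`` are 1-based and unique; ``parent`` holds the parent *node id*
    of each node (-1 for the root).  Node positions are in µm.
    """

    node_ids: np.ndarray  # (n,) int
    xyz: np.ndarray  # (n, 3) float, µm
    radius: np.ndarray  # (n,) float, µm
    compartment: np.ndarray  # (n,) int SWC codes
    parent: np.ndarray  # (n,) int node ids, -1 for root

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.radius = np.asarray(self.radius, dtype=float)
        self.compartment = np.asarray(self.compartment, dtype=np.int64)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self._index = {int(n): i for i, n in enumerate(self.node_ids)}
        self.validate()

    # -- structure ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def root(self) -> int:
        (roots,) = np.nonzero(self.parent == -1)
        return int(self.node_ids[roots[0]])

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def has_node(self, node_id: int) -> bool:
        return int(node_id) in self._index

    def validate(self) -> None:
        if len(set(self._index)) != self.n_nodes:
            raise SkeletonFormatError("duplicate node ids")
        roots = np.nonzero(self.parent == -1)[0]
        if len(roots) != 1:
            raise SkeletonFormatError(
                f"skeleton must have exactly one root, found {len(roots)}"
            )
        for nid, pid in zip(self.node_ids, self.parent):
            if pid == -1:
                continue
            if int(pid) not in self._index:
                raise SkeletonFormatError(
                    f"node {int(nid)} references absent parent {int(pid)}"
                )
        # acyclicity / connectivity: every node must reach the root
        order = self.topological_order()
        if len(order) != self.n_nodes:
            raise SkeletonFormatError("skeleton is disconnected or cyclic")

    def topological_order(self) -> np.ndarray:
        """Indices ordered root-first (parents before children)."""
        children: dict[int, list[int]] = {int(n): [] for n in self.node_ids}
        root_idx = None
        for i, (nid, pid) in enumerate(zip(self.node_ids, self.parent)):
            if pid == -1:
                root_idx = i
            elif int(pid) in children:
                children[int(pid)].append(i)
        order: list[int] = []
        stack = [root_idx] if root_idx is not None else []
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(children[int(self.node_ids[i])])
        return np.asarray(order, dtype=np.int64)

    # -- metrics ------------------------------------------------------------

    def edge_lengths(self) -> np.ndarray:
        """Per-node Euclidean length of the edge to the parent (0 at root)."""
        lengths = np.zeros(self.n_nodes)
        has_parent = self.parent != -1
        pidx = np.array(
            [self._index[int(p)] if p != -1 else 0 for p in self.parent]
        )
        d = np.linalg.norm(self.xyz - self.xyz[pidx], axis=1)
        lengths[has_parent] = d[has_parent]
        return lengths

    def total_cable_length(self) -> float:
        return float(self.edge_lengths().sum())

    def path_distances_to_root(self) -> np.ndarray:
        """Path distance (µm) from every node to the root, in node order."""
        lengths = self.edge_lengths()
        dist = np.zeros(self.n_nodes)
        for i in self.topological_order():
            p = self.parent[i]
            if p != -1:
                dist[i] = dist[self._index[int(p)]] + lengths[i]
        return dist

    def path_distance_between(self, node_a: int, node_b: int) -> float:
        """Tree-path distance (µm) between two nodes via their common ancestor."""
        dist = self.path_distances_to_root()
        anc_a: dict[int, float] = {}
        nid = int(node_a)
        while nid != -1:
            anc_a[nid] = dist[self._index[nid]]
            nid = int(self.parent[self._index[nid]])
        nid = int(node_b)
        while nid != -1:
            if nid in anc_a:
                d_lca = dist[self._index[nid]]
                return float(anc_a[node_a] + dist[self._index[node_b]] - 2 * d_lca)
            nid = int(self.parent[self._index[nid]])
        raise SkeletonFormatError("nodes share no ancestor")

    def tips(self) -> np.ndarray:
        """Node ids of leaves (nodes that are no node's parent)."""
        parents = set(int(p) for p in self.parent if p != -1)
        return np.asarray(
            [int(n) for n in self.node_ids if int(n) not in parents], dtype=np.int64
        )

    # -- SWC I/O ------------------------------------------------------------

    @classmethod
    def from_swc(cls, path: Path | str) -> "Skeleton":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SkeletonFormatError(f"{path}: expected 7 columns, got {len(parts)}")
            rows.append(parts)
        if not rows:
            raise SkeletonFormatError(f"{path}: no nodes")
        arr = np.asarray(rows)
        try:
            return cls(
                node_ids=arr[:, 0].astype(np.int64),
                compartment=arr[:, 1].astype(np.int64),
                xyz=arr[:, 2:5].astype(float),
                radius=arr[:, 5].astype(float),
                parent=arr[:, 6].astype(np.int64),
            )
        except SkeletonFormatError as err:
            raise SkeletonFormatError(f"{path}: {err}") from err

    def to_swc(self, path: Path | str) -> Path:
        path = Path(path)
        order = np.argsort(self.node_ids)
        lines = ["# node_id type x y z radius parent"]
        for i in order:
            lines.append(
                f"{int(self.node_ids[i])} {int(self.compartment[i])} "
                f"{self.xyz[i, 0]:.6f} {self.xyz[i, 1]:.6f} {self.xyz[i, 2]:.6f} "
                f"{self.radius[i]:.6f} {int(self.parent[i])}"
            )
        path.write_text("\n".join(lines) + "\n")
        return path


# ---------------------------------------------------------------------------
# Geometry and Connectome containers
# ---------------------------------------------------------------------------


@dataclass
class VolumeGeometry:
    """Bounding box of the volume plus the two reference planes."""

    bounds: np.ndarray  # (3, 2) µm, [min, max] per axis
    border_x: float = 0.0  # VISp (x < border) / HVA (x >= border)
    pia_y: float = 0.0  # depth 0; depth increases downward

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float).reshape(3, 2)

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        return np.all(
            (xyz >= self.bounds[:, 0]) & (xyz <= self.bounds[:, 1]), axis=1
        )

    def area_of(self, x: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(x) < self.border_x, "VISp", "HVA")

    def to_dict(self) -> dict:
        return {
            "bounds": self.bounds.tolist(),
            "border_x": self.border_x,
            "pia_y": self.pia_y,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeGeometry":
        return cls(
            bounds=np.asarray(d["bounds"]),
            border_x=float(d["border_x"]),
            pia_y=float(d["pia_y"]),
        )


@dataclass
class Connectome:
    """Neuron table, skeletons, synapse table and volume geometry."""

    neurons: pd.DataFrame
    synapses: pd.DataFrame
    skeletons: dict[int, Skeleton] = field(default_factory=dict)
    geometry: VolumeGeometry = field(
        default_factory=lambda: VolumeGeometry(
            bounds=[[-550.0, 550.0], [0.0, 900.0], [0.0, 550.0]]
        )
    )

    def __post_init__(self) -> None:
        self.neurons = _normalize_neuron_table(self.neurons)
        self.synapses = _normalize_synapse_table(self.synapses)

    # convenience lookups ----------------------------------------------------

    def neuron_ids(self) -> np.ndarray:
        return self.neurons["neuron_id"].to_numpy()

    def soma_xyz(self, neuron_id: int) -> np.ndarray:
        cache = getattr(self, "_soma_cache", None)
        if cache is None or len(cache) != len(self.neurons):
            cache = self.neurons.set_index("neuron_id")[["x", "y", "z"]]
            object.__setattr__(self, "_soma_cache", cache)
        try:
            return cache.loc[int(neuron_id)].to_numpy(dtype=float)
        except KeyError:
            raise KeyError(f"neuron {neuron_id} not in table") from None

    def class_of(self) -> pd.Series:
        """cell_class indexed by neuron_id."""
        return self.neurons.set_index("neuron_id")["cell_class"]

    def subclass_of(self) -> pd.Series:
        return self.neurons.set_index("neuron_id")["subclass"]

    def outputs_of(self, neuron_id: int) -> pd.DataFrame:
        return self.synapses[self.synapses["pre_id"] == neuron_id]


# ---------------------------------------------------------------------------
# Table normalization
# ---------------------------------------------------------------------------


def _coerce_enum(series: pd.Series, allowed: tuple[str, ...], name: str) -> pd.Series:
    vals = series.astype(str)
    bad = ~vals.isin(allowed)
    if bad.any():
        logger.warning(
            "%d unknown %s value(s) mapped to 'unknown': %s",
            int(bad.sum()),
            name,
            sorted(vals[bad].unique())[:5],
        )
        vals = vals.where(~bad, "unknown")
    return vals


def _normalize_neuron_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in NEURON_COLUMNS:
        if col not in df.columns:
            if col in ("area", "layer", "cell_class", "subclass", "proofread_status"):
                df[col] = "unknown" if col != "proofread_status" else "none"
            else:
                raise ValueError(f"neuron table missing column {col!r}")
    df["neuron_id"] = df["neuron_id"].astype(np.int64)
    df["area"] = _coerce_enum(df["area"], AREAS + ("unknown",), "area")
    df["layer"] = _coerce_enum(df["layer"], LAYERS + ("unknown",), "layer")
    df["cell_class"] = _coerce_enum(df["cell_class"], CELL_CLASSES, "cell_class")
    df["subclass"] = _coerce_enum(df["subclass"], SUBCLASSES, "subclass")
    df["proofread_status"] = _coerce_enum(
        df["proofread_status"], PROOFREAD_STATUSES, "proofread_status"
    )
    return df[NEURON_COLUMNS].sort_values("neuron_id").reset_index(drop=True)


def _normalize_synapse_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in SYNAPSE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"synapse table missing column {col!r}")
    df["synapse_id"] = df["synapse_id"].astype(np.int64)
    df["pre_id"] = df["pre_id"].astype(np.int64)
    # orphan convention: empty/NaN post -> <NA>
    df["post_id"] = pd.array(
        [pd.NA if (pd.isna(v) or v == "") else int(v) for v in df["post_id"]],
        dtype="Int64",
    )
    df["size_voxels"] = df["size_voxels"].astype(np.int64)
    df["post_compartment"] = _coerce_enum(
        df["post_compartment"], COMPARTMENTS, "post_compartment"
    )
    df["pre_node"] = df["pre_node"].astype(np.int64)
    return df[SYNAPSE_COLUMNS].sort_values("synapse_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Load / save
# ---------------------------------------------------------------------------


def save_connectome(connectome: Connectome, directory: Path | str) -> Path:
    """Write a connectome as CSV tables, SWC skeletons and JSON geometry.

    Output is byte-stable for a fixed connectome: tables are sorted by id and
    floats written with fixed precision.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "skeletons").mkdir(exist_ok=True)

    neurons = connectome.neurons.sort_values("neuron_id")
    neurons.to_csv(directory / "neurons.csv", index=False, float_format="%.6f")
    synapses = connectome.synapses.sort_values("synapse_id")
    synapses.to_csv(directory / "synapses.csv", index=False, float_format="%.6f")
    with open(directory / "geometry.json", "w") as fh:
        json.dump(connectome.geometry.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    for nid in sorted(connectome.skeletons):
        connectome.skeletons[nid].to_swc(directory / "skeletons" / f"{nid}.swc")
    return directory


def load_connectome(directory: Path | str) -> Connectome:
    """Load a connectome saved by :func:`save_connectome`."""
    directory = Path(directory)
    for fname in ("neurons.csv", "synapses.csv", "geometry.json"):
        if not (directory / fname).exists():
            raise ConnectomeLoadError(f"missing file: {directory / fname}")
    neurons = pd.read_csv(directory / "neurons.csv", dtype={"neuron_id": np.int64})
    synapses = pd.read_csv(directory / "synapses.csv")
    with open(directory / "geometry.json") as fh:
        geometry = VolumeGeometry.from_dict(json.load(fh))
    skeletons: dict[int, Skeleton] = {}
    skel_dir = directory / "skeletons"
    if skel_dir.exists():
        for swc in sorted(skel_dir.glob("*.swc")):
            skeletons[int(swc.stem)] = Skeleton.from_swc(swc)
    return Connectome(
        neurons=neurons, synapses=synapses, skeletons=skeletons, geometry=geometry
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    issues: list[str]
    class_counts: dict[str, int]

    @property
    def ok(self) -> bool:
        return not self.issues

    def to_dict(self) -> dict:
        return {"ok": self.ok, "issues": self.issues, "class_counts": self.class_counts}


def classify_synapse_targets(connectome: Connectome) -> pd.Series:
    """Target cell class per synapse: excitatory / inhibitory / unknown.

    Synapses with no attached post cell (orphans) are 'unknown'.
    """
    class_of = connectome.class_of()
    post = connectome.synapses["post_id"]
    out = pd.Series("unknown", index=connectome.synapses.index, dtype=object)
    attached = post.notna()
    mapped = post[attached].astype(np.int64).map(class_of)
    out.loc[attached] = mapped.fillna("unknown").to_numpy()
    return out


def validate_connectome(connectome: Connectome) -> ValidationReport:
    """Structural validation; report-only, never raises.

    Checks id uniqueness, referential integrity, bounds, subclass/class
    consistency, skeleton pre_node references, and the class-partition
    conservation n_exc + n_inh + n_undetermined = n_total.
    """
    issues: list[str] = []
    neurons, synapses = connectome.neurons, connectome.synapses

    dup = neurons["neuron_id"].duplicated()
    if dup.any():
        issues.append(f"duplicate neuron ids: {sorted(neurons['neuron_id'][dup])[:5]}")
    dup = synapses["synapse_id"].duplicated()
    if dup.any():
        issues.append(
            f"duplicate synapse ids: {sorted(synapses['synapse_id'][dup])[:5]}"
        )

    inside = connectome.geometry.contains(neurons[["x", "y", "z"]].to_numpy())
    if not inside.all():
        bad = neurons["neuron_id"][~inside].tolist()[:5]
        issues.append(f"somata outside volume bounds: neurons {bad}")

    mismatch = neurons["subclass"].map(SUBCLASS_TO_CLASS) != neurons["cell_class"]
    mismatch &= neurons["subclass"] != "unknown"
    if mismatch.any():
        bad = neurons["neuron_id"][mismatch].tolist()[:5]
        issues.append(f"subclass/cell_class inconsistency: neurons {bad}")

    known = set(neurons["neuron_id"].tolist())
    missing_pre = ~synapses["pre_id"].isin(known)
    if missing_pre.any():
        bad = synapses["synapse_id"][missing_pre].tolist()[:5]
        issues.append(f"synapses with pre_id not in neuron table: synapses {bad}")
    attached = synapses["post_id"].notna()
    missing_post = attached & ~synapses["post_id"].isin(known)
    if missing_post.any():
        bad = synapses["synapse_id"][missing_post].tolist()[:5]
        issues.append(
            f"synapses referencing absent post cells (use null): synapses {bad}"
        )

    bad_size = synapses["size_voxels"] <= 0
    if bad_size.any():
        bad = synapses["synapse_id"][bad_size].tolist()[:5]
        issues.append(f"non-positive synapse sizes: synapses {bad}")

    orphanspine = synapses["post_compartment"] == "orphan_spine"
    if (orphanspine & synapses["post_id"].notna()).any():
        bad = synapses["synapse_id"][orphanspine & attached].tolist()[:5]
        issues.append(f"orphan_spine synapses with a post cell: synapses {bad}")

    for nid, skel in connectome.skeletons.items():
        rows = synapses[synapses["pre_id"] == nid]
        bad_nodes = [
            int(s)
            for s, n in zip(rows["synapse_id"], rows["pre_node"])
            if not skel.has_node(int(n))
        ]
        if bad_nodes:
            issues.append(
                f"synapses with pre_node absent from skeleton {nid}: {bad_nodes[:5]}"
            )

    # class-partition conservation
    target_class = classify_synapse_targets(connectome)
    n_exc = int((target_class == "excitatory").sum())
    n_inh = int((target_class == "inhibitory").sum())
    n_und = int((target_class == "unknown").sum())
    counts = {
        "n_excitatory": n_exc,
        "n_inhibitory": n_inh,
        "n_undetermined": n_und,
        "n_total": len(synapses),
    }
    if n_exc + n_inh + n_und != len(synapses):
        issues.append("class partition does not conserve the synapse count")

    return ValidationReport(issues=issues, class_counts=counts)
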