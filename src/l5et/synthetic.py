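"""Synthetic connectome generator.

Emulates the statistical structure of a cortical EM connectome centred on
layer-5 extratelencephalic (L5-ET) neuron output, so that every downstream
analysis is testable at desk scale, with ground-truth labels for recovery
tests.  The generator reproduces, by construction or by calibrated sampling:

* subclass abundances (inhibitory fraction ~0.13; L5-IT 12.4%, L5-ET 3.5%,
  L5-NP 1.5% of excitatory cells),
* the distance-dependent excitatory/inhibitory targeting of L5-ET axons
  (inhibitory-target probability ~0.8 at the soma falling to ~0.2 at 750 µm
  of axonal path length, modelled as a two-asymptote logistic),
* connection multiplicity (zero-truncated negative binomial; inhibitory
  targets mean 1.9, range 1-28; excitatory mean 1.1, range 1-4),
* per-pair lognormal synapse-size distributions with optional tail
  truncation (default: ET->NP lacks the extreme sizes seen in ET->ET),
* group-structured interneuron output (a bimodal mixture of ET-targeting
  fractions; 78% of ET->interneuron synapses land on high-targeting
  "group 2" cells; reciprocity is more likely for group-2 partners),
* axon scale (cable length ~7,324 +/- 2,128 µm; ~461 outputs per cell;
  10/12 cells send an interareal collateral across the area border).

Axons are phenomenological branching persistent random walks; only summary
statistics are matched, not real morphology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core_model import (
    Connectome,
    Skeleton,
    VolumeGeometry,
    EXC_SUBCLASSES,
    INH_SUBCLASSES,
)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class DistanceRule:
    """Inhibitory-target probability vs axonal path distance (µm).

    p_inh(d) = p_distal + (p_proximal - p_distal) * logistic((d_half - d)/d_scale)
    """

    p_inh_proximal: float = 0.8
    p_inh_distal: float = 0.2
    d_half: float = 375.0
    d_scale: float = 150.0


@dataclass
class MultiplicityModel:
    """Zero-truncated negative binomial synapse-per-connection counts."""

    inh_mean: float = 1.9
    inh_max: int = 28
    inh_dispersion: float = 0.25
    exc_mean: float = 1.1
    exc_max: int = 4
    exc_dispersion: float = 1.0


@dataclass
class SizeModel:
    """Per-(pre,post) lognormal synapse sizes in voxels.

    ``truncate_pairs`` maps a (pre_subclass, post_subclass) pair to a central
    quantile band; draws outside the band are redrawn, removing both tails.
    The default removes the extreme-size tails from ET->NP synapses only.
    """

    log_mean: float = 8.2  # ~3,600 voxels median
    log_sigma: float = 0.7
    pair_overrides: dict = field(default_factory=dict)
    truncate_pairs: dict = field(
        default_factory=lambda: {("L5-ET", "L5-NP"): (0.10, 0.90)}
    )


@dataclass
class GroupModel:
    """Interneuron ET-targeting structure.

    ET-targeting output fractions are drawn from a Beta mixture whose modes
    straddle the 25% partition threshold; ET->interneuron synapses are
    allocated so the group-2 share matches ``group2_synapse_share``;
    reciprocal (return) connections are added per connected pair with a
    group-dependent probability.
    """

    group2_weight: float = 0.35
    beta_group1: tuple = (2.0, 18.0)
    beta_group2: tuple = (12.0, 12.0)
    group2_synapse_share: float = 0.78
    recip_p_group1: float = 0.15
    recip_p_group2: float = 0.60
    outputs_mean: float = 350.0
    outputs_sd: float = 100.0


@dataclass
class AxonModel:
    """Branching persistent random walk for axon skeletons."""

    step: float = 20.0  # µm per node
    persistence: float = 0.85
    n_primary: int = 4
    branch_rate: float = 0.0025  # per µm per tip
    term_rate: float = 0.0005  # per µm per tip
    cable_mean: float = 7324.0
    cable_sd: float = 2128.0
    cable_min: float = 1500.0
    interareal_collateral_prob: float = 10.0 / 12.0
    inh_cable_mean: float = 3500.0
    inh_cable_sd: float = 800.0
    synapses_mean: float = 461.0
    synapses_sd: float = 200.0
    synapses_min: int = 150
    synapses_max: int = 940


@dataclass
class GeneratorConfig:
    n_neurons: int = 3000
    class_mix: float = 0.13  # inhibitory fraction of neurons
    excitatory_subclass_mix: dict = field(
        default_factory=lambda: {
            "L5-IT": 0.124,
            "L5-ET": 0.035,
            "L5-NP": 0.015,
            "L23P": 0.40,
            "L4P": 0.20,
            "L6P": 0.226,
        }
    )
    inhibitory_subclass_mix: dict = field(
        default_factory=lambda: {
            "PeriTC": 0.40,
            "DistTC": 0.40,
            "SparTC": 0.10,
            "InhTC": 0.10,
        }
    )
    # L5-ET output composition, fractions of synapses among *excitatory*
    # targets follow the printed mix; orphan_frac is the undetermined share.
    target_subclass_mix: dict = field(
        default_factory=lambda: {
            "L6P": 0.17,
            "L5-IT": 0.14,
            "L23P": 0.07,
            "L5-NP": 0.05,
            "L5-ET": 0.04,
        }
    )
    orphan_frac: float = 0.07
    lateral_radius: float = 250.0  # µm, target search radius
    distance_rule: DistanceRule = field(default_factory=DistanceRule)
    multiplicity: MultiplicityModel = field(default_factory=MultiplicityModel)
    size_model: SizeModel = field(default_factory=SizeModel)
    group_model: GroupModel = field(default_factory=GroupModel)
    axon_model: AxonModel = field(default_factory=AxonModel)
    bounds: tuple = ((-550.0, 550.0), (0.0, 900.0), (0.0, 523.0))
    seed: int = 0

    def validate(self) -> None:
        for name, mix in (
            ("excitatory_subclass_mix", self.excitatory_subclass_mix),
            ("inhibitory_subclass_mix", self.inhibitory_subclass_mix),
        ):
            total = sum(mix.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(not 0 <= v <= 1 for v in mix.values()):
                raise ValueError(f"{name} fractions must lie in [0, 1]")
        if not 0 <= self.class_mix <= 1:
            raise ValueError("class_mix must lie in [0, 1]")
        if self.distance_rule.d_scale <= 0:
            raise ValueError("d_scale must be positive")
        if self.multiplicity.inh_mean < 1 or self.multiplicity.exc_mean < 1:
            raise ValueError("multiplicity means must be >= 1")
        n_et = _apportion(
            round(self.n_neurons * (1 - self.class_mix)),
            list(self.excitatory_subclass_mix.values()),
        )[list(self.excitatory_subclass_mix).index("L5-ET")]
        if n_et == 0:
            raise ValueError("config yields zero L5-ET neurons")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key, sub in (
            ("distance_rule", DistanceRule),
            ("multiplicity", MultiplicityModel),
            ("size_model", SizeModel),
            ("group_model", GroupModel),
            ("axon_model", AxonModel),
        ):
            if key in d and isinstance(d[key], dict):
                sub_d = d[key]
                if key == "size_model" and "truncate_pairs" in sub_d:
                    sub_d["truncate_pairs"] = {
                        tuple(k.split("->")) if isinstance(k, str) else tuple(k): tuple(v)
                        for k, v in sub_d["truncate_pairs"].items()
                    }
                d[key] = sub(**sub_d)
        return cls(**d)


# layer depth bands (µm below pia)
LAYER_BANDS = {
    "L1": (0.0, 70.0),
    "L23": (70.0, 280.0),
    "L4": (280.0, 420.0),
    "L5": (420.0, 670.0),
    "L6": (670.0, 880.0),
}
SUBCLASS_LAYER = {
    "L23P": "L23",
    "L4P": "L4",
    "L5-IT": "L5",
    "L5-ET": "L5",
    "L5-NP": "L5",
    "L6P": "L6",
}


@dataclass
class GroundTruth:
    """Generator-side truth for recovery tests."""

    subclass: dict  # neuron_id -> true subclass
    group: dict  # interneuron id -> "group1"/"group2"
    et_target_fraction: dict  # interneuron id -> drawn Beta fraction
    config: dict
    provenance: pd.DataFrame  # synapse_id, distance_at_draw, class_drawn

    def to_json(self, path: Path | str) -> Path:
        path = Path(path)
        payload = {
            "subclass": {str(k): v for k, v in self.subclass.items()},
            "group": {str(k): v for k, v in self.group.items()},
            "et_target_fraction": {
                str(k): float(v) for k, v in self.et_target_fraction.items()
            },
            "config": _jsonable(self.config),
            "provenance": self.provenance.to_dict(orient="list"),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {
            ("->".join(k) if isinstance(k, tuple) else str(k)): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Elementary samplers
# ---------------------------------------------------------------------------


def _apportion(n: int, fractions: list[float]) -> np.ndarray:
    """Deterministic largest-remainder apportionment of n into len(fractions)."""
    fr = np.asarray(fractions, dtype=float)
    fr = fr / fr.sum()
    raw = fr * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def p_inhibitory(path_distance, rule: DistanceRule) -> np.ndarray:
    """Per-synapse probability that the target is inhibitory."""
    d = np.asarray(path_distance, dtype=float)
    lo, hi = rule.p_inh_distal, rule.p_inh_proximal
    return lo + (hi - lo) * special.expit((rule.d_half - d) / rule.d_scale)


def sample_target_class(path_distance, config: GeneratorConfig, rng) -> np.ndarray:
    """Bernoulli draw of target class at the given axonal path distance(s)."""
    p = p_inhibitory(path_distance, config.distance_rule)
    draw = rng.random(np.shape(p)) < p
    out = np.where(draw, "inhibitory", "excitatory")
    return out if out.shape else out.item()


@lru_cache(maxsize=64)
def _ztnb_mu(target_mean: float, r: float) -> float:
    """Negative-binomial mean whose zero-truncation has the target mean."""
    if target_mean <= 1.0:
        return 1e-9

    def f(mu):
        p0 = (r / (r + mu)) ** r
        return mu / (1 - p0) - target_mean

    return optimize.brentq(f, 1e-9, 10 * target_mean)


def _ztnb_draw(rng, mu: float, r: float, size: int) -> np.ndarray:
    """Zero-truncated negative binomial via resampling of zeros."""
    p = r / (r + mu)
    out = rng.negative_binomial(r, p, size=size)
    zeros = out == 0
    while zeros.any():
        out[zeros] = rng.negative_binomial(r, p, size=int(zeros.sum()))
        zeros = out == 0
    return out


def sample_connection_multiplicity(
    target_class: str, config: GeneratorConfig, rng, size: int | None = None
) -> np.ndarray | int:
    """Synapse count per connection: zero-truncated NB, clipped at the class max."""
    m = config.multiplicity
    if target_class == "inhibitory":
        mean, r, cap = m.inh_mean, m.inh_dispersion, m.inh_max
    else:
        mean, r, cap = m.exc_mean, m.exc_dispersion, m.exc_max
    n = 1 if size is None else size
    if mean <= 1.0:
        draws = np.ones(n, dtype=np.int64)
    else:
        draws = np.minimum(_ztnb_draw(rng, _ztnb_mu(mean, r), r, n), cap)
    return int(draws[0]) if size is None else draws


def _size_params(pre_sub: str, post_sub: str, model: SizeModel):
    mu, sig = model.pair_overrides.get((pre_sub, post_sub), (model.log_mean, model.log_sigma))
    band = model.truncate_pairs.get((pre_sub, post_sub))
    return mu, sig, band


def sample_synapse_size(
    pre_subclass: str,
    post_subclass: str,
    config: GeneratorConfig,
    rng,
    size: int | None = None,
) -> np.ndarray | int:
    """Positive integer voxel counts from the per-pair lognormal model."""
    mu, sig, band = _size_params(pre_subclass, post_subclass, config.size_model)
    n = 1 if size is None else size
    draws = rng.lognormal(mu, sig, size=n)
    if band is not None:
        lo = stats.lognorm.ppf(band[0], sig, scale=np.exp(mu))
        hi = stats.lognorm.ppf(band[1], sig, scale=np.exp(mu))
        bad = (draws < lo) | (draws > hi)
        while bad.any():
            draws[bad] = rng.lognormal(mu, sig, size=int(bad.sum()))
            bad = (draws < lo) | (draws > hi)
    out = np.maximum(np.round(draws).astype(np.int64), 1)
    return int(out[0]) if size is None else out


# ---------------------------------------------------------------------------
# Axon skeletons
# ---------------------------------------------------------------------------


def _random_unit(rng, n=1):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_axon_skeleton(
    soma,
    config: GeneratorConfig,
    rng,
    *,
    cable_length: float | None = None,
    collateral: bool | None = None,
    inhibitory: bool = False,
) -> Skeleton:
    """Grow a rooted axon tree from the soma by a branching persistent walk.

    ``soma`` is any mapping with ``x``, ``y``, ``z`` (µm).  L5-ET axons cross
    the area border (plane x = border_x) iff ``collateral``; non-collateral
    axons are reflected at the border.  The walk stops once the drawn cable
    budget is spent.
    """
    am = config.axon_model
    bounds = np.asarray(config.bounds, dtype=float)
    border_x = 0.0
    soma_xyz = np.array([soma["x"], soma["y"], soma["z"]], dtype=float)
    side = 1.0 if soma_xyz[0] >= border_x else -1.0

    if cable_length is None:
        mean = am.inh_cable_mean if inhibitory else am.cable_mean
        sd = am.inh_cable_sd if inhibitory else am.cable_sd
        cable_length = max(float(rng.normal(mean, sd)), am.cable_min)
    if collateral is None:
        collateral = (not inhibitory) and (
            rng.random() < am.interareal_collateral_prob
        )

    xyz = [soma_xyz]
    parent = [-1]
    comp = [1]  # root = soma
    # active tips: (node index, direction, collateral flag)
    tips: list[list] = []
    n_primary = max(am.n_primary, 1)
    dirs = _random_unit(rng, n_primary)
    dirs[:, 1] = np.abs(dirs[:, 1]) * 0.5 + 0.2  # mild downward bias
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    collateral_tip = int(rng.integers(n_primary)) if collateral else -1
    for k in range(n_primary):
        tips.append([0, dirs[k], k == collateral_tip])

    cable = 0.0
    crossed = False
    alpha = am.persistence
    noise_scale = np.sqrt(max(1.0 - alpha**2, 1e-9))
    while cable < cable_length and tips:
        new_tips = []
        for node_idx, direction, is_coll in tips:
            if cable >= cable_length:
                break
            d = alpha * direction + noise_scale * _random_unit(rng)[0]
            if is_coll and not crossed:
                d[0] -= side * 0.6  # steer toward the border
            d /= np.linalg.norm(d)
            pos = xyz[node_idx] + am.step * d
            # reflect at the volume bounds
            for ax in range(3):
                if pos[ax] < bounds[ax, 0]:
                    pos[ax] = 2 * bounds[ax, 0] - pos[ax]
                    d[ax] = -d[ax]
                elif pos[ax] > bounds[ax, 1]:
                    pos[ax] = 2 * bounds[ax, 1] - pos[ax]
                    d[ax] = -d[ax]
            # non-collateral tips never cross the area border
            if not is_coll and (pos[0] - border_x) * side < 0:
                pos[0] = 2 * border_x - pos[0]
                d[0] = -d[0]
            if is_coll and (pos[0] - border_x) * side < 0:
                crossed = True
            xyz.append(pos)
            parent.append(node_idx)
            comp.append(2)
            cable += am.step
            new_idx = len(xyz) - 1
            step_len = am.step
            if rng.random() < am.term_rate * step_len and len(tips) + len(new_tips) > 1:
                continue
            new_tips.append([new_idx, d, is_coll])
            if rng.random() < am.branch_rate * step_len:
                bd = alpha * d + noise_scale * _random_unit(rng)[0]
                bd /= np.linalg.norm(bd)
                new_tips.append([new_idx, bd, False])
        if not new_tips:  # restart from a random node to finish the budget
            idx = int(rng.integers(len(xyz)))
            new_tips.append([idx, _random_unit(rng)[0], False])
        tips = new_tips

    n = len(xyz)
    node_ids = np.arange(1, n + 1, dtype=np.int64)
    parent_ids = np.array([-1 if p == -1 else p + 1 for p in parent], dtype=np.int64)
    return Skeleton(
        node_ids=node_ids,
        xyz=np.asarray(xyz),
        radius=np.full(n, 0.3),
        compartment=np.asarray(comp, dtype=np.int64),
        parent=parent_ids,
    )


# ---------------------------------------------------------------------------
# Neuron table
# ---------------------------------------------------------------------------


def _place_neurons(config: GeneratorConfig, rng) -> pd.DataFrame:
    n = config.n_neurons
    n_inh = int(round(n * config.class_mix))
    n_exc = n - n_inh
    exc_names = list(config.excitatory_subclass_mix)
    inh_names = list(config.inhibitory_subclass_mix)
    exc_counts = _apportion(n_exc, list(config.excitatory_subclass_mix.values()))
    inh_counts = _apportion(n_inh, list(config.inhibitory_subclass_mix.values()))

    subclasses = np.concatenate(
        [np.repeat(exc_names, exc_counts), np.repeat(inh_names, inh_counts)]
    )
    classes = np.where(
        np.isin(subclasses, list(EXC_SUBCLASSES)), "excitatory", "inhibitory"
    )
    bounds = np.asarray(config.bounds)
    x = rng.uniform(bounds[0, 0], bounds[0, 1], size=n)
    z = rng.uniform(bounds[2, 0], bounds[2, 1], size=n)
    y = np.empty(n)
    layers = np.empty(n, dtype=object)
    for i, sub in enumerate(subclasses):
        if sub in SUBCLASS_LAYER:
            layer = SUBCLASS_LAYER[sub]
        else:  # interneurons across L23-L6
            layer = ["L23", "L4", "L5", "L6"][int(rng.integers(4))]
        lo, hi = LAYER_BANDS[layer]
        y[i] = rng.uniform(lo, hi)
        layers[i] = layer
    area = np.where(x < 0.0, "VISp", "HVA")
    proof = np.where(
        subclasses == "L5-ET",
        "clean_axon_comprehensive",
        np.where(classes == "inhibitory", "clean_axon_extended", "clean_dendrite"),
    )
    return pd.DataFrame(
        {
            "neuron_id": np.arange(1, n + 1, dtype=np.int64),
            "x": x,
            "y": y,
            "z": z,
            "area": area,
            "layer": layers,
            "cell_class": classes,
            "subclass": subclasses,
            "proofread_status": proof,
        }
    )


# ---------------------------------------------------------------------------
# L5-ET outputs
# ---------------------------------------------------------------------------


class _LateralIndex:
    """Per-subclass KD-trees over soma positions in the lateral (x, z) plane."""

    def __init__(self, neurons: pd.DataFrame):
        from scipy.spatial import cKDTree

        self.trees = {}
        self.ids = {}
        for sub, grp in neurons.groupby("subclass"):
            pts = grp[["x", "z"]].to_numpy()
            self.trees[sub] = cKDTree(pts)
            self.ids[sub] = grp["neuron_id"].to_numpy()

    def pick(self, sub: str, xz: np.ndarray, radius: float, rng,
             exclude: int = -1, used: set | None = None):
        """One target of the given subclass near xz.

        Candidates already in ``used`` (per-presynaptic-cell connection
        partners) are avoided so each (pre, post) pair forms one connection;
        the search widens (nearest unused, then any unused) before falling
        back to reuse.
        """
        tree = self.trees.get(sub)
        if tree is None:
            return None
        used = used or set()
        ball = [c for c in tree.query_ball_point(xz, radius)
                if self.ids[sub][c] != exclude]
        cand = [c for c in ball if int(self.ids[sub][c]) not in used]
        if not cand:
            k = min(50, len(self.ids[sub]))
            _, idx = tree.query(xz, k=k)
            cand = [
                int(i) for i in np.atleast_1d(idx)
                if self.ids[sub][int(i)] != exclude
                and int(self.ids[sub][int(i)]) not in used
            ]
        if not cand:
            fresh = [i for i, nid in enumerate(self.ids[sub])
                     if nid != exclude and int(nid) not in used]
            cand = fresh or ball
            if not cand:
                return None
        return int(self.ids[sub][cand[int(rng.integers(len(cand)))]])


_EXC_COMPARTMENTS = (("spine", 0.90), ("shaft", 0.08), ("soma", 0.01), ("other", 0.01))
_INH_COMPARTMENTS = (("shaft", 0.62), ("spine", 0.35), ("soma", 0.01), ("soma_spine", 0.01), ("other", 0.01))


def _draw_compartment(rng, table) -> str:
    names, probs = zip(*table)
    return names[int(rng.choice(len(names), p=np.asarray(probs) / sum(probs)))]


def _connection_prob_inh(p_syn: float, config: GeneratorConfig) -> float:
    """Connection-level inhibitory probability whose synapse-level marginal is p_syn.

    Connections carry class-dependent multiplicities, so drawing classes per
    connection at probability p_syn would inflate the synapse-level inhibitory
    fraction by the multiplicity ratio; this inverts that mapping.
    """
    m_i = config.multiplicity.inh_mean
    m_e = config.multiplicity.exc_mean
    return p_syn * m_e / (m_i * (1 - p_syn) + p_syn * m_e)


def _generate_et_outputs(
    et_row: pd.Series,
    skel: Skeleton,
    config: GeneratorConfig,
    rng,
    index: _LateralIndex,
    interneurons: pd.DataFrame,
    groups: dict,
):
    """Synapse rows for one L5-ET axon, in path-distance order.

    Returns (rows, provenance) where rows are dicts missing only synapse_id.
    """
    am = config.axon_model
    n_syn = int(
        np.clip(round(rng.normal(am.synapses_mean, am.synapses_sd)),
                am.synapses_min, am.synapses_max)
    )
    dist = skel.path_distances_to_root()
    lengths = skel.edge_lengths()
    w = lengths / lengths.sum()
    slot_nodes = rng.choice(skel.n_nodes, size=n_syn, p=w)
    slot_nodes = slot_nodes[np.argsort(dist[slot_nodes], kind="stable")]
    slot_dist = dist[slot_nodes]
    slot_xyz = skel.xyz[slot_nodes] + rng.normal(0, 1.0, size=(n_syn, 3))

    g2_ids = interneurons.loc[
        [groups[i] == "group2" for i in interneurons["neuron_id"]], "neuron_id"
    ].to_numpy()
    g1_ids = interneurons.loc[
        [groups[i] == "group1" for i in interneurons["neuron_id"]], "neuron_id"
    ].to_numpy()
    exc_names = list(config.target_subclass_mix)
    exc_probs = np.asarray(list(config.target_subclass_mix.values()), dtype=float)
    exc_probs /= exc_probs.sum()
    pre_id = int(et_row["neuron_id"])

    rows, provenance = [], []
    used_inh: set[int] = set()
    used_exc: set[int] = set()
    i = 0
    while i < n_syn:
        d = float(slot_dist[i])
        if rng.random() < config.orphan_frac:
            rows.append(
                dict(
                    pre_id=pre_id,
                    post_id=None,
                    x=slot_xyz[i, 0], y=slot_xyz[i, 1], z=slot_xyz[i, 2],
                    size_voxels=sample_synapse_size("L5-ET", "unknown", config, rng),
                    post_compartment="orphan_spine",
                    pre_node=int(skel.node_ids[slot_nodes[i]]),
                )
            )
            provenance.append((d, "orphan"))
            i += 1
            continue
        p_syn = float(p_inhibitory(d, config.distance_rule))
        inh = rng.random() < _connection_prob_inh(p_syn, config)
        if inh:
            gshare = config.group_model.group2_synapse_share
            use_g2 = (rng.random() < gshare and len(g2_ids)) or not len(g1_ids)
            pool = g2_ids if use_g2 else g1_ids
            fresh = pool[~np.isin(pool, list(used_inh))]
            pool = fresh if len(fresh) else pool
            target = int(pool[int(rng.integers(len(pool)))])
            used_inh.add(target)
            m = sample_connection_multiplicity("inhibitory", config, rng)
            comp_table = _INH_COMPARTMENTS
            post_sub = "inhibitory"
        else:
            sub = exc_names[int(rng.choice(len(exc_names), p=exc_probs))]
            target = index.pick(sub, slot_xyz[i, [0, 2]], config.lateral_radius, rng,
                                exclude=pre_id, used=used_exc)
            if target is None:
                i += 1
                continue
            used_exc.add(target)
            m = sample_connection_multiplicity("excitatory", config, rng)
            comp_table = _EXC_COMPARTMENTS
            post_sub = sub
        m = min(m, n_syn - i)
        for k in range(m):
            rows.append(
                dict(
                    pre_id=pre_id,
                    post_id=target,
                    x=slot_xyz[i + k, 0], y=slot_xyz[i + k, 1], z=slot_xyz[i + k, 2],
                    size_voxels=sample_synapse_size(
                        "L5-ET", post_sub if post_sub != "inhibitory" else "PeriTC",
                        config, rng),
                    post_compartment=_draw_compartment(rng, comp_table),
                    pre_node=int(skel.node_ids[slot_nodes[i + k]]),
                )
            )
            provenance.append((float(slot_dist[i + k]),
                               "inhibitory" if inh else "excitatory"))
        i += m
    return rows, provenance


# ---------------------------------------------------------------------------
# Interneuron outputs
# ---------------------------------------------------------------------------

# per-subclass output profile: (distance model, compartment table, multiplicity)
_IN_PROFILE = {
    "PeriTC": dict(
        dist=("halfnormal", 22.0),
        compartments=(("soma", 0.35), ("shaft", 0.38), ("spine", 0.20), ("soma_spine", 0.07)),
        mult_mean=3.2, mult_max=12, apical_frac=0.05, frac_onto_inh=0.10,
    ),
    "DistTC": dict(
        dist=("shifted_exp", 55.0, 85.0),
        compartments=(("spine", 0.55), ("shaft", 0.43), ("soma", 0.01), ("soma_spine", 0.01)),
        mult_mean=2.2, mult_max=10, apical_frac=0.55, frac_onto_inh=0.10,
    ),
    "SparTC": dict(
        dist=("shifted_exp", 20.0, 70.0),
        compartments=(("spine", 0.50), ("shaft", 0.50)),
        mult_mean=1.0, mult_max=1, apical_frac=0.20, frac_onto_inh=0.15,
    ),
    "InhTC": dict(
        dist=("shifted_exp", 10.0, 50.0),
        compartments=(("shaft", 0.80), ("spine", 0.20)),
        mult_mean=1.5, mult_max=6, apical_frac=0.10, frac_onto_inh=0.75,
    ),
}


def _draw_offset_distance(rng, spec_):
    if spec_[0] == "halfnormal":
        return abs(rng.normal(0, spec_[1]))
    return spec_[1] + rng.exponential(spec_[2])


def _synapse_position(target_xyz, rng, profile):
    """Cleft position near the target soma, per the subclass placement profile."""
    r = _draw_offset_distance(rng, profile["dist"])
    u = _random_unit(rng)[0]
    apical = rng.random() < profile["apical_frac"]
    if apical:
        u[1] = -abs(u[1]) - 0.5  # above the soma, toward the pia
        u /= np.linalg.norm(u)
    return target_xyz + r * u, r, apical


def generate_interneuron_outputs(
    config: GeneratorConfig,
    rng,
    neurons: pd.DataFrame,
    skeletons: dict[int, Skeleton],
    groups: dict,
    fractions: dict,
    forced_returns: list[tuple[int, int]],
    partners_by_in: dict | None = None,
):
    """Synapse rows for every interneuron axon.

    Each interneuron's ET-targeting output fraction was drawn from the Beta
    mixture upstream (``fractions``); this routine realises those outputs and
    the explicit reciprocal returns (``forced_returns``: (interneuron, ET)
    pairs that must receive at least one return connection).  ET-directed
    synapses other than forced returns go to ETs that are *not* presynaptic
    partners, so the measured reciprocal rate reflects the configured
    probabilities.
    """
    from scipy.spatial import cKDTree

    soma = neurons.set_index("neuron_id")[["x", "y", "z"]]
    sub_of = neurons.set_index("neuron_id")["subclass"]
    et_ids = neurons.loc[neurons["subclass"] == "L5-ET", "neuron_id"].to_numpy()
    exc_non_et = neurons.loc[
        (neurons["cell_class"] == "excitatory") & (neurons["subclass"] != "L5-ET"),
        "neuron_id",
    ].to_numpy()
    inh_ids = neurons.loc[neurons["cell_class"] == "inhibitory", "neuron_id"].to_numpy()
    gm = config.group_model

    forced_by_in: dict[int, list[int]] = {}
    for in_id, et_id in forced_returns:
        forced_by_in.setdefault(in_id, []).append(et_id)

    rows = []
    for in_id in sorted(fractions):
        profile = _IN_PROFILE[str(sub_of.loc[in_id])]
        skel = skeletons[in_id]
        node_tree = cKDTree(skel.xyz)
        n_out = int(max(round(rng.normal(gm.outputs_mean, gm.outputs_sd)), 60))
        f_et = float(fractions[in_id])
        n_et = int(round(f_et * n_out))

        # every ET already presynaptic to this interneuron is excluded from the
        # free ET-directed draws, so reciprocity is exactly the forced set
        partners = set((partners_by_in or {}).get(in_id, []))
        partners |= set(forced_by_in.get(in_id, []))
        et_connections: list[int] = list(forced_by_in.get(in_id, []))
        non_partner_ets = np.asarray([e for e in et_ids if e not in partners])

        def emit(target_id, n_syn_conn, inhibitory_target=False):
            txyz = soma.loc[target_id].to_numpy(dtype=float)
            anchor, _, _ = _synapse_position(txyz, rng, profile)
            for _ in range(n_syn_conn):
                pos = anchor + rng.normal(0, 4.0, size=3)
                node_idx = int(node_tree.query(pos)[1])
                rows.append(
                    dict(
                        pre_id=int(in_id),
                        post_id=int(target_id),
                        x=pos[0], y=pos[1], z=pos[2],
                        size_voxels=sample_synapse_size(
                            str(sub_of.loc[in_id]), str(sub_of.loc[target_id]),
                            config, rng),
                        post_compartment=_draw_compartment(rng, profile["compartments"]),
                        pre_node=int(skel.node_ids[node_idx]),
                    )
                )

        def mult():
            if profile["mult_mean"] <= 1.0:
                return 1
            mu = _ztnb_mu(profile["mult_mean"], 1.0)
            return int(min(_ztnb_draw(rng, mu, 1.0, 1)[0], profile["mult_max"]))

        n_emitted_et = 0
        for et in et_connections:
            m = mult()
            emit(et, m)
            n_emitted_et += m
        while n_emitted_et < n_et and len(non_partner_ets):
            et = int(non_partner_ets[int(rng.integers(len(non_partner_ets)))])
            m = min(mult(), n_et - n_emitted_et)
            emit(et, m)
            n_emitted_et += m
        # non-ET outputs
        n_rest = max(n_out - n_emitted_et, 0)
        emitted = 0
        while emitted < n_rest:
            if rng.random() < profile["frac_onto_inh"] and len(inh_ids) > 1:
                tid = int(inh_ids[int(rng.integers(len(inh_ids)))])
                if tid == in_id:
                    continue
            else:
                tid = int(exc_non_et[int(rng.integers(len(exc_non_et)))])
            m = min(mult(), n_rest - emitted)
            emit(tid, m)
            emitted += m
    return rows


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------


def generate_connectome(config: GeneratorConfig, seed: int | None = None):
    """Generate a full synthetic connectome plus ground truth.

    Deterministic given (config, seed).
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    neurons = _place_neurons(config, rng)
    index = _LateralIndex(neurons)
    interneurons = neurons[neurons["cell_class"] == "inhibitory"]
    et_cells = neurons[neurons["subclass"] == "L5-ET"]

    # group structure
    gm = config.group_model
    groups, fractions = {}, {}
    for in_id in interneurons["neuron_id"]:
        if rng.random() < gm.group2_weight:
            groups[int(in_id)] = "group2"
            fractions[int(in_id)] = float(rng.beta(*gm.beta_group2))
        else:
            groups[int(in_id)] = "group1"
            fractions[int(in_id)] = float(rng.beta(*gm.beta_group1))

    skeletons: dict[int, Skeleton] = {}
    rows: list[dict] = []
    provenance: list[tuple] = []

    for _, et_row in et_cells.iterrows():
        skel = generate_axon_skeleton(et_row, config, rng)
        skeletons[int(et_row["neuron_id"])] = skel
        r, p = _generate_et_outputs(
            et_row, skel, config, rng, index, interneurons, groups
        )
        rows.extend(r)
        provenance.extend(p)

    # reciprocal flags per connected (ET -> interneuron) pair
    pairs = sorted(
        {
            (row["pre_id"], row["post_id"])
            for row in rows
            if row["post_id"] is not None and int(row["post_id"]) in groups
        }
    )
    forced_returns = []
    partners_by_in: dict[int, list[int]] = {}
    for et_id, in_id in pairs:
        partners_by_in.setdefault(int(in_id), []).append(int(et_id))
        p_r = gm.recip_p_group2 if groups[int(in_id)] == "group2" else gm.recip_p_group1
        if rng.random() < p_r:
            forced_returns.append((int(in_id), int(et_id)))

    for _, in_row in interneurons.iterrows():
        skeletons[int(in_row["neuron_id"])] = generate_axon_skeleton(
            in_row, config, rng, inhibitory=True
        )
    in_rows = generate_interneuron_outputs(
        config, rng, neurons, skeletons, groups, fractions, forced_returns,
        partners_by_in=partners_by_in,
    )
    rows.extend(in_rows)
    provenance.extend([(np.nan, "interneuron_output")] * len(in_rows))

    synapses = pd.DataFrame(rows)
    synapses.insert(0, "synapse_id", np.arange(1, len(rows) + 1, dtype=np.int64))
    prov = pd.DataFrame(
        {
            "synapse_id": synapses["synapse_id"],
            "distance_at_draw": [p[0] for p in provenance],
            "class_drawn": [p[1] for p in provenance],
        }
    )
    geometry = VolumeGeometry(bounds=np.asarray(config.bounds))
    # clip cleft jitter back into the volume
    for ax, col in enumerate(("x", "y", "z")):
        synapses[col] = synapses[col].clip(geometry.bounds[ax, 0], geometry.bounds[ax, 1])

    connectome = Connectome(
        neurons=neurons, synapses=synapses, skeletons=skeletons, geometry=geometry
    )
    truth = GroundTruth(
        subclass={int(r.neuron_id): r.subclass for r in neurons.itertuples()},
        group=groups,
        et_target_fraction=fractions,
        config=config.to_dict(),
        provenance=prov,
    )
    return connectome, truth


# ---------------------------------------------------------------------------
# Light-weight cohort generator for the potential-synapse shuffle
# ---------------------------------------------------------------------------


def generate_shuffle_cohort(
    rng,
    n_cells: int = 12,
    n_synapses: int = 300,
    n_sites: int = 320_000,
    box: float = 150.0,
    subclass_mix: dict | None = None,
    preference: dict | None = None,
):
    """A candidate-site field plus observed output profiles for shuffle tests.

    Candidate postsynaptic sites are scattered uniformly in a cube of side
    ``box`` µm with subclass labels drawn from ``subclass_mix`` (default: the
    L5-ET excitatory target composition, normalised).  Each presynaptic cell's
    observed synapses sit exactly on candidate sites.  With ``preference``
    absent, observed sites are picked uniformly, so the observed profile is
    one more draw from the shuffle null (abundance-only).  ``preference`` maps
    a subclass to a target fold-enrichment x: observed synapses then pick a
    site of that subclass with the extra probability needed to make the
    observed count x times the abundance expectation.

    Returns ``(site_xyz, site_subclass, site_owner, observed)`` where
    ``observed`` maps cell id -> DataFrame(columns x, y, z, target_subclass).
    """
    if subclass_mix is None:
        subclass_mix = {"L6P": 0.17, "L5-IT": 0.14, "L23P": 0.07,
                        "L5-NP": 0.05, "L5-ET": 0.04}
    names = list(subclass_mix)
    probs = np.asarray(list(subclass_mix.values()), dtype=float)
    probs /= probs.sum()

    site_xyz = rng.uniform(0.0, box, size=(n_sites, 3))
    site_code = rng.choice(len(names), size=n_sites, p=probs)
    site_subclass = np.asarray(names, dtype=object)[site_code]
    site_owner = rng.integers(10_000, 20_000, size=n_sites)  # synthetic target ids

    pick_extra = None
    if preference:
        (sub, fold), = preference.items()
        p_sub = probs[names.index(sub)]
        pi = (fold - 1.0) * p_sub / (1.0 - p_sub)
        if not 0 <= pi <= 1:
            raise ValueError("infeasible preference fold for this abundance")
        pool = np.nonzero(site_subclass == sub)[0]
        pick_extra = (pool, pi)

    observed = {}
    for cell in range(1, n_cells + 1):
        idx = rng.integers(n_sites, size=n_synapses)
        if pick_extra is not None:
            pool, pi = pick_extra
            use = rng.random(n_synapses) < pi
            idx[use] = pool[rng.integers(len(pool), size=int(use.sum()))]
        observed[cell] = pd.DataFrame(
            {
                "x": site_xyz[idx, 0],
                "y": site_xyz[idx, 1],
                "z": site_xyz[idx, 2],
                "target_subclass": site_subclass[idx],
            }
        )
    return site_xyz, site_subclass, site_owner, observed
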