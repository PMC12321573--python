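"""Potential-synapse spatial shuffle null.

For every observed output synapse onto an excitatory cell, the candidate set
is every postsynaptic site within a small radius (default 5 µm, a typical
upper bound on spine length) that belongs to a cell with an assigned
excitatory subclass.  Shuffled connectivity profiles draw one candidate per
observed synapse, which normalises for axon trajectory, local target-site
density and reconstruction completeness; comparing observed subclass counts
to the shuffled distribution measures cell-type-specific enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .core_model import Connectome, EXC_SUBCLASSES

logger = logging.getLogger("l5et")

DEFAULT_RADIUS = 5.0  # µm
DEFAULT_REPLICATES = 10_000


# ---------------------------------------------------------------------------
# Candidate index
# ---------------------------------------------------------------------------


@dataclass
class CandidateIndex:
    """Spatial index over postsynaptic sites on excitatory-subclass cells."""

    xyz: np.ndarray  # (n, 3) µm
    subclass: np.ndarray  # (n,) object
    owner: np.ndarray  # (n,) target neuron id
    tree: cKDTree

    @classmethod
    def from_arrays(cls, xyz, subclass, owner) -> "CandidateIndex":
        xyz = np.asarray(xyz, dtype=float)
        subclass = np.asarray(subclass, dtype=object)
        owner = np.asarray(owner, dtype=np.int64)
        bad = ~np.isin(subclass, list(EXC_SUBCLASSES))
        if bad.any():
            raise ValueError(
                "all candidate sites must belong to excitatory-subclass cells"
            )
        return cls(xyz=xyz, subclass=subclass, owner=owner, tree=cKDTree(xyz))

    @classmethod
    def from_connectome(cls, connectome: Connectome) -> "CandidateIndex":
        """Index every synapse whose target has an assigned excitatory subclass."""
        sub_of = connectome.subclass_of()
        syn = connectome.synapses
        attached = syn[syn["post_id"].notna()].copy()
        attached["sub"] = attached["post_id"].astype(np.int64).map(sub_of)
        keep = attached[attached["sub"].isin(list(EXC_SUBCLASSES))]
        return cls.from_arrays(
            keep[["x", "y", "z"]].to_numpy(dtype=float),
            keep["sub"].to_numpy(dtype=object),
            keep["post_id"].astype(np.int64).to_numpy(),
        )


def potential_synapses(
    site,
    index: CandidateIndex,
    radius: float = DEFAULT_RADIUS,
    exclude_owner: int | None = None,
) -> np.ndarray:
    """Indices of all candidate sites within ``radius`` of ``site`` (inclusive).

    ``exclude_owner`` removes sites on a given cell (autapse candidates).
    """
    idx = np.asarray(index.tree.query_ball_point(np.asarray(site, dtype=float),
                                                 radius), dtype=np.int64)
    if exclude_owner is not None and len(idx):
        idx = idx[index.owner[idx] != exclude_owner]
    return np.sort(idx)


# ---------------------------------------------------------------------------
# Shuffle profiles
# ---------------------------------------------------------------------------


@dataclass
class ShuffleResult:
    cell: int
    observed: pd.Series  # observed subclass counts
    shuffled: pd.DataFrame  # n_replicates x subclasses counts
    n_replicates: int
    n_skipped: int  # observed synapses with empty neighbourhoods

    def median_shuffled(self) -> pd.Series:
        return self.shuffled.median(axis=0)

    def ratios(self, pseudocount: float = 0.5):
        """Observed / median-shuffled count ratio per subclass.

        When the shuffled median is zero a pseudocount is added to both
        numerator and denominator, and the subclass is flagged.
        """
        med = self.median_shuffled()
        flagged = []
        vals = {}
        for sub in med.index:
            o, m = float(self.observed.get(sub, 0)), float(med[sub])
            if m == 0:
                o, m = o + pseudocount, m + pseudocount
                flagged.append(sub)
            vals[sub] = o / m
        return pd.Series(vals), flagged


def shuffle_profiles(
    cell: int,
    observed: pd.DataFrame,
    index: CandidateIndex,
    n: int = DEFAULT_REPLICATES,
    seed: int = 0,
    radius: float = DEFAULT_RADIUS,
    exclude_self: bool = True,
    subclasses: tuple = EXC_SUBCLASSES,
) -> ShuffleResult:
    """Shuffled target-subclass profiles for one presynaptic cell.

    ``observed`` lists the cell's output synapses onto excitatory targets
    (columns x, y, z, target_subclass); inhibitory-target synapses must be
    excluded upstream.  Each replicate redraws one candidate uniformly from
    every observed synapse's neighbourhood; synapses with empty
    neighbourhoods are skipped (counted in ``n_skipped``).
    """
    rng = np.random.default_rng(seed)
    code_of = {s: i for i, s in enumerate(subclasses)}
    site_codes = np.array([code_of[s] for s in index.subclass], dtype=np.int8)

    pos = observed[["x", "y", "z"]].to_numpy(dtype=float)
    neighbourhoods = []
    n_skipped = 0
    kept_rows = []
    for i in range(len(pos)):
        cand = potential_synapses(
            pos[i], index, radius, exclude_owner=cell if exclude_self else None
        )
        if len(cand) == 0:
            n_skipped += 1
            continue
        neighbourhoods.append(cand)
        kept_rows.append(i)
    if not neighbourhoods:
        raise ValueError(f"cell {cell}: all candidate neighbourhoods are empty")
    if n_skipped:
        logger.info("cell %s: %d synapses skipped (empty neighbourhood)",
                    cell, n_skipped)

    n_syn = len(neighbourhoods)
    # cumulative subclass probabilities per synapse -> vectorised categorical
    cum = np.zeros((n_syn, len(subclasses)))
    for i, cand in enumerate(neighbourhoods):
        counts = np.bincount(site_codes[cand], minlength=len(subclasses))
        cum[i] = np.cumsum(counts / counts.sum())
    u = rng.random((n_syn, n))
    codes = (u[:, :, None] > cum[:, None, :]).sum(axis=2).astype(np.int32)
    flat = (np.arange(n, dtype=np.int64)[None, :] * len(subclasses) + codes).ravel()
    counts = np.bincount(flat, minlength=n * len(subclasses)).reshape(
        n, len(subclasses)
    )
    shuffled = pd.DataFrame(counts, columns=list(subclasses))

    obs_counts = (
        observed.iloc[kept_rows]["target_subclass"].value_counts()
        .reindex(list(subclasses), fill_value=0)
    )
    return ShuffleResult(
        cell=int(cell),
        observed=obs_counts,
        shuffled=shuffled,
        n_replicates=n,
        n_skipped=n_skipped,
    )


def observed_excitatory_outputs(cell: int, connectome: Connectome) -> pd.DataFrame:
    """The cell's output synapses onto excitatory-subclass targets."""
    sub_of = connectome.subclass_of()
    out = connectome.outputs_of(int(cell))
    attached = out[out["post_id"].notna()].copy()
    attached["target_subclass"] = attached["post_id"].astype(np.int64).map(sub_of)
    keep = attached[attached["target_subclass"].isin(list(EXC_SUBCLASSES))]
    return keep[["x", "y", "z", "target_subclass"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------


def enrichment_stats(
    results: list[ShuffleResult],
    subclasses: tuple = EXC_SUBCLASSES,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-subclass median observed/shuffle ratio and Wilcoxon signed-rank p.

    The test is two-sided on per-cell log ratios (exact distribution for
    n <= 25).  Subclasses absent from every observed and shuffled profile
    are omitted with a note.
    """
    if len(results) < 6:
        logger.warning("signed-rank test on %d cells is weak", len(results))
    per_cell = []
    for res in results:
        ratios, flagged = res.ratios(pseudocount)
        per_cell.append((res, ratios, set(flagged), res.median_shuffled()))
    rows = []
    for sub in subclasses:
        log_ratios, flagged_any = [], False
        present = False
        for res, ratios, flagged, med in per_cell:
            if float(res.observed.get(sub, 0)) > 0 or float(med.get(sub, 0)) > 0:
                present = True
            if sub in flagged:
                flagged_any = True
            log_ratios.append(np.log(ratios[sub]))
        if not present:
            logger.info("subclass %s absent everywhere; omitted", sub)
            continue
        lr = np.asarray(log_ratios)
        if np.allclose(lr, 0):
            p = 1.0
        else:
            method = "exact" if len(lr) <= 25 else "auto"
            try:
                p = float(stats.wilcoxon(lr, alternative="two-sided",
                                         method=method).pvalue)
            except ValueError:  # ties/zeros force the normal approximation
                p = float(stats.wilcoxon(lr, alternative="two-sided",
                                         method="approx").pvalue)
        rows.append(
            {
                "subclass": sub,
                "median_ratio": float(np.exp(np.median(lr))),
                "wilcoxon_p": p,
                "n_cells": len(lr),
                "pseudocount_used": flagged_any,
            }
        )
    return pd.DataFrame(rows).set_index("subclass")
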