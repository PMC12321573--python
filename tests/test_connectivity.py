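"""Descriptive connectivity analyses: fractions, groups, distances, matrices."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from l5et import connectivity as ca
from l5et.core_model import Skeleton

from conftest import build_connectome, neuron_row, straight_skeleton, synapse_row, y_skeleton


def _toy(neurons, synapses, skeletons=None):
    return build_connectome(neurons=neurons, synapses=synapses, skeletons=skeletons)


class TestOutputClassFractions:
    def test_seven_of_ten(self):
        neurons = [neuron_row(1, subclass="L5-ET")]
        neurons += [neuron_row(10 + i, x=10, subclass="PeriTC", cell_class="inhibitory")
                    for i in range(7)]
        neurons += [neuron_row(20 + i, x=-10, subclass="L5-IT") for i in range(3)]
        syn = [synapse_row(i + 1, 1, 10 + i) for i in range(7)]
        syn += [synapse_row(8 + i, 1, 20 + i) for i in range(3)]
        conn = _toy(neurons, syn)
        n_exc, n_inh, n_und, frac = ca.output_class_fractions(1, conn)
        assert (n_exc, n_inh, n_und) == (3, 7, 0)
        assert frac == pytest.approx(0.7)

    def test_counts_conserve_total(self, default_connectome):
        conn, _ = default_connectome
        cell = int(conn.neurons.loc[conn.neurons["subclass"] == "L5-ET",
                                    "neuron_id"].iloc[0])
        n_exc, n_inh, n_und, _ = ca.output_class_fractions(cell, conn)
        assert n_exc + n_inh + n_und == len(conn.outputs_of(cell))

    def test_proximal_100_median_two_thirds(self, default_connectome):
        """Proximal-axon replication: median inhibitory fraction ~ 2/3."""
        conn, _ = default_connectome
        ets = conn.neurons.loc[conn.neurons["subclass"] == "L5-ET", "neuron_id"]
        fracs = [
            ca.output_class_fractions(int(c), conn, proximal_n=100)[3] for c in ets
        ]
        assert abs(np.median(fracs) - 2 / 3) <= 0.08


class TestGroupPartition:
    def _interneuron_with_fraction(self, n_et_syn, n_total):
        neurons = [
            neuron_row(1, subclass="PeriTC", cell_class="inhibitory"),
            neuron_row(2, x=10, subclass="L5-ET"),
            neuron_row(3, x=-10, subclass="L5-IT"),
        ]
        syn = [synapse_row(i + 1, 1, 2) for i in range(n_et_syn)]
        syn += [synapse_row(n_et_syn + i + 1, 1, 3) for i in range(n_total - n_et_syn)]
        return _toy(neurons, syn)

    def test_boundary_quarter_is_group2(self):
        conn = self._interneuron_with_fraction(250, 1000)
        part = ca.partition_groups([1], conn)
        assert part.labels[1] == "group2"

    def test_just_below_threshold_is_group1(self):
        conn = self._interneuron_with_fraction(249, 1000)
        part = ca.partition_groups([1], conn)
        assert part.fractions[1] == pytest.approx(0.249)
        assert part.labels[1] == "group1"

    def test_threshold_monotone(self):
        conn = self._interneuron_with_fraction(300, 1000)
        low = ca.partition_groups([1], conn, threshold=0.25)
        high = ca.partition_groups([1], conn, threshold=0.35)
        assert low.labels[1] == "group2" and high.labels[1] == "group1"

    def test_zero_output_cell_excluded(self):
        conn = self._interneuron_with_fraction(1, 4)
        part = ca.partition_groups([1, 3], conn)  # cell 3 has no outputs
        assert 3 in part.excluded and 3 not in part.labels.index

    def test_group2_share_on_default_generator(self, default_connectome):
        conn, truth = default_connectome
        ets = conn.neurons.loc[conn.neurons["subclass"] == "L5-ET", "neuron_id"]
        inh = conn.neurons.loc[conn.neurons["cell_class"] == "inhibitory", "neuron_id"]
        part = ca.partition_groups(inh, conn)
        share = ca.group2_synapse_share(ets, part, conn)
        # 0.78 by construction; partition misassignments and multiplicity
        # clustering admit a small measurement tolerance
        assert abs(share - 0.78) <= 0.025


class TestReciprocity:
    def test_exhaustive_toy(self):
        neurons = [neuron_row(i, subclass="L5-ET") for i in (1, 2, 3)]
        neurons += [neuron_row(i, x=10, subclass="PeriTC", cell_class="inhibitory")
                    for i in (4, 5, 6)]
        syn = [
            synapse_row(1, 1, 4),
            synapse_row(2, 2, 5),
            synapse_row(3, 3, 6),
            synapse_row(4, 4, 1),  # the only return
        ]
        conn = _toy(neurons, syn)
        # oracle: enumerate all (pre, post) connected pairs and check returns
        pairs = {(1, 4), (2, 5), (3, 6)}
        returns = {(4, 1)}
        expected = sum((b, a) in returns for a, b in pairs) / len(pairs)
        assert ca.reciprocity_rate([1, 2, 3], [4, 5, 6], conn) == pytest.approx(expected)
        assert expected == pytest.approx(1 / 3)

    def test_all_reciprocal(self):
        neurons = [neuron_row(1, subclass="L5-ET"),
                   neuron_row(2, x=10, subclass="PeriTC", cell_class="inhibitory")]
        syn = [synapse_row(1, 1, 2), synapse_row(2, 2, 1)]
        assert ca.reciprocity_rate([1], [2], _toy(neurons, syn)) == 1.0

    def test_group2_rate_exceeds_group1(self, default_connectome):
        conn, truth = default_connectome
        ets = conn.neurons.loc[conn.neurons["subclass"] == "L5-ET", "neuron_id"]
        g1 = [i for i, g in truth.group.items() if g == "group1"]
        g2 = [i for i, g in truth.group.items() if g == "group2"]
        assert ca.reciprocity_rate(ets, g2, conn) > ca.reciprocity_rate(ets, g1, conn)


class TestConnectionStats:
    def test_toy_multiplicities(self):
        # five connections with sizes {1, 1, 2, 3, 1} -> mean 1.6, range 1..3
        neurons = [neuron_row(1, subclass="L5-ET")]
        neurons += [neuron_row(10 + i, x=10, subclass="L5-IT") for i in range(5)]
        sizes = [1, 1, 2, 3, 1]
        syn, sid = [], 1
        for k, m in enumerate(sizes):
            for _ in range(m):
                syn.append(synapse_row(sid, 1, 10 + k))
                sid += 1
        stats_ = ca.connection_stats(_toy(neurons, syn), [1])
        m = stats_["multiplicity"]["excitatory"]
        assert m["mean"] == pytest.approx(np.mean(sizes))
        assert (m["min"], m["max"]) == (1, 3)

    def test_single_synapse_connections(self):
        neurons = [neuron_row(1, subclass="L5-ET"),
                   neuron_row(2, x=10, subclass="L5-IT"),
                   neuron_row(3, x=-10, subclass="L6P")]
        syn = [synapse_row(1, 1, 2), synapse_row(2, 1, 3)]
        m = ca.connection_stats(_toy(neurons, syn), [1])["multiplicity"]["excitatory"]
        assert m["mean"] == 1.0 and m["sd"] == 0.0

    def test_generator_recovers_configured_means(self, default_connectome):
        conn, _ = default_connectome
        ets = conn.neurons.loc[conn.neurons["subclass"] == "L5-ET", "neuron_id"]
        m = ca.connection_stats(conn, ets)["multiplicity"]
        for cls, target in (("inhibitory", 1.9), ("excitatory", 1.1)):
            got = m[cls]
            se = got["sd"] / np.sqrt(got["n_connections"])
            assert abs(got["mean"] - target) <= 3 * se

    def test_compartment_fractions_sum_to_one(self, default_connectome):
        conn, _ = default_connectome
        ets = conn.neurons.loc[conn.neurons["subclass"] == "L5-ET", "neuron_id"]
        comp = ca.connection_stats(conn, ets)["compartments"]
        for cls, fracs in comp.items():
            assert sum(fracs.values()) == pytest.approx(1.0)


class TestDistanceProfiles:
    def test_synapse_at_root_has_zero_path(self):
        skel = straight_skeleton(n=5)
        neurons = [neuron_row(1, subclass="L5-ET"), neuron_row(2, x=10, subclass="L5-IT")]
        syn = [synapse_row(1, 1, 2, pre_node=1)]
        conn = _toy(neurons, syn, skeletons={1: skel})
        d = ca.synapse_path_distances(1, conn)
        assert d.iloc[0] == 0.0

    def test_straight_axon_path_equals_euclid(self):
        skel = straight_skeleton(n=11, step=10.0)  # 100 µm straight
        neurons = [neuron_row(1, subclass="L5-ET"), neuron_row(2, x=10, subclass="L5-IT")]
        tip = skel.xyz[-1]
        syn = [synapse_row(1, 1, 2, x=tip[0], y=tip[1], z=tip[2], pre_node=11)]
        conn = _toy(neurons, syn, skeletons={1: skel})
        path = ca.synapse_path_distances(1, conn).iloc[0]
        prof_e = ca.distance_profiles([1], conn, metric="euclidean", bin_width=10)
        assert path == pytest.approx(100.0)
        # euclidean histogram puts the synapse in the [100, 110) bin
        assert prof_e.exc_counts[10] == 1

    def test_path_matches_dijkstra_oracle(self):
        import networkx as nx

        skel = y_skeleton()
        g = nx.Graph()
        for nid, pid in zip(skel.node_ids, skel.parent):
            if pid == -1:
                continue
            w = float(np.linalg.norm(
                skel.xyz[skel.index_of(int(nid))] - skel.xyz[skel.index_of(int(pid))]
            ))
            g.add_edge(int(nid), int(pid), weight=w)
        oracle = nx.single_source_dijkstra_path_length(g, skel.root, weight="weight")
        d = skel.path_distances_to_root()
        for nid in skel.node_ids:
            if int(nid) == skel.root:
                continue
            assert d[skel.index_of(int(nid))] == pytest.approx(oracle[int(nid)])

    def test_missing_pre_node_excluded(self):
        skel = straight_skeleton(n=5)
        neurons = [neuron_row(1, subclass="L5-ET"), neuron_row(2, x=10, subclass="L5-IT")]
        syn = [synapse_row(1, 1, 2, pre_node=1), synapse_row(2, 1, 2, pre_node=99)]
        conn = _toy(neurons, syn, skeletons={1: skel})
        d = ca.synapse_path_distances(1, conn)
        assert len(d) == 1

    def test_generator_distance_dependence(self, default_connectome):
        """Inhibitory fraction falls from near 0.8 proximally to near 0.2 at 750 µm."""
        conn, _ = default_connectome
        ets = conn.neurons.loc[conn.neurons["subclass"] == "L5-ET", "neuron_id"]
        prof = ca.distance_profiles(ets, conn, metric="path")
        frac = prof.inh_fraction
        assert abs(frac[0] - 0.8) <= 0.10
        assert abs(frac[15] - 0.2) <= 0.10  # [750, 800) bin
        # monotone decreasing trend across deciles of the distance range
        deciles = [np.nanmean(frac[i:i + 2]) for i in range(0, 16, 2)]
        rho = stats.spearmanr(np.arange(len(deciles)), deciles).statistic
        assert rho <= -0.95


class TestSubclassMatrix:
    def test_rows_sum_to_one(self, default_connectome):
        conn, _ = default_connectome
        ets = conn.neurons.loc[conn.neurons["subclass"] == "L5-ET", "neuron_id"][:10]
        mat = ca.subclass_matrix(ets, conn, scope="all")
        sums = mat.table.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_local_plus_interareal_equals_all(self, default_connectome):
        conn, _ = default_connectome
        cell = int(conn.neurons.loc[conn.neurons["subclass"] == "L5-ET",
                                    "neuron_id"].iloc[0])
        out = conn.outputs_of(cell)
        soma_side = conn.soma_xyz(cell)[0] >= conn.geometry.border_x
        syn_side = out["x"].to_numpy() >= conn.geometry.border_x
        n_local = int((syn_side == soma_side).sum())
        n_inter = int((syn_side != soma_side).sum())
        assert n_local + n_inter == len(out)

    def test_all_local_cell_omitted_from_interareal(self):
        neurons = [neuron_row(1, x=-100, subclass="L5-ET"),
                   neuron_row(2, x=-90, subclass="L5-IT")]
        syn = [synapse_row(i, 1, 2, x=-95.0) for i in range(1, 6)]
        mat = ca.subclass_matrix([1], _toy(neurons, syn), scope="interareal")
        assert 1 in mat.omitted

    def test_within_excitatory_composition_matches_config(self, default_connectome):
        conn, truth = default_connectome
        ets = conn.neurons.loc[conn.neurons["subclass"] == "L5-ET", "neuron_id"]
        mat = ca.subclass_matrix(ets, conn, scope="all")
        row = mat.table.loc["all"]
        mix = truth.config["target_subclass_mix"]
        total = sum(row[k] for k in mix)
        n = sum(len(conn.outputs_of(int(c))) for c in ets)
        for sub, target in mix.items():
            got = row[sub] / total
            want = target / sum(mix.values())
            se = np.sqrt(want * (1 - want) / n)
            assert abs(got - want) <= 3 * se + 0.01


class TestSynapseSizeTests:
    def test_type_one_error_calibrated(self):
        """All groups from one distribution: omnibus exceeds alpha rarely."""
        rng = np.random.default_rng(7)
        false_pos = 0
        n_rep = 400
        for _ in range(n_rep):
            groups = {k: rng.lognormal(8, 0.7, 50) for k in "abcd"}
            out = ca.synapse_size_tests(groups)
            false_pos += out["kruskal_p"] < 0.05
        assert false_pos / n_rep <= 0.06 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_identical_samples_ks_null(self):
        x = np.arange(100.0)
        out = ca.synapse_size_tests({"a": x, "b": x.copy()}, pairwise_ks=True)
        ks = out["pairwise_ks"].iloc[0]
        assert ks["statistic"] == 0.0 and ks["p"] == 1.0

    def test_location_shift_power(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(100):
            groups = {
                "a": rng.normal(0, 1, 200),
                "b": rng.normal(1.0, 1, 200),  # one-s.d. shift
            }
            hits += ca.synapse_size_tests(groups)["kruskal_p"] < 0.05
        assert hits >= 90

    def test_conover_reported_only_when_omnibus_significant(self):
        rng = np.random.default_rng(9)
        null_groups = {k: rng.normal(0, 1, 30) for k in "ab"}
        shifted = {"a": rng.normal(0, 1, 200), "b": rng.normal(2, 1, 200)}
        out_shift = ca.synapse_size_tests(shifted)
        assert out_shift["pairwise_conover"] is not None
        assert (out_shift["pairwise_conover"]["p_adjusted"] <= 1).all()

    def test_small_group_excluded(self):
        rng = np.random.default_rng(10)
        groups = {"a": rng.normal(0, 1, 50), "b": rng.normal(0, 1, 50), "c": [1.0]}
        out = ca.synapse_size_tests(groups)
        assert out["kruskal_H"] > 0  # ran on the two valid groups
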