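import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mbmodel import connectome as ct


def make_table(rows):
    return pd.DataFrame(rows, columns=list(ct.SYNAPSE_COLUMNS))


def pn_row(pre, post, count, subtype="g-main", roi="CA(R)"):
    return (pre, post, "PN", subtype, roi, count)


class TestFilterConnections:
    def test_two_or_fewer_synapses_dropped(self):
        t = make_table([pn_row(f"PN{i}", "KC0", c) for i, c in enumerate([1, 2, 3, 5])])
        out = ct.filter_connections(t)
        assert sorted(out["synapse_count"]) == [3, 5]

    def test_min_one_is_identity(self):
        t = make_table([pn_row("PN0", "KC0", 1), pn_row("PN1", "KC0", 2)])
        assert len(ct.filter_connections(t, min_synapses=1)) == 2

    def test_empty_table(self):
        assert ct.filter_connections(make_table([])).empty

    def test_only_pn_rows_affected_by_default(self):
        t = make_table(
            [pn_row("PN0", "KC0", 1), ("APL", "KC0", "APL", "g-main", "CA(R)", 1)]
        )
        out = ct.filter_connections(t)
        assert list(out["pre_class"]) == ["APL"]


class TestPerKcStats:
    def test_aggregate_arithmetic(self):
        t = make_table([pn_row("PN0", "KC0", 4), pn_row("PN1", "KC0", 6)])
        s = ct.per_kc_stats(t)
        row = s.iloc[0]
        assert row["N"] == 2 and row["mean_syn"] == 5 and row["total_syn"] == 10

    def test_apl_restricted_to_calyx(self):
        t = make_table(
            [
                pn_row("PN0", "KC0", 3),
                pn_row("PN1", "KC0", 4),
                pn_row("PN2", "KC0", 5),
                ("APL", "KC0", "APL", "g-main", "CA(R)", 7),
                ("APL", "KC0", "APL", "g-main", "PED(R)", 3),
            ]
        )
        s = ct.per_kc_stats(t)
        assert s.iloc[0]["apl_calyx_syn"] == 7
        assert s.iloc[0]["N"] == 3

    def test_excluded_subtypes_dropped(self):
        t = make_table(
            [pn_row("PN0", "KC0", 5), pn_row("PN0", "KC1", 5, subtype="g-d")]
        )
        s = ct.per_kc_stats(t)
        assert list(s["post_id"]) == ["KC0"]


class TestGeodesic:
    @pytest.fixture()
    def chain(self):
        # straight 3-node chain of unit edges along x, boundary at the origin
        return ct.Skeleton(
            node_id=np.array([1, 2, 3]),
            parent=np.array([-1, 1, 2]),
            xyz=np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]),
            radius=np.ones(3),
            boundary_point=np.array([0.0, 0, 0]),
        )

    def test_boundary_node_distance_zero(self, chain):
        d = ct.geodesic_distance_to_boundary(chain, np.array([[0.0, 0, 0]]))
        assert d[0] == pytest.approx(0.0)

    def test_chain_far_end(self, chain):
        d = ct.geodesic_distance_to_boundary(chain, np.array([[2.0, 0, 0]]))
        assert d[0] == pytest.approx(2.0)

    def test_l_branch_matches_graph_search_oracle(self):
        # L-shaped tree: geodesic must follow the bend, not the straight line
        skel = ct.Skeleton(
            node_id=np.arange(1, 6),
            parent=np.array([-1, 1, 2, 3, 4]),
            xyz=np.array(
                [[0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0], [2, 2, 0]], dtype=float
            ),
            radius=np.ones(5),
            boundary_point=np.array([0.0, 0, 0]),
        )
        pos = np.array([[2.0, 2.0, 0.0]])
        d = ct.geodesic_distance_to_boundary(skel, pos)
        oracle = nx.shortest_path_length(skel.graph(), 5, 1, weight="length")
        assert d[0] == pytest.approx(oracle)
        assert d[0] == pytest.approx(4.0)  # not the Euclidean 2*sqrt(2)

    def test_unsnappable_synapse_nan(self, chain):
        d = ct.geodesic_distance_to_boundary(
            chain, np.array([[50.0, 0, 0]]), snap_radius=1.0
        )
        assert np.isnan(d[0])

    def test_swc_roundtrip(self, chain, tmp_path):
        path = tmp_path / "kc.swc"
        chain.to_swc(path)
        back = ct.Skeleton.from_swc(path, boundary_point=[0, 0, 0])
        assert np.array_equal(back.node_id, chain.node_id)
        assert np.array_equal(back.parent, chain.parent)
        assert np.allclose(back.xyz, chain.xyz)


class TestPercentSlope:
    def test_linear_example(self):
        n = np.arange(4, 9, dtype=float)
        y = 10.0 - n
        assert ct.percent_slope(n, y) == pytest.approx(-25.0)

    def test_flat_is_zero(self):
        assert ct.percent_slope(np.arange(5.0), np.full(5, 3.0)) == pytest.approx(0.0)

    def test_invariant_to_y_rescaling(self):
        rng = np.random.default_rng(0)
        x = rng.integers(2, 12, 50).astype(float)
        y = 20 - x + rng.normal(0, 0.5, 50)
        assert ct.percent_slope(x, 7.3 * y) == pytest.approx(ct.percent_slope(x, y))

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            ct.percent_slope(np.array([1.0, 1.0, 2.0]), np.ones(3))


class TestCorrelationGrid:
    def test_exactly_linear_fixture(self):
        df = pd.DataFrame(
            {"subtype": "s", "N": np.arange(20.0), "mean_syn": 2 * np.arange(20.0) + 1}
        )
        g = ct.correlation_grid(df, pairs=(("N", "mean_syn"),))
        assert g["r"].iloc[0] == pytest.approx(1.0)
        assert g["significant"].iloc[0]

    def test_constant_column_undefined(self):
        df = pd.DataFrame({"subtype": "s", "N": np.ones(20), "mean_syn": np.arange(20.0)})
        g = ct.correlation_grid(df, pairs=(("N", "mean_syn"),))
        assert np.isnan(g["r"].iloc[0])

    def test_small_group_skipped(self):
        df = pd.DataFrame({"subtype": "s", "N": np.arange(5.0), "mean_syn": np.arange(5.0)})
        g = ct.correlation_grid(df, pairs=(("N", "mean_syn"),), min_n=10)
        assert np.isnan(g["r"].iloc[0])


PLANTED_PAIRS = (("N", "mean_syn"), ("N", "mean_distance"), ("total_syn", "apl_calyx_syn"))


class TestSynthConnectome:
    def test_seeded_determinism(self):
        a, _, _ = ct.synth_connectome(n_kc=50, rng_seed=5, make_skeletons=False)
        b, _, _ = ct.synth_connectome(n_kc=50, rng_seed=5, make_skeletons=False)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_couplings_recovered(self):
        table, skels, pos = ct.synth_connectome(n_kc=300, rng_seed=6)
        kc = ct.per_kc_stats(ct.filter_connections(table))
        kc = kc.merge(
            ct.kc_mean_distances(skels, pos).rename_axis("post_id").reset_index(),
            on="post_id",
        )
        g = ct.correlation_grid(kc, pairs=PLANTED_PAIRS).set_index(["x", "y"])
        assert g.loc[("N", "mean_syn"), "r"] < 0
        assert g.loc[("N", "mean_distance"), "r"] > 0
        assert g.loc[("total_syn", "apl_calyx_syn"), "r"] > 0
        assert g["significant"].all()

    def test_null_mode_type_i_control(self):
        """Without planted couplings the three correlations are null; the
        Holm-controlled grid flags them in at most a small fraction of seeds."""
        hits = 0
        n_seeds = 12
        for s in range(n_seeds):
            table, skels, pos = ct.synth_connectome(
                n_kc=300, coupling_w_n=0.0, coupling_apl=0.0, coupling_dist_n=0.0,
                rng_seed=100 + s,
            )
            kc = ct.per_kc_stats(ct.filter_connections(table))
            kc = kc.merge(
                ct.kc_mean_distances(skels, pos).rename_axis("post_id").reset_index(),
                on="post_id",
            )
            g = ct.correlation_grid(kc, pairs=PLANTED_PAIRS)
            hits += int(g["significant"].any())
        assert hits <= 2

    def test_model_population_negative_weight_slope(self, dists):
        """Populations with compensatory weights show the anatomical signature:
        fewer synapses-worth of weight per connection for each extra input."""
        from mbmodel.compensation import (
            apply_activity_independent,
            fit_conditional_weight_components,
        )
        from mbmodel.network import ModelSpec, sample_population

        sampler = fit_conditional_weight_components(dists, rng_seed=7)
        spec = ModelSpec(variable_w=True, variable_N=True, variable_theta=True, n_kc=2000)
        pop = sample_population(spec, dists, 24, rng_seed=8)
        pop = apply_activity_independent(pop, sampler, rng_seed=9)
        assert ct.percent_slope(pop.claw_counts, pop.mean_w) < -5
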