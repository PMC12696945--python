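"""Federation: sufficient-statistic additivity, guards, pooled equivalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fedgamlss import (
    DisclosureError,
    FederatedSession,
    HarmonizationError,
    ModelSpec,
    Node,
    SuffStats,
    Thresholds,
    aggregate,
    broadcast_spec,
    disclosure_guard,
    fit_federated,
    fit_pooled,
    node_suffstats,
    pooled_knots,
)
from fedgamlss.fit_core import NodeWorker, coefs_to_wire


def _split(df, D):
    n = len(df)
    return {f"n{i}": df.iloc[i * n // D:(i + 1) * n // D] for i in range(D)}


class TestSuffStats:
    def _built_workers(self, sbp_tables, sbp_spec, parts):
        from fedgamlss.model import merge_schemas, resolve_plan, schema_of
        plan = resolve_plan(sbp_spec, merge_schemas(
            {k: schema_of(v) for k, v in parts.items()}))
        workers = {}
        for nid, d in parts.items():
            w = NodeWorker(nid, d)
            w.build(plan)
            w.set_initial({"mu": {"beta": [100.0, 0.0, 0.0], "gamma": []},
                           "sigma": {"beta": [2.0, 0.0], "gamma": []}})
            w.begin_inner("mu")
            workers[nid] = w
        return plan, workers

    def test_split_stats_sum_to_pooled(self, sbp_tables, sbp_spec):
        tables, _ = sbp_tables
        df = pd.concat(tables.values(), ignore_index=True)
        pooled_parts = {"all": df}
        split_parts = {"a": df.iloc[:1500], "b": df.iloc[1500:]}
        coefs = {"beta": np.array([100.0, 0.0, 0.0]), "gamma": []}
        _, pw = self._built_workers(sbp_tables, sbp_spec, pooled_parts)
        _, sw = self._built_workers(sbp_tables, sbp_spec, split_parts)
        whole = pw["all"].term_stats("mu", "linear", coefs)
        parts = aggregate([w.term_stats("mu", "linear", coefs) for w in sw.values()])
        np.testing.assert_allclose(parts.ctwc, whole.ctwc, rtol=1e-12)
        np.testing.assert_allclose(parts.ctwr, whole.ctwr, rtol=1e-12)
        assert parts.n == whole.n
        assert parts.rtwr == pytest.approx(whole.rtwr, rel=1e-12)

    def test_two_single_observation_nodes_hand_sum(self):
        # design value 1, w = 1, z = 3 and z = 5 -> aggregate (C'WC, C'Wz) = (2, 8)
        a = SuffStats(ctwc=np.array([[1.0]]), ctwr=np.array([3.0]), rtwr=9.0, n=1)
        b = SuffStats(ctwc=np.array([[1.0]]), ctwr=np.array([5.0]), rtwr=25.0, n=1)
        tot = aggregate([a, b])
        assert tot.ctwc[0, 0] == 2.0 and tot.ctwr[0] == 8.0 and tot.n == 2

    def test_single_node_aggregate_is_identity(self):
        s = SuffStats(ctwc=np.eye(2), ctwr=np.array([1.0, 2.0]), rtwr=5.0, n=7)
        t = aggregate([s])
        assert np.array_equal(t.ctwc, s.ctwc) and t.n == 7

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 5000), d=st.integers(1, 4))
    def test_aggregate_commutes_and_associates(self, seed, d):
        rng = np.random.default_rng(seed)
        stats = [SuffStats(ctwc=rng.normal(size=(d, d)), ctwr=rng.normal(size=d),
                           rtwr=float(rng.normal()), n=int(rng.integers(1, 100)))
                 for _ in range(4)]
        perm = [stats[i] for i in rng.permutation(4)]
        t1, t2 = aggregate(stats), aggregate(perm)
        np.testing.assert_allclose(t1.ctwc, t2.ctwc, atol=1e-12)
        two_way = aggregate([aggregate(stats[:2]), aggregate(stats[2:])])
        np.testing.assert_allclose(two_way.ctwc, t1.ctwc, atol=1e-12)
        np.testing.assert_allclose(two_way.ctwr, t1.ctwr, atol=1e-12)

    def test_dimension_mismatch_is_protocol_error(self):
        from fedgamlss import ProtocolError
        a = SuffStats(ctwc=np.eye(2), ctwr=np.zeros(2), rtwr=0.0, n=1)
        b = SuffStats(ctwc=np.eye(3), ctwr=np.zeros(3), rtwr=0.0, n=1)
        with pytest.raises(ProtocolError):
            aggregate([a, b])


class TestDisclosureGuard:
    def test_pass(self):
        meta = {"n": 1000, "columns": {}}
        assert disclosure_guard(20, meta, Thresholds(df_ratio=0.33)) == []

    def test_sparse_category_blocked(self):
        meta = {"n": 1000,
                "columns": {"sex": {"kind": "factor",
                                    "levels": {"female": 998, "male": 2}}}}
        v = disclosure_guard(5, meta, Thresholds(category_min=3))
        assert len(v) == 1 and "category count" in v[0]

    def test_df_overrun_blocked(self):
        meta = {"n": 1000, "columns": {}}
        v = disclosure_guard(400, meta, Thresholds(df_ratio=0.33))
        assert len(v) == 1 and "degrees of freedom" in v[0]

    def test_tiny_node_blocked(self):
        v = disclosure_guard(1, {"n": 2, "columns": {}}, Thresholds(k_anonymity=3))
        assert any("k-anonymity" in msg for msg in v)


class TestBroadcast:
    def test_nodes_share_identical_knots(self, growth_no_tables, growth_no_spec):
        tables, _ = growth_no_tables
        session = FederatedSession(tables)
        plan = broadcast_spec(session, growth_no_spec)
        knots = plan["params"]["mu"]["smooths"][0]["knots"]
        assert plan["params"]["sigma"]["smooths"][0]["knots"] == knots
        # anonymized knot range strictly covers every node's observed ages
        for df in tables.values():
            assert knots[3] <= df["age"].min() and knots[-4] >= df["age"].max()

    def test_missing_column_names_node(self, growth_no_tables, growth_no_spec):
        tables, _ = growth_no_tables
        broken = dict(tables)
        broken["node1"] = tables["node1"].drop(columns=["age"])
        with pytest.raises(HarmonizationError, match="age"):
            fit_federated(growth_no_spec, broken)

    def test_sparse_factor_on_one_node_blocks_fit(self, sbp_tables, sbp_spec):
        tables, _ = sbp_tables
        t = {k: v.copy() for k, v in tables.items()}
        t["node0"] = t["node0"].copy()
        t["node0"].loc[t["node0"].index[:2], "sex"] = "other"
        t["node0"].loc[t["node0"].index[2:], "sex"] = "female"
        with pytest.raises(DisclosureError, match="category"):
            fit_federated(sbp_spec, t)

    def test_df_ratio_blocks_fit(self, sbp_tables, sbp_spec):
        tables, _ = sbp_tables
        with pytest.raises(DisclosureError, match="degrees of freedom"):
            fit_federated(sbp_spec, tables, thresholds=Thresholds(df_ratio=1e-4))


class TestEquivalence:
    def test_single_node_is_bitwise_pooled(self, sbp_tables, sbp_spec):
        tables, _ = sbp_tables
        df = pd.concat(tables.values(), ignore_index=True)
        mp = fit_pooled(sbp_spec, df)
        mf = fit_federated(sbp_spec, {"all": df})
        for k in ("mu", "sigma"):
            assert np.array_equal(mp.coef_vector(k), mf.coef_vector(k))
        assert mp.comm_log is None and mf.comm_log is not None

    def test_two_node_heteroscedastic_equivalence(self, sbp_tables, sbp_spec):
        tables, _ = sbp_tables
        df = pd.concat(tables.values(), ignore_index=True)
        mp = fit_pooled(sbp_spec, df)
        mf = fit_federated(sbp_spec, tables)
        for k in ("mu", "sigma"):
            np.testing.assert_allclose(mp.coef_vector(k), mf.coef_vector(k),
                                       atol=1e-10)

    def test_split_invariance_and_uneven_splits(self, growth_no_pooled,
                                                growth_no_spec):
        df = growth_no_pooled
        kn = pooled_knots(growth_no_spec, df)
        ref = None
        for parts in [_split(df, 1), _split(df, 2), _split(df, 4), _split(df, 8),
                      {"a": df.iloc[:500], "b": df.iloc[500:]}]:   # 500 vs 1500
            m = fit_federated(growth_no_spec, parts, knots=kn)
            vec = np.concatenate([m.coef_vector("mu"), m.coef_vector("sigma")])
            if ref is None:
                ref = vec
            else:
                assert np.max(np.abs(vec - ref)) < 1e-8
        mp = fit_pooled(growth_no_spec, df, knots=kn)
        pooled_vec = np.concatenate([mp.coef_vector("mu"), mp.coef_vector("sigma")])
        assert np.max(np.abs(ref - pooled_vec)) < 1e-8

    def test_node_suffstats_via_wire_match_direct(self, sbp_tables, sbp_spec):
        from fedgamlss.model import merge_schemas, resolve_plan, schema_of
        tables, _ = sbp_tables
        plan = resolve_plan(sbp_spec, merge_schemas(
            {k: schema_of(v) for k, v in tables.items()}))
        node = Node("node0", tables["node0"])
        node._worker.build(plan)
        coefs = {"beta": np.array([100.0, 0.0, 0.0]), "gamma": []}
        node._worker.set_initial({"mu": coefs_to_wire(coefs),
                                  "sigma": {"beta": [2.0, 0.0], "gamma": []}})
        node._worker.begin_inner("mu")
        via_wire = node_suffstats(node, "mu", "linear", coefs_to_wire(coefs))
        direct = node._worker.term_stats("mu", "linear", coefs)
        np.testing.assert_array_equal(via_wire.ctwc, direct.ctwc)
        np.testing.assert_array_equal(via_wire.ctwr, direct.ctwr)


class TestCommunication:
    def test_payload_sizes_independent_of_n(self, growth_no_spec):
        from fedgamlss.synthetic import SimConfig, simulate_growth

        sizes = {}
        for n in (150, 300):
            tables, _ = simulate_growth(
                SimConfig(scenario="growth_NO", n_per_node=[n, n], seed=12))
            spec = ModelSpec(
                family="NO",
                formulas={"mu": "1 + age + pb(age, n_intervals=6)",
                          "sigma": "1 + age + pb(age, n_intervals=6)"},
                response="height")
            m = fit_federated(spec, tables)
            per_kind = {}
            for e in m.comm_log:
                k = e["kind"]
                per_kind[k] = max(per_kind.get(k, 0),
                                  e["request_scalars"], e["response_scalars"])
            sizes[n] = per_kind
        assert sizes[150] == sizes[300]

    def test_term_payload_bound(self, growth_no_tables, growth_no_spec):
        tables, _ = growth_no_tables
        m = fit_federated(growth_no_spec, tables)
        max_term_df = 23   # pb default: 20 intervals, degree 3
        bound = max_term_df**2 + max_term_df + 3
        for e in m.comm_log:
            if e["kind"] == "term_stats":
                assert e["response_scalars"] <= bound

    def test_round_count_deterministic(self, growth_no_tables, growth_no_spec):
        tables, _ = growth_no_tables
        m1 = fit_federated(growth_no_spec, tables)
        m2 = fit_federated(growth_no_spec, tables)
        assert len(m1.comm_log) == len(m2.comm_log)
        assert [e["kind"] for e in m1.comm_log] == [e["kind"] for e in m2.comm_log]
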