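"""Unit and property tests for domain types, validation and I/O."""

from __future__ import annotations

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ripenet.core_model import (
    AbundanceTable,
    DesignMap,
    FeatureDescriptor,
    PathwayEdge,
    PathwayMap,
    SampleDescriptor,
    ValidationError,
    read_abundance_table,
    read_feature_table,
    read_pathway_map,
    read_sample_table,
    validate_design,
    write_abundance_table,
    write_feature_table,
    write_pathway_map,
    write_sample_table,
)
from ripenet.defaults import (
    default_design_map,
    default_feature_catalog,
    default_pathway_map,
    default_samples,
)

from .conftest import make_features, make_samples, make_table


class TestDescriptors:
    def test_kind_validated(self):
        with pytest.raises(ValidationError):
            FeatureDescriptor("x", "x", "protein", "CAR")

    def test_step_index_requires_branch(self):
        with pytest.raises(ValidationError):
            FeatureDescriptor("x", "x", "metabolite", "CAR", step_index=1)
        with pytest.raises(ValidationError):
            FeatureDescriptor("x", "x", "metabolite", "CAR", branch_id="b")
        FeatureDescriptor("x", "x", "metabolite", "CAR", branch_id="b", step_index=0)

    def test_negative_step_index_rejected(self):
        with pytest.raises(ValidationError):
            FeatureDescriptor("x", "x", "metabolite", "CAR", branch_id="b", step_index=-1)

    def test_replicate_positive(self):
        with pytest.raises(ValidationError):
            SampleDescriptor("s", "AC", "AC", "MG", 0)

    def test_detected_values_must_be_nonnegative(self):
        with pytest.raises(ValidationError):
            make_table(np.array([[-1.0, 2.0]]))

    def test_nd_cells_are_nan_internally(self):
        t = make_table(
            np.array([[1.0, 2.0]]), detected=np.array([[True, False]])
        )
        assert np.isnan(t.values[0, 1])

    def test_duplicate_genotype_stage_replicate_rejected(self):
        samples = [
            SampleDescriptor("a", "AC", "AC", "MG", 1),
            SampleDescriptor("b", "AC", "AC", "MG", 1),
        ]
        with pytest.raises(ValidationError):
            AbundanceTable(make_features(1), samples, np.ones((1, 2)), np.ones((1, 2), bool))


class TestAbundanceIO:
    def test_nd_cell_encoding(self, tmp_path):
        # 2 features x 2 samples with one ND cell
        path = tmp_path / "t.tsv"
        path.write_text(
            "feature_id\tS0\tS1\nF0\t1.5\t2.5\nF1\t3.5\tND\n"
        )
        features = make_features(2)
        samples = [SampleDescriptor(f"S{j}", "AC", "AC", "MG", j + 1) for j in range(2)]
        t = read_abundance_table(path, features, samples)
        assert t.detected.tolist() == [[True, True], [True, False]]
        assert t.values[0, 0] == 1.5 and np.isnan(t.values[1, 1])

    def test_unknown_sample_named_in_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("feature_id\tS0\tGHOST\nF0\t1\t2\n")
        features = make_features(1)
        samples = [SampleDescriptor("S0", "AC", "AC", "MG", 1)]
        with pytest.raises(ValidationError, match="GHOST"):
            read_abundance_table(path, features, samples)

    def test_unknown_feature_named_in_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("feature_id\tS0\nNOPE\t1\n")
        with pytest.raises(ValidationError, match="NOPE"):
            read_abundance_table(
                path, make_features(1), [SampleDescriptor("S0", "AC", "AC", "MG", 1)]
            )

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("feature_id\tS0\nF0\t-3\n")
        with pytest.raises(ValidationError, match="negative|non-finite"):
            read_abundance_table(
                path, make_features(1), [SampleDescriptor("S0", "AC", "AC", "MG", 1)]
            )

    def test_duplicate_row_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("feature_id\tS0\nF0\t1\nF0\t2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_abundance_table(
                path, make_features(1), [SampleDescriptor("S0", "AC", "AC", "MG", 1)]
            )

    def test_transposed_matrix_rejected_with_hint(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample_id\tF0\tF1\nS0\t1\t2\n")
        features = make_features(2)
        samples = [SampleDescriptor("S0", "AC", "AC", "MG", 1)]
        with pytest.raises(ValidationError, match="transposed"):
            read_abundance_table(path, features, samples)

    def test_all_detected_writes_no_sentinel(self, tmp_path):
        t = make_table(np.array([[1.0, 2.0], [3.0, 4.0]]))
        path = tmp_path / "t.tsv"
        write_abundance_table(t, path)
        assert "ND" not in path.read_text()

    def test_empty_feature_list_writes_header_only(self, tmp_path):
        t = make_table(
            np.zeros((0, 2)),
            features=[],
            samples=[SampleDescriptor(f"S{j}", "AC", "AC", "MG", j + 1) for j in range(2)],
        )
        path = tmp_path / "t.tsv"
        write_abundance_table(t, path)
        assert path.read_text() == "feature_id\tS0\tS1\n"

    def test_round_trip_100_random_tables(self, tmp_path):
        rng = np.random.default_rng(42)
        features = make_features(6)
        samples = [SampleDescriptor(f"S{j}", "AC", "AC", "MG", j + 1) for j in range(5)]
        for i in range(100):
            values = rng.random((6, 5)) * 10.0 ** float(rng.integers(-3, 6))
            detected = rng.random((6, 5)) > 0.2
            t = AbundanceTable(features, samples, values, detected)
            p = tmp_path / f"t{i}.tsv"
            write_abundance_table(t, p)
            t2 = read_abundance_table(p, features, samples)
            assert np.array_equal(t.detected, t2.detected)
            assert np.array_equal(
                t.values[t.detected], t2.values[t2.detected]
            )  # bit-identical
            assert t.feature_ids == t2.feature_ids
            assert t.sample_ids == t2.sample_ids

    def test_write_read_write_idempotent(self, tmp_path):
        rng = np.random.default_rng(7)
        t = make_table(rng.random((4, 3)) * 100,
                       detected=rng.random((4, 3)) > 0.3)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_abundance_table(t, p1)
        t2 = read_abundance_table(p1, t.features, t.samples)
        write_abundance_table(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    @settings(max_examples=25, deadline=None)
    @given(
        vals=st.lists(
            st.floats(min_value=0, max_value=1e12, allow_nan=False),
            min_size=4, max_size=4,
        )
    )
    def test_round_trip_property(self, vals, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("rt")
        t = make_table(np.array(vals).reshape(2, 2))
        p = tmp / "t.tsv"
        write_abundance_table(t, p)
        t2 = read_abundance_table(p, t.features, t.samples)
        assert np.array_equal(t.values, t2.values)


class TestMetadataIO:
    def test_sample_table_round_trip(self, tmp_path):
        samples = default_samples()
        p = tmp_path / "samples.tsv"
        write_sample_table(samples, p)
        assert read_sample_table(p) == samples

    def test_feature_table_round_trip(self, tmp_path):
        features = default_feature_catalog()
        p = tmp_path / "features.tsv"
        write_feature_table(features, p)
        assert read_feature_table(p) == features


class TestValidateDesign:
    def test_default_panel_has_no_flags(self):
        report = validate_design(default_samples(), default_design_map())
        assert report.ok
        # 7 genotypes x 3 stages x 3 replicates
        assert len(report.replicate_counts) == 21
        assert all(n == 3 for n in report.replicate_counts.values())

    def test_single_replicate_cell_flagged(self):
        samples = make_samples({"w": "w", "m": "w"}, stages=("MG", "FR"), reps=3)
        samples = [
            s for s in samples if not (s.genotype == "m" and s.stage == "FR" and s.replicate > 1)
        ]
        report = validate_design(samples, DesignMap({"m": "w"}))
        assert ("m", "FR", 1) in report.low_replicate_cells

    def test_unmatched_mutant_flagged(self):
        samples = make_samples({"AC": "AC", "Del": "M82"})
        report = validate_design(samples, DesignMap({}))  # omits Del -> M82
        assert report.unmatched_mutants == ["Del"]

    def test_mapped_wildtype_must_exist_in_samples(self):
        samples = make_samples({"Del": "M82"})
        report = validate_design(samples, DesignMap({"Del": "M82"}))
        assert report.unmatched_mutants == ["Del"]

    def test_counts_match_brute_force_groupby(self):
        rng = np.random.default_rng(3)
        samples = []
        for g, bg in [("AC", "AC"), ("m1", "AC"), ("m2", "AC")]:
            for st in ("MG", "Br", "FR"):
                for r in range(1, int(rng.integers(1, 5)) + 1):
                    samples.append(SampleDescriptor(f"{g}_{st}_{r}", g, bg, st, r))
        report = validate_design(samples, DesignMap({"m1": "AC", "m2": "AC"}))
        expected = collections.Counter((s.genotype, s.stage) for s in samples)
        assert report.replicate_counts == dict(expected)

    def test_total_never_raises_on_empty(self):
        report = validate_design([], DesignMap({"m": "w"}))
        assert report.replicate_counts == {}


def _has_cycle_dfs(nodes, edges):
    """Independent iterative three-color DFS cycle detector."""
    adj = {n: [] for n in nodes}
    for a, b in edges:
        adj[a].append(b)
    color = {n: 0 for n in nodes}  # 0 white, 1 gray, 2 black
    for start in nodes:
        if color[start]:
            continue
        stack = [(start, iter(adj[start]))]
        color[start] = 1
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == 1:
                    return True
                if color[nxt] == 0:
                    color[nxt] = 1
                    stack.append((nxt, iter(adj[nxt])))
                    advanced = True
                    break
            if not advanced:
                color[node] = 2
                stack.pop()
    return False


class TestPathwayMap:
    def test_linear_chain_valid(self):
        pm = PathwayMap(
            nodes=["A", "B", "C"],
            edges=[PathwayEdge("A", "B", "g1"), PathwayEdge("B", "C", "g2")],
        )
        assert len(pm.edges) == 2
        assert pm.entry_nodes() == ["A"]

    def test_branch_fractions_must_sum_to_one(self):
        edges = [PathwayEdge("A", "B", "g1"), PathwayEdge("A", "C", "g2")]
        PathwayMap(nodes=["A", "B", "C"], edges=edges,
                   branch_fractions={"A": {"B": 0.6, "C": 0.4}})
        with pytest.raises(ValidationError, match="sum"):
            PathwayMap(nodes=["A", "B", "C"], edges=edges,
                       branch_fractions={"A": {"B": 0.6, "C": 0.5}})

    def test_branching_node_requires_fractions(self):
        with pytest.raises(ValidationError, match="branch_fractions"):
            PathwayMap(
                nodes=["A", "B", "C"],
                edges=[PathwayEdge("A", "B", "g1"), PathwayEdge("A", "C", "g2")],
            )

    def test_cycle_named_in_error(self):
        with pytest.raises(ValidationError, match="cycle"):
            PathwayMap(
                nodes=["A", "B"],
                edges=[PathwayEdge("A", "B", "g1"), PathwayEdge("B", "A", "g2")],
            )

    def test_edge_gene_must_be_in_transcript_catalog(self):
        pm = PathwayMap(nodes=["A", "B"], edges=[PathwayEdge("A", "B", "gX")])
        with pytest.raises(ValidationError, match="gX"):
            pm.check_genes(["g1", "g2"])

    def test_default_map_branches_downstream_of_lycopene(self):
        pm = default_pathway_map()
        outs = pm.out_edges("lycopene")
        assert len(outs) >= 2
        catalog = default_feature_catalog()
        pm.check_genes([f.feature_id for f in catalog if f.kind == "transcript"])

    def test_json_round_trip(self, tmp_path):
        pm = default_pathway_map()
        p = tmp_path / "map.json"
        write_pathway_map(pm, p)
        pm2 = read_pathway_map(p)
        assert pm2.nodes == pm.nodes
        assert pm2.edges == pm.edges
        assert pm2.branch_fractions == pm.branch_fractions

    def test_loader_accepts_exactly_acyclic_graphs(self):
        # cross-check against an independent cycle detector on 200 random graphs
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            nodes = [f"N{i}" for i in range(n)]
            pairs = []
            for i in range(n):
                for j in range(n):
                    if i != j and rng.random() < 0.25:
                        pairs.append((nodes[i], nodes[j]))
            # uniform fractions so only acyclicity can fail
            out_count = collections.Counter(a for a, _ in pairs)
            fractions = {}
            for node, k in out_count.items():
                if k > 1:
                    prods = [b for a, b in pairs if a == node]
                    fractions[node] = {p: 1.0 / k for p in prods}
            edges = [PathwayEdge(a, b, "g") for a, b in pairs]
            cyclic = _has_cycle_dfs(nodes, pairs)
            if cyclic:
                with pytest.raises(ValidationError):
                    PathwayMap(nodes=nodes, edges=edges, branch_fractions=fractions)
            else:
                PathwayMap(nodes=nodes, edges=edges, branch_fractions=fractions)
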