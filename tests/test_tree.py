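"""Pigeonhole clone trees, aberration classification and SVG rendering."""

import itertools
import math
import xml.etree.ElementTree as ET

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from umclone.cluster import Cluster
from umclone.tree import (
    MRCA_ID,
    NORMAL_ID,
    build_tree,
    classify_aberrations,
    enumerate_topologies,
    render_life_history_svg,
)


def mk_clusters(ccfs, n=50, ci_half=0.06):
    return [
        Cluster(
            id=i,
            mean_ccf=c,
            ccf_ci95=(c - ci_half, c + ci_half),
            n_mutations_point=n,
            n_mutations_ci95=(n - 5, n + 5),
            members=list(range(i * n, (i + 1) * n)),
        )
        for i, c in enumerate(ccfs)
    ]


def brute_force_parent_sets(ccfs, tol):
    """Independent oracle: try every parent vector, validate by walking the
    resulting tree node by node."""
    k = len(ccfs) - 1
    sets = [set() for _ in range(k)]
    for parents in itertools.product(*(range(i) for i in range(1, k + 1))):
        children = {j: [] for j in range(len(ccfs))}
        for child, par in enumerate(parents, start=1):
            children[par].append(child)
        if all(sum(ccfs[c] for c in children[j]) <= ccfs[j] + tol for j in children):
            for i in range(k):
                sets[i].add(parents[i])
    return sets


class TestBuildTree:
    def test_single_cluster_root_and_mrca_only(self):
        tree = build_tree(mk_clusters([1.0]))
        assert [n.id for n in tree.nodes] == [NORMAL_ID, MRCA_ID]
        assert tree.node(MRCA_ID).parent == NORMAL_ID
        assert tree.consistent

    def test_chain_forced_when_siblings_overflow(self):
        # 0.7 + 0.5 > 1.0 + tol: the only valid topology is a chain
        tree = build_tree(mk_clusters([1.0, 0.7, 0.5]))
        parents = {n.id: n.parent for n in tree.nodes}
        assert parents[2] == MRCA_ID and parents[3] == 2
        assert all(not n.ambiguous_parents for n in tree.nodes)

    def test_ambiguous_placement_recorded_on_all_parents(self):
        # 0.3 fits under the MRCA next to 0.6, and nested under 0.6
        tree = build_tree(mk_clusters([1.0, 0.6, 0.3]))
        node = tree.nodes[3]
        assert node.ambiguous_parents == {MRCA_ID, 2}

    def test_mrca_node_carries_ccf_one(self):
        tree = build_tree(mk_clusters([0.95, 0.4]))
        assert tree.node(MRCA_ID).ccf == 1.0

    def test_many_clusters_use_greedy_but_stay_valid(self):
        # beyond the enumeration limit the greedy path still satisfies the
        # pigeonhole invariant at every node
        ccfs = [1.0, 0.45, 0.4, 0.35, 0.3, 0.25, 0.2, 0.15, 0.1, 0.08]
        tree = build_tree(mk_clusters(ccfs), tolerance=0.0)
        assert tree.consistent
        for n in tree.nodes:
            kid_sum = sum(c.ccf for c in tree.children(n.id) if c.id != MRCA_ID)
            assert kid_sum <= n.ccf + 1e-9

    def test_cna_attached_to_matching_clone(self):
        tree = build_tree(
            mk_clusters([1.0, 0.6]),
            cna_fractions={"LOH3": 1.0, "6p+": 0.58},
        )
        assert "LOH3" in tree.node(MRCA_ID).aberrations
        assert "6p+" in tree.nodes[2].aberrations

    def test_pigeonhole_invariant_on_emitted_tree(self):
        tree = build_tree(mk_clusters([1.0, 0.5, 0.3, 0.15]))
        for n in tree.nodes:
            kid_sum = sum(c.ccf for c in tree.children(n.id) if c.id != MRCA_ID)
            assert kid_sum <= n.ccf + 0.05 + 1e-9


@settings(max_examples=300, deadline=None)
@given(
    ccfs=st.lists(st.floats(0.05, 0.99), min_size=0, max_size=3),
    tol=st.sampled_from([0.0, 0.05, 0.1]),
)
def test_enumeration_matches_brute_force_oracle(ccfs, tol):
    """Every <= 4-cluster instance: placements equal exhaustive enumeration."""
    ccfs = [1.0] + sorted(ccfs, reverse=True)
    topos = enumerate_topologies(ccfs, tol)
    sets = [set() for _ in range(len(ccfs) - 1)]
    for t in topos:
        for i, p in enumerate(t):
            sets[i].add(p)
    assert sets == brute_force_parent_sets(ccfs, tol)
    # the tree itself exposes exactly the ambiguous placements
    if topos:
        tree = build_tree(mk_clusters(ccfs), tolerance=tol)
        for i, s in enumerate(sets):
            node = tree.nodes[2 + i]
            expected = {p + MRCA_ID for p in s}
            if len(s) > 1:
                assert node.ambiguous_parents == expected
            else:
                assert node.parent in expected and not node.ambiguous_parents


class TestClassifyAberrations:
    def test_clonal_driver_called_mrca(self):
        tree = build_tree(
            mk_clusters([1.0, 0.6]),
            driver_labels={"GNAQ": 0},
            cna_fractions={"LOH3": 1.0},
        )
        calls = {c.label: c.status for c in classify_aberrations(tree, ["GNAQ"], ["LOH3"])}
        assert calls == {"GNAQ": "MRCA", "LOH3": "MRCA"}

    def test_subclonal_bap1_with_clonal_loh3(self):
        # the recurring class-2 pattern: LOH3 in all tumor cells, BAP1 in a subclone
        tree = build_tree(
            mk_clusters([1.0, 0.6]),
            driver_labels={"GNAQ": 0, "BAP1": 1},
            cna_fractions={"LOH3": 0.98},
        )
        calls = {c.label: c.status for c in classify_aberrations(tree, ["GNAQ", "BAP1"], ["LOH3"])}
        assert calls["LOH3"] == "MRCA"
        assert calls["BAP1"] == "subclone"

    def test_missing_label_called_absent(self):
        tree = build_tree(mk_clusters([1.0]))
        (call,) = classify_aberrations(tree, ["SF3B1"], [])
        assert call.status == "absent" and math.isnan(call.ccf)

    def test_mrca_call_requires_interval_compatible_with_one(self):
        # top cluster clearly below 1: its aberrations cannot be clonal calls
        clusters = mk_clusters([0.7, 0.3], ci_half=0.04)
        tree = build_tree(clusters, driver_labels={"GNAQ": 0})
        (call,) = classify_aberrations(tree, ["GNAQ"], [])
        assert call.status == "subclone"

    def test_truth_class_table_reproduced_without_clustering(self, canonical_um_sample):
        # bypass inference: build the tree directly from simulator truth
        _m, _s, _p, truth = canonical_um_sample
        clusters = mk_clusters(truth.clone_ccfs, ci_half=0.03)
        tree = build_tree(
            clusters,
            driver_labels={"GNAQ": 0, "BAP1": 1},
            cna_fractions={"LOH3": 1.0, "8q+": 1.0},
        )
        calls = {
            c.label: c.status
            for c in classify_aberrations(tree, ["GNAQ", "BAP1", "SF3B1"], ["LOH3", "8q+"])
        }
        assert calls == {
            "GNAQ": "MRCA",
            "BAP1": "subclone",
            "SF3B1": "absent",
            "LOH3": "MRCA",
            "8q+": "MRCA",
        }


class TestSvg:
    def test_single_clone_svg_has_two_node_discs(self, tmp_path):
        path = tmp_path / "tree.svg"
        doc = render_life_history_svg(build_tree(mk_clusters([1.0])), str(path))
        root = ET.fromstring(path.read_text())
        circles = [e for e in root.iter() if e.tag.endswith("circle")]
        assert len(circles) == 2
        assert doc == path.read_text()

    def test_branch_lengths_proportional_to_mutation_counts(self):
        clusters = mk_clusters([1.0, 0.6])
        clusters[0].n_mutations_point = 100
        clusters[1].n_mutations_point = 50
        doc = render_life_history_svg(build_tree(clusters))
        root = ET.fromstring(doc)
        lines = [e for e in root.iter() if e.tag.endswith("line")]
        drops = sorted(abs(float(l.get("y2")) - float(l.get("y1"))) for l in lines)
        assert drops[1] / drops[0] == pytest.approx(2.0, rel=0.02)

    def test_node_area_proportional_to_cell_fraction(self):
        doc = render_life_history_svg(build_tree(mk_clusters([1.0, 0.25])))
        root = ET.fromstring(doc)
        radii = sorted(
            float(e.get("r"))
            for e in root.iter()
            if e.tag.endswith("circle") and "ghost" not in (e.get("class") or "")
        )
        # area ratio 4 => radius ratio 2 between the 25% subclone and the MRCA
        assert radii[-1] / radii[0] == pytest.approx(2.0, rel=0.05)

    def test_ambiguous_node_drawn_under_each_parent(self):
        doc = render_life_history_svg(build_tree(mk_clusters([1.0, 0.6, 0.3])))
        root = ET.fromstring(doc)
        ghosts = [e for e in root.iter() if "ghost" in (e.get("class") or "")]
        assert len(ghosts) >= 2  # one dashed branch + disc for the alternative


def test_topology_recovery_end_to_end():
    """Chain tumors (forced topology, well-separated clusters) recovered in
    >= 90% of 20 seeds."""
    from umclone.cluster import (
        assign_clusters,
        consolidate_clusters,
        filter_low_ccf_clusters,
        gibbs_sample,
    )
    from umclone.simulate import SimulationConfig, generate_sample

    hits = 0
    n_seeds = 20
    for seed in range(1, n_seeds + 1):
        cfg = SimulationConfig(
            purity=1.0, mean_depth=100, n_clonal_mutations=100,
            subclone_ccfs=[0.75, 0.35], subclone_mutation_counts=[80, 80],
            subclone_parents=[0, 1], neutral_mu_over_beta=0.0, seed=seed,
        )
        m, s, p, truth = generate_sample(cfg)
        clusters = consolidate_clusters(
            filter_low_ccf_clusters(assign_clusters(gibbs_sample(m, s, p, seed=seed)))
        )
        tree = build_tree(clusters)
        parents = [n.parent for n in tree.nodes if n.id > MRCA_ID]
        # truth chain: normal -> MRCA -> 0.7 -> 0.5 (spurious extra clusters fail)
        if parents == [MRCA_ID, MRCA_ID + 1] and not any(
            n.ambiguous_parents for n in tree.nodes
        ):
            hits += 1
    assert hits / n_seeds >= 0.9
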