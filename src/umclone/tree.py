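"""Life-history clone trees by the pigeonhole principle.

Clusters of mutations, ordered by descending CCF, are assembled into a
rooted tree: normal cell -> MRCA (the highest cluster, carrying everything
present in 100% of tumor cells) -> subclones. A placement is admissible
only if, at every node, the CCFs of its children sum to no more than the
node's own CCF (plus a small tolerance): two sibling subclones cannot
jointly contain more cells than their parent. All admissible topologies
are enumerated; where several exist, the affected cluster is recorded with
every possible parent rather than forcing an arbitrary choice.

Canonical copy-number alterations enter with their clonal fraction and are
attached to the clone whose CCF interval contains it, which yields the
MRCA-versus-subclone classification of each driver aberration. The tree
can be rendered as an SVG life-history plot: node area proportional to the
percentage of cells in the clone, branch length to the number of mutations
acquired on that branch, branch width to the percentage of cells carrying
them.
"""

from __future__ import annotations

import itertools
import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from umclone.cluster import Cluster

NORMAL_ID = 0
MRCA_ID = 1

#: Above this many clusters exhaustive topology enumeration is abandoned
#: for greedy shallow attachment (never reached on real uveal melanoma).
_ENUM_LIMIT = 8


@dataclass
class CloneNode:
    """One clone in the life-history tree.

    ``ccf`` is the fraction of tumor cells in the clone's lineage (the
    normal root and the MRCA both carry 1.0). ``ambiguous_parents`` is
    non-empty when the pigeonhole constraint admits several placements.
    """

    id: int
    ccf: float
    parent: int | None
    branch_mutation_count: int = 0
    aberrations: list[str] = field(default_factory=list)
    ambiguous_parents: set[int] = field(default_factory=set)
    ccf_ci: tuple[float, float] = (float("nan"), float("nan"))
    cluster_id: int | None = None
    cluster_mean_ccf: float = float("nan")


@dataclass
class CloneTree:
    """Rooted life-history tree: normal cell -> MRCA -> subclones."""

    nodes: list[CloneNode]
    consistent: bool = True

    def node(self, node_id: int) -> CloneNode:
        return next(n for n in self.nodes if n.id == node_id)

    def children(self, node_id: int) -> list[CloneNode]:
        return [n for n in self.nodes if n.parent == node_id]

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "consistent": self.consistent,
                "nodes": [
                    {
                        "id": n.id,
                        "ccf": n.ccf,
                        "parent": n.parent,
                        "branch_mutation_count": n.branch_mutation_count,
                        "aberrations": n.aberrations,
                        "ambiguous_parents": sorted(n.ambiguous_parents),
                        "ccf_ci": list(n.ccf_ci),
                    }
                    for n in self.nodes
                ],
            },
            **kwargs,
        )


@dataclass(frozen=True)
class AberrationCall:
    """MRCA-vs-subclone status of one driver mutation or CNA."""

    label: str
    status: str  # "MRCA" | "subclone" | "absent"
    ccf: float = float("nan")
    ccf_ci: tuple[float, float] = (float("nan"), float("nan"))


def _valid_assignment(ccfs: list[float], parents: tuple[int, ...], tol: float) -> bool:
    """Check the pigeonhole sum at every node of a full parent assignment.

    ``ccfs[0]`` is the MRCA; ``parents[i]`` is the index (into ``ccfs``) of
    the parent of cluster ``i + 1``.
    """
    for node in range(len(ccfs)):
        s = sum(ccfs[i + 1] for i, p in enumerate(parents) if p == node)
        if s > ccfs[node] + tol:
            return False
    return True


def enumerate_topologies(
    ccfs: list[float], tolerance: float = 0.05
) -> list[tuple[int, ...]]:
    """All pigeonhole-admissible parent assignments for descending CCFs.

    Each subclone may attach to any strictly earlier (higher-CCF) cluster;
    an assignment survives if no node's children exceed it. Returned in
    lexicographic order of parent indices, so the first entry prefers
    shallow (closer to the MRCA) attachments.
    """
    k = len(ccfs) - 1
    out = []
    for parents in itertools.product(*(range(i) for i in range(1, k + 1))):
        if _valid_assignment(ccfs, parents, tolerance):
            out.append(parents)
    return out


def build_tree(
    clusters: list[Cluster],
    cna_fractions: dict[str, float] | None = None,
    tolerance: float = 0.05,
    driver_labels: dict[str, int] | None = None,
) -> CloneTree:
    """Assemble the life-history tree from filtered clusters.

    Parameters
    ----------
    clusters:
        Filtered clusters; the highest-CCF cluster becomes the MRCA (all
    	its mutations are taken to be in every tumor cell).
    cna_fractions:
        Map of CNA label to its clonal fraction; each CNA is attached to
        the clone whose CCF interval contains the fraction (nearest mean
        on ties or no hit).
    tolerance:
        Slack on the pigeonhole sums, absorbing CI-level noise in cluster
        locations.
    driver_labels:
        Map of driver gene label to the ``Cluster.id`` containing it; the
        label is placed on that cluster's node.

    Clusters are attached in descending CCF order (larger cluster first on
    ties). When several placements are admissible the canonical tree uses
    the shallowest one and records ``ambiguous_parents`` with every
    admissible parent. A cluster with no admissible placement attaches to
    the MRCA and the tree is flagged inconsistent.
    """
    if not clusters:
        raise ValueError("cannot build a tree without clusters")
    ordered = sorted(clusters, key=lambda c: (-c.mean_ccf, -c.n_mutations_point))
    # node ccfs on the tree scale: the MRCA is 100% of tumor cells by definition
    ccfs = [1.0] + [c.mean_ccf for c in ordered[1:]]
    k = len(ccfs) - 1

    if k + 1 <= _ENUM_LIMIT:
        topologies = enumerate_topologies(ccfs, tolerance)
    else:
        topologies = []
    if topologies:
        canonical = topologies[0]
        parent_sets = [set() for _ in range(k)]
        for t in topologies:
            for i, p in enumerate(t):
                parent_sets[i].add(p)
        consistent = True
    else:
        # greedy shallowest-valid placement; nesting under the previous
        # cluster is always admissible for descending CCFs, so this cannot
        # fail, but any cluster forced deeper than the MRCA's children is
        # placed without ambiguity tracking
        canonical_list: list[int] = []
        child_sum = [0.0] * (k + 1)
        for i in range(k):
            placed = False
            for p in range(i + 1):
                if child_sum[p] + ccfs[i + 1] <= ccfs[p] + tolerance:
                    canonical_list.append(p)
                    child_sum[p] += ccfs[i + 1]
                    placed = True
                    break
            if not placed:  # defensive: attach to MRCA and flag
                canonical_list.append(0)
                child_sum[0] += ccfs[i + 1]
        canonical = tuple(canonical_list)
        parent_sets = [{p} for p in canonical_list]
        consistent = _valid_assignment(ccfs, canonical, tolerance)

    nodes = [
        CloneNode(id=NORMAL_ID, ccf=1.0, parent=None),
        CloneNode(
            id=MRCA_ID,
            ccf=1.0,
            parent=NORMAL_ID,
            branch_mutation_count=ordered[0].n_mutations_point,
            ccf_ci=ordered[0].ccf_ci95,
            cluster_id=ordered[0].id,
            cluster_mean_ccf=ordered[0].mean_ccf,
        ),
    ]
    for i in range(k):
        amb = {p + MRCA_ID for p in parent_sets[i]} if len(parent_sets[i]) > 1 else set()
        nodes.append(
            CloneNode(
                id=MRCA_ID + 1 + i,
                ccf=ccfs[i + 1],
                parent=canonical[i] + MRCA_ID,
                branch_mutation_count=ordered[i + 1].n_mutations_point,
                ambiguous_parents=amb,
                ccf_ci=ordered[i + 1].ccf_ci95,
                cluster_id=ordered[i + 1].id,
                cluster_mean_ccf=ordered[i + 1].mean_ccf,
            )
        )

    cluster_to_node = {n.cluster_id: n for n in nodes if n.cluster_id is not None}
    if driver_labels:
        for label, cid in driver_labels.items():
            if cid in cluster_to_node:
                cluster_to_node[cid].aberrations.append(label)
    if cna_fractions:
        candidates = nodes[1:]  # CNAs live in tumor clones only
        for label, cf in cna_fractions.items():
            hits = [
                n for n in candidates
                if not math.isnan(n.ccf_ci[0]) and n.ccf_ci[0] <= cf <= n.ccf_ci[1]
            ]
            pool = hits if hits else candidates
            best = min(pool, key=lambda n: abs(n.ccf - cf))
            best.aberrations.append(label)

    return CloneTree(nodes=nodes, consistent=consistent)


def classify_aberrations(
    tree: CloneTree,
    driver_labels: list[str],
    cna_labels: list[str],
    require_ci_overlap_one: bool = True,
) -> list[AberrationCall]:
    """Call each aberration MRCA, subclone or absent from its tree placement.

    An aberration on the MRCA node is called MRCA — present in 100% of
    tumor cells and so predating the most recent common ancestor — provided
    the supporting cluster's CCF interval is compatible with 1 (interval
    contains 1.0 and mean >= 0.9, the operational reading of "present in
    all tumor cells" under sampling noise; disable with
    ``require_ci_overlap_one=False``). Aberrations on any lower node are
    subclonal; labels absent from the tree are called absent.
    """
    where: dict[str, CloneNode] = {}
    for n in tree.nodes:
        for lab in n.aberrations:
            where[lab] = n
    calls = []
    for label in list(driver_labels) + list(cna_labels):
        n = where.get(label)
        if n is None:
            calls.append(AberrationCall(label=label, status="absent"))
            continue
        if n.id == MRCA_ID:
            mrca_ok = True
            if require_ci_overlap_one and not math.isnan(n.ccf_ci[1]):
                # top cluster must be compatible with 100% of tumor cells
                mrca_ok = n.ccf_ci[1] >= 1.0 and n.cluster_mean_ccf >= 0.9
            status = "MRCA" if mrca_ok else "subclone"
        else:
            status = "subclone"
        calls.append(
            AberrationCall(label=label, status=status, ccf=n.ccf, ccf_ci=n.ccf_ci)
        )
    return calls


# --------------------------------------------------------------------------
# SVG rendering
# --------------------------------------------------------------------------

_SVG_NS = "http://www.w3.org/2000/svg"
_PX_PER_MUTATION = 2.0
_MIN_BRANCH = 12.0  # only for zero-mutation branches
_MAX_NODE_AREA = 1600.0  # px^2 disc area of a 100% clone
_MAX_BRANCH_W = 14.0


def _node_radius(ccf: float) -> float:
    return math.sqrt(max(ccf, 0.01) * _MAX_NODE_AREA / math.pi)


def render_life_history_svg(tree: CloneTree, path: str | None = None) -> str:
    """Render the life-history plot and return the SVG document text.

    Disc area is proportional to the percentage of cells in the clone,
    branch length to the number of mutations acquired on the branch, and
    branch width to the percentage of cells carrying those mutations.
    Nodes with ambiguous placement are additionally drawn dashed under
    each alternative parent.
    """
    # vertical layout: depth = cumulative branch length from the root
    ys: dict[int, float] = {NORMAL_ID: 40.0}
    order = [n for n in tree.nodes if n.id != NORMAL_ID]
    for n in order:  # nodes are stored parent-before-child
        length = n.branch_mutation_count * _PX_PER_MUTATION
        if n.branch_mutation_count == 0:
            length = _MIN_BRANCH
        ys[n.id] = ys[n.parent] + length

    # horizontal layout: leaves evenly spaced, parents centered over children
    xs: dict[int, float] = {}
    leaves = [n for n in tree.nodes if not tree.children(n.id)]
    spacing = 150.0
    for i, n in enumerate(leaves):
        xs[n.id] = 80.0 + i * spacing
    for n in reversed(tree.nodes):
        if n.id not in xs:
            kids = tree.children(n.id)
            xs[n.id] = sum(xs[k.id] for k in kids) / len(kids)

    width = max(xs.values()) + 160
    height = max(ys.values()) + 80
    svg = ET.Element(
        "svg", xmlns=_SVG_NS, width=str(int(width)), height=str(int(height)),
        viewBox=f"0 0 {int(width)} {int(height)}",
    )

    colors = {NORMAL_ID: "#d9d9d9", MRCA_ID: "#636363"}
    for n in tree.nodes:
        if n.parent is not None:
            ET.SubElement(
                svg, "line",
                {
                    "class": "branch",
                    "x1": f"{xs[n.parent]:.1f}", "y1": f"{ys[n.parent]:.1f}",
                    "x2": f"{xs[n.id]:.1f}", "y2": f"{ys[n.id]:.1f}",
                    "stroke": "#969696",
                    "stroke-width": f"{max(1.0, n.ccf * _MAX_BRANCH_W):.1f}",
                },
            )
            if n.aberrations:
                txt = ET.SubElement(
                    svg, "text",
                    {
                        "class": "aberrations",
                        "x": f"{(xs[n.parent] + xs[n.id]) / 2 + 8:.1f}",
                        "y": f"{(ys[n.parent] + ys[n.id]) / 2:.1f}",
                        "font-size": "12",
                    },
                )
                txt.text = ", ".join(n.aberrations)
            # ghost placements under the alternative parents
            for alt in sorted(n.ambiguous_parents - {n.parent}):
                ET.SubElement(
                    svg, "line",
                    {
                        "class": "branch ghost",
                        "x1": f"{xs[alt]:.1f}", "y1": f"{ys[alt]:.1f}",
                        "x2": f"{xs[n.id] + 30:.1f}",
                        "y2": f"{ys[alt] + n.branch_mutation_count * _PX_PER_MUTATION:.1f}",
                        "stroke": "#969696", "stroke-dasharray": "6 4",
                        "stroke-width": f"{max(1.0, n.ccf * _MAX_BRANCH_W):.1f}",
                    },
                )
                ET.SubElement(
                    svg, "circle",
                    {
                        "class": "node ghost",
                        "cx": f"{xs[n.id] + 30:.1f}",
                        "cy": f"{ys[alt] + n.branch_mutation_count * _PX_PER_MUTATION:.1f}",
                        "r": f"{_node_radius(n.ccf):.1f}",
                        "fill": "none", "stroke": "#3182bd",
                        "stroke-dasharray": "4 3",
                    },
                )
    for n in tree.nodes:
        ET.SubElement(
            svg, "circle",
            {
                "class": "node",
                "cx": f"{xs[n.id]:.1f}", "cy": f"{ys[n.id]:.1f}",
                "r": f"{_node_radius(n.ccf):.1f}",
                "fill": colors.get(n.id, "#3182bd"),
            },
        )
        lab = ET.SubElement(
            svg, "text",
            {
                "class": "node-label",
                "x": f"{xs[n.id] + _node_radius(n.ccf) + 4:.1f}",
                "y": f"{ys[n.id] + 4:.1f}",
                "font-size": "11",
            },
        )
        if n.id == NORMAL_ID:
            lab.text = "normal"
        elif n.id == MRCA_ID:
            lab.text = "MRCA"
        else:
            lab.text = f"subclone {n.ccf * 100:.0f}%"

    doc = ET.tostring(svg, encoding="unicode", xml_declaration=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(doc)
    return doc
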