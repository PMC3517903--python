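"""Phylogeny handling: Newick I/O, branch partitions and parameter counts.

Codon models here operate on unrooted trees (likelihood under a
reversible model is invariant to root placement), so a rooted input is
derooted to a basal trifurcation and carries 2n-3 free branch lengths.

The branch partition machinery assigns every branch a label used by the
branch-model families:

* OG      — the branch leading to the outgroup
* early   — the basal branch descending into each paralog clade
            (the lineage immediately after the duplication)
* late    — all more recent branches within a clade
* cladeA / cladeB — paralog identity

Schemes: M0 (one shared ratio), MP (per-paralog), MA (early/late),
MPA (both axes), and CLADE (no outgroup; every branch assigned to the
clade on whose side it lies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "LabeledPhylogeny",
    "BranchPartition",
    "PartitionError",
    "read_newick",
    "write_newick",
    "partition_branches",
    "count_parameters",
    "SCHEME_LABELS",
]

DEFAULT_BRANCH_LENGTH = 0.1


class PartitionError(ValueError):
    """Clade sets do not induce a valid branch partition."""


@dataclass
class LabeledPhylogeny:
    """An unrooted phylogeny flattened to arrays for fast traversal.

    Node ids follow a postorder enumeration; the (trifurcating) root is
    the last id and carries no edge.  ``edge id == child node id``: the
    edge above node v.  Branch lengths are expected substitutions per
    codon site.
    """

    parent: np.ndarray            # parent[node] (root -> -1)
    children: list[list[int]]
    postorder: list[int]          # tips first guaranteed only locally; root last
    edge_length: np.ndarray       # length of edge above node; root entry unused
    tip_ids: dict[str, int]       # taxon name -> node id
    newick_source: str = ""

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.postorder[-1]

    @property
    def edges(self) -> list[int]:
        """All edge ids (every node except the root)."""
        return [v for v in self.postorder if v != self.root]

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    @property
    def taxa(self) -> list[str]:
        return sorted(self.tip_ids, key=self.tip_ids.get)

    def descendant_tips(self, node: int) -> frozenset[str]:
        """Tip names below ``node`` (inclusive for a tip)."""
        return self._desc[node]

    def __post_init__(self) -> None:
        names = {v: n for n, v in self.tip_ids.items()}
        desc: dict[int, frozenset[str]] = {}
        for v in self.postorder:
            if not self.children[v]:
                desc[v] = frozenset([names[v]])
            else:
                acc: frozenset[str] = frozenset()
                for c in self.children[v]:
                    acc |= desc[c]
                desc[v] = acc
        self._desc = desc

    def with_edge_lengths(self, lengths: np.ndarray) -> "LabeledPhylogeny":
        t = LabeledPhylogeny(
            parent=self.parent,
            children=self.children,
            postorder=self.postorder,
            edge_length=np.asarray(lengths, dtype=float).copy(),
            tip_ids=self.tip_ids,
            newick_source=self.newick_source,
        )
        return t

    def subtree(self, taxa: list[str]) -> "LabeledPhylogeny":
        """Unrooted induced subtree on the given tips, path lengths preserved."""
        dt = _to_dendropy(self)
        keep = set(taxa)
        missing = keep - set(self.tip_ids)
        if missing:
            raise PartitionError(f"taxa not in tree: {sorted(missing)}")
        sub = dt.extract_tree_with_taxa_labels(list(keep), suppress_unifurcations=True)
        sub.deroot()
        return _from_dendropy(sub)

    def total_length(self) -> float:
        return float(sum(self.edge_length[e] for e in self.edges))


def _from_dendropy(dt: dendropy.Tree) -> LabeledPhylogeny:
    nodes = list(dt.postorder_node_iter())
    ids = {nd: i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    lengths = np.zeros(n)
    tip_ids: dict[str, int] = {}
    for nd, i in ids.items():
        for ch in nd.child_nodes():
            parent[ids[ch]] = i
            children[i].append(ids[ch])
        if nd.parent_node is not None:
            el = nd.edge.length
            lengths[i] = DEFAULT_BRANCH_LENGTH if el is None else float(el)
            if lengths[i] < 0:
                raise ValueError(f"negative branch length {lengths[i]}")
        if nd.is_leaf():
            name = nd.taxon.label if nd.taxon is not None else None
            if not name:
                raise ValueError("unnamed tip in tree")
            if name in tip_ids:
                raise ValueError(f"duplicate tip name {name!r}")
            tip_ids[name] = i
    return LabeledPhylogeny(
        parent=parent,
        children=children,
        postorder=list(range(n)),
        edge_length=lengths,
        tip_ids=tip_ids,
    )


def _to_dendropy(tree: LabeledPhylogeny) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace(tree.taxa)
    dt = dendropy.Tree(taxon_namespace=taxa)
    names = {v: n for n, v in tree.tip_ids.items()}
    dnodes: dict[int, dendropy.Node] = {}
    for v in tree.postorder:
        nd = dendropy.Node()
        if not tree.children[v]:
            nd.taxon = taxa.get_taxon(names[v])
        for c in tree.children[v]:
            nd.add_child(dnodes[c])
            dnodes[c].edge.length = float(tree.edge_length[c])
        dnodes[v] = nd
    dt.seed_node = dnodes[tree.root]
    return dt


def read_newick(text: str) -> LabeledPhylogeny:
    """Parse a Newick string into an unrooted LabeledPhylogeny.

    Missing branch lengths default to 0.1; a bifurcating root is
    collapsed (the two basal edge lengths are summed).
    """
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    if len(dt.seed_node.child_nodes()) == 2 and len(dt.leaf_nodes()) > 2:
        dt.deroot()
    tree = _from_dendropy(dt)
    tree.newick_source = text
    return tree


def write_newick(tree: LabeledPhylogeny) -> str:
    dt = _to_dendropy(tree)
    return dt.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# branch partitions

SCHEME_LABELS = {
    "M0": ("OG", "all"),
    "MP": ("OG", "cladeA", "cladeB"),
    "MA": ("OG", "early", "late"),
    "MPA": ("OG", "cladeA:early", "cladeB:early", "cladeA:late", "cladeB:late"),
    "CLADE": ("cladeA", "cladeB"),
}


@dataclass
class BranchPartition:
    """Map edge id -> label under one of the branch labeling schemes."""

    scheme: str
    labels: dict[int, str]
    label_set: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.label_set = SCHEME_LABELS[self.scheme]
        stray = set(self.labels.values()) - set(self.label_set)
        if stray:
            raise PartitionError(f"labels outside scheme {self.scheme}: {sorted(stray)}")

    def to_tsv(self, tree: LabeledPhylogeny) -> str:
        lines = ["edge\tclade_side\tlabel"]
        for e, lab in sorted(self.labels.items()):
            side = ",".join(sorted(tree.descendant_tips(e)))
            lines.append(f"{e}\t{side}\t{lab}")
        return "\n".join(lines) + "\n"


def _edge_sides(tree: LabeledPhylogeny) -> dict[int, frozenset[str]]:
    """Descendant-tip set of every edge under the current (arbitrary) rooting."""
    return {e: tree.descendant_tips(e) for e in tree.edges}


def partition_branches(
    tree: LabeledPhylogeny,
    clade_a: set[str],
    clade_b: set[str],
    outgroup: set[str],
    scheme: str,
    early_override: dict[str, list[int]] | None = None,
) -> BranchPartition:
    """Label every branch of the tree under a branch-model scheme.

    ``clade_a``, ``clade_b`` and ``outgroup`` must partition the tips and
    each clade must be monophyletic with respect to the outgroup rooting.
    ``early_override`` maps 'cladeA'/'cladeB' to explicit edge-id lists to
    treat as early, replacing the default (the single basal branch of
    each clade); this covers analyses that reassign an ancestral branch.
    """
    if scheme not in SCHEME_LABELS:
        raise PartitionError(f"unknown scheme {scheme!r}")
    clade_a, clade_b, outgroup = set(clade_a), set(clade_b), set(outgroup)
    tips = set(tree.tip_ids)
    if scheme == "CLADE":
        expected = clade_a | clade_b
        if outgroup:
            raise PartitionError("CLADE scheme takes no outgroup")
    else:
        expected = clade_a | clade_b | outgroup
        if not outgroup:
            raise PartitionError(f"scheme {scheme} requires an outgroup")
    if expected != tips or (clade_a & clade_b) or (clade_a & outgroup) or (clade_b & outgroup):
        raise PartitionError(
            "clade sets must partition the tips; offending: "
            f"{sorted((expected ^ tips) | (clade_a & clade_b))}"
        )

    labels: dict[int, str] = {}
    basal: dict[str, list[int]] = {"cladeA": [], "cladeB": []}
    interior: dict[str, list[int]] = {"cladeA": [], "cladeB": []}
    for e, desc in _edge_sides(tree).items():
        comp = tips - desc
        # side of the edge away from the outgroup (for CLADE: containing
        # neither full clade, i.e. the smaller induced side)
        if scheme == "CLADE":
            side = desc if (desc <= clade_a or desc <= clade_b) else comp
        else:
            side = desc if not (desc & outgroup) else comp
        if scheme != "CLADE" and (clade_a | clade_b) <= side:
            # edge on the outgroup side of the duplication node
            labels[e] = "OG"
            continue
        if side <= clade_a:
            which = "cladeA"
        elif side <= clade_b:
            which = "cladeB"
        else:
            raise PartitionError(
                f"clade not monophyletic at edge {e}: side mixes "
                f"{sorted(side & clade_a)} and {sorted(side & clade_b)}"
            )
        (basal if side in (clade_a, clade_b) else interior)[which].append(e)

    if scheme != "CLADE":
        for which, clade in (("cladeA", clade_a), ("cladeB", clade_b)):
            if len(clade) > 1 and not basal[which]:
                raise PartitionError(f"{which} ({sorted(clade)}) is not monophyletic")

    early: dict[str, set[int]] = {}
    for which in ("cladeA", "cladeB"):
        if early_override and which in early_override:
            early[which] = set(early_override[which])
        else:
            early[which] = set(basal[which])

    for which in ("cladeA", "cladeB"):
        for e in basal[which] + interior[which]:
            if scheme == "M0":
                labels[e] = "all"
            elif scheme in ("MP", "CLADE"):
                labels[e] = which
            elif scheme == "MA":
                labels[e] = "early" if e in early[which] else "late"
            else:  # MPA
                labels[e] = f"{which}:early" if e in early[which] else f"{which}:late"

    if set(labels) != set(tree.edges):
        raise PartitionError("internal error: branches left unlabeled")
    return BranchPartition(scheme=scheme, labels=labels)


# ---------------------------------------------------------------------------
# free-parameter accounting

# free parameters of the omega structure per model family, beyond branch
# lengths and kappa.  Branch families include the outgroup ratio.
_FAMILY_PARAMS = {
    "M0": 2,      # omega_all, omega_OG
    "MP": 3,
    "MA": 3,
    "MPA": 5,
    "M8A": 3,     # p, q, p_ad (omega_ad fixed at 1)
    "M8": 4,      # p, q, p_ad, omega_ad
}


def family_param_count(family: str, k: int | None = None) -> int:
    if family in _FAMILY_PARAMS:
        return _FAMILY_PARAMS[family]
    if family == "M3":
        return 2 * _require_k(family, k) - 1  # k ratios + (k-1) proportions
    if family == "MD":
        return 2 * _require_k(family, k)      # M3(k) + one clade-divergent ratio
    raise ValueError(f"unknown model family {family!r}")


def _require_k(family: str, k: int | None) -> int:
    if k is None or k < 2:
        raise ValueError(f"family {family} needs a class count k >= 2")
    return k


def count_parameters(tree: LabeledPhylogeny, family: str, k: int | None = None) -> int:
    """Number of free parameters: branch lengths (2n-3 on the unrooted
    tree) + 1 (transition/transversion ratio kappa) + the family's
    omega-structure parameters."""
    return tree.n_edges + 1 + family_param_count(family, k)
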