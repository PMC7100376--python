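"""Phylogenetic classification of beta-hydroxylase stereospecificity.

TauD-family beta-hydroxylases acting on carrier-protein-bound Asp segregate
phylogenetically by the configuration of the C-3 hydroxyl they install:
enzymes producing the 3R product cluster together, as do 3S producers.  An
uncharacterized enzyme can therefore be assigned a predicted stereo class
from its placement among labeled reference sequences.

The pipeline here is distance-based: p-distances with pairwise gap deletion,
a neighbor-joining tree (deterministic lowest-index tie-break, negative
branch lengths clamped to zero with the remainder shifted to the sister
edge), rooting by a declared outgroup or at the midpoint, and column-
resampled bootstrap supports.  The classification claim is clade membership,
which at the divergences involved does not require likelihood inference —
and it is a *prediction*: hydroxylase phylogenies can track genus-level
mutational history as much as function, so the call is reported with its
supporting clade, never guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "LabeledAlignment",
    "pdistance_matrix",
    "neighbor_joining",
    "classify_query",
    "bootstrap_support",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY") | {"-", "X"}
_LABELS = {"3R", "3S", "query", "outgroup"}


@dataclass(frozen=True)
class LabeledAlignment:
    """An aligned protein family with per-sequence stereo-class labels."""

    sequences: tuple[tuple[str, str], ...]  # (name, aligned sequence)
    labels: tuple[tuple[str, str], ...]  # (name, label)

    def __post_init__(self):
        seqs = dict(self.sequences)
        if len(seqs) != len(self.sequences):
            raise ValueError("duplicate sequence names")
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        for name, seq in self.sequences:
            bad = set(seq.upper()) - _AA
            if bad:
                raise ValueError(f"{name}: invalid characters {sorted(bad)}")
        for name, label in self.labels:
            if label not in _LABELS:
                raise ValueError(f"{name}: label must be one of {sorted(_LABELS)}")
            if name not in seqs:
                raise ValueError(f"label for unknown sequence {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.sequences)

    @property
    def label_map(self) -> dict[str, str]:
        return dict(self.labels)

    def sequence(self, name: str) -> str:
        return dict(self.sequences)[name]

    def queries(self) -> tuple[str, ...]:
        return tuple(n for n, l in self.labels if l == "query")

    def outgroup(self) -> Optional[str]:
        for n, l in self.labels:
            if l == "outgroup":
                return n
        return None

    def subsample_columns(self, columns: Sequence[int]) -> "LabeledAlignment":
        cols = list(columns)
        return LabeledAlignment(
            sequences=tuple(
                (n, "".join(s[c] for c in cols)) for n, s in self.sequences
            ),
            labels=self.labels,
        )


def pdistance_matrix(aln: LabeledAlignment) -> DistanceMatrix:
    """p-distances (mismatches / compared columns) with pairwise gap deletion.

    Columns where either sequence has a gap are excluded for that pair;
    a pair with zero comparable columns is an error naming the pair.
    """
    names = aln.names
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([list(aln.sequence(n).upper()) for n in names])
    gap = arr == "-"
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            total = int(ok.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {names[i]!r} and {names[j]!r}"
                )
            mism = int((arr[i, ok] != arr[j, ok]).sum())
            d[i, j] = d[j, i] = mism / total
    return DistanceMatrix(d, ids=list(names))


def neighbor_joining(
    d: DistanceMatrix | np.ndarray,
    ids: Optional[Sequence[str]] = None,
    outgroup: Optional[str] = None,
) -> TreeNode:
    """Neighbor-joining tree from a distance matrix, returned rooted.

    Standard NJ agglomeration with two determinism/robustness choices: the
    minimum-Q pair is broken toward the lowest index pair, and a negative
    branch length is clamped to zero with the remainder shifted onto the
    sister edge (total preserved).  The unrooted result is rooted at the
    declared outgroup when given, else at the midpoint.  On an exactly
    additive metric NJ recovers the generating tree and branch lengths.
    """
    if not isinstance(d, DistanceMatrix):
        d = DistanceMatrix(np.asarray(d, dtype=float), ids=list(ids or []) or None)
    names = list(d.ids)
    n = len(names)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    dm = np.array(d.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=nm) for nm in names]

    while len(nodes) > 3:
        m = len(nodes)
        r = dm.sum(axis=1)
        q = (m - 2) * dm - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index (i, j) among minima, i < j
        best = None
        qmin = q.min()
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] <= qmin + 1e-12:
                    best = (i, j)
                    break
            if best:
                break
        i, j = best
        li = 0.5 * dm[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dm[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new = TreeNode(children=[child_i, child_j])
        du = 0.5 * (dm[i] + dm[j] - dm[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        dm = np.vstack([dm[keep][:, keep], du[keep][None, :]])
        last = np.append(du[keep], 0.0)
        dm = np.hstack([dm, last[:, None]])
        nodes = [nodes[k] for k in keep] + [new]

    # resolve the final three nodes around a star point
    (a, b, c) = nodes
    dab, dac, dbc = dm[0, 1], dm[0, 2], dm[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    tree = TreeNode(children=[a, b, c])

    if outgroup is not None:
        tree = tree.root_by_outgroup([outgroup])
    else:
        tree = tree.root_at_midpoint()
    return tree


def classify_query(
    tree: TreeNode,
    labels: Mapping[str, str],
    query: Optional[str] = None,
) -> dict:
    """Stereo-class call for a query leaf by smallest pure enclosing clade.

    Walks rootward from the query tip and returns the label of the first
    ancestor all of whose non-query leaves share one stereo-class label
    (outgroup leaves break purity).  If no such clade exists below the
    root, falls back to the nearest labeled leaf by path length; an exact
    tie between different labels is ``ambiguous``.  The deciding clade's
    bootstrap support is attached when available.
    """
    label_map = dict(labels)
    if query is None:
        queries = [n for n, l in label_map.items() if l == "query"]
        if len(queries) != 1:
            raise ValueError(
                f"expected exactly one query (got {len(queries)}); pass query= explicitly"
            )
        query = queries[0]
    ref_labels = {n: l for n, l in label_map.items() if l in ("3R", "3S")}
    if not ref_labels:
        raise ValueError("no labeled reference leaves")
    tip = tree.find(query)
    for anc in tip.ancestors():
        leaf_labels = {
            label_map.get(t.name, "unlabeled")
            for t in anc.tips()
            if t.name != query
        }
        leaf_labels.discard("query")  # other queries do not break purity
        if not leaf_labels:
            continue
        if len(leaf_labels) == 1 and (lab := leaf_labels.pop()) in ("3R", "3S"):
            support = getattr(anc, "support", None)
            return {
                "call": lab,
                "support": support,
                "clade_size": anc.count(tips=True),
                "method": "smallest pure clade",
            }
        if anc.is_root():
            break
    # fallback: nearest labeled leaf by path length
    dists = sorted(
        (tip.distance(tree.find(n)), n, l) for n, l in ref_labels.items()
    )
    best_d, _, best_l = dists[0]
    tied = {l for dd, _, l in dists if abs(dd - best_d) < 1e-12}
    if len(tied) > 1:
        return {"call": "ambiguous", "support": None, "method": "nearest leaf (tie)"}
    return {"call": best_l, "support": None, "method": "nearest leaf"}


def _bipartitions(tree: TreeNode, all_names: frozenset[str]) -> set[frozenset[str]]:
    """Canonical unrooted bipartitions (sides normalized by a reference name)."""
    ref = min(all_names)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if not 1 < len(side) < len(all_names) - 1:
            continue
        if ref in side:
            side = all_names - side
        parts.add(side)
    return parts


def bootstrap_support(
    aln: LabeledAlignment,
    n_replicates: int = 100,
    seed: int = 0,
    outgroup: Optional[str] = None,
) -> TreeNode:
    """NJ tree with bootstrap supports from column-resampled replicates.

    Each replicate resamples alignment columns with replacement, rebuilds
    the p-distance NJ tree, and every internal edge of the original tree is
    assigned the percentage of replicates containing its bipartition.
    Seeded and fully reproducible.  Supports land on ``node.support`` (and
    serialize as internal node labels in Newick output).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if outgroup is None:
        outgroup = aln.outgroup()
    tree = neighbor_joining(pdistance_matrix(aln), outgroup=outgroup)
    all_names = frozenset(aln.names)
    length = len(aln.sequence(aln.names[0]))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        rep_aln = aln.subsample_columns(cols)
        try:
            rep_tree = neighbor_joining(pdistance_matrix(rep_aln), outgroup=outgroup)
        except ValueError:
            continue  # replicate with an incomparable pair contributes nothing
        for part in _bipartitions(rep_tree, all_names):
            counts[part] = counts.get(part, 0) + 1
    ref = min(all_names)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if not 1 < len(side) < len(all_names) - 1:
            continue
        if ref in side:
            side = all_names - side
        support = 100.0 * counts.get(side, 0) / n_replicates
        node.support = round(support, 1)
        node.name = f"{node.support:g}"
    return tree
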