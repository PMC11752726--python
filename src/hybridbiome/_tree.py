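"""Branch-segment indexing for rooted phylogenies.

Phylogenetic metrics in this package (Faith's PD, phylogenetic multisite
beta, unweighted-UniFrac-style branch partitions, the branch-length 4H
index) all reduce to the same primitive: for every non-root branch of a
rooted tree, which taxa descend from it, and how long is it.  ``BranchIndex``
computes that once per tree and exposes vectorised queries, so bootstrap
loops never re-traverse the tree.

A branch is "present on" a community (an animal, or a pooled group) iff at
least one of its descendant tips is present -- standard UniFrac semantics.
The root's own stem is excluded from every total.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode


class BranchIndex:
    """Precomputed branch/clade table for a rooted tree.

    Parameters
    ----------
    tree : skbio.TreeNode
        Rooted tree with branch lengths.  Tip names must be unique and must
        be a superset of `taxa`.
    taxa : sequence of str, optional
        Column order for presence matrices.  Defaults to the tree's tips in
        postorder.  Tree tips absent from `taxa` are ignored (their
        tip-only branches can never be present).
    """

    def __init__(self, tree: TreeNode, taxa=None):
        tip_names = [t.name for t in tree.tips()]
        if len(set(tip_names)) != len(tip_names):
            raise ValueError("tree tip labels are not unique")
        if taxa is None:
            taxa = tip_names
        else:
            missing = set(taxa) - set(tip_names)
            if missing:
                raise ValueError(
                    f"taxa absent from the tree: {sorted(missing)[:5]}"
                    f"{'...' if len(missing) > 5 else ''}"
                )
        self.taxa = list(taxa)
        col = {name: i for i, name in enumerate(self.taxa)}
        n = len(self.taxa)

        lengths = []
        clades = []
        # postorder accumulation: a node's clade is the union of its children's
        node_mask: dict[int, np.ndarray] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                mask = np.zeros(n, dtype=bool)
                if node.name in col:
                    mask[col[node.name]] = True
            else:
                mask = np.zeros(n, dtype=bool)
                for child in node.children:
                    mask |= node_mask.pop(id(child))
            node_mask[id(node)] = mask
            if node.is_root():
                continue
            lengths.append(0.0 if node.length is None else float(node.length))
            clades.append(mask)

        self.lengths = np.asarray(lengths, dtype=float)
        self.clades = np.asarray(clades, dtype=bool)  # (n_branches, n_taxa)
        self._clades_f = self.clades.astype(np.float32)

    @property
    def n_branches(self) -> int:
        return len(self.lengths)

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def presence_to_branches(self, presence: np.ndarray) -> np.ndarray:
        """Map taxon presence to branch presence.

        Parameters
        ----------
        presence : bool array, shape (n_taxa,) or (n_taxa, m)
            Taxon incidence for one or `m` communities, rows ordered as
            ``self.taxa``.

        Returns
        -------
        bool array, shape (n_branches,) or (n_branches, m)
        """
        presence = np.asarray(presence)
        squeeze = presence.ndim == 1
        if squeeze:
            presence = presence[:, None]
        if presence.shape[0] != len(self.taxa):
            raise ValueError("presence rows do not match indexed taxa")
        # float32 matmul is much faster than boolean any() loops for the
        # sizes used in bootstrap resampling
        out = (self._clades_f @ presence.astype(np.float32)) > 0.5
        return out[:, 0] if squeeze else out

    def faith_pd(self, presence: np.ndarray):
        """Faith's PD (rooted; includes the path to the root) for one or
        several communities given as taxon incidence."""
        branches = self.presence_to_branches(presence)
        return self.lengths @ branches


def tip_depths(tree: TreeNode) -> dict[str, float]:
    """Root-to-tip path length for every tip."""
    depths = {}
    for tip in tree.tips():
        d = 0.0
        node = tip
        while node.parent is not None:
            d += 0.0 if node.length is None else node.length
            node = node.parent
        depths[tip.name] = d
    return depths


def is_ultrametric(tree: TreeNode, tol: float = 1e-6) -> bool:
    d = list(tip_depths(tree).values())
    return (max(d) - min(d)) <= tol * max(max(d), 1.0)
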