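"""The 4H restructuring index: intersection / union / gain / loss.

The 4H index places a hybrid community on the 3-simplex according to four
models of how its members relate to the two progenitor communities.  With
H, P1, P2 the hybrid and progenitor core sets and Omega = H u P1 u P2:

    intersection = |H n P1 n P2| / |Omega|          (kept from both)
    union        = |H n (P1 xor P2)| / |Omega|      (kept from exactly one)
    gain         = |H \\ (P1 u P2)| / |Omega|        (novel to the hybrid)
    loss         = |(P1 u P2) \\ H| / |Omega|        (progenitor-only)

The set-based form counts taxa; the branch-length form replaces |.| with
summed phylogenetic branch length over core branch segments, where a
branch segment belongs to an animal iff at least one descendant tip is
present on it (UniFrac semantics), and to a population core iff it is on
at least ceil(f*n) animals (floor 1; f = 0 gives the full microbiota).
The four components always sum to 1.  ``gain + loss`` is the support for
the transgressive axis, ``intersection + union`` for the parental axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._tree import BranchIndex
from .diversity import core_threshold
from .ordination import hybrid_null_incidence

COMPONENTS = ("intersection", "union", "gain", "loss")


@dataclass
class CoreSpec:
    """Core construction and subsampling parameters for 4H runs."""

    threshold: float = 0.0
    n_sub: int = 12
    n_trials: int = 100
    unit: str = "branch_segments"   # or "taxa"

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.n_sub < 1 or self.n_trials < 1:
            raise ValueError("n_sub and n_trials must be >= 1")
        if self.unit not in ("taxa", "branch_segments"):
            raise ValueError(f"unknown unit {self.unit!r}")


@dataclass
class FourHPoint:
    intersection: float
    union: float
    gain: float
    loss: float

    def __post_init__(self):
        vals = self.as_array()
        if (vals < -1e-12).any():
            raise ValueError("4H components must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"4H components sum to {vals.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.intersection, self.union, self.gain, self.loss])

    @property
    def transgressive_axis(self) -> float:
        return self.gain + self.loss

    @property
    def parental_axis(self) -> float:
        return self.intersection + self.union

    @property
    def retention_ratio(self) -> float:
        """Fraction of progenitor-derived hybrid material shared with BOTH
        progenitors: intersection / (intersection + union)."""
        denom = self.intersection + self.union
        return self.intersection / denom if denom > 0 else float("nan")


def fourh_from_masks(h: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                     weights: np.ndarray | None = None) -> FourHPoint:
    """4H point from aligned boolean membership masks with optional unit
    weights (branch lengths)."""
    h, p1, p2 = (np.asarray(m, dtype=bool) for m in (h, p1, p2))
    w = np.ones(len(h)) if weights is None else np.asarray(weights, dtype=float)
    omega = h | p1 | p2
    total = float(w[omega].sum())
    if total <= 0:
        raise ValueError("union of the three communities is empty")
    return FourHPoint(
        intersection=float(w[h & p1 & p2].sum()) / total,
        union=float(w[h & (p1 ^ p2)].sum()) / total,
        gain=float(w[h & ~p1 & ~p2].sum()) / total,
        loss=float(w[~h & (p1 | p2)].sum()) / total,
    )


def fourh_sets(hybrid: set, p1: set, p2: set) -> FourHPoint:
    """Set-based (taxon-count) 4H index."""
    universe = sorted(hybrid | p1 | p2)
    if not universe:
        raise ValueError("all three taxon sets are empty")
    idx = {t: i for i, t in enumerate(universe)}
    masks = []
    for s in (hybrid, p1, p2):
        m = np.zeros(len(universe), dtype=bool)
        m[[idx[t] for t in s]] = True
        masks.append(m)
    return fourh_from_masks(*masks)


def fourh_branches(hybrid_branches: dict, p1_branches: dict,
                   p2_branches: dict) -> FourHPoint:
    """Branch-length 4H from branch-id -> length mappings per community.

    A branch's length must agree across the mappings in which it appears.
    """
    lengths: dict = {}
    for d in (hybrid_branches, p1_branches, p2_branches):
        for k, v in d.items():
            if k in lengths and not math.isclose(lengths[k], v, rel_tol=1e-9):
                raise ValueError(f"conflicting lengths for branch {k!r}")
            lengths[k] = float(v)
    universe = sorted(lengths)
    idx = {b: i for i, b in enumerate(universe)}
    w = np.array([lengths[b] for b in universe])
    masks = []
    for d in (hybrid_branches, p1_branches, p2_branches):
        m = np.zeros(len(universe), dtype=bool)
        m[[idx[b] for b in d]] = True
        masks.append(m)
    return fourh_from_masks(*masks, weights=w)


def core_branches(presence: pd.DataFrame, tree: TreeNode | None = None,
                  f: float = 0.0,
                  branch_index: BranchIndex | None = None) -> dict:
    """Core branch segments of one population.

    `presence` is taxa x animals (bool); returns branch id -> length for
    every branch present on at least ceil(f*n) animals (floor 1).  Branch
    ids are indices into the tree's postorder non-root branch list.
    """
    if presence.shape[0] == 0:
        return {}
    if branch_index is None:
        if tree is None:
            raise ValueError("core_branches requires a tree or a BranchIndex")
        branch_index = BranchIndex(tree, list(presence.index))
    per_animal = branch_index.presence_to_branches(presence.to_numpy() > 0)
    thr = core_threshold(presence.shape[1], f)
    mask = per_animal.sum(axis=1) >= thr
    return {int(b): float(branch_index.lengths[b]) for b in np.nonzero(mask)[0]}


def _group_core_mask(presence: np.ndarray, f: float) -> np.ndarray:
    thr = core_threshold(presence.shape[1], f)
    return presence.sum(axis=1) >= thr


@dataclass
class FourHBootstrap:
    points: pd.DataFrame          # trial x (intersection, union, gain, loss)
    mean: FourHPoint
    spec: CoreSpec

    def summary(self) -> dict:
        return {
            **{c: float(getattr(self.mean, c if c != "union" else "union"))
               for c in COMPONENTS},
            "transgressive_axis": self.mean.transgressive_axis,
            "parental_axis": self.mean.parental_axis,
            "retention_ratio": self.mean.retention_ratio,
            "n_trials": len(self.points),
        }


def _mean_point(points: pd.DataFrame) -> FourHPoint:
    m = points[list(COMPONENTS)].mean()
    return FourHPoint(m["intersection"], m["union"], m["gain"], m["loss"])


def fourh_bootstrap(presence: pd.DataFrame, hybrid_ids, p1_ids, p2_ids,
                    spec: CoreSpec | None = None,
                    tree: TreeNode | None = None,
                    branch_index: BranchIndex | None = None,
                    seed=0, rng=None) -> FourHBootstrap:
    """Subsampled 4H index.

    Per trial, `spec.n_sub` animals are drawn without replacement from each
    of the hybrid group (site1-only, site2-only or pooled -- the caller
    chooses by passing the corresponding `hybrid_ids`) and the two
    progenitor groups; population cores are built at `spec.threshold` and
    the 4H point computed in the requested unit.
    """
    spec = spec or CoreSpec()
    if rng is None:
        rng = np.random.default_rng(seed)
    use_branches = spec.unit == "branch_segments"
    if use_branches and branch_index is None:
        if tree is None:
            raise ValueError("branch_segments unit requires a tree")
        branch_index = BranchIndex(tree, list(presence.index))

    X = presence.to_numpy() > 0
    col = {s: i for i, s in enumerate(presence.columns)}
    groups = []
    for label, ids in (("hybrid", hybrid_ids), ("p1", p1_ids), ("p2", p2_ids)):
        ids = list(ids)
        if len(ids) < spec.n_sub:
            raise ValueError(
                f"{label} group has {len(ids)} < n_sub={spec.n_sub} animals")
        groups.append(np.array([col[s] for s in ids]))

    if use_branches:
        branch_per_animal = branch_index.presence_to_branches(X)
        weights = branch_index.lengths
    else:
        branch_per_animal = X
        weights = None

    rows = []
    for t in range(spec.n_trials):
        masks = []
        for idx in groups:
            pick = idx[rng.choice(len(idx), size=spec.n_sub, replace=False)]
            masks.append(_group_core_mask(branch_per_animal[:, pick], spec.threshold))
        point = fourh_from_masks(*masks, weights=weights)
        rows.append({"trial": t, **{c: getattr(point, c) for c in COMPONENTS}})
    points = pd.DataFrame(rows)
    return FourHBootstrap(points=points, mean=_mean_point(points), spec=spec)


# ---------------------------------------------------------------------------
# null plane and retention test
# ---------------------------------------------------------------------------

@dataclass
class NullPlaneResult:
    """Operational null surface: the cloud of 4H points of incidence-null
    pseudo-hybrids plus an affine 2-plane fitted through it by SVD.  The
    construction is an operational definition, not a published one."""

    points: pd.DataFrame
    origin: np.ndarray
    basis: np.ndarray            # (2, 4) orthonormal in-plane directions

    def mean(self) -> FourHPoint:
        return _mean_point(self.points)


def null_plane(presence: pd.DataFrame, p1_ids, p2_ids,
               spec: CoreSpec | None = None,
               tree: TreeNode | None = None,
               branch_index: BranchIndex | None = None,
               seed=0, rng=None) -> NullPlaneResult:
    """Null cloud of 4H points under the incidence hybrid null model.

    Per trial, `spec.n_sub` progenitor pairs (drawn with replacement) are
    mixed into pseudo-hybrid animals; the pseudo-hybrid group is compared
    with `spec.n_sub`-animal subsamples of each progenitor.  Null hybrids
    carry no taxa outside the progenitor pool, so their gain component is
    zero up to core-threshold sampling effects.
    """
    spec = spec or CoreSpec()
    if rng is None:
        rng = np.random.default_rng(seed)
    use_branches = spec.unit == "branch_segments"
    if use_branches and branch_index is None:
        if tree is None:
            raise ValueError("branch_segments unit requires a tree")
        branch_index = BranchIndex(tree, list(presence.index))

    X = presence.to_numpy() > 0
    col = {s: i for i, s in enumerate(presence.columns)}
    idx1 = np.array([col[s] for s in p1_ids])
    idx2 = np.array([col[s] for s in p2_ids])
    for name, idx in (("p1", idx1), ("p2", idx2)):
        if len(idx) < spec.n_sub:
            raise ValueError(f"{name} group has {len(idx)} < n_sub animals")

    if use_branches:
        branch_per_animal = branch_index.presence_to_branches(X)
        weights = branch_index.lengths
    else:
        branch_per_animal = X
        weights = None

    rows = []
    for t in range(spec.n_trials):
        pseudo = np.empty((X.shape[0], spec.n_sub), dtype=bool)
        for j in range(spec.n_sub):
            a = X[:, idx1[rng.integers(len(idx1))]]
            b = X[:, idx2[rng.integers(len(idx2))]]
            pseudo[:, j] = hybrid_null_incidence(a, b, rng)
        if use_branches:
            pseudo_units = branch_index.presence_to_branches(pseudo)
        else:
            pseudo_units = pseudo
        h_mask = _group_core_mask(pseudo_units, spec.threshold)
        masks = [h_mask]
        for idx in (idx1, idx2):
            pick = idx[rng.choice(len(idx), size=spec.n_sub, replace=False)]
            masks.append(_group_core_mask(branch_per_animal[:, pick], spec.threshold))
        point = fourh_from_masks(*masks, weights=weights)
        rows.append({"trial": t, **{c: getattr(point, c) for c in COMPONENTS}})
    points = pd.DataFrame(rows)

    P = points[list(COMPONENTS)].to_numpy()
    origin = P.mean(axis=0)
    centred = P - origin
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    basis = vt[:2]
    return NullPlaneResult(points=points, origin=origin, basis=basis)


@dataclass
class RetentionTest:
    observed_ratio: float
    null_ratios: np.ndarray
    p_value: float


def retention_bias_test(observed, null_points: pd.DataFrame) -> RetentionTest:
    """One-sided empirical test for preferential retention of branches (or
    taxa) shared by BOTH progenitors.

    The statistic is intersection/(intersection+union); the p-value is the
    empirical fraction of null-cloud points with a ratio at least as large,
    with an add-one floor of 1/(n_null + 1).
    """
    if isinstance(observed, FourHBootstrap):
        ratio = observed.mean.retention_ratio
    elif isinstance(observed, FourHPoint):
        ratio = observed.retention_ratio
    else:
        ratio = float(observed)
    if not np.isfinite(ratio):
        raise ValueError("observed retention ratio is undefined")
    pts = null_points[["intersection", "union"]].to_numpy(dtype=float)
    denom = pts.sum(axis=1)
    ok = denom > 0
    null_ratios = pts[ok, 0] / denom[ok]
    n = len(null_ratios)
    if n == 0:
        raise ValueError("null cloud has no defined retention ratios")
    p = (1 + int((null_ratios >= ratio).sum())) / (n + 1)
    return RetentionTest(observed_ratio=ratio, null_ratios=null_ratios, p_value=p)


def quaternary_coordinates(points: pd.DataFrame) -> pd.DataFrame:
    """Barycentric 3-simplex coordinates (regular tetrahedron) for plotting
    4H points with external tools."""
    vertices = np.array([
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ]) / math.sqrt(3)
    P = points[list(COMPONENTS)].to_numpy(dtype=float)
    xyz = P @ vertices
    return pd.DataFrame(xyz, columns=["x", "y", "z"], index=points.index)
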