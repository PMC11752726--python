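"""Distance matrices, PCoA/PCA and triangle-plot statistics with null models.

The triangle statistic summarises where a hybrid population sits relative
to its two progenitors in ordination space: with centroids P1, P2 and H in
the retained k-dimensional principal-coordinate space,

    position = <H - P1, P2 - P1> / ||P2 - P1||^2
    height   = ||(H - P1) - position (P2 - P1)|| / ||P2 - P1||

so P1 maps to position 0, P2 to position 1, and height is the perpendicular
deviation from the inter-progenitor axis, both normalised by the
inter-progenitor distance.  Null models place pseudo-hybrids built from
progenitor individuals (incidence or abundance mixing) or plain progenitor
subsamples into the same space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .tableio import SampleTable, to_relative

DISTANCE_METRICS = ("euclidean", "jaccard", "braycurtis", "u_unifrac", "w_unifrac")
_INCIDENCE_METRICS = ("jaccard", "u_unifrac")


def distance_matrix(table: SampleTable, metric: str,
                    tree: TreeNode | None = None) -> DistanceMatrix:
    """Pairwise sample distances.

    Incidence metrics (jaccard, unweighted UniFrac) use presence/absence;
    abundance metrics (euclidean, Bray-Curtis, weighted UniFrac) use
    relative abundances.  UniFrac metrics require a tree whose tips cover
    the table's taxa.
    """
    if metric not in DISTANCE_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if (table.sample_sums() == 0).any():
        empty = list(table.sample_sums().index[table.sample_sums() == 0])
        raise ValueError(f"empty sample(s): {empty}")
    ids = table.samples
    taxa = table.taxa
    if metric in ("u_unifrac", "w_unifrac"):
        if tree is None:
            raise ValueError(f"{metric} requires a tree")
        name = "unweighted_unifrac" if metric == "u_unifrac" else "weighted_unifrac"
        counts = table.counts.T.to_numpy()
        if metric == "u_unifrac":
            counts = (counts > 0).astype(int)
            kwargs = {}
        else:
            counts = to_relative(table).T.to_numpy()
            kwargs = {"normalized": True}
        dm = beta_diversity(name, counts, ids=ids, taxa=taxa, tree=tree,
                            validate=True, **kwargs)
        return dm
    if metric == "jaccard":
        X = (table.counts.T.to_numpy() > 0)
        condensed = pdist(X, metric="jaccard")
    else:
        X = to_relative(table).T.to_numpy()
        condensed = pdist(X, metric=metric)
    return DistanceMatrix(squareform(condensed), ids=ids)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """PCoA output: samples x axes coordinates, positive eigenvalues and
    their relative magnitudes; negative-eigenvalue mass is recorded, not
    corrected."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa_ordination(dm: DistanceMatrix) -> OrdinationResult:
    """Classical (Gower-centred) principal coordinate analysis.

    Axes with non-positive eigenvalues are dropped; the total magnitude of
    negative eigenvalues is logged on the result.
    """
    if dm.shape[0] < 3:
        raise ValueError("PCoA needs at least 3 samples")
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(dm, method="eigh")
    eig = res.eigvals.to_numpy()
    neg_mass = float(np.abs(eig[eig < 0]).sum())
    keep = eig > 1e-12 * max(eig.max(), 1.0)
    eig_pos = eig[keep]
    coords = res.samples.loc[:, keep].to_numpy()
    order = np.argsort(eig_pos)[::-1]
    eig_pos = eig_pos[order]
    coords = coords[:, order]
    columns = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=columns),
        eigenvalues=eig_pos,
        proportion_explained=eig_pos / eig_pos.sum(),
        negative_eigenvalue_mass=neg_mass,
    )


def n_retained_axes(result: OrdinationResult, max_axes: int = 20,
                    target: float = 0.95) -> int:
    """Axis-retention rule for triangle statistics: 20 axes when at least 20
    positive axes exist and together they explain > `target` of the
    variance, otherwise the smallest k reaching `target` (capped at the
    number of positive axes)."""
    cum = np.cumsum(result.proportion_explained)
    if len(cum) >= max_axes and cum[max_axes - 1] > target:
        return max_axes
    reaching = np.nonzero(cum >= target)[0]
    return int(reaching[0]) + 1 if len(reaching) else len(cum)


@dataclass
class PCAResult:
    variance_pct: np.ndarray
    loading_share: pd.DataFrame   # taxa x axes, percent of squared loading
    dominant: pd.DataFrame        # per axis: taxon, share_pct, variance_pct


def pca_dominant_loadings(relabund: pd.DataFrame, n_axes: int = 2) -> PCAResult:
    """Covariance PCA on samples x taxa relative abundances.

    Input is taxa x samples (as produced by ``to_relative``).  Data are
    centred but not variance-scaled; per axis we report the percent of
    variance explained and each taxon's squared-loading share, whose
    largest entry is the axis's "dominant" taxon.
    """
    X = relabund.T.to_numpy(dtype=float)
    taxa = list(relabund.index)
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("constant table: PCA undefined (zero variance)")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    n_axes = min(n_axes, (var > 1e-15 * var.max()).sum())
    variance_pct = 100.0 * var[:n_axes] / var.sum()
    loadings = vt[:n_axes].T                       # taxa x axes, unit columns
    share = 100.0 * loadings ** 2
    axes = [f"PC{i + 1}" for i in range(n_axes)]
    share_df = pd.DataFrame(share, index=taxa, columns=axes)
    rows = []
    for i, axis in enumerate(axes):
        top = share_df[axis].idxmax()
        rows.append({"axis": axis, "taxon": top,
                     "share_pct": float(share_df.loc[top, axis]),
                     "variance_pct": float(variance_pct[i])})
    return PCAResult(variance_pct, share_df, pd.DataFrame(rows).set_index("axis"))


# ---------------------------------------------------------------------------
# triangle statistics
# ---------------------------------------------------------------------------

def triangle_position_height(hybrid: np.ndarray, p1: np.ndarray,
                             p2: np.ndarray) -> tuple:
    """Projection (position) and perpendicular deviation (height) of a
    hybrid centroid relative to the two progenitor centroids, normalised by
    the inter-progenitor distance."""
    hybrid, p1, p2 = (np.asarray(v, dtype=float) for v in (hybrid, p1, p2))
    axis = p2 - p1
    denom = float(axis @ axis)
    if denom < 1e-24:
        raise ValueError("progenitor centroids coincide; axis undefined")
    position = float((hybrid - p1) @ axis / denom)
    perp = (hybrid - p1) - position * axis
    height = float(np.linalg.norm(perp) / np.sqrt(denom))
    return position, height


def triangle_bootstrap(coords: pd.DataFrame, groups, hybrid_label: str,
                       p1_label: str, p2_label: str, n_sub: int = 12,
                       trials: int = 50, seed=0, rng=None) -> pd.DataFrame:
    """Subsampled triangle statistics.

    Per trial, `n_sub` individuals are drawn without replacement from each
    of the hybrid and two progenitor groups; position and height are
    computed from the subsample centroids in the full k-dimensional space.

    `groups` is either a sample -> label Series/mapping, or a
    label -> sample-id-list dict (which allows the same samples to serve as
    both the pseudo-hybrid and a progenitor group in progenitor null runs).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(groups, dict) and all(
            isinstance(v, (list, tuple)) for v in groups.values()):
        members = {lab: list(groups[lab])
                   for lab in (hybrid_label, p1_label, p2_label)}
    else:
        groups = pd.Series(groups)
        members = {lab: list(groups.index[groups == lab])
                   for lab in (hybrid_label, p1_label, p2_label)}
    for lab, ids in members.items():
        if len(ids) < n_sub:
            raise ValueError(f"group {lab!r} has {len(ids)} < n_sub={n_sub} members")
    X = coords.to_numpy(dtype=float)
    row = {s: i for i, s in enumerate(coords.index)}
    rows = []
    for t in range(trials):
        cents = {}
        for lab, ids in members.items():
            pick = rng.choice(len(ids), size=n_sub, replace=False)
            idx = [row[ids[i]] for i in pick]
            cents[lab] = X[idx].mean(axis=0)
        pos, height = triangle_position_height(
            cents[hybrid_label], cents[p1_label], cents[p2_label])
        rows.append({"trial": t, "position": pos, "height": height})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

def hybrid_null_incidence(p1_presence, p2_presence, rng) -> np.ndarray:
    """Incidence null pseudo-hybrid from one progenitor pair.

    Taxa present on both parents are kept; of the m taxa present on exactly
    one parent, exactly round(m/2) are kept, chosen uniformly without
    replacement.  The pseudo-individual's richness is therefore
    deterministic given the parent pair.
    """
    x1 = np.asarray(p1_presence) > 0
    x2 = np.asarray(p2_presence) > 0
    out = x1 & x2
    sym = np.nonzero(x1 ^ x2)[0]
    m = len(sym)
    k = int(np.floor(m / 2 + 0.5))
    if k:
        out = out.copy()
        out[rng.choice(sym, size=k, replace=False)] = True
    return out


def hybrid_null_abundance(p1_relabund, p2_relabund) -> np.ndarray:
    """Abundance null pseudo-hybrid: arithmetic mean of the two parents'
    relative-abundance vectors (sums to 1 when the parents do)."""
    a1 = np.asarray(p1_relabund, dtype=float)
    a2 = np.asarray(p2_relabund, dtype=float)
    return (a1 + a2) / 2.0


def null_hybrid_profiles(matrix: pd.DataFrame, p1_ids, p2_ids, n: int,
                         mode: str, rng, prefix: str = "nullH") -> pd.DataFrame:
    """Build `n` pseudo-hybrid sample profiles from random progenitor pairs.

    `matrix` is taxa x samples: presence (mode="incidence") or relative
    abundance (mode="abundance").  Pairs are drawn with replacement.
    """
    if mode not in ("incidence", "abundance"):
        raise ValueError(f"unknown null mode {mode!r}")
    cols = {}
    p1_ids, p2_ids = list(p1_ids), list(p2_ids)
    for j in range(n):
        a = matrix[p1_ids[rng.integers(len(p1_ids))]].to_numpy()
        b = matrix[p2_ids[rng.integers(len(p2_ids))]].to_numpy()
        if mode == "incidence":
            cols[f"{prefix}_{j:03d}"] = hybrid_null_incidence(a, b, rng).astype(int)
        else:
            cols[f"{prefix}_{j:03d}"] = hybrid_null_abundance(a, b)
    return pd.DataFrame(cols, index=matrix.index)


def triangle_compare(observed: pd.DataFrame, null: pd.DataFrame,
                     axis: str = "position") -> float:
    """Two-sided Mann-Whitney U between observed and null per-trial
    triangle statistics.

    The per-trial subsample statistics are treated as the units of
    comparison (pseudo-replication caveat: trials reuse individuals, so the
    p-value is a heuristic stand-in, not an exact test).
    """
    if axis not in ("position", "height"):
        raise ValueError("axis must be 'position' or 'height'")
    a = observed[axis].to_numpy(dtype=float)
    b = null[axis].to_numpy(dtype=float)
    pooled = np.concatenate([a, b])
    if np.allclose(pooled, pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def axis_group_test(coords: pd.DataFrame, axis: int, group_a_ids,
                    group_b_ids) -> float:
    """Two-sided Mann-Whitney U between two groups of samples along one
    ordination axis (0-based index)."""
    a = coords.iloc[:, axis].loc[list(group_a_ids)].to_numpy(dtype=float)
    b = coords.iloc[:, axis].loc[list(group_b_ids)].to_numpy(dtype=float)
    pooled = np.concatenate([a, b])
    if np.allclose(pooled, pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
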