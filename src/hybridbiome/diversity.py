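"""Alpha/beta/gamma/core diversity with Chao-style bootstrap assemblages.

Population-level diversity traits (multisite beta, gamma, core, unique
core) are single numbers per population, so their uncertainty is assessed
by resampling from an estimated "bootstrap assemblage": per-taxon detection
probabilities shrunk for imperfect detection, plus an estimated number of
undetected taxa (Chao2-style, incidence data).  From each assemblage, B
pseudo-populations of n individuals are drawn, the trait is recomputed on
each, and an 83.4% percentile interval is formed; two populations are
declared different when their intervals are disjoint, which corresponds to
a pairwise test at roughly alpha = 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from skbio.diversity.alpha import shannon as _skbio_shannon
from statsmodels.stats.multitest import multipletests

from ._tree import BranchIndex, is_ultrametric, tip_depths

ALPHA_METRICS = ("richness", "shannon", "simpson", "faith_pd", "rao_q")


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(counts, metric: str, tree: TreeNode | None = None, taxa=None) -> float:
    """Single-sample diversity.

    Parameters
    ----------
    counts : 1-D array or pandas Series
        Taxon counts for one sample.  If a Series, its index supplies taxon
        ids; otherwise `taxa` must be given for phylogenetic metrics.
    metric : one of richness, shannon, simpson, faith_pd, rao_q
        shannon uses natural log; simpson is Gini-Simpson (1 - sum p^2);
        faith_pd is the rooted form (root path included); rao_q is
        sum_ij d_ij p_i p_j with cophenetic distances on an ultrametric
        tree.
    """
    if metric not in ALPHA_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if isinstance(counts, pd.Series):
        taxa = list(counts.index)
        values = counts.to_numpy(dtype=float)
    else:
        values = np.asarray(counts, dtype=float)
    total = values.sum()
    if metric == "richness":
        return float((values > 0).sum())
    if total == 0:
        raise ValueError(f"{metric} is undefined for an empty sample")
    if metric == "shannon":
        return float(_skbio_shannon(values))
    if metric == "simpson":
        p = values / total
        return float(1.0 - (p ** 2).sum())
    if tree is None:
        raise ValueError(f"{metric} requires a tree")
    if taxa is None:
        raise ValueError(f"{metric} requires taxon ids")
    index = BranchIndex(tree, taxa)
    if metric == "faith_pd":
        return float(index.faith_pd(values > 0))
    # rao_q
    if not is_ultrametric(tree):
        raise ValueError(
            "rao_q requires an ultrametric tree; run ultrametricize_mpl first"
        )
    present = values > 0
    p = values[present] / total
    names = [t for t, keep in zip(taxa, present) if keep]
    dm = tree.tip_tip_distances(set(names))
    d = dm.filter(names).data
    return float(p @ d @ p)


def ultrametricize_mpl(tree: TreeNode) -> TreeNode:
    """Mean-path-length dating: make a tree ultrametric.

    Multichotomies are resolved to arbitrary binary nodes (zero-length
    internal edges) first; each internal node is then aged at the mean path
    length from the node to its descendant tips, bottom-up, and branch
    lengths are rewritten as age differences.  Tip set is preserved.
    """
    tree = tree.copy()
    _resolve_multichotomies(tree)
    ages: dict[int, float] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            ages[id(node)] = 0.0
        else:
            paths = []
            for child in node.children:
                length = 0.0 if child.length is None else child.length
                paths.append(ages[id(child)] + length)
            ages[id(node)] = float(np.mean(paths))
    if ages[id(tree)] == 0.0:
        warnings.warn("tree has zero total depth; all ages are 0", stacklevel=2)
    negative = 0
    for node in tree.preorder(include_self=False):
        new_len = ages[id(node.parent)] - ages[id(node)]
        if new_len < 0:
            negative += 1
            new_len = 0.0
            # keep the tree consistent: pull the node's age up to its parent
            ages[id(node)] = ages[id(node.parent)]
        node.length = new_len
    if negative:
        warnings.warn(
            f"{negative} branch(es) clamped to zero during mean-path-length "
            "dating", stacklevel=2,
        )
    tree.length = 0.0
    return tree


def _resolve_multichotomies(tree: TreeNode):
    for node in list(tree.postorder(include_self=True)):
        while len(node.children) > 2:
            a = node.children[0]
            b = node.children[1]
            node.remove(a)
            node.remove(b)
            joined = TreeNode(length=0.0, children=[a, b])
            node.append(joined)


# ---------------------------------------------------------------------------
# bootstrap assemblages (incidence data)
# ---------------------------------------------------------------------------

@dataclass
class IncidenceProfile:
    """Incidence summary of one population: T sampling units (individuals)
    and per-taxon incidence frequencies Y_i (only detected taxa, Y_i >= 1)."""

    T: int
    frequencies: pd.Series

    def __post_init__(self):
        if self.T < 2:
            raise ValueError("need at least T = 2 sampling units")
        y = self.frequencies
        if ((y < 1) | (y > self.T)).any():
            raise ValueError("incidence frequencies must lie in [1, T]")

    @property
    def U(self) -> int:
        return int(self.frequencies.sum())

    @property
    def Q1(self) -> int:
        return int((self.frequencies == 1).sum())

    @property
    def Q2(self) -> int:
        return int((self.frequencies == 2).sum())


def incidence_profile(incidence) -> IncidenceProfile:
    """Build a profile from a taxa x individuals presence table."""
    inc = incidence if isinstance(incidence, pd.DataFrame) else pd.DataFrame(incidence)
    y = (inc > 0).sum(axis=1)
    return IncidenceProfile(T=inc.shape[1], frequencies=y[y > 0].astype(int))


@dataclass
class BootstrapAssemblage:
    """Estimated community: detection probabilities for observed taxa plus
    `q0` anonymous undetected taxa at probability `pi0`."""

    taxa: list
    pi: np.ndarray
    q0: int
    pi0: float | None
    observed_only: bool = False
    q0_hat: float = 0.0   # continuous Chao2 estimate before rounding

    @property
    def size(self) -> int:
        return len(self.taxa) + self.q0

    def all_probabilities(self) -> np.ndarray:
        if self.q0:
            return np.concatenate([self.pi, np.full(self.q0, self.pi0)])
        return self.pi

    def all_taxa(self, anon_prefix: str = "undetected") -> list:
        return list(self.taxa) + [f"{anon_prefix}_{k}" for k in range(self.q0)]


def chao_assemblage(profile: IncidenceProfile, observed_only: bool = False) -> BootstrapAssemblage:
    """Chao2-style bootstrap assemblage from incidence frequencies.

    The undetected richness is the Chao2 estimator

        Q0 = ((T-1)/T) Q1^2 / (2 Q2)          if Q2 > 0
        Q0 = ((T-1)/T) Q1 (Q1-1) / 2          if Q2 = 0

    the incidence coverage deficit is (Q1/U) (T-1)Q1 / ((T-1)Q1 + 2Q2),
    observed detection probabilities are shrunk as
    pi_i = (Y_i/T) (1 - lambda (1 - Y_i/T)^T) with lambda chosen so the
    total shrinkage equals the estimated deficit, and each undetected taxon
    gets the deficit spread evenly.  With `observed_only` the undetected
    component is dropped (used for unique-core analyses, where anonymous
    taxa cannot be matched across populations).
    """
    T = profile.T
    y = profile.frequencies.to_numpy(dtype=float)
    U = profile.U
    if U == 0:
        raise ValueError("empty population: no incidences")
    Q1, Q2 = profile.Q1, profile.Q2

    if Q1 == 0:
        q0_hat = 0.0
        deficit = 0.0
    else:
        if Q2 > 0:
            q0_hat = ((T - 1) / T) * Q1 ** 2 / (2 * Q2)
        else:
            q0_hat = ((T - 1) / T) * Q1 * (Q1 - 1) / 2
        deficit = (Q1 / U) * ((T - 1) * Q1 / ((T - 1) * Q1 + 2 * Q2))

    rel = y / T
    denom = float((rel * (1 - rel) ** T).sum())
    lam = ((U / T) * deficit / denom) if denom > 0 else 0.0
    pi = rel * (1 - lam * (1 - rel) ** T)
    pi = np.clip(pi, 1e-12, 1.0)

    if observed_only or q0_hat == 0:
        q0, pi0 = 0, None
    else:
        q0 = int(round(q0_hat))
        if q0 == 0:
            pi0 = None
        else:
            pi0 = float(np.clip((U / T) * deficit / q0_hat, 0.0, 1.0))
    return BootstrapAssemblage(
        taxa=list(profile.frequencies.index), pi=pi, q0=q0, pi0=pi0,
        observed_only=observed_only, q0_hat=float(q0_hat),
    )


def draw_bootstrap_population(assemblage: BootstrapAssemblage, n: int = 15,
                              seed=None, rng=None) -> pd.DataFrame:
    """One pseudo-population: taxa x n boolean incidence, each taxon present
    in each pseudo-individual independently with its detection probability."""
    if rng is None:
        rng = np.random.default_rng(seed)
    p = assemblage.all_probabilities()
    draws = rng.random((len(p), n)) < p[:, None]
    return pd.DataFrame(draws, index=assemblage.all_taxa())


def draw_bootstrap_matrix(assemblage: BootstrapAssemblage, n: int, B: int,
                          rng) -> np.ndarray:
    """B pseudo-populations at once: bool array (B, n_taxa_total, n)."""
    p = assemblage.all_probabilities()
    return rng.random((B, len(p), n)) < p[None, :, None]


# ---------------------------------------------------------------------------
# multisite beta / gamma / core
# ---------------------------------------------------------------------------

def _site_branch_matrix(incidence: np.ndarray, index: BranchIndex) -> np.ndarray:
    return index.presence_to_branches(incidence)


def multisite_beta(incidence, family: str = "jaccard",
                   tree: TreeNode | None = None,
                   branch_index: BranchIndex | None = None) -> float:
    """Multiple-site Jaccard-family dissimilarity across N communities.

    With S_i the richness of site i, S_T the pooled richness and b_ij the
    number of taxa exclusive to site i relative to site j:

        beta = (sum_min + sum_max) /
               ((sum_i S_i - S_T) + sum_min + sum_max)

    where sum_min = sum_{i<j} min(b_ij, b_ji) and sum_max the analogous
    maximum.  The ``phylo_jaccard`` variant replaces taxa with branch
    segments weighted by branch length (richness -> Faith's PD, exclusives
    -> exclusive branch length).  For N = 2 this reduces to the pairwise
    (phylogenetic) Jaccard dissimilarity.
    """
    if family not in ("jaccard", "phylo_jaccard"):
        raise ValueError(f"unknown family {family!r}")
    if isinstance(incidence, pd.DataFrame):
        taxa = list(incidence.index)
        X = incidence.to_numpy() > 0
    else:
        taxa = None
        X = np.asarray(incidence) > 0
    n_sites = X.shape[1]
    if n_sites < 2:
        raise ValueError("multisite beta needs at least 2 communities")
    if (X.sum(axis=0) == 0).any():
        raise ValueError("empty community passed to multisite_beta")

    if family == "phylo_jaccard":
        if branch_index is None:
            if tree is None:
                raise ValueError("phylo_jaccard requires a tree")
            branch_index = BranchIndex(tree, taxa)
        Xb = _site_branch_matrix(X, branch_index)
        w = branch_index.lengths
    else:
        Xb = X
        w = np.ones(X.shape[0])

    # b_ij = weighted count of units present in i and absent in j
    Wb = Xb * w[:, None]
    b = Wb.T @ (~Xb)                     # (N, N)
    iu = np.triu_indices(n_sites, k=1)
    bij, bji = b[iu], b.T[iu]
    sum_min = np.minimum(bij, bji).sum()
    sum_max = np.maximum(bij, bji).sum()
    s_sites = Wb.sum(axis=0).sum()
    s_total = w[Xb.any(axis=1)].sum()
    denom = (s_sites - s_total) + sum_min + sum_max
    if denom == 0:
        return 0.0
    return float((sum_min + sum_max) / denom)


def gamma_diversity(incidence, metric: str = "richness",
                    tree: TreeNode | None = None,
                    branch_index: BranchIndex | None = None) -> float:
    """Diversity of the pooled (union) community across all individuals."""
    if isinstance(incidence, pd.DataFrame):
        taxa = list(incidence.index)
        X = incidence.to_numpy() > 0
    else:
        taxa = None
        X = np.asarray(incidence) > 0
    union = X.any(axis=1)
    if metric == "richness":
        return float(union.sum())
    if metric == "faith_pd":
        if branch_index is None:
            if tree is None:
                raise ValueError("faith_pd requires a tree")
            branch_index = BranchIndex(tree, taxa)
        return float(branch_index.faith_pd(union))
    raise ValueError(f"unknown gamma metric {metric!r}")


def core_threshold(n: int, f: float) -> int:
    """Minimum host count for core membership: ceil(f*n) with a floor of 1.

    At n = 15 and f = 0.5 this is 8 hosts; f = 0 means present on at least
    one host, i.e. the full microbiota.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("core threshold fraction must be in [0, 1]")
    return max(1, math.ceil(f * n))


def core_set(incidence, f: float = 0.5) -> set:
    """Taxa present on at least the core-threshold number of individuals."""
    inc = incidence if isinstance(incidence, pd.DataFrame) else pd.DataFrame(incidence)
    thr = core_threshold(inc.shape[1], f)
    y = (inc > 0).sum(axis=1)
    return set(y.index[y >= thr])


def unique_core_set(cores: dict, roles: dict) -> dict:
    """Per-population unique cores.

    A progenitor's unique core excludes the cores of all other populations;
    a hybrid's unique core excludes only the two progenitor cores (a taxon
    shared with the other hybrid core still counts as unique).
    """
    progenitors = [p for p, r in roles.items() if r in ("maternal", "paternal")]
    out = {}
    for pop, core in cores.items():
        if roles[pop] == "hybrid":
            exclude = set().union(*(cores[p] for p in progenitors)) if progenitors else set()
        else:
            exclude = set().union(*(cores[q] for q in cores if q != pop))
        out[pop] = core - exclude
    return out


# ---------------------------------------------------------------------------
# bootstrap suite over populations
# ---------------------------------------------------------------------------

CORE_TRAITS = ("beta", "gamma", "core", "pct_core", "unique_core", "pct_unique_core")


def bootstrap_core_suite(incidence_by_pop: dict, roles: dict,
                         tree: TreeNode | None = None,
                         metric: str = "richness", f: float = 0.5,
                         B: int = 500, n: int = 15, seed: int = 0,
                         observed_only: bool | None = None) -> pd.DataFrame:
    """Bootstrap beta/gamma/core/unique-core traits for several populations.

    Parameters
    ----------
    incidence_by_pop : dict
        Population label -> taxa x individuals presence table (DataFrame).
    roles : dict
        Population label -> hybrid / maternal / paternal (drives the
        unique-core rule).
    metric : "richness" or "faith_pd"
        Unit of diversity.  `faith_pd` requires `tree` and forces
        observed-taxa-only assemblages (anonymous undetected taxa have no
        placement on the tree).
    observed_only : bool, optional
        Default: True for faith_pd, False for richness.

    Returns a long DataFrame with columns population, replicate, trait,
    value.  Replicates where a ratio is undefined (empty core) carry NaN.
    """
    if metric not in ("richness", "faith_pd"):
        raise ValueError(f"unsupported metric {metric!r}")
    phylo = metric == "faith_pd"
    if observed_only is None:
        observed_only = phylo
    if phylo and not observed_only:
        raise ValueError("faith_pd bootstraps require observed-only assemblages")

    assemblages = {
        pop: chao_assemblage(incidence_profile(inc), observed_only=observed_only)
        for pop, inc in incidence_by_pop.items()
    }
    pops = list(assemblages)

    # global taxon space so cores can be compared across populations
    global_taxa: list = []
    position: dict = {}
    pop_index = {}
    for pop in pops:
        asm = assemblages[pop]
        labels = asm.all_taxa(anon_prefix=f"{pop}|undetected")
        idx = np.empty(len(labels), dtype=int)
        for k, t in enumerate(labels):
            if t not in position:
                position[t] = len(global_taxa)
                global_taxa.append(t)
            idx[k] = position[t]
        pop_index[pop] = idx

    branch_index = None
    if phylo:
        if tree is None:
            raise ValueError("faith_pd requires a tree")
        branch_index = BranchIndex(tree, global_taxa)

    rng = np.random.default_rng(seed)
    n_global = len(global_taxa)
    records = []
    family = "phylo_jaccard" if phylo else "jaccard"
    n_empty_core = 0
    for b in range(B):
        cores = {}
        per_pop = {}
        for pop in pops:
            asm = assemblages[pop]
            p = asm.all_probabilities()
            draw = rng.random((len(p), n)) < p[:, None]
            X = np.zeros((n_global, n), dtype=bool)
            X[pop_index[pop]] = draw
            thr = core_threshold(n, f)
            core_mask = X.sum(axis=1) >= thr
            gamma_mask = X.any(axis=1)
            if phylo:
                gamma_val = float(branch_index.faith_pd(gamma_mask))
                core_val = float(branch_index.faith_pd(core_mask))
            else:
                gamma_val = float(gamma_mask.sum())
                core_val = float(core_mask.sum())
            beta_val = multisite_beta(X, family=family, branch_index=branch_index)
            cores[pop] = core_mask
            per_pop[pop] = (beta_val, gamma_val, core_val)
        # unique cores across populations
        progenitors = [p for p in pops if roles[p] in ("maternal", "paternal")]
        for pop in pops:
            beta_val, gamma_val, core_val = per_pop[pop]
            if roles[pop] == "hybrid":
                exclude = np.zeros(n_global, dtype=bool)
                for q in progenitors:
                    exclude |= cores[q]
            else:
                exclude = np.zeros(n_global, dtype=bool)
                for q in pops:
                    if q != pop:
                        exclude |= cores[q]
            unique_mask = cores[pop] & ~exclude
            if phylo:
                uniq_val = float(branch_index.faith_pd(unique_mask))
            else:
                uniq_val = float(unique_mask.sum())
            pct_core = 100.0 * core_val / gamma_val if gamma_val > 0 else np.nan
            if core_val > 0:
                pct_unique = 100.0 * uniq_val / core_val
            else:
                pct_unique = np.nan
                n_empty_core += 1
            values = {
                "beta": beta_val, "gamma": gamma_val, "core": core_val,
                "pct_core": pct_core, "unique_core": uniq_val,
                "pct_unique_core": pct_unique,
            }
            for trait, value in values.items():
                records.append((pop, b, trait, value))
    if n_empty_core:
        warnings.warn(
            f"{n_empty_core} replicate(s) had an empty core; their percent "
            "unique-core values are missing", stacklevel=2,
        )
    return pd.DataFrame(records, columns=["population", "replicate", "trait", "value"])


def ci_from_bootstraps(values, level: float = 0.834) -> tuple:
    """Percentile interval from bootstrap replicates by order statistics.

    For B = 500 and the default 83.4% level, the bounds are the 83rd and
    417th sorted values; generally round((1-level)*B) and round(level*B)
    (1-indexed).  Missing values are dropped first.
    """
    v = np.asarray(values, dtype=float)
    v = np.sort(v[~np.isnan(v)])
    B = len(v)
    if B == 0:
        raise ValueError("no finite bootstrap values")
    lo = min(max(int(round((1 - level) * B)), 1), B)
    hi = min(max(int(round(level * B)), 1), B)
    return float(v[lo - 1]), float(v[hi - 1])


def ci_overlap_test(a: tuple, b: tuple) -> bool:
    """True (significant) iff the two intervals are disjoint; touching
    endpoints count as overlap."""
    return bool(a[1] < b[0] or b[1] < a[0])


def summarize_bootstrap(long_df: pd.DataFrame, level: float = 0.834) -> pd.DataFrame:
    """Median + CI per (trait, population), plus the effective replicate
    count after dropping missing values."""
    rows = []
    for (trait, pop), grp in long_df.groupby(["trait", "population"]):
        v = grp["value"].to_numpy(dtype=float)
        finite = v[~np.isnan(v)]
        lo, hi = ci_from_bootstraps(finite, level=level)
        rows.append({
            "trait": trait, "population": pop,
            "median": float(np.median(finite)), "ci_lo": lo, "ci_hi": hi,
            "n_effective": len(finite),
        })
    return pd.DataFrame(rows)


def pairwise_ci_significance(summary: pd.DataFrame) -> pd.DataFrame:
    """All pairwise disjoint-CI calls per trait from a summary table."""
    rows = []
    for trait, grp in summary.groupby("trait"):
        pops = list(grp["population"])
        ci = {r["population"]: (r["ci_lo"], r["ci_hi"]) for _, r in grp.iterrows()}
        for i, a in enumerate(pops):
            for b in pops[i + 1:]:
                rows.append({
                    "trait": trait, "population_a": a, "population_b": b,
                    "significant": ci_overlap_test(ci[a], ci[b]),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nonparametric group tests
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    omnibus_p: float
    omnibus_test: str
    pairwise: pd.DataFrame | None
    alpha: float

    def pairwise_p(self, a: str, b: str) -> float | None:
        if self.pairwise is None:
            return None
        m = self.pairwise
        hit = m[((m["group_a"] == a) & (m["group_b"] == b))
                | ((m["group_a"] == b) & (m["group_b"] == a))]
        return float(hit["p_adjusted"].iloc[0]) if len(hit) else None


def group_tests(groups: dict, alpha: float = 0.05) -> GroupTestResult:
    """Kruskal-Wallis omnibus across groups, then pairwise Mann-Whitney U
    with Benjamini-Hochberg correction when the omnibus is significant.
    Two groups use Mann-Whitney U directly."""
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    for g, arr in zip(labels, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        omnibus_p, test = 1.0, "degenerate"
    elif len(labels) == 2:
        omnibus_p = float(stats.mannwhitneyu(
            arrays[0], arrays[1], alternative="two-sided").pvalue)
        test = "mannwhitneyu"
    else:
        omnibus_p = float(stats.kruskal(*arrays).pvalue)
        test = "kruskal"

    pairwise = None
    if omnibus_p <= alpha and len(labels) > 2:
        pairs, raw = [], []
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                xa, xb = groups[a], groups[b]
                both = np.concatenate([xa, xb])
                if np.allclose(both, both[0]):
                    p = 1.0
                else:
                    p = float(stats.mannwhitneyu(
                        xa, xb, alternative="two-sided").pvalue)
                pairs.append((a, b))
                raw.append(p)
        adjusted = multipletests(raw, method="fdr_bh")[1]
        pairwise = pd.DataFrame({
            "group_a": [p[0] for p in pairs],
            "group_b": [p[1] for p in pairs],
            "p_raw": raw,
            "p_adjusted": adjusted,
        })
    return GroupTestResult(omnibus_p, test, pairwise, alpha)
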