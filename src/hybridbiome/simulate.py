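"""Synthetic hybrid/progenitor community generator with known ground truth.

Emulates the sampling design of a two-site hybrid-parthenogen study: at one
site the hybrid co-occurs with its maternal progenitor, at the other with
its paternal progenitor, with ~15 all-female individuals per population and
one body site per table.  Taxon pools are explicit -- shared between both
progenitors, exclusive to one progenitor, or novel (available only to the
hybrid) -- so the true (intersection, union, gain, loss) composition of the
hybrid microbiota is known exactly and downstream estimators can be tested
for parameter recovery.

The generative model:

* the hybrid taxon pool keeps each shared taxon with probability
  ``p_keep_shared``, each progenitor-exclusive taxon with
  ``p_keep_exclusive``, and gains each novel taxon with ``p_gain``;
* every (population, taxon) pair gets an independent Beta-distributed
  detection probability (occupancy), producing the high interindividual
  turnover typical of squamate skin/gut communities;
* per-individual presence is Bernoulli(occupancy); counts are multinomial
  at a fixed read depth with log-normal relative-abundance weights,
  conditional on presence (absent taxa get zero counts);
* the phylogeny is a random binary tree over all pool taxa with
  exponential branch lengths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tableio import SampleTable

POPULATIONS = (
    ("hybrid_site1", "A. neomexicanus", "site1", "hybrid"),
    ("maternal_site1", "A. marmoratus", "site1", "maternal"),
    ("hybrid_site2", "A. neomexicanus", "site2", "hybrid"),
    ("paternal_site2", "A. inornatus", "site2", "paternal"),
)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the field design the generator emulates: 15 individuals
    per population, a few hundred taxa, read depths in the 1e4--1e5 range,
    and Beta(2, 2) occupancy heterogeneity.
    """

    seed: int = 0
    n_individuals: int = 15
    n_shared: int = 120
    n_p1_only: int = 60   # maternal-progenitor-exclusive pool
    n_p2_only: int = 60   # paternal-progenitor-exclusive pool
    n_novel: int = 60
    p_keep_shared: float = 0.9
    p_keep_exclusive: float = 0.35
    p_gain: float = 0.25
    occupancy_shape: tuple = (2.0, 2.0)
    occupancy: float | None = None  # fixed occupancy overriding the Beta draw
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    read_depth: int = 20000
    site_effect: float = 0.0        # additive shift on occupancy logits at site2
    site_effect_fraction: float = 0.25
    tree_rate: float = 1.0
    body_site: str = "gut"

    def __post_init__(self):
        for name in ("p_keep_shared", "p_keep_exclusive", "p_gain"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name in ("n_shared", "n_p1_only", "n_p2_only", "n_novel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.occupancy is not None and not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must be in (0, 1]")
        if self.site_effect < 0:
            raise ValueError("site_effect must be nonnegative")


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    pool_labels: dict            # taxon -> shared / p1_only / p2_only / novel
    hybrid_pool: set             # realized hybrid taxon pool
    fourh_true: dict             # intersection/union/gain/loss of the pools
    occupancy: dict              # population -> pandas Series (taxon -> prob)
    degenerate: bool = False     # hybrid pool came out empty

    def __post_init__(self):
        total = sum(self.fourh_true.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"true 4H fractions sum to {total}, not 1")


def simulate_tree(n_taxa: int, rate: float = 1.0, seed: int = 0, labels=None) -> TreeNode:
    """Random rooted binary tree with Exp(rate) branch lengths.

    Built by uniform random joins (a Yule-type labelled topology); every
    non-root branch gets an independent exponential length, the root stem
    gets length 0.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    if labels is None:
        width = max(3, len(str(n_taxa)))
        labels = [f"t{i:0{width}d}" for i in range(n_taxa)]
    elif len(labels) != n_taxa:
        raise ValueError("labels length must equal n_taxa")

    def _edge():
        # strictly positive exponential branch length
        return float(rng.exponential(1.0 / rate)) + 1e-9

    nodes = []
    for name in labels:
        tip = TreeNode(name=name, length=_edge())
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=_edge(), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def _pool_taxa(config: SimConfig) -> dict:
    width = 3
    return {
        "shared": [f"sh{i:0{width}d}" for i in range(config.n_shared)],
        "p1_only": [f"m{i:0{width}d}" for i in range(config.n_p1_only)],
        "p2_only": [f"p{i:0{width}d}" for i in range(config.n_p2_only)],
        "novel": [f"nv{i:0{width}d}" for i in range(config.n_novel)],
    }


def assemble_hybrid_pool(config: SimConfig, rng: np.random.Generator) -> set:
    """Bernoulli assembly of the hybrid pool.

    Draw order is fixed (shared, then p1-exclusive, then p2-exclusive, then
    novel, one uniform per taxon) so the assembly can be replayed
    independently from the same seed.
    """
    pools = _pool_taxa(config)
    hybrid = set()
    for taxon in pools["shared"]:
        if rng.random() < config.p_keep_shared:
            hybrid.add(taxon)
    for taxon in pools["p1_only"] + pools["p2_only"]:
        if rng.random() < config.p_keep_exclusive:
            hybrid.add(taxon)
    for taxon in pools["novel"]:
        if rng.random() < config.p_gain:
            hybrid.add(taxon)
    return hybrid


def _occupancy(taxa, config: SimConfig, rng) -> pd.Series:
    if config.occupancy is not None:
        probs = np.full(len(taxa), config.occupancy)
    else:
        a, b = config.occupancy_shape
        probs = rng.beta(a, b, size=len(taxa))
    # keep detection probabilities away from exactly 0
    probs = np.clip(probs, 1e-6, 1.0)
    return pd.Series(probs, index=list(taxa))


def _fourh_of_pools(hybrid: set, p1: set, p2: set) -> dict:
    omega = hybrid | p1 | p2
    if not omega:
        return {"intersection": 0.0, "union": 0.0, "gain": 0.0, "loss": 1.0}
    n = len(omega)
    return {
        "intersection": len(hybrid & p1 & p2) / n,
        "union": len(hybrid & ((p1 | p2) - (p1 & p2))) / n,
        "gain": len(hybrid - (p1 | p2)) / n,
        "loss": len((p1 | p2) - hybrid) / n,
    }


def simulate_populations(config: SimConfig):
    """Generate (SampleTable, GroundTruth, TreeNode) for four populations.

    Two hybrid populations (one per site) share a single clonal hybrid
    taxon pool; the maternal progenitor occurs at site1 and the paternal
    progenitor at site2.
    """
    ss = np.random.SeedSequence(config.seed)
    tree_seed, pool_child, occ_child, count_child = ss.spawn(4)

    pools = _pool_taxa(config)
    all_taxa = pools["shared"] + pools["p1_only"] + pools["p2_only"] + pools["novel"]
    pool_labels = {}
    for label, taxa in pools.items():
        for t in taxa:
            pool_labels[t] = label

    tree = simulate_tree(
        len(all_taxa), rate=config.tree_rate,
        seed=tree_seed.generate_state(1)[0] & 0x7FFFFFFF, labels=all_taxa,
    )

    p1_pool = set(pools["shared"]) | set(pools["p1_only"])
    p2_pool = set(pools["shared"]) | set(pools["p2_only"])
    hybrid_pool = assemble_hybrid_pool(config, np.random.default_rng(pool_child))
    degenerate = len(hybrid_pool) == 0
    if degenerate:
        warnings.warn(
            "hybrid taxon pool is empty after assembly; table will contain "
            "all-zero hybrid samples",
            stacklevel=2,
        )

    pop_pools = {
        "hybrid_site1": hybrid_pool,
        "maternal_site1": p1_pool,
        "hybrid_site2": hybrid_pool,
        "paternal_site2": p2_pool,
    }

    occ_rng = np.random.default_rng(occ_child)
    occupancy = {}
    site2_shift_taxa = None
    for pop, _, site, _ in POPULATIONS:
        occ = _occupancy(sorted(pop_pools[pop]), config, occ_rng)
        if config.site_effect > 0 and site == "site2":
            if site2_shift_taxa is None:
                k = int(round(config.site_effect_fraction * len(all_taxa)))
                site2_shift_taxa = set(
                    occ_rng.choice(all_taxa, size=k, replace=False)
                )
            hit = [t for t in occ.index if t in site2_shift_taxa]
            logit = np.log(occ[hit] / (1 - occ[hit] + 1e-12))
            occ[hit] = 1.0 / (1.0 + np.exp(-(logit + config.site_effect)))
        occupancy[pop] = occ

    # global log-normal abundance weight per taxon keeps the incidence and
    # abundance layers consistent across populations
    count_rng = np.random.default_rng(count_child)
    weights = pd.Series(
        count_rng.lognormal(config.lognormal_mu, config.lognormal_sigma, len(all_taxa)),
        index=all_taxa,
    )

    columns = {}
    meta_rows = []
    for pop, species, site, role in POPULATIONS:
        occ = occupancy[pop]
        for j in range(config.n_individuals):
            sample_id = f"{pop}_{j:02d}"
            counts = np.zeros(len(all_taxa), dtype=np.int64)
            if len(occ):
                present = occ.index[count_rng.random(len(occ)) < occ.values]
                if len(present) == 0:
                    # guarantee a non-empty community for a non-empty pool
                    present = [occ.idxmax()]
                w = weights[present].to_numpy()
                p = w / w.sum()
                drawn = count_rng.multinomial(config.read_depth, p)
                idx = [all_taxa.index(t) for t in present]
                counts[idx] = drawn
            columns[sample_id] = counts
            meta_rows.append(
                {"sample_id": sample_id, "species": species, "site": site,
                 "role": role, "body_site": config.body_site,
                 "population": pop}
            )

    counts = pd.DataFrame(columns, index=all_taxa)
    counts.index.name = "taxon_id"
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    taxonomy = {
        t: f"Bacteria;SimPhylum_{pool_labels[t]};SimGenus_{t[:4]}" for t in all_taxa
    }
    table = SampleTable(counts, taxonomy, metadata)

    truth = GroundTruth(
        pool_labels=pool_labels,
        hybrid_pool=hybrid_pool,
        fourh_true=_fourh_of_pools(hybrid_pool, p1_pool, p2_pool),
        occupancy=occupancy,
        degenerate=degenerate,
    )
    return table, truth, tree


def write_simulation(outdir, table: SampleTable, truth: GroundTruth, tree: TreeNode):
    """Write count TSV, metadata TSV, newick tree and ground-truth JSON."""
    import json
    from pathlib import Path

    from . import tableio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tableio.write_counts_tsv(table, outdir / "counts.tsv")
    tableio.write_metadata_tsv(table, outdir / "metadata.tsv")
    tableio.write_taxonomy_tsv(table, outdir / "taxonomy.tsv")
    tableio.write_tree(tree, outdir / "tree.nwk")
    doc = {
        "pool_labels": truth.pool_labels,
        "hybrid_pool": sorted(truth.hybrid_pool),
        "fourh_true": truth.fourh_true,
        "degenerate": truth.degenerate,
        "occupancy": {pop: occ.to_dict() for pop, occ in truth.occupancy.items()},
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(doc, fh, indent=1)
    return outdir
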