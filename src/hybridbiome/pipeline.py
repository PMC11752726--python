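"""End-to-end orchestration: simulate -> prepare -> diversity -> ordination
-> 4H -> classify, with one master seed and a machine-readable manifest.

Each stage writes TSV/JSON artifacts into its own subdirectory of the run
directory; the final stage assembles per-trait comparisons from the stage
outputs, classifies every trait for each hybrid population, and emits an
outcome-code table plus a per-family tally.

Significance sources are wired per trait family and never chosen ad hoc:
alpha diversity and microbial abundances use rank tests (Kruskal-Wallis +
pairwise Mann-Whitney with Benjamini-Hochberg), the bootstrap diversity
traits use disjoint 83.4% CIs, principal-coordinate axes use per-axis
Mann-Whitney, and triangle statistics are compared against progenitor null
models.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import TraitComparison, classify_trait as classify_comparison, tally_outcomes
from . import diversity as dv
from . import fourh as fh
from . import ordination as od
from . import simulate as sim
from . import tableio as tio

logger = logging.getLogger(__name__)

PROGENITOR_OF = {"P1": "paternal_site2", "P2": "maternal_site1"}
SYNTOPIC_OF = {"hybrid_site1": "P2", "hybrid_site2": "P1"}  # site1 = maternal


@dataclass
class RunConfig:
    """Run parameters; defaults follow the study design."""

    seed: int = 0
    outdir: str = "hybridbiome_run"
    # either simulate ...
    simulation: dict = field(default_factory=dict)
    # ... or load existing inputs
    table: str | None = None
    tree: str | None = None
    metadata: str | None = None
    taxonomy: str | None = None

    min_reads: int = 10000
    rarefy_depth: int | None = None       # default: minimum retained sample sum
    diversity_metric: str = "faith_pd"    # or "richness"
    alpha_metric: str = "faith_pd"
    n_bootstraps: int = 500
    bootstrap_n: int = 15
    core_threshold: float = 0.5
    distance_metric: str = "u_unifrac"
    triangle_trials: int = 50
    triangle_n: int = 12
    fourh_trials: int = 100
    fourh_n: int = 12
    fourh_threshold: float = 0.0
    fourh_unit: str = "branch_segments"
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh_:
            doc = yaml.safe_load(fh_) or {}
        return cls(**doc)


def _child_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def load_inputs(config: RunConfig, outdir: Path):
    """Stage 0: simulate, or read the table/tree/metadata paths."""
    if config.table is None:
        simcfg = sim.SimConfig(seed=_child_seed(config.seed, "simulate"),
                               **config.simulation)
        table, truth, tree = sim.simulate_populations(simcfg)
        stage_dir = outdir / "simulate"
        sim.write_simulation(stage_dir, table, truth, tree)
        return table, tree, truth
    table = tio.read_table(config.table, taxonomy=config.taxonomy,
                           metadata=config.metadata)
    if config.tree is None:
        raise ValueError("phylogenetic metrics requested but no tree given")
    tree = tio.read_tree(config.tree)
    return table, tree, None


def prepare(table, tree, config: RunConfig, outdir: Path):
    """Stage 1: domain filter, depth filter, rarefaction, tree pruning."""
    table = tio.filter_domain(table)
    table = tio.filter_depth(table, min_reads=config.min_reads)
    if table.counts.shape[1] == 0:
        raise ValueError("no samples left after the depth filter")
    depth = config.rarefy_depth or int(table.sample_sums().min())
    table = tio.rarefy(table, depth, seed=_child_seed(config.seed, "rarefy"))
    tree = tio.prune_tree_to_table(tree, table)
    stage_dir = outdir / "prepare"
    stage_dir.mkdir(parents=True, exist_ok=True)
    tio.write_counts_tsv(table, stage_dir / "table.tsv")
    tio.write_metadata_tsv(table, stage_dir / "metadata.tsv")
    tio.write_tree(tree, stage_dir / "tree.nwk")
    (stage_dir / "params.json").write_text(
        json.dumps({"rarefy_depth": depth, "min_reads": config.min_reads}))
    return table, tree


def _populations(table) -> dict:
    md = table.metadata
    pops = {}
    for pop in sorted(md["population"].unique()):
        pops[pop] = list(md.index[md["population"] == pop])
    return pops


def diversity_stage(table, tree, config: RunConfig, outdir: Path) -> dict:
    """Stage 2: per-individual alpha diversity with rank tests, and the
    bootstrap suite for population-level traits with 83.4% CIs."""
    stage_dir = outdir / "diversity"
    stage_dir.mkdir(parents=True, exist_ok=True)
    pops = _populations(table)
    roles = {pop: table.metadata.loc[ids[0], "role"] for pop, ids in pops.items()}

    alpha_values = {
        pop: np.array([
            dv.alpha_diversity(table.counts[s], config.alpha_metric,
                               tree=tree, taxa=table.taxa)
            for s in ids
        ])
        for pop, ids in pops.items()
    }
    alpha_tests = dv.group_tests(alpha_values, alpha=config.alpha)
    pd.DataFrame({p: pd.Series(v) for p, v in alpha_values.items()}).to_csv(
        stage_dir / "alpha_values.tsv", sep="\t", index=False)
    if alpha_tests.pairwise is not None:
        alpha_tests.pairwise.to_csv(stage_dir / "alpha_pairwise.tsv",
                                    sep="\t", index=False)

    incidence = table.incidence()
    inc_by_pop = {pop: incidence[ids] for pop, ids in pops.items()}
    long = dv.bootstrap_core_suite(
        inc_by_pop, roles, tree=tree, metric=config.diversity_metric,
        f=config.core_threshold, B=config.n_bootstraps, n=config.bootstrap_n,
        seed=_child_seed(config.seed, "divboot"),
    )
    summary = dv.summarize_bootstrap(long)
    signif = dv.pairwise_ci_significance(summary)
    long.to_csv(stage_dir / "bootstrap_values.tsv", sep="\t", index=False)
    summary.to_csv(stage_dir / "bootstrap_summary.tsv", sep="\t", index=False)
    signif.to_csv(stage_dir / "bootstrap_significance.tsv", sep="\t", index=False)
    return {"alpha_values": alpha_values, "alpha_tests": alpha_tests,
            "summary": summary, "significance": signif, "roles": roles}


def ordination_stage(table, tree, config: RunConfig, outdir: Path) -> dict:
    """Stage 3: PCoA with axis tests; triangle statistics for observed
    hybrid groups against progenitor and pseudo-hybrid null models."""
    stage_dir = outdir / "ordination"
    stage_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(_child_seed(config.seed, "ordination"))
    pops = _populations(table)
    p1_ids = pops[PROGENITOR_OF["P1"]]
    p2_ids = pops[PROGENITOR_OF["P2"]]
    hybrid_pops = [p for p in pops if p.startswith("hybrid")]

    # pseudo-hybrid null individuals live in the same ordination space
    incidence = table.incidence().astype(int)
    n_null = max(len(p1_ids), len(p2_ids))
    null_mode = "incidence" if config.distance_metric in ("jaccard", "u_unifrac") \
        else "abundance"
    if null_mode == "incidence":
        null_cols = od.null_hybrid_profiles(incidence, p1_ids, p2_ids,
                                            n_null, "incidence", rng)
        aug_counts = pd.concat([table.counts, null_cols], axis=1)
    else:
        rel = tio.to_relative(table)
        null_cols = od.null_hybrid_profiles(rel, p1_ids, p2_ids,
                                            n_null, "abundance", rng)
        # scale back to pseudo-counts at the common depth
        depth = int(table.sample_sums().iloc[0])
        aug_counts = pd.concat(
            [table.counts, (null_cols * depth).round().astype(int)], axis=1)
    null_ids = list(null_cols.columns)
    aug_md = table.metadata.reindex(table.metadata.index.union(null_ids))
    aug_md.loc[null_ids, ["species", "site", "role", "body_site", "population"]] = \
        ["null", "null", "null", table.metadata["body_site"].iloc[0], "null_mix"]
    aug = tio.SampleTable(aug_counts, dict(table.taxonomy), aug_md)

    dm = od.distance_matrix(aug, config.distance_metric, tree=tree)
    ordination = od.pcoa_ordination(dm)
    k = od.n_retained_axes(ordination)
    coords = ordination.coordinates.iloc[:, :k]
    coords.to_csv(stage_dir / "coordinates.tsv", sep="\t")
    pd.DataFrame({
        "eigenvalue": ordination.eigenvalues,
        "proportion": ordination.proportion_explained,
    }).to_csv(stage_dir / "eigenvalues.tsv", sep="\t", index=False)

    tri_seed = _child_seed(config.seed, "triangle")

    def tri(hybrid_group_ids, label):
        members = {label: list(hybrid_group_ids),
                   PROGENITOR_OF["P1"]: p1_ids, PROGENITOR_OF["P2"]: p2_ids}
        return od.triangle_bootstrap(
            coords, members, label, PROGENITOR_OF["P1"], PROGENITOR_OF["P2"],
            n_sub=config.triangle_n, trials=config.triangle_trials,
            rng=np.random.default_rng(tri_seed))

    observed = {}
    pooled_ids = sum((pops[h] for h in hybrid_pops), [])
    observed["hybrid_pooled"] = tri(pooled_ids, "hybrid_pooled")
    for h in hybrid_pops:
        observed[h] = tri(pops[h], h)
    nulls = {
        "null_P1": tri(p1_ids, "null_P1"),
        "null_P2": tri(p2_ids, "null_P2"),
        "null_P1P2": tri(p1_ids + p2_ids, "null_P1P2"),
        "null_mix": tri(null_ids, "null_mix"),
    }
    all_stats = pd.concat(
        {name: df for name, df in {**observed, **nulls}.items()},
        names=["group", "row"],
    ).reset_index(level=0)
    all_stats.to_csv(stage_dir / "triangle_stats.tsv", sep="\t", index=False)

    comparisons = []
    for name, obs in observed.items():
        for null_name, null in nulls.items():
            for axis in ("position", "height"):
                comparisons.append({
                    "observed": name, "null": null_name, "axis": axis,
                    "p_value": od.triangle_compare(obs, null, axis=axis),
                })
    tri_tests = pd.DataFrame(comparisons)
    tri_tests.to_csv(stage_dir / "triangle_tests.tsv", sep="\t", index=False)

    axis_tests = []
    for h in hybrid_pops:
        for prog_key, prog_pop in PROGENITOR_OF.items():
            for axis in (0, 1):
                axis_tests.append({
                    "hybrid": h, "progenitor": prog_key, "axis": axis + 1,
                    "p_value": od.axis_group_test(
                        coords, axis, pops[h], pops[prog_pop]),
                })
    axis_tests = pd.DataFrame(axis_tests)
    axis_tests.to_csv(stage_dir / "axis_tests.tsv", sep="\t", index=False)

    return {"coords": coords, "k": k, "ordination": ordination,
            "observed": observed, "nulls": nulls, "triangle_tests": tri_tests,
            "axis_tests": axis_tests, "pops": pops}


def abundance_stage(table, config: RunConfig, outdir: Path) -> dict:
    """Stage 4: PCA dominant-loading taxa and their abundance rank tests."""
    stage_dir = outdir / "abundance"
    stage_dir.mkdir(parents=True, exist_ok=True)
    rel = tio.to_relative(table)
    pca = od.pca_dominant_loadings(rel, n_axes=2)
    pca.dominant.to_csv(stage_dir / "pca_dominant.tsv", sep="\t")
    pops = _populations(table)
    results = {}
    for axis, row in pca.dominant.iterrows():
        taxon = row["taxon"]
        values = {pop: rel.loc[taxon, ids].to_numpy() for pop, ids in pops.items()}
        results[taxon] = {
            "axis": axis,
            "values": values,
            "tests": dv.group_tests(values, alpha=config.alpha),
        }
    return {"pca": pca, "abundance": results}


def fourh_stage(table, tree, config: RunConfig, outdir: Path) -> dict:
    """Stage 5: 4H bootstrap (per hybrid site and pooled), null plane,
    retention-bias test and quaternary plot coordinates."""
    stage_dir = outdir / "fourh"
    stage_dir.mkdir(parents=True, exist_ok=True)
    pops = _populations(table)
    p1_ids = pops[PROGENITOR_OF["P1"]]
    p2_ids = pops[PROGENITOR_OF["P2"]]
    spec = fh.CoreSpec(threshold=config.fourh_threshold, n_sub=config.fourh_n,
                       n_trials=config.fourh_trials, unit=config.fourh_unit)
    incidence = table.incidence()
    bindex = None
    if spec.unit == "branch_segments":
        from ._tree import BranchIndex
        bindex = BranchIndex(tree, table.taxa)
    seed = _child_seed(config.seed, "fourh")

    hybrid_sets = {
        "site1": pops["hybrid_site1"],
        "site2": pops["hybrid_site2"],
        "pooled": pops["hybrid_site1"] + pops["hybrid_site2"],
    }
    results = {}
    summaries = {}
    for name, ids in hybrid_sets.items():
        boot = fh.fourh_bootstrap(incidence, ids, p1_ids, p2_ids, spec=spec,
                                  branch_index=bindex, seed=seed)
        results[name] = boot
        summaries[name] = boot.summary()
        boot.points.to_csv(stage_dir / f"points_{name}.tsv", sep="\t", index=False)
        fh.quaternary_coordinates(boot.points).to_csv(
            stage_dir / f"quaternary_{name}.tsv", sep="\t", index=False)

    plane = fh.null_plane(incidence, p1_ids, p2_ids, spec=spec,
                          branch_index=bindex, seed=seed + 1)
    plane.points.to_csv(stage_dir / "null_points.tsv", sep="\t", index=False)
    retention = {
        name: fh.retention_bias_test(boot, plane.points)
        for name, boot in results.items()
    }
    summary_doc = {
        "subsamples": spec.n_trials, "n_sub": spec.n_sub,
        "core_threshold": spec.threshold, "unit": spec.unit,
        "null_plane": "operational: incidence-null pseudo-hybrid cloud + SVD plane",
        "groups": summaries,
        "retention_bias": {
            name: {"ratio": t.observed_ratio, "p_value": t.p_value}
            for name, t in retention.items()
        },
    }
    (stage_dir / "summary.json").write_text(json.dumps(summary_doc, indent=1))
    return {"bootstraps": results, "plane": plane, "retention": retention}


# ---------------------------------------------------------------------------
# classification wiring
# ---------------------------------------------------------------------------

def _median(values) -> float:
    return float(np.median(values))


def build_comparisons(div, ordn, abund, config: RunConfig) -> list:
    """Assemble TraitComparison rows for each hybrid population from the
    stage outputs."""
    comparisons = []
    alpha_level = config.alpha
    pops = ordn["pops"]
    hybrid_pops = [p for p in pops if p.startswith("hybrid")]
    p1_pop, p2_pop = PROGENITOR_OF["P1"], PROGENITOR_OF["P2"]
    body_site = "all"

    def pairwise_sig(tests: dv.GroupTestResult, a, b) -> bool:
        if tests.omnibus_p > alpha_level:
            return False
        p = tests.pairwise_p(a, b)
        return p is not None and p <= alpha_level

    # alpha diversity
    tests = div["alpha_tests"]
    for h in hybrid_pops:
        comparisons.append(TraitComparison(
            trait="alpha", family="diversity", body_site=body_site,
            hybrid_population=h,
            hybrid_value=_median(div["alpha_values"][h]),
            p1_value=_median(div["alpha_values"][p1_pop]),
            p2_value=_median(div["alpha_values"][p2_pop]),
            sig_p1=pairwise_sig(tests, h, p1_pop),
            sig_p2=pairwise_sig(tests, h, p2_pop),
            syntopic=SYNTOPIC_OF[h],
            sig_syntopic=pairwise_sig(tests, h, PROGENITOR_OF[SYNTOPIC_OF[h]]),
        ))

    # bootstrap traits with CI-overlap significance
    summary, signif = div["summary"], div["significance"]

    def boot_median(trait, pop):
        row = summary[(summary["trait"] == trait) & (summary["population"] == pop)]
        return float(row["median"].iloc[0])

    def boot_sig(trait, a, b):
        m = signif[(signif["trait"] == trait)
                   & (((signif["population_a"] == a) & (signif["population_b"] == b))
                      | ((signif["population_a"] == b) & (signif["population_b"] == a)))]
        return bool(m["significant"].iloc[0])

    for trait in dv.CORE_TRAITS:
        for h in hybrid_pops:
            comparisons.append(TraitComparison(
                trait=trait, family="diversity", body_site=body_site,
                hybrid_population=h,
                hybrid_value=boot_median(trait, h),
                p1_value=boot_median(trait, p1_pop),
                p2_value=boot_median(trait, p2_pop),
                sig_p1=boot_sig(trait, h, p1_pop),
                sig_p2=boot_sig(trait, h, p2_pop),
                syntopic=SYNTOPIC_OF[h],
                sig_syntopic=boot_sig(trait, h, PROGENITOR_OF[SYNTOPIC_OF[h]]),
            ))

    # PCoA axes
    coords, axis_tests = ordn["coords"], ordn["axis_tests"]
    for axis in (1, 2):
        for h in hybrid_pops:
            def axis_sig(prog_key):
                m = axis_tests[(axis_tests["hybrid"] == h)
                               & (axis_tests["progenitor"] == prog_key)
                               & (axis_tests["axis"] == axis)]
                return bool(m["p_value"].iloc[0] <= alpha_level)

            mean_of = lambda pop: float(coords.iloc[:, axis - 1].loc[pops[pop]].mean())
            comparisons.append(TraitComparison(
                trait=f"pcoa_axis{axis}", family="composition",
                body_site=body_site, hybrid_population=h,
                hybrid_value=mean_of(h), p1_value=mean_of(p1_pop),
                p2_value=mean_of(p2_pop),
                sig_p1=axis_sig("P1"), sig_p2=axis_sig("P2"),
                syntopic=SYNTOPIC_OF[h], sig_syntopic=axis_sig(SYNTOPIC_OF[h]),
                statistic="mean",
            ))

    # triangle statistics vs progenitor null models
    tri_tests = ordn["triangle_tests"]
    for axis in ("position", "height"):
        for h in hybrid_pops:
            def tri_sig(null_name):
                m = tri_tests[(tri_tests["observed"] == h)
                              & (tri_tests["null"] == null_name)
                              & (tri_tests["axis"] == axis)]
                return bool(m["p_value"].iloc[0] <= alpha_level)

            obs_mean = float(ordn["observed"][h][axis].mean())
            null1 = float(ordn["nulls"]["null_P1"][axis].mean())
            null2 = float(ordn["nulls"]["null_P2"][axis].mean())
            syn = SYNTOPIC_OF[h]
            comparisons.append(TraitComparison(
                trait=f"triangle_{axis}", family="composition",
                body_site=body_site, hybrid_population=h,
                hybrid_value=obs_mean, p1_value=null1, p2_value=null2,
                sig_p1=tri_sig("null_P1"), sig_p2=tri_sig("null_P2"),
                syntopic=syn, sig_syntopic=tri_sig(f"null_{syn}"),
                statistic="mean",
            ))

    # dominant-loading abundances
    for taxon, info in abund["abundance"].items():
        tests = info["tests"]
        for h in hybrid_pops:
            comparisons.append(TraitComparison(
                trait=taxon, family="abundance", body_site=body_site,
                hybrid_population=h,
                hybrid_value=_median(info["values"][h]),
                p1_value=_median(info["values"][p1_pop]),
                p2_value=_median(info["values"][p2_pop]),
                sig_p1=pairwise_sig(tests, h, p1_pop),
                sig_p2=pairwise_sig(tests, h, p2_pop),
                syntopic=SYNTOPIC_OF[h],
                sig_syntopic=pairwise_sig(tests, h, PROGENITOR_OF[SYNTOPIC_OF[h]]),
            ))
    return comparisons


def classify_stage(comparisons, outdir: Path) -> dict:
    stage_dir = outdir / "classify"
    stage_dir.mkdir(parents=True, exist_ok=True)
    outcomes = [classify_comparison(c) for c in comparisons]
    table = pd.DataFrame([{
        "body_site": o.body_site, "family": o.family, "trait": o.trait,
        "hybrid_population": o.hybrid_population,
        "code": o.code_string(), "vs_both": o.code,
        "conserved_with": o.conserved_with, "direction": o.direction,
        "syntopic": o.syntopic_code, "syn_direction": o.syntopic_direction,
    } for o in outcomes])
    table.to_csv(stage_dir / "trait_outcomes.tsv", sep="\t", index=False)
    tally = tally_outcomes(outcomes)
    tally.to_csv(stage_dir / "outcome_tally.tsv", sep="\t")
    return {"outcomes": outcomes, "table": table, "tally": tally}


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the run directory.

    A failure in any stage aborts with the stage name while preserving the
    artifacts of completed stages.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    t0 = time.time()
    stage = "load"
    try:
        table, tree, truth = load_inputs(config, outdir)
        stage = "prepare"
        table, tree = prepare(table, tree, config, outdir)
        stage = "diversity"
        div = diversity_stage(table, tree, config, outdir)
        stage = "ordination"
        ordn = ordination_stage(table, tree, config, outdir)
        stage = "abundance"
        abund = abundance_stage(table, config, outdir)
        stage = "fourh"
        fourh_res = fourh_stage(table, tree, config, outdir)
        stage = "classify"
        comparisons = build_comparisons(div, ordn, abund, config)
        classified = classify_stage(comparisons, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": ["simulate" if config.table is None else "load", "prepare",
                   "diversity", "ordination", "abundance", "fourh", "classify"],
        "elapsed_seconds": round(time.time() - t0, 2),
        "artifacts": {
            str(p.relative_to(outdir)): _checksum(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
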