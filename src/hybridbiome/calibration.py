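"""Self-validation procedures: calibration and parameter-recovery runs.

These routines exercise the package's statistical machinery under known
generative conditions, the way simulation-backed packages validate their
estimators: the disjoint-CI rule should reject at roughly its nominal 5%
rate when two samples come from one community, the retention-bias test
should produce uniform p-values under its own null, progenitor null models
should bracket the triangle axis, and the 4H estimator should recover the
generator's true pool fractions.  Both the test suite and the acceptance
script run them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import diversity as dv
from . import fourh as fh
from . import ordination as od
from ._tree import BranchIndex
from .simulate import SimConfig, simulate_populations, simulate_tree


def ci_overlap_calibration(n_reps: int = 1000, n_taxa: int = 180, T: int = 15,
                           B: int = 500, occupancy_shape=(2.0, 2.0),
                           seed: int = 0) -> float:
    """Fraction of replicate pairs declared different by the disjoint-83.4%-CI
    rule when both populations are sampled from one community.

    One fixed community (per-taxon Beta occupancies) is sampled twice per
    replicate; each sample gets a Chao-style bootstrap assemblage, `B`
    pseudo-populations of `T` individuals, and a gamma-richness CI.  Under
    approximate normality the disjoint-CI rule corresponds to a two-sample
    test at roughly alpha = 0.05.
    """
    rng = np.random.default_rng(seed)
    truth = np.clip(rng.beta(*occupancy_shape, n_taxa), 1e-6, 1.0)
    hits = 0
    for _ in range(n_reps):
        cis = []
        for _ in range(2):
            X = rng.random((n_taxa, T)) < truth[:, None]
            profile = dv.incidence_profile(pd.DataFrame(X))
            asm = dv.chao_assemblage(profile)
            p = asm.all_probabilities()
            draws = rng.random((B, len(p), T)) < p[None, :, None]
            gamma = draws.any(axis=2).sum(axis=1)
            cis.append(dv.ci_from_bootstraps(gamma))
        hits += dv.ci_overlap_test(*cis)
    return hits / n_reps


def retention_null_pvalues(n_runs: int = 200, n_null: int = 100,
                           n_taxa: int = 120, T: int = 15, n_sub: int = 12,
                           seed: int = 0) -> np.ndarray:
    """Retention-bias p-values when the observed hybrid IS a null hybrid.

    Per run, two progenitor populations are sampled from fixed Beta
    occupancies; the null cloud and the "observed" point are generated by
    the same incidence-null mechanism (one pseudo-hybrid group per run, so
    the observed statistic is exchangeable with the null points).  The
    returned p-values should be approximately uniform.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_taxa, seed=seed)
    taxa = [t.name for t in tree.tips()]
    bindex = BranchIndex(tree, taxa)
    occ1 = np.clip(rng.beta(2, 2, n_taxa), 1e-6, 1.0)
    occ2 = np.clip(rng.beta(2, 2, n_taxa), 1e-6, 1.0)
    spec_cloud = fh.CoreSpec(threshold=0.0, n_sub=n_sub, n_trials=n_null,
                             unit="branch_segments")
    spec_obs = fh.CoreSpec(threshold=0.0, n_sub=n_sub, n_trials=1,
                           unit="branch_segments")
    p1_ids = [f"p1_{j}" for j in range(T)]
    p2_ids = [f"p2_{j}" for j in range(T)]
    pvals = []
    for _ in range(n_runs):
        P1 = rng.random((n_taxa, T)) < occ1[:, None]
        P2 = rng.random((n_taxa, T)) < occ2[:, None]
        presence = pd.DataFrame(
            np.concatenate([P1, P2], axis=1), index=taxa,
            columns=p1_ids + p2_ids)
        cloud = fh.null_plane(presence, p1_ids, p2_ids, spec=spec_cloud,
                              branch_index=bindex, rng=rng)
        obs = fh.null_plane(presence, p1_ids, p2_ids, spec=spec_obs,
                            branch_index=bindex, rng=rng)
        point = fh.FourHPoint(*obs.points[list(fh.COMPONENTS)].iloc[0])
        pvals.append(fh.retention_bias_test(point, cloud.points).p_value)
    return np.asarray(pvals)


def retention_null_uniformity(n_runs: int = 200, seed: int = 0, **kwargs) -> float:
    """Kolmogorov-Smirnov p-value of the retention null p-values against
    the uniform distribution."""
    pvals = retention_null_pvalues(n_runs=n_runs, seed=seed, **kwargs)
    return float(stats.kstest(pvals, "uniform").pvalue)


def fourh_recovery(seed: int = 0, n_trials: int = 100) -> dict:
    """Set-based f=0 4H estimation error against the generator's truth.

    Study conditions: keep probabilities (1, 0.5, 0.2) for shared /
    exclusive / novel taxa, occupancy 0.95, 15 individuals per population.
    Returns the per-component absolute errors and their maximum.
    """
    cfg = SimConfig(seed=seed, n_individuals=15, p_keep_shared=1.0,
                    p_keep_exclusive=0.5, p_gain=0.2, occupancy=0.95)
    table, truth, _ = simulate_populations(cfg)
    md = table.metadata
    pops = {p: list(md.index[md["population"] == p])
            for p in md["population"].unique()}
    spec = fh.CoreSpec(threshold=0.0, n_sub=12, n_trials=n_trials, unit="taxa")
    boot = fh.fourh_bootstrap(
        table.incidence(),
        pops["hybrid_site1"] + pops["hybrid_site2"],
        pops["paternal_site2"], pops["maternal_site1"],
        spec=spec, seed=seed)
    errors = {c: abs(getattr(boot.mean, c) - truth.fourh_true[c])
              for c in fh.COMPONENTS}
    return {"errors": errors, "max_error": max(errors.values()),
            "estimate": {c: getattr(boot.mean, c) for c in fh.COMPONENTS},
            "truth": truth.fourh_true}


def gain_sweep(p_gains=(0.0, 0.1, 0.2, 0.4), seed: int = 0,
               n_trials: int = 60) -> pd.DataFrame:
    """Mean estimated 4H gain across a sweep of simulated gain rates.

    The estimated gain should be monotone in the simulated `p_gain`
    (Spearman rho = 1 across the sweep means).
    """
    rows = []
    for i, p_gain in enumerate(p_gains):
        cfg = SimConfig(seed=seed + i, n_individuals=15, p_keep_shared=1.0,
                        p_keep_exclusive=0.5, p_gain=p_gain, occupancy=0.95)
        table, truth, _ = simulate_populations(cfg)
        md = table.metadata
        pops = {p: list(md.index[md["population"] == p])
                for p in md["population"].unique()}
        spec = fh.CoreSpec(threshold=0.0, n_sub=12, n_trials=n_trials,
                           unit="taxa")
        boot = fh.fourh_bootstrap(
            table.incidence(),
            pops["hybrid_site1"] + pops["hybrid_site2"],
            pops["paternal_site2"], pops["maternal_site1"],
            spec=spec, seed=seed + i)
        rows.append({"p_gain": p_gain, "estimated_gain": boot.mean.gain,
                     "true_gain": truth.fourh_true["gain"]})
    return pd.DataFrame(rows)


def progenitor_null_positions(n_runs: int = 20, seed: int = 0) -> dict:
    """Mean triangle positions of the two progenitor null models on
    simulated data embedded by unweighted-UniFrac PCoA."""
    from . import tableio as tio

    rng = np.random.default_rng(seed)
    means1, means2 = [], []
    for run in range(n_runs):
        cfg = SimConfig(seed=seed * 1000 + run, n_shared=60, n_p1_only=30,
                        n_p2_only=30, n_novel=30, read_depth=5000)
        table, _, tree = simulate_populations(cfg)
        md = table.metadata
        pops = {p: list(md.index[md["population"] == p])
                for p in md["population"].unique()}
        dm = od.distance_matrix(table, "u_unifrac", tree=tree)
        res = od.pcoa_ordination(dm)
        k = od.n_retained_axes(res)
        coords = res.coordinates.iloc[:, :k]
        p1, p2 = pops["paternal_site2"], pops["maternal_site1"]
        members = {"P1": p1, "P2": p2}
        null1 = od.triangle_bootstrap(
            coords, {**members, "N": p1}, "N", "P1", "P2", n_sub=12,
            trials=25, rng=rng)
        null2 = od.triangle_bootstrap(
            coords, {**members, "N": p2}, "N", "P1", "P2", n_sub=12,
            trials=25, rng=rng)
        means1.append(null1["position"].mean())
        means2.append(null2["position"].mean())
    means1, means2 = np.asarray(means1), np.asarray(means2)
    return {
        "p1_mean_position": float(means1.mean()),
        "p2_mean_position": float(means2.mean()),
        "order_correct_rate": float((means1 < means2).mean()),
    }


def null_hybrid_gain(seed: int = 0, n_trials: int = 60) -> float:
    """Mean 4H gain of incidence-null pseudo-hybrids at high occupancy
    (should be ~0: null hybrids carry no taxa outside the progenitor
    pool)."""
    cfg = SimConfig(seed=seed, occupancy=0.95)
    table, _, tree = simulate_populations(cfg)
    md = table.metadata
    pops = {p: list(md.index[md["population"] == p])
            for p in md["population"].unique()}
    spec = fh.CoreSpec(threshold=0.0, n_sub=12, n_trials=n_trials,
                       unit="branch_segments")
    plane = fh.null_plane(table.incidence(), pops["paternal_site2"],
                          pops["maternal_site1"], spec=spec, tree=tree,
                          seed=seed)
    return float(plane.points["gain"].mean())
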