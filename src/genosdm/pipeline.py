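"""Pipeline orchestration: simulate -> filter -> cluster -> fit -> overlap -> rank.

A :class:`PipelineConfig` carries every run-level setting; :func:`run_all`
executes the stages in order, writes per-stage outputs under an output
directory, and returns a manifest (config echo, derived seeds, output
hashes, stage wall times) that makes reruns comparable. All randomness flows
from the single config seed through named substreams.
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
import yaml

from .admixture import assign_clusters, choose_L, estimate_admixture_joint, \
    estimate_q_projection, AncestryMatrix
from .enm import fit_niche_model, sample_background, auc
from .fst import fst_weir_cockerham
from .genotypes import filter_sites
from .grids import write_ascii_grid
from .overlap import mantel_test, schoener_d, similarity_test, welch_pairwise
from .risk import scenario_compare
from .simulate import ScenarioSpec, generate_scenario

logger = logging.getLogger("genosdm")

__all__ = ["PipelineConfig", "validate_config", "run_all"]


@dataclass
class PipelineConfig:
    """Run-level settings for the full analysis."""

    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    betamultiplier: float = 1.0
    n_background: int = 1000
    buffer_radius: float = 1.0  # map units; default one cell width
    k: int = 3
    L_values: tuple = (3,)
    n_folds_cv: int = 3
    min_maf: float = 0.05
    max_missing: float = 0.0
    n_reps_similarity: int = 0
    n_perm_mantel: int = 999
    n_z: int = 1001
    seed: int = 0
    output_dir: str = "genosdm_run"

    def to_yaml(self) -> str:
        d = asdict(self)
        spec = d.pop("scenario")
        for k, v in spec.items():
            if isinstance(v, np.ndarray):
                spec[k] = v.tolist()
        d["scenario"] = spec
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        spec = d.pop("scenario", {})
        for key in ("grid_size", "truncation_box", "layer_range"):
            if spec.get(key) is not None:
                spec[key] = tuple(spec[key])
        d["L_values"] = tuple(d.get("L_values", (3,)))
        return cls(scenario=ScenarioSpec(**spec), **d)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of issues; empty iff the config is usable."""
    issues = []
    for name in ("betamultiplier", "n_background", "k", "n_perm_mantel",
                 "n_z"):
        if getattr(config, name) <= 0:
            issues.append(f"{name} must be positive")
    if config.buffer_radius < 0:
        issues.append("buffer_radius must be non-negative")
    if config.n_reps_similarity < 0:
        issues.append("n_reps_similarity must be non-negative")
    if not config.L_values:
        issues.append("L_values must be non-empty")
    elif any(L < 1 for L in config.L_values):
        issues.append("L_values entries must be >= 1")
    if not 0 <= config.min_maf <= 0.5:
        issues.append("min_maf must be in [0, 0.5]")
    if not 0 <= config.max_missing <= 1:
        issues.append("max_missing must be in [0, 1]")
    try:
        round_trip = PipelineConfig.from_yaml(config.to_yaml())
        if round_trip.to_yaml() != config.to_yaml():
            issues.append("config does not round-trip through serialization")
    except Exception as exc:  # unserializable field values
        issues.append(f"config serialization failed: {exc}")
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(manifest: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            dt = time.perf_counter() - self.t0
            manifest["stages"][name] = {"seconds": round(dt, 3)}
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Timer()


def run_all(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the run manifest."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 99])
    manifest: dict = {"config": yaml.safe_load(config.to_yaml()),
                      "stages": {}, "outputs": {}, "warnings": []}

    # 1. simulate ----------------------------------------------------------
    with _stage(manifest, "simulate"):
        data = generate_scenario(config.scenario)
        for name, grid in data.grids.items():
            for layer in grid.layer_names:
                write_ascii_grid(grid.single(layer),
                                 out / f"{name}_{layer}.asc")
        data.all_occurrences().to_csv(out / "occurrences.csv")
        data.genotypes.write_vcf(out / "genotypes.vcf")
        (out / "truth.json").write_text(json.dumps({
            "q": data.q_truth.q.tolist(),
            "allele_freqs": data.allele_freqs_truth.tolist()}))
    target_name = data.target_range
    target = data.grids[target_name]

    # 2. filter genotypes --------------------------------------------------
    with _stage(manifest, "filter"):
        geno = filter_sites(data.genotypes, config.min_maf,
                            config.max_missing)
        manifest["n_sites_after_filter"] = geno.n_sites

    # 3. cluster -----------------------------------------------------------
    with _stage(manifest, "cluster"):
        native = data.spec.range_name(0)
        native_mask = geno.range_labels == native
        g_native = geno.subset_samples(native_mask)
        L = choose_L(g_native, config.L_values, n_folds=config.n_folds_cv,
                     seed=int(rng.integers(2**31 - 1)))
        manifest["chosen_L"] = L
        anc_native, P = estimate_admixture_joint(
            g_native, L, seed=int(rng.integers(2**31 - 1)))
        q_all = np.empty((geno.n_samples, L))
        q_all[native_mask] = anc_native.q
        other = ~native_mask
        if other.any():
            q_all[other] = estimate_q_projection(
                geno.subset_samples(other), P).q
        anc = assign_clusters(AncestryMatrix(q_all, sample_ids=geno.sample_ids),
                              config.k, seed=int(rng.integers(2**31 - 1)))
        pd.DataFrame(anc.q, index=geno.sample_ids).assign(
            cluster=anc.cluster, range=geno.range_labels).to_csv(
                out / "ancestry.csv")
        # F_ST between clusters, per range and global
        fst_rows = []
        for scope, mask in ([("global", np.ones(geno.n_samples, bool))]
                            + [(r, geno.range_labels == r)
                               for r in data.grids]):
            labs = anc.cluster[mask]
            for c1 in range(1, config.k + 1):
                for c2 in range(c1 + 1, config.k + 1):
                    pair = mask.copy()
                    pair[mask] = np.isin(labs, [c1, c2])
                    if len(set(anc.cluster[pair])) < 2:
                        continue
                    _, w = fst_weir_cockerham(geno.subset_samples(pair),
                                              anc.cluster[pair])
                    fst_rows.append({"scope": scope, "cluster1": c1,
                                     "cluster2": c2, "fst": w})
        fst_table = pd.DataFrame(fst_rows)
        fst_table.to_csv(out / "fst.csv", index=False)

    # 4. fit niche models --------------------------------------------------
    with _stage(manifest, "fit"):
        occ = data.all_occurrences()
        id_to_cluster = dict(zip(geno.sample_ids, anc.cluster))
        occ.df["cluster"] = [id_to_cluster.get(i)
                             for i in occ.df["individual_id"]]
        range_models, cluster_records = {}, {}
        auc_rows = []
        for name, grid in data.grids.items():
            recs = occ.for_range(name)
            bg = sample_background(grid, recs, config.n_background,
                                   buffer_radius=config.buffer_radius,
                                   seed=int(rng.integers(2**31 - 1)))
            model = fit_niche_model(recs, bg, grid,
                                    betamultiplier=config.betamultiplier)
            range_models[name] = model
            a = auc(model.predict_points(grid.extract(recs.x, recs.y)),
                    model.predict_points(grid.extract(bg.x, bg.y)))
            auc_rows.append({"model": name, "cluster": None, "auc": a,
                             "n_records": len(recs)})
            (out / f"model_{name}.json").write_text(model.to_json())
            for cl in range(1, config.k + 1):
                sub = recs.subset(recs.df["cluster"].to_numpy() == cl)
                cluster_records[(name, cl)] = sub
        pd.DataFrame(auc_rows).to_csv(out / "auc.csv", index=False)
        manifest["auc"] = {r["model"]: r["auc"] for r in auc_rows}

    # 5. overlap -----------------------------------------------------------
    with _stage(manifest, "overlap"):
        # cluster-level D on the target grid, pooling ranges per cluster
        cluster_proj = {}
        for cl in range(1, config.k + 1):
            sub = occ.subset(occ.df["cluster"].to_numpy() == cl)
            if len(sub) < 2:
                manifest["warnings"].append(
                    f"cluster {cl}: <2 records, no model")
                continue
            bg = sample_background(target, sub, config.n_background,
                                   buffer_radius=config.buffer_radius,
                                   seed=int(rng.integers(2**31 - 1)))
            model = fit_niche_model(sub, bg, target,
                                    betamultiplier=config.betamultiplier)
            cluster_proj[cl] = model.predict_grid(target)
        d_rows = []
        D_mat = np.zeros((config.k, config.k))
        for c1 in sorted(cluster_proj):
            for c2 in sorted(cluster_proj):
                if c2 <= c1:
                    continue
                d = schoener_d(cluster_proj[c1], cluster_proj[c2])
                d_rows.append({"cluster1": c1, "cluster2": c2, "D": d})
                D_mat[c1 - 1, c2 - 1] = D_mat[c2 - 1, c1 - 1] = d
        overlap_table = pd.DataFrame(d_rows)
        overlap_table.to_csv(out / "overlap.csv", index=False)
        manifest["overlap"] = d_rows

        # Mantel: niche dissimilarity (1 - D) vs genetic distance (F_ST)
        manifest["mantel"] = None
        if len(cluster_proj) == config.k and config.k >= 3:
            k = config.k
            F_mat = np.zeros((k, k))
            glob = fst_table[fst_table["scope"] == "global"]
            for _, row in glob.iterrows():
                i, j = int(row["cluster1"]) - 1, int(row["cluster2"]) - 1
                F_mat[i, j] = F_mat[j, i] = row["fst"]
            niche_dist = (1.0 - D_mat) - np.eye(k)  # dissimilarity, zero diag
            try:
                r, p = mantel_test(niche_dist, F_mat,
                                   n_perm=config.n_perm_mantel,
                                   seed=int(rng.integers(2**31 - 1)))
                manifest["mantel"] = {"r": r, "p": p,
                                      "note": "D converted to 1-D"}
            except ValueError as exc:
                manifest["warnings"].append(f"mantel skipped: {exc}")

        # Welch t-tests of the first environmental layer between clusters
        env_by_cluster = {}
        for cl in range(1, config.k + 1):
            sub = occ.subset(occ.df["cluster"].to_numpy() == cl)
            vals = []
            for name, grid in data.grids.items():
                e = sub.for_range(name).env_at(grid)["env1"].dropna()
                vals.append(e.to_numpy())
            v = np.concatenate(vals) if vals else np.empty(0)
            if v.size >= 2:
                env_by_cluster[f"CLUS{cl}"] = v
        if len(env_by_cluster) >= 2:
            welch_pairwise(env_by_cluster).to_csv(out / "welch_env1.csv",
                                                  index=False)

        # similarity tests between ranges (optional)
        if config.n_reps_similarity > 0:
            sim_rows = []
            names = list(data.grids)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    res = similarity_test(
                        occ.for_range(a), occ.for_range(b),
                        data.grids[a], data.grids[b], target,
                        n_reps=config.n_reps_similarity,
                        seed=int(rng.integers(2**31 - 1)),
                        betamultiplier=config.betamultiplier,
                        n_background=config.n_background,
                        buffer_radius=config.buffer_radius)
                    sim_rows.append({"range1": a, "range2": b, "D": res.D,
                                     "lo": res.percentile_low,
                                     "hi": res.percentile_high,
                                     "significant": res.significant})
            pd.DataFrame(sim_rows).to_csv(out / "similarity.csv", index=False)
            manifest["similarity"] = sim_rows
        else:
            manifest["similarity"] = "skipped (n_reps_similarity = 0)"

    # 6. rank scenarios ----------------------------------------------------
    with _stage(manifest, "rank"):
        sources = {(name, cl): recs
                   for (name, cl), recs in cluster_records.items()
                   if name != target_name}
        ranking = scenario_compare(
            occ.for_range(target_name), sources, data.grids, target,
            betamultiplier=config.betamultiplier,
            n_background=config.n_background,
            buffer_radius=config.buffer_radius,
            seed=int(rng.integers(2**31 - 1)))
        ranking.to_csv(out / "threat_ranking.csv", index=False)
        manifest["threat_ranking"] = ranking.to_dict(orient="records")

    # manifest -------------------------------------------------------------
    for p in sorted(out.glob("*")):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return manifest
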