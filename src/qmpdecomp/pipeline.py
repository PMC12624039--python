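"""Pipeline stages over the tabular bundle.

Each stage reads its predecessors' outputs from the run directory, writes
its own tables with provenance headers, and is deterministic given the
config seed.  Stage order: simulate -> calibrate -> diversity / network /
metabolome -> integrate -> predict.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, calibration, cohort, diversity, integration, metabolomics, network, pmi
from .core import AbundanceMatrix, subseeds
from .io import Bundle, RunConfig, read_bundle, read_tsv, write_bundle, write_graphml, write_json, write_tsv

logger = logging.getLogger("qmpdecomp")

STAGES = ("simulate", "calibrate", "diversity", "network", "metabolome", "integrate", "predict")


class MissingStageError(RuntimeError):
    pass


def _require(outdir: Path, filename: str, stage: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise MissingStageError(f"missing {filename}: run the '{stage}' stage first")
    return path


def _manifest(outdir: Path, config: RunConfig, stage: str) -> None:
    write_json(
        {"stage": stage, "config_hash": config.hash(), "seed": config.seed, "version": __version__},
        outdir / f"manifest_{stage}.json",
    )


def stage_simulate(config: RunConfig) -> Bundle:
    outdir = Path(config.outdir)
    design = cohort.CohortDesign(read_depth=config.read_depth, seed=config.seed)
    coh = cohort.simulate_cohort(design, n_metabolite_features=config.n_metabolite_features)
    write_bundle(coh, outdir, config)
    _manifest(outdir, config, "simulate")
    logger.info("simulated %d samples into %s", len(coh.metadata), outdir)
    return read_bundle(outdir)


def _load_mode(outdir: Path, prefix: str, domain: str, mode: str) -> AbundanceMatrix:
    data = read_tsv(_require(outdir, f"{prefix}_{domain}.tsv", "calibrate"), numeric=True)
    return AbundanceMatrix(data, mode=mode, domain=domain)


def stage_calibrate(config: RunConfig) -> dict:
    """QMP (spike-calibrated copies per gram) and RMP (rarefied) profiles
    per domain, plus the per-sample calibration report."""
    outdir = Path(config.outdir)
    _require(outdir, "metadata.tsv", "simulate")
    bundle = read_bundle(outdir)
    seeds = subseeds(config.seed, len(bundle.counts))
    out = {}
    for (domain, counts), rare_seed in zip(bundle.counts.items(), seeds):
        qmp, report = calibration.qmp_profile(counts, bundle.spikes[domain], bundle.metadata["mass_g"])
        rmp = calibration.rmp_profile(
            counts, bundle.spikes[domain].spike_ids, depth=config.rarefaction_depth, seed=rare_seed
        )
        write_tsv(qmp.data, outdir / f"qmp_{domain}.tsv", "calibrate", config, mode="copies_per_gram")
        write_tsv(rmp.data, outdir / f"rmp_{domain}.tsv", "calibrate", config,
                  mode="rarefied_reads", depth=int(rmp.data.sum(axis=0).iloc[0]))
        write_tsv(report, outdir / f"calibration_report_{domain}.tsv", "calibrate", config)
        out[domain] = {"qmp": qmp, "rmp": rmp, "report": report}
    _manifest(outdir, config, "calibrate")
    return out


def _profiles(outdir: Path, bundle: Bundle) -> dict:
    out = {}
    for domain in bundle.counts:
        out[domain] = {
            "qmp": _load_mode(outdir, "qmp", domain, "copies_per_gram"),
            "rmp": _load_mode(outdir, "rmp", domain, "rarefied_reads"),
        }
    return out


def stage_diversity(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    bundle = read_bundle(outdir)
    prof = _profiles(outdir, bundle)
    meta = bundle.metadata
    results: dict = {}
    shannon_rows, decay_rows = [], []
    for domain, p in prof.items():
        for mode in ("qmp", "rmp"):
            h = diversity.shannon_table(p[mode])
            for s, v in h.items():
                shannon_rows.append({"sample_id": s, "domain": domain, "mode": mode, "shannon": v})
        for stype in meta["sample_type"].unique():
            sel = meta.index[meta["sample_type"] == stype]
            for mode in ("qmp", "rmp"):
                mat = p[mode]
                cols = sel.intersection(mat.samples)
                if len(cols) < 6:
                    continue
                sub = mat.with_data(mat.data[cols])
                d = diversity.bray_curtis(sub)
                if stype == "tissue" and mode == "qmp":
                    scores, rel = diversity.pcoa(d)
                    write_tsv(scores, outdir / f"pcoa_{domain}_{stype}.tsv", "diversity", config,
                              relative_eigenvalues=",".join(f"{x:.4f}" for x in rel))
                try:
                    td = diversity.time_decay(d, meta["day"])
                except ValueError:
                    continue
                decay_rows.append({"domain": domain, "sample_type": stype, "mode": mode, **td})
        tissue = meta.index[meta["sample_type"] == "tissue"].intersection(p["qmp"].samples)
        if len(tissue) >= 10:
            kd = diversity.identify_key_decomposers(
                p["qmp"].with_data(p["qmp"].data[tissue]), meta["day"],
                r_min=config.r_min, p_max=config.p_max, seed=config.seed,
            )
            write_tsv(kd, outdir / f"key_decomposers_{domain}.tsv", "diversity", config,
                      r_min=config.r_min, p_max=config.p_max)
            results[f"key_decomposers_{domain}"] = kd
        for stype in ("grave_soil", "tissue"):
            sel = meta.index[meta["sample_type"] == stype]
            cols = sel.intersection(p["qmp"].samples).intersection(p["rmp"].samples)
            if len(cols) < 8:
                continue
            disc = diversity.trend_discordance(
                p["qmp"].with_data(p["qmp"].data[cols]),
                p["rmp"].with_data(p["rmp"].data[cols]),
                meta["day"],
                early_days=config.early_days,
                late_days=config.late_days,
                top_n=config.top_n_genera,
            )
            write_tsv(disc, outdir / f"discordance_{domain}_{stype}.tsv", "diversity", config,
                      early_days=config.early_days, late_days=config.late_days)
            results[f"discordance_{domain}_{stype}"] = disc
    write_tsv(pd.DataFrame(shannon_rows).set_index("sample_id"), outdir / "shannon.tsv", "diversity", config)
    decay = pd.DataFrame(decay_rows)
    write_tsv(decay.set_index(["domain", "sample_type", "mode"]) if len(decay) else decay,
              outdir / "time_decay.tsv", "diversity", config)
    results["time_decay"] = decay
    _manifest(outdir, config, "diversity")
    return results


def stage_network(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    bundle = read_bundle(outdir)
    prof = _profiles(outdir, bundle)
    meta = bundle.metadata
    tissue = meta.index[meta["sample_type"] == "tissue"]
    domains_map = bundle.taxonomy["domain"] if "domain" in bundle.taxonomy else None
    results: dict = {}
    nets = {}
    for domain, p in prof.items():
        for mode in ("qmp", "rmp"):
            mat = p[mode]
            cols = tissue.intersection(mat.samples)
            net = network.build_network(
                mat.with_data(mat.data[cols]), r_min=config.r_min, p_max=config.p_max,
                top_n=config.top_n_genera, domains=domains_map,
            )
            nets[(domain, mode)] = net
        results[f"overlap_{domain}"] = network.edge_overlap(nets[(domain, "qmp")], nets[(domain, "rmp")])
    # combined-domain QMP network: top genera selected within each domain,
    # then genus matrices concatenated on shared tissue samples
    mats = [p["qmp"] for p in prof.values()]
    shared = tissue
    for m in mats:
        shared = shared.intersection(m.samples)
    tops = [m.data.loc[network.top_genera(m, config.top_n_genera), shared] for m in mats]
    combined = AbundanceMatrix(pd.concat(tops), mode="copies_per_gram")
    comb_net = network.build_network(
        combined, r_min=config.r_min, p_max=config.p_max,
        top_n=len(combined.taxa), domains=domains_map,
    )
    stats = network.network_stats(comb_net)
    write_tsv(comb_net.edges, outdir / "network_edges_combined.tsv", "network", config,
              r_min=config.r_min, p_max=config.p_max)
    write_tsv(comb_net.nodes, outdir / "network_nodes_combined.tsv", "network", config)
    write_graphml(comb_net, outdir / "network_combined.graphml")
    write_json({"combined": stats, "overlap": {d: results[f"overlap_{d}"] for d in prof}},
               outdir / "network_summary.json")
    eig = network.module_eigengenes(combined, comb_net)
    if len(eig.columns):
        write_tsv(eig, outdir / "module_eigengenes.tsv", "network", config)
    results.update({"combined_network": comb_net, "combined_stats": stats, "eigengenes": eig, "nets": nets})
    if bundle.metabolites is not None and len(eig.columns):
        grid = network.module_metabolite_correlation(
            eig, bundle.metabolites.data, bundle.metabolites.superclass, seed=config.seed
        )
        write_tsv(grid.set_index(["module", "superclass"]), outdir / "module_metabolite_correlation.tsv",
                  "network", config)
        results["module_metabolite"] = grid
    _manifest(outdir, config, "network")
    return results


def stage_metabolome(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    bundle = read_bundle(outdir)
    if bundle.metabolites is None:
        raise MissingStageError("bundle has no metabolite table")
    meta = bundle.metadata
    scaled = metabolomics.normalize(bundle.metabolites)
    scores, ev = metabolomics.pca(scaled)
    write_tsv(scores, outdir / "metabolite_pca.tsv", "metabolome", config,
              explained_fractions=",".join(f"{x:.4f}" for x in ev))
    groups = meta.loc[scaled.samples, "day"].astype(int).astype(str).radd("day")
    model = metabolomics.plsda(scaled, groups)
    vip_table = metabolomics.vip_select(model, scaled, vip_min=config.vip_min, p_max=config.vip_p_max)
    write_tsv(vip_table, outdir / "metabolite_vip.tsv", "metabolome", config,
              vip_min=config.vip_min, p_max=config.vip_p_max,
              explained_y=",".join(f"{x:.4f}" for x in model.explained_y))
    corr, composition = metabolomics.pmi_correlated_metabolites(
        metabolomics.sum_normalize(bundle.metabolites), meta["day"],
        r_min=config.r_min, p_max=config.p_max, seed=config.seed,
    )
    write_tsv(corr, outdir / "metabolite_pmi_clusters.tsv", "metabolome", config,
              r_min=config.r_min, p_max=config.p_max)
    return {
        "scaled": scaled, "pca_scores": scores, "pca_explained": ev, "plsda": model,
        "vip": vip_table, "pmi_clusters": corr, "cluster_composition": composition,
    }


def stage_integrate(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    bundle = read_bundle(outdir)
    if bundle.metabolites is None:
        raise MissingStageError("bundle has no metabolite table")
    prof = _profiles(outdir, bundle)
    meta = bundle.metadata
    tissue = meta.index[meta["sample_type"] == "tissue"]
    scaled = metabolomics.normalize(bundle.metabolites)
    shared = tissue.intersection(scaled.samples)
    for p in prof.values():
        shared = shared.intersection(p["qmp"].samples)
    shared = pd.Index(sorted(shared))
    mscores, _ = metabolomics.pca(
        metabolomics.MetaboliteMatrix(scaled.data[shared], scaled.superclass, state="pareto_scaled")
    )
    results: dict = {"procrustes": {}, "mantel": {}, "partial_mantel": {}}
    s_proc, s_mant, s_rda, s_rf = subseeds(config.seed, 4)
    bc = {}
    for domain, p in prof.items():
        sub = p["qmp"].with_data(p["qmp"].data[shared])
        d = diversity.bray_curtis(sub)
        bc[domain] = d.loc[shared, shared]
        scores, _ = diversity.pcoa(bc[domain])
        res = integration.procrustes(scores, mscores.loc[shared], n_perm=config.n_permutations, seed=s_proc)
        results["procrustes"][domain] = res
        results["mantel"][domain] = integration.mantel(
            bc[domain], _metab_bc(bundle.metabolites, shared), n_perm=config.n_permutations, seed=s_mant
        )
    if len(bc) == 2:
        dmet = _metab_bc(bundle.metabolites, shared)
        (da, db) = bc.keys()
        results["partial_mantel"][da] = integration.partial_mantel(
            bc[da], dmet, bc[db], n_perm=config.n_permutations, seed=s_mant, controlled_name=db
        )
        results["partial_mantel"][db] = integration.partial_mantel(
            bc[db], dmet, bc[da], n_perm=config.n_permutations, seed=s_mant, controlled_name=da
        )
    # RDA: total copies/g per domain, alpha diversity, phylum-level abundance
    expl = {}
    for domain, p in prof.items():
        sub = p["qmp"].data[shared]
        expl[f"log10_total_{domain}"] = np.log10(sub.sum(axis=0))
        expl[f"shannon_{domain}"] = diversity.shannon_table(p["qmp"].with_data(sub))
        phyla = bundle.taxonomy.loc[bundle.taxonomy["domain"] == domain, "phylum"]
        agg = sub.groupby(phyla.reindex(sub.index)).sum()
        top_phyla = agg.mean(axis=1).nlargest(3 if domain == "bacteria" else 4).index
        for phylum in top_phyla:
            expl[str(phylum)] = np.log10(agg.loc[phylum] + 1.0)
    explanatory = pd.DataFrame(expl, index=shared)
    rda_res = integration.rda(scaled.data[shared].T, explanatory,
                              n_perm=min(config.n_permutations, 199), seed=s_rda)
    write_tsv(rda_res["variables"], outdir / "rda_variables.tsv", "integrate", config)
    results["rda"] = rda_res
    # random-forest metabolite association per domain + class intersection
    assoc = {}
    for domain, p in prof.items():
        summary = np.log10(p["qmp"].data[shared].sum(axis=0))
        assoc[domain] = integration.rf_metabolite_association(
            bundle.metabolites.data[shared], summary, superclass=bundle.metabolites.superclass,
            n_trees=min(config.n_trees, 500), seed=s_rf,
        )
        write_tsv(assoc[domain]["importance"], outdir / f"rf_association_{domain}.tsv", "integrate", config)
    results["rf_association"] = assoc
    if len(assoc) == 2:
        a, b = assoc.values()
        results["class_intersection"] = integration.top_class_intersection(a, b)
    recs = {
        d: {"procrustes_m2": results["procrustes"][d].m2, "procrustes_r": results["procrustes"][d].r,
            "procrustes_p": results["procrustes"][d].p_value,
            "mantel_r": results["mantel"][d].r, "mantel_p": results["mantel"][d].p_value}
        for d in results["procrustes"]
    }
    for d, res in results["partial_mantel"].items():
        recs[d]["partial_mantel_r"] = res.r
        recs[d]["partial_mantel_p"] = res.p_value
    write_json({"domains": recs, "n_permutations": config.n_permutations, "seed": config.seed},
               outdir / "integration_summary.json")
    _manifest(outdir, config, "integrate")
    return results


def _euclidean_distance(scores: pd.DataFrame) -> pd.DataFrame:
    from scipy.spatial.distance import pdist, squareform

    return pd.DataFrame(squareform(pdist(scores.to_numpy())), index=scores.index, columns=scores.index)


def _metab_bc(metabolites, samples) -> pd.DataFrame:
    norm = metabolomics.sum_normalize(metabolites)
    mat = AbundanceMatrix(norm.data[samples], mode="relative")
    return diversity.bray_curtis(mat).loc[samples, samples]


def stage_predict(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    bundle = read_bundle(outdir)
    prof = _profiles(outdir, bundle)
    meta = bundle.metadata
    tissue = meta.index[meta["sample_type"] == "tissue"]
    days = meta["day"]
    s_split, s_opt, s_eval = subseeds(config.seed, 3)
    split = pmi.stratified_split(meta.loc[tissue], ratio=(2, 1), seed=s_split)
    feature_sets: dict[str, pd.DataFrame] = {}
    for domain, p in prof.items():
        for mode in ("qmp", "rmp"):
            mat = p[mode]
            cols = tissue.intersection(mat.samples)
            feature_sets[f"{mode}_{domain}"] = pmi.features_from_abundance(mat.with_data(mat.data[cols]))
    if bundle.metabolites is not None:
        feature_sets["metabolites"] = bundle.metabolites.data[tissue.intersection(bundle.metabolites.samples)].T
        blocks = {f"qmp_{d}": feature_sets[f"qmp_{d}"] for d in prof}
        blocks["metabolites"] = feature_sets["metabolites"]
        feature_sets["multi_omics"] = pmi.multi_omics_concat(blocks)
    records, curves = {}, []
    for name, feats in feature_sets.items():
        feats = feats.loc[feats.index.intersection(split.train.union(split.test))]
        train_feats = feats.loc[split.train.intersection(feats.index)]
        opt = pmi.optimize_biomarkers(
            train_feats, days, k_folds=config.k_folds, repeats=config.cv_repeats,
            n_trees=config.n_trees, seed=s_opt,
        )
        ev = pmi.evaluate(feats[opt["selected"]], days, split, n_runs=config.n_eval_runs,
                          n_trees=config.n_trees, seed=s_eval)
        records[name] = {
            "best_k": opt["best_k"],
            "selected": opt["selected"],
            "train_mae": ev.train_mae, "test_mae": ev.test_mae,
            "train_r2": ev.train_r2, "test_r2": ev.test_r2,
            "n_runs": ev.n_runs,
        }
        curves.extend({"feature_set": name, "k": k, "cv_mae": v} for k, v in opt["cv_curve"].items())
    records["null_test_mae"] = pmi.null_mae(days, split)
    write_json({"split_seed": s_split, "eval_seed": s_eval, "models": records},
               outdir / "pmi_models.json")
    write_tsv(pd.DataFrame(curves).set_index("feature_set"), outdir / "pmi_cv_curves.tsv", "predict", config)
    _manifest(outdir, config, "predict")
    return {"split": split, "records": records}


def run_stage(stage: str, config: RunConfig):
    funcs = {
        "simulate": stage_simulate, "calibrate": stage_calibrate, "diversity": stage_diversity,
        "network": stage_network, "metabolome": stage_metabolome, "integrate": stage_integrate,
        "predict": stage_predict,
    }
    if stage == "all":
        return {name: funcs[name](config) for name in STAGES}
    if stage not in funcs:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES + ('all',)}")
    return funcs[stage](config)
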