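"""Study orchestration: configuration, simulation, loading, and the
end-to-end analysis run.

A ``StudyBundle`` holds the aligned genotype / expression / fitness / trait /
annotation inputs (plus the simulation ground truth when the study is
synthetic). ``run_all`` executes the stages in dependency order —
quantitative genetics, selection scan, response prediction, decoherence,
eQTL mapping, regulatory architecture — writing every stage's tables, a
manifest with parameter echoes and filter attrition counts, and a summary
report of the headline statistics. All randomness derives from the single
config seed through named substreams, so a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import copy
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decohere as deco
from . import eqtlmap, exprqg, io, regarch, respond, selscan
from .datatypes import (
    ENVIRONMENTS,
    ExpressionMatrix,
    FitnessTable,
    GenotypeMatrix,
    SimulationTruth,
)
from .synthdata import (
    place_genes,
    plant_architecture,
    simulate_annotations,
    simulate_expression,
    simulate_fitness,
    simulate_genotypes,
    stage_rng,
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "genotypes": {
        "n_accessions": 150,
        "chrom_lengths": {f"chr{i}": 30_000_000 for i in range(1, 6)},
        "n_snps": 3000,
        "maf_spectrum": ["uniform", 0.05, 0.5],
        "inbreeding": 0.99,
        "ld_block": 50_000,
        "n_subpops": 3,
        "fst": 0.25,
        "missing_rate": 0.01,
    },
    "architecture": {
        "n_genes": 1000,
        "cis_fraction": 0.2,
        "dual_fraction": 0.05,
        "trans_fraction": 0.1,
        "reinforce_fraction": 0.6,
        "effect_dist": ["uniform", 0.6, 1.4],
        "hotspot_targets": 50,
        "hotspot_environment": "saline",
    },
    "design": {"replicates": 3, "blocks": 3},
    "fitness": {
        "base_fecundity": {"normal": 150.0, "saline": 100.0},
        "noise_sd": 0.3,
        "zero_rate": 0.05,
        "n_normal_only": 16,
        "n_saline_only": 16,
        "n_shared": 8,
        "s_values": [-0.2, -0.1, 0.1, 0.2],
        "c_saline": -0.1,
        "n_stabilizing": 8,
    },
    "annotations": {"n_terms": 60, "size_dist": ["uniform", 20, 40]},
    "filters": {
        "detection_fraction": 0.10,
        "min_n": 20,
        "maf": 0.05,
        "max_missing": 0.2,
        "max_het": 0.05,
        "thin_bp": 1000,
    },
    "fdr": {"anova": 0.001, "eqtl": 0.001, "gxe": 0.05, "cilp": 0.05},
    # |S| is on the raw (unstandardized) scale and shrinks with transcript SD;
    # the synthetic transcripts have SD ~1.8, so the entry threshold is set to
    # admit the selected tail of the synthetic S distribution.
    "decohere": {"s_threshold": 0.04, "detect_frac": 0.5},
    "respond": {"max_pcs": 20},
    "ld_test": {"n_perm": 1000},
}


def default_config(seed: int | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


@dataclass
class StudyBundle:
    geno: GenotypeMatrix
    expr: ExpressionMatrix
    fitness: FitnessTable
    gene_positions: pd.DataFrame
    terms: dict
    traits: pd.DataFrame | None = None
    truth: SimulationTruth | None = None
    config: dict = field(default_factory=dict)
    provenance: list = field(default_factory=list)

    def log(self, **event) -> None:
        self.provenance.append(event)


def _plant_selection_truth(
    transcript_ids, fit_cfg: dict, seed: int
) -> dict:
    """Assign planted S (and some stabilizing C) to chosen transcripts.

    Mirrors the observed structure: selection mostly environment-specific
    (conditional neutrality), a shared same-sign subset, no planted
    opposite-sign (antagonistic) pairs.
    """
    rng = stage_rng(seed, "selection-truth")
    n_total = (
        fit_cfg["n_normal_only"] + fit_cfg["n_saline_only"] + fit_cfg["n_shared"]
    )
    chosen = rng.choice(np.asarray(transcript_ids, object), n_total, replace=False)
    s_vals = np.asarray(fit_cfg["s_values"], float)
    truth = {"normal": {}, "saline": {}}
    k = 0
    for _ in range(fit_cfg["n_normal_only"]):
        truth["normal"][str(chosen[k])] = (float(rng.choice(s_vals)), 0.0)
        k += 1
    for _ in range(fit_cfg["n_saline_only"]):
        truth["saline"][str(chosen[k])] = (float(rng.choice(s_vals)), 0.0)
        k += 1
    for _ in range(fit_cfg["n_shared"]):
        s = float(rng.choice(s_vals))
        truth["normal"][str(chosen[k])] = (s, 0.0)
        truth["saline"][str(chosen[k])] = (s, 0.0)
        k += 1
    stab = rng.choice(
        np.asarray(list(truth["saline"]), object),
        min(fit_cfg["n_stabilizing"], len(truth["saline"])),
        replace=False,
    )
    for t in stab:
        s, _ = truth["saline"][str(t)]
        truth["saline"][str(t)] = (s, float(fit_cfg["c_saline"]))
    return truth


def _simulate_traits(expr: ExpressionMatrix, seed: int) -> pd.DataFrame:
    """Small organismal-trait table: accession-structured values with one
    strongly correlated trait pair (exercises the correlation pruning)."""
    rng = stage_rng(seed, "traits")
    acc_levels, ai = np.unique(expr.accession.astype(str), return_inverse=True)
    base = rng.normal(0.0, 1.0, size=(len(acc_levels), 4))
    noise = rng.normal(0.0, 0.5, size=(expr.n_plants, 4))
    t = base[ai] + noise
    traits = pd.DataFrame(
        {
            "LOP": t[:, 0],
            "Chl_a": t[:, 1],
            "FT": t[:, 2],
            "height": t[:, 3],
            "biomass": 0.95 * t[:, 3] + rng.normal(0.0, 0.2, expr.n_plants),
        },
        index=pd.Index(expr.plant_ids, name="plant_id"),
    )
    return traits


def simulate_study(config: dict | None = None) -> StudyBundle:
    """Generate the full synthetic study described by the config."""
    cfg = config or default_config()
    seed = int(cfg["seed"])
    g = cfg["genotypes"]
    geno = simulate_genotypes(
        n_accessions=g["n_accessions"],
        chrom_lengths=g["chrom_lengths"],
        n_snps=g["n_snps"],
        maf_spectrum=tuple(g["maf_spectrum"]) if not np.isscalar(g["maf_spectrum"]) else g["maf_spectrum"],
        inbreeding=g["inbreeding"],
        ld_block=g["ld_block"],
        seed=seed,
        n_subpops=g.get("n_subpops", 1),
        fst=g.get("fst", 0.0),
        missing_rate=g.get("missing_rate", 0.0),
    )
    a = cfg["architecture"]
    gene_positions = place_genes(geno, a["n_genes"], seed=seed)
    hotspot = None
    if a.get("hotspot_targets"):
        # master regulator: the SNP closest to the middle of the first chromosome
        chrom0 = str(geno.chrom[0])
        on_c = np.flatnonzero(geno.chrom == chrom0)
        mid = geno.pos[on_c].max() // 2
        hs = on_c[np.argmin(np.abs(geno.pos[on_c] - mid))]
        hotspot = (str(geno.snp_ids[hs]), int(a["hotspot_targets"]))
    truth = plant_architecture(
        geno,
        a["n_genes"],
        gene_positions=gene_positions,
        cis_fraction=a["cis_fraction"],
        dual_fraction=a["dual_fraction"],
        trans_fraction=a["trans_fraction"],
        reinforce_fraction=a["reinforce_fraction"],
        hotspot_spec=hotspot,
        effect_dist=tuple(a["effect_dist"]),
        seed=seed,
        hotspot_environment=a.get("hotspot_environment", "both"),
    )
    d = cfg["design"]
    expr = simulate_expression(
        geno,
        truth,
        gene_positions,
        design=(ENVIRONMENTS, d["replicates"], d["blocks"]),
        seed=seed,
    )
    f = cfg["fitness"]
    truth.selection = _plant_selection_truth(expr.transcript_ids, f, seed)
    fitness = simulate_fitness(
        expr,
        truth.selection,
        base_fecundity=f["base_fecundity"],
        noise_sd=f["noise_sd"],
        zero_rate=f["zero_rate"],
        seed=seed,
    )
    ann = cfg["annotations"]
    terms = simulate_annotations(
        expr.transcript_ids,
        ann["n_terms"],
        tuple(ann["size_dist"]) if not np.isscalar(ann["size_dist"]) else ann["size_dist"],
        seed=seed,
    )
    bundle = StudyBundle(
        geno=geno,
        expr=expr,
        fitness=fitness,
        gene_positions=gene_positions,
        terms=terms,
        traits=_simulate_traits(expr, seed),
        truth=truth,
        config=cfg,
    )
    bundle.log(stage="simulate", n_accessions=geno.n_accessions,
               n_snps=geno.n_snps, n_transcripts=expr.n_transcripts)
    return bundle


def write_study(bundle: StudyBundle, directory: str | Path) -> dict:
    """Write every table of the bundle; returns the file map."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files = {
        "vcf": str(io.write_vcf(bundle.geno, d / "genotypes.vcf")),
        "expression": str(io.write_expression(bundle.expr, d / "expression.tsv")),
        "fitness": str(io.write_fitness(bundle.fitness, d / "fitness.tsv")),
        "gene_positions": str(
            io.write_gene_positions(bundle.gene_positions, d / "gene_positions.tsv")
        ),
        "terms": str(io.write_term_map(bundle.terms, d / "terms.tsv")),
    }
    if bundle.traits is not None:
        bundle.traits.to_csv(d / "traits.tsv", sep="\t", float_format="%.6g")
        files["traits"] = str(d / "traits.tsv")
    if bundle.truth is not None:
        files["truth"] = str(io.write_truth(bundle.truth, d / "truth.json"))
    with open(d / "config.yaml", "w") as fh:
        yaml.safe_dump(bundle.config, fh, sort_keys=True)
    files["config"] = str(d / "config.yaml")
    return files


def load_study(config_path: str | Path) -> StudyBundle:
    """Load a study from a YAML config that names the input files.

    Cross-validates sample ids (expression accessions absent from the
    genotypes are dropped with a logged count) and applies the transcript
    detection filter (expressed in at least ``detection_fraction`` of
    plants).
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    file_cfg = cfg.get("files", {})
    base = config_path.parent
    paths = {}
    for key in ("vcf", "expression", "fitness", "gene_positions", "terms"):
        if key not in file_cfg:
            raise ValueError(f"config is missing required file entry: {key}")
        p = Path(file_cfg[key])
        p = p if p.is_absolute() else base / p
        if not p.exists():
            raise FileNotFoundError(f"missing input file for {key!r}: {p}")
        paths[key] = p
    geno = io.read_vcf(paths["vcf"])
    gene_positions = io.read_gene_positions(paths["gene_positions"])
    expr = io.read_expression(paths["expression"], gene_positions)
    fitness = io.read_fitness(paths["fitness"])
    terms = io.read_term_map(paths["terms"])
    truth = traits = None
    for key in ("truth", "traits"):
        if key in file_cfg:
            p = Path(file_cfg[key])
            p = p if p.is_absolute() else base / p
            if key == "truth":
                truth = io.read_truth(p)
            else:
                traits = pd.read_csv(p, sep="\t", index_col=0)

    bundle = StudyBundle(
        geno=geno, expr=expr, fitness=fitness, gene_positions=gene_positions,
        terms=terms, traits=traits, truth=truth,
        config={**default_config(), **cfg},
    )
    _cross_validate(bundle)
    return bundle


def _cross_validate(bundle: StudyBundle) -> None:
    known = set(bundle.geno.accession_ids)
    keep = np.asarray([a in known for a in bundle.expr.accession])
    dropped = int((~keep).sum())
    if dropped:
        bad = sorted({a for a in bundle.expr.accession[~keep]})[:10]
        bundle.log(stage="load", dropped_plants=dropped, unknown_accessions=bad)
        bundle.expr = bundle.expr.subset_plants(keep)
    det = bundle.config["filters"]["detection_fraction"]
    detected = (bundle.expr.values > 0).mean(axis=0) >= det
    n_dropped = int((~detected).sum())
    if n_dropped:
        bundle.expr = bundle.expr.subset_transcripts(np.flatnonzero(detected))
    bundle.log(stage="detection_filter", transcripts_in=len(detected),
               transcripts_out=int(detected.sum()), removed=n_dropped)


# ---------------------------------------------------------------------------
# end-to-end run


def _stage_qg(bundle: StudyBundle, outdir: Path, summary: dict) -> dict:
    cfg = bundle.config
    anova = exprqg.transcriptome_anova(bundle.expr, fdr=cfg["fdr"]["anova"])
    anova.to_csv(outdir / "transcript_anova.tsv", sep="\t", float_format="%.6g")
    acc_of = dict(zip(bundle.expr.plant_ids, bundle.expr.accession))
    fit_acc = np.asarray([acc_of[p] for p in bundle.fitness.plant_ids], object)
    tests = exprqg.fitness_environment_tests(
        bundle.fitness.fecundity, fit_acc, bundle.fitness.environment
    )
    fec_vc = exprqg.partition_variance(
        bundle.fitness.fecundity.astype(float), fit_acc, bundle.fitness.environment
    )
    fec_vc.table.to_csv(outdir / "fecundity_anova.tsv", sep="\t", float_format="%.6g")
    with open(outdir / "fitness_tests.json", "w") as fh:
        json.dump(tests, fh, indent=1)
    summary["h2_median"] = float(anova["H2"].median())
    summary["n_sig_G"] = int(anova["sig_G"].sum())
    summary["n_sig_GxE"] = int(anova["sig_GxE"].sum())
    summary["fitness_tests"] = tests
    return {"anova": anova, "fitness_tests": tests}


def _stage_selection(bundle: StudyBundle, outdir: Path, summary: dict) -> dict:
    cfg = bundle.config
    tables, pca, gradients, w_by_env = {}, {}, {}, {}
    for env in ENVIRONMENTS:
        tab = selscan.selection_differentials(
            bundle.expr, bundle.fitness, env, min_n=cfg["filters"]["min_n"]
        )
        tab.to_csv(outdir / f"selection_{env}.tsv", sep="\t", float_format="%.6g")
        tables[env] = tab
        summary[f"median_abs_S_{env}"] = float(tab["S"].abs().median())

        mask = bundle.expr.env_mask(env)
        fec = bundle.fitness.aligned_to(bundle.expr.plant_ids[mask])
        rf = selscan.relative_fitness(fec)
        w_by_env[env] = rf
        sub = bundle.expr.subset_plants(mask).subset_plants(rf.retained)
        res = selscan.expression_pca(sub)
        pca[env] = (res, sub)
        k = min(int(res.retained.sum()), cfg["respond"]["max_pcs"])
        scores = res.scores[:, :k]
        grad = selscan.selection_gradients(scores, rf.w)
        grad["direction"] = selscan.pc_direction(
            res.loadings[:, :k], res.transcript_ids, tables[env]
        )
        grad["var_frac"] = res.var_frac[:k]
        grad.to_csv(outdir / f"gradients_{env}.tsv", sep="\t", float_format="%.6g")
        gradients[env] = grad

        go = selscan.go_selection(
            tab[tab["skipped"] == ""], bundle.terms, seed=int(cfg["seed"]) + 7
        )
        go.to_csv(outdir / f"go_selection_{env}.tsv", sep="\t", float_format="%.6g")

    labels = selscan.classify_cn_ap(tables["normal"], tables["saline"])
    labels.to_frame().to_csv(outdir / "cn_ap_labels.tsv", sep="\t")
    counts = labels.value_counts().to_dict()
    summary["cn_ap_counts"] = {str(k): int(v) for k, v in counts.items()}

    if bundle.traits is not None:
        env = "saline"
        mask = bundle.expr.env_mask(env)
        fec = bundle.fitness.aligned_to(bundle.expr.plant_ids[mask])
        rf = selscan.relative_fitness(fec)
        traits = bundle.traits.loc[bundle.expr.plant_ids[mask][rf.retained]]
        tg = selscan.trait_gradients(traits, rf.w)
        tg.to_csv(outdir / "trait_gradients_saline.tsv", sep="\t",
                  float_format="%.6g")
    return {"tables": tables, "pca": pca, "gradients": gradients,
            "labels": labels, "w": w_by_env}


def _stage_respond(bundle: StudyBundle, outdir: Path, summary: dict,
                   selection: dict) -> dict:
    k_mat = respond.grm(bundle.geno)
    io.write_matrix(k_mat, bundle.geno.accession_ids, outdir / "grm.tsv")
    out = {}
    for env in ENVIRONMENTS:
        res, sub = selection["pca"][env]
        grad = selection["gradients"][env]
        k = len(grad)
        eig = respond.eigengene_scores(
            res.scores[:, :k], sub.accession
        ).reindex(bundle.geno.accession_ids)
        if eig.isna().any().any():
            eig = eig.dropna()
            order = [list(bundle.geno.accession_ids).index(a) for a in eig.index]
            km = k_mat[np.ix_(order, order)]
        else:
            km = k_mat
        gres = respond.estimate_g_matrix(eig.to_numpy(), km)
        io.write_matrix(gres.g, np.asarray(eig.columns, object),
                        outdir / f"g_matrix_{env}.tsv")
        resp = respond.predict_response(gres.g, grad["beta"].to_numpy())
        resp["G_ii"] = np.diag(gres.g)
        resp.to_csv(outdir / f"response_{env}.tsv", sep="\t", float_format="%.6g")
        out[env] = {"g": gres, "response": resp}
        summary[f"n_constrained_pcs_{env}"] = int(resp["constrained"].sum())
    return out


def _stage_decohere(bundle: StudyBundle, outdir: Path, summary: dict,
                    selection: dict) -> dict:
    cfg = bundle.config
    chosen = deco.select_cilp_transcripts(
        selection["tables"]["normal"], selection["tables"]["saline"],
        bundle.expr,
        s_threshold=cfg["decohere"]["s_threshold"],
        detect_frac=cfg["decohere"]["detect_frac"],
    )
    if len(chosen) < 2:
        summary["decoherence"] = {"n_transcripts": int(len(chosen)),
                                  "n_significant_pairs": 0}
        return {"chosen": chosen, "result": None}
    result = deco.cilp(bundle.expr, transcripts=chosen, fdr=cfg["fdr"]["cilp"])
    result.pairs.to_csv(outdir / "cilp_pairs.tsv", sep="\t", index=False,
                        float_format="%.6g")
    hubs, med = deco.decoherence_hubs(result)
    result.counts.rename("n_significant_pairs").to_csv(
        outdir / "cilp_transcript_counts.tsv", sep="\t"
    )
    summary["decoherence"] = {
        "n_transcripts": int(len(chosen)),
        "n_pairs": int(len(result.pairs)),
        "n_significant_pairs": int(result.pairs["significant"].sum()),
        "n_hubs": int(len(hubs)),
        "hub_median": None if np.isnan(med) else float(med),
    }
    return {"chosen": chosen, "result": result}


def _stage_eqtl(bundle: StudyBundle, outdir: Path, summary: dict) -> dict:
    cfg = bundle.config
    f = cfg["filters"]
    filtered = eqtlmap.filter_genotypes(
        bundle.geno, maf=f["maf"], max_missing=f["max_missing"],
        max_het=f["max_het"], thin_bp=f["thin_bp"], seed=int(cfg["seed"]) + 13
    )
    bundle.log(stage="genotype_filter", snps_in=bundle.geno.n_snps,
               snps_out=filtered.n_snps)
    covs = eqtlmap.kinship_pcs(filtered, k=5)
    acc_in_geno = set(filtered.accession_ids)
    keep = np.asarray([a in acc_in_geno for a in bundle.expr.accession])
    expr = bundle.expr.subset_plants(keep) if not keep.all() else bundle.expr

    records, means = {}, {}
    for env in ENVIRONMENTS:
        m = expr.accession_means(env).reindex(filtered.accession_ids)
        means[env] = m
        rec = eqtlmap.map_eqtl(m, filtered, covs, fdr=cfg["fdr"]["eqtl"],
                               environment=env)
        rec = eqtlmap.annotate_cis_trans(rec, bundle.gene_positions)
        rec = eqtlmap.lead_snps(rec)
        rec.to_csv(outdir / f"eqtl_{env}.tsv", sep="\t", index=False,
                   float_format="%.6g")
        records[env] = rec
        summary[f"n_eqtl_{env}"] = int(len(rec))
        summary[f"n_genes_with_eqtl_{env}"] = int(rec["gene"].nunique())
    gxe = eqtlmap.map_gxe_eqtl(
        means["normal"] - means["saline"], filtered, covs, fdr=cfg["fdr"]["gxe"]
    )
    gxe = eqtlmap.lead_snps(eqtlmap.annotate_cis_trans(gxe, bundle.gene_positions))
    gxe.to_csv(outdir / "eqtl_gxe.tsv", sep="\t", index=False,
               float_format="%.6g")
    summary["n_gxe_eqtl"] = int(len(gxe))
    return {"filtered": filtered, "records": records, "gxe": gxe, "covs": covs}


def _stage_architecture(bundle: StudyBundle, outdir: Path, summary: dict,
                        eqtl: dict) -> dict:
    cfg = bundle.config
    filtered = eqtl["filtered"]
    out = {}
    for env in ENVIRONMENTS:
        rec = eqtl["records"][env]
        leads = rec[rec["lead"]]
        hot = regarch.detect_hotspots(leads[leads["class"] == "trans"])
        hot.to_csv(outdir / f"hotspots_{env}.tsv", sep="\t", index=False)
        calls = regarch.classify_modes(rec, filtered)
        calls.to_csv(outdir / f"mode_calls_{env}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        env_summary = {"n_hotspots": int(len(hot))}
        if len(hot):
            env_summary["top_hotspot"] = {
                "chrom": str(hot.iloc[0]["chrom"]),
                "bin_start": int(hot.iloc[0]["bin_start"]),
                "n_genes": int(hot.iloc[0]["n_genes"]),
            }
        classified = calls[calls["mode"] != "unclassified"]
        if len(classified):
            env_summary["modes"] = regarch.summarize_modes(calls)
            try:
                iv = exprqg.intervarietal_variance(bundle.expr, env)
                env_summary["mode_expression_contrast"] = (
                    regarch.mode_expression_contrast(calls, iv)
                )
            except ValueError:
                pass
            pairs = []
            lead_by_gene = rec[rec["lead"]]
            for gene in classified["gene"]:
                g = lead_by_gene[lead_by_gene["gene"] == gene]
                cis = g[g["class"] == "cis"].sort_values(["p", "pos"])
                for _, tr in g[g["class"] == "trans"].iterrows():
                    pairs.append((str(cis.iloc[0]["snp"]), str(tr["snp"])))
            if pairs:
                ld = regarch.ld_permutation_test(
                    pairs, filtered, n_perm=cfg["ld_test"]["n_perm"],
                    seed=int(cfg["seed"]) + 29
                )
                env_summary["ld_test"] = {
                    "observed_mean_r2": ld["observed_mean_r2"],
                    "null_mean_r2": ld["null_mean_r2"],
                    "p": ld["p"],
                }
        cis_snps = set(rec.loc[rec["class"] == "cis", "snp"])
        trans_snps = set(rec.loc[rec["class"] == "trans", "snp"])
        trans_counts = rec[rec["class"] == "trans"].groupby("snp")["gene"].nunique()
        multi = set(trans_counts[trans_counts > 1].index)
        background = set(filtered.snp_ids) - cis_snps - trans_snps
        contrast = regarch.maf_contrast(
            {"cis": cis_snps, "trans": trans_snps, "trans_multi": multi,
             "background": background},
            filtered,
        )
        env_summary["mean_maf"] = contrast["mean_maf"]
        if cis_snps:
            pi = regarch.pi_contrast(filtered, cis_snps)
            env_summary["pi"] = {k: pi[k] for k in
                                 ("window_pi_mean", "background_pi_mean", "p")}
        summary[f"architecture_{env}"] = env_summary
        out[env] = {"hotspots": hot, "calls": calls, "maf": contrast}
    return out


STAGES = ("qg", "selection", "respond", "decohere", "eqtl", "architecture")
_DEPS = {
    "respond": ("selection",),
    "decohere": ("selection",),
    "architecture": ("eqtl",),
}


def run_all(bundle: StudyBundle, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute every stage; returns {stage: result}. A failed stage is
    recorded in the manifest and its dependents are skipped."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        bundle.config = copy.deepcopy(bundle.config)
        bundle.config["seed"] = int(seed)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(bundle.config, fh, sort_keys=True)

    summary: dict = {}
    manifest: dict = {"stages": {}}
    results: dict = {}
    for stage in STAGES:
        deps = _DEPS.get(stage, ())
        if any(manifest["stages"].get(d, {}).get("status") != "ok" for d in deps):
            manifest["stages"][stage] = {"status": "skipped",
                                         "reason": f"dependency failed: {deps}"}
            continue
        stage_dir = outdir / stage
        stage_dir.mkdir(exist_ok=True)
        try:
            if stage == "qg":
                results[stage] = _stage_qg(bundle, stage_dir, summary)
            elif stage == "selection":
                results[stage] = _stage_selection(bundle, stage_dir, summary)
            elif stage == "respond":
                results[stage] = _stage_respond(bundle, stage_dir, summary,
                                                results["selection"])
            elif stage == "decohere":
                results[stage] = _stage_decohere(bundle, stage_dir, summary,
                                                 results["selection"])
            elif stage == "eqtl":
                results[stage] = _stage_eqtl(bundle, stage_dir, summary)
            elif stage == "architecture":
                results[stage] = _stage_architecture(bundle, stage_dir, summary,
                                                     results["eqtl"])
            files = sorted(str(p.relative_to(outdir)) for p in stage_dir.iterdir())
            manifest["stages"][stage] = {"status": "ok", "files": files}
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            manifest["stages"][stage] = {
                "status": "failed",
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(),
            }

    if bundle.truth is not None:
        summary["recovery"] = _truth_recovery(bundle, results)
    manifest["provenance"] = bundle.provenance
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    results["summary"] = summary
    results["manifest"] = manifest
    return results


def _truth_recovery(bundle: StudyBundle, results: dict) -> dict:
    """Planted-vs-estimated comparison appended for truth-aware runs."""
    rec: dict = {}
    truth = bundle.truth
    sel = results.get("selection")
    if sel:
        for env in ENVIRONMENTS:
            planted = truth.selection.get(env, {})
            tab = sel["tables"][env]
            got = []
            for t, (s_true, _) in planted.items():
                if t in tab.index and tab.loc[t, "skipped"] == "":
                    got.append((s_true, float(tab.loc[t, "S_s"])))
            if got:
                arr = np.asarray(got)
                rec[f"selection_{env}"] = {
                    "n": len(arr),
                    "mean_abs_error_S": float(np.abs(arr[:, 1] - arr[:, 0]).mean()),
                }
    eqtl = results.get("eqtl")
    if eqtl:
        planted_cis = {(e.snp, e.gene): e.beta for e in truth.cis_effects()}
        found = 0
        errs = []
        for env in ENVIRONMENTS:
            recs = eqtl["records"][env]
            key = set(zip(recs["snp"], recs["gene"]))
            for (snp, gene), beta in planted_cis.items():
                if (snp, gene) in key:
                    found += 1
                    row = recs[(recs["snp"] == snp) & (recs["gene"] == gene)]
                    errs.append(abs(float(row.iloc[0]["beta"]) - beta))
        rec["cis_eqtl"] = {
            "n_planted": len(planted_cis) * 2,
            "n_recovered_exact_snp": found,
            "mean_abs_beta_error": float(np.mean(errs)) if errs else None,
        }
    return rec
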