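"""Synthetic study generator.

Emulates the structure of a field common-garden experiment on ~130 highly
inbred rice accessions grown in two environments (normal paddy vs moderate
salinity) with 3 replicates in blocks: inbred biallelic genotypes with local
LD and optional population structure, a planted cis/trans regulatory
architecture (including a master-regulator hotspot and dual-control genes
with reinforcing or compensating cis-trans effects), transcript expression
with genotype / environment / GxE / residual variance components, fecundity
with planted linear and quadratic selection on chosen transcripts, and
GO-style term annotations.

Every stage draws from an independent substream spawned from one master seed,
so adding or re-running one stage never perturbs another.
"""

from __future__ import annotations

import warnings
import zlib

import numpy as np
import pandas as pd

from .datatypes import (
    ENVIRONMENTS,
    MISSING,
    ExpressionMatrix,
    FitnessTable,
    GenotypeMatrix,
    PlantedEffect,
    SimulationTruth,
)

CIS_WINDOW = 100_000  # bp; cis SNP within this distance of the gene
TRANS_MIN_DIST = 1_000_000  # bp; same-chromosome trans SNPs at least this far


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, named substream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(stage.encode()),))
    )


def _draw_maf(rng: np.random.Generator, spec, n: int) -> np.ndarray:
    """MAF spectrum spec: scalar, ("uniform", lo, hi) or ("beta", a, b)/2."""
    if np.isscalar(spec):
        maf = np.full(n, float(spec))
    elif spec[0] == "uniform":
        maf = rng.uniform(spec[1], spec[2], size=n)
    elif spec[0] == "beta":
        maf = 0.5 * rng.beta(spec[1], spec[2], size=n)
    else:  # pragma: no cover - config error
        raise ValueError(f"unknown maf spectrum: {spec!r}")
    if (maf <= 0).any() or (maf > 0.5).any():
        raise ValueError("maf spectrum must be bounded in (0, 0.5]")
    return maf


def simulate_genotypes(
    n_accessions: int,
    chrom_lengths: dict | list,
    n_snps: int,
    maf_spectrum=("uniform", 0.05, 0.5),
    inbreeding: float = 0.99,
    ld_block: int = 50_000,
    seed: int = 0,
    n_subpops: int = 1,
    fst: float = 0.0,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Inbred diploid dosages with block-local LD and optional structure.

    SNPs are placed uniformly along chromosomes (allocation proportional to
    length) and sorted. Within each ``ld_block`` window all SNPs on one
    haplotype share a latent uniform, producing strong local LD. Selfing:
    the second haplotype copies the first with probability ``inbreeding``
    (``inbreeding=1`` forces dosages into {0, 2}). With ``n_subpops > 1``
    subpopulation allele frequencies are drawn around the global MAF with a
    Balding-Nichols model at differentiation ``fst``, which creates the
    genome-wide LD and kinship structure of a structured inbred panel.
    """
    if n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    if n_snps < 0:
        raise ValueError("n_snps must be non-negative")
    if isinstance(chrom_lengths, dict):
        chrom_names = list(chrom_lengths)
        lengths = np.asarray([chrom_lengths[c] for c in chrom_names], dtype=float)
    else:
        lengths = np.asarray(chrom_lengths, dtype=float)
        chrom_names = [f"chr{i + 1}" for i in range(len(lengths))]
    if len(lengths) == 0 or (lengths <= 0).any():
        raise ValueError("chromosome lengths must be positive")

    rng = stage_rng(seed, "genotypes")
    accession_ids = np.asarray(
        [f"acc{i + 1:04d}" for i in range(n_accessions)], dtype=object
    )
    if n_snps == 0:
        return GenotypeMatrix(
            accession_ids=accession_ids,
            snp_ids=np.empty(0, object),
            chrom=np.empty(0, object),
            pos=np.empty(0, np.int64),
            dosage=np.zeros((n_accessions, 0), np.int8),
        )

    # largest-remainder allocation of SNP counts per chromosome
    share = lengths / lengths.sum() * n_snps
    counts = np.floor(share).astype(int)
    rem = n_snps - counts.sum()
    counts[np.argsort(share - np.floor(share))[::-1][:rem]] += 1

    chrom, pos = [], []
    for name, length, k in zip(chrom_names, lengths.astype(int), counts):
        if k == 0:
            continue
        p = np.array([], dtype=np.int64)
        while len(p) < k:
            p = np.unique(
                np.concatenate([p, rng.integers(1, length + 1, size=2 * k)])
            )
        p = np.sort(rng.choice(p, size=k, replace=False))
        chrom.extend([name] * k)
        pos.append(p)
    chrom = np.asarray(chrom, dtype=object)
    pos = np.concatenate(pos)

    maf = _draw_maf(rng, maf_spectrum, n_snps)
    subpop = np.arange(n_accessions) % max(n_subpops, 1)
    if n_subpops > 1 and fst > 0:
        a = maf * (1 - fst) / fst
        b = (1 - maf) * (1 - fst) / fst
        freqs = rng.beta(a, b, size=(n_subpops, n_snps))
        freqs = np.clip(freqs, 1e-4, 1 - 1e-4)
    else:
        freqs = np.tile(maf, (max(n_subpops, 1), 1))
    p_acc = freqs[subpop]  # (n_acc, n_snps)

    # shared block-level uniforms per haplotype -> comonotone copula within blocks
    block_id = np.zeros(n_snps, dtype=np.int64)
    offset = 0
    for name in chrom_names:
        m = chrom == name
        block_id[m] = offset + pos[m] // max(ld_block, 1)
        offset = block_id[m].max() + 1 if m.any() else offset
    _, block_idx = np.unique(block_id, return_inverse=True)
    n_blocks = block_idx.max() + 1

    u1 = rng.uniform(size=(n_accessions, n_blocks))[:, block_idx]
    u2 = rng.uniform(size=(n_accessions, n_blocks))[:, block_idx]
    hap1 = (u1 < p_acc).astype(np.int8)
    hap2 = (u2 < p_acc).astype(np.int8)
    selfed = rng.uniform(size=(n_accessions, 1)) < inbreeding
    hap2 = np.where(selfed, hap1, hap2)
    dosage = (hap1 + hap2).astype(np.int8)

    if missing_rate > 0:
        miss = rng.uniform(size=dosage.shape) < missing_rate
        dosage[miss] = MISSING

    return GenotypeMatrix(
        accession_ids=accession_ids,
        snp_ids=np.asarray([f"s{i + 1:06d}" for i in range(n_snps)], dtype=object),
        chrom=chrom,
        pos=pos,
        dosage=dosage,
    )


def place_genes(
    geno: GenotypeMatrix, n_genes: int, gene_length: int = 3000, seed: int = 0
) -> pd.DataFrame:
    """Place gene bodies uniformly on the genotyped chromosomes."""
    rng = stage_rng(seed, "genes")
    chroms = pd.unique(geno.chrom.astype(str))
    lengths = np.asarray(
        [int(geno.pos[geno.chrom == c].max()) for c in chroms], dtype=float
    )
    which = rng.choice(len(chroms), size=n_genes, p=lengths / lengths.sum())
    start = np.asarray(
        [rng.integers(1, max(int(lengths[w]) - gene_length, 2)) for w in which]
    )
    return pd.DataFrame(
        {
            "chrom": [chroms[w] for w in which],
            "start": start,
            "end": start + gene_length - 1,
        },
        index=[f"g{i + 1:05d}" for i in range(n_genes)],
    )


def _draw_effect(rng: np.random.Generator, spec) -> float:
    """Signed effect size; spec: ("fixed",b), ("uniform",lo,hi), ("normal",sd)."""
    sign = 1.0 if rng.uniform() < 0.5 else -1.0
    if np.isscalar(spec):
        return sign * float(spec)
    if spec[0] == "fixed":
        return sign * float(spec[1])
    if spec[0] == "uniform":
        return sign * rng.uniform(spec[1], spec[2])
    if spec[0] == "normal":
        return rng.normal(0.0, spec[1])
    raise ValueError(f"unknown effect distribution: {spec!r}")


def plant_architecture(
    geno: GenotypeMatrix,
    n_genes: int,
    gene_positions: pd.DataFrame | None = None,
    cis_fraction: float = 0.2,
    dual_fraction: float = 0.0,
    reinforce_fraction: float = 0.6,
    hotspot_spec: tuple | None = None,
    effect_dist=("uniform", 0.5, 1.5),
    seed: int = 0,
    trans_fraction: float = 0.1,
    trans_env_specific_fraction: float = 0.5,
    hotspot_environment: str = "both",
    hotspot_effect_dist=("uniform", 1.2, 1.8),
    sigma2_g_mean: float = 0.8,
    sigma2_ge_mean: float = 0.7,
    sigma2_err_mean: float = 1.8,
    env_shift_sd: float = 0.3,
    baseline_mean: float = 6.0,
    baseline_sd: float = 1.0,
) -> SimulationTruth:
    """Plant the regulatory architecture and per-transcript variance components.

    Gene modes are assigned by the requested fractions (cis-only, dual,
    trans-only, remainder null). A dual gene carries one cis SNP (within
    100 kb of its start) and one distant trans SNP; its trans partner is the
    eligible SNP whose dosage is most positively correlated with the cis SNP,
    mimicking the genetic fixation (cis-trans LD) that makes per-individual
    reinforcement/compensation calls possible. Dual effects share their sign
    with probability ``reinforce_fraction`` (reinforcing), otherwise oppose
    (compensating). ``hotspot_spec=(snp_id, n_targets)`` wires one master
    regulator to exactly ``n_targets`` genes in trans.
    """
    for frac in (cis_fraction, dual_fraction, reinforce_fraction, trans_fraction):
        if not 0 <= frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    rng = stage_rng(seed, "architecture")
    if gene_positions is None:
        gene_positions = place_genes(geno, n_genes, seed=seed)
    if len(gene_positions) != n_genes:
        raise ValueError("gene_positions length disagrees with n_genes")
    gene_ids = list(gene_positions.index)

    n_dual = int(round(dual_fraction * n_genes))
    n_cis = int(round(cis_fraction * n_genes))
    n_trans = int(round(trans_fraction * n_genes))
    if n_dual + n_cis + n_trans > n_genes:
        raise ValueError("cis/dual/trans fractions exceed 1 in total")
    order = rng.permutation(n_genes)
    mode = {g: "null" for g in gene_ids}
    for i in order[:n_dual]:
        mode[gene_ids[i]] = "dual"
    for i in order[n_dual : n_dual + n_cis]:
        mode[gene_ids[i]] = "cis-only"
    for i in order[n_dual + n_cis : n_dual + n_cis + n_trans]:
        mode[gene_ids[i]] = "trans-only"

    pos_by_chrom = {c: geno.pos[geno.chrom == c] for c in pd.unique(geno.chrom)}
    dose = geno.dosage_imputed()
    dose_c = dose - dose.mean(0)
    dose_sd = dose_c.std(0)

    def cis_candidates(g: str) -> np.ndarray:
        row = gene_positions.loc[g]
        same = geno.chrom == row["chrom"]
        return np.flatnonzero(same & (np.abs(geno.pos - row["start"]) < CIS_WINDOW))

    def trans_candidates(g: str) -> np.ndarray:
        row = gene_positions.loc[g]
        same = geno.chrom == row["chrom"]
        far = np.abs(geno.pos - row["start"]) >= TRANS_MIN_DIST
        return np.flatnonzero(~same | far)

    def trans_env(r: np.random.Generator) -> str:
        if r.uniform() < trans_env_specific_fraction:
            return "normal" if r.uniform() < 0.5 else "saline"
        return "both"

    effects: list[PlantedEffect] = []
    for g in gene_ids:
        m = mode[g]
        if m == "null":
            continue
        if m in ("cis-only", "dual"):
            cands = cis_candidates(g)
            if len(cands) == 0:
                warnings.warn(
                    f"no SNP within {CIS_WINDOW} bp of {g}; demoted to trans-only"
                )
                mode[g] = m = "trans-only"
            else:
                snp = int(rng.choice(cands))
                beta_c = _draw_effect(rng, effect_dist)
                effects.append(
                    PlantedEffect(g, str(geno.snp_ids[snp]), "cis", beta_c, "both")
                )
                if m == "dual":
                    tc = trans_candidates(g)
                    if len(tc) == 0:
                        mode[g] = "cis-only"
                        continue
                    # pick the distant SNP most positively LD-linked to the cis SNP
                    with np.errstate(invalid="ignore", divide="ignore"):
                        r = (dose_c[:, tc] * dose_c[:, [snp]]).mean(0) / (
                            dose_sd[tc] * dose_sd[snp]
                        )
                    r = np.nan_to_num(r, nan=-np.inf)
                    t_snp = int(tc[np.argmax(r)])
                    reinforcing = rng.uniform() < reinforce_fraction
                    mag = abs(_draw_effect(rng, effect_dist))
                    beta_t = mag * np.sign(beta_c) * (1 if reinforcing else -1)
                    effects.append(
                        PlantedEffect(
                            g, str(geno.snp_ids[t_snp]), "trans", float(beta_t), "both"
                        )
                    )
                    mode[g] = "dual-reinforcing" if reinforcing else "dual-compensating"
        if mode[g] == "trans-only":
            tc = trans_candidates(g)
            if len(tc) == 0:
                mode[g] = "null"
                continue
            snp = int(rng.choice(tc))
            effects.append(
                PlantedEffect(
                    g,
                    str(geno.snp_ids[snp]),
                    "trans",
                    _draw_effect(rng, effect_dist),
                    trans_env(rng),
                )
            )

    hotspot_snp = None
    if hotspot_spec is not None:
        hotspot_snp, n_targets = hotspot_spec
        if hotspot_snp not in set(geno.snp_ids):
            raise ValueError(f"hotspot SNP {hotspot_snp} not in genotypes")
        h_idx = geno.snp_index(hotspot_snp)
        eligible = []
        for g in gene_ids:
            row = gene_positions.loc[g]
            if geno.chrom[h_idx] != row["chrom"] or (
                abs(int(geno.pos[h_idx]) - int(row["start"])) >= TRANS_MIN_DIST
            ):
                if mode[g] in ("null", "trans-only"):
                    eligible.append(g)
        if len(eligible) < n_targets:
            raise ValueError("not enough eligible genes for the hotspot target count")
        targets = rng.choice(np.asarray(eligible, object), n_targets, replace=False)
        for g in targets:
            effects.append(
                PlantedEffect(
                    str(g),
                    str(hotspot_snp),
                    "trans",
                    _draw_effect(rng, hotspot_effect_dist),
                    hotspot_environment,
                )
            )
            if mode[str(g)] == "null":
                mode[str(g)] = "trans-only"

    shape = 4.0  # gamma shape for per-transcript variance heterogeneity
    return SimulationTruth(
        gene_ids=gene_ids,
        mode=mode,
        effects=effects,
        sigma2_g=rng.gamma(shape, sigma2_g_mean / shape, n_genes),
        sigma2_ge=rng.gamma(shape, sigma2_ge_mean / shape, n_genes),
        sigma2_err=rng.gamma(shape, sigma2_err_mean / shape, n_genes),
        env_shift=rng.normal(0.0, env_shift_sd, n_genes),
        baseline=rng.normal(baseline_mean, baseline_sd, n_genes),
        hotspot_snp=hotspot_snp,
        seed=seed,
    )


def simulate_expression(
    geno: GenotypeMatrix,
    truth: SimulationTruth,
    gene_positions: pd.DataFrame,
    design: tuple = (ENVIRONMENTS, 3, 3),
    seed: int = 0,
    sigma2_block: float = 0.1,
) -> ExpressionMatrix:
    """Plant-level expression from the planted architecture.

    value = baseline + sum(beta * dosage, over effects active in the plant's
    environment) + accession effect N(0, sigma2_g) + environment shift
    + accession-x-environment effect N(0, sigma2_ge) + block effect
    + residual N(0, sigma2_err), floored at 0 (log2(x+1) scale).
    """
    environments, n_rep, n_blocks = design
    for arr in (truth.sigma2_g, truth.sigma2_ge, truth.sigma2_err):
        if (np.asarray(arr) < 0).any():
            raise ValueError("variance components must be non-negative")
    known = set(geno.snp_ids)
    for e in truth.effects:
        if e.snp not in known:
            raise ValueError(f"truth references unknown SNP {e.snp}")

    rng = stage_rng(seed if truth.seed is None else truth.seed, "expression")
    n_acc, n_genes = geno.n_accessions, len(truth.gene_ids)
    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    dose = geno.dosage_imputed()

    # genetic signal per accession x gene, per environment
    env_signal = {}
    a_g = rng.normal(0.0, np.sqrt(truth.sigma2_g), size=(n_acc, n_genes))
    for env in environments:
        sig = truth.baseline[None, :] + a_g.copy()
        if env == "saline":
            sig = sig + truth.env_shift[None, :]
        sig += rng.normal(0.0, np.sqrt(truth.sigma2_ge), size=(n_acc, n_genes))
        env_signal[env] = sig
    for e in truth.effects:
        j = gene_index[e.gene]
        x = dose[:, geno.snp_index(e.snp)]
        for env in environments:
            if e.environment in ("both", env):
                env_signal[env][:, j] += e.beta * x

    block_eff = rng.normal(
        0.0, np.sqrt(sigma2_block), size=(len(environments), n_blocks, n_genes)
    )

    plant_ids, accession, environment, block, rows = [], [], [], [], []
    for ei, env in enumerate(environments):
        for rep in range(n_rep):
            b = rep % n_blocks + 1
            noise = rng.normal(
                0.0, np.sqrt(truth.sigma2_err), size=(n_acc, n_genes)
            )
            rows.append(env_signal[env] + block_eff[ei, b - 1][None, :] + noise)
            for a in geno.accession_ids:
                plant_ids.append(f"{a}_{env}_r{rep + 1}")
                accession.append(a)
                environment.append(env)
                block.append(b)

    values = np.clip(np.concatenate(rows, axis=0), 0.0, None)
    gp = gene_positions.loc[truth.gene_ids]
    return ExpressionMatrix(
        plant_ids=np.asarray(plant_ids, object),
        accession=np.asarray(accession, object),
        environment=np.asarray(environment, object),
        block=np.asarray(block, np.int64),
        transcript_ids=np.asarray(truth.gene_ids, object),
        values=values,
        gene_chrom=gp["chrom"].to_numpy(object),
        gene_start=gp["start"].to_numpy(np.int64),
        gene_end=gp["end"].to_numpy(np.int64),
    )


def simulate_fitness(
    expr: ExpressionMatrix,
    selection_truth: dict | None = None,
    base_fecundity=None,
    noise_sd: float = 0.3,
    zero_rate: float = 0.05,
    seed: int = 0,
) -> FitnessTable:
    """Fecundity with planted linear/quadratic selection on chosen transcripts.

    ``selection_truth`` maps environment -> {transcript: (S_true, C_true)};
    relative fitness is built on within-environment standardized expression z
    as w = 1 + sum(S * z) + sum((C / 2) * (z^2 - 1)) + noise (the quadratic
    term is mean-centered so planted coefficients sit on the relative-fitness
    scale), then scaled to integer grain counts and floored at 0. An extra
    ``zero_rate`` fraction of plants is set to zero fecundity (plants that
    set no filled grain at all, common under stress).
    """
    selection_truth = selection_truth or {}
    if base_fecundity is None:
        base_fecundity = {"normal": 150.0, "saline": 100.0}
    if np.isscalar(base_fecundity):
        base_fecundity = {e: float(base_fecundity) for e in ENVIRONMENTS}
    rng = stage_rng(seed, "fitness")
    tr_index = {t: i for i, t in enumerate(expr.transcript_ids)}

    fecundity = np.zeros(expr.n_plants, dtype=np.int64)
    for env in pd.unique(expr.environment):
        mask = expr.env_mask(env)
        n_env = int(mask.sum())
        w = np.ones(n_env)
        for transcript, (s_true, c_true) in selection_truth.get(env, {}).items():
            if transcript not in tr_index:
                raise ValueError(f"unknown transcript in selection truth: {transcript}")
            x = expr.values[mask, tr_index[transcript]]
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError(f"constant transcript {transcript} cannot be selected")
            z = (x - x.mean()) / sd
            w += s_true * z + (c_true / 2.0) * (z**2 - 1.0)
        w += rng.normal(0.0, noise_sd, n_env)
        counts = np.round(base_fecundity[env] * np.clip(w, 0.0, None))
        if zero_rate > 0:
            counts[rng.uniform(size=n_env) < zero_rate] = 0
        if counts.mean() <= 0:
            raise ValueError("configuration yields non-positive mean fecundity")
        fecundity[mask] = counts.astype(np.int64)

    return FitnessTable(
        plant_ids=expr.plant_ids.copy(),
        fecundity=fecundity,
        environment=expr.environment.copy(),
        block=expr.block.copy(),
    )


def simulate_annotations(
    transcript_ids, n_terms: int, size_dist=25, seed: int = 0
) -> dict:
    """GO-style term -> transcript map; overlapping terms, unique members."""
    transcript_ids = np.asarray(transcript_ids, dtype=object)
    rng = stage_rng(seed, "annotations")
    if np.isscalar(size_dist):
        sizes = np.full(n_terms, int(size_dist))
    elif size_dist[0] == "uniform":
        sizes = rng.integers(size_dist[1], size_dist[2] + 1, size=n_terms)
    else:
        raise ValueError(f"unknown size distribution: {size_dist!r}")
    if (sizes < 1).any():
        raise ValueError("term sizes must be >= 1")
    if (sizes > len(transcript_ids)).any():
        raise ValueError("term size exceeds transcript count")
    return {
        f"TERM:{i + 1:04d}": sorted(
            rng.choice(transcript_ids, size=int(sizes[i]), replace=False)
        )
        for i in range(n_terms)
    }
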