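"""Core in-memory containers shared across the pipeline.

All genomic coordinates are 1-based inclusive (VCF convention). Genotypes are
stored as minor-allele dosages in {0, 1, 2} with -1 marking a missing call;
the accessions are highly inbred, so heterozygotes (dosage 1) are rare by
construction and capped by the hard filters downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

MISSING = -1

Environment = Literal["normal", "saline"]
ENVIRONMENTS: tuple[str, str] = ("normal", "saline")


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic SNPs, minor-allele dosage coding."""

    accession_ids: np.ndarray  # (n_acc,) str
    snp_ids: np.ndarray  # (n_snps,) str
    chrom: np.ndarray  # (n_snps,) str
    pos: np.ndarray  # (n_snps,) int, 1-based
    dosage: np.ndarray  # (n_acc, n_snps) int8, -1 = missing

    def __post_init__(self) -> None:
        self.accession_ids = np.asarray(self.accession_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.accession_ids), len(self.snp_ids)):
            raise ValueError("dosage shape does not match accession/snp ids")
        valid = np.isin(self.dosage, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("dosage values must be in {0,1,2} or -1 (missing)")
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def allele_frequency(self) -> np.ndarray:
        """Per-SNP frequency of the dosage-counted allele among non-missing calls."""
        d = self.dosage.astype(float)
        d[d == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def het_fraction(self) -> np.ndarray:
        ok = self.dosage != MISSING
        with np.errstate(invalid="ignore"):
            return (self.dosage == 1).sum(0) / np.maximum(ok.sum(0), 1)

    def missing_fraction(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(0)

    def dosage_imputed(self) -> np.ndarray:
        """Float dosage with missing calls replaced by the per-SNP mean."""
        d = self.dosage.astype(float)
        d[d == MISSING] = np.nan
        col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(d))
        d[idx] = col_mean[idx[1]]
        return d

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            accession_ids=self.accession_ids,
            snp_ids=self.snp_ids[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            dosage=self.dosage[:, index],
        )

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if len(hits) == 0:
            raise KeyError(f"unknown SNP id: {snp_id}")
        return int(hits[0])


@dataclass
class ExpressionMatrix:
    """Plant-level log2 expression with accession/environment/block metadata.

    ``values`` is plants x transcripts on the non-negative
    log2(normalized count + 1) scale.
    """

    plant_ids: np.ndarray
    accession: np.ndarray  # accession id per plant
    environment: np.ndarray  # per plant, in ENVIRONMENTS
    block: np.ndarray  # per plant, small int
    transcript_ids: np.ndarray
    values: np.ndarray  # (n_plants, n_transcripts) float
    gene_chrom: np.ndarray | None = None
    gene_start: np.ndarray | None = None
    gene_end: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.plant_ids = np.asarray(self.plant_ids, dtype=object)
        self.accession = np.asarray(self.accession, dtype=object)
        self.environment = np.asarray(self.environment, dtype=object)
        self.block = np.asarray(self.block, dtype=np.int64)
        self.transcript_ids = np.asarray(self.transcript_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.plant_ids), len(self.transcript_ids)):
            raise ValueError("values shape does not match plant/transcript ids")
        if (self.values < 0).any():
            raise ValueError("expression values must be >= 0 (log2(x+1) scale)")

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def env_mask(self, environment: str) -> np.ndarray:
        return self.environment == environment

    def subset_plants(self, mask: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            plant_ids=self.plant_ids[mask],
            accession=self.accession[mask],
            environment=self.environment[mask],
            block=self.block[mask],
            transcript_ids=self.transcript_ids,
            values=self.values[mask],
            gene_chrom=self.gene_chrom,
            gene_start=self.gene_start,
            gene_end=self.gene_end,
        )

    def subset_transcripts(self, index: np.ndarray) -> "ExpressionMatrix":
        sub = lambda a: None if a is None else a[index]
        return ExpressionMatrix(
            plant_ids=self.plant_ids,
            accession=self.accession,
            environment=self.environment,
            block=self.block,
            transcript_ids=self.transcript_ids[index],
            values=self.values[:, index],
            gene_chrom=sub(self.gene_chrom),
            gene_start=sub(self.gene_start),
            gene_end=sub(self.gene_end),
        )

    def accession_means(self, environment: str) -> pd.DataFrame:
        """Replicate-mean expression per accession within one environment."""
        mask = self.env_mask(environment)
        df = pd.DataFrame(self.values[mask], columns=self.transcript_ids)
        df["__acc"] = self.accession[mask]
        return df.groupby("__acc", sort=True).mean()

    def gene_positions(self) -> pd.DataFrame:
        if self.gene_chrom is None:
            raise ValueError("expression matrix carries no gene positions")
        return pd.DataFrame(
            {
                "gene": self.transcript_ids,
                "chrom": self.gene_chrom,
                "start": self.gene_start,
                "end": self.gene_end,
            }
        ).set_index("gene")


@dataclass
class FitnessTable:
    """Per-plant fecundity (filled-grain count, non-negative integer)."""

    plant_ids: np.ndarray
    fecundity: np.ndarray
    environment: np.ndarray
    block: np.ndarray

    def __post_init__(self) -> None:
        self.plant_ids = np.asarray(self.plant_ids, dtype=object)
        self.fecundity = np.asarray(self.fecundity, dtype=np.int64)
        self.environment = np.asarray(self.environment, dtype=object)
        self.block = np.asarray(self.block, dtype=np.int64)
        if (self.fecundity < 0).any():
            raise ValueError("fecundity must be non-negative")
        if len(np.unique(self.plant_ids.astype(str))) != len(self.plant_ids):
            raise ValueError("duplicate plant ids in fitness table")

    def aligned_to(self, plant_ids: np.ndarray) -> np.ndarray:
        """Fecundity reordered to match an external plant-id order."""
        lookup = {p: w for p, w in zip(self.plant_ids, self.fecundity)}
        return np.array([lookup[p] for p in plant_ids], dtype=np.int64)


@dataclass
class PlantedEffect:
    """One planted eQTL effect on one gene."""

    gene: str
    snp: str
    kind: Literal["cis", "trans"]
    beta: float  # log2-expression units per dosage unit
    environment: Literal["both", "normal", "saline"] = "both"


@dataclass
class SimulationTruth:
    """Everything needed to check parameter recovery, closed over the seed."""

    gene_ids: list
    mode: dict  # gene -> cis-only|trans-only|dual-reinforcing|dual-compensating|null
    effects: list  # list[PlantedEffect]
    sigma2_g: np.ndarray
    sigma2_ge: np.ndarray
    sigma2_err: np.ndarray
    env_shift: np.ndarray
    baseline: np.ndarray
    selection: dict = field(default_factory=dict)  # env -> {gene: (S_true, C_true)}
    hotspot_snp: str | None = None
    seed: int | None = None

    def cis_effects(self) -> list:
        return [e for e in self.effects if e.kind == "cis"]

    def trans_effects(self) -> list:
        return [e for e in self.effects if e.kind == "trans"]

    def effects_for_gene(self, gene: str) -> list:
        return [e for e in self.effects if e.gene == gene]

    def to_dict(self) -> dict:
        return {
            "gene_ids": [str(g) for g in self.gene_ids],
            "mode": {str(k): v for k, v in self.mode.items()},
            "effects": [dataclasses.asdict(e) for e in self.effects],
            "sigma2_g": list(map(float, self.sigma2_g)),
            "sigma2_ge": list(map(float, self.sigma2_ge)),
            "sigma2_err": list(map(float, self.sigma2_err)),
            "env_shift": list(map(float, self.env_shift)),
            "baseline": list(map(float, self.baseline)),
            "selection": {
                env: {str(g): [float(s), float(c)] for g, (s, c) in d.items()}
                for env, d in self.selection.items()
            },
            "hotspot_snp": self.hotspot_snp,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        return cls(
            gene_ids=list(d["gene_ids"]),
            mode=dict(d["mode"]),
            effects=[PlantedEffect(**e) for e in d["effects"]],
            sigma2_g=np.asarray(d["sigma2_g"], float),
            sigma2_ge=np.asarray(d["sigma2_ge"], float),
            sigma2_err=np.asarray(d["sigma2_err"], float),
            env_shift=np.asarray(d["env_shift"], float),
            baseline=np.asarray(d["baseline"], float),
            selection={
                env: {g: (s, c) for g, (s, c) in dd.items()}
                for env, dd in d.get("selection", {}).items()
            },
            hotspot_snp=d.get("hotspot_snp"),
            seed=d.get("seed"),
        )
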