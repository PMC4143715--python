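"""Synthetic family data: pedigrees, gene-dropped genotypes, and
longitudinal blood-pressure-like phenotypes.

The generator emulates the structure of a pedigree-based longitudinal
GWAS panel: a few hundred families measured at three exam waves for a
quantitative trait (systolic or diastolic blood pressure) with age,
sex, smoking and medication covariates; a dense SNP panel containing
one planted causal variant (default MAF 0.367, matching the MAP4
variant rs6442089 on chromosome 3); and replicate phenotype simulations
over one fixed genotype set.

Generative model per replicate, for individual (i, j) at wave t:

    y_ijt = b0 + b_age*age_ijt + b_male*male + b_smoke*smoke_ijt
            + b_med*med_ijt + v*z_t + gamma*SNP_causal
            + G_ij + s_ij*(z_t - z_bar) + eps_ijt

with G ~ MVN(0, 2*Phi*sigma_g2) over the pedigree, subject-specific
time slopes s_ij ~ N(0, slope_sd^2) centered at the mid-study wave
(they perturb single-wave measurements but average out of a subject's
mean — the mechanism by which traits with volatile trajectories reward
longitudinal analysis), and iid residuals eps ~ N(0, sigma_e2).
Covariate trajectories are drawn once per configuration and held fixed
across replicates, mirroring designs in which real covariates are
paired with repeatedly simulated phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genotype import GenotypeMatrix
from .pedigree import Member, Pedigree, kinship_matrix, relationship_matrix

DEFAULT_SEED = 20180818

FAMILY_STRUCTURES = ("trio", "nuclear", "three_generation")


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Variances are in squared phenotype units (mmHg^2); effects in mmHg
    (per allele copy for ``causal_effect``, per unit time score for
    ``time_effect`` and ``slope_sd``, per year for the age effect).
    """

    n_families: int = 200
    family_structure: str = "trio"
    n_offspring: int = 2              # nuclear families only
    n_snps: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.5
    causal_maf: float | None = 0.367
    causal_snp_id: str = "rs6442089"
    causal_position: int = 47_956_424
    causal_effect: float = 4.0
    sigma_g2: float = 20.0
    sigma_e2: float = 10.0
    slope_sd: float = 0.0
    time_effect: float = 1.5
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.4, "male": 3.0, "smoke": 2.5, "med": -6.0}
    )
    intercept: float = 120.0
    n_timepoints: int = 3
    missing_genotype_rate: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.family_structure not in FAMILY_STRUCTURES:
            raise ValueError(
                f"family_structure must be one of {FAMILY_STRUCTURES}"
            )
        if self.sigma_g2 < 0 or self.sigma_e2 < 0 or self.slope_sd < 0:
            raise ValueError("variance parameters must be nonnegative")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("MAF bounds must satisfy 0 < low <= high <= 0.5")
        if self.causal_maf is not None and not (0.0 < self.causal_maf <= 0.5):
            raise ValueError("causal MAF must lie in (0, 0.5]")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if not (0.0 <= self.missing_genotype_rate < 1.0):
            raise ValueError("missing_genotype_rate must lie in [0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def preset(name: str, **overrides) -> SimulationConfig:
    """Named study conditions.

    ``sbp-like``: stable within-subject trajectories (small slope_sd);
    ``dbp-like``: volatile subject-specific slopes (large slope_sd),
    the regime in which longitudinal analysis is expected to win;
    ``null``: no causal effect, for type-I-error calibration.
    """
    base = {
        "sbp-like": dict(slope_sd=0.5, intercept=120.0),
        "dbp-like": dict(slope_sd=4.0, intercept=80.0),
        "null": dict(slope_sd=0.5, intercept=120.0, causal_effect=0.0),
    }
    if name not in base:
        raise ValueError(f"unknown preset {name!r}; expected one of {sorted(base)}")
    kw = dict(base[name])
    kw.update(overrides)
    return SimulationConfig(**kw)


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Deterministic family structures: trio, nuclear (2 parents +
    ``n_offspring``), or three-generation (grandparents, one parent with
    a married-in spouse, two grandchildren)."""
    members: list[Member] = []
    for i in range(1, cfg.n_families + 1):
        fid = f"F{i}"
        if cfg.family_structure == "trio":
            members += [
                Member(fid, f"{fid}_1", None, None, "male"),
                Member(fid, f"{fid}_2", None, None, "female"),
                Member(fid, f"{fid}_3", f"{fid}_1", f"{fid}_2",
                       "male" if i % 2 else "female"),
            ]
        elif cfg.family_structure == "nuclear":
            members += [
                Member(fid, f"{fid}_1", None, None, "male"),
                Member(fid, f"{fid}_2", None, None, "female"),
            ]
            for k in range(cfg.n_offspring):
                members.append(
                    Member(fid, f"{fid}_{3 + k}", f"{fid}_1", f"{fid}_2",
                           "male" if k % 2 else "female")
                )
        else:  # three_generation
            members += [
                Member(fid, f"{fid}_1", None, None, "male"),
                Member(fid, f"{fid}_2", None, None, "female"),
                Member(fid, f"{fid}_3", f"{fid}_1", f"{fid}_2", "male"),
                Member(fid, f"{fid}_4", None, None, "female"),
                Member(fid, f"{fid}_5", f"{fid}_3", f"{fid}_4", "female"),
                Member(fid, f"{fid}_6", f"{fid}_3", f"{fid}_4", "male"),
            ]
    return Pedigree(members)


def gene_drop(ped: Pedigree, cfg: SimulationConfig, seed: int | None = None) -> GenotypeMatrix:
    """Gene-dropping genotype simulation over a pedigree.

    Founder alleles are Bernoulli draws at each SNP's allele frequency;
    non-founders receive one allele from each parent, chosen uniformly
    (Mendelian transmission).  Missing calls are masked after
    transmission at ``missing_genotype_rate``.  The counted allele of
    every SNP is the variant allele whose population frequency is the
    configured MAF.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    m = cfg.n_snps
    mafs = rng.uniform(cfg.maf_low, cfg.maf_high, m)
    causal_idx = m // 2
    if cfg.causal_maf is not None:
        mafs[causal_idx] = cfg.causal_maf
    n = len(ped)
    alleles = np.empty((n, m, 2), dtype=np.int8)
    idx = ped.id_index
    for k, member in enumerate(ped.members):
        if member.is_founder:
            alleles[k] = rng.random((m, 2)) < mafs[:, None]
        else:
            f, mo = idx[member.father], idx[member.mother]
            pick_f = rng.integers(0, 2, m)
            pick_m = rng.integers(0, 2, m)
            cols = np.arange(m)
            alleles[k, :, 0] = alleles[f, cols, pick_f]
            alleles[k, :, 1] = alleles[mo, cols, pick_m]
    dosage = alleles.sum(axis=2).astype(float)
    if cfg.missing_genotype_rate > 0:
        dosage[rng.random((n, m)) < cfg.missing_genotype_rate] = np.nan

    snp_ids = [f"snp{j + 1:05d}" for j in range(m)]
    if cfg.causal_maf is not None:
        snp_ids[causal_idx] = cfg.causal_snp_id
    positions = cfg.causal_position + (np.arange(m) - causal_idx) * 1000
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "3",
            "position": positions,
            "a1": "A",
            "a2": "G",
        }
    )
    g = GenotypeMatrix(sample_ids=ped.ids, snps=snps, dosage=dosage)
    g.snps.attrs["maf"] = mafs
    return g


def _simulate_covariates(ped: Pedigree, cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Fixed covariate trajectories: ages by generation advancing 5 years
    per wave; persistent smoking states; near-absorbing medication use."""
    n = len(ped)
    T = cfg.n_timepoints
    depth = ped.generation_depth()
    age1 = np.clip(rng.normal(58.0 - 20.0 * depth, 6.0), 16.0, None)
    male = np.array([1 if m.sex == "male" else 0 for m in ped.members])
    smoke = np.empty((n, T), dtype=int)
    med = np.empty((n, T), dtype=int)
    smoke[:, 0] = rng.random(n) < 0.25
    med[:, 0] = rng.random(n) < 0.15
    for t in range(1, T):
        switch = rng.random(n) < 0.10
        smoke[:, t] = np.where(switch, 1 - smoke[:, t - 1], smoke[:, t - 1])
        start = rng.random(n) < 0.10
        med[:, t] = np.where(med[:, t - 1] == 1, 1, start.astype(int))
    rows = []
    for t in range(T):
        rows.append(
            pd.DataFrame(
                {
                    "IID": ped.ids,
                    "TIME": t + 1,
                    "AGE": age1 + 5.0 * t,
                    "SEX": np.where(male == 1, 1, 2),
                    "SMOKE": smoke[:, t],
                    "MED": med[:, t],
                }
            )
        )
    return pd.concat(rows, ignore_index=True).sort_values(["IID", "TIME"], kind="stable").reset_index(drop=True)


def simulate_phenotypes(
    ped: Pedigree,
    g: GenotypeMatrix,
    cfg: SimulationConfig,
    n_replicates: int = 1,
    seed: int | None = None,
) -> list[pd.DataFrame]:
    """Replicate phenotype simulations over fixed genotypes.

    Returns ``n_replicates`` long-format phenotype tables sharing one
    covariate draw; each table's ``attrs`` record the replicate index
    and its derived random seed.  Replicate r uses the child stream
    ``SeedSequence(master, spawn_key=(r + 1,))`` so any single replicate
    can be replayed in isolation.
    """
    master = cfg.seed if seed is None else seed
    cov_rng = np.random.default_rng(np.random.SeedSequence(master, spawn_key=(0,)))
    cov = _simulate_covariates(ped, cfg, cov_rng)

    ids = ped.ids
    n = len(ids)
    T = cfg.n_timepoints
    # factor of A = 2*Phi for sampling the polygenic vector
    A = relationship_matrix(kinship_matrix(ped))
    evals, evecs = np.linalg.eigh(A)
    Lfac = evecs * np.sqrt(np.clip(evals, 0.0, None))

    causal = np.zeros(n)
    if cfg.causal_maf is not None and cfg.causal_effect != 0.0:
        j = g.snp_index(cfg.causal_snp_id)
        row = {s: i for i, s in enumerate(g.sample_ids)}
        dos = g.dosage[[row[i] for i in ids], j]
        expect = 2.0 * cfg.causal_maf
        causal = np.where(np.isnan(dos), expect, dos)

    z = np.arange(1, T + 1, dtype=float)
    zc = z - z.mean()
    eff = cfg.covariate_effects
    base = (
        cfg.intercept
        + eff.get("age", 0.0) * cov["AGE"].to_numpy()
        + eff.get("male", 0.0) * (cov["SEX"].to_numpy() == 1)
        + eff.get("smoke", 0.0) * cov["SMOKE"].to_numpy()
        + eff.get("med", 0.0) * cov["MED"].to_numpy()
        + cfg.time_effect * cov["TIME"].to_numpy()
    )
    iid_pos = {iid: k for k, iid in enumerate(ids)}
    row_ind = np.array([iid_pos[i] for i in cov["IID"]])
    row_zc = zc[cov["TIME"].to_numpy() - 1]

    tables: list[pd.DataFrame] = []
    for r in range(n_replicates):
        ss = np.random.SeedSequence(master, spawn_key=(r + 1,))
        rng = np.random.default_rng(ss)
        G = np.sqrt(cfg.sigma_g2) * (Lfac @ rng.standard_normal(n))
        s = rng.normal(0.0, cfg.slope_sd, n) if cfg.slope_sd > 0 else np.zeros(n)
        eps = rng.normal(0.0, np.sqrt(cfg.sigma_e2), len(cov))
        y = (
            base
            + cfg.causal_effect * causal[row_ind]
            + G[row_ind]
            + s[row_ind] * row_zc
            + eps
        )
        tbl = cov.copy()
        tbl.insert(2, "PHENO", y)
        tbl.attrs["replicate"] = r
        tbl.attrs["replicate_seed"] = int(ss.generate_state(1)[0])
        tables.append(tbl)
    return tables


def simulate_dataset(
    cfg: SimulationConfig, n_replicates: int = 1, seed: int | None = None
) -> tuple[Pedigree, GenotypeMatrix, list[pd.DataFrame]]:
    """Convenience wrapper: pedigree + gene-dropped genotypes + replicate
    phenotype tables, all from one configuration."""
    ped = simulate_pedigree(cfg)
    g = gene_drop(ped, cfg, seed=seed)
    tables = simulate_phenotypes(ped, g, cfg, n_replicates=n_replicates, seed=seed)
    return ped, g, tables
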