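"""Stage 2: residual-on-SNP association scans (GRAMMAR step).

Each SNP is tested by ordinary least squares of the stage-1 conditional
residuals (per-individual; mean over time points in the longitudinal
modes) on an intercept plus the minor-allele dosage, with a two-sided p
value from the t distribution on n_used - 2 degrees of freedom.  SNPs
are ranked by ascending p value, ties broken by genomic position then
identifier.  Missing dosages are handled per SNP by complete-case
analysis; a SNP whose dosage is constant among the complete cases (or
with fewer than 3 of them) is untestable and carries no rank.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import build_design
from .genotype import GenotypeMatrix, apply_qc
from .lmm import PolygenicLMM, PolygenicLMMResults, eig_structure, reml_fit_rotated
from .pedigree import Pedigree, KinshipMatrix, kinship_matrix, relationship_matrix

logger = logging.getLogger(__name__)

_TINY_RSS = 1e-24
_MIN_VAR = 1e-12

SnpRegression = namedtuple("SnpRegression", "beta se t p n_used intercept")


def snp_regression(residuals, dosages) -> SnpRegression:
    """Simple linear regression of residuals on one SNP's dosages.

    Complete cases only; returns NaN statistics when fewer than 3
    complete pairs remain or the dosage is constant among them.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    d = np.asarray(dosages, dtype=float).ravel()
    if r.shape != d.shape:
        raise ValueError("residuals and dosages differ in length")
    ok = ~(np.isnan(r) | np.isnan(d))
    r, d = r[ok], d[ok]
    n = r.size
    if n < 3 or np.ptp(d) == 0:
        return SnpRegression(np.nan, np.nan, np.nan, np.nan, int(n), np.nan)
    sxx = float(np.sum((d - d.mean()) ** 2))
    sxy = float(np.sum((d - d.mean()) * (r - r.mean())))
    beta = sxy / sxx
    intercept = float(r.mean() - beta * d.mean())
    rss = max(float(np.sum((r - intercept - beta * d) ** 2)), _TINY_RSS)
    se = np.sqrt(rss / (n - 2) / sxx)
    t = beta / se
    p = float(np.clip(2.0 * stats.t.sf(abs(t), n - 2), np.finfo(float).tiny, 1.0))
    return SnpRegression(float(beta), float(se), float(t), p, int(n), intercept)


@dataclass
class _ScanCache:
    """Dosage sufficient statistics reused across phenotype replicates."""

    sample_order: list[str]
    D0: np.ndarray         # dosages with missing set to 0
    mask: np.ndarray       # non-missing indicator
    n_used: np.ndarray
    sx: np.ndarray
    sxx_c: np.ndarray      # centered sum of squares per SNP


def _build_scan_cache(g: GenotypeMatrix, sample_order: list[str]) -> _ScanCache:
    row = {s: i for i, s in enumerate(g.sample_ids)}
    take = [row[s] for s in sample_order]
    D = g.dosage[take]
    mask = ~np.isnan(D)
    D0 = np.where(mask, D, 0.0)
    n_used = mask.sum(axis=0).astype(float)
    sx = D0.sum(axis=0)
    sxx = (D0 * D0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sxx_c = sxx - sx * sx / n_used
    return _ScanCache(sample_order, D0, mask, n_used, sx, sxx_c)


def _bulk_regression(r: np.ndarray, cache: _ScanCache) -> pd.DataFrame:
    n_used = cache.n_used
    sy = r @ cache.mask
    syy = (r * r) @ cache.mask
    sxy = r @ cache.D0
    with np.errstate(invalid="ignore", divide="ignore"):
        sxy_c = sxy - cache.sx * sy / n_used
        syy_c = syy - sy * sy / n_used
        testable = (n_used >= 3) & (cache.sxx_c > _MIN_VAR)
        beta = np.where(testable, sxy_c / np.where(testable, cache.sxx_c, 1.0), np.nan)
        rss = np.clip(syy_c - beta * sxy_c, _TINY_RSS, None)
        dfree = n_used - 2
        se = np.sqrt(rss / dfree / np.where(testable, cache.sxx_c, 1.0))
        t = beta / se
        p = np.clip(2.0 * stats.t.sf(np.abs(t), dfree), np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "N": n_used.astype(int),
            "BETA": np.where(testable, beta, np.nan),
            "SE": np.where(testable, se, np.nan),
            "T": np.where(testable, t, np.nan),
            "P": np.where(testable, p, np.nan),
        }
    )
    return out


@dataclass
class ScanResult:
    """Per-SNP stage-2 regression results with ranks.

    ``table`` columns: SNP, POS, N, BETA, SE, T, P, RANK (RANK is a
    nullable integer; untestable SNPs carry missing P and no rank).
    """

    table: pd.DataFrame
    mode: str | None = None
    stage1: PolygenicLMMResults | None = None

    def rank_of(self, snp_id: str) -> int | None:
        row = self.table.loc[self.table["SNP"] == snp_id, "RANK"]
        if row.empty or pd.isna(row.iloc[0]):
            return None
        return int(row.iloc[0])

    def p_of(self, snp_id: str) -> float:
        row = self.table.loc[self.table["SNP"] == snp_id, "P"]
        return float(row.iloc[0]) if not row.empty else np.nan

    def write(self, path, sep: str = "\t") -> None:
        cols = ["SNP", "N", "BETA", "SE", "T", "P", "RANK"]
        self.table[cols].to_csv(path, sep=sep, index=False, na_rep="NA")


def rank_snps(table: pd.DataFrame) -> pd.DataFrame:
    """Assign ranks 1..k by ascending p value over testable SNPs.

    Ties are broken by ascending genomic position (POS column, when
    present), then lexicographic SNP id — deterministic by construction.
    """
    out = table.copy()
    testable = out["P"].notna()
    if not testable.any():
        logger.warning("no testable SNPs; empty ranking")
        out["RANK"] = pd.array([pd.NA] * len(out), dtype="Int64")
        return out
    sub = out.loc[testable]
    pos = sub["POS"] if "POS" in sub.columns else pd.Series(0, index=sub.index)
    order = np.lexsort(
        (sub["SNP"].astype(str).to_numpy(), pos.to_numpy(), sub["P"].to_numpy())
    )
    ranked_idx = sub.index.to_numpy()[order]
    pos_in_out = out.index.get_indexer(ranked_idx)
    ranks = np.full(len(out), -1, dtype=int)
    ranks[pos_in_out] = np.arange(1, len(ranked_idx) + 1)
    out["RANK"] = pd.array(
        [r if r > 0 else pd.NA for r in ranks], dtype="Int64"
    )
    return out


def scan_snps(
    residuals: pd.Series,
    genotypes: GenotypeMatrix,
    mode: str | None = None,
    stage1: PolygenicLMMResults | None = None,
) -> ScanResult:
    """Regress per-individual residuals on every SNP and rank the results.

    ``residuals`` is indexed by IID; only individuals present in both
    the residual vector and the genotype matrix are used.
    """
    have = set(genotypes.sample_ids)
    order = [s for s in residuals.index if s in have]
    cache = _build_scan_cache(genotypes, order)
    r = residuals.loc[order].to_numpy(dtype=float)
    stats_df = _bulk_regression(r, cache)
    table = pd.concat(
        [
            pd.DataFrame(
                {
                    "SNP": genotypes.snps["snp_id"],
                    "POS": genotypes.snps["position"],
                }
            ),
            stats_df,
        ],
        axis=1,
    )
    return ScanResult(table=rank_snps(table), mode=mode, stage1=stage1)


class PipelineRunner:
    """Run one analysis mode repeatedly over phenotype replicates.

    The pedigree, genotypes and covariate structure are fixed across
    replicates (only the phenotype column changes), so the relationship
    eigendecomposition and per-SNP dosage statistics are computed once
    and reused; each replicate costs one rotation, one 1-D REML search
    and one vectorized scan.
    """

    def __init__(
        self,
        pedigree: Pedigree,
        genotypes: GenotypeMatrix,
        mode: str,
        kinship: KinshipMatrix | None = None,
    ):
        self.pedigree = pedigree
        self.genotypes = genotypes
        self.mode = mode
        self.kinship = kinship if kinship is not None else kinship_matrix(pedigree)
        self._prepared = False

    def _prepare(self, pheno: pd.DataFrame) -> None:
        known = set(self.kinship.ids)
        geno = set(self.genotypes.sample_ids)
        pheno_ids = set(pheno["IID"].astype(str))
        orphans = sorted((pheno_ids - known) | (pheno_ids - geno))
        if orphans:
            raise ValueError(
                f"{len(orphans)} phenotyped individual(s) missing from the "
                f"pedigree or genotype matrix: {orphans[:5]}"
            )
        ids = [i for i in self.kinship.ids if i in geno]
        dm = build_design(pheno, self.mode, ids=ids)
        self._dm = dm
        self._A = relationship_matrix(self.kinship, ids=dm.ids)
        from .lmm import _check_full_rank

        _check_full_rank(dm.X, dm.exog_names)
        self._U, self._d = eig_structure(dm.Z, self._A)
        self._Xtil = self._U.T @ dm.X
        self._scan_cache = _build_scan_cache(self.genotypes, dm.ids)
        self._counts = dm.Z.sum(axis=0)
        if self.mode in ("baseline", "mean"):
            # outcome keyed by individual
            self._row_key = dm.ids
        else:
            self._row_key = list(zip(dm.obs_ids, map(int, self._obs_times(pheno, dm))))
        self._prepared = True

    @staticmethod
    def _obs_times(pheno: pd.DataFrame, dm) -> list[int]:
        pt = pheno.copy()
        pt["IID"] = pt["IID"].astype(str)
        pt = pt[pt["IID"].isin(set(dm.ids))].sort_values(["IID", "TIME"], kind="stable")
        return pt["TIME"].tolist()

    def _extract_outcome(self, pheno: pd.DataFrame) -> np.ndarray:
        pt = pheno.copy()
        pt["IID"] = pt["IID"].astype(str)
        if self.mode == "baseline":
            t1 = pt[pt["TIME"] == pt["TIME"].min()].set_index("IID")["PHENO"]
            return t1.reindex(self._dm.obs_ids).to_numpy(dtype=float)
        if self.mode == "mean":
            m = pt.groupby("IID")["PHENO"].mean()
            return m.reindex(self._dm.obs_ids).to_numpy(dtype=float)
        keyed = pt.set_index([pt["IID"], pt["TIME"].astype(int)])["PHENO"]
        return keyed.reindex(self._row_key).to_numpy(dtype=float)

    def run(self, pheno: pd.DataFrame) -> ScanResult:
        if not self._prepared:
            self._prepare(pheno)
        y = self._extract_outcome(pheno)
        if np.isnan(y).any():
            raise ValueError("phenotype replicate does not match the prepared design")
        ytil = self._U.T @ y
        opt = reml_fit_rotated(ytil, self._Xtil, self._d)
        beta = opt["beta"]
        if opt["w"] is None:  # sigma_g2 = 0 boundary: no polygenic prediction
            blup = np.zeros(self._dm.Z.shape[1])
        else:
            r_rot = ytil - self._Xtil @ beta
            u = self._U @ (r_rot / opt["w"])
            blup = self._A @ (self._dm.Z.T @ u)
        resid = y - self._dm.X @ beta - self._dm.Z @ blup
        resid_ind = (self._dm.Z.T @ resid) / self._counts
        stats_df = _bulk_regression(resid_ind, self._scan_cache)
        table = pd.concat(
            [
                pd.DataFrame(
                    {
                        "SNP": self.genotypes.snps["snp_id"],
                        "POS": self.genotypes.snps["position"],
                    }
                ),
                stats_df,
            ],
            axis=1,
        )
        model = PolygenicLMM(
            y, self._dm.X, self._A, incidence=self._dm.Z, ids=self._dm.ids,
            exog_names=self._dm.exog_names, obs_ids=self._dm.obs_ids, mode=self.mode,
            eig=(self._U, self._d),
        )
        stage1 = PolygenicLMMResults(model, opt, blup, resid)
        logger.info(
            "mode=%s sigma_g2=%.3f sigma_e2=%.3f h2=%.3f",
            self.mode, stage1.sigma_g2, stage1.sigma_e2, stage1.heritability,
        )
        return ScanResult(table=rank_snps(table), mode=self.mode, stage1=stage1)


def run_pipeline(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    mode: str,
    kinship: KinshipMatrix | None = None,
    qc: dict | None = None,
) -> ScanResult:
    """End-to-end two-stage scan for one mode.

    ``qc`` optionally carries :func:`~pedlmm.genotype.apply_qc` keyword
    thresholds; when None, QC is assumed already applied (bypass).
    Deterministic given its inputs.
    """
    if qc is not None:
        genotypes, _ = apply_qc(genotypes, **qc)
    runner = PipelineRunner(pedigree, genotypes, mode, kinship=kinship)
    return runner.run(pheno)
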