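"""Genotype matrices, PLINK text ped/map I/O, and GWAS quality control.

Genotypes are held as an individuals x SNPs dosage matrix counting
copies of the minor allele (0/1/2, NaN = missing call).  Quality control
applies the standard pre-association filters: sample-level missingness
exclusion first, then per-SNP minor allele frequency, call rate, and an
exact Hardy-Weinberg equilibrium test, with every failure reason
recorded in a :class:`QCReport`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

logger = logging.getLogger(__name__)

SNP_COLUMNS = ["snp_id", "chrom", "position", "a1", "a2"]


class GenotypeFormatError(ValueError):
    """Raised for malformed ped/map input."""


@dataclass
class GenotypeMatrix:
    """Additively coded genotypes for a set of samples.

    ``dosage[i, j]`` counts copies of allele ``a1`` (the minor allele at
    read time) of SNP *j* carried by sample *i*; NaN marks a missing
    call.  ``snps`` is a DataFrame with columns snp_id, chrom, position,
    a1, a2.
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.sample_ids):
            raise ValueError("dosage rows do not match sample_ids")
        if m != len(self.snps):
            raise ValueError("dosage columns do not match snps table")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("snp ids are not unique")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage values must be in {0, 1, 2} or missing")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snps["snp_id"].to_numpy() == snp_id)
        if hits.size == 0:
            raise KeyError(snp_id)
        return int(hits[0])

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in sample_idx],
            snps=self.snps.iloc[snp_idx].reset_index(drop=True),
            dosage=self.dosage[np.ix_(sample_idx, snp_idx)].copy(),
        )


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text .ped/.map files into a minor-allele dosage matrix.

    The .map file carries (chrom, snp_id, cM, position); each .ped row
    carries 6 leading columns (FID IID PAT MAT SEX PHENO) followed by
    two alleles per SNP.  "0" alleles mark missing calls.  Per SNP the
    less frequent allele becomes the counted allele a1 (ties broken
    lexicographically); more than two observed alleles is an error.
    """
    snp_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise GenotypeFormatError(
                    f"{map_path}: line {lineno}: expected 4 columns "
                    "(chrom, snp_id, cM, position)"
                )
            snp_rows.append((fields[1], fields[0], int(fields[3])))
    m = len(snp_rows)

    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise GenotypeFormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} columns "
                    f"for {m} SNPs, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            allele_rows.append(fields[6:])

    n = len(sample_ids)
    alleles = np.array(allele_rows, dtype=object).reshape(n, m, 2) if n else np.empty((0, m, 2), object)
    dosage = np.full((n, m), np.nan)
    a1_list: list[str] = []
    a2_list: list[str] = []
    for j, (snp_id, _, _) in enumerate(snp_rows):
        pair = alleles[:, j, :]
        missing = (pair == "0").any(axis=1)
        observed = pair[~missing].ravel()
        uniq, counts = np.unique(observed, return_counts=True) if observed.size else (np.array([]), np.array([]))
        if uniq.size > 2:
            raise GenotypeFormatError(
                f"SNP {snp_id!r} has more than two alleles: {sorted(uniq)}"
            )
        if uniq.size == 0:
            a1, a2 = ".", "."
        elif uniq.size == 1:
            a1, a2 = ".", str(uniq[0])  # monomorphic: counted (minor) allele unseen
        else:
            # minor = least frequent, ties broken lexicographically
            order = np.lexsort((uniq, counts))
            a1, a2 = str(uniq[order[0]]), str(uniq[order[1]])
        a1_list.append(a1)
        a2_list.append(a2)
        dos = (pair == a1).sum(axis=1).astype(float)
        dos[missing] = np.nan
        dosage[:, j] = dos

    snps = pd.DataFrame(
        {
            "snp_id": [r[0] for r in snp_rows],
            "chrom": [r[1] for r in snp_rows],
            "position": [r[2] for r in snp_rows],
            "a1": a1_list,
            "a2": a2_list,
        }
    )
    return GenotypeMatrix(sample_ids=sample_ids, snps=snps, dosage=dosage)


def write_ped_map(g: GenotypeMatrix, ped_path, map_path, fam: pd.DataFrame | None = None) -> None:
    """Write PLINK text .ped/.map.  ``fam`` optionally supplies the six
    leading .ped columns (FID IID PAT MAT SEX PHENO) indexed by IID."""
    with open(map_path, "w") as fh:
        for row in g.snps.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.position}\n")
    a1 = g.snps["a1"].to_numpy()
    a2 = g.snps["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(g.sample_ids):
            if fam is not None and iid in fam.index:
                r = fam.loc[iid]
                lead = [str(r["FID"]), iid, str(r["PAT"]), str(r["MAT"]), str(r["SEX"]), str(r.get("PHENO", -9))]
            else:
                lead = [iid, iid, "0", "0", "0", "-9"]
            cells = []
            for j in range(g.n_snps):
                d = g.dosage[i, j]
                if np.isnan(d):
                    cells.append("0 0")
                elif d == 0:
                    cells.append(f"{a2[j]} {a2[j]}")
                elif d == 1:
                    cells.append(f"{a1[j]} {a2[j]}")
                else:
                    cells.append(f"{a1[j]} {a1[j]}")
            fh.write(" ".join(lead) + " " + " ".join(cells) + "\n")


def minor_allele_frequency(dosages: np.ndarray) -> float | np.ndarray:
    """MAF from non-missing dosages: min(p, 1-p), p = sum / (2 * n_called).

    Accepts a single SNP vector or a samples x SNPs matrix (per-column
    result).  An all-missing SNP yields NaN.
    """
    d = np.asarray(dosages, dtype=float)
    squeeze = d.ndim == 1
    if squeeze:
        d = d[:, None]
    called = np.sum(~np.isnan(d), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * called)
        maf = np.minimum(p, 1.0 - p)
    maf = np.where(called == 0, np.nan, maf)
    return float(maf[0]) if squeeze else maf


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Sums, over all heterozygote counts consistent with the observed
    allele counts, the conditional probabilities no larger than that of
    the observed configuration.  Log-factorial accumulation keeps the
    enumeration stable at large counts.  Symmetric in the two homozygote
    counts; monomorphic SNPs return 1.
    """
    n_hom1, n_het, n_hom2 = int(n_hom1), int(n_het), int(n_hom2)
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_a = 2 * n_hom1 + n_het  # copies of allele 1
    n_b = 2 * n_hom2 + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    # log P(n_het = h | allele counts) up to a common constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_r + 1)
        - gammaln(hets + 1)
        - gammaln(hom_c + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    observed = prob[np.flatnonzero(hets == n_het)[0]]
    p = prob[prob <= observed * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_chisq_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """One-df chi-square HWE test (cross-check alternative to the exact test)."""
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    p = (2 * n_hom1 + n_het) / (2.0 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
    stat = float(((obs - exp) ** 2 / exp).sum())
    return float(chi2.sf(stat, df=1))


@dataclass
class QCReport:
    """Per-SNP and per-sample quality-control outcome and thresholds used."""

    snps: pd.DataFrame      # snp_id, maf, call_rate, hwe_p, passed, fail_reasons
    samples: pd.DataFrame   # sample_id, missing_fraction, excluded
    thresholds: dict = field(default_factory=dict)

    @property
    def n_snps_retained(self) -> int:
        return int(self.snps["passed"].sum())

    @property
    def n_samples_retained(self) -> int:
        return int((~self.samples["excluded"]).sum())

    def write(self, path, sep: str = "\t") -> None:
        with open(path, "w") as fh:
            fh.write("# thresholds: " + ", ".join(f"{k}={v}" for k, v in self.thresholds.items()) + "\n")
            self.snps.to_csv(fh, sep=sep, index=False)


def apply_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.90,
    hwe_p_min: float = 1e-6,
    sample_missing_max: float = 0.5,
    hwe_method: str = "exact",
    hwe_sample_ids: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample-missingness exclusion, then per-SNP MAF / call-rate /
    Hardy-Weinberg filters.

    Samples with a missing-genotype fraction strictly above
    ``sample_missing_max`` are dropped first; all SNP statistics are then
    computed on the retained samples.  A SNP fails when its MAF is
    strictly below ``maf_min``, its call rate strictly below
    ``call_rate_min``, or its HWE p value is <= ``hwe_p_min`` (boundary
    semantics follow the usual "MAF < 1% excluded" / "HWE p <= 1e-6"
    conventions).  ``hwe_sample_ids`` optionally restricts the HWE test
    to a subset (e.g. founders); default is all retained samples.

    Returns the filtered matrix (dosages re-coded so the counted allele
    is minor on the retained samples) and a :class:`QCReport` listing
    every failure reason.
    """
    miss_frac = np.isnan(g.dosage).mean(axis=1) if g.n_snps else np.zeros(g.n_samples)
    excluded = miss_frac > sample_missing_max
    samples_df = pd.DataFrame(
        {"sample_id": g.sample_ids, "missing_fraction": miss_frac, "excluded": excluded}
    )
    keep_samples = np.flatnonzero(~excluded)
    d = g.dosage[keep_samples]

    # re-code so the counted allele is minor among retained samples
    snps = g.snps.copy()
    called = np.sum(~np.isnan(d), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.nansum(d, axis=0) / (2.0 * called)
    flip = np.nan_to_num(p1, nan=0.0) > 0.5
    if flip.any():
        d = d.copy()
        d[:, flip] = 2.0 - d[:, flip]
        a1 = snps["a1"].to_numpy().copy()
        a2 = snps["a2"].to_numpy().copy()
        a1[flip], a2[flip] = a2[flip], a1[flip].copy()
        snps["a1"], snps["a2"] = a1, a2

    maf = minor_allele_frequency(d) if d.size else np.full(g.n_snps, np.nan)
    maf = np.atleast_1d(maf)
    call_rate = called / max(len(keep_samples), 1)

    hwe_test = hwe_exact_p if hwe_method == "exact" else hwe_chisq_p
    if hwe_sample_ids is not None:
        subset = set(hwe_sample_ids)
        rows = [i for i, s in enumerate(keep_samples) if g.sample_ids[s] in subset]
        d_hwe = d[rows]
    else:
        d_hwe = d
    hwe_p = np.ones(g.n_snps)
    for j in range(g.n_snps):
        col = d_hwe[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            hwe_p[j] = np.nan
            continue
        hwe_p[j] = hwe_test(
            int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())
        )

    reasons: list[str] = []
    passed = np.ones(g.n_snps, dtype=bool)
    for j in range(g.n_snps):
        why = []
        if np.isnan(maf[j]) or maf[j] < maf_min:
            why.append("maf")
        if call_rate[j] < call_rate_min:
            why.append("call_rate")
        if np.isnan(hwe_p[j]) or hwe_p[j] <= hwe_p_min:
            why.append("hwe")
        reasons.append(";".join(why))
        passed[j] = not why

    snps_df = pd.DataFrame(
        {
            "snp_id": snps["snp_id"],
            "maf": maf,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "passed": passed,
            "fail_reasons": reasons,
        }
    )
    report = QCReport(
        snps=snps_df,
        samples=samples_df,
        thresholds={
            "maf_min": maf_min,
            "call_rate_min": call_rate_min,
            "hwe_p_min": hwe_p_min,
            "sample_missing_max": sample_missing_max,
            "hwe_method": hwe_method,
        },
    )
    keep_snps = np.flatnonzero(passed)
    if keep_snps.size == 0:
        warnings.warn("quality control removed every SNP", RuntimeWarning, stacklevel=2)
    filtered = GenotypeMatrix(
        sample_ids=[g.sample_ids[i] for i in keep_samples],
        snps=snps.iloc[keep_snps].reset_index(drop=True),
        dosage=d[:, keep_snps].copy(),
    )
    logger.info(
        "QC retained %d/%d samples and %d/%d SNPs",
        filtered.n_samples, g.n_samples, filtered.n_snps, g.n_snps,
    )
    return filtered, report
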