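"""Replicate-simulation power evaluation.

Estimates, over repeated phenotype simulations on one fixed genotype
set, the proportion of replicates in which the planted causal SNP is
selected by each analysis mode — either because its association rank
falls within the best N SNPs (top-N criterion) or because its p value
is strictly below a cutoff alpha.  Selection sets are nested in N and
alpha, so the estimated proportions are monotone by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .scan import PipelineRunner, ScanResult
from .simulate import SimulationConfig, simulate_pedigree, gene_drop, simulate_phenotypes
from .pedigree import kinship_matrix

logger = logging.getLogger(__name__)

DEFAULT_MODES = ("baseline", "mean", "longitudinal_A", "longitudinal_B")
DEFAULT_TOP_N = (1, 10, 50, 100, 200)
DEFAULT_ALPHA = (1e-4, 1e-3, 1e-2, 0.05)


def selection_indicator(scan: ScanResult, causal_id: str, criterion: tuple) -> bool:
    """Whether the causal SNP is selected under one criterion.

    ``criterion`` is ``("top_n", N)`` — selected iff rank <= N — or
    ``("p_cutoff", alpha)`` — selected iff p < alpha (strict).  An
    untestable causal SNP counts as not selected (and is logged).
    """
    kind, value = criterion
    rank = scan.rank_of(causal_id)
    if rank is None:
        logger.warning("causal SNP %s untestable in this replicate", causal_id)
        return False
    if kind == "top_n":
        return rank <= int(value)
    if kind == "p_cutoff":
        return scan.p_of(causal_id) < float(value)
    raise ValueError(f"unknown criterion kind {kind!r}")


@dataclass
class PowerResult:
    """Selection proportions over a grid of one criterion family."""

    mode: str
    criterion: str               # "top_n" or "p_cutoff"
    values: np.ndarray           # grid of N or alpha
    counts: np.ndarray           # replicates in which the SNP was selected
    n_replicates: int            # denominator (failed replicates excluded)

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.n_replicates

    @property
    def standard_errors(self) -> np.ndarray:
        p = self.proportions
        return np.sqrt(p * (1.0 - p) / self.n_replicates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mode": self.mode,
                "criterion": self.criterion,
                "value": self.values,
                "count": self.counts,
                "n_replicates": self.n_replicates,
                "proportion": self.proportions,
                "se": self.standard_errors,
            }
        )


def estimate_power(
    cfg: SimulationConfig,
    modes: Sequence[str] = DEFAULT_MODES,
    top_n_grid: Sequence[int] = DEFAULT_TOP_N,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA,
    n_replicates: int = 200,
    seed: int | None = None,
    causal_id: str | None = None,
) -> dict[str, dict[str, PowerResult]]:
    """Replicate protocol: simulate phenotypes ``n_replicates`` times over
    one gene-dropped genotype set, run every mode's two-stage scan on
    each replicate, and count causal-SNP selections per criterion value.

    Replicate-level seeds derive deterministically from the master seed
    (see :func:`~pedlmm.simulate.simulate_phenotypes`); a replicate whose
    pipeline fails is excluded from that mode's denominator and logged.
    Returns ``{mode: {"top_n": PowerResult, "p_cutoff": PowerResult}}``.
    """
    top_n_grid = np.asarray(sorted(top_n_grid), dtype=int)
    alpha_grid = np.asarray(sorted(alpha_grid), dtype=float)
    if top_n_grid.size == 0 and alpha_grid.size == 0:
        raise ValueError("at least one non-empty criterion grid is required")
    if cfg.causal_maf is None:
        raise ValueError("configuration has no planted causal SNP")
    causal_id = causal_id if causal_id is not None else cfg.causal_snp_id

    ped = simulate_pedigree(cfg)
    g = gene_drop(ped, cfg, seed=seed)
    kin = kinship_matrix(ped)
    tables = simulate_phenotypes(ped, g, cfg, n_replicates=n_replicates, seed=seed)

    out: dict[str, dict[str, PowerResult]] = {}
    for mode in modes:
        runner = PipelineRunner(ped, g, mode, kinship=kin)
        top_counts = np.zeros(top_n_grid.size, dtype=int)
        p_counts = np.zeros(alpha_grid.size, dtype=int)
        n_ok = 0
        n_fail = 0
        for tbl in tables:
            try:
                scan = runner.run(tbl)
            except Exception as err:
                n_fail += 1
                logger.warning(
                    "mode %s replicate %s failed: %s", mode, tbl.attrs.get("replicate"), err
                )
                continue
            n_ok += 1
            rank = scan.rank_of(causal_id)
            pval = scan.p_of(causal_id)
            if rank is None:
                logger.warning("causal SNP untestable (mode %s)", mode)
                continue
            top_counts += rank <= top_n_grid
            p_counts += pval < alpha_grid
        if n_fail:
            logger.warning("mode %s: %d replicate(s) excluded", mode, n_fail)
        out[mode] = {
            "top_n": PowerResult(mode, "top_n", top_n_grid, top_counts, max(n_ok, 1)),
            "p_cutoff": PowerResult(mode, "p_cutoff", alpha_grid, p_counts, max(n_ok, 1)),
        }
    return out


def power_report(
    results: dict[str, dict[str, PowerResult]],
    table_path=None,
    figure_path=None,
) -> pd.DataFrame:
    """Tabulate (and optionally plot) selection proportions.

    One table row per (mode, criterion, grid value); the figure shows
    one panel per criterion family with one curve per mode.
    """
    if not results:
        raise ValueError("no power results to report")
    frames = [pr.to_frame() for by_crit in results.values() for pr in by_crit.values()]
    table = pd.concat(frames, ignore_index=True)
    if table_path is not None:
        table.to_csv(table_path, sep="\t", index=False)
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        criteria = table["criterion"].unique()
        fig, axes = plt.subplots(1, len(criteria), figsize=(6 * len(criteria), 4.5))
        axes = np.atleast_1d(axes)
        for ax, crit in zip(axes, criteria):
            sub = table[table["criterion"] == crit]
            for mode, grp in sub.groupby("mode"):
                ax.plot(grp["value"], grp["proportion"], marker="o", label=mode)
            ax.set_xlabel("top N" if crit == "top_n" else "p-value cutoff")
            ax.set_ylabel("selection proportion")
            ax.set_ylim(-0.02, 1.02)
            if crit == "p_cutoff":
                ax.set_xscale("log")
            ax.legend(fontsize=8)
            ax.set_title(f"causal-SNP selection by {crit}")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=120)
        plt.close(fig)
    return table
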