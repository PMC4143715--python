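"""Stage 1: the polygenic linear mixed model.

The model is

    y = X beta + Z g + e,    g ~ N(0, sigma_g2 * A),   e ~ N(0, sigma_e2 * I)

with A = 2*Phi the additive relationship matrix from the pedigree, so
Var(y) = sigma_g2 * Z A Z' + sigma_e2 * I.  Variance components are
estimated by REML after a single eigendecomposition of M = Z A Z'
(the EMMA device): for the variance ratio delta = sigma_e2 / sigma_g2
the covariance is diagonal in the rotated basis, beta and sigma_g2 are
profiled out analytically, and the restricted likelihood is maximized
over delta by a log-scale grid search with local refinement.

The fitted object exposes the GLS fixed effects, the variance
components, the BLUP of the polygenic effect, and the *conditional*
residuals e_hat = y - X beta_hat - Z g_hat that downstream association
scans regress on each SNP.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, qr
from scipy.optimize import minimize_scalar

from .design import DesignMatrices, build_design
from .pedigree import Pedigree, KinshipMatrix, kinship_matrix, relationship_matrix

_LOG2PI = np.log(2.0 * np.pi)

DELTA_LOWER = 1e-5
DELTA_UPPER = 1e5
N_GRID = 100
REFINE_TOL = 1e-8  # on log(delta)


class RankDeficientError(np.linalg.LinAlgError):
    """Fixed-effect design is rank deficient; names the collinear columns."""


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    r = qr(X, mode="r", pivoting=True)
    diag = np.abs(np.diag(r[0]))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[j] for j in r[1][rank:]]
        raise RankDeficientError(f"collinear fixed-effect columns: {bad}")


def eig_structure(Z: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of M = Z A Z' at observation level.

    Returns (U, d) with M = U diag(d) U'; tiny negative eigenvalues are
    clipped to zero, genuinely negative ones raise.
    """
    M = Z @ A @ Z.T
    d, U = np.linalg.eigh(M)
    top = max(d[-1], 1.0)
    if d[0] < -1e-8 * top:
        raise np.linalg.LinAlgError(
            f"Z A Z' is not positive semi-definite (min eigenvalue {d[0]:.3e})"
        )
    return U, np.clip(d, 0.0, None)


def _profile(log_delta: float, ytil: np.ndarray, Xtil: np.ndarray, d: np.ndarray):
    """Profiled restricted log-likelihood at a variance ratio delta.

    Returns (loglik, beta, sigma_g2, XtWX_cho) with beta and sigma_g2 at
    their conditional optima.
    """
    n, p = Xtil.shape
    delta = np.exp(log_delta)
    w = d + delta
    Xw = Xtil / w[:, None]
    XtWX = Xtil.T @ Xw
    cho = cho_factor(XtWX)
    beta = cho_solve(cho, Xw.T @ ytil)
    r = ytil - Xtil @ beta
    rss_w = float(np.sum(r * r / w))
    sg2 = rss_w / (n - p)
    logdet_xtwx = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    ll = -0.5 * (
        (n - p) * (_LOG2PI + np.log(sg2) + 1.0)
        + float(np.sum(np.log(w)))
        + logdet_xtwx
    )
    return ll, beta, sg2, cho


def reml_fit_rotated(
    ytil: np.ndarray,
    Xtil: np.ndarray,
    d: np.ndarray,
    lower: float = DELTA_LOWER,
    upper: float = DELTA_UPPER,
    n_grid: int = N_GRID,
    tol: float = REFINE_TOL,
) -> dict:
    """Maximize the restricted likelihood over delta in the rotated basis.

    Log-scale grid of ``n_grid`` points on [lower, upper] followed by
    bounded local refinement; returns the optimum's parameters and flags.
    """
    grid = np.linspace(np.log(lower), np.log(upper), n_grid)
    lls = np.array([_profile(g, ytil, Xtil, d)[0] for g in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, n_grid - 1)]
    converged = True
    try:
        res = minimize_scalar(
            lambda g: -_profile(g, ytil, Xtil, d)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": tol},
        )
        log_delta = float(res.x) if res.success else grid[best]
        converged = bool(res.success)
    except Exception:  # pragma: no cover - numerical failure fallback
        log_delta = grid[best]
        converged = False
    if _profile(log_delta, ytil, Xtil, d)[0] < lls[best]:
        log_delta = grid[best]
    ll, beta, sg2, cho = _profile(log_delta, ytil, Xtil, d)
    delta = float(np.exp(log_delta))
    n, p = Xtil.shape

    # exact sigma_g2 = 0 corner (V = sigma_e2 * I): if the restricted
    # likelihood there is at least as high, the boundary estimate is the
    # genuine optimum and the fit degenerates to OLS exactly
    XtX = Xtil.T @ Xtil
    cho0 = cho_factor(XtX)
    beta0 = cho_solve(cho0, Xtil.T @ ytil)
    r0 = ytil - Xtil @ beta0
    s2_ols = float(r0 @ r0) / (n - p)
    ll0 = -0.5 * (
        (n - p) * (_LOG2PI + np.log(s2_ols) + 1.0)
        + 2.0 * float(np.sum(np.log(np.diag(cho0[0]))))
    )
    if ll0 >= ll:
        return {
            "log_delta": np.inf,
            "delta": np.inf,
            "sigma_g2": 0.0,
            "sigma_e2": s2_ols,
            "beta": beta0,
            "cov_beta": s2_ols * cho_solve(cho0, np.eye(p)),
            "llf": float(ll0),
            "converged": converged,
            "at_boundary": True,
            "w": None,
        }

    w = d + delta
    cov_beta = sg2 * cho_solve(cho, np.eye(p))
    at_boundary = log_delta <= grid[0] + 1e-12 or log_delta >= grid[-1] - 1e-12
    return {
        "log_delta": float(log_delta),
        "delta": delta,
        "sigma_g2": float(sg2),
        "sigma_e2": float(delta * sg2),
        "beta": beta,
        "cov_beta": cov_beta,
        "llf": float(ll),
        "converged": converged,
        "at_boundary": bool(at_boundary),
        "w": w,
    }


class PolygenicLMM:
    """Polygenic mixed model for one outcome vector.

    Parameters
    ----------
    endog : (n_obs,) outcome vector.
    exog : (n_obs, p) fixed-effect design including an intercept column.
    relationship : (q, q) additive relationship matrix A = 2*kinship over
        the individuals, ordered like ``ids``.
    incidence : (n_obs, q) observation->individual incidence matrix Z;
        identity when omitted (one observation per individual).
    ids : individual identifiers ordering the columns of Z / rows of A.
    exog_names, obs_ids, mode : optional metadata carried into results.
    """

    def __init__(
        self,
        endog,
        exog,
        relationship,
        incidence=None,
        ids=None,
        exog_names=None,
        obs_ids=None,
        mode=None,
        eig=None,
    ):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        n = self.endog.shape[0]
        if self.exog.shape[0] != n:
            raise ValueError("endog and exog have different numbers of rows")
        self.A = np.asarray(relationship, dtype=float)
        if incidence is None:
            if self.A.shape[0] != n:
                raise ValueError("relationship matrix does not match n_obs; pass incidence")
            self.Z = np.eye(n)
        else:
            self.Z = np.asarray(incidence, dtype=float)
        q = self.Z.shape[1]
        if self.A.shape != (q, q):
            raise ValueError("relationship matrix does not match incidence columns")
        self.ids = list(ids) if ids is not None else [str(i) for i in range(q)]
        self.obs_ids = list(obs_ids) if obs_ids is not None else list(self.ids)
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        self.mode = mode
        _check_full_rank(self.exog, self.exog_names)
        # `eig` lets a caller reuse a precomputed (U, d) of Z A Z' when
        # fitting many outcomes over one fixed design (replicate loops)
        self._U, self._d = eig if eig is not None else eig_structure(self.Z, self.A)
        self._ytil = self._U.T @ self.endog
        self._Xtil = self._U.T @ self.exog

    @classmethod
    def from_phenotype_table(
        cls,
        pheno: pd.DataFrame,
        pedigree: Pedigree | None = None,
        mode: str = "baseline",
        kinship: KinshipMatrix | None = None,
    ) -> "PolygenicLMM":
        """Build the model for one analysis mode from a long-format
        phenotype table and a pedigree (or precomputed kinship)."""
        if kinship is None:
            if pedigree is None:
                raise ValueError("either a pedigree or a kinship matrix is required")
            kinship = kinship_matrix(pedigree)
        known = set(kinship.ids)
        orphans = sorted(set(pheno["IID"].astype(str)) - known)
        if orphans:
            raise ValueError(
                f"{len(orphans)} phenotyped individual(s) absent from the pedigree: "
                f"{orphans[:5]}"
            )
        dm = build_design(pheno, mode, ids=list(kinship.ids))
        A = relationship_matrix(kinship, ids=dm.ids)
        return cls(
            dm.y,
            dm.X,
            A,
            incidence=dm.Z,
            ids=dm.ids,
            exog_names=dm.exog_names,
            obs_ids=dm.obs_ids,
            mode=mode,
        )

    @classmethod
    def from_design(cls, dm: DesignMatrices, A: np.ndarray) -> "PolygenicLMM":
        return cls(
            dm.y, dm.X, A, incidence=dm.Z, ids=dm.ids,
            exog_names=dm.exog_names, obs_ids=dm.obs_ids, mode=dm.mode,
        )

    @property
    def nobs(self) -> int:
        return self.endog.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.Z.shape[1]

    def reml_loglike(self, sigma_g2: float, sigma_e2: float) -> float:
        """Restricted log-likelihood at arbitrary variance components
        (evaluated in the rotated basis)."""
        n, p = self._Xtil.shape
        if sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be positive")
        if sigma_g2 < 0:
            raise ValueError("sigma_g2 must be nonnegative")
        v = sigma_g2 * self._d + sigma_e2
        Xw = self._Xtil / v[:, None]
        XtVX = self._Xtil.T @ Xw
        cho = cho_factor(XtVX)
        beta = cho_solve(cho, Xw.T @ self._ytil)
        r = self._ytil - self._Xtil @ beta
        quad = float(np.sum(r * r / v))
        logdet_v = float(np.sum(np.log(v)))
        logdet_x = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        return -0.5 * ((n - p) * _LOG2PI + logdet_v + logdet_x + quad)

    def fit(
        self,
        lower: float = DELTA_LOWER,
        upper: float = DELTA_UPPER,
        n_grid: int = N_GRID,
        tol: float = REFINE_TOL,
    ) -> "PolygenicLMMResults":
        opt = reml_fit_rotated(
            self._ytil, self._Xtil, self._d,
            lower=lower, upper=upper, n_grid=n_grid, tol=tol,
        )
        beta = opt["beta"]
        if opt["w"] is None:  # sigma_g2 = 0: no polygenic prediction
            blup = np.zeros(self.n_individuals)
        else:
            r_rot = self._ytil - self._Xtil @ beta
            # g_hat = sigma_g2 * A Z' V^{-1} (y - X beta) = A Z' U (r_rot / w)
            u = self._U @ (r_rot / opt["w"])
            blup = self.A @ (self.Z.T @ u)
        resid = self.endog - self.exog @ beta - self.Z @ blup
        return PolygenicLMMResults(self, opt, blup, resid)


class PolygenicLMMResults:
    """REML fit of a :class:`PolygenicLMM`.

    Attributes
    ----------
    fe_params, bse : fixed-effect estimates and standard errors (Series).
    sigma_g2, sigma_e2 : additive genetic and residual variances.
    blups : per-individual predicted polygenic effect (Series by IID).
    resid : conditional residuals y - X beta_hat - Z g_hat, one per
        observation; the stage-2 association outcome.
    llf : restricted log-likelihood at the optimum.
    """

    def __init__(self, model: PolygenicLMM, opt: dict, blup: np.ndarray, resid: np.ndarray):
        self.model = model
        self.fe_params = pd.Series(opt["beta"], index=model.exog_names)
        self.bse = pd.Series(np.sqrt(np.diag(opt["cov_beta"])), index=model.exog_names)
        self.cov_params = pd.DataFrame(
            opt["cov_beta"], index=model.exog_names, columns=model.exog_names
        )
        self.sigma_g2 = opt["sigma_g2"]
        self.sigma_e2 = opt["sigma_e2"]
        self.delta = opt["delta"]
        self.llf = opt["llf"]
        self.converged = opt["converged"]
        self.at_boundary = opt["at_boundary"]
        self.blups = pd.Series(blup, index=model.ids)
        self.resid = resid

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def n_individuals(self) -> int:
        return self.model.n_individuals

    @property
    def heritability(self) -> float:
        """Narrow-sense variance fraction sigma_g2 / (sigma_g2 + sigma_e2)."""
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.endog - self.resid

    def resid_individual(self) -> pd.Series:
        """Per-individual stage-2 outcome.

        For one-row-per-individual modes this is the conditional residual
        itself; for longitudinal modes it is the arithmetic mean of each
        individual's observation-level residuals.
        """
        counts = self.model.Z.sum(axis=0)
        sums = self.model.Z.T @ self.resid
        return pd.Series(sums / counts, index=self.model.ids)

    def summary(self) -> str:
        lines = [
            "Polygenic linear mixed model (REML)",
            "=" * 52,
            f"mode:             {self.model.mode or '-'}",
            f"observations:     {self.nobs}",
            f"individuals:      {self.n_individuals}",
            f"converged:        {self.converged}"
            + ("  (variance ratio at search boundary)" if self.at_boundary else ""),
            f"REML loglik:      {self.llf:.4f}",
            f"sigma_g2:         {self.sigma_g2:.4f}",
            f"sigma_e2:         {self.sigma_e2:.4f}",
            f"h2 (sg2/(sg2+se2)): {self.heritability:.4f}",
            "-" * 52,
            f"{'effect':<12}{'coef':>12}{'se':>12}{'z':>10}",
        ]
        for name in self.fe_params.index:
            coef = self.fe_params[name]
            se = self.bse[name]
            z = coef / se if se > 0 else np.nan
            lines.append(f"{name:<12}{coef:>12.4f}{se:>12.4f}{z:>10.2f}")
        lines.append("=" * 52)
        return "\n".join(lines)

    def write_residuals(self, path, sep: str = "\t") -> None:
        self.resid_individual().rename("RESID").rename_axis("IID").reset_index().to_csv(
            path, sep=sep, index=False
        )
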