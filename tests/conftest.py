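import numpy as np
import pytest

from pedlmm import Member, Pedigree, kinship_matrix


@pytest.fixture
def trio_pedigree():
    return Pedigree(
        [
            Member("F1", "dad", None, None, "male"),
            Member("F1", "mom", None, None, "female"),
            Member("F1", "kid", "dad", "mom", "male"),
        ]
    )


@pytest.fixture
def three_generation_pedigree():
    """Grandparents -> parent + married-in spouse -> two grandchildren."""
    return Pedigree(
        [
            Member("F1", "gf", None, None, "male"),
            Member("F1", "gm", None, None, "female"),
            Member("F1", "dad", "gf", "gm", "male"),
            Member("F1", "mom", None, None, "female"),
            Member("F1", "c1", "dad", "mom", "male"),
            Member("F1", "c2", "dad", "mom", "female"),
        ]
    )


@pytest.fixture
def inbred_loop_pedigree():
    """Full-sib mating: the offspring is inbred (F = 1/4)."""
    return Pedigree(
        [
            Member("F1", "gf", None, None, "male"),
            Member("F1", "gm", None, None, "female"),
            Member("F1", "s1", "gf", "gm", "male"),
            Member("F1", "s2", "gf", "gm", "female"),
            Member("F1", "x", "s1", "s2", "male"),
        ]
    )


def genedrop_kinship_oracle(ped: Pedigree, n_rep: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo IBD oracle for expected kinship.

    Drops two uniquely labelled alleles per founder down the pedigree
    ``n_rep`` times and estimates phi(a, b) as the probability that one
    allele drawn from a and one from b are identical by descent.
    Returns (phi_hat, mc_se), each n x n.  Independent of the package's
    recursive computation.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    idx = ped.id_index
    alleles = np.empty((n_rep, n, 2), dtype=np.int32)
    label = 0
    for k, m in enumerate(ped.members):
        if m.is_founder:
            alleles[:, k, 0] = label
            alleles[:, k, 1] = label + 1
            label += 2
        else:
            f, mo = idx[m.father], idx[m.mother]
            pf = rng.integers(0, 2, n_rep)
            pm = rng.integers(0, 2, n_rep)
            rows = np.arange(n_rep)
            alleles[:, k, 0] = alleles[rows, f, pf]
            alleles[:, k, 1] = alleles[rows, mo, pm]
    phi = np.zeros((n, n))
    se = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            ibd = np.zeros(n_rep)
            for i in range(2):
                for j in range(2):
                    ibd += alleles[:, a, i] == alleles[:, b, j]
            ibd *= 0.25
            phi[a, b] = phi[b, a] = ibd.mean()
            se[a, b] = se[b, a] = ibd.std(ddof=1) / np.sqrt(n_rep)
    return phi, se


def reml_loglik_dense(y, X, V):
    """Dense-matrix restricted log-likelihood, independent of the
    package's rotated-basis evaluation."""
    n, p = X.shape
    sign, logdet_v = np.linalg.slogdet(V)
    assert sign > 0
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    sign2, logdet_x = np.linalg.slogdet(XtViX)
    assert sign2 > 0
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_v + logdet_x + r @ Vi @ r)


def reml_grid_oracle(y, X, M, n_pts: int = 30):
    """Iteratively refined 2-D grid search of the dense REML criterion
    over (sigma_g2, sigma_e2).  Each round re-grids around the running
    optimum with a shrinking multiplicative half-width, so boundary
    optima (either variance near zero) are tracked as well as interior
    ones.  Returns (best_ll, sg2, se2)."""
    n = len(y)
    var_y = np.var(y)
    best = (-np.inf, var_y / 2, var_y / 2)
    for zoom in (1e4, 1e2, 30.0, 10.0, 4.0, 2.0, 1.4, 1.15, 1.05, 1.02, 1.005, 1.002):
        _, sg0, se0 = best
        gs = np.geomspace(sg0 / zoom, sg0 * zoom, n_pts)
        es = np.geomspace(se0 / zoom, se0 * zoom, n_pts)
        for sg in gs:
            for se_ in es:
                ll = reml_loglik_dense(y, X, sg * M + se_ * np.eye(n))
                if ll > best[0]:
                    best = (ll, sg, se_)
    return best
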