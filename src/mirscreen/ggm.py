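"""Sparse Gaussian graphical models of phosphoprotein responses.

A cell line's phosphoprotein network is the sparse precision matrix
estimated from its perturbation-response matrix by the graphical lasso;
edges are scored by partial correlation
``rho_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj)``, which quantifies the
interplay between two phosphoproteins after accounting for all others.
The penalty is chosen by the extended BIC (gamma = 0.5).  Networks from
several cell lines are compared by exact edge-set intersections
(Venn-style regions), which surfaces links shared by all lines versus
links private to a mutational or lineage background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._glasso import glasso_cd
from .screens import ScreenMatrix, is_phospho
from .simulate import partial_correlations

__all__ = [
    "GlassoResult",
    "GGMNetwork",
    "NetworkComparison",
    "GlassoConvergenceError",
    "graphical_lasso",
    "penalized_objective",
    "kkt_violation",
    "ebic",
    "select_lambda",
    "default_lambda_grid",
    "infer_network",
    "compare_networks",
]

EDGE_EPS = 1e-8  # |Theta_ij| above this counts as an edge


class GlassoConvergenceError(RuntimeError):
    """Raised when the sweep budget is exhausted; carries the last iterate."""

    def __init__(self, message: str, theta: np.ndarray, residual: float):
        super().__init__(message)
        self.theta = theta
        self.residual = residual


@dataclass
class GlassoResult:
    theta: np.ndarray
    W: np.ndarray                 # working covariance (approximate inverse)
    lam: float
    n_sweeps: int
    primal_path: np.ndarray       # penalized log-likelihood per sweep
    dual_path: np.ndarray         # log det W per sweep (monotone surrogate)
    converged: bool


def penalized_objective(S: np.ndarray, theta: np.ndarray, lam: float) -> float:
    """log det Theta - tr(S Theta) - lam * sum_offdiag |Theta_ij|."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    pen = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    return float(logdet - np.trace(S @ theta) - lam * pen)


def _theta_from_wb(W: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Reconstruct the precision matrix from the working covariance and coefs."""
    p = W.shape[0]
    theta = np.zeros((p, p))
    for j in range(p):
        idx = np.array([i for i in range(p) if i != j])
        beta = B[idx, j]
        w12 = W[idx, j]
        denom = W[j, j] - float(w12 @ beta)
        tjj = 1.0 / denom
        theta[j, j] = tjj
        theta[idx, j] = -beta * tjj
    return (theta + theta.T) / 2.0


def graphical_lasso(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    inner_tol: float = 1e-9,
    inner_max: int = 1000,
    warm: GlassoResult | None = None,
    check_monotone: bool = True,
) -> GlassoResult:
    """Graphical lasso by block coordinate descent (diagonal unpenalized).

    Convergence: mean absolute change of the working covariance per sweep
    below ``tol`` times the mean |off-diagonal of S|.  The surrogate
    objective log det W is asserted non-decreasing every sweep; the
    penalized log-likelihood trajectory is returned alongside.  Exceeding
    ``max_iter`` raises :class:`GlassoConvergenceError` carrying the last
    iterate and its residual.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be square symmetric")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    lo = float(np.linalg.eigvalsh(S).min())
    if lo <= 0:
        S = S + (1e-8 * np.mean(np.diag(S)) if np.mean(np.diag(S)) > 0 else 1e-8) * np.eye(p)
        if float(np.linalg.eigvalsh(S).min()) <= 0:
            raise ValueError("S is not positive-semidefinite even after diagonal loading")
    if warm is not None:
        B0 = _coefs_from(warm)
        W0 = warm.W
        use_warm = True
    else:
        W0 = np.zeros((p, p))
        B0 = np.zeros((p, p))
        use_warm = False
    Lam = np.full((p, p), float(lam))
    W, B, W_path, B_path, n_sweeps, converged = glasso_cd(
        S, Lam, float(tol), int(max_iter), float(inner_tol),
        int(inner_max), W0, B0, use_warm,
    )
    dual = np.array([np.linalg.slogdet(Wt)[1] for Wt in W_path])
    primal = np.array(
        [penalized_objective(S, _theta_from_wb(Wt, Bt), lam)
         for Wt, Bt in zip(W_path, B_path)]
    )
    if check_monotone and len(dual) > 1:
        drops = np.diff(dual)
        slack = 1e-8 * (1.0 + np.abs(dual[:-1]))
        if np.any(drops < -slack):
            raise RuntimeError("monotone ascent violated in graphical lasso sweep")
    theta = _theta_from_wb(W, B)
    if np.linalg.eigvalsh(theta).min() <= 0:
        raise RuntimeError("estimated precision is not positive-definite")
    if not converged:
        resid = float(np.mean(np.abs(W_path[-1] - W_path[-2]))) if len(W_path) > 1 else np.inf
        raise GlassoConvergenceError(
            f"graphical lasso did not converge in {n_sweeps} sweeps "
            f"(residual {resid:.3g})", theta, resid,
        )
    return GlassoResult(theta, W, float(lam), n_sweeps, primal, dual, converged)


def _coefs_from(res: GlassoResult) -> np.ndarray:
    p = res.theta.shape[0]
    B = np.zeros((p, p))
    for j in range(p):
        idx = np.array([i for i in range(p) if i != j])
        B[idx, j] = -res.theta[idx, j] / res.theta[j, j]
    return B


def kkt_violation(S: np.ndarray, theta: np.ndarray, lam: float) -> float:
    """Maximum stationarity violation of the penalized-likelihood problem.

    Zero at the exact optimum: ``Theta^{-1} - S = lam * sign(Theta_ij)``
    on nonzeros, ``|Theta^{-1} - S| <= lam`` on zeros, exact match on the
    diagonal.
    """
    G = np.linalg.inv(theta) - S
    p = theta.shape[0]
    viol = np.abs(np.diag(G)).max() if p else 0.0
    iu = np.triu_indices(p, k=1)
    g = G[iu]
    t = theta[iu]
    nz = np.abs(t) > EDGE_EPS
    if nz.any():
        viol = max(viol, np.abs(g[nz] - lam * np.sign(t[nz])).max())
    if (~nz).any():
        viol = max(viol, max(0.0, (np.abs(g[~nz]) - lam).max()))
    return float(viol)


def constrained_mle(
    S: np.ndarray,
    support: set[tuple[int, int]] | frozenset[tuple[int, int]],
    tol: float = 1e-7,
    max_iter: int = 500,
) -> np.ndarray:
    """Gaussian MLE of the precision matrix constrained to a given support.

    Solved with the same block-coordinate machinery using per-entry
    penalties: zero on the support (and diagonal), effectively infinite
    elsewhere.  With an empty support this is the diagonal MLE
    diag(1 / S_jj).
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    big = 1e6 * max(1.0, float(np.abs(S).max()))
    Lam = np.full((p, p), big)
    for i, j in support:
        Lam[i, j] = Lam[j, i] = 0.0
    np.fill_diagonal(Lam, 0.0)
    W0 = np.zeros((p, p))
    B0 = np.zeros((p, p))
    W, B, _, _, _, converged = glasso_cd(
        S, Lam, float(tol), int(max_iter), 1e-10, 2000, W0, B0, False,
    )
    if not converged:
        raise GlassoConvergenceError(
            "constrained MLE refit did not converge", _theta_from_wb(W, B), np.nan
        )
    return _theta_from_wb(W, B)


def ebic(S: np.ndarray, theta: np.ndarray, n: int, gamma: float = 0.5) -> float:
    """Extended BIC: -2 loglik + |E| (log n + 4 gamma log p)."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(theta)
    ll = 0.5 * n * (logdet - np.trace(S @ theta))
    iu = np.triu_indices(p, k=1)
    n_edges = int((np.abs(theta[iu]) > EDGE_EPS).sum())
    return float(-2.0 * ll + n_edges * (np.log(n) + 4.0 * gamma * np.log(p)))


def default_lambda_grid(S: np.ndarray, n_lambda: int = 20, lam_min: float = 0.01) -> np.ndarray:
    """Log-spaced penalties from lam_min up to the largest |off-diagonal| of S."""
    p = S.shape[0]
    iu = np.triu_indices(p, k=1)
    lam_max = float(np.abs(S[iu]).max())
    lam_max = max(lam_max, lam_min * 1.01)
    return np.geomspace(lam_min, lam_max, n_lambda)


def select_lambda(
    X: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    gamma: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 500,
    return_path: bool = False,
):
    """EBIC (default gamma = 0.5) model selection over a penalty grid.

    The grid is scanned from the sparsest (largest) penalty down with warm
    starts; ties break toward the larger (sparser) penalty.  Each
    candidate support is scored on its support-constrained MLE refit, so
    the l1 shrinkage of the path estimate does not distort the
    likelihood term.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    S = np.corrcoef(X, rowvar=False)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(S)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")
    order = np.argsort(lambda_grid)[::-1]
    best_lam, best_score = None, np.inf
    rows = []
    prev: GlassoResult | None = None
    iu = np.triu_indices(S.shape[0], k=1)
    seen: dict[frozenset, float] = {}
    for lam in lambda_grid[order]:
        res = graphical_lasso(S, float(lam), tol=tol, max_iter=max_iter, warm=prev)
        prev = res
        support = frozenset(
            (int(i), int(j)) for i, j in zip(*iu)
            if abs(res.theta[i, j]) > EDGE_EPS
        )
        if support in seen:
            score = seen[support]
        else:
            refit = constrained_mle(S, support)
            score = ebic(S, refit, n, gamma=gamma)
            seen[support] = score
        rows.append({"lam": float(lam), "ebic": score, "n_edges": len(support)})
        if score < best_score:  # strict: first (largest) lambda wins ties
            best_score, best_lam = score, float(lam)
    if return_path:
        return best_lam, pd.DataFrame(rows)
    return best_lam


@dataclass
class GGMNetwork:
    """Estimated sparse precision network for one cell line."""

    cell_line: str
    proteins: list[str]
    S: np.ndarray
    theta: np.ndarray
    lam: float
    edges: pd.DataFrame    # columns: protein_a, protein_b, rho, sign

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            tuple(sorted((a, b)))
            for a, b in zip(self.edges["protein_a"], self.edges["protein_b"])
        )

    def to_edge_table(self) -> pd.DataFrame:
        """Edge list in the generic exporter's source/target/score/sign shape."""
        return pd.DataFrame({
            "source": self.edges["protein_a"],
            "target": self.edges["protein_b"],
            "score": self.edges["rho"],
            "sign": self.edges["sign"],
        })


def _edges_from_theta(theta: np.ndarray, proteins: list[str]) -> pd.DataFrame:
    rho = partial_correlations(theta)
    rows = []
    p = theta.shape[0]
    for i in range(p):
        for j in range(i + 1, p):
            if abs(theta[i, j]) > EDGE_EPS:
                rows.append({
                    "protein_a": proteins[i], "protein_b": proteins[j],
                    "rho": float(rho[i, j]), "sign": int(np.sign(rho[i, j])),
                })
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b", "rho", "sign"])
    return df.sort_values(["protein_a", "protein_b"], kind="mergesort").reset_index(drop=True)


def infer_network(
    screen: ScreenMatrix,
    phospho_ids: list[str] | None = None,
    lambda_grid: np.ndarray | None = None,
    gamma: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 500,
    lambda_min: float = 0.01,
    n_lambda: int = 20,
) -> GGMNetwork:
    """Estimate a phosphoprotein partial-correlation network for one screen.

    Restricts to ``phospho_ids`` (auto-detected by the ``_p`` suffix when
    omitted), standardizes columns, estimates the correlation matrix,
    selects the penalty by EBIC and reports the nonzero partial
    correlations.  Constant columns are dropped with a warning; fewer
    than 30 rows triggers a warning (the estimate is then fragile).
    """
    if phospho_ids is None:
        phospho_ids = [p for p in screen.protein_ids if is_phospho(p)]
    if len(phospho_ids) < 2:
        raise ValueError("need at least two phosphoproteins")
    sub = screen.subset(proteins=phospho_ids)
    x = sub.values
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [p for p, k in zip(sub.protein_ids, keep) if not k]
        warnings.warn(f"dropping constant columns: {dropped}")
        x = x[:, keep]
        phospho_ids = [p for p, k in zip(sub.protein_ids, keep) if k]
    n = x.shape[0]
    if n < 30:
        warnings.warn(f"only {n} rows; network estimate will be unstable")
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    S = np.corrcoef(x, rowvar=False)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(S, n_lambda=n_lambda, lam_min=lambda_min)
    lam = select_lambda(x, lambda_grid=lambda_grid, gamma=gamma, tol=tol,
                        max_iter=max_iter)
    res = graphical_lasso(S, lam, tol=tol, max_iter=max_iter)
    iu = np.triu_indices(S.shape[0], k=1)
    support = {(int(i), int(j)) for i, j in zip(*iu)
               if abs(res.theta[i, j]) > EDGE_EPS}
    # topology from the penalized fit; edge scores from the unshrunken
    # support-constrained MLE so partial correlations are not biased toward 0
    theta = constrained_mle(S, support)
    edges = _edges_from_theta(theta, list(phospho_ids))
    return GGMNetwork(screen.cell_line, list(phospho_ids), S, theta, lam, edges)


@dataclass
class NetworkComparison:
    """Exact edge-set regions across cell lines (inclusion–exclusion consistent)."""

    lines: list[str]
    edge_sets: dict[str, frozenset[tuple[str, str]]]
    region_counts: dict[tuple[str, ...], int] = field(default_factory=dict)
    common_core: list[tuple[str, str]] = field(default_factory=list)

    def count(self, *lines: str) -> int:
        """Edges present in exactly the given lines and absent elsewhere."""
        return self.region_counts.get(tuple(sorted(lines)), 0)

    def intersection(self, *lines: str) -> frozenset[tuple[str, str]]:
        sets = [self.edge_sets[l] for l in lines]
        out = sets[0]
        for s in sets[1:]:
            out = out & s
        return out

    def to_frame(self) -> pd.DataFrame:
        """Hive-plot-ready edge table: one row per edge with line membership."""
        all_edges = sorted(set().union(*self.edge_sets.values()))
        rows = []
        for e in all_edges:
            membership = [l for l in self.lines if e in self.edge_sets[l]]
            rows.append({
                "protein_a": e[0], "protein_b": e[1],
                "lines": "&".join(membership), "n_lines": len(membership),
            })
        return pd.DataFrame(rows, columns=["protein_a", "protein_b", "lines", "n_lines"])


def compare_networks(nets: list[GGMNetwork]) -> NetworkComparison:
    """Edge-set intersections for every subset of cell-line networks.

    Networks over different protein universes are compared on the
    intersection of their universes (with a warning).
    """
    lines = [n.cell_line for n in nets]
    universes = [set(n.proteins) for n in nets]
    common = set.intersection(*universes)
    if any(u != common for u in universes):
        warnings.warn("networks cover different protein universes; comparing on the intersection")
    edge_sets = {
        n.cell_line: frozenset(e for e in n.edge_set()
                               if e[0] in common and e[1] in common)
        for n in nets
    }
    all_edges = set().union(*edge_sets.values())
    region_counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(lines) + 1):
        for subset in combinations(sorted(lines), r):
            region_counts[subset] = 0
    for e in all_edges:
        membership = tuple(sorted(l for l in lines if e in edge_sets[l]))
        region_counts[membership] += 1
    core = sorted(set.intersection(*[set(s) for s in edge_sets.values()])) if nets else []
    return NetworkComparison(lines, edge_sets, region_counts, core)
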