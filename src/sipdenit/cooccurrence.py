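"""Compositionality-aware correlation networks from OTU counts.

Sequencing counts only carry relative information, so ordinary Pearson
correlations on proportions are confounded by the closure to a constant
sum. The approach here infers *basis* correlations from log-ratio
variances: with t_ij = Var(log(x_i/x_j)) and per-OTU basis variances
ω_i², the identity t_ij = ω_i² + ω_j² − 2ρ_ij ω_i ω_j lets the ω_i² be
solved from the linear system Σ_j t_ij ≈ (m−2)ω_i² + Σ_j ω_j² under the
assumption that most pairs are uncorrelated; strongly correlated pairs
(which violate that assumption) are iteratively excluded and the system
re-solved. Counts are converted to compositions by posterior Dirichlet
draws with a uniform prior, and the whole estimate is repeated over inner
iterations with the element-wise median reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationEstimate",
    "NetworkEdge",
    "sparcc_correlations",
    "bootstrap_significance",
    "build_network",
    "to_networkx",
]


@dataclass(frozen=True)
class CorrelationEstimate:
    """Inferred basis correlations with their ingredients.

    ``rho`` is symmetric with unit diagonal, entries clipped to [−1, 1];
    ``t_ij`` is the (median) log-ratio variation matrix and ``omega`` the
    basis standard deviations, both on the filtered OTU set.
    """

    rho: pd.DataFrame
    t_ij: pd.DataFrame
    omega: pd.Series


@dataclass(frozen=True)
class NetworkEdge:
    """An undirected signed edge between two OTUs."""

    otu_a: str
    otu_b: str
    rho: float
    p: float

    @property
    def sign(self) -> str:
        return "positive" if self.rho >= 0 else "negative"


def _variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """t_ij = Var(log(x_i/x_j)) over samples; fractions is samples × OTUs."""
    logf = np.log(fractions)
    cov = np.cov(logf, rowvar=False)
    var = np.diag(cov)
    return var[:, None] + var[None, :] - 2.0 * cov


def _solve_basis(
    t: np.ndarray, excluded: set[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Solve basis variances and correlations given excluded pairs."""
    m = t.shape[0]
    mat = np.full((m, m), 1.0)
    np.fill_diagonal(mat, float(m - 2))
    rhs = t.sum(axis=1)
    for i, j in excluded:
        mat[i, i] -= 1.0
        mat[j, j] -= 1.0
        mat[i, j] -= 1.0
        mat[j, i] -= 1.0
        rhs[i] -= t[i, j]
        rhs[j] -= t[i, j]
    try:
        omega2 = np.linalg.solve(mat, rhs)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular basis-variance system; try fewer excluded pairs or "
            "more samples"
        ) from err
    omega2 = np.maximum(omega2, 1e-12)
    omega = np.sqrt(omega2)
    rho = (omega2[:, None] + omega2[None, :] - t) / (2.0 * np.outer(omega, omega))
    np.fill_diagonal(rho, 1.0)
    return rho, omega


def _sparcc_once(
    counts: np.ndarray,
    rng: np.random.Generator,
    n_exclude_iter: int,
    exclude_threshold: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One inner iteration: posterior composition draw → rho, omega, t."""
    n_samples, m = counts.shape
    fractions = np.empty_like(counts, dtype=float)
    for s in range(n_samples):
        fractions[s] = rng.dirichlet(counts[s] + 1.0)
    t = _variation_matrix(fractions)

    excluded: set[tuple[int, int]] = set()
    rho, omega = _solve_basis(t, excluded)
    for _ in range(n_exclude_iter):
        masked = np.abs(rho.copy())
        np.fill_diagonal(masked, 0.0)
        for i, j in excluded:
            masked[i, j] = masked[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclude_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        try:
            rho, omega = _solve_basis(t, excluded)
        except np.linalg.LinAlgError:
            # too many exclusions for this few components: keep the last
            # solvable estimate
            excluded.discard((min(i, j), max(i, j)))
            break
    return rho, omega, t


def sparcc_correlations(
    counts: pd.DataFrame,
    n_inner: int = 20,
    n_exclude_iter: int = 10,
    exclude_threshold: float = 0.1,
    seed: int | None = None,
    min_prevalence: float = 0.3,
) -> CorrelationEstimate:
    """Infer basis correlations from an OTU × sample count table.

    OTUs observed in fewer than ``min_prevalence`` of samples are dropped
    first (rare taxa destabilize log-ratio variances). Requires at least 4
    remaining OTUs and 3 samples. The final estimate is the element-wise
    median over ``n_inner`` posterior composition draws; values outside
    [−1, 1] are clipped with a warning.
    """
    n_samples = counts.shape[1]
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    prevalence = (counts > 0).sum(axis=1) / n_samples
    kept = counts.loc[prevalence >= min_prevalence]
    if kept.shape[0] < 4:
        raise ValueError(
            f"need at least 4 OTUs after prevalence filtering, have {kept.shape[0]}"
        )
    mat = kept.to_numpy(dtype=float).T  # samples × OTUs

    rng = np.random.default_rng(seed)
    rhos, omegas, ts = [], [], []
    for _ in range(n_inner):
        rho, omega, t = _sparcc_once(mat, rng, n_exclude_iter, exclude_threshold)
        rhos.append(rho)
        omegas.append(omega)
        ts.append(t)
    rho_med = np.median(rhos, axis=0)
    if np.any(np.abs(rho_med) > 1.0 + 1e-9):
        warnings.warn("correlations outside [-1, 1]; clipping", stacklevel=2)
    rho_med = np.clip(rho_med, -1.0, 1.0)
    np.fill_diagonal(rho_med, 1.0)
    ids = list(kept.index)
    return CorrelationEstimate(
        rho=pd.DataFrame(rho_med, index=ids, columns=ids),
        t_ij=pd.DataFrame(np.median(ts, axis=0), index=ids, columns=ids),
        omega=pd.Series(np.median(omegas, axis=0), index=ids),
    )


def bootstrap_significance(
    counts: pd.DataFrame,
    n_boot: int = 100,
    seed: int | None = None,
    **sparcc_kwargs,
) -> tuple[CorrelationEstimate, pd.DataFrame]:
    """Pseudo p-values by permuting each OTU's counts across samples.

    Under the permutation null all cross-OTU dependence is destroyed while
    marginal count distributions are preserved. The add-one estimator
    p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (n_boot + 1) keeps p in (0, 1].
    Returns the observed estimate and the per-pair p-value matrix.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    sparcc_kwargs.setdefault("seed", int(rng.integers(2**31)))
    obs = sparcc_correlations(counts, **sparcc_kwargs)
    kept = counts.loc[obs.rho.index]
    mat = kept.to_numpy()

    exceed = np.zeros_like(obs.rho.to_numpy())
    abs_obs = np.abs(obs.rho.to_numpy())
    inner_kwargs = dict(sparcc_kwargs)
    inner_kwargs["min_prevalence"] = 0.0  # set is already filtered
    for _ in range(n_boot):
        perm = np.empty_like(mat)
        for i in range(mat.shape[0]):
            perm[i] = rng.permutation(mat[i])
        inner_kwargs["seed"] = int(rng.integers(2**31))
        est = sparcc_correlations(
            pd.DataFrame(perm, index=kept.index, columns=kept.columns),
            **inner_kwargs,
        )
        exceed += np.abs(est.rho.to_numpy()) >= abs_obs - 1e-12
    p = (1.0 + exceed) / (n_boot + 1.0)
    np.fill_diagonal(p, 1.0)
    pvals = pd.DataFrame(p, index=obs.rho.index, columns=obs.rho.columns)
    return obs, pvals


def build_network(
    estimate: CorrelationEstimate,
    pvalues: pd.DataFrame,
    rho_min: float = 0.3,
    alpha: float = 0.05,
) -> tuple[list[NetworkEdge], pd.DataFrame]:
    """Threshold correlations into a signed edge list.

    An edge is kept iff |ρ| ≥ ``rho_min`` and p < ``alpha``. Also returns a
    per-node table of positive/negative incident edge counts (the signed
    degree used to summarize hub taxa).
    """
    if not (0 <= rho_min <= 1) or not (0 < alpha <= 1):
        raise ValueError("thresholds out of range")
    ids = list(estimate.rho.index)
    rho = estimate.rho.to_numpy()
    p = pvalues.loc[ids, ids].to_numpy()
    edges: list[NetworkEdge] = []
    pos = {o: 0 for o in ids}
    neg = {o: 0 for o in ids}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(rho[i, j]) >= rho_min and p[i, j] < alpha:
                edges.append(
                    NetworkEdge(ids[i], ids[j], float(rho[i, j]), float(p[i, j]))
                )
                d = pos if rho[i, j] >= 0 else neg
                d[ids[i]] += 1
                d[ids[j]] += 1
    degrees = pd.DataFrame(
        {"positive": pd.Series(pos), "negative": pd.Series(neg)}
    )
    return edges, degrees


def to_networkx(edges: list[NetworkEdge]):
    """Edge list as a networkx Graph (rho, p, sign as edge attributes)."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_edge(e.otu_a, e.otu_b, rho=e.rho, p=e.p, sign=e.sign)
    return g
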