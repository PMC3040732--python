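"""Independent component decomposition of expression matrices by negentropy
maximization, plus the ANOVA machinery that ranks components (and selects
miRNAs) against the experimental design.

Model
-----
The genes x samples log-ratio matrix ``E`` is decomposed as ``E = C M``:
``C`` (genes x components) holds each component's gene *loads*, ``M``
(components x samples) holds its per-sample *mixes*. Loads act as the
non-Gaussian sources; each gene is one observation of an S-dimensional random
vector. Up to ``n = min(G, S)`` components are extracted — no PCA
pre-reduction is performed.

Estimation is fixed-point fastICA with the exponential contrast

    G(u) = -exp(-u^2 / 2),    g(u) = u exp(-u^2 / 2),
    g'(u) = (1 - u^2) exp(-u^2 / 2)

and symmetric (parallel) decorrelation. Negentropy is approximated by
``J(y) = (mean(G(y)) - E[G(v)])^2`` with ``v ~ N(0, 1)``; the reference
expectation has the closed form ``E[G(v)] = -1/sqrt(2)``.

Conventions: components are ordered by descending negentropy; each
component's loads are standardized to mean 0 / variance 1 and signed so the
load of largest absolute value is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, SampleDesign, ConfigurationError

logger = logging.getLogger(__name__)

#: Closed-form E[-exp(-v^2/2)] for v ~ N(0,1): the integral evaluates to
#: -1/sqrt(2) (Gaussian product identity), so no reference sampling is needed.
GAUSSIAN_CONTRAST_EXPECTATION = -1.0 / np.sqrt(2.0)


class NotStandardizedError(ValueError):
    """Input vector is not mean-0 / variance-1."""


class RankDeficientError(ValueError):
    """Whitening failed because the sample covariance is rank deficient."""


def _contrast(u: np.ndarray) -> np.ndarray:
    return -np.exp(-0.5 * u * u)


def _g(u: np.ndarray) -> np.ndarray:
    return u * np.exp(-0.5 * u * u)


def _g_prime(u: np.ndarray) -> np.ndarray:
    return (1.0 - u * u) * np.exp(-0.5 * u * u)


def negentropy(y: np.ndarray, n_reference_samples: int | None = None,
               rng_seed: int | None = None, std_tol: float = 1e-2) -> float:
    """Approximate negentropy ``J(y) = (mean(G(y)) - E[G(v)])^2`` of a
    standardized vector.

    Parameters
    ----------
    y
        Vector with mean ~0 and variance ~1 (checked to ``std_tol``).
    n_reference_samples, rng_seed
        Accepted for API symmetry with sampled-reference variants; ignored
        because ``E[G(v)]`` is evaluated in closed form (``-1/sqrt(2)``).
    """
    y = np.asarray(y, dtype=float)
    if abs(float(y.mean())) > std_tol or abs(float(y.std()) - 1.0) > std_tol:
        raise NotStandardizedError(
            f"expected mean 0 / sd 1 input, got mean {y.mean():.4g}, sd {y.std():.4g}"
        )
    return float((np.mean(_contrast(y)) - GAUSSIAN_CONTRAST_EXPECTATION) ** 2)


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

@dataclass
class ICADecomposition:
    """Result of a fastICA run on a genes x samples matrix.

    ``loads`` is genes x components (matrix C), ``mixes`` components x
    samples (matrix M); ``loads @ mixes`` reconstructs the column-centered
    input. ``col_means`` holds the removed per-sample means.
    """

    gene_ids: list
    sample_ids: list
    loads: np.ndarray
    mixes: np.ndarray
    n_components: int
    converged: np.ndarray
    negentropies: np.ndarray
    rng_seed: int
    col_means: np.ndarray = field(default=None)  # type: ignore[assignment]

    def mix_row(self, component: int) -> np.ndarray:
        return self.mixes[component]

    def load_column(self, component: int) -> np.ndarray:
        return self.loads[:, component]

    def loads_frame(self) -> pd.DataFrame:
        cols = [f"IC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.loads, index=self.gene_ids, columns=cols)

    def mixes_frame(self) -> pd.DataFrame:
        idx = [f"IC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.mixes, index=idx, columns=self.sample_ids)


def _whiten(X: np.ndarray, n_components: int, rank_tol: float = 1e-10):
    """Center columns and whiten; returns (Z, K, col_means) with
    cov(Z) = I_n and Z = (X - mean) @ K."""
    G = X.shape[0]
    col_means = X.mean(axis=0)
    Xc = X - col_means
    cov = (Xc.T @ Xc) / G
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    thresh = rank_tol * max(evals[0], 1.0)
    if n_components > int((evals > thresh).sum()):
        raise RankDeficientError(
            f"covariance rank {int((evals > thresh).sum())} < requested "
            f"{n_components} components (deficient dimension "
            f"{int((evals > thresh).sum())})"
        )
    K = evecs[:, :n_components] / np.sqrt(evals[:n_components])
    return Xc @ K, K, col_means


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    # W <- (W W^T)^{-1/2} W
    s, u = np.linalg.eigh(W @ W.T)
    return (u / np.sqrt(s)) @ u.T @ W


def _fastica_once(Z: np.ndarray, tol: float, max_iter: int, rng: np.random.Generator):
    """One symmetric fastICA run on whitened data Z (G x n)."""
    G, n = Z.shape
    W = _sym_decorrelate(rng.standard_normal((n, n)))
    per_comp_delta = np.full(n, np.inf)
    for _ in range(max_iter):
        Y = Z @ W.T  # G x n, column j = component j
        W_new = (_g(Y).T @ Z) / G - np.diag(_g_prime(Y).mean(axis=0)) @ W
        W_new = _sym_decorrelate(W_new)
        per_comp_delta = np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0)
        W = W_new
        if per_comp_delta.max() < tol:
            break
    return W, per_comp_delta < tol


def fast_ica(
    E: ExpressionMatrix | np.ndarray,
    n_components: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    restarts: int = 8,
    rng_seed: int = 0,
    gene_ids: Sequence | None = None,
    sample_ids: Sequence | None = None,
) -> ICADecomposition:
    """Decompose an expression matrix into independent components.

    The best of ``restarts`` random initializations (by total negentropy,
    fully-converged runs preferred) is retained. Deterministic for a given
    ``rng_seed``.
    """
    if isinstance(E, ExpressionMatrix):
        X = E.values
        gene_ids = E.row_ids
        sample_ids = E.col_ids
    else:
        X = np.asarray(E, dtype=float)
        gene_ids = list(gene_ids) if gene_ids is not None else [f"g{i+1}" for i in range(X.shape[0])]
        sample_ids = list(sample_ids) if sample_ids is not None else [f"s{j+1}" for j in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError("expression matrix contains missing values; drop or impute first")
    G, S = X.shape
    n = min(G, S) if n_components is None else int(n_components)
    if n > min(G, S):
        raise ValueError(f"n_components={n} exceeds min(G, S)={min(G, S)}")

    Z, K, col_means = _whiten(X, n)
    Xc = X - col_means

    best = None
    child_seeds = np.random.SeedSequence(rng_seed).spawn(restarts)
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        W, conv = _fastica_once(Z, tol, max_iter, rng)
        Y = Z @ W.T
        # columns of Y are mean-0 by construction; variance ~1 by orthonormality
        Ystd = Y / Y.std(axis=0)
        J = np.array([negentropy(Ystd[:, j], std_tol=1e-3) for j in range(n)])
        key = (bool(conv.all()), float(J.sum()))
        if best is None or key > best[0]:
            best = (key, W, conv, J)
    assert best is not None
    _, W, conv, J = best
    if not conv.all():
        logger.warning("%d/%d components did not converge within max_iter", int((~conv).sum()), n)

    loads = Z @ W.T
    # order by descending negentropy
    order = np.argsort(J)[::-1]
    loads, J, conv = loads[:, order], J[order], conv[order]
    # standardize loads: mean 0 / variance 1 per component
    loads = loads - loads.mean(axis=0)
    loads = loads / loads.std(axis=0)
    # sign convention: largest-|load| entry positive
    flip = np.sign(loads[np.abs(loads).argmax(axis=0), np.arange(n)])
    flip[flip == 0] = 1.0
    loads = loads * flip
    # mixes solve loads @ M ~= Xc in least squares
    mixes, *_ = np.linalg.lstsq(loads, Xc, rcond=None)

    return ICADecomposition(
        gene_ids=list(gene_ids),
        sample_ids=list(sample_ids),
        loads=loads,
        mixes=mixes,
        n_components=n,
        converged=conv,
        negentropies=J,
        rng_seed=rng_seed,
        col_means=col_means,
    )


# ---------------------------------------------------------------------------
# ANOVA ranking
# ---------------------------------------------------------------------------

class FTestResult(NamedTuple):
    F: float
    p: float
    degenerate: bool = False


def one_way_F(values: Sequence[float], groups: Sequence) -> FTestResult:
    """Classical one-way ANOVA F statistic and p-value.

    Zero within-group variance with unequal group means yields
    ``F = inf, p = 0`` with the ``degenerate`` flag set.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    labels, inverse = np.unique(groups, return_inverse=True)
    k = len(labels)
    ntot = len(values)
    if k < 2:
        raise ValueError("one-way ANOVA requires >= 2 groups")
    sizes = np.bincount(inverse, minlength=k)
    if (sizes == 0).any():
        raise ValueError("empty group in ANOVA")
    if ntot <= k:
        raise ValueError("total sample size must exceed the number of groups")
    grand = values.mean()
    group_means = np.bincount(inverse, weights=values) / sizes
    ssb = float((sizes * (group_means - grand) ** 2).sum())
    ssw = float(((values - group_means[inverse]) ** 2).sum())
    df1, df2 = k - 1, ntot - k
    if ssw == 0.0:
        if ssb == 0.0:
            return FTestResult(0.0, 1.0, False)
        return FTestResult(float("inf"), 0.0, True)
    F = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(F, df1, df2))
    return FTestResult(float(F), p, False)


@dataclass
class ComponentRanking:
    component: int  # 0-based index into the decomposition
    F: float
    p: float
    p_bonferroni: float
    significant: bool
    degenerate: bool = False


def rank_mixes(
    mixes: np.ndarray,
    sample_ids: Sequence,
    design: SampleDesign,
    alpha: float = 1e-4,
    factors: Sequence | None = None,
) -> list:
    """Rank mix rows by one-way ANOVA across the full factor
    cross-classification; Bonferroni over the number of rows."""
    mixes = np.asarray(mixes, dtype=float)
    labels = np.asarray(design.group_labels(sample_ids, factors))
    _, inv = np.unique(labels, return_inverse=True)
    if np.bincount(inv).max() < 2:
        raise ConfigurationError("every design group has < 2 replicates; F undefined")
    n = mixes.shape[0]
    out = []
    for i in range(n):
        res = one_way_F(mixes[i], labels)
        p_bonf = min(1.0, res.p * n)
        # alpha >= 1 flags everything (capped q of exactly 1 is never < 1)
        sig = p_bonf < alpha or alpha >= 1.0
        out.append(ComponentRanking(i, res.F, res.p, p_bonf, sig, res.degenerate))
    out.sort(key=lambda r: (r.p, r.component))
    return out


def rank_components(
    decomp: ICADecomposition,
    design: SampleDesign,
    alpha: float = 1e-4,
    factors: Sequence | None = None,
) -> list:
    """Rank the components of a decomposition against the design (Bonferroni
    corrected one-way ANOVA on the mixes, threshold ``alpha``)."""
    return rank_mixes(decomp.mixes, decomp.sample_ids, design, alpha=alpha, factors=factors)


def ranking_frame(rankings: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "component": f"IC{r.component + 1}",
                "F": r.F,
                "p": r.p,
                "p_bonferroni": r.p_bonferroni,
                "significant": r.significant,
                "degenerate": r.degenerate,
            }
            for r in rankings
        ]
    )


def select_significant_mirnas(
    mirna_matrix: ExpressionMatrix,
    design: SampleDesign,
    q_threshold: float = 0.1,
    factors: Sequence | None = None,
) -> pd.DataFrame:
    """Per-miRNA one-way ANOVA across the design groups with Bonferroni
    correction over the number of profiled miRNAs; rows with corrected value
    below ``q_threshold`` are flagged ``selected``."""
    labels = np.asarray(design.group_labels(mirna_matrix.col_ids, factors))
    m = mirna_matrix.n_rows
    rows = []
    for i, mid in enumerate(mirna_matrix.row_ids):
        res = one_way_F(mirna_matrix.values[i], labels)
        q = min(1.0, res.p * m)
        rows.append({"mirna_id": mid, "F": res.F, "p": res.p,
                     "q_bonferroni": q, "selected": q < q_threshold})
    df = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    return df
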