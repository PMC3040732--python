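"""Rank-based enrichment tests on gene-level score vectors.

Covers: Wilcoxon rank-sum (exact by enumeration for small tie-free samples,
normal approximation with tie and continuity correction otherwise),
target-set enrichment in IC loads / Pearson-correlation vectors / external
fold changes, pairwise miRNA cooperativity in one component's loads, pathway
overrepresentation among miRNA targets, and multiple-testing adjustment
(Bonferroni for few tests, Benjamini-Hochberg FDR for many).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, GeneSetCollection
from .ica_core import ICADecomposition
from .seed_targets import TargetMap

logger = logging.getLogger(__name__)

EXACT_LIMIT = 12  # largest pooled size for exact enumeration


class DegenerateHypothesisError(ValueError):
    """Target set empty or equal to the whole universe."""


class RankSumResult(NamedTuple):
    W: float
    p: float


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    mode: str = "auto",
) -> RankSumResult:
    """Wilcoxon rank-sum test of ``x`` against ``y``.

    ``W`` is the sum of the (mid-)ranks of ``x`` in the pooled sample. With
    ``mode='exact'`` (or ``'auto'`` with pooled size <= 12 and no ties) the
    p-value is computed by full enumeration of rank assignments; otherwise the
    normal approximation with tie correction and a 0.5 continuity correction
    is used. ``alternative='less'`` tests for ``x`` shifted below ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")

    n, m = x.size, y.size
    N = n + m
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    W = float(ranks[:n].sum())
    has_ties = len(np.unique(pooled)) < N

    use_exact = (mode == "exact" or (mode == "auto" and N <= EXACT_LIMIT)) and not has_ties
    if (mode == "exact") and has_ties:
        logger.debug("ties present; falling back to the normal approximation")

    if use_exact:
        total = 0
        n_le = 0
        n_ge = 0
        for comb in combinations(range(1, N + 1), n):
            s = sum(comb)
            total += 1
            if s <= W:
                n_le += 1
            if s >= W:
                n_ge += 1
        p_less = n_le / total
        p_greater = n_ge / total
        if alternative == "less":
            p = p_less
        elif alternative == "greater":
            p = p_greater
        else:
            p = min(1.0, 2.0 * min(p_less, p_greater))
        return RankSumResult(W, p)

    mu = n * (N + 1) / 2.0
    # tie-corrected variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (N * (N - 1)) if N > 1 else 0.0
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return RankSumResult(W, 1.0)  # all values identical
    sd = np.sqrt(var)
    if alternative == "less":
        p = float(stats.norm.cdf((W - mu + 0.5) / sd))
    elif alternative == "greater":
        p = float(stats.norm.sf((W - mu - 0.5) / sd))
    else:
        z = (abs(W - mu) - 0.5) / sd
        p = float(2.0 * stats.norm.sf(max(z, 0.0)))
    return RankSumResult(W, min(1.0, max(p, 0.0)))


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def adjust_pvalues(p: Sequence[float], method: str = "bh_fdr") -> np.ndarray:
    """Adjust p-values: ``bonferroni`` -> min(1, m*p); ``bh_fdr`` ->
    Benjamini-Hochberg step-up with enforced monotonicity."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "bh_fdr":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.minimum(1.0, q_sorted)
        return q
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Score vectors and generic target enrichment
# ---------------------------------------------------------------------------

@dataclass
class ScoreVector:
    """Gene ids aligned with real-valued scores (IC loads, correlations or
    fold changes)."""

    gene_ids: list
    values: np.ndarray
    kind: str = "ic_loads"  # ic_loads | correlation | fold_change
    context: str = ""

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in score vector")
        if len(self.gene_ids) != self.values.size:
            raise ValueError("ids and values length mismatch")


@dataclass
class EnrichmentResult:
    label: str
    n_target: int
    n_background: int
    W: float
    direction: str  # negative_shift | positive_shift
    p: float
    q: float | None = None
    method: str | None = None


def score_enrichment(
    scores: ScoreVector,
    target_set: Iterable,
    alternative: str = "two_sided",
    label: str | None = None,
    mode: str = "auto",
) -> EnrichmentResult:
    """Wilcoxon rank-sum of target-gene scores against all other scores.

    Direction is recorded from the sign of the median difference
    (targets minus background)."""
    target_set = set(target_set)
    universe = set(scores.gene_ids)
    stray = target_set - universe
    if stray:
        raise ValueError(f"target genes outside the score universe: {sorted(stray)[:5]}")
    if not target_set or target_set == universe:
        raise DegenerateHypothesisError(
            "target set must be a non-empty proper subset of the score universe"
        )
    mask = np.fromiter((g in target_set for g in scores.gene_ids), bool, len(scores.gene_ids))
    x = scores.values[mask]
    y = scores.values[~mask]
    W, p = wilcoxon_rank_sum(x, y, alternative=alternative, mode=mode)
    diff = float(np.median(x) - np.median(y))
    direction = "negative_shift" if diff < 0 else "positive_shift"
    return EnrichmentResult(
        label=label or (scores.context or scores.kind),
        n_target=int(mask.sum()),
        n_background=int((~mask).sum()),
        W=W,
        direction=direction,
        p=p,
    )


def _results_frame(results: list, extra_cols: dict | None = None) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "label": r.label,
            "n_target": r.n_target,
            "n_background": r.n_background,
            "W": r.W,
            "direction": r.direction,
            "p": r.p,
            "q": r.q,
            "method": r.method,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    if extra_cols:
        for k, v in extra_cols.items():
            df[k] = v
    return df


# ---------------------------------------------------------------------------
# Pipeline-level tests
# ---------------------------------------------------------------------------

def _shared_universe(decomp_gene_ids: Sequence, targets: TargetMap) -> list:
    universe = [g for g in decomp_gene_ids if g in targets.gene_universe]
    n_dropped = len(decomp_gene_ids) - len(universe)
    if n_dropped:
        logger.info("restricting to %d genes shared with the UTR universe (%d dropped)",
                    len(universe), n_dropped)
    return universe


def ic_target_enrichment(
    decomp: ICADecomposition,
    targets: TargetMap,
    significant_ics: Sequence[int],
    mirna_ids: Sequence | None = None,
) -> tuple:
    """Test every miRNA's seed-predicted targets for enrichment in every
    significant component's loads (two-sided), BH-FDR over all miRNA x IC
    tests.

    Returns ``(table, summary)``: the full per-test table and a per-miRNA
    summary whose ``q_min`` is the smallest adjusted q across the significant
    components (with the component achieving it).
    """
    significant_ics = list(significant_ics)
    if not significant_ics:
        raise ValueError("no significant components; run rank_components first")
    mirna_ids = list(mirna_ids) if mirna_ids is not None else list(targets.mirna_ids)
    universe = _shared_universe(decomp.gene_ids, targets)
    uni_set = set(universe)
    pos = {g: i for i, g in enumerate(decomp.gene_ids)}
    uni_idx = np.array([pos[g] for g in universe])

    results = []
    meta = []
    for m in mirna_ids:
        tset = targets.targets.get(m, set()) & uni_set
        if not tset or tset == uni_set:
            logger.warning("miRNA %s skipped: degenerate target set (%d targets)", m, len(tset))
            continue
        for ic in significant_ics:
            sv = ScoreVector(universe, decomp.loads[uni_idx, ic],
                             kind="ic_loads", context=f"IC{ic + 1}")
            res = score_enrichment(sv, tset, alternative="two_sided",
                                   label=f"{m}|IC{ic + 1}")
            results.append(res)
            meta.append((m, ic))
    if not results:
        raise DegenerateHypothesisError("no testable miRNA target sets")
    q = adjust_pvalues([r.p for r in results], "bh_fdr")
    for r, qi in zip(results, q):
        r.q, r.method = float(qi), "fdr"
    table = _results_frame(results)
    table.insert(0, "mirna_id", [m for m, _ in meta])
    table.insert(1, "ic", [f"IC{ic + 1}" for _, ic in meta])

    summary_rows = []
    for m in dict.fromkeys(t[0] for t in meta):
        sub = table[table["mirna_id"] == m]
        best = sub.loc[sub["q"].idxmin()]
        summary_rows.append({"mirna_id": m, "best_ic": best["ic"],
                             "q_min": float(best["q"]), "p_min": float(sub["p"].min())})
    summary = pd.DataFrame(summary_rows).sort_values("q_min", kind="stable").reset_index(drop=True)
    return table, summary


def correlation_enrichment(
    mrna: ExpressionMatrix,
    mirna_profile: Sequence[float],
    targets: Iterable,
    label: str = "correlation",
) -> EnrichmentResult:
    """Negative-correlation baseline: per-gene Pearson correlation with the
    miRNA profile, then one-sided (``less``) target enrichment toward r = -1.

    Zero-variance gene rows are dropped (logged); a constant miRNA profile is
    an error.
    """
    y = np.asarray(mirna_profile, dtype=float)
    if y.size != mrna.n_cols:
        raise ValueError("miRNA profile length does not match sample columns")
    yc = y - y.mean()
    y_norm = float(np.sqrt((yc ** 2).sum()))
    if y_norm == 0.0:
        raise ValueError("constant miRNA profile: correlations undefined")
    X = mrna.values
    Xc = X - X.mean(axis=1, keepdims=True)
    row_norm = np.sqrt((Xc ** 2).sum(axis=1))
    keep = row_norm > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d zero-variance gene rows from correlation", n_dropped)
    r = (Xc[keep] @ yc) / (row_norm[keep] * y_norm)
    ids = [g for g, k in zip(mrna.row_ids, keep) if k]
    tset = set(targets) & set(ids)
    sv = ScoreVector(ids, r, kind="correlation", context=label)
    return score_enrichment(sv, tset, alternative="less", label=label)


def correlation_enrichment_table(
    mrna: ExpressionMatrix,
    mirna_matrix: ExpressionMatrix,
    targets: TargetMap,
    mirna_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Per-miRNA negative-correlation enrichment with BH-FDR across miRNAs."""
    mirna_ids = list(mirna_ids) if mirna_ids is not None else list(targets.mirna_ids)
    mrna_aligned = mrna.reorder_cols(mirna_matrix.col_ids)
    shared = set(mrna.row_ids) & targets.gene_universe
    results = []
    kept = []
    for m in mirna_ids:
        if m not in mirna_matrix.row_ids:
            logger.warning("miRNA %s absent from the expression matrix; skipped", m)
            continue
        tset = targets.targets.get(m, set()) & shared
        if not tset:
            logger.warning("miRNA %s skipped: no targets in the shared universe", m)
            continue
        res = correlation_enrichment(mrna_aligned, mirna_matrix.row(m), tset, label=m)
        results.append(res)
        kept.append(m)
    if not results:
        raise DegenerateHypothesisError("no testable miRNAs for correlation enrichment")
    q = adjust_pvalues([r.p for r in results], "bh_fdr")
    for r, qi in zip(results, q):
        r.q, r.method = float(qi), "fdr"
    df = _results_frame(results)
    df.insert(0, "mirna_id", kept)
    return df


def pairwise_cooperativity(
    decomp: ICADecomposition,
    targets: TargetMap,
    ic: int,
    mirna_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Test all unordered miRNA pairs for enrichment of their *common*
    targets in one component's loads; Bonferroni over the pairs actually
    tested. Pairs with an empty target intersection are skipped (logged)."""
    if not (0 <= ic < decomp.n_components):
        raise ValueError(f"component index {ic} out of range")
    mirna_ids = list(mirna_ids) if mirna_ids is not None else list(targets.mirna_ids)
    universe = _shared_universe(decomp.gene_ids, targets)
    uni_set = set(universe)
    pos = {g: i for i, g in enumerate(decomp.gene_ids)}
    loads = decomp.loads[np.array([pos[g] for g in universe]), ic]
    sv = ScoreVector(universe, loads, kind="ic_loads", context=f"IC{ic + 1}")

    results = []
    kept_pairs = []
    n_skipped = 0
    for m1, m2 in combinations(mirna_ids, 2):
        common = targets.targets.get(m1, set()) & targets.targets.get(m2, set()) & uni_set
        if not common or common == uni_set:
            logger.info("pair %s/%s skipped: empty or degenerate common target set", m1, m2)
            n_skipped += 1
            continue
        res = score_enrichment(sv, common, alternative="two_sided", label=f"{m1}|{m2}")
        results.append(res)
        kept_pairs.append((m1, m2))
    if results:
        q = adjust_pvalues([r.p for r in results], "bonferroni")
        for r, qi in zip(results, q):
            r.q, r.method = float(qi), "bonferroni"
    df = _results_frame(results) if results else pd.DataFrame(
        columns=["label", "n_target", "n_background", "W", "direction", "p", "q", "method"])
    df.insert(0, "mirna_1", [p[0] for p in kept_pairs])
    df.insert(1, "mirna_2", [p[1] for p in kept_pairs])
    df.attrs["n_pairs_skipped"] = n_skipped
    df.attrs["n_pairs_tested"] = len(kept_pairs)
    return df


def pathway_enrichment(
    decomp: ICADecomposition,
    targets: TargetMap,
    genesets: GeneSetCollection,
    load_threshold: float = 2.0,
    ics: Sequence[int] | None = None,
    min_mapped: int = 3,
    restrict_to_targets: bool = True,
) -> pd.DataFrame:
    """Pathway overrepresentation among miRNA targets, per component.

    The analysis universe is the union of all miRNAs' targets (flag off: the
    whole shared universe). For every component and pathway with at least
    ``min_mapped`` universe genes, the pathway genes' loads are rank-sum
    tested against the remaining universe (two-sided); the reported sign is
    positive when the pathway's median load is > 0. Genes with
    ``|load| > load_threshold`` form the pathway's driver list. BH-FDR across
    all pathway x IC tests.
    """
    shared = _shared_universe(decomp.gene_ids, targets)
    if restrict_to_targets:
        all_targets = set().union(*targets.targets.values()) if targets.targets else set()
        universe = [g for g in shared if g in all_targets]
    else:
        universe = shared
    if not universe:
        raise DegenerateHypothesisError("empty target universe for pathway analysis")
    uni_set = set(universe)
    pos = {g: i for i, g in enumerate(decomp.gene_ids)}
    uni_idx = np.array([pos[g] for g in universe])
    ics = list(ics) if ics is not None else list(range(decomp.n_components))

    rows = []
    pvals = []
    for ic in ics:
        loads = decomp.loads[uni_idx, ic]
        gene_pos = {g: i for i, g in enumerate(universe)}
        for name in genesets.names():
            mapped = genesets.genes(name) & uni_set
            if len(mapped) < min_mapped or len(mapped) == len(universe):
                logger.info("pathway %s skipped in IC%d: %d mapped genes", name, ic + 1, len(mapped))
                continue
            idx = np.array([gene_pos[g] for g in mapped])
            x = loads[idx]
            mask = np.zeros(len(universe), bool)
            mask[idx] = True
            W, p = wilcoxon_rank_sum(x, loads[~mask], alternative="two_sided")
            med = float(np.median(x))
            sign = "positive" if med > 0 else "negative"
            drivers = sorted(g for g in mapped if abs(loads[gene_pos[g]]) > load_threshold)
            rows.append({
                "pathway": name,
                "ic": f"IC{ic + 1}",
                "sign": sign,
                "n_pathway": len(mapped),
                "n_background": len(universe) - len(mapped),
                "W": W,
                "median_load": med,
                "p": p,
                "drivers": ",".join(drivers),
            })
            pvals.append(p)
    df = pd.DataFrame(rows, columns=["pathway", "ic", "sign", "n_pathway", "n_background",
                                     "W", "median_load", "p", "drivers"])
    if len(df):
        df["q"] = adjust_pvalues(pvals, "bh_fdr")
        df["method"] = "fdr"
    else:
        df["q"] = []
        df["method"] = []
    return df.sort_values(["q", "p"], kind="stable").reset_index(drop=True)


def foldchange_validation(
    fold_changes: ScoreVector,
    targets: TargetMap,
    mirna_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Test each miRNA's targets for enrichment in an external fold-change
    vector (two-sided, direction reported), BH-FDR across miRNAs."""
    mirna_ids = list(mirna_ids) if mirna_ids is not None else list(targets.mirna_ids)
    shared_ids = [g for g in fold_changes.gene_ids if g in targets.gene_universe]
    if len(shared_ids) < len(fold_changes.gene_ids):
        logger.info("fold-change universe restricted to %d genes with UTRs", len(shared_ids))
    gpos = {g: i for i, g in enumerate(fold_changes.gene_ids)}
    sv = ScoreVector(shared_ids, fold_changes.values[[gpos[g] for g in shared_ids]],
                     kind="fold_change", context=fold_changes.context)
    shared = set(shared_ids)
    results = []
    kept = []
    for m in mirna_ids:
        tset = targets.targets.get(m, set()) & shared
        if not tset or tset == shared:
            logger.warning("miRNA %s skipped in fold-change validation", m)
            continue
        results.append(score_enrichment(sv, tset, alternative="two_sided", label=m))
        kept.append(m)
    if not results:
        raise DegenerateHypothesisError("no testable miRNAs for fold-change validation")
    q = adjust_pvalues([r.p for r in results], "bh_fdr")
    for r, qi in zip(results, q):
        r.q, r.method = float(qi), "fdr"
    df = _results_frame(results)
    df.insert(0, "mirna_id", kept)
    return df
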