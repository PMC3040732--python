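"""Least-squares representation of miRNA expression profiles as linear
superpositions of component mixes.

Each profile is regressed (no intercept by default) on the selected mix rows;
coefficients are rescaled to absolute sum 1 and fit quality is reported as
percent variance explained, 100 * R^2 with the total sum of squares taken
about the profile mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix
from .ica_core import ICADecomposition

logger = logging.getLogger(__name__)


class CollinearityWarning(UserWarning):
    pass


@dataclass
class SuperpositionFit:
    mirna_id: str
    coefficients: np.ndarray       # scaled to sum(|c|) = 1 (unless all-zero)
    raw_coefficients: np.ndarray   # unscaled least-squares solution
    r_squared: float               # NaN when undefined (zero/constant profile)
    variance_explained_pct: float
    ic_indices: list
    undefined: bool = False


def fit_superposition(
    mirna_profile: Sequence[float],
    mixes: np.ndarray,
    ic_subset: Sequence[int] | None = None,
    intercept: bool = False,
    mirna_id: str = "",
) -> SuperpositionFit:
    """Fit ``profile ~= sum_t c_t * mix_t`` by ordinary least squares.

    A rank-deficient design yields the minimum-norm solution with a
    ``CollinearityWarning``. A zero profile skips the abs-sum-1 scaling and
    reports R^2 as undefined (NaN).
    """
    y = np.asarray(mirna_profile, dtype=float)
    mixes = np.asarray(mixes, dtype=float)
    idx = list(ic_subset) if ic_subset is not None else list(range(mixes.shape[0]))
    if mixes.shape[1] != y.size:
        raise ValueError("profile length does not match mix columns")
    if len(idx) > y.size:
        raise ValueError("more components than samples in the fit")
    A = mixes[idx].T  # samples x k
    if intercept:
        A = np.column_stack([A, np.ones(y.size)])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            f"rank-deficient mix rows (rank {rank} < {A.shape[1]}); "
            "returning the minimum-norm solution", CollinearityWarning,
        )
    raw = coef[: len(idx)]
    abs_sum = float(np.abs(raw).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if abs_sum == 0.0 or ss_tot == 0.0:
        return SuperpositionFit(
            mirna_id=mirna_id,
            coefficients=np.zeros(len(idx)),
            raw_coefficients=raw.copy(),
            r_squared=float("nan"),
            variance_explained_pct=float("nan"),
            ic_indices=idx,
            undefined=True,
        )
    scaled = raw / abs_sum
    resid = y - A @ coef
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
    r2 = min(1.0, max(0.0, r2))
    return SuperpositionFit(
        mirna_id=mirna_id,
        coefficients=scaled,
        raw_coefficients=raw.copy(),
        r_squared=r2,
        variance_explained_pct=100.0 * r2,
        ic_indices=idx,
    )


def fit_all_mirnas(
    mirna_matrix: ExpressionMatrix,
    decomp: ICADecomposition,
    ic_subset: Sequence[int] | None = None,
    intercept: bool = False,
) -> pd.DataFrame:
    """One superposition fit per miRNA row against the selected components
    (default: all). Returns the coefficient table, one column per component
    plus R^2 and percent variance explained."""
    missing = [s for s in decomp.sample_ids if s not in mirna_matrix.col_ids]
    extra = [s for s in mirna_matrix.col_ids if s not in decomp.sample_ids]
    if missing or extra:
        raise ValueError(
            f"sample mismatch between miRNA matrix and decomposition; "
            f"missing from miRNA matrix: {missing}, unknown: {extra}"
        )
    aligned = mirna_matrix.reorder_cols(decomp.sample_ids)
    idx = list(ic_subset) if ic_subset is not None else list(range(decomp.n_components))
    rows = []
    for i, mid in enumerate(aligned.row_ids):
        fit = fit_superposition(aligned.values[i], decomp.mixes, idx,
                                intercept=intercept, mirna_id=mid)
        row = {"mirna_id": mid}
        for j, ic in enumerate(idx):
            row[f"IC{ic + 1}"] = float(fit.coefficients[j])
        row["r_squared"] = fit.r_squared
        row["variance_explained_pct"] = fit.variance_explained_pct
        row["undefined"] = fit.undefined
        rows.append(row)
    return pd.DataFrame(rows)
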