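"""Factorial correspondence analysis (FCA) of a dominant binary marker table.

The 0/1 marker table is doubled — each marker contributes a presence and an
absence column — so every row of the indicator table sums to the number of
markers.  This is the classical treatment of dominant genotype data in FCA
software: it makes row masses equal and lets absences contribute inertia
symmetrically.  Correspondence analysis then proceeds by the generalized
SVD of the standardized residuals of the doubled table; individuals are
reported in principal coordinates, axes ordered by decreasing inertia.

Missing calls are mean-imputed per marker before doubling (logged via a
warning); an individual with every call missing cannot be placed and is an
error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import MarkerMatrix

__all__ = ["fca", "FcaResult"]


@dataclass
class FcaResult:
    coordinates: pd.DataFrame  # individuals x axes, principal coordinates
    axis_inertia_pct: np.ndarray  # per retained axis, % of total inertia
    total_inertia: float
    group_barycentres: pd.DataFrame | None = None

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def _doubled_table(m: MarkerMatrix) -> np.ndarray:
    X = m.values().copy()
    if np.isnan(X).all(axis=1).any():
        bad = np.asarray(m.individuals)[np.isnan(X).all(axis=1)]
        raise ValueError(f"individual(s) with all calls missing: {list(bad)[:5]}")
    if np.isnan(X).any():
        warnings.warn("missing calls mean-imputed per marker before FCA")
        col_mean = np.nanmean(X, axis=0)
        ind = np.where(np.isnan(X))
        X[ind] = col_mean[ind[1]]
    return np.hstack([X, 1.0 - X])


def fca(m: MarkerMatrix, n_axes: int = 2, doubled: bool = True) -> FcaResult:
    """Correspondence analysis of the (doubled) marker indicator table.

    Parameters
    ----------
    n_axes
        Number of leading axes to return; fewer are returned (with a
        warning) when the table has lower rank.
    doubled
        If False, analyse the raw 0/1 table directly instead of the
        presence+absence doubled table.

    Returns
    -------
    FcaResult with individual principal coordinates, per-axis inertia
    percentages (over *all* non-null axes, so they sum to 100 across the
    full spectrum) and group barycentres when group labels are present.
    """
    N = _doubled_table(m) if doubled else m.values().copy()
    if not doubled and np.isnan(N).any():
        warnings.warn("missing calls mean-imputed per marker before FCA")
        col_mean = np.nanmean(N, axis=0)
        ind = np.where(np.isnan(N))
        N[ind] = col_mean[ind[1]]
    total = N.sum()
    if total <= 0:
        raise ValueError("indicator table has zero mass")
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    keep_cols = c > 0
    P, c = P[:, keep_cols], c[keep_cols]
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    tol = max(S.shape) * np.finfo(float).eps * (sv[0] if len(sv) else 0.0)
    nz = sv > max(tol, 1e-12)
    sv, U = sv[nz], U[:, nz]
    inertias = sv**2
    total_inertia = float(inertias.sum())
    if total_inertia == 0:
        raise ValueError("table carries no inertia (all rows identical)")
    k = min(n_axes, len(sv))
    if k < n_axes:
        warnings.warn(f"only {k} informative axes available (requested {n_axes})")
    # row principal coordinates
    F = (U * sv) / np.sqrt(r)[:, None]
    coords = pd.DataFrame(
        F[:, :k], index=m.individuals, columns=[f"axis{i+1}" for i in range(k)]
    )
    pct = 100.0 * inertias / total_inertia
    bary = None
    if m.group_labels is not None:
        bary = coords.groupby(m.group_labels).mean()
    return FcaResult(coords, pct, total_inertia, bary)
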