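"""Post-processing of Bayesian clustering output: Evanno's delta-K, entropy
based admixture decomposition, and membership classification.

Inputs are plain tables rather than raw clustering-program output: a run
table of (K, run, lnP) replicate log-likelihoods and a Q matrix of
per-individual membership proportions (rows sum to 1).

delta-K is the absolute second difference of the mean log-likelihood across
consecutive K, standardized by the between-run standard deviation at K:

    dK(K) = |mean lnP(K+1) - 2 mean lnP(K) + mean lnP(K-1)| / sd(lnP(K))

The admixture of an individual is the Shannon entropy of its membership row
(zero when fully assigned, maximal when uniform).  For a labeled group,
Sh_total is the entropy of the group's mean membership row and Sh_mean the
mean of member entropies; concavity guarantees Sh_mean <= Sh_total, and the
gap splits the group's admixture into a within-individual share
(100 * Sh_mean / Sh_total) and an among-individual share (the complement).
The split is invariant to the entropy log base (default base 10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "read_q_matrix",
    "read_run_likelihoods",
    "delta_k",
    "admixture_shannon",
    "admixture_split",
    "admixture_decomposition",
    "classify_membership",
]

_LOG = {2: math.log(2), "e": 1.0, 10: math.log(10)}


def read_q_matrix(path) -> pd.DataFrame:
    """Read a Q-matrix TSV (columns: individual, q1..qK) into a validated frame."""
    q = pd.read_csv(path, sep="\t").set_index("individual")
    _validate_q(q)
    return q


def _validate_q(q: pd.DataFrame) -> None:
    vals = q.to_numpy(dtype=float)
    if (vals < -1e-9).any() or (vals > 1 + 1e-9).any():
        raise ValueError("membership proportions must lie in [0, 1]")
    rows = vals.sum(axis=1)
    if np.abs(rows - 1.0).max() > 1e-6:
        bad = q.index[np.argmax(np.abs(rows - 1.0))]
        raise ValueError(f"membership rows must sum to 1; row {bad!r} sums to {rows.max():.6f}")


def read_run_likelihoods(path) -> pd.DataFrame:
    """Read a run-likelihood TSV with columns K, run, lnP."""
    return pd.read_csv(path, sep="\t")[["K", "run", "lnP"]]


def delta_k(runs: pd.DataFrame) -> pd.DataFrame:
    """Evanno's delta-K table from replicate log-likelihoods.

    Returns a frame indexed by K with ``mean_lnP``, ``sd_lnP`` and
    ``delta_K``; endpoints of the K range, and any K whose between-run sd is
    zero, carry NaN delta-K (a zero sd leaves the statistic undefined rather
    than infinite).
    """
    g = runs.groupby("K")["lnP"]
    mean, sd = g.mean(), g.std(ddof=1)
    ks = sorted(mean.index)
    if len(ks) < 3:
        raise ValueError("delta-K needs at least three K values")
    if ks != list(range(min(ks), max(ks) + 1)):
        raise ValueError("K values must form a contiguous range")
    dk = pd.Series(np.nan, index=ks, dtype=float)
    for k in ks[1:-1]:
        second = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
        if sd[k] and sd[k] > 0 and not np.isnan(sd[k]):
            dk[k] = second / sd[k]
    out = pd.DataFrame({"mean_lnP": mean, "sd_lnP": sd, "delta_K": dk})
    out.index.name = "K"
    return out


def _entropy(p: np.ndarray, log_base) -> float:
    p = np.asarray(p, dtype=float)
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum() / _LOG[log_base])


def admixture_shannon(q: pd.DataFrame, log_base=10) -> pd.Series:
    """Per-individual Shannon entropy of membership proportions."""
    _validate_q(q)
    vals = q.to_numpy(dtype=float)
    return pd.Series([_entropy(row, log_base) for row in vals], index=q.index, name="sh")


def admixture_split(sh_total: float, sh_mean: float) -> tuple[float, float]:
    """Decompose a group's admixture entropy into (within_pct, among_pct).

    within = 100 * Sh_mean / Sh_total, among = 100 * (Sh_total - Sh_mean) /
    Sh_total.  Undefined (NaN, NaN) when Sh_total is 0 — every member fully
    assigned to one common cluster.
    """
    if sh_total == 0:
        return (float("nan"), float("nan"))
    within = 100.0 * sh_mean / sh_total
    return (within, 100.0 - within)


def admixture_decomposition(q: pd.DataFrame, groups, log_base=10) -> pd.DataFrame:
    """Per-group admixture decomposition.

    Returns a frame indexed by group with ``n``, ``sh_total`` (entropy of the
    mean membership row), ``sh_mean`` (mean member entropy), ``within_pct``
    and ``among_pct``.
    """
    _validate_q(q)
    labels = pd.Series(groups)
    missing = set(q.index) - set(labels.index)
    if missing:
        raise ValueError(f"unlabeled individuals: {sorted(missing)[:5]}")
    labels = labels.loc[q.index]
    per_ind = admixture_shannon(q, log_base)
    rows = []
    for g, members in q.groupby(labels):
        sh_total = _entropy(members.mean(axis=0).to_numpy(), log_base)
        sh_mean = float(per_ind.loc[members.index].mean())
        within, among = admixture_split(sh_total, sh_mean)
        rows.append(
            {"group": g, "n": len(members), "sh_total": sh_total,
             "sh_mean": sh_mean, "within_pct": within, "among_pct": among}
        )
    return pd.DataFrame(rows).set_index("group")


def classify_membership(
    q: pd.DataFrame,
    rep_threshold: float = 0.90,
    mixed_threshold: float = 0.75,
) -> pd.DataFrame:
    """Classify individuals by their largest membership proportion.

    strictly above ``rep_threshold`` -> representative of the argmax cluster;
    in [``mixed_threshold``, ``rep_threshold``] -> intermediate;
    below ``mixed_threshold`` -> mixed (no cluster assigned).
    """
    if not rep_threshold > mixed_threshold:
        raise ValueError("rep_threshold must exceed mixed_threshold")
    _validate_q(q)
    vals = q.to_numpy(dtype=float)
    qmax = vals.max(axis=1)
    amax = vals.argmax(axis=1)
    cluster_names = list(q.columns)
    cls, assigned = [], []
    for mx, am in zip(qmax, amax):
        if mx > rep_threshold:
            cls.append("representative")
            assigned.append(cluster_names[am])
        elif mx >= mixed_threshold:
            cls.append("intermediate")
            assigned.append(cluster_names[am])
        else:
            cls.append("mixed")
            assigned.append(None)
    return pd.DataFrame(
        {"max_q": qmax, "class": cls, "cluster": assigned}, index=q.index
    )
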