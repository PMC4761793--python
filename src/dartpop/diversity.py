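"""Per-locus and per-group diversity indices for dominant biallelic markers.

For an inbred panel the band-presence frequency f at a locus is the allele
frequency, and the four classical indices reduce to closed forms in f
(q = 1 - f):

    Sh  = -(f log f + q log q)           Shannon diversity (default log base 2)
    Ne  = 1 / (f^2 + q^2)                effective number of alleles
    He  = 1 - f^2 - q^2                  expected heterozygosity (gene diversity)
    PIC = 1 - (f^2 + q^2) - 2 f^2 q^2    polymorphic information content

Group summaries report per-locus means plus the percentage of polymorphic
loci and a rarity index RI_j = (1/I) sum_i p_ij / P_i, the mean over loci of
the group frequency divided by the whole-dataset frequency: RI > 1 marks a
group enriched for globally rare bands.  The size-weighted mean of RI over
the groups of any partition is identically 1 when no calls are missing.

Group comparisons use a locus-paired permutation test in place of a
repeated-measures ANOVA: loci are the paired units and the null (no group
effect given locus) is built by flipping group assignment independently
per locus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import MarkerMatrix

__all__ = [
    "locus_diversity",
    "group_diversity",
    "rarity_index",
    "compare_group_diversity",
    "diversity_indices",
]

_LOG = {2: math.log(2), "e": 1.0, 10: math.log(10)}


def _log_scale(log_base) -> float:
    try:
        return _LOG[log_base]
    except KeyError:
        raise ValueError(f"log_base must be one of 2, 'e', 10; got {log_base!r}")


def diversity_indices(f: np.ndarray, log_base=2) -> dict[str, np.ndarray]:
    """Vectorised closed forms of Sh, Ne, He and PIC at presence frequency ``f``.

    Frequencies of 0 or 1 yield Sh=He=PIC=0 and Ne=1 (0*log0 = 0).
    NaN frequencies propagate.
    """
    f = np.asarray(f, dtype=float)
    q = 1.0 - f
    scale = _log_scale(log_base)
    with np.errstate(divide="ignore", invalid="ignore"):
        sh = -(np.where(f > 0, f * np.log(f), 0.0) + np.where(q > 0, q * np.log(q), 0.0)) / scale
    sh = np.where(np.isnan(f), np.nan, sh)
    homo = f**2 + q**2
    ne = 1.0 / homo
    he = 1.0 - homo
    # clip guards against ~1e-246 negatives when f underflows near 0 or 1
    pic = np.clip(1.0 - homo - 2.0 * f**2 * q**2, 0.0, None)
    return {"sh": sh, "ne": ne, "he": he, "pic": pic}


def locus_diversity(
    m: MarkerMatrix,
    subset: list[str] | None = None,
    log_base=2,
) -> pd.DataFrame:
    """Per-marker diversity table over ``subset`` (default: all individuals).

    Returns a DataFrame indexed by marker with columns ``f, sh, ne, he, pic,
    polymorphic``.  Markers unscored in every subset individual carry NaN
    indices and ``polymorphic=False``; they are excluded from any means
    taken downstream.
    """
    if subset is not None and len(subset) == 0:
        raise ValueError("subset must be non-empty")
    f = m.presence_frequencies(subset)
    idx = diversity_indices(f.to_numpy(), log_base)
    fv = f.to_numpy()
    poly = (fv > 0) & (fv < 1)
    return pd.DataFrame(
        {"f": fv, **idx, "polymorphic": np.where(np.isnan(fv), False, poly)},
        index=f.index,
    )


def rarity_index(m: MarkerMatrix, level: str = "group") -> dict[str, float]:
    """Rarity index RI_j per group: mean over loci of p_ij / P_i.

    P_i is the presence frequency of marker i in the whole dataset; markers
    with P_i = 0 (or unscored overall) are skipped, shrinking the locus count
    I accordingly.  A marker unscored within a group is likewise skipped for
    that group.
    """
    groups = m.groups(level)
    total_f = m.presence_frequencies().to_numpy()
    usable = ~np.isnan(total_f) & (total_f > 0)
    out: dict[str, float] = {}
    for g, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"group {g!r} is empty")
        pf = m.presence_frequencies(members).to_numpy()
        ok = usable & ~np.isnan(pf)
        if not ok.any():
            raise ValueError(f"group {g!r} has no scorable markers")
        out[g] = float(np.mean(pf[ok] / total_f[ok]))
    return out


def group_diversity(
    m: MarkerMatrix,
    level: str = "group",
    log_base=2,
    include_monomorphic: bool = True,
) -> pd.DataFrame:
    """Per-group diversity summary (one row per group, plus a Total row).

    Columns mirror the standard report layout: n, %P, mean Sh/Ne/He/PIC and
    RI.  ``%P`` is the percentage of analyzed markers with both states
    observed within the group.  By default means run over all analyzable
    loci, monomorphic ones contributing their zero (Ne: one) values;
    ``include_monomorphic=False`` restricts means to loci polymorphic within
    the group.
    """
    groups = m.groups(level)
    ri = rarity_index(m, level)
    rows = []
    for g, members in groups.items():
        if len(members) == 1:
            warnings.warn(f"group {g!r} has a single individual; indices are unreliable")
        tab = locus_diversity(m, members, log_base)
        analyzed = tab.dropna(subset=["f"])
        use = analyzed[analyzed["polymorphic"]] if not include_monomorphic else analyzed
        rows.append(
            {
                "group": g,
                "n": len(members),
                "pct_polymorphic": 100.0 * analyzed["polymorphic"].mean(),
                "sh_mean": use["sh"].mean(),
                "ne_mean": use["ne"].mean(),
                "he_mean": use["he"].mean(),
                "pic_mean": use["pic"].mean(),
                "ri": ri[g],
            }
        )
    tab = locus_diversity(m, None, log_base)
    analyzed = tab.dropna(subset=["f"])
    use = analyzed[analyzed["polymorphic"]] if not include_monomorphic else analyzed
    rows.append(
        {
            "group": "Total",
            "n": m.n_individuals,
            "pct_polymorphic": 100.0 * analyzed["polymorphic"].mean(),
            "sh_mean": use["sh"].mean(),
            "ne_mean": use["ne"].mean(),
            "he_mean": use["he"].mean(),
            "pic_mean": use["pic"].mean(),
            "ri": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("group")


def _paired_permutation_p(a: np.ndarray, b: np.ndarray, n_perm: int, rng) -> float:
    """Two-sided locus-paired permutation p for mean(a - b) = 0.

    Flips the sign of each per-locus difference independently (equivalent to
    swapping the two group values at that locus).  Uses the +1 correction.
    """
    diff = a - b
    obs = abs(diff.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_perm, diff.size))
    null = np.abs((signs * diff).mean(axis=1))
    return (np.count_nonzero(null >= obs - 1e-12) + 1) / (n_perm + 1)


@dataclass
class GroupComparison:
    index: str
    pairs: pd.DataFrame  # columns: group1, group2, observed_diff, p_raw, p_bonferroni


def compare_group_diversity(
    m: MarkerMatrix,
    index: str = "he",
    level: str = "group",
    n_perm: int = 10_000,
    seed: int = 0,
    log_base=2,
) -> GroupComparison:
    """Pairwise locus-paired permutation comparison of a diversity index.

    For every pair of groups the observed statistic is the mean over loci of
    the within-locus difference of the chosen index; the null permutes group
    identity independently within each locus.  Raw p-values are
    Bonferroni-adjusted by the number of pairs (capped at 1).
    """
    if index not in {"sh", "ne", "he", "pic"}:
        raise ValueError(f"unknown index {index!r}")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low; p-value resolution will be poor")
    groups = m.groups(level)
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups to compare")
    per_group = {
        g: locus_diversity(m, members, log_base)[index].to_numpy()
        for g, members in groups.items()
    }
    rng = np.random.default_rng(seed)
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = per_group[names[i]], per_group[names[j]]
            ok = ~np.isnan(a) & ~np.isnan(b)
            p = _paired_permutation_p(a[ok], b[ok], n_perm, rng)
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "observed_diff": float((a[ok] - b[ok]).mean()),
                    "p_raw": p,
                    "p_bonferroni": min(1.0, p * n_pairs),
                }
            )
    return GroupComparison(index, pd.DataFrame(rows))
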