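"""Analysis of molecular variance (AMOVA) for binary marker data.

AMOVA partitions the total sum of squared pairwise genetic distances into
hierarchical variance components by the method of moments.  For a set S of
individuals the sum of squared deviations is taken directly from the
squared-distance matrix,

    SSD(S) = (1 / |S|) * sum_{i<j in S} d2[i, j],

and the one-level decomposition is SSD(total) = SSD(among groups) +
SSD(within groups).  With G groups of sizes n_g (N total) the expected mean
squares give

    sigma2_w = SSD(within) / (N - G)
    sigma2_a = (SSD(among) / (G - 1) - sigma2_w) / n'
    n' = (N - sum(n_g^2) / N) / (G - 1)          (average group size
                                                  corrected for unequal n_g)

and Phi_ST = sigma2_a / (sigma2_a + sigma2_w).  The two-level (region /
group / individual) design adds the among-region stratum with the analogous
coefficients (below) and the statistics Phi_CT (among regions), Phi_SC
(among groups within regions) and Phi_ST (groups + regions jointly).

Significance is assessed by non-parametric permutation with the scheme
appropriate to each statistic: Phi_ST permutes individuals among groups over
the whole set, Phi_SC permutes individuals among groups within their region,
Phi_CT permutes whole groups among regions.  P-values use the +1 correction,
p = (#{Phi_perm >= Phi_obs} + 1) / (n_perm + 1).

Negative variance-component estimates are reported as computed (they arise
whenever the true component is near zero); percentages of total variance are
taken over the signed total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .markers import MarkerMatrix

__all__ = [
    "amova_distance",
    "amova_one_level",
    "amova_two_level",
    "pairwise_phi",
    "AmovaResult",
    "PairwisePhiMatrix",
]


@dataclass
class AmovaResult:
    strata: pd.DataFrame  # source, df, ssd, sigma2, pct_total
    phi: dict[str, float]
    p_values: dict[str, float]
    n_perm: int
    seed: int | None = None

    def to_table(self) -> pd.DataFrame:
        """Report table in the conventional layout (df, variance components,
        % total variance, Phi, P)."""
        tab = self.strata.copy()
        phi_col, p_col = [], []
        order = ["phi_CT", "phi_SC", "phi_ST"]
        keys = [k for k in order if k in self.phi] or list(self.phi)
        for i in range(len(tab)):
            if i < len(keys):
                phi_col.append(self.phi[keys[i]])
                p_col.append(self.p_values.get(keys[i], np.nan))
            else:
                phi_col.append(np.nan)
                p_col.append(np.nan)
        tab["phi"] = phi_col
        tab["P"] = p_col
        return tab


@dataclass
class PairwisePhiMatrix:
    labels: list[str]
    phi: np.ndarray
    p: np.ndarray

    def to_table(self) -> pd.DataFrame:
        """Lower triangle Phi_ST, upper triangle permutation P."""
        k = len(self.labels)
        out = np.full((k, k), np.nan)
        iu, il = np.triu_indices(k, 1), np.tril_indices(k, -1)
        out[il] = self.phi[il]
        out[iu] = self.p[iu]
        return pd.DataFrame(out, index=self.labels, columns=self.labels)


def amova_distance(m: MarkerMatrix) -> DistanceMatrix:
    """Squared inter-individual distance: count of mismatching loci.

    The mismatch (Hamming) count over loci scored in both individuals is the
    standard squared Euclidean distance for binary data and the metric AMOVA
    expects.  No rescaling for missingness by default.
    """
    if m.n_individuals < 2:
        raise ValueError("need at least two individuals")
    X = m.values()
    obs = ~np.isnan(X)
    Xz = np.where(obs, X, 0.0)
    o = obs.astype(float)
    # mismatches = presences in i scored in j  +  presences in j scored in i
    #              - 2 * joint presences
    joint = Xz @ Xz.T
    d2 = (Xz * o) @ o.T + o @ (Xz * o).T - 2 * joint
    n_shared = o @ o.T
    if (n_shared == 0).any():
        i, j = np.argwhere(n_shared == 0)[0]
        raise ValueError(
            f"individuals {m.individuals[i]!r} and {m.individuals[j]!r} share no scored loci"
        )
    np.fill_diagonal(d2, 0.0)
    d2 = (d2 + d2.T) / 2.0
    return DistanceMatrix(d2, ids=m.individuals)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _codes(labels, ids) -> np.ndarray:
    s = pd.Series(labels)
    missing = [i for i in ids if i not in s.index]
    if missing:
        raise ValueError(f"no group label for individuals: {missing[:5]}")
    return pd.Categorical(s.loc[list(ids)]).codes.astype(np.int64)


def _ssd_total(d2: np.ndarray) -> float:
    n = d2.shape[0]
    return float(d2.sum()) / (2.0 * n)


def _ssd_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ssd = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            ssd += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ssd


def _one_level_components(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    n = d2.shape[0]
    sizes = np.bincount(codes, minlength=n_groups).astype(float)
    ssd_t = _ssd_total(d2)
    ssd_w = _ssd_within(d2, codes, n_groups)
    ssd_a = ssd_t - ssd_w
    df_a, df_w = n_groups - 1, n - n_groups
    sigma_w = ssd_w / df_w if df_w > 0 else 0.0
    n_prime = (n - (sizes**2).sum() / n) / df_a
    sigma_a = (ssd_a / df_a - sigma_w) / n_prime
    return ssd_t, ssd_a, ssd_w, sigma_a, sigma_w


def _phi_st_one_level(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    _, _, _, sa, sw = _one_level_components(d2, codes, n_groups)
    tot = sa + sw
    return sa / tot if tot != 0 else 0.0


def _distinct_label_arrangements(codes: np.ndarray):
    """All distinct assignments of the label multiset to positions."""
    seen = set()
    for p in permutations(codes.tolist()):
        if p not in seen:
            seen.add(p)
            yield np.asarray(p, dtype=np.int64)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def amova_one_level(
    d: DistanceMatrix,
    groups,
    n_perm: int = 10_000,
    seed: int = 0,
    exact: bool = False,
) -> AmovaResult:
    """One-level AMOVA: among vs within groups, with a Phi_ST permutation test.

    Parameters
    ----------
    d
        Squared-distance matrix (e.g. from :func:`amova_distance`).
    groups
        Mapping or Series individual -> group label covering every id in ``d``.
    exact
        Enumerate every distinct assignment of the observed label multiset
        instead of Monte-Carlo sampling (feasible only for small N); the
        exact p-value is #{Phi_perm >= Phi_obs} / #arrangements.
    """
    d2 = d.data
    codes = _codes(groups, d.ids)
    n_groups = int(codes.max()) + 1
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if np.bincount(codes).min() < 1:
        raise ValueError("every group needs at least one member")

    ssd_t, ssd_a, ssd_w, sigma_a, sigma_w = _one_level_components(d2, codes, n_groups)
    n = d2.shape[0]
    phi = sigma_a / (sigma_a + sigma_w) if (sigma_a + sigma_w) != 0 else 0.0

    if exact:
        vals = np.array(
            [_phi_st_one_level(d2, p, n_groups) for p in _distinct_label_arrangements(codes)]
        )
        p_val = float(np.count_nonzero(vals >= phi - 1e-12) / len(vals))
        n_used = len(vals)
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        perm = codes.copy()
        for _ in range(n_perm):
            rng.shuffle(perm)
            if _phi_st_one_level(d2, perm, n_groups) >= phi - 1e-12:
                hits += 1
        p_val = (hits + 1) / (n_perm + 1)
        n_used = n_perm

    total = sigma_a + sigma_w
    strata = pd.DataFrame(
        {
            "source": ["Among groups", "Within groups"],
            "df": [n_groups - 1, n - n_groups],
            "ssd": [ssd_a, ssd_w],
            "sigma2": [sigma_a, sigma_w],
            "pct_total": [100 * sigma_a / total, 100 * sigma_w / total],
        }
    )
    return AmovaResult(strata, {"phi_ST": phi}, {"phi_ST": p_val}, n_used, seed)


def _two_level_components(d2, g_codes, r_codes, n_groups, n_regions):
    n = d2.shape[0]
    g_sizes = np.bincount(g_codes, minlength=n_groups).astype(float)
    r_sizes = np.bincount(r_codes, minlength=n_regions).astype(float)
    region_of_group = np.full(n_groups, -1, dtype=np.int64)
    for g in range(n_groups):
        rs = np.unique(r_codes[g_codes == g])
        if len(rs) != 1:
            raise ValueError("non-nested design: a group spans multiple regions")
        region_of_group[g] = rs[0]

    ssd_t = _ssd_total(d2)
    ssd_wg = _ssd_within(d2, g_codes, n_groups)
    ssd_wr = _ssd_within(d2, r_codes, n_regions)
    ssd_ag = ssd_wr - ssd_wg  # among groups within regions
    ssd_ar = ssd_t - ssd_wr  # among regions

    df_ar = n_regions - 1
    df_ag = n_groups - n_regions
    df_wg = n - n_groups

    # method-of-moments size coefficients for the nested design
    sum_g2_over_r = sum(
        (g_sizes[region_of_group == r] ** 2).sum() / r_sizes[r] for r in range(n_regions)
    )
    n1 = (n - sum_g2_over_r) / df_ag if df_ag > 0 else np.nan
    n2 = (sum_g2_over_r - (g_sizes**2).sum() / n) / df_ar
    n3 = (n - (r_sizes**2).sum() / n) / df_ar

    sigma_c = ssd_wg / df_wg if df_wg > 0 else 0.0
    sigma_b = (ssd_ag / df_ag - sigma_c) / n1 if df_ag > 0 else 0.0
    sigma_a = (ssd_ar / df_ar - sigma_c - n2 * sigma_b) / n3
    return ssd_t, ssd_ar, ssd_ag, ssd_wg, sigma_a, sigma_b, sigma_c, region_of_group


def amova_two_level(
    d: DistanceMatrix,
    groups,
    regions,
    n_perm: int = 10_000,
    seed: int = 0,
) -> AmovaResult:
    """Two-level hierarchical AMOVA (regions / groups within regions / individuals).

    Degenerate nesting with exactly one group per region collapses the
    among-groups-within-regions stratum: Phi_SC is 0 by convention and
    Phi_CT equals the one-level Phi_ST among regions.
    """
    d2 = d.data
    g_codes = _codes(groups, d.ids)
    r_codes = _codes(regions, d.ids)
    n_groups = int(g_codes.max()) + 1
    n_regions = int(r_codes.max()) + 1
    if n_regions < 2:
        raise ValueError("need at least two regions")
    n = d2.shape[0]

    (ssd_t, ssd_ar, ssd_ag, ssd_wg, sigma_a, sigma_b, sigma_c, region_of_group) = (
        _two_level_components(d2, g_codes, r_codes, n_groups, n_regions)
    )
    degenerate = n_groups == n_regions  # one group per region
    if degenerate:
        sigma_b = 0.0

    total = sigma_a + sigma_b + sigma_c
    phi_ct = sigma_a / total if total != 0 else 0.0
    phi_st = (sigma_a + sigma_b) / total if total != 0 else 0.0
    phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 and not degenerate else 0.0

    rng = np.random.default_rng(seed)

    def stat_ct(gc, rc):
        *_, sa, sb, sc, _ = _two_level_components(d2, gc, rc, n_groups, n_regions)
        tot = sa + sb + sc
        return sa / tot if tot != 0 else 0.0

    # Phi_ST: permute individuals over the whole set (keep labels paired)
    hits_st = 0
    idx = np.arange(n)
    for _ in range(n_perm):
        rng.shuffle(idx)
        gc, rc = g_codes[idx], r_codes[idx]
        *_, sa, sb, sc, _ = _two_level_components(d2, gc, rc, n_groups, n_regions)
        tot = sa + sb + sc
        if (sa + sb) / tot >= phi_st - 1e-12 if tot != 0 else phi_st <= 0:
            hits_st += 1

    # Phi_SC: permute individuals among groups within each region
    hits_sc = 0
    if not degenerate:
        for _ in range(n_perm):
            gc = g_codes.copy()
            for r in range(n_regions):
                sel = np.flatnonzero(r_codes == r)
                gc[sel] = gc[sel[rng.permutation(len(sel))]]
            *_, sa, sb, sc, _ = _two_level_components(d2, gc, r_codes, n_groups, n_regions)
            val = sb / (sb + sc) if (sb + sc) != 0 else 0.0
            if val >= phi_sc - 1e-12:
                hits_sc += 1

    # Phi_CT: permute whole groups among regions (preserving group sizes)
    hits_ct = 0
    group_region = region_of_group.copy()
    for _ in range(n_perm):
        perm_regions = group_region[rng.permutation(n_groups)]
        rc = perm_regions[g_codes]
        if stat_ct(g_codes, rc) >= phi_ct - 1e-12:
            hits_ct += 1

    p = lambda h: (h + 1) / (n_perm + 1)
    strata = pd.DataFrame(
        {
            "source": [
                "Among regions",
                "Among groups within regions",
                "Within groups",
            ],
            "df": [n_regions - 1, n_groups - n_regions, n - n_groups],
            "ssd": [ssd_ar, ssd_ag, ssd_wg],
            "sigma2": [sigma_a, sigma_b, sigma_c],
            "pct_total": [
                100 * sigma_a / total,
                100 * sigma_b / total,
                100 * sigma_c / total,
            ],
        }
    )
    phi_map = {"phi_CT": phi_ct, "phi_SC": phi_sc, "phi_ST": phi_st}
    p_map = {"phi_CT": p(hits_ct), "phi_SC": p(hits_sc) if not degenerate else np.nan,
             "phi_ST": p(hits_st)}
    return AmovaResult(strata, phi_map, p_map, n_perm, seed)


def pairwise_phi(
    d: DistanceMatrix,
    groups,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PairwisePhiMatrix:
    """Pairwise Phi_ST between all group pairs, each from a one-level AMOVA
    restricted to the two groups' individuals.

    Negative estimates are retained as computed.  Single-member groups are
    allowed but flagged with a warning (the within-group component is then
    poorly estimated).
    """
    import warnings

    codes = _codes(groups, d.ids)
    s = pd.Series(groups)
    labels = list(pd.Categorical(s.loc[list(d.ids)]).categories)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes, minlength=k)
    if sizes.min() == 1:
        warnings.warn("group(s) of size 1: pairwise Phi_ST entries involving them are unreliable")
    ids = np.asarray(d.ids)
    phi = np.zeros((k, k))
    pvals = np.zeros((k, k))
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            sel = np.flatnonzero((codes == i) | (codes == j))
            sub = DistanceMatrix(d.data[np.ix_(sel, sel)], ids=[str(x) for x in ids[sel]])
            sub_groups = pd.Series(codes[sel].astype(str), index=[str(x) for x in ids[sel]])
            res = amova_one_level(sub, sub_groups, n_perm=n_perm,
                                  seed=int(rng.integers(0, 2**31 - 1)))
            phi[i, j] = phi[j, i] = res.phi["phi_ST"]
            pvals[i, j] = pvals[j, i] = res.p_values["phi_ST"]
    return PairwisePhiMatrix(labels, phi, pvals)
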