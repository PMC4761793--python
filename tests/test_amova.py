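"""AMOVA variance components, Phi-statistics and permutation tests against
direct brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from dartpop import (
    MarkerMatrix,
    amova_distance,
    amova_one_level,
    amova_two_level,
    pairwise_phi,
)
from .conftest import random_marker_matrix


# ---------------------------------------------------------------------------
# brute-force oracle: every SSD term straight from the definitions
# ---------------------------------------------------------------------------

def ssd(d2, idx):
    idx = list(idx)
    total = 0.0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            total += d2[idx[a], idx[b]]
    return total / len(idx)


def oracle_one_level(d2, labels):
    n = d2.shape[0]
    groups = sorted(set(labels))
    ssd_t = ssd(d2, range(n))
    ssd_w = sum(ssd(d2, [i for i in range(n) if labels[i] == g]) for g in groups)
    ssd_a = ssd_t - ssd_w
    g = len(groups)
    sizes = [labels.count(x) for x in groups]
    sigma_w = ssd_w / (n - g)
    n_prime = (n - sum(s * s for s in sizes) / n) / (g - 1)
    sigma_a = (ssd_a / (g - 1) - sigma_w) / n_prime
    phi = sigma_a / (sigma_a + sigma_w)
    return ssd_t, ssd_a, ssd_w, sigma_a, sigma_w, phi


def _mm(rows, groups, regions=None):
    calls = pd.DataFrame(rows, dtype=float)
    calls.index = [f"i{k}" for k in range(len(rows))]
    calls.columns = [f"m{k}" for k in range(len(rows[0]))]
    g = pd.Series(groups, index=calls.index)
    r = None if regions is None else pd.Series(regions, index=calls.index)
    return MarkerMatrix(calls, g, r)


class TestSquaredDistance:
    def test_hand_counts(self):
        m = _mm([[1, 1, 0], [1, 0, 1]], ["a", "b"])
        assert amova_distance(m)["i0", "i1"] == 2.0

    def test_identical_and_complement(self):
        m = _mm([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]], list("aab"))
        d = amova_distance(m)
        assert d["i0", "i1"] == 0.0
        assert d["i0", "i2"] == 4.0

    def test_missing_loci_excluded(self):
        m = _mm([[1, np.nan, 0], [0, 1, 1]], ["a", "b"])
        assert amova_distance(m)["i0", "i1"] == 2.0  # m1 not jointly scored


class TestOneLevel:
    def test_toy_two_vs_two(self):
        m = _mm([[1], [1], [0], [0]], ["p1", "p1", "p2", "p2"])
        res = amova_one_level(amova_distance(m), m.group_labels, exact=True)
        assert res.strata.loc[0, "sigma2"] == pytest.approx(0.5)
        assert res.strata.loc[1, "sigma2"] == pytest.approx(0.0)
        assert res.phi["phi_ST"] == pytest.approx(1.0)
        assert res.p_values["phi_ST"] == pytest.approx(1 / 3)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            n = int(rng.integers(4, 9))
            n_groups = int(rng.integers(2, min(n, 4)))
            m = random_marker_matrix(rng, n_ind=n, n_loci=int(rng.integers(3, 10)),
                                     n_groups=n_groups)
            labels = list(m.group_labels)
            if len(set(labels)) < 2 or n - len(set(labels)) == 0:
                continue
            d = amova_distance(m)
            res = amova_one_level(d, m.group_labels, n_perm=10, seed=0)
            ssd_t, ssd_a, ssd_w, sa, sw, phi = oracle_one_level(d.data, labels)
            assert res.strata.loc[0, "ssd"] == pytest.approx(ssd_a, abs=1e-10)
            assert res.strata.loc[1, "ssd"] == pytest.approx(ssd_w, abs=1e-10)
            assert res.strata.loc[0, "sigma2"] == pytest.approx(sa, abs=1e-10)
            assert res.strata.loc[1, "sigma2"] == pytest.approx(sw, abs=1e-10)
            assert res.phi["phi_ST"] == pytest.approx(phi, abs=1e-10)
            # SSD additivity
            assert ssd_a + ssd_w == pytest.approx(ssd_t, abs=1e-10)

    def test_monte_carlo_p_matches_exact(self):
        rng = np.random.default_rng(2)
        m = random_marker_matrix(rng, n_ind=7, n_loci=6, n_groups=2)
        d = amova_distance(m)
        exact = amova_one_level(d, m.group_labels, exact=True)
        n_perm = 20_000
        mc = amova_one_level(d, m.group_labels, n_perm=n_perm, seed=1)
        p = exact.p_values["phi_ST"]
        se = np.sqrt(p * (1 - p) / n_perm)
        assert abs(mc.p_values["phi_ST"] - p) <= 3 * se + 1 / n_perm

    def test_all_one_group_rejected(self):
        m = _mm([[1], [0]], ["g", "g"])
        with pytest.raises(ValueError):
            amova_one_level(amova_distance(m), m.group_labels)


class TestTwoLevel:
    def _toy(self):
        # 2 regions x 2 groups x 2 individuals
        rng = np.random.default_rng(6)
        rows = (rng.random((8, 10)) < 0.5).astype(float).tolist()
        groups = ["g1", "g1", "g2", "g2", "g3", "g3", "g4", "g4"]
        regions = ["R1", "R1", "R1", "R1", "R2", "R2", "R2", "R2"]
        return _mm(rows, groups, regions)

    def test_ssds_match_brute_force(self):
        m = self._toy()
        d = amova_distance(m)
        res = amova_two_level(d, m.group_labels, m.region_labels, n_perm=10, seed=0)
        d2 = d.data
        labels = list(m.group_labels)
        regs = list(m.region_labels)
        ssd_t = ssd(d2, range(8))
        ssd_wg = sum(ssd(d2, [i for i in range(8) if labels[i] == g])
                     for g in sorted(set(labels)))
        ssd_wr = sum(ssd(d2, [i for i in range(8) if regs[i] == r])
                     for r in sorted(set(regs)))
        assert res.strata.loc[2, "ssd"] == pytest.approx(ssd_wg, abs=1e-10)
        assert res.strata.loc[1, "ssd"] == pytest.approx(ssd_wr - ssd_wg, abs=1e-10)
        assert res.strata.loc[0, "ssd"] == pytest.approx(ssd_t - ssd_wr, abs=1e-10)
        # df partition
        assert res.strata["df"].sum() == 7

    def test_degenerate_nesting_collapses_to_one_level(self):
        rng = np.random.default_rng(4)
        m = random_marker_matrix(rng, n_ind=8, n_loci=12, n_groups=2)
        regions = m.group_labels.map({"0": "R0", "1": "R1"})
        d = amova_distance(m)
        two = amova_two_level(d, m.group_labels, regions, n_perm=10, seed=0)
        one = amova_one_level(d, m.group_labels, n_perm=10, seed=0)
        assert two.phi["phi_SC"] == 0.0
        assert two.phi["phi_CT"] == pytest.approx(one.phi["phi_ST"], abs=1e-10)

    def test_region_effect_dominates(self):
        from dartpop import PopulationSpec, generate_markers

        spec = PopulationSpec(
            sizes=(15, 15, 15, 15), n_loci=300, fst=0.02,
            regions=("R1", "R1", "R2", "R2"), region_fst=0.25,
        )
        m, _ = generate_markers(spec, seed=9)
        res = amova_two_level(amova_distance(m), m.group_labels, m.region_labels,
                              n_perm=50, seed=0)
        assert res.phi["phi_CT"] > res.phi["phi_SC"]

    def test_non_nested_rejected(self):
        rows = [[1.0], [0.0], [1.0], [0.0]]
        calls = pd.DataFrame(rows, index=list("abcd"), columns=["m"])
        g = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        r_ok = pd.Series(["R1", "R1", "R2", "R2"], index=list("abcd"))
        m = MarkerMatrix(calls, g, r_ok)
        d = amova_distance(m)
        r_bad = pd.Series(["R1", "R2", "R1", "R2"], index=list("abcd"))
        with pytest.raises(ValueError, match="[Nn]on-nested|multiple regions"):
            amova_two_level(d, g, r_bad, n_perm=5, seed=0)


class TestPairwisePhi:
    def test_identical_copy_groups_near_zero(self):
        rng = np.random.default_rng(12)
        block = (rng.random((4, 15)) < 0.5).astype(float)
        other = (rng.random((4, 15)) < 0.5).astype(float)
        rows = np.vstack([block, block, other]).tolist()
        groups = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        m = _mm(rows, groups)
        pw = pairwise_phi(amova_distance(m), m.group_labels, n_perm=50, seed=0)
        i, j = pw.labels.index("A"), pw.labels.index("B")
        assert pw.phi[i, j] <= 0.0 + 1e-10  # identical groups: no among-variance

    def test_entries_match_independent_one_level_runs(self):
        rng = np.random.default_rng(13)
        m = random_marker_matrix(rng, n_ind=12, n_loci=20, n_groups=3)
        d = amova_distance(m)
        pw = pairwise_phi(d, m.group_labels, n_perm=20, seed=0)
        for i, gi in enumerate(pw.labels):
            for j in range(i + 1, len(pw.labels)):
                gj = pw.labels[j]
                keep = [ind for ind in m.individuals
                        if m.group_labels[ind] in (gi, gj)]
                sub = m.select_individuals(keep)
                res = amova_one_level(amova_distance(sub), sub.group_labels,
                                      n_perm=20, seed=0)
                assert pw.phi[i, j] == pytest.approx(res.phi["phi_ST"], abs=1e-10)

    def test_negative_values_retained(self):
        # two groups drawn from one population often yield small negatives
        rng = np.random.default_rng(21)
        found_negative = False
        for seed in range(30):
            m = random_marker_matrix(np.random.default_rng(seed), n_ind=10,
                                     n_loci=25, n_groups=2)
            pw = pairwise_phi(amova_distance(m), m.group_labels, n_perm=10, seed=0)
            if pw.phi[0, 1] < 0:
                found_negative = True
                break
        assert found_negative, "expected at least one negative pairwise estimate"
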