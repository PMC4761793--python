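"""Synthetic data with known truth: marker matrices, Q matrices and
log-likelihood curves.

Marker matrices follow the Balding-Nichols model: each locus has an
ancestral band frequency p ~ Beta(a, b); each population draws its own
frequency from Beta(p (1-F)/F, (1-p)(1-F)/F), whose mean is p and whose
variance is F p (1-p) — so F is, in expectation, the Phi_ST-scale
differentiation that AMOVA estimates (the mapping is approximate and should
be tested as an interval, not a point).  Individuals are inbred lines: one
Bernoulli draw per locus at the ancestry-mixed frequency.  Optional
admixture draws each individual's ancestry from a symmetric Dirichlet; a
nested variant draws region frequencies first and population frequencies
within regions with a second, smaller F, so a two-level AMOVA should find
Phi_CT > Phi_SC.

Two presets mirror the study designs this package targets: a two-program
panel of 63 + 26 inbred cultivars typed at 1,229 markers ("cbp") and a
seven-country panel of 523 cultivars in two regions typed at 166 markers
("ebp").

All generators are pure functions of their arguments: the same spec and
seed give bit-identical output (numpy Generator with a fixed seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MarkerMatrix

__all__ = [
    "PopulationSpec",
    "TruthRecord",
    "generate_markers",
    "generate_q_matrix",
    "generate_run_likelihoods",
    "preset",
]


@dataclass
class PopulationSpec:
    """Parameters of the marker-matrix generator.

    fst
        Balding-Nichols F between populations (0 = panmixia).
    region_fst
        When region assignments are given, F between regions; the per-pop
        ``fst`` then acts within regions and should be smaller.
    ancestral_freq_dist
        (a, b) of the Beta distribution of ancestral presence frequencies.
        The default (0.8, 0.8) gives the mildly U-shaped spectrum typical of
        genotyping-array markers after ascertainment.
    admixture_alpha
        Symmetric Dirichlet concentration for individual ancestries;
        0 means every individual belongs wholly to its population.
    """

    sizes: tuple[int, ...] = (30, 30)
    n_loci: int = 300
    fst: float = 0.05
    ancestral_freq_dist: tuple[float, float] = (0.8, 0.8)
    admixture_alpha: float = 0.0
    missing_rate: float = 0.0
    pop_names: tuple[str, ...] | None = None
    regions: tuple[str, ...] | None = None  # region of each population
    region_fst: float | None = None

    def __post_init__(self):
        if any(s <= 0 for s in self.sizes):
            raise ValueError("population sizes must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if min(self.ancestral_freq_dist) <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.regions is not None and len(self.regions) != len(self.sizes):
            raise ValueError("regions must name one region per population")


@dataclass
class TruthRecord:
    pop_freqs: np.ndarray  # n_pops x n_loci
    ancestry: np.ndarray  # n_individuals x n_pops
    spec: PopulationSpec = field(repr=False, default=None)


def _bn_draw(rng, base_freq: np.ndarray, F: float) -> np.ndarray:
    """One Balding-Nichols frequency draw around ``base_freq``."""
    if F == 0.0:
        return base_freq.copy()
    c = (1.0 - F) / F
    return rng.beta(np.clip(base_freq * c, 1e-12, None),
                    np.clip((1.0 - base_freq) * c, 1e-12, None))


def generate_markers(spec: PopulationSpec, seed: int = 0) -> tuple[MarkerMatrix, TruthRecord]:
    """Simulate a dominant binary marker matrix with known population truth."""
    rng = np.random.default_rng(seed)
    n_pops = len(spec.sizes)
    a, b = spec.ancestral_freq_dist
    p_anc = rng.beta(a, b, size=spec.n_loci)

    if spec.regions is not None and spec.region_fst is not None:
        region_names = list(dict.fromkeys(spec.regions))
        region_freqs = {r: _bn_draw(rng, p_anc, spec.region_fst) for r in region_names}
        pop_freqs = np.stack(
            [_bn_draw(rng, region_freqs[spec.regions[k]], spec.fst) for k in range(n_pops)]
        )
    else:
        pop_freqs = np.stack([_bn_draw(rng, p_anc, spec.fst) for _ in range(n_pops)])

    n_total = sum(spec.sizes)
    pop_of = np.repeat(np.arange(n_pops), spec.sizes)
    if spec.admixture_alpha > 0:
        ancestry = rng.dirichlet([spec.admixture_alpha] * n_pops, size=n_total)
        # bias each individual toward its home population
        home = np.eye(n_pops)[pop_of]
        ancestry = 0.5 * ancestry + 0.5 * home
    else:
        ancestry = np.eye(n_pops)[pop_of]

    mixed_freq = ancestry @ pop_freqs  # n_total x n_loci
    calls = (rng.random((n_total, spec.n_loci)) < mixed_freq).astype(float)
    if spec.missing_rate > 0:
        calls[rng.random(calls.shape) < spec.missing_rate] = np.nan

    pop_names = spec.pop_names or tuple(f"pop{k+1}" for k in range(n_pops))
    individuals = [f"{pop_names[p]}_{i:03d}" for i, p in enumerate(pop_of)]
    groups = pd.Series([pop_names[p] for p in pop_of], index=individuals)
    regions = None
    if spec.regions is not None:
        regions = pd.Series([spec.regions[p] for p in pop_of], index=individuals)
    calls_df = pd.DataFrame(
        calls, index=individuals, columns=[f"M{i+1:05d}" for i in range(spec.n_loci)]
    )
    m = MarkerMatrix(calls_df, groups, regions)
    return m, TruthRecord(pop_freqs, ancestry, spec)


def generate_q_matrix(
    n_individuals: int,
    K: int,
    concentration: float | dict[str, float] = 1.0,
    groups: pd.Series | None = None,
    group_bias: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a membership-proportion (Q) matrix.

    Rows are Dirichlet draws.  A scalar ``concentration`` applies to all
    individuals; with per-group concentrations (dict keyed by group label)
    and optional ``group_bias`` (group -> favoured cluster index) groups can
    be pushed toward distinct clusters: low concentration yields
    representative-like rows, high concentration near-uniform (mixed) rows.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    rng = np.random.default_rng(seed)
    if groups is None:
        groups = pd.Series(["all"] * n_individuals,
                           index=[f"ind{i:03d}" for i in range(n_individuals)])
    rows = []
    for ind in groups.index:
        g = groups[ind]
        conc = concentration[g] if isinstance(concentration, dict) else concentration
        alpha = np.full(K, max(conc, 1e-6))
        if group_bias and g in group_bias:
            alpha[group_bias[g]] += 10.0 * max(conc, 0.1)
        rows.append(rng.dirichlet(alpha))
    q = pd.DataFrame(rows, index=groups.index, columns=[f"q{k+1}" for k in range(K)])
    return q


def generate_run_likelihoods(
    k_range: tuple[int, int] = (1, 6),
    k_true: int = 3,
    runs: int = 10,
    knee_size: float = 200.0,
    noise_sd: float = 5.0,
    base_lnp: float = -10_000.0,
    slope: float = 500.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate log-likelihood curves with a slope knee at ``k_true``.

    The mean curve rises by ``slope`` per K up to ``k_true`` and by
    ``slope - knee_size`` beyond it; each replicate adds Gaussian noise of
    sd ``noise_sd``.  With knee_size >> noise_sd, delta-K peaks at k_true.
    """
    kmin, kmax = k_range
    if not kmin < k_true < kmax:
        raise ValueError("k_true must be interior to k_range")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(kmin, kmax + 1):
        mean = base_lnp + slope * min(k - kmin, k_true - kmin) \
            + (slope - knee_size) * max(0, k - k_true)
        for r in range(runs):
            rows.append({"K": k, "run": r + 1, "lnP": mean + rng.normal(0.0, noise_sd)})
    return pd.DataFrame(rows)


_PRESETS = {
    # two breeding programs, eastern vs western, 1,229 markers
    "cbp": dict(
        sizes=(63, 26),
        n_loci=1229,
        fst=0.06,
        pop_names=("PIO", "BcFAZ"),
        missing_rate=0.02,
    ),
    # seven countries in two regions, 166 shared markers
    "ebp": dict(
        sizes=(89, 22, 214, 99, 11, 10, 78),
        n_loci=166,
        fst=0.04,
        pop_names=("Croatia", "Denmark", "France", "Germany", "Hungary", "Sweden", "UK"),
        regions=("CE", "NWE", "NWE", "NWE", "CE", "NWE", "NWE"),
        region_fst=0.16,
        missing_rate=0.02,
    ),
}


def preset(name: str, **overrides) -> PopulationSpec:
    """Named study-shaped generator presets ('cbp', 'ebp')."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    kw = dict(_PRESETS[name])
    kw.update(overrides)
    return PopulationSpec(**kw)
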