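"""Hierarchical AMOVA on both panels.

(A) one-level partition between the two breeding programs;
(B) one-level partition among the seven countries;
(C) two-level partition among regions / among countries within regions /
    within countries;
plus the pairwise Phi_ST matrix among countries with the UPGMA tree built
from it.  Permutation tests use 1,000 permutations here (the analysis is a
demonstration; the package default is 10,000).
"""

from pathlib import Path

import numpy as np
from skbio import DistanceMatrix

from dartpop import (
    amova_distance,
    amova_one_level,
    amova_two_level,
    pairwise_phi,
    read_marker_matrix,
    upgma,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"
N_PERM = 1000
SEED = 13


def main():
    cbp = read_marker_matrix(DATA / "cbp_calls.tsv",
                             groups_path=DATA / "cbp_groups.tsv")
    d = amova_distance(cbp)
    res = amova_one_level(d, cbp.group_labels, n_perm=N_PERM, seed=SEED)
    res.to_table().round(4).to_csv(ROOT / "cbp_amova.tsv", sep="\t", index=False)
    print("(A) two-program panel:")
    print(res.to_table().round(4).to_string(index=False))

    ebp = read_marker_matrix(DATA / "ebp_filtered.tsv",
                             groups_path=DATA / "ebp_filtered_groups.tsv")
    d = amova_distance(ebp)
    one = amova_one_level(d, ebp.group_labels, n_perm=N_PERM, seed=SEED)
    one.to_table().round(4).to_csv(ROOT / "ebp_amova_countries.tsv", sep="\t",
                                   index=False)
    print("\n(B) among countries:")
    print(one.to_table().round(4).to_string(index=False))

    two = amova_two_level(d, ebp.group_labels, ebp.region_labels,
                          n_perm=N_PERM, seed=SEED)
    two.to_table().round(4).to_csv(ROOT / "ebp_amova_regions.tsv", sep="\t",
                                   index=False)
    print("\n(C) regions / countries within regions / within countries:")
    print(two.to_table().round(4).to_string(index=False))

    pw = pairwise_phi(d, ebp.group_labels, n_perm=N_PERM, seed=SEED)
    pw.to_table().round(4).to_csv(ROOT / "ebp_pairwise_phi.tsv", sep="\t")
    tri = pw.phi[np.triu_indices(len(pw.labels), 1)]
    print(f"\npairwise Phi_ST: mean {tri.mean():.3f}, "
          f"range [{tri.min():.3f}, {tri.max():.3f}]")
    tree = upgma(DistanceMatrix(pw.phi.clip(min=0.0), ids=pw.labels))
    tree.write(str(ROOT / "ebp_phi_upgma.nwk"))
    print(f"UPGMA tree on the Phi_ST matrix -> {ROOT / 'ebp_phi_upgma.nwk'}")


if __name__ == "__main__":
    main()
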