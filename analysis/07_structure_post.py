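"""Post-process the Bayesian-clustering stand-ins for the two-program panel.

Computes the Evanno delta-K profile from the replicate likelihood table
(the generated curves put the knee at K = 2), the per-program admixture
entropy decomposition at K = 5, and the representative / intermediate /
mixed membership classification.
"""

from pathlib import Path

from dartpop import (
    admixture_decomposition,
    classify_membership,
    delta_k,
    read_marker_matrix,
    read_q_matrix,
    read_run_likelihoods,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main():
    runs = read_run_likelihoods(DATA / "cbp_run_likelihoods.tsv")
    dk = delta_k(runs)
    dk.round(3).to_csv(ROOT / "cbp_delta_k.tsv", sep="\t")
    best = int(dk["delta_K"].idxmax())
    print(f"delta-K profile over K = 1..11: argmax at K = {best} "
          f"(delta-K = {dk['delta_K'].max():.1f})")

    q = read_q_matrix(DATA / "cbp_qmatrix_k5.tsv")
    m = read_marker_matrix(DATA / "cbp_calls.tsv",
                           groups_path=DATA / "cbp_groups.tsv")
    dec = admixture_decomposition(q, m.group_labels, log_base=10)
    dec.round(3).to_csv(ROOT / "cbp_admixture_decomposition.tsv", sep="\t")
    print("\nper-program admixture decomposition (K = 5, log base 10):")
    print(dec.round(3).to_string())

    classes = classify_membership(q)
    classes.to_csv(ROOT / "cbp_membership_classes.tsv", sep="\t")
    print("\nmembership classes:")
    print(classes["class"].value_counts().to_string())


if __name__ == "__main__":
    main()
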