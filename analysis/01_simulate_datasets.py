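"""Generate the two synthetic study panels and the clustering inputs.

Writes, under scratch/data/ (bulky, regenerated on demand):
  * a two-program panel (63 + 26 inbred lines, 1,229 dominant markers,
    modest differentiation) — the "cbp" preset;
  * a seven-country panel (523 lines in two regions, 166 markers, strong
    between-region differentiation) — the "ebp" preset;
  * a Q matrix (K = 5) and a replicate log-likelihood table with a knee at
    K = 2 for the two-program panel.

Both panels carry a truth sidecar with the generating frequencies.
"""

import json
from pathlib import Path

import numpy as np

from dartpop import (
    generate_markers,
    generate_q_matrix,
    generate_run_likelihoods,
    preset,
    write_marker_matrix,
)

SEED = 20160184
OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"
OUT.mkdir(parents=True, exist_ok=True)


def main():
    for name in ("cbp", "ebp"):
        spec = preset(name)
        m, truth = generate_markers(spec, seed=SEED)
        write_marker_matrix(
            m,
            OUT / f"{name}_calls.tsv",
            groups_path=OUT / f"{name}_groups.tsv",
        )
        (OUT / f"{name}_truth.json").write_text(
            json.dumps(
                {
                    "seed": SEED,
                    "sizes": list(spec.sizes),
                    "fst": spec.fst,
                    "region_fst": spec.region_fst,
                    "pop_freq_mean": np.round(truth.pop_freqs.mean(axis=1), 4).tolist(),
                },
                indent=2,
            )
        )
        print(f"{name}: {m.n_individuals} individuals x {m.n_markers} markers -> "
              f"{OUT / (name + '_calls.tsv')}")

    cbp, _ = generate_markers(preset("cbp"), seed=SEED)
    q = generate_q_matrix(
        cbp.n_individuals, K=5, concentration={"PIO": 0.9, "BcFAZ": 0.35},
        groups=cbp.group_labels, group_bias={"BcFAZ": 3}, seed=SEED,
    )
    q.rename_axis("individual").to_csv(OUT / "cbp_qmatrix_k5.tsv", sep="\t")
    runs = generate_run_likelihoods((1, 11), k_true=2, runs=10, knee_size=300,
                                    noise_sd=40, seed=SEED)
    runs.to_csv(OUT / "cbp_run_likelihoods.tsv", sep="\t", index=False)
    print(f"Q matrix (K=5) and likelihood table for 10 runs/K over K=1..11 written.")


if __name__ == "__main__":
    main()
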