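"""End-to-end analysis pipeline: filtering, diversity, trees, AMOVA, FCA and
clustering post-processing in one call, with every table written to disk and
a manifest recording the effective configuration.

The pipeline is a library function; the numbered scripts under ``analysis/``
are thin drivers around it.  Stages that need inputs the dataset lacks
(quality scores, region labels, Q matrices) are skipped with a logged
notice rather than failing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd

from . import __version__
from .amova import amova_distance, amova_one_level, amova_two_level, pairwise_phi
from .diversity import group_diversity
from .markers import MarkerMatrix, apply_filter_chain
from .ordination import fca
from .structure import admixture_decomposition, classify_membership, delta_k
from .trees import bootstrap_support, dice_distance, upgma

log = logging.getLogger("dartpop.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str = "dartpop_out"
    min_q: float | None = None  # None skips the quality filter
    max_missing: float = 0.10
    min_maf: float = 0.05
    max_r: float = 0.95
    log_base_div: object = 2
    log_base_admix: object = 10
    n_perm: int = 10_000
    n_bootstrap: int = 1000
    n_fca_axes: int = 2
    seed: int = 0
    skip_filtering: bool = False
    extra: dict = field(default_factory=dict)


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", **kw)


def run_pipeline(
    m: MarkerMatrix,
    config: PipelineConfig,
    q_matrix: pd.DataFrame | None = None,
    run_likelihoods: pd.DataFrame | None = None,
) -> dict:
    """Run the full analysis sequence on a marker matrix.

    Returns a manifest dict (also written to ``manifest.json``) listing the
    outputs produced, stage timings, the effective configuration and the
    seed of every stochastic step.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": {k: v for k, v in asdict(config).items() if k != "extra"},
        "n_individuals": m.n_individuals,
        "n_markers_in": m.n_markers,
        "stages": {},
        "warnings": [],
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **info}
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

        return done

    # 1. filtering ---------------------------------------------------------
    if not config.skip_filtering:
        end = stage("filter")
        m, reports = apply_filter_chain(
            m, config.min_q, config.max_missing, config.min_maf, config.max_r
        )
        _write(
            pd.DataFrame(
                [
                    {"rule": r.rule, "n_in": r.n_markers_in, "n_removed": r.n_removed,
                     "n_out": r.n_markers_out}
                    for r in reports
                ]
            ),
            out / "filter_report.tsv",
            index=False,
        )
        end(n_markers_out=m.n_markers)

    # 2. diversity ---------------------------------------------------------
    end = stage("diversity")
    div = group_diversity(m, "group", config.log_base_div)
    _write(div.round(3), out / "group_diversity.tsv")
    if m.region_labels is not None:
        _write(group_diversity(m, "region", config.log_base_div).round(3),
               out / "region_diversity.tsv")
    end()

    # 3. distances + NJ tree ----------------------------------------------
    end = stage("tree")
    dm = dice_distance(m)
    dm.write(str(out / "dice_distances.txt"))
    tree = bootstrap_support(m, "nj", n_reps=config.n_bootstrap, seed=config.seed)
    tree.write(str(out / "nj_tree.nwk"))
    end(n_bootstrap=config.n_bootstrap, seed=config.seed)

    # 4. AMOVA -------------------------------------------------------------
    end = stage("amova")
    d2 = amova_distance(m)
    res1 = amova_one_level(d2, m.group_labels, n_perm=config.n_perm, seed=config.seed)
    _write(res1.to_table().round(4), out / "amova_one_level.tsv", index=False)
    if m.region_labels is not None and m.region_labels.nunique() > 1:
        res2 = amova_two_level(
            d2, m.group_labels, m.region_labels, n_perm=config.n_perm, seed=config.seed
        )
        _write(res2.to_table().round(4), out / "amova_two_level.tsv", index=False)
    else:
        log.info("two-level AMOVA skipped: no region labels")
        manifest["warnings"].append("two-level AMOVA skipped: no region labels")
    end(n_perm=config.n_perm, seed=config.seed)

    # 5. pairwise Phi_ST + UPGMA ------------------------------------------
    end = stage("pairwise_phi")
    if m.group_labels.nunique() > 1:
        pw = pairwise_phi(d2, m.group_labels, n_perm=config.n_perm, seed=config.seed)
        _write(pw.to_table().round(4), out / "pairwise_phi.tsv")
        from skbio import DistanceMatrix

        # negative estimates are reported in the table but clipped to zero
        # when Phi_ST doubles as an inter-group distance
        phi_dm = DistanceMatrix(pw.phi.clip(min=0.0), ids=pw.labels)
        upgma(phi_dm).write(str(out / "phi_upgma.nwk"))
    end()

    # 6. FCA ---------------------------------------------------------------
    end = stage("fca")
    res = fca(m, n_axes=config.n_fca_axes)
    _write(res.coordinates.join(m.group_labels.rename("group")), out / "fca_coordinates.tsv")
    _write(
        pd.DataFrame({"axis": range(1, len(res.axis_inertia_pct) + 1),
                      "inertia_pct": res.axis_inertia_pct}),
        out / "fca_inertia.tsv",
        index=False,
    )
    if res.group_barycentres is not None:
        _write(res.group_barycentres, out / "fca_barycentres.tsv")
    end(axes=res.n_axes)

    # 7. clustering post-processing ---------------------------------------
    if run_likelihoods is not None:
        end = stage("delta_k")
        _write(delta_k(run_likelihoods).round(3), out / "delta_k.tsv")
        end()
    if q_matrix is not None:
        end = stage("structure_post")
        dec = admixture_decomposition(
            q_matrix, m.group_labels.loc[q_matrix.index], config.log_base_admix
        )
        _write(dec.round(3), out / "admixture_decomposition.tsv")
        _write(classify_membership(q_matrix), out / "membership_classes.tsv")
        end()

    manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
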