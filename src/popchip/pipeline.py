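"""End-to-end orchestration: QC -> diversity -> ROH -> LD/Ne -> F_ST/tree -> PCA,
with TSV outputs and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .differentiation import distance_matrix, fst_tn_table, nj_tree
from .diversity import diversity_table
from .genotype_io import GenotypeDataset, QCParams, apply_qc, read_plink, summarize_map
from .ld_ne import current_ne, ld_profile, past_ne_trajectory
from .pca import genotype_pca
from .roh import ROHParams, breed_roh_table

log = logging.getLogger("popchip")


@dataclass
class RunConfig:
    ped_path: str | None = None
    map_path: str | None = None
    out_dir: str = "popchip_out"
    qc: QCParams = field(default_factory=QCParams)
    roh: ROHParams = field(default_factory=ROHParams)
    cm_per_mb: float = 1.0
    ld_max_dist_mb: float = 5.0
    ne_sample_correction: bool = False
    pca_components: int = 10
    seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, ds: GenotypeDataset | None = None) -> dict[str, Path]:
    """Run every analysis stage in dependency order and write the report bundle.

    Either pass a pre-loaded dataset or set ``ped_path``/``map_path``.
    Returns a mapping of artifact name to written path.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    t0 = time.time()

    checksums = {}
    if ds is None:
        if not (config.ped_path and config.map_path):
            raise ValueError("run_all needs a dataset or ped/map paths")
        log.info("stage load: reading %s / %s", config.ped_path, config.map_path)
        checksums = {
            "ped": _sha256(Path(config.ped_path)),
            "map": _sha256(Path(config.map_path)),
        }
        ds = read_plink(config.ped_path, config.map_path)
    n_input_snps = ds.n_snps

    def stage(name: str):
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)

    stage("qc")
    try:
        ds_qc, removal_log = apply_qc(ds, config.qc)
    except Exception as exc:
        raise RuntimeError(f"stage qc failed: {exc}") from exc
    removal_log.to_csv(out / "qc_removed.tsv", sep="\t", index=False)
    artifacts["qc_removed"] = out / "qc_removed.tsv"

    stage("map_summary")
    map_table, grand_mean = summarize_map(ds_qc)
    map_table.to_csv(out / "map_summary.tsv", sep="\t", index=False)
    artifacts["map_summary"] = out / "map_summary.tsv"

    stage("diversity")
    try:
        table1 = diversity_table(ds_qc)
    except Exception as exc:
        raise RuntimeError(f"stage diversity failed: {exc}") from exc

    stage("ld_ne")
    profiles, profile_objs, traj_frames, ne_by_breed = [], [], [], {}
    for breed in ds_qc.breeds:
        try:
            prof = ld_profile(ds_qc, breed, config.ld_max_dist_mb)
            n = int(ds_qc.breed_indices(breed).size)
            ne_by_breed[breed] = current_ne(
                prof, config.cm_per_mb, n, config.ne_sample_correction
            )
            traj = past_ne_trajectory(
                prof, config.cm_per_mb, n, config.ne_sample_correction
            )
        except Exception as exc:
            raise RuntimeError(f"stage ld_ne failed for breed {breed}: {exc}") from exc
        bins = prof.bins.copy()
        bins.insert(0, "breed", breed)
        profiles.append(bins)
        profile_objs.append(prof)
        traj.insert(0, "breed", breed)
        traj_frames.append(traj)
    pd.concat(profiles, ignore_index=True).to_csv(
        out / "ld_profiles.tsv", sep="\t", index=False
    )
    artifacts["ld_profiles"] = out / "ld_profiles.tsv"
    pd.concat(traj_frames, ignore_index=True).to_csv(
        out / "ne_trajectories.tsv", sep="\t", index=False
    )
    artifacts["ne_trajectories"] = out / "ne_trajectories.tsv"

    table1["ne"] = table1["breed"].map(ne_by_breed)
    table1.to_csv(out / "table1.tsv", sep="\t", index=False)
    artifacts["table1"] = out / "table1.tsv"

    stage("roh")
    try:
        table2 = breed_roh_table(ds_qc, config.roh)
    except Exception as exc:
        raise RuntimeError(f"stage roh failed: {exc}") from exc
    table2.to_csv(out / "table2.tsv", sep="\t", index=False)
    artifacts["table2"] = out / "table2.tsv"

    stage("differentiation")
    try:
        tn, fst = distance_matrix(ds_qc)
        tree = nj_tree(tn) if len(ds_qc.breeds) >= 3 else None
    except Exception as exc:
        raise RuntimeError(f"stage differentiation failed: {exc}") from exc
    fst_tn_table(tn, fst).to_csv(out / "table3.tsv", sep="\t")
    artifacts["table3"] = out / "table3.tsv"
    if tree is not None:
        (out / "tree.nwk").write_text(tree.newick() + "\n")
        artifacts["tree"] = out / "tree.nwk"

    stage("pca")
    try:
        pca = genotype_pca(ds_qc, config.pca_components)
    except Exception as exc:
        raise RuntimeError(f"stage pca failed: {exc}") from exc
    pca.to_frame().to_csv(out / "pca_scores.tsv", sep="\t", index=False)
    artifacts["pca_scores"] = out / "pca_scores.tsv"
    pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(pca.k)],
            "eigenvalue": pca.eigenvalues[: pca.k],
            "variance_fraction": pca.variance_fractions,
        }
    ).to_csv(out / "pca_eigenvalues.tsv", sep="\t", index=False)
    artifacts["pca_eigenvalues"] = out / "pca_eigenvalues.tsv"

    stage("plots")
    from .plots import ld_decay_plot, pca_scatter

    ld_decay_plot(profile_objs, out / "ld_decay.svg")
    artifacts["ld_decay_plot"] = out / "ld_decay.svg"
    pca_scatter(pca, out / "pca_scatter.svg")
    artifacts["pca_scatter_plot"] = out / "pca_scatter.svg"

    manifest = {
        "popchip_version": __version__,
        "seed": config.seed,
        "input_checksums": checksums,
        "n_samples": ds.n_samples,
        "n_input_snps": n_input_snps,
        "n_snps_post_qc": ds_qc.n_snps,
        "mean_adjacent_spacing_bp": grand_mean,
        "qc": {"call_rate_min": config.qc.call_rate_min, "maf_min": config.qc.maf_min},
        "roh": vars(config.roh).copy() if not hasattr(config.roh, "__dataclass_fields__")
        else {k: getattr(config.roh, k) for k in config.roh.__dataclass_fields__},
        "cm_per_mb": config.cm_per_mb,
        "ld_max_dist_mb": config.ld_max_dist_mb,
        "ne_sample_correction": config.ne_sample_correction,
        "pca_components": config.pca_components,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = out / "manifest.json"
    log.info("done in %.1fs", time.time() - t0)
    return artifacts
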