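"""End-to-end orchestration: design -> simulate -> quantify -> noise -> model.

The pipeline config carries every stage threshold with its canonical default
(RNA read filter 100, bin-profile filters 200 / 5 / 2% / 30%, peak delta
0.05, 16 bins, 10,000 random sets) and all seeds; a resolved-config snapshot
plus a checksummed output manifest is emitted with every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import flowquant, io, libdesign, noisemod, rnaquant, seqfeatures, simgen, splicemodel

log = logging.getLogger("mprasplice")


@dataclass
class PipelineConfig:
    n_contexts: int = 40
    splicing_type: str = "retained_intron"
    subsets: tuple = ("wt", "constvar", "SFvar", "nuc")
    n_barcode_controls: int = 8
    min_reads: int = 100
    min_bin_reads: int = 200
    bin_zero_count: int = 5
    bin_zero_frac: float = 0.02
    retained_mass: float = 0.30
    delta: float = 0.05
    n_bins: int = 16
    n_random: int = 10000
    read_depth_rna: int = 10000
    cells_per_variant: int = 5000
    reads_per_variant_bins: int = 2000
    model_grid: Optional[dict] = None
    cv_folds: int = 10
    seed: int = 0


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def run_pipeline(config: PipelineConfig, out_dir, train_model: bool = False) -> Dict[str, pd.DataFrame]:
    """Run design, simulation, RNA and protein quantification and the noise
    model in dependency order, writing all tables under ``out_dir``.

    Model training is off by default (it is the most expensive stage); the
    RNA branch completes even if the bin-profile branch fails.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, pd.DataFrame] = {}
    outputs: Dict[str, str] = {}

    # --- design ---------------------------------------------------------
    log.info("designing library (%d contexts)", config.n_contexts)
    contexts = simgen.random_contexts(
        config.n_contexts, config.splicing_type, seed=config.seed
    )
    variants = libdesign.design_library(
        contexts,
        subsets=config.subsets,
        n_barcode_controls=config.n_barcode_controls,
        seed=config.seed,
    )
    if not variants:
        raise StageError("design", "no variants produced")
    io.write_library_fasta(variants, out / "library.fa")
    io.write_design_manifest(variants, out / "manifest.tsv")
    outputs["library.fa"] = str(out / "library.fa")
    outputs["manifest.tsv"] = str(out / "manifest.tsv")
    manifest = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "barcode": [v.barcode for v in variants],
            "context_id": [v.context_id for v in variants],
            "subset": [v.subset for v in variants],
            "variable_region": [v.variable_region for v in variants],
        }
    )
    results["manifest"] = manifest

    # --- features (for truth planting and modelling) --------------------
    ctx_by_id = {c.context_id: c for c in contexts}
    sequences = {v.variant_id: v.variable_region for v in variants}
    schemes = {}
    anchors = {}
    for v in variants:
        ctx = ctx_by_id[v.context_id]
        schemes[v.variant_id] = seqfeatures.RegionScheme.from_anchors(
            ctx.splicing_type, len(v.variable_region), ctx.splice_site_positions
        )
        anchors[v.variant_id] = ctx.splice_site_positions
    features = seqfeatures.build_feature_matrix(sequences, schemes, anchors)
    io.write_tsv(features.reset_index(), out / "features.tsv")
    outputs["features.tsv"] = str(out / "features.tsv")
    results["features"] = features

    # --- simulate -------------------------------------------------------
    sim_config = simgen.SimConfig(
        n_variants=len(variants),
        read_depth_rna=config.read_depth_rna,
        cells_per_variant=config.cells_per_variant,
        reads_per_variant_bins=config.reads_per_variant_bins,
        n_bins=config.n_bins,
        effect_sizes={"gc_intron": -1.0, "strength_site1": 1.0, "strength_site2": 0.8},
        seed=config.seed,
    )
    truth = simgen.plant_truth(manifest, features, sim_config)
    iso = simgen.simulate_rna_reads(truth, sim_config)
    try:
        profiles, medians, boundaries = simgen.simulate_sorted_bins(truth, sim_config)
    except Exception as exc:  # protein branch unavailable; RNA branch continues
        log.warning("bin-profile simulation failed (%s); protein stages skipped", exc)
        profiles = medians = None
    for name, df in [("truth.tsv", truth), ("iso_counts.tsv", iso)]:
        io.write_tsv(df, out / name)
        outputs[name] = str(out / name)
    if profiles is not None:
        for name, df in [("bin_profiles.tsv", profiles), ("bin_medians.tsv", medians)]:
            io.write_tsv(df, out / name)
            outputs[name] = str(out / name)
        results.update(profiles=profiles, medians=medians)
    results.update(truth=truth, iso=iso)

    # --- RNA quantification --------------------------------------------
    rna = rnaquant.quantify(iso, min_reads=config.min_reads)
    rna_norm = rnaquant.normalize_to_wildtype(rna, manifest)
    io.write_tsv(rna_norm, out / "rna.tsv")
    outputs["rna.tsv"] = str(out / "rna.tsv")
    results["rna"] = rna_norm

    # --- protein quantification and noise model (skipped without bins) --
    if profiles is not None:
        params = flowquant.FilterParams(
            min_total_reads=config.min_bin_reads,
            min_bin_reads=config.bin_zero_count,
            min_bin_fraction=config.bin_zero_frac,
            min_retained_mass=config.retained_mass,
            peak_delta=config.delta,
        )
        prot = flowquant.quantify_profiles(
            profiles, medians["median_log2_ratio"].to_numpy(), params
        )
        io.write_tsv(prot, out / "protein.tsv")
        outputs["protein.tsv"] = str(out / "protein.tsv")
        results["protein"] = prot

        merged = rna.merge(prot, on="variant_id")
        complete = (
            merged["splicing_value"].notna()
            & merged["noise_strength"].notna()
            & merged["expression"].notna()
        )
        if complete.sum() >= noisemod.MIN_COMPLETE_CASES:
            fit = noisemod.fit_noise_model(
                merged.loc[complete, "splicing_value"],
                merged.loc[complete, "expression"],
                merged.loc[complete, "noise_strength"],
            )
            noise = merged.loc[complete, ["variant_id"]].copy()
            noise["noise_residual"] = fit.residuals
            io.write_tsv(noise, out / "noise.tsv")
            outputs["noise.tsv"] = str(out / "noise.tsv")
            results["noise"] = noise
        else:
            log.warning("too few complete cases for the noise model; stage skipped")

    # --- model training (optional) --------------------------------------
    if train_model:
        labelled = rna[rna["pass_filter"]].set_index("variant_id")
        X = features.loc[labelled.index].fillna(0.0)
        seqs = manifest.set_index("variant_id").loc[labelled.index, "variable_region"]
        Xtr, ytr, Xte, yte = splicemodel.dedup_and_split(
            X, labelled["splicing_ratio"], seqs, seed=config.seed
        )
        model = splicemodel.tune_and_select(
            Xtr,
            ytr,
            grid=config.model_grid or {"learning_rate": [0.1], "n_estimators": [100], "max_depth": [3]},
            folds=min(config.cv_folds, max(2, len(Xtr) // 10)),
            seed=config.seed,
        )
        r2, pearson = splicemodel.evaluate(model, Xte, yte)
        results["model_metrics"] = pd.DataFrame(
            [{"r2": r2, "pearson_r": pearson, "n_train": len(Xtr), "n_test": len(Xte)}]
        )
        io.write_tsv(results["model_metrics"], out / "model_metrics.tsv")
        outputs["model_metrics.tsv"] = str(out / "model_metrics.tsv")

    io.write_config_snapshot(config, out / "config_snapshot.json")
    io.write_output_manifest(outputs, out / "outputs_manifest.tsv")
    return results
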