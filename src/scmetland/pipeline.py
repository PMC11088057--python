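"""End-to-end orchestration from a single YAML config.

A run either simulates its inputs (``simulate:`` block) or loads them
from disk (``inputs:`` block), then executes preprocess -> pathway
activity -> heterogeneity/GSEA -> signatures -> clinical association in
dependency order, writing one CSV per stage plus a machine-readable
manifest (input hashes, per-stage seeds and timings, package version).

A single global seed fans out to per-stage seeds by stable hashing of
the stage name, so each stage is reproducible independently of execution
order. Reruns with identical config and inputs produce identical outputs
and identical manifests apart from timestamps.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import clinical as clin
from . import heterogeneity as het
from . import io as sio
from . import pathway as pw
from . import preprocess as pp
from . import signatures as sig
from . import synthetic as syn
from .errors import ScmetlandError, ValidationError


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValidationError("pipeline config must be a YAML mapping")
    return config


def validate_config(config: dict) -> None:
    """Check structure and referenced paths before any compute."""
    if "simulate" not in config and "inputs" not in config:
        raise ValidationError("config needs a 'simulate' or an 'inputs' block")
    if "inputs" in config:
        inputs = config["inputs"]
        for key in ("matrix", "annotation", "gene_sets"):
            if key not in inputs:
                raise ValidationError(f"inputs block missing {key!r}")
            if not Path(inputs[key]).exists():
                raise ValidationError(f"input path does not exist: {inputs[key]}")
        if "clinical" in inputs and not Path(inputs["clinical"]).exists():
            raise ValidationError(f"input path does not exist: {inputs['clinical']}")


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Run all configured stages; returns the manifest (also written to disk)."""
    if not isinstance(config, dict):
        config = load_config(config)
    validate_config(config)
    seed = int(config.get("seed", 0))
    outdir = Path(output_dir or config.get("output_dir", "scmetland_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stages": [],
        "inputs": {},
        "outputs": {},
        "timestamps": {"started": time.time()},
    }

    def record(stage: str, t0: float) -> None:
        manifest["stages"].append({"stage": stage, "elapsed_s": round(time.time() - t0, 4)})

    def emit(name: str, frame) -> None:
        path = outdir / name
        frame.to_csv(path, index=False)
        manifest["outputs"][name] = _hash_file(path)

    try:
        # ---- load or simulate inputs -------------------------------------
        t0 = time.time()
        truth = None
        if "simulate" in config:
            sim_cfg = syn.SimulationConfig(
                **{**config["simulate"], "seed": config["simulate"].get("seed", stage_seed(seed, "simulate"))}
            )
            matrix, annotation, gene_sets, truth = syn.simulate(sim_cfg)
            manifest["inputs"]["simulate"] = {
                k: v for k, v in config["simulate"].items()
            } | {"seed": sim_cfg.seed}
        else:
            inputs = config["inputs"]
            fmt = inputs.get("matrix_format", "tsv")
            matrix = sio.read_expression(inputs["matrix"], format=fmt)
            annotation = sio.read_annotation(inputs["annotation"])
            gene_sets = sio.read_gmt(inputs["gene_sets"])
            for key in ("matrix", "annotation", "gene_sets"):
                manifest["inputs"][key] = _hash_file(Path(inputs[key]))
        record("load", t0)

        # ---- preprocess ---------------------------------------------------
        t0 = time.time()
        pre_opts = dict(config.get("preprocess", {}))
        pre_cfg = pp.PreprocessConfig(
            **{**pre_opts, "seed": pre_opts.get("seed", stage_seed(seed, "preprocess"))}
        )
        matrix, annotation, filter_report = pp.filter_cell_types(
            matrix, annotation, pre_cfg.min_cells_per_type
        )
        manifest["filter_report"] = filter_report
        if pre_cfg.log_transform:
            matrix = pp.log_transform(matrix)
        matrix = pp.impute(matrix, pre_cfg, annotation)
        record("preprocess", t0)

        # ---- pathway activity --------------------------------------------
        t0 = time.time()
        pa_opts = dict(config.get("pathway_activity", {}))
        pa = pw.permutation_test(
            matrix, annotation, gene_sets,
            n_perm=int(pa_opts.get("n_perm", 1000)),
            seed=int(pa_opts.get("seed", stage_seed(seed, "pathway_activity"))),
            tukey_k=float(pa_opts.get("tukey_k", pw.DEFAULT_TUKEY_K)),
            min_genes=int(pa_opts.get("min_genes", pw.DEFAULT_MIN_GENES)),
        )
        emit("pathway_activity.csv", pa.to_long_frame())
        emit("pathway_activity_wide.csv", pa.to_wide_frame().rename_axis("pathway").reset_index())
        record("pathway_activity", t0)

        # ---- heterogeneity ------------------------------------------------
        t0 = time.time()
        het_opts = dict(config.get("heterogeneity", {}))
        metabolic_genes = sorted({g for s in gene_sets.metabolic_sets.values() for g in s})
        pca = het.pca_gene_scores(
            matrix, annotation,
            scope=het_opts.get("scope"),
            genes=metabolic_genes,
            missing=het_opts.get("missing", "pairwise"),
        )
        ranked = het.rank_genes(pca)
        gsea = het.gsea_preranked(
            ranked, gene_sets,
            weight_exponent=float(het_opts.get("weight_exponent", 1.0)),
            n_perm=int(het_opts.get("n_perm", 1000)),
            seed=int(het_opts.get("seed", stage_seed(seed, "heterogeneity"))),
        )
        emit("pca_gene_scores.csv", ranked)
        emit("gsea.csv", gsea.table)
        record("heterogeneity", t0)

        # ---- signatures ---------------------------------------------------
        t0 = time.time()
        sig_opts = dict(config.get("signatures", {}))
        hyp_name = sig_opts.get("hypoxia_set", syn.HYPOXIA_SET_NAME)
        gly_name = sig_opts.get("glycolysis_set", syn.GLYCOLYSIS_SET_NAME)
        sets_to_score = {}
        if hyp_name in gene_sets and gly_name in gene_sets:
            sets_to_score = {"hypoxia": gene_sets[hyp_name], "glycolysis": gene_sets[gly_name]}
            oxp_name = sig_opts.get("oxphos_set")
            if oxp_name and oxp_name in gene_sets:
                sets_to_score["oxphos"] = gene_sets[oxp_name]
            scores = sig.CellSignatureScores.compute(matrix, sets_to_score)
            corr = sig.correlate_by_type(
                scores, annotation, method=sig_opts.get("method", "spearman")
            )
            emit("hypoxia_correlations.csv", corr)
        compare_genes = sig_opts.get("compare_genes", [])
        groups = set(annotation.table["tissue_group"])
        if compare_genes and groups == {"tumor", "normal"}:
            comp = sig.compare_groups(matrix, annotation, compare_genes)
            emit("group_comparison.csv", comp.summary)
            emit("dotplot_stats.csv", comp.dotplot)
        record("signatures", t0)

        # ---- clinical -----------------------------------------------------
        t0 = time.time()
        ihc_opts = dict(config.get("ihc", {}))
        cohort = None
        if "inputs" in config and "clinical" in config["inputs"]:
            cohort = sio.read_clinical(config["inputs"]["clinical"])
            manifest["inputs"]["clinical"] = _hash_file(Path(config["inputs"]["clinical"]))
        elif "counts" in ihc_opts:
            cohort = syn.generate_ihc_cohort(
                ihc_opts["counts"], seed=int(ihc_opts.get("seed", stage_seed(seed, "ihc")))
            )
        if cohort is not None:
            results = clin.associate(
                cohort,
                alpha=float(ihc_opts.get("alpha", clin.ALPHA_DEFAULT)),
                adjust=bool(ihc_opts.get("adjust", False)),
            )
            emit("ihc_associations.csv", clin.association_frame(results))
        record("clinical", t0)
    except ScmetlandError:
        raise
    except Exception as err:  # pragma: no cover - defensive
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "load"
        raise ScmetlandError(f"pipeline failed after stage {stage!r}: {err}") from err

    manifest["timestamps"]["finished"] = time.time()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
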