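"""End-to-end orchestration of the analysis stages.

Stages run in method order — simulate (or load) -> transcript QC ->
methylation deconvolution -> bulk + cell-type TWAS -> pathway enrichment ->
mediation (regulation) scan -> cross-context concordance — each stage
consuming the previous stage's output.  Every output file carries a header
comment with the package version, a hash of the configuration and the seed;
the returned manifest lists all files with checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deconvolution import compare_proportions, estimate_proportions
from .enrichment import (
    circular_permutation_enrichment,
    cluster_pathways,
    map_markers_to_genes,
)
from .io import PathwayDB, read_gmt, transcript_qc_filter, write_tsv
from .mediation import MediationSpec, run_regulation_scan
from .overlap import sign_test, top_fraction_overlap
from .synthetic import SimulationConfig, read_dataset, simulate_cohort, write_dataset
from .twas import TwasModelSpec, fit_bulk_twas, fit_celltype_twas, permutation_calibration

logger = logging.getLogger("cttwas")


class PipelineConfigError(ValueError):
    """The pipeline configuration is invalid; raised before any computation."""


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def default_config(seed: int = 0) -> dict:
    """Demo configuration: a simulated cohort with planted signal."""
    return {
        "seed": seed,
        "simulate": {
            "n_samples": 300,
            "n_cases": 150,
            "n_transcripts": 400,
            "n_snps": 60,
            "effect_map": [[t, 2, 1.8] for t in range(12)],  # B-cell effects
            "eqtl_map": [[0, 0, None, 0.15], [1, 1, None, 0.15]],
            "mediation_map": [[0, 0, 3.0, 0.0], [1, 1, 3.0, 0.0]],
        },
        "twas": {"covariates": ["age"], "fdr_threshold": 0.1},
        "enrichment": {
            "n_perm": 1000,
            "min_genes": 3,
            "flank": 10_000,
            "context": "B",
            "genes_per_set": 10,
        },
        "mediation": {"marker_type": "snp", "cis_window": 10_000,
                      "preselect_alpha": 0.05, "max_sims": 10_000},
        "overlap": {"frac": 0.05},
    }


def _synthetic_pathways(gene_ids: list[str], genes_per_set: int, seed: int) -> PathwayDB:
    """Bundle annotation genes into disjoint synthetic gene sets for the demo."""
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(gene_ids))
    sets = {}
    for i in range(0, len(order) - genes_per_set + 1, genes_per_set):
        sets[f"SYNPATH_{i // genes_per_set:03d}"] = set(order[i : i + genes_per_set])
    return PathwayDB(sets, source="synthetic")


def run_pipeline(config: dict, output_dir=None) -> dict:
    """Run all stages; returns a manifest of outputs with checksums."""
    seed = int(config.get("seed", 0))
    outdir = Path(output_dir or config.get("output_dir", "cttwas_output"))

    # validate paths before any computation
    if "inputs" in config:
        required = ("expression", "annotation", "methylation", "cpg_coords",
                    "reference", "genotypes", "snp_coords", "phenotypes")
        for key in required:
            if key not in config["inputs"]:
                raise PipelineConfigError(f"inputs.{key} missing from config")
            if not Path(config["inputs"][key]).exists():
                raise PipelineConfigError(
                    f"inputs.{key}: no such file {config['inputs'][key]}"
                )
    elif "simulate" not in config:
        raise PipelineConfigError("config needs either 'simulate' or 'inputs'")

    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    header = [f"cttwas {__version__}", f"config_hash {chash}", f"seed {seed}"]
    manifest: dict[str, dict] = {}
    timings: dict[str, float] = {}

    def _save(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        write_tsv(df, path, header_lines=header)
        manifest[name] = {"path": str(path), "sha256": _sha256(path)}

    def _stage(name):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def _done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    try:
        # --- simulate / load ------------------------------------------------
        s = _stage("data")
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"])
            sim_kwargs.setdefault("seed", seed)
            for key in ("effect_map", "eqtl_map", "mediation_map"):
                if key in sim_kwargs:
                    sim_kwargs[key] = [tuple(e) for e in sim_kwargs[key]]
            sim_config = SimulationConfig(**sim_kwargs)
            ds = simulate_cohort(sim_config)
            data_dir = outdir / "data"
            files = write_dataset(ds, data_dir)
            for k, v in files.items():
                manifest[f"data/{k}"] = {"path": v, "sha256": _sha256(Path(v))}
        else:
            ds = read_dataset(Path(config["inputs"]["expression"]).parent)
        _done(s)

        # --- transcript QC ---------------------------------------------------
        s = _stage("qc")
        expr, qc_report = transcript_qc_filter(
            ds.expression, tpm_low=config.get("qc", {}).get("tpm_low", 1.0)
        )
        _save("qc_report", pd.DataFrame([qc_report]))
        _done(s)

        # --- deconvolution ----------------------------------------------------
        s = _stage("deconvolve")
        P = estimate_proportions(ds.methylation, ds.reference_panel)
        _save("proportions", P.values)
        prop_cmp = compare_proportions(P, ds.phenotypes)
        _save("proportion_differences", prop_cmp)
        _done(s)

        # --- TWAS ---------------------------------------------------------------
        s = _stage("twas")
        tw_cfg = config.get("twas", {})
        spec = TwasModelSpec(
            covariates=tw_cfg.get("covariates", []),
            fdr_threshold=tw_cfg.get("fdr_threshold", 0.1),
        )
        bulk = fit_bulk_twas(expr, ds.phenotypes, P, spec)
        ct = fit_celltype_twas(expr, ds.phenotypes, P, spec)
        _save("twas_bulk", bulk)
        _save("twas_celltype", ct)
        calib = permutation_calibration(
            expr, ds.phenotypes, P, spec, n_perm=tw_cfg.get("n_calibration_perm", 3),
            seed=seed,
        )
        _save("twas_calibration", pd.DataFrame({"lambda": calib["lambdas"]}))
        _done(s)

        # --- pathway enrichment ---------------------------------------------------
        s = _stage("pathways")
        en_cfg = config.get("enrichment", {})
        context = en_cfg.get("context", "B")
        ct_res = ct[ct["context"] == context]
        if "gmt" in en_cfg:
            pathways = read_gmt(en_cfg["gmt"])
        else:
            pathways = _synthetic_pathways(
                sorted(set(expr.gene_ids.dropna())),
                en_cfg.get("genes_per_set", 10),
                seed,
            )
        marker_coords = expr.annotation[["chrom", "start"]].rename(
            columns={"start": "pos"}
        )
        gene_ann = expr.annotation.reset_index()[
            ["gene_id", "chrom", "start", "end", "strand"]
        ].drop_duplicates("gene_id")
        marker_map = map_markers_to_genes(
            marker_coords, gene_ann, upstream_flank=en_cfg.get("flank", 10_000)
        )
        enr = circular_permutation_enrichment(
            ct_res,
            marker_map,
            pathways,
            top_rule=lambda r: r["q"] < spec.fdr_threshold,
            n_perm=en_cfg.get("n_perm", 10_000),
            min_genes=en_cfg.get("min_genes", 3),
            seed=seed,
        )
        sig = enr[enr["significant"]]
        if len(sig) > 0:
            clusters = cluster_pathways(sig, pathways, seed=seed)
            enr.loc[clusters.index, "cluster"] = clusters
        _save("enrichment", enr)
        _done(s)

        # --- regulation (mediation) scan --------------------------------------------
        s = _stage("regulation")
        med_cfg = config.get("mediation", {})
        max_sims = med_cfg.get("max_sims", 1_000_000)
        schedule = tuple(
            k for k in MediationSpec().sims_schedule if k <= max_sims
        )
        med_spec = MediationSpec(
            marker_type=med_cfg.get("marker_type", "snp"),
            cis_window=med_cfg.get("cis_window", 10_000),
            preselect_alpha=med_cfg.get("preselect_alpha", 0.05),
            sims_schedule=schedule,
            seed=seed,
        )
        de_genes = sorted(set(ct_res.loc[ct_res["q"] < spec.fdr_threshold, "gene"]))
        # residualize QC-passed abundance on covariates before mediation
        resid = expr.abundance.copy()
        covs = spec.covariates
        if covs:
            import statsmodels.api as sm

            X = sm.add_constant(ds.phenotypes.loc[resid.columns, covs].to_numpy(float))
            Y = resid.to_numpy(float).T
            beta = np.linalg.lstsq(X, Y, rcond=None)[0]
            resid = pd.DataFrame(
                (Y - X @ beta).T, index=resid.index, columns=resid.columns
            )
        if de_genes:
            scan = run_regulation_scan(
                ds.genotypes.dosages,
                ds.genotypes.coords,
                resid,
                expr.annotation,
                ds.phenotypes,
                de_genes,
                med_spec,
            )
        else:
            scan = pd.DataFrame()
            logger.info("regulation: no differentially expressed genes; skipped")
        _save("regulation", scan)
        _done(s)

        # --- overlap / concordance ---------------------------------------------------
        s = _stage("overlap")
        ov_cfg = config.get("overlap", {})
        ov = top_fraction_overlap(bulk, ct_res, frac=ov_cfg.get("frac", 0.05))
        if len(ov) > 0:
            st = sign_test(len(ov), int(ov["concordant"].sum()))
            ov_summary = pd.DataFrame(
                [{"n_overlap": st.n, "n_concordant": st.k, "sign_test_p": st.p}]
            )
        else:
            ov_summary = pd.DataFrame(
                [{"n_overlap": 0, "n_concordant": 0, "sign_test_p": np.nan}]
            )
        _save("overlap_genes", ov)
        _save("overlap_summary", ov_summary)
        _done(s)
    except PipelineConfigError:
        raise
    except Exception as exc:  # surface the failing stage
        failed = max(timings, key=lambda k: timings[k])
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    manifest_meta = {
        "version": __version__,
        "seed": seed,
        "config_hash": chash,
        "timings_s": timings,
        "files": manifest,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest_meta, fh, indent=1)
    return manifest_meta
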