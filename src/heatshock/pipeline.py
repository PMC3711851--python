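"""End-to-end pipeline: noise fit -> SLR calling -> clustering /
enrichment -> binding calls -> integration, with a machine-readable run
manifest.

The configuration is a plain dict (loadable from YAML/JSON through the
CLI). Every stage that samples randomness takes an explicit seed which is
recorded in the manifest, so a rerun with the same configuration is
bit-identical.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import pandas as pd

from . import diffexpr, enrich, integrate, io, noise, profiles
from .chip import PromoterBindingModel

__all__ = ["PipelineError", "run_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger("heatshock")

DEFAULT_CONFIG = {
    "run_id": "run",
    "contrast": ["SC:C", "SC:HS"],
    "noise": {"k_min": 2, "k_max": 5, "seed": 11},
    "slr": {"k_min": 1, "k_max": 5, "seed": 12},
    "cluster": {"enabled": True, "k_min": 2, "k_max": 20, "seed": 13,
                "profile": "group_means"},
    "enrich": {"enabled": True, "cutoff": 0.05, "query": "up"},
    "chip": {"window": 5, "b_perm": 999, "seed": 14,
             "score_min": 15.0, "q_max": 0.05},
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _merge(defaults: dict, override: dict) -> dict:
    out = {}
    for key, val in defaults.items():
        if isinstance(val, dict):
            out[key] = _merge(val, override.get(key, {}))
        else:
            out[key] = override.get(key, val)
    for key in override:
        if key not in out:
            out[key] = override[key]
    return out


def run_pipeline(config: dict) -> Path:
    """Run every configured stage and return the output directory.

    ``config['inputs']`` must name existing files for at least ``matrix``
    and ``design``; ``chip_signals``+``promoter_map`` enable the binding
    and integration stages, ``gene_term`` (+ optional ``dag``) the
    enrichment stage. All inputs are checked before any stage runs.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    if "inputs" not in cfg or "out_dir" not in cfg:
        raise PipelineError("pre-flight: config needs 'inputs' and 'out_dir'")
    inputs = {k: Path(v) for k, v in cfg["inputs"].items()}
    missing = [f"{k}={v}" for k, v in inputs.items() if not v.exists()]
    if missing:
        raise PipelineError(f"pre-flight: missing input paths: {missing}")
    for key in ("matrix", "design"):
        if key not in inputs:
            raise PipelineError(f"pre-flight: required input {key!r} not configured")
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- noise fit -------------------------------------------------------
    matrix, design = stage("read")(io.read_expression, inputs["matrix"], inputs["design"])
    ncfg = cfg["noise"]
    groups = noise._group_samples(design)
    thresholds, noise_rows = {}, []
    for group, samples in groups.items():
        res = stage("noise-fit")(
            noise.SignalNoiseModel(
                matrix[samples].to_numpy().ravel(), label=group
            ).fit,
            k_range=(ncfg["k_min"], ncfg["k_max"]),
            seed=ncfg["seed"],
        )
        thresholds[group] = res.threshold
        for comp in range(res.k):
            noise_rows.append(
                {"group": group, "component": comp + 1,
                 "weight": res.weights[comp], "mean_log2": res.means[comp],
                 "sd_log2": res.sds[comp], "threshold_log2": res.threshold,
                 "bic": res.bic}
            )
    pd.DataFrame(noise_rows).to_csv(out_dir / "noise_models.tsv", sep="\t", index=False)
    calls = noise.call_expressed(matrix, design, thresholds)
    calls.to_csv(out_dir / "expression_calls.tsv", sep="\t")
    log.info("noise-fit: %d groups, %d/%d genes expressed anywhere",
             len(groups), int(calls["expressed_anywhere"].sum()), len(calls))

    # --- SLR -------------------------------------------------------------
    scfg = cfg["slr"]
    contrast = tuple(cfg["contrast"])
    table = stage("slr")(diffexpr.compute_slr, matrix, design, calls, contrast)
    slr_res = stage("slr")(
        diffexpr.SlrMixtureModel(table).fit,
        k_range=(scfg["k_min"], scfg["k_max"]), seed=scfg["seed"],
    )
    slr_res.report_table().to_csv(out_dir / "contrast.tsv", sep="\t")
    slr_res.summary().to_csv(out_dir / "slr_summary.tsv", sep="\t", index=False)
    log.info("slr: %s evaluated=%d up=%d down=%d", contrast,
             sum(slr_res.counts.values()), slr_res.counts["up"], slr_res.counts["down"])

    # --- clustering ------------------------------------------------------
    ccfg = cfg["cluster"]
    if ccfg["enabled"]:
        if ccfg["profile"] == "group_means":
            prof = pd.DataFrame(
                {g: matrix[s].mean(axis=1) for g, s in groups.items()}
            )
        else:  # contrast means (control, heat shock)
            prof = slr_res.table[["mean_c", "mean_hs"]]
        prof = prof.loc[calls["expressed_anywhere"]]
        clus = stage("cluster")(
            profiles.ProfileClusterModel(prof).fit,
            k_range=(ccfg["k_min"], ccfg["k_max"]), seed=ccfg["seed"],
        )
        clus.labels.to_frame().to_csv(out_dir / "clusters.tsv", sep="\t")
        clus.summary().to_csv(out_dir / "cluster_summary.tsv", sep="\t", index=False)
        log.info("cluster: K=%d over %d genes", clus.k, len(prof))

    # --- enrichment ------------------------------------------------------
    ecfg = cfg["enrich"]
    if ecfg["enabled"] and "gene_term" in inputs:
        annotation = stage("enrich")(
            io.read_annotation, inputs["gene_term"], inputs.get("dag"),
            set(matrix.index),
        )
        query_class = ecfg["query"]
        query = set(slr_res.table.index[slr_res.table["de_class"] == query_class])
        query &= annotation.universe
        rows = stage("enrich")(
            enrich.conditional_enrichment, query, annotation, ecfg["cutoff"]
        )
        rows.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
        log.info("enrich: %d terms tested for %d %s-regulated genes",
                 len(rows), len(query), query_class)

    # --- binding calls + integration ------------------------------------
    pcfg = cfg["chip"]
    if "chip_signals" in inputs and "promoter_map" in inputs:
        signals = stage("chip-call")(io.read_chip_signals, inputs["chip_signals"])
        pmap = stage("chip-call")(io.read_promoter_map, inputs["promoter_map"])
        model = stage("chip-call")(PromoterBindingModel, signals, pmap)
        binding = stage("chip-call")(
            model.fit, seed=pcfg["seed"], window=pcfg["window"],
            b_perm=pcfg["b_perm"], score_min=pcfg["score_min"],
            q_max=pcfg["q_max"],
        )
        binding.table.to_csv(out_dir / "binding.tsv", sep="\t", index=False)
        log.info("chip-call: %d/%d promoters bound",
                 len(binding.bound), len(binding.table))

        scores = integrate.gene_binding_scores(binding.table)
        xtab = stage("integrate")(integrate.crosstab, set(binding.bound), slr_res.table)
        xtab.to_csv(out_dir / "integration.tsv", sep="\t", index=False)
        sp_rows = []
        for direction in ("up", "down"):
            sp = integrate.spearman_binding_expression(
                slr_res.table, scores, direction
            )
            sp_rows.append(
                {"direction": direction, "n": sp.n, "rho": sp.rho, "p": sp.p}
            )
        pd.DataFrame(sp_rows).to_csv(out_dir / "spearman.tsv", sep="\t", index=False)
        sets = {
            "bound": set(binding.bound),
            "induced": set(slr_res.table.index[slr_res.table["de_class"] == "up"]),
            "repressed": set(slr_res.table.index[slr_res.table["de_class"] == "down"]),
        }
        integrate.overlap_sets(sets).to_csv(
            out_dir / "overlaps.tsv", sep="\t", index=False
        )
        log.info("integrate: crosstab and correlations written")

    io.write_manifest(
        out_dir / "manifest.json",
        seeds={"noise": ncfg["seed"], "slr": scfg["seed"],
               "cluster": ccfg["seed"] if ccfg["enabled"] else None,
               "chip": pcfg["seed"]},
        parameters=cfg,
        inputs={k: str(v) for k, v in inputs.items()},
    )
    return out_dir


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    have = {getattr(h, "_hs_tag", None) for h in log.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler(sys.stderr)
        h._hs_tag = "stderr"
        h.setFormatter(logging.Formatter("[heatshock] %(message)s"))
        log.addHandler(h)
    fh = logging.FileHandler(out_dir / "pipeline.log")
    fh._hs_tag = "file"
    fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(fh)
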