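"""End-to-end orchestration: simulate/load -> filter -> cluster -> enrich
-> score -> survival -> drug, with TSV outputs and a JSON run manifest.

The manifest records package version, master seed, per-stage parameters,
output shapes, and a SHA-256 digest of every written file; a run hash over
the canonical manifest JSON makes byte-level reproducibility checkable.
Nothing time-dependent is written, so one seed gives identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from ubipattern import __version__, consensus, de, drug, enrichment, io, score, survival
from ubipattern.synthetic import (
    ImmuneSetSpec,
    SyntheticConfig,
    default_immune_sets,
    generate_expression,
    generate_gene_sets,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


class ValidationError(ValueError):
    """Configuration or input-schema problem."""


DEFAULTS: dict = {
    "seed": 0,
    "filter": {"mad_threshold": 0.5, "enabled": True},
    "cluster": {"k_min": 2, "k_max": 6, "reps": 100, "subsample": 0.8, "k": "auto"},
    "enrich": {"alpha": 0.25, "normalize": True, "diff_threshold": 0.15,
               "set_alpha": 0.05},
    "score": {"boruta_alpha": 0.01, "max_iter": 100, "n_trees": 150,
              "min_abs_r": 0.0},
    "survival": {"min_prop": 0.1, "adjust": []},
    "drug": {"enabled": True, "n_cell_lines": 60, "n_genes": 30, "folds": 10,
             "noise_sd": 0.1},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a YAML mapping")
    return cfg


def _merged(cfg: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def _synthetic_config(block: dict, seed: int) -> SyntheticConfig:
    block = dict(block)
    sets = block.pop("immune_sets", None)
    n_patterns = int(block.get("n_patterns", 3))
    if sets is None:
        immune = default_immune_sets(n_patterns)
    else:
        immune = tuple(
            ImmuneSetSpec(s["name"], int(s["size"]), tuple(s["pattern_shifts"]))
            for s in sets
        )
    props = block.pop("pattern_props", None)
    return SyntheticConfig(
        immune_sets=immune,
        pattern_props=tuple(props) if props else None,
        seed=int(block.pop("seed", seed)),
        **{k: v for k, v in block.items()},
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages in order; return the run manifest."""
    cfg = _merged(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {"version": __version__, "seed": seed, "stages": {}}
    files: dict[str, Path] = {}

    def record(stage: str, params: dict, outputs: dict[str, Path],
               shapes: dict | None = None) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "shapes": shapes or {},
            "outputs": {name: str(p.name) for name, p in outputs.items()},
        }
        files.update({p.name: p for p in outputs.values()})

    def fail(stage: str, exc: Exception) -> PipelineError:
        return PipelineError(f"stage {stage!r} failed: {exc}")

    # ---------------------------------------------------------------- inputs
    stage = "input"
    try:
        if "synthetic" in cfg:
            syn_cfg = _synthetic_config(cfg["synthetic"], seed)
            dataset = generate_expression(syn_cfg)
            expr = dataset.expression
            clinical = dataset.clinical
            gene_sets = generate_gene_sets(dataset)
            truth = pd.DataFrame(
                {"sample": dataset.planted_score.index,
                 "true_pattern": dataset.true_labels.to_numpy(),
                 "planted_score": dataset.planted_score.to_numpy()}
            )
            paths = {
                "expression": outdir / "expression.tsv",
                "clinical": outdir / "clinical.tsv",
                "gene_sets": outdir / "gene_sets.gmt",
                "truth": outdir / "truth.tsv",
                "gene_roles": outdir / "gene_roles.tsv",
            }
            io.write_expression(expr, paths["expression"])
            io.write_clinical(clinical, paths["clinical"])
            io.write_gmt(gene_sets, paths["gene_sets"])
            _write_tsv(truth, paths["truth"], index=False)
            _write_tsv(dataset.gene_roles.rename("role").to_frame(), paths["gene_roles"])
            params = {"mode": "synthetic", "n_samples": syn_cfg.n_samples,
                      "n_patterns": syn_cfg.n_patterns,
                      "pattern_separation": syn_cfg.pattern_separation,
                      "seed": syn_cfg.seed}
        elif "inputs" in cfg:
            blk = cfg["inputs"]
            expr = io.read_expression(blk["expression"])
            clinical = io.read_clinical(blk["clinical"])
            gene_sets = io.read_gmt(blk["gene_sets"])
            dataset = None
            paths = {}
            params = {"mode": "files", **{k: str(v) for k, v in blk.items()}}
        else:
            raise ValidationError("config needs a 'synthetic' or 'inputs' block")
        clin_samples = set(clinical["sample"])
        missing = sorted(set(expr.columns) - clin_samples)
        if missing:
            raise ValidationError(
                f"clinical table is missing expression sample id(s): {missing}"
            )
        record(stage, params, paths,
               {"expression": list(expr.shape), "clinical": list(clinical.shape)})
    except (ValidationError, io.SchemaError):
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise fail(stage, exc) from exc

    # ---------------------------------------------------------------- filter
    stage = "filter"
    fparams = cfg["filter"]
    try:
        if fparams.get("enabled", True):
            filtered = de.mad_filter(expr, float(fparams["mad_threshold"]))
        else:
            filtered = expr
        fpath = outdir / "expression_filtered.tsv"
        io.write_expression(filtered, fpath)
        record(stage, dict(fparams), {"filtered": fpath},
               {"filtered": list(filtered.shape)})
    except Exception as exc:
        raise fail(stage, exc) from exc

    # ---------------------------------------------------------------- cluster
    stage = "cluster"
    cparams = cfg["cluster"]
    try:
        if "REGULATORS" in gene_sets:
            reg_genes = [g for g in gene_sets["REGULATORS"] if g in filtered.index]
        else:
            reg_genes = list(filtered.index)
        if len(reg_genes) < 2:
            raise ValidationError("fewer than 2 regulator genes after filtering")
        reg_expr = filtered.loc[reg_genes]
        k_range = list(range(int(cparams["k_min"]), int(cparams["k_max"]) + 1))
        result = consensus.consensus_cluster(
            reg_expr, k_range, reps=int(cparams["reps"]),
            subsample=float(cparams["subsample"]), seed=seed,
        )
        areas = consensus.cdf_delta_area(result)
        if cparams.get("k", "auto") == "auto":
            candidates = areas.index[1:]  # smallest k has delta = area, not a gain
            chosen_k = int(areas.loc[candidates, "delta_area"].idxmax())
        else:
            chosen_k = int(cparams["k"])
        assignment = consensus.assign_patterns(result, chosen_k)
        cpaths = {"stats": outdir / "cluster_stats.tsv",
                  "labels": outdir / "patterns.tsv"}
        _write_tsv(areas, cpaths["stats"])
        lab_df = pd.DataFrame({"sample": assignment.labels.index,
                               "pattern": assignment.labels.to_numpy(),
                               "silhouette": assignment.silhouette.to_numpy()})
        _write_tsv(lab_df, cpaths["labels"], index=False)
        for k in k_range:
            p = outdir / f"consensus_k{k}.tsv"
            _write_tsv(pd.DataFrame(result.consensus[k], index=result.samples,
                                    columns=result.samples), p)
            cpaths[f"consensus_k{k}"] = p
        record(stage, {**{k: v for k, v in cparams.items()}, "chosen_k": chosen_k},
               cpaths, {"regulator_matrix": list(reg_expr.shape)})
    except Exception as exc:
        raise fail(stage, exc) from exc

    # ---------------------------------------------------------------- enrich
    stage = "enrich"
    eparams = cfg["enrich"]
    try:
        immune_sets = io.GeneSetCollection(
            {n: gene_sets[n] for n in gene_sets if n != "REGULATORS"}
        )
        epaths = {}
        if len(immune_sets):
            enr = enrichment.ssgsea_scores(
                filtered, immune_sets, alpha=float(eparams["alpha"]),
                normalize=bool(eparams["normalize"]),
            )
            table = enrichment.characterize_patterns(
                enr, assignment, diff_threshold=float(eparams["diff_threshold"]),
                alpha=float(eparams["set_alpha"]),
            )
            epaths = {"scores": outdir / "enrichment.tsv",
                      "signatures": outdir / "pattern_signatures.tsv"}
            _write_tsv(enr, epaths["scores"])
            _write_tsv(table, epaths["signatures"], index=False)
            shapes = {"enrichment": list(enr.shape)}
        else:
            log.warning("no immune/pathway gene sets supplied; skipping enrichment")
            shapes = {}
        record(stage, dict(eparams), epaths, shapes)
    except Exception as exc:
        raise fail(stage, exc) from exc

    # ---------------------------------------------------------------- score
    stage = "score"
    sparams = cfg["score"]
    try:
        partition = score.derive_partition(
            reg_expr, assignment, max_iter=int(sparams["max_iter"]),
            alpha=float(sparams["boruta_alpha"]), seed=seed,
            min_abs_r=float(sparams["min_abs_r"]), n_trees=int(sparams["n_trees"]),
        )
        result_s = score.pc1_score(reg_expr, partition)
        spaths = {"partition": outdir / "signature_partition.tsv",
                  "score": outdir / "score.tsv"}
        part_df = pd.DataFrame({
            "gene": partition.correlations.index,
            "r": partition.correlations.to_numpy(),
            "status": partition.boruta_status.reindex(partition.correlations.index)
                      .to_numpy(),
            "pool": ["A" if g in set(partition.genes_a)
                     else ("B" if g in set(partition.genes_b) else "-")
                     for g in partition.correlations.index],
        })
        _write_tsv(part_df, spaths["partition"], index=False)
        score_df = pd.DataFrame({"sample": result_s.score.index,
                                 "pc1_a": result_s.pc1_a.to_numpy(),
                                 "pc1_b": result_s.pc1_b.to_numpy(),
                                 "score": result_s.score.to_numpy()})
        _write_tsv(score_df, spaths["score"], index=False)
        record(stage, dict(sparams), spaths,
               {"genes_a": len(partition.genes_a), "genes_b": len(partition.genes_b)})
    except Exception as exc:
        raise fail(stage, exc) from exc

    # ---------------------------------------------------------------- survival
    stage = "survival"
    vparams = cfg["survival"]
    try:
        cut = survival.best_cutpoint(result_s.score, clinical,
                                     min_prop=float(vparams["min_prop"]))
        curves, chi2, logrank_p = survival.km_logrank(cut.labels, clinical)
        covs = pd.DataFrame({"score": result_s.score})
        adjust = list(vparams.get("adjust") or [])
        clin_idx = clinical.set_index("sample")
        for col in adjust:
            if col not in clin_idx.columns:
                raise ValidationError(f"adjustment covariate {col!r} not in clinical table")
            covs[col] = clin_idx[col].astype(float)
        fit = survival.cox_fit(covs, clinical)
        vpaths = {"cutpoint": outdir / "cutpoint.tsv",
                  "cox": outdir / "cox.tsv",
                  "km_high": outdir / "km_high.tsv",
                  "km_low": outdir / "km_low.tsv"}
        _write_tsv(pd.DataFrame([{
            "cutoff": cut.cutoff, "logrank_chi2": chi2, "logrank_p": logrank_p,
            "selection_biased": cut.selection_biased,
            "n_high": int((cut.labels == "high").sum()),
            "n_low": int((cut.labels == "low").sum()),
        }]), vpaths["cutpoint"], index=False)
        _write_tsv(fit.summary, vpaths["cox"])
        _write_tsv(curves["high"], vpaths["km_high"], index=False)
        _write_tsv(curves["low"], vpaths["km_low"], index=False)
        record(stage, dict(vparams), vpaths,
               {"logrank_p": logrank_p, "score_hr": float(fit.summary.loc["score", "hr"])})
    except Exception as exc:
        raise fail(stage, exc) from exc

    # ---------------------------------------------------------------- drug
    stage = "drug"
    dparams = cfg["drug"]
    try:
        dpaths = {}
        shapes = {}
        if dparams.get("enabled", True):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 104_729]))
            n_genes = min(int(dparams["n_genes"]), filtered.shape[0])
            genes = list(filtered.index[:n_genes])
            n_cells = int(dparams["n_cell_lines"])
            cell_x = rng.normal(8.0, 1.0, size=(n_genes, n_cells))
            beta = rng.normal(0.0, 1.0, size=n_genes)
            ic50_vals = cell_x.T @ beta / np.sqrt(n_genes)
            ic50_vals += rng.normal(0.0, float(dparams["noise_sd"]), size=n_cells)
            cell_expr = pd.DataFrame(cell_x, index=genes,
                                     columns=[f"CL{i:03d}" for i in range(n_cells)])
            ic50 = pd.Series(ic50_vals, index=cell_expr.columns)
            model = drug.ridge_train(cell_expr, ic50, folds=int(dparams["folds"]),
                                     seed=seed)
            pred = drug.predict_ic50(model, filtered)
            hi = pred[cut.labels.index[cut.labels == "high"]]
            lo = pred[cut.labels.index[cut.labels == "low"]]
            wstat, wp = stats.mannwhitneyu(hi, lo, alternative="two-sided")
            dpaths = {"predictions": outdir / "predicted_ic50.tsv"}
            _write_tsv(pred.rename("predicted_ic50").to_frame(), dpaths["predictions"])
            shapes = {"lambda": model.lambda_, "wilcoxon_p": float(wp),
                      "n_cell_lines": n_cells}
        record(stage, dict(dparams), dpaths, shapes)
    except Exception as exc:
        raise fail(stage, exc) from exc

    # ---------------------------------------------------------------- manifest
    manifest["files"] = {name: _sha256(p) for name, p in sorted(files.items())}
    body = json.dumps(manifest, sort_keys=True, default=str)
    manifest["manifest_hash"] = hashlib.sha256(body.encode()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
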