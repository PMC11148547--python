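"""End-to-end orchestration: simulate -> deconvolve -> EWAS -> delta-beta
-> cluster -> score -> evaluate, with plain-file handoff between stages.

Every stage reads only files and writes only files inside the run
directory, so any stage can be re-run or replaced (e.g. externally
estimated cell fractions can stand in for the deconvolution stage).  A
manifest records the seed, per-stage row counts, output hashes and
collected warnings.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cell_specific, deconvolution, evaluation, ewas, scoring, signature_clustering
from . import io_formats as iof
from . import simulate as sim

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_run_config"]

STAGES = ("simulate", "deconvolve", "ewas", "delta", "cluster", "score", "evaluate")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    out_dir: str
    seed: int = 0
    sim: dict = field(default_factory=dict)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    alpha: float = 0.05
    k: int = 4
    auto_k: bool = False
    n_reference_cpgs: int | None = 200
    min_n: int = cell_specific.MIN_N_PER_GROUP
    spread_min: float = cell_specific.SPREAD_MIN
    comparisons: list = field(default_factory=lambda: [["current", "never"]])
    external_fractions: dict | None = None  # tissue -> CSV path

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def load_run_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": {},
        "warnings": [],
        "outputs": {},
    }
    collected: list[str] = []

    def _stage(name: str, fn):
        if not config.enabled(name):
            manifest["stages"][name] = {"skipped": True}
            return
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                info = fn() or {}
            collected.extend(f"{name}: {w.message}" for w in caught)
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        info["wall_s"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][name] = info

    sim_cfg = sim.SimConfig(**{**config.sim, "seed": config.seed})
    tissues: list[str] = [
        t for t in sim.TISSUES if sim_cfg.n_samples.get(t)
    ]

    def stage_simulate():
        truth = sim.build_truth(sim_cfg)
        data = sim.simulate_dataset(truth, sim_cfg)
        truth.to_json(out / "truth.json")
        truth.archetype.to_frame().assign(cpg_id=truth.archetype.index)[
            ["cpg_id", "archetype"]
        ].to_csv(out / "archetypes_true.tsv", sep="\t", index=False)
        rows = {}
        for tissue, (beta, sheet, fractions) in data.items():
            iof.write_beta_matrix(beta, out / f"beta_{tissue}.tsv")
            iof.write_sample_sheet(sheet, out / f"sheet_{tissue}.csv")
            deconvolution.write_fractions(
                fractions, out / f"fractions_true_{tissue}.csv"
            )
            ref = sim.simulate_reference(truth, tissue, config.n_reference_cpgs)
            deconvolution.write_reference(ref, out / f"reference_{tissue}.tsv")
            rows[tissue] = {"cpgs": len(beta.cpg_ids), "samples": len(beta.sample_ids)}
        return {"tissues": rows}

    def stage_deconvolve():
        rows = {}
        for tissue in tissues:
            target = out / f"fractions_{tissue}.csv"
            if config.external_fractions and tissue in config.external_fractions:
                fr = deconvolution.read_fractions(config.external_fractions[tissue])
                deconvolution.write_fractions(fr, target)
                rows[tissue] = {"samples": len(fr.sample_ids), "source": "external"}
                continue
            beta = iof.read_beta_matrix(out / f"beta_{tissue}.tsv")
            ref = deconvolution.read_reference(out / f"reference_{tissue}.tsv")
            fr = deconvolution.estimate_fractions(beta, ref)
            deconvolution.write_fractions(fr, target)
            rows[tissue] = {"samples": len(fr.sample_ids), "source": "nnls"}
        return {"tissues": rows}

    def _fractions(tissue: str) -> deconvolution.CellFractions:
        path = out / f"fractions_{tissue}.csv"
        if not path.exists():  # deconvolution disabled: fall back to truth
            path = out / f"fractions_true_{tissue}.csv"
        return deconvolution.read_fractions(path)

    def stage_ewas():
        rows = {}
        for tissue in tissues:
            beta = iof.read_beta_matrix(out / f"beta_{tissue}.tsv")
            sheet = iof.read_sample_sheet(out / f"sheet_{tissue}.csv")
            res = ewas.run_ewas(beta, sheet, _fractions(tissue), tissue)
            ewas.write_ewas_result(res, out / f"ewas_{tissue}.tsv")
            rows[tissue] = {
                "tested": int(res.table["p"].notna().sum()),
                "holm_significant": int(len(res.significant(config.alpha))),
                "lambda_gc": round(res.lambda_gc, 4),
            }
        results = [
            ewas.read_ewas_result(out / f"ewas_{t}.tsv") for t in tissues
        ]
        annotation = None
        ann_path = out / "annotation.tsv"
        if ann_path.exists():
            annotation = iof.read_annotation(ann_path)
        sig = ewas.significant_sites(results, alpha=config.alpha, annotation=annotation)
        (out / "significant_cpgs.txt").write_text("\n".join(sig) + "\n")
        rows["union_significant"] = len(sig)
        return rows

    def stage_delta():
        cpgs = (out / "significant_cpgs.txt").read_text().split()
        datasets = {}
        for tissue in tissues:
            datasets[tissue] = (
                iof.read_beta_matrix(out / f"beta_{tissue}.tsv"),
                iof.read_sample_sheet(out / f"sheet_{tissue}.csv"),
                _fractions(tissue),
            )
        profile = cell_specific.build_delta_matrix(
            datasets, cpgs, min_n=config.min_n, spread_min=config.spread_min
        )
        cell_specific.write_delta_matrix(profile, out / "delta_matrix.tsv")
        return {"cpgs": len(cpgs), "tissues": len(datasets)}

    def stage_cluster():
        profile = cell_specific.read_delta_matrix(out / "delta_matrix.tsv")
        if config.auto_k:
            res = signature_clustering.select_k(profile)
        else:
            res = signature_clustering.cluster_delta_matrix(profile, k=config.k)
        signature_clustering.write_cluster_result(
            res, out / "clusters.tsv", out / "cluster_summary.tsv"
        )
        iof.write_cpg_sets(res.to_cpg_sets(), out / "signature_sets.tsv")
        return {
            "k": res.k,
            "silhouette": None if pd.isna(res.silhouette) else round(res.silhouette, 4),
            "labels": {str(c): l for c, l in res.labels.items()},
        }

    def stage_score():
        sets = iof.read_cpg_sets(out / "signature_sets.tsv")
        rows = {}
        for tissue in tissues:
            beta = iof.read_beta_matrix(out / f"beta_{tissue}.tsv")
            sheet = iof.read_sample_sheet(out / f"sheet_{tissue}.csv")
            fr = _fractions(tissue)
            f = (
                fr.lymphoid_proportion
                if tissue == "blood"
                else fr.immune_proportion
            )
            table = scoring.score_table(beta, sets, f, sheet)
            scoring.write_score_table(table, out / f"scores_{tissue}.csv")
            rows[tissue] = {"rows": len(table)}
        return rows

    def stage_evaluate():
        frames = []
        for tissue in tissues:
            table = pd.read_csv(out / f"scores_{tissue}.csv")
            res = evaluation.evaluate_comparisons(
                table, [tuple(c) for c in config.comparisons]
            )
            res.insert(0, "tissue", tissue)
            frames.append(res)
        combined = pd.concat(frames, ignore_index=True)
        combined.to_csv(out / "evaluation.csv", index=False, float_format="%.6f")
        return {"rows": len(combined)}

    _stage("simulate", stage_simulate)
    _stage("deconvolve", stage_deconvolve)
    _stage("ewas", stage_ewas)
    _stage("delta", stage_delta)
    _stage("cluster", stage_cluster)
    _stage("score", stage_score)
    _stage("evaluate", stage_evaluate)

    manifest["warnings"] = collected
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out
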