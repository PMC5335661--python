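"""End-to-end orchestration: simulate -> signature -> screen -> overlap ->
survival from a single YAML config, with a machine-readable run manifest.

All randomness flows from one top-level seed; rerunning with an identical
config and inputs reproduces byte-identical outputs.  Outputs are written
atomically (temp file + rename).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import pandas as pd
import yaml

from . import __version__
from .connectivity import ConnectivityScreen
from .io import (
    read_expression_matrix, read_gmt, read_rank_database, read_survival_table,
    write_expression_matrix, write_rank_database, write_survival_table,
)
from .overlap import PROTEIN_CODING_GENES, GeneSetOverlap
from .signature import GeneSignature, SignatureModel, read_signature, write_signature
from .survival import BiomarkerSurvival
from .synthetic import (
    SimulationConfig, simulate_expression, simulate_rank_database, simulate_survival,
)

__all__ = ["RunManifest", "run_pipeline", "truth_signature"]

logger = logging.getLogger("sigreverse")

STAGES = ("simulate", "signature", "screen", "overlap", "survival")


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: config digest, seed, versions,
    input digests and per-stage summary counts."""

    config_hash: str
    seed: int
    version: str
    stages: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        _atomic_write_text(Path(path), json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "version": self.version, "stages": self.stages, "inputs": self.inputs},
            indent=2, sort_keys=True))


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def truth_signature(sim: SimulationConfig) -> GeneSignature:
    """The planted ground-truth signature of a simulated expression matrix
    (used to build a rank database consistent with the planted DE genes)."""
    from .io import GeneSet

    _, truth = simulate_expression(sim)
    up = tuple(truth.loc[truth["direction"] == "up", "gene"])
    down = tuple(truth.loc[truth["direction"] == "down", "gene"])
    return GeneSignature(
        up=GeneSet("truth_UP", "planted up-regulated genes", up) if up else None,
        down=GeneSet("truth_DN", "planted down-regulated genes", down) if down else None,
        fdr_threshold=0.05,
        provenance="planted simulation truth",
    )


def _simulate_stage(cfg: dict, out: Path, seed: int) -> dict:
    sim = SimulationConfig(seed=int(cfg.get("seed", seed)),
                           **{k: v for k, v in cfg.items() if k != "seed"})
    out.mkdir(parents=True, exist_ok=True)
    matrix, de_truth = simulate_expression(sim)
    write_expression_matrix(matrix, out / "expression.tsv", out / "groups.tsv")
    de_truth.to_csv(out / "expression_truth.tsv", sep="\t", index=False)

    sig = truth_signature(sim)
    db, db_truth = simulate_rank_database(sim, sig)
    write_rank_database(db, out / "ranks.tsv", out / "meta.tsv")
    db_truth.to_csv(out / "ranks_truth.tsv", sep="\t", index=False)

    cohort, surv_truth = simulate_survival(sim)
    write_survival_table(cohort, out / "survival.tsv")
    surv_truth.to_csv(out / "survival_truth.tsv", sep="\t", index=False)
    return {
        "genes": sim.genes, "samples_per_group": sim.samples_per_group,
        "planted_de": sim.planted_de, "instances": sim.instances,
        "compounds": sim.compounds, "cohort_size": sim.cohort_size,
        "out_dir": str(out),
    }


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Run the stages requested in a YAML config.

    The config carries ``schema_version``, a top-level ``seed``, optional
    ``out_dir`` and a ``stages`` mapping; any subset of
    simulate/signature/screen/overlap/survival may be requested.  When the
    simulate stage runs first, later stages default their inputs to the
    simulated fixture files.  Missing inputs abort before any stage runs.
    """
    config_path = Path(config_path)
    raw = config_path.read_bytes()
    cfg = yaml.safe_load(raw) or {}
    if int(cfg.get("schema_version", 1)) != 1:
        raise ValueError(f"unsupported config schema_version {cfg.get('schema_version')}")
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", config_path.parent / "sigreverse_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages_cfg: dict = cfg.get("stages", {}) or {}
    unknown = set(stages_cfg) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) in config: {sorted(unknown)}")

    fixtures = out / "fixtures"

    def resolved(stage: str, key: str, default: Path | None) -> Path:
        val = (stages_cfg.get(stage) or {}).get(key)
        if val is not None:
            return Path(val)
        if default is not None and ("simulate" in stages_cfg or default.exists()):
            return default
        raise FileNotFoundError(f"stage {stage!r}: missing required input {key!r}")

    # ---- pre-flight: every requested stage must be able to name its inputs
    plan: dict[str, dict[str, Path]] = {}
    if "signature" in stages_cfg:
        plan["signature"] = {
            "matrix": resolved("signature", "matrix", fixtures / "expression.tsv"),
            "groups": resolved("signature", "groups", fixtures / "groups.tsv"),
        }
        ortho = (stages_cfg.get("signature") or {}).get("orthologs")
        if ortho:
            plan["signature"]["orthologs"] = Path(ortho)
    if "screen" in stages_cfg:
        plan["screen"] = {
            "ranks": resolved("screen", "ranks", fixtures / "ranks.tsv"),
            "meta": resolved("screen", "meta", fixtures / "meta.tsv"),
        }
        sig_path = (stages_cfg.get("screen") or {}).get("signature")
        if sig_path:
            plan["screen"]["signature"] = Path(sig_path)
        elif "signature" not in stages_cfg:
            raise FileNotFoundError("stage 'screen': missing required input 'signature'")
    if "overlap" in stages_cfg:
        plan["overlap"] = {
            "set_a": resolved("overlap", "set_a", None),
            "set_b": resolved("overlap", "set_b", None),
        }
    if "survival" in stages_cfg:
        plan["survival"] = {
            "table": resolved("survival", "table", fixtures / "survival.tsv"),
        }
    for stage, inputs in plan.items():
        for key, path in inputs.items():
            will_be_simulated = "simulate" in stages_cfg and path.parent == fixtures
            if not will_be_simulated and not path.exists():
                raise FileNotFoundError(f"stage {stage!r}: input {key}={path} does not exist")

    manifest = RunManifest(config_hash=hashlib.sha256(raw).hexdigest(),
                           seed=seed, version=__version__)
    for s in STAGES:
        manifest.stages[s] = {"requested": s in stages_cfg}

    def record(stage: str, summary: dict, t0: float) -> None:
        # timings go to the structured log only; the manifest stays
        # deterministic so identical runs produce identical bytes
        elapsed = round(time.perf_counter() - t0, 3)
        manifest.stages[stage].update(summary)
        logger.info("stage=%s elapsed_s=%s %s", stage, elapsed,
                    " ".join(f"{k}={v}" for k, v in summary.items()))

    try:
        if "simulate" in stages_cfg:
            t0 = time.perf_counter()
            record("simulate", _simulate_stage(stages_cfg["simulate"] or {}, fixtures, seed), t0)

        signature_file = out / "signature.gmt"
        if "signature" in stages_cfg:
            t0 = time.perf_counter()
            sc = stages_cfg["signature"] or {}
            model = SignatureModel.from_files(
                plan["signature"]["matrix"], plan["signature"]["groups"],
                plan["signature"].get("orthologs"))
            res = model.fit(permutations=int(sc.get("permutations", 1000)),
                            seed=int(sc.get("seed", seed)),
                            fdr_threshold=float(sc.get("fdr_threshold", 0.05)))
            write_signature(res.signature, signature_file,
                            sidecar={"permutations": res.permutations, "seed": res.seed})
            de_out = out / "de_results.tsv"
            _atomic_write_text(de_out, res.de.to_csv(sep="\t", index_label="gene"))
            record("signature", {"genes_tested": len(res.de),
                                 "n_up": res.signature.n_up,
                                 "n_down": res.signature.n_down}, t0)
            manifest.inputs[str(plan["signature"]["matrix"])] = _sha256(plan["signature"]["matrix"])

        if "screen" in stages_cfg:
            t0 = time.perf_counter()
            sc = stages_cfg["screen"] or {}
            sig_path = plan["screen"].get("signature", signature_file)
            model = ConnectivityScreen.from_files(
                plan["screen"]["ranks"], plan["screen"]["meta"], sig_path)
            res = model.fit(alpha=float(sc.get("alpha", 0.05)),
                            permutations=int(sc.get("permutations", 10000)),
                            seed=int(sc.get("seed", seed)),
                            sided=str(sc.get("p_sided", "two")))
            _atomic_write_text(out / "screen.tsv", res.table.to_csv(sep="\t", index=False))
            record("screen", {"compounds": len(res.table),
                              "selected": int(res.table["selected"].sum())}, t0)
            manifest.inputs[str(plan["screen"]["ranks"])] = _sha256(plan["screen"]["ranks"])

        if "overlap" in stages_cfg:
            t0 = time.perf_counter()
            sc = stages_cfg["overlap"] or {}
            set_a = read_gmt(plan["overlap"]["set_a"])[0]
            set_b = read_gmt(plan["overlap"]["set_b"])[0]
            bg = sc.get("background")
            background = read_gmt(bg)[0] if bg else int(sc.get("background_size",
                                                               PROTEIN_CODING_GENES))
            res = GeneSetOverlap(set_a, set_b, background).fit()
            _atomic_write_text(out / "overlap.json", json.dumps(res.as_dict(), indent=2))
            record("overlap", {"k": res.k, "expected": round(res.expected, 4),
                               "p_point": round(res.p_point, 4),
                               "p_tail": round(res.p_tail, 4)}, t0)

        if "survival" in stages_cfg:
            t0 = time.perf_counter()
            res = BiomarkerSurvival.from_file(plan["survival"]["table"]).fit()
            _atomic_write_text(out / "survival.json", json.dumps(res.as_dict(), indent=2))
            summary = {"n": len(res.model.cohort), **{f"n_{g}": v for g, v in
                                                      res.group_sizes.items()}}
            if res.logrank is not None:
                summary["logrank_p"] = round(res.logrank.p, 6)
            record("survival", summary, t0)
            manifest.inputs[str(plan["survival"]["table"])] = _sha256(plan["survival"]["table"])
    except Exception:
        manifest.stages["failed"] = True
        manifest.write(out / "manifest.json")
        raise

    manifest.write(out / "manifest.json")
    return manifest
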