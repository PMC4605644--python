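"""End-to-end orchestration: preprocessing, evaluation, combination, reports.

Every stochastic stage receives a seed derived deterministically from the
master seed and the stage name, and the run manifest records inputs, seeds
and SHA-256 hashes of every output so identical configurations reproduce
identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import combine as combine_mod
from . import evalsel, io, preprocess
from .pensvm import PenaltySpec


@dataclass
class PipelineConfig:
    matrix_path: str
    sheet_path: str
    out_dir: str
    problems: list[str] = field(default_factory=lambda: ["CD_vs_HC", "UC_vs_HC", "CD_vs_UC"])
    penalty_kind: str = "elasticscad"
    n_holdouts: int = 50
    n_permutations: int = 1000
    grid: list[dict] | None = None
    combine_classes: list[str] = field(default_factory=lambda: ["CD", "UC", "HC"])
    stages: list[str] = field(default_factory=lambda: ["preprocess", "evaluate", "combine"])
    seed: int = 0
    control_group: str = "HC"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _parse_grid(grid_cfg, kind):
    if grid_cfg is None:
        return None
    return [PenaltySpec(kind=kind, **g) for g in grid_cfg]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in fixed order and write the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # pre-flight: inputs must exist before any compute
    for p in (config.matrix_path, config.sheet_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file missing: {p}")

    matrix = io.read_expression_tsv(config.matrix_path)
    sheet = io.read_sample_sheet(config.sheet_path)
    io.check_matrix_sheet(matrix, sheet)

    manifest: dict = {
        "inputs": {
            "matrix": str(config.matrix_path),
            "sheet": str(config.sheet_path),
            "matrix_sha256": _sha256(Path(config.matrix_path)),
        },
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    schemes = evalsel.standard_problems()
    evaluations: dict[str, evalsel.HoldoutEvaluation] = {}
    selected: dict[str, tuple] = {}

    current_matrix, current_sheet = matrix, sheet
    for stage in config.stages:
        if stage == "preprocess":
            normalized, kept_sheet, fit, report = preprocess.preprocess_pipeline(
                matrix, sheet, control_group=config.control_group
            )
            current_matrix, current_sheet = normalized, kept_sheet
            norm_path = out / "normalized.tsv"
            normalized.to_csv(norm_path, sep="\t")
            io.write_json(report, out / "qc_report.json")
            manifest["stages"]["preprocess"] = report
            manifest["outputs"]["normalized.tsv"] = _sha256(norm_path)
            manifest["outputs"]["qc_report.json"] = _sha256(out / "qc_report.json")
        elif stage == "evaluate":
            for prob_name in config.problems:
                scheme = schemes.get(prob_name) or _ad_hoc_scheme(prob_name)
                ev = evalsel.evaluate_problem(
                    current_matrix,
                    current_sheet,
                    scheme,
                    penalty_kind=config.penalty_kind,
                    n_holdouts=config.n_holdouts,
                    grid=_parse_grid(config.grid, config.penalty_kind),
                    seed=stage_seed(config.seed, f"evaluate:{prob_name}"),
                )
                evaluations[prob_name] = ev
                model, sig = evalsel.select_sparsest_median(ev)
                selected[prob_name] = (model, scheme, sig)
                metrics = pd.DataFrame([r.metrics for r in ev.records])
                mpath = out / f"metrics_{prob_name}.csv"
                metrics.to_csv(mpath, index=False)
                io.write_json(
                    {
                        "problem": prob_name,
                        "median_auc": ev.median_auc,
                        "median_sparsity_pct_removed": ev.median_sparsity_pct_removed,
                        "n_failures": ev.n_failures,
                        "median_signature": sig.feature_ids,
                        "model": model.to_dict(),
                    },
                    out / f"model_{prob_name}.json",
                )
                manifest["outputs"][f"metrics_{prob_name}.csv"] = _sha256(mpath)
                manifest["outputs"][f"model_{prob_name}.json"] = _sha256(out / f"model_{prob_name}.json")
            manifest["stages"]["evaluate"] = {
                p: {"median_auc": evaluations[p].median_auc} for p in config.problems
            }
        elif stage == "combine":
            if not selected:
                raise RuntimeError("combine stage requires evaluate stage outputs")
            clf = combine_mod.CombinedClassifier(
                classes=tuple(config.combine_classes),
                models=[(m, s) for m, s, _ in selected.values()],
            )
            overall, per_group = combine_mod.combined_error_rate(clf, current_matrix, current_sheet)
            perm = combine_mod.permutation_z_test(
                clf,
                current_matrix,
                current_sheet,
                n_perm=config.n_permutations,
                seed=stage_seed(config.seed, "combine"),
            )
            report = {
                "classes": list(config.combine_classes),
                "error_rate": overall,
                "per_group_error": per_group,
                "permutation": {
                    "observed_error": perm.observed_error,
                    "null_mean": perm.null_mean,
                    "null_sd": perm.null_sd,
                    "z": perm.z,
                    "p": perm.p,
                    "significant": perm.significant,
                },
            }
            io.write_json(report, out / "combined_report.json")
            manifest["stages"]["combine"] = report
            manifest["outputs"]["combined_report.json"] = _sha256(out / "combined_report.json")
        else:
            raise ValueError(f"unknown stage {stage!r}")

    manifest_path = out / "manifest.json"
    io.write_json(manifest, manifest_path)
    return manifest


def _ad_hoc_scheme(name: str) -> evalsel.GroupScheme:
    """Parse problem names like 'CD_vs_UC+HC' into a GroupScheme."""
    try:
        pos, neg = name.split("_vs_")
    except ValueError as exc:
        raise ValueError(f"cannot parse problem name {name!r}") from exc
    expand = lambda s: tuple(evalsel.IC_GROUPS) if s == "IC" else (s,)
    positive = sum((expand(t) for t in pos.split("+")), ())
    negative = sum((expand(t) for t in neg.split("+")), ())
    return evalsel.GroupScheme(name=name, positive=positive, negative=negative)
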