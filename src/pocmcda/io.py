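"""File formats, configuration and the end-to-end pipeline.

All tabular inputs and outputs are long-format, comma-delimited UTF-8 text
with a header row; the wide matrix layout exists only in rendered reports.
The decision configuration is YAML with fields mirroring the domain types
(see ``config_to_dict`` for the schema).  Every pipeline run writes a JSON
manifest recording the seed and a SHA-256 digest of each input, so a run
can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .model import (
    Criterion,
    DecisionConfig,
    ImportanceSummary,
    Option,
    RatingScale,
    SatisficeRule,
    validate_config,
)
from .report import render_matrix
from .scoring import ScoringMatrix, build_matrix, validate_votes
from .screening import apply_exclusions
from .sensitivity import jackknife_ranks, perturb_weights
from .weights import assign_weights, summarize_all, validate_importance

__all__ = [
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "read_votes",
    "read_importance",
    "read_exclusions",
    "read_means",
    "PipelineError",
    "PipelineRun",
    "PipelineResult",
    "run_pipeline",
]


# ---------------------------------------------------------------- config


def config_to_dict(cfg: DecisionConfig) -> dict:
    """Serialise a DecisionConfig to plain data (the YAML schema)."""
    return {
        "rounding_dp": cfg.rounding_dp,
        "top_k": cfg.top_k,
        "criteria": [
            {
                "id": c.id,
                "description": c.description,
                "weight": c.weight,
                "scale": [[code, label] for code, label in c.scale.levels],
                "satisfice": sorted(c.satisfice.excluded_codes),
                **(
                    {
                        "importance": {
                            "mean": c.weight_summary.mean,
                            "median": c.weight_summary.median,
                            "minimum": c.weight_summary.minimum,
                            "maximum": c.weight_summary.maximum,
                            "n_respondents": c.weight_summary.n_respondents,
                        }
                    }
                    if c.weight_summary is not None
                    else {}
                ),
            }
            for c in cfg.criteria
        ],
        "options": [
            {"id": o.id, "label": o.label, "pre_excluded": o.pre_excluded}
            for o in cfg.options
        ],
        "exclude": list(cfg.excluded_option_ids),
    }


def config_from_dict(data: dict) -> DecisionConfig:
    """Parse the YAML schema back into a DecisionConfig."""
    criteria = []
    for c in data.get("criteria", []):
        summary = None
        if "importance" in c:
            summary = ImportanceSummary(**c["importance"])
        criteria.append(
            Criterion(
                id=c["id"],
                description=c.get("description", ""),
                weight=float(c.get("weight", 0.0)),
                scale=RatingScale(
                    levels=tuple((int(code), str(label)) for code, label in c["scale"])
                ),
                satisfice=SatisficeRule(
                    excluded_codes=frozenset(int(x) for x in c.get("satisfice", []))
                ),
                weight_summary=summary,
            )
        )
    options = [
        Option(
            id=o["id"],
            label=o.get("label", ""),
            pre_excluded=bool(o.get("pre_excluded", False)),
        )
        for o in data.get("options", [])
    ]
    return DecisionConfig(
        criteria=tuple(criteria),
        options=tuple(options),
        rounding_dp=int(data.get("rounding_dp", 2)),
        top_k=int(data.get("top_k", 3)),
        excluded_option_ids=tuple(data.get("exclude", [])),
    )


def load_config(path: str | Path) -> DecisionConfig:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(cfg: DecisionConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------- tables


def read_votes(path: str | Path, cfg: DecisionConfig) -> pd.DataFrame:
    """Read and validate a long-format vote table.

    Raises ``ValueError`` listing every problem with its row number.
    """
    votes = pd.read_csv(path)
    problems = validate_votes(votes, cfg)
    if problems:
        raise ValueError(f"invalid vote table {path}:\n" + "\n".join(problems))
    return votes


def read_importance(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format importance-response table."""
    responses = pd.read_csv(path)
    problems = validate_importance(responses)
    if problems:
        raise ValueError(f"invalid importance table {path}:\n" + "\n".join(problems))
    return responses


def read_exclusions(path: str | Path) -> list[str]:
    """Read a one-column text file of option ids (blank lines, '#' comments ok)."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#") and line.lower() != "option":
            out.append(line)
    return out


def read_means(path: str | Path) -> pd.DataFrame:
    """Read a pre-aggregated cell-mean table (option, criterion, mean[, n_votes])."""
    df = pd.read_csv(path)
    missing = [c for c in ("option", "criterion", "mean") if c not in df.columns]
    if missing:
        raise ValueError(f"means table {path}: missing column(s) {missing}")
    return df


# -------------------------------------------------------------- pipeline


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineRun:
    """Inputs for one end-to-end run."""

    config_path: Path
    votes_path: Path
    out_dir: Path
    importance_path: Optional[Path] = None
    exclude_path: Optional[Path] = None
    seed: int = 0
    run_sensitivity: bool = False
    n_reps: int = 10_000
    noise_scale: float = 0.1
    top_k: Optional[int] = None


@dataclass
class PipelineResult:
    matrix: ScoringMatrix
    manifest: dict
    sensitivity: Optional[object] = None
    jackknife: Optional[object] = None
    exclusions: tuple = field(default_factory=tuple)


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(run: PipelineRun) -> PipelineResult:
    """Weights -> exclusions -> scoring -> ranking -> (optional) sensitivity.

    Writes to ``run.out_dir``: ``matrix_cells.csv``, ``option_totals.csv``,
    ``exclusions.csv``, ``report.txt``, ``manifest.json`` and, when
    sensitivity is requested, ``sensitivity_ranks.csv`` and
    ``jackknife_ranks.csv``.  Any stage error raises
    :class:`PipelineError` naming the stage.
    """
    log: list[str] = []
    manifest: dict = {"seed": run.seed, "inputs": {}, "stages": log}

    # --- configuration
    try:
        cfg = load_config(run.config_path)
        manifest["inputs"]["config"] = _digest(run.config_path)
        problems = validate_config(cfg)
        if problems:
            raise ValueError("; ".join(problems))
        if run.top_k is not None:
            cfg = cfg.model_copy(update={"top_k": run.top_k})
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("config", e) from e
    log.append("config: loaded and validated")

    # --- weights from importance survey (optional; else config weights)
    if run.importance_path is not None:
        try:
            responses = read_importance(run.importance_path)
            manifest["inputs"]["importance"] = _digest(run.importance_path)
            summaries = summarize_all(responses)
            cfg = cfg.model_copy(
                update={"criteria": assign_weights(cfg.criteria, summaries)}
            )
        except Exception as e:
            raise PipelineError("weights", e) from e
        log.append(f"weights: assigned from {len(responses)} survey responses")
    else:
        log.append("weights: taken from configuration")

    # --- pre-scoring exclusions
    try:
        excluded = list(cfg.excluded_option_ids)
        excluded += [o.id for o in cfg.options if o.pre_excluded and o.id not in excluded]
        if run.exclude_path is not None:
            manifest["inputs"]["exclude"] = _digest(run.exclude_path)
            excluded += [
                oid for oid in read_exclusions(run.exclude_path) if oid not in excluded
            ]
        survivors, records = apply_exclusions(cfg.options, excluded)
        scoring_cfg = cfg.model_copy(update={"options": survivors})
    except Exception as e:
        raise PipelineError("screen", e) from e
    log.append(f"screen: excluded {len(records)}, {len(survivors)} options remain")

    # --- scoring and ranking
    try:
        votes = read_votes(run.votes_path, scoring_cfg)
        manifest["inputs"]["votes"] = _digest(run.votes_path)
        matrix = build_matrix(scoring_cfg, votes)
    except Exception as e:
        raise PipelineError("score", e) from e
    log.append(f"score: {len(matrix.cells)} cells, top-{scoring_cfg.top_k} = "
               f"{list(matrix.top_k_ids)}")

    # --- sensitivity (optional)
    sens = jack = None
    if run.run_sensitivity:
        try:
            jack = jackknife_ranks(scoring_cfg, votes)
            sens = perturb_weights(
                scoring_cfg,
                matrix,
                n_reps=run.n_reps,
                noise_scale=run.noise_scale,
                seed=run.seed,
            )
        except Exception as e:
            raise PipelineError("sensitivity", e) from e
        log.append(
            f"sensitivity: top-k retention {sens.top_k_retention:.4f} over "
            f"{run.n_reps} replicates (noise scale {run.noise_scale})"
        )

    # --- outputs
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.cells.to_csv(out / "matrix_cells.csv", index=False)
    matrix.options.to_csv(out / "option_totals.csv", index=False)
    pd.DataFrame(
        [
            {"option": r.option_id, "reason": r.reason.value, "detail": r.detail}
            for r in records
        ],
        columns=["option", "reason", "detail"],
    ).to_csv(out / "exclusions.csv", index=False)
    (out / "report.txt").write_text(render_matrix(matrix), encoding="utf-8")
    if jack is not None:
        jack.ranks.to_csv(out / "jackknife_ranks.csv", index=False)
    if sens is not None:
        sens.rank_freq.to_csv(out / "sensitivity_ranks.csv", index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.append(f"write: outputs in {out}")

    return PipelineResult(
        matrix=matrix,
        manifest=manifest,
        sensitivity=sens,
        jackknife=jack,
        exclusions=records,
    )
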