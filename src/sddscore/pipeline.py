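"""End-to-end pipeline: simulate -> score -> reduce -> map outcomes -> associate -> report.

Every run is fully determined by its configuration (including the seed):
output CSVs are written with a fixed float format so re-running a config
reproduces them bit-identically. Each stage's outputs land in the configured
output directory together with the effective config and a run log; a stage
failure aborts with the stage name and a manifest of what was produced.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .codebook import Codebook, default_codebook
from .models import descriptive_tables, run_battery
from .outcomes import ConditionMap, apply_outcomes, synthetic_condition_map
from .reduction import FactorReducer
from .scoring import score_cohort
from .simulate import GeneratorConfig, generate_cohort, truth_report

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, manifest: list[str], cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.__cause__ = cause


class PipelineConfig(BaseModel):
    """Configuration for one pipeline run.

    Either ``cohort_path`` points at an existing cohort CSV, or
    ``simulate_n`` asks the generator for a synthetic cohort of that size.
    Codebook and condition map default to the shipped 17-item codebook and
    the synthetic test mapping.
    """

    out_dir: Path
    cohort_path: Optional[Path] = None
    simulate_n: Optional[int] = None
    codebook_path: Optional[Path] = None
    condition_map_path: Optional[Path] = None
    seed: int = 0
    total_mode: str = "item_mean"  # or "domain_mean"
    loading_threshold: float = 0.4
    alpha_threshold: float = 0.7
    n_factors: int | str = "auto"
    model_levels: list[int] = Field(default_factory=lambda: [1, 2, 3])
    stratify: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def validate_inputs(self) -> None:
        if self.cohort_path is None and self.simulate_n is None:
            raise ValueError("either cohort_path or simulate_n is required")
        for p in (self.cohort_path, self.codebook_path, self.condition_map_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full pipeline and return the manifest of written files."""
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    written: dict[str, Path] = {}

    def emit(name: str, path: Path) -> None:
        manifest.append(str(path))
        written[name] = path

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    (out / "partial_manifest.json").write_text(
                        json.dumps({"failed_stage": name, "written": manifest}, indent=2)
                    )
                    raise PipelineError(name, manifest, exc) from exc
                return False

        return _Ctx()

    cfg_path = out / "effective_config.yaml"
    cfg_path.write_text(
        yaml.safe_dump(
            json.loads(config.model_dump_json()), sort_keys=False
        )
    )
    emit("config", cfg_path)

    codebook = (
        Codebook.from_file(config.codebook_path)
        if config.codebook_path
        else default_codebook()
    )
    cmap = (
        ConditionMap.from_csv(config.condition_map_path)
        if config.condition_map_path
        else synthetic_condition_map()
    )

    with stage("simulate"):
        if config.simulate_n is not None:
            gen = GeneratorConfig(
                n=config.simulate_n, seed=config.seed, codebook=codebook
            )
            cohort = generate_cohort(gen)
            _write_csv(cohort, out / "cohort.csv")
            emit("cohort", out / "cohort.csv")
            (out / "truth.json").write_text(json.dumps(truth_report(gen), indent=2))
            emit("truth", out / "truth.json")
        else:
            cohort = pd.read_csv(config.cohort_path, dtype={"condition_codes": str})

    with stage("score"):
        scored = score_cohort(cohort, codebook, mode=config.total_mode)
        data = pd.concat([cohort, scored], axis=1)
        _write_csv(data, out / "scored.csv")
        emit("scored", out / "scored.csv")

    with stage("reduce"):
        unit = scored[[f"score_{n}" for n in codebook.item_names]].rename(
            columns=lambda c: c.removeprefix("score_")
        )
        reducer = FactorReducer(
            n_factors=config.n_factors,
            loading_threshold=config.loading_threshold,
            alpha_threshold=config.alpha_threshold,
        ).fit(unit)
        selection = reducer.selection_
        _write_csv(selection.report(), out / "table4_selection_report.csv")
        emit("selection", out / "table4_selection_report.csv")

    with stage("map_outcomes"):
        flags = apply_outcomes(cohort, cmap)
        data = pd.concat([data, flags], axis=1)

    with stage("associate"):
        tables = run_battery(
            data,
            codebook,
            selection=selection,
            levels=config.model_levels,
            stratify=config.stratify,
        )
        name_map = {
            "total": "table2_total.csv",
            "conditions": "table3_conditions.csv",
            "selected_variables": "table4_selected_variables.csv",
            "ordinal": "ordinal_condition_count.csv",
            "stratified": "stratified.csv",
        }
        for key, fname in name_map.items():
            if key in tables:
                _write_csv(tables[key], out / fname)
                emit(key, out / fname)

    with stage("report"):
        desc = descriptive_tables(data, codebook)
        _write_csv(desc["characteristics"], out / "table1_characteristics.csv")
        emit("characteristics", out / "table1_characteristics.csv")
        _write_csv(desc["domain_comparison"], out / "fig1_domain_comparison.csv")
        emit("domain_comparison", out / "fig1_domain_comparison.csv")
        run_log = {
            "package_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "n": int(len(data)),
            "selected_items": selection.selected_items,
            "manifest": manifest,
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
        emit("run_log", out / "run_log.json")

    return written
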