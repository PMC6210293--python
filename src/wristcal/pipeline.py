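"""End-to-end orchestration: simulate -> filter -> compare -> calibrate -> classify.

``run_pipeline`` runs the whole analysis from a :class:`PipelineConfig`
and writes a manifest recording seeds, the package version, and a SHA-256
digest of every output file; re-running with the same config reproduces
byte-identical outputs.  Any stage failure aborts the run with the stage
name and removes the files that stage had begun writing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .epoch_io import (
    add_vector_magnitude,
    apply_observation_filter,
    write_epoch_dir,
    write_observation_log,
)
from .profiles import reference_profiles
from .quantile_comparison import BootstrapConfig, compare_all
from .roc_calibration import CalibrationConfig, calibrate_all
from .sedentary_summary import classify_epochs, summarize
from .synthetic_data import (
    ActivityProfile,
    GeneratorConfig,
    WristQuantiles,
    generate_dataset,
)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

logger = logging.getLogger("wristcal")


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = field(
        default_factory=lambda: GeneratorConfig(activities=reference_profiles())
    )
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    output_dir: Path = Path("wristcal_output")
    log_level: str = "INFO"

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Override every stage seed from one master seed."""
        return replace(
            self,
            generator=replace(self.generator, seed=seed),
            bootstrap=replace(self.bootstrap, seed=seed + 1),
            calibration=replace(self.calibration, seed=seed + 2),
        )


def _activity_from_dict(d: dict) -> ActivityProfile:
    kwargs = dict(d)
    kwargs["dominant"] = WristQuantiles(*kwargs["dominant"])
    kwargs["non_dominant"] = WristQuantiles(*kwargs["non_dominant"])
    return ActivityProfile(**kwargs)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Build a pipeline config from a YAML file; missing keys use defaults."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    gen_raw = dict(raw.get("generator", {}))
    activities = gen_raw.pop("activities", None)
    if activities is None:
        profiles = reference_profiles()
    else:
        profiles = tuple(_activity_from_dict(a) for a in activities)
    generator = GeneratorConfig(activities=profiles, **gen_raw)
    boot_raw = dict(raw.get("bootstrap", {}))
    calib_raw = dict(raw.get("calibration", {}))
    if "signals" in calib_raw:
        calib_raw["signals"] = tuple(calib_raw["signals"])
    return PipelineConfig(
        generator=generator,
        bootstrap=BootstrapConfig(**boot_raw),
        calibration=CalibrationConfig(**calib_raw),
        output_dir=Path(raw.get("output_dir", "wristcal_output")),
        log_level=str(raw.get("log_level", "INFO")),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _config_dict(config: PipelineConfig) -> dict:
    d = {
        "generator": asdict(config.generator),
        "bootstrap": asdict(config.bootstrap),
        "calibration": asdict(config.calibration),
        "output_dir": str(config.output_dir),
        "log_level": config.log_level,
    }
    d["calibration"]["signals"] = list(config.calibration.signals)
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written as manifest.json)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.setLevel(config.log_level.upper())
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)

    produced: list[Path] = []
    stage = "simulate"
    try:
        logger.info("stage simulate: %d children x %d activities",
                    config.generator.n_children, len(config.generator.activities))
        epochs, log = generate_dataset(config.generator)
        epoch_dir = out / "epochs"
        if epoch_dir.exists():
            shutil.rmtree(epoch_dir)
        write_epoch_dir(epochs, epoch_dir)
        produced.append(epoch_dir)
        write_observation_log(log, out / "observation_log.tsv")
        produced.append(out / "observation_log.tsv")

        stage = "filter"
        filtered = apply_observation_filter(epochs, log)
        logger.info("stage filter: kept %d of %d epochs", len(filtered), len(epochs))
        filtered = add_vector_magnitude(filtered)
        filtered.to_csv(out / "filtered_epochs.csv", index=False,
                        float_format="%.6g")
        produced.append(out / "filtered_epochs.csv")

        stage = "compare-quantiles"
        diffs = compare_all(filtered, config.bootstrap)
        _write_tsv(diffs, out / "quantile_diffs.tsv")
        produced.append(out / "quantile_diffs.tsv")
        logger.info("stage compare-quantiles: %d contrasts", len(diffs))

        stage = "calibrate"
        cutpoints, folds = calibrate_all(filtered, config.calibration)
        _write_tsv(cutpoints, out / "cutpoints.tsv")
        _write_tsv(folds, out / "cutpoint_folds.tsv")
        produced += [out / "cutpoints.tsv", out / "cutpoint_folds.tsv"]
        logger.info("stage calibrate: %d signal x wrist cut-points", len(cutpoints))

        stage = "classify"
        rows = []
        for _, row in cutpoints[cutpoints["signal"] == "axis1"].iterrows():
            wrist = row["wrist"]
            series = filtered.loc[filtered["wrist"] == wrist, "axis1"]
            labels = classify_epochs(series, row["cutpoint_int"])
            summ = summarize(labels)
            rows.append(
                {
                    "wrist": wrist,
                    "cutpoint": row["cutpoint_int"],
                    "minutes_sedentary": summ.minutes_sedentary,
                    "minutes_light_plus": summ.minutes_light_plus,
                    "total_minutes": summ.total_minutes,
                    "epochs_classified": summ.epochs_classified,
                }
            )
        _write_tsv(pd.DataFrame(rows), out / "sedentary_summary.tsv")
        produced.append(out / "sedentary_summary.tsv")

        stage = "manifest"
        files = sorted(
            p for p in out.rglob("*")
            if p.is_file() and p.name not in ("manifest.json", "pipeline.log")
        )
        manifest = {
            "version": __version__,
            "config": _config_dict(config),
            "outputs": {
                str(p.relative_to(out)): _sha256(p) for p in files
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return manifest
    except Exception as exc:
        for p in produced:
            if p.is_dir():
                shutil.rmtree(p, ignore_errors=True)
            elif p.exists():
                p.unlink()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
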