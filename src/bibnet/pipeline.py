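"""End-to-end pipeline: phantoms -> preprocess -> train -> infer -> evaluate.

A run is fully described by a :class:`RunConfig` (nested sections, strict
schema: unknown keys are rejected with the offending field named) plus a
root seed; every artifact directory is stamped with the seed and a hash of
the canonical config so drift between runs is detectable.  All randomness
flows from the root seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .core_io import StructureSet, write_image, write_structure_set
from .evaluation import evaluate_cohort
from .inference import PostprocessSpec, infer_full_image, postprocess
from .models import BibNetConfig, build_bibnet, save_model
from .phantoms import PhantomSpec, generate_cohort
from .training import TrainConfig, tournament_train

__all__ = ["RunConfig", "ConfigSchemaError", "run_pipeline", "config_hash"]

log = logging.getLogger("bibnet")


class ConfigSchemaError(ValueError):
    """A configuration dictionary violates the schema."""


@dataclass(frozen=True)
class RunConfig:
    n_train: int = 8
    n_val: int = 4
    n_test: int = 4
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    model: BibNetConfig = field(default_factory=BibNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    post: PostprocessSpec = field(default_factory=PostprocessSpec)
    seed: int = 0

    @staticmethod
    def from_dict(raw: dict[str, Any]) -> "RunConfig":
        """Build from a nested dict, rejecting unknown keys field by field."""

        def build(cls, section: dict[str, Any], path: str):
            if not isinstance(section, dict):
                raise ConfigSchemaError(f"{path}: expected a mapping")
            names = {f.name: f for f in dataclasses.fields(cls)}
            unknown = set(section) - set(names)
            if unknown:
                raise ConfigSchemaError(
                    f"{path}: unknown field(s) {sorted(unknown)}; "
                    f"allowed: {sorted(names)}"
                )
            kwargs = {}
            for key, value in section.items():
                f = names[key]
                if dataclasses.is_dataclass(f.type) or key in (
                    "phantom", "model", "train", "post", "sampler"
                ):
                    sub_cls = {
                        "phantom": PhantomSpec, "model": BibNetConfig,
                        "train": TrainConfig, "post": PostprocessSpec,
                    }.get(key)
                    if sub_cls is None:
                        from .sampling import SamplerConfig
                        sub_cls = SamplerConfig
                    kwargs[key] = build(sub_cls, value, f"{path}.{key}")
                elif isinstance(value, list):
                    kwargs[key] = tuple(
                        tuple(v) if isinstance(v, list) else v for v in value
                    )
                else:
                    kwargs[key] = value
            try:
                return cls(**kwargs)
            except (TypeError, ValueError) as exc:
                raise ConfigSchemaError(f"{path}: {exc}") from exc

        return build(RunConfig, dict(raw), "config")


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stamp(out_dir: Path, config: RunConfig, stage: str, seconds: float) -> None:
    stamp_path = out_dir / "run.json"
    record = {"config_hash": config_hash(config), "seed": config.seed, "stages": {}}
    if stamp_path.exists():
        record = json.loads(stamp_path.read_text())
    record["stages"][stage] = {"wall_time_s": round(seconds, 3)}
    stamp_path.write_text(json.dumps(record, indent=1))


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run phantom generation, training, inference and evaluation.

    Returns the path of the evaluation report CSV.  Partial artifacts are
    retained if a later stage fails.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    organs = list(config.train.organs)

    t0 = time.time()
    n_total = config.n_train + config.n_val + config.n_test
    spec = dataclasses.replace(config.phantom, seed=config.seed)
    cases = generate_cohort(spec, n_total, seed=config.seed)
    train_cases = [(c.image, c.structures) for c in cases[: config.n_train]]
    val_cases = [
        (c.image, c.structures)
        for c in cases[config.n_train : config.n_train + config.n_val]
    ]
    test_cases = cases[config.n_train + config.n_val :]
    log.info("generated %d phantoms (%.1fs)", n_total, time.time() - t0)
    _stamp(out_dir, config, "phantoms", time.time() - t0)

    t0 = time.time()
    model_cfg = dataclasses.replace(config.model, out_channels=len(organs))

    def factory(seed: int):
        return build_bibnet(
            dataclasses.replace(model_cfg, seed=seed), output_names=tuple(organs)
        )

    train_cfg = dataclasses.replace(config.train, seed=config.seed)
    net, state = tournament_train(
        factory, train_cases, val_cases, train_cfg, log_path=out_dir / "training_log.csv"
    )
    save_model(net, str(out_dir / "model"))
    log.info("training finished at epoch %d (%.1fs)", state.epoch, time.time() - t0)
    _stamp(out_dir, config, "train", time.time() - t0)

    t0 = time.time()
    predictions: dict[str, StructureSet] = {}
    truths: dict[str, StructureSet] = {}
    for case in test_cases:
        probs = infer_full_image(net, case.image, window=train_cfg.intensity_window)
        masks = {}
        for organ in organs:
            mask, _empty = postprocess(probs[organ], case.image, config.post)
            masks[organ] = mask
        predictions[case.case_id] = StructureSet(masks)
        truths[case.case_id] = StructureSet(
            {o: case.structures[o] for o in organs}
        )
        case_dir = out_dir / "predictions" / case.case_id
        write_structure_set(predictions[case.case_id], case_dir)
        write_image(case.image, case_dir / "image.nii.gz")
    _stamp(out_dir, config, "infer", time.time() - t0)

    t0 = time.time()
    report = evaluate_cohort(predictions, truths, organs=organs)
    report_path = out_dir / "report.csv"
    report.to_csv(report_path)
    _stamp(out_dir, config, "evaluate", time.time() - t0)
    log.info("report written to %s", report_path)
    return report_path
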