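"""End-to-end orchestration: phantom -> preprocess -> patches -> train -> evaluate.

`build_dataset` is the in-memory path used by the library, tests and the
acceptance script; `run_pipeline` is the on-disk, stage-wise path behind the
CLI (artifacts + resolved config + checksum manifest per stage).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluate import ablation_run, comparison_table, render_projection
from .model import AugmentRanges, TrainConfig
from .patches import DatasetManifest, build_manifest, extract_patches, split_sections
from .phantom import PhantomParams, PhantomSection, generate_phantom, read_section, write_section
from .preprocess import (
    ChannelStats,
    LabelMap,
    MultimodalStack,
    ParameterError,
    assemble_stack,
    normalize_to_amide1,
    resample,
    tissue_mask,
)

__all__ = ["PipelineConfig", "build_dataset", "preprocess_section", "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = ("phantom", "preprocess", "patch", "train", "evaluate")


class DependencyError(RuntimeError):
    """A requested stage is missing its upstream artifacts."""


@dataclass
class PipelineConfig:
    """Resolved configuration for a full pipeline run."""

    out_dir: str = "specseg-run"
    n_sections: int = 12
    phantom: PhantomParams = field(default_factory=PhantomParams)
    clip_max: float = 3.0
    mask_method: str = "otsu"
    df_grayscale: bool = True
    patch_size: int = 256
    min_tissue_frac: float = 0.5
    split_counts: tuple[int, ...] = (8, 2, 2)
    two_way_split: bool = False  # held-out sections double as validation
    train: TrainConfig = field(default_factory=TrainConfig)
    modalities: tuple[str, ...] = ("DF", "IR", "COMBINED")
    tile: int = 256
    overlap: int = 32
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.n_sections < 3:
            raise ParameterError("need at least 3 sections")
        if self.patch_size <= 0 or not (0 <= self.min_tissue_frac <= 1):
            raise ParameterError("invalid patch rules")
        if sum(self.split_counts) > self.n_sections:
            raise ParameterError("split counts exceed n_sections")
        for m in self.modalities:
            if m not in ("DF", "IR", "COMBINED"):
                raise ParameterError(f"unknown modality {m}")
        if self.mask_method not in ("otsu", "fixed"):
            raise ParameterError("mask_method must be otsu or fixed")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d.pop("version", None)
        if "phantom" in d and isinstance(d["phantom"], dict):
            d["phantom"] = PhantomParams(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in d["phantom"].items()}
            )
        if "train" in d and isinstance(d["train"], dict):
            td = dict(d["train"])
            if "augment" in td and isinstance(td["augment"], dict):
                td["augment"] = AugmentRanges(**td["augment"])
            d["train"] = TrainConfig(**td)
        for key in ("split_counts", "modalities"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# in-memory path
# ---------------------------------------------------------------------------

def make_sections(
    params: PhantomParams, n_sections: int, seed: int = 0
) -> list[PhantomSection]:
    """Generate n sections with per-section seeds derived from ``seed``."""
    out = []
    for i in range(n_sections):
        p = dataclasses.replace(params, seed=int(seed) + i)
        out.append(generate_phantom(p, section_id=f"phantom-{seed:04d}-{i:03d}"))
    return out


def preprocess_section(
    section: PhantomSection,
    clip_max: float = 3.0,
    mask_method: str = "otsu",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, LabelMap]:
    """Bring one section onto the 1 um grid: (r1238, r1546, df, mask, labels)."""
    bands = {}
    for wn, band in section.raw_band_images.items():
        bands[wn] = resample(band.pixels, band.pixel_size, 1.0, mode="intensity")
    df = resample(section.darkfield, section.darkfield_pixel_um, 1.0, mode="intensity")
    mask = tissue_mask(bands[1658.0], method=mask_method)
    norm = normalize_to_amide1(
        bands[1238.0], bands[1546.0], bands[1658.0], mask, clip_max=clip_max
    )
    return norm.r1238, norm.r1546, df, norm.mask, section.labels


def build_dataset(
    sections: list[PhantomSection],
    split_counts: tuple[int, ...] = (8, 2, 2),
    seed: int = 0,
    patch_size: int = 256,
    min_tissue_frac: float = 0.5,
    clip_max: float = 3.0,
    two_way_split: bool = False,
) -> tuple[DatasetManifest, dict[str, MultimodalStack], dict[str, LabelMap], dict[str, list[str]]]:
    """Preprocess sections, split by section, and build the patch manifest.

    Standardization statistics are computed over the masked pixels of the
    *training* sections only, stored on the manifest and on every stack
    (training and held-out alike), so test channels are never re-estimated.
    """
    pre = {s.section_id: preprocess_section(s, clip_max=clip_max) for s in sections}
    names = ("train", "test") if (two_way_split or len(split_counts) == 2) else None
    splits = split_sections(
        [s.section_id for s in sections], counts=split_counts, seed=seed, split_names=names
    )
    # train-split channel statistics
    sums = np.zeros(3)
    sqs = np.zeros(3)
    n = 0
    for sid in splits["train"]:
        r1, r2, df, mask, _ = pre[sid]
        ch = np.stack([r1, r2, df]).astype(np.float64)[:, mask]
        sums += ch.sum(axis=1)
        sqs += (ch**2).sum(axis=1)
        n += ch.shape[1]
    mean = sums / max(n, 1)
    var = np.maximum(sqs / max(n, 1) - mean**2, 0.0)
    sd = np.where(var > 0, np.sqrt(var), 1.0)
    stats = ChannelStats(mean=mean, sd=sd)

    stacks: dict[str, MultimodalStack] = {}
    labels: dict[str, LabelMap] = {}
    patches_by_section = {}
    for sid, (r1, r2, df, mask, lab) in pre.items():
        stack, _ = assemble_stack(r1, r2, df, mask, labels=lab, stats=stats, section_id=sid)
        stacks[sid] = stack
        labels[sid] = lab
        patches_by_section[sid] = extract_patches(
            stack, lab, patch_size=patch_size, min_tissue_frac=min_tissue_frac
        )
    manifest = build_manifest(splits, patches_by_section, stats=stats)
    return manifest, stacks, labels, splits


# ---------------------------------------------------------------------------
# on-disk stage runner (CLI back end)
# ---------------------------------------------------------------------------

def _stage_dir(cfg: PipelineConfig, stage: str) -> Path:
    return Path(cfg.out_dir) / stage


def _stage_done(cfg: PipelineConfig, stage: str) -> bool:
    return (_stage_dir(cfg, stage) / ".complete").exists()


def _finish_stage(cfg: PipelineConfig, stage: str) -> None:
    d = _stage_dir(cfg, stage)
    checksums = {}
    for f in sorted(d.rglob("*")):
        if f.is_file() and f.name not in (".complete", "files.json"):
            checksums[str(f.relative_to(d))] = hashlib.sha256(f.read_bytes()).hexdigest()
    (d / "files.json").write_text(json.dumps(checksums, indent=2))
    cfg.to_yaml(d / "config.yaml")
    (d / ".complete").write_text(__version__)


def run_pipeline(
    config: PipelineConfig,
    stages: tuple[str, ...] = STAGES,
    force: bool = False,
) -> dict:
    """Execute the requested stages in order, reusing completed artifacts.

    Completed stages are skipped unless ``force``.  Each stage directory
    receives the resolved config, the package version, and a checksum
    manifest of every file it produced.  Requesting a stage whose upstream
    artifacts are absent raises :class:`DependencyError` naming the missing
    stage.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(s for s in STAGES if s in stages)
    result: dict = {}

    if "phantom" in stages and (force or not _stage_done(config, "phantom")):
        d = _stage_dir(config, "phantom")
        d.mkdir(parents=True, exist_ok=True)
        for section in make_sections(config.phantom, config.n_sections, config.seed):
            write_section(section, d)
        _finish_stage(config, "phantom")
    result["phantom_dir"] = str(_stage_dir(config, "phantom"))

    needs_dataset = {"preprocess", "patch", "train", "evaluate"} & set(stages)
    if needs_dataset:
        if not _stage_done(config, "phantom"):
            raise DependencyError("stage 'phantom' has not produced artifacts yet")
        sections = [
            read_section(p)
            for p in sorted(_stage_dir(config, "phantom").iterdir())
            if p.is_dir()
        ]
        manifest, stacks, labels, splits = build_dataset(
            sections,
            split_counts=config.split_counts,
            seed=config.seed,
            patch_size=config.patch_size,
            min_tissue_frac=config.min_tissue_frac,
            clip_max=config.clip_max,
            two_way_split=config.two_way_split,
        )
        result["splits"] = splits

    if "preprocess" in stages and (force or not _stage_done(config, "preprocess")):
        d = _stage_dir(config, "preprocess")
        d.mkdir(parents=True, exist_ok=True)
        manifest.stats.to_json(d / "channel_stats.json")
        json.dump(
            {sid: int(stacks[sid].tissue_mask.sum()) for sid in stacks},
            (d / "mask_areas.json").open("w"),
        )
        _finish_stage(config, "preprocess")

    if "patch" in stages and (force or not _stage_done(config, "patch")):
        d = _stage_dir(config, "patch")
        d.mkdir(parents=True, exist_ok=True)
        manifest.entries.to_csv(d / "manifest.csv", index=False)
        from .patches import class_pixel_summary

        summary = {
            split: class_pixel_summary(manifest, split) for split in splits
        }
        (d / "class_pixel_counts.json").write_text(json.dumps(summary, indent=2))
        _finish_stage(config, "patch")

    if "train" in stages:
        if not _stage_done(config, "patch"):
            raise DependencyError("stage 'patch' has not produced artifacts yet")
        if force or not _stage_done(config, "train"):
            from .model import ModalityConfig, train as _train

            d = _stage_dir(config, "train")
            d.mkdir(parents=True, exist_ok=True)
            for name in config.modalities:
                models = _train(manifest, ModalityConfig(name), config.train)
                for m in models:
                    m.save(d / f"{name}_rep{m.replicate}.npz")
            _finish_stage(config, "train")
        result["train_dir"] = str(_stage_dir(config, "train"))

    if "evaluate" in stages:
        if not _stage_done(config, "train"):
            raise DependencyError("stage 'train' has not produced artifacts yet")
        if force or not _stage_done(config, "evaluate"):
            d = _stage_dir(config, "evaluate")
            d.mkdir(parents=True, exist_ok=True)
            test_ids = splits.get("test", [])
            reports = {}
            last_model = None
            for name in config.modalities:
                models = _load_models(config, name)
                reps = []
                from .evaluate import EvalReport, evaluate_model

                for m in models:
                    reps.append(
                        evaluate_model(
                            m,
                            [stacks[s] for s in test_ids],
                            [labels[s] for s in test_ids],
                            tile=config.tile,
                            overlap=config.overlap,
                        )
                    )
                    last_model = m
                reports[name] = EvalReport(modality=name, replicates=reps).finalize()
            for name, rep in reports.items():
                rep.to_json(d / f"report_{name}.json")
            comparison_table(reports).to_csv(d / "comparison.csv", index=False)
            if test_ids and last_model is not None:
                from .model import predict_section

                sid = test_ids[0]
                pred = predict_section(
                    last_model, stacks[sid], tile=config.tile, overlap=config.overlap
                )
                render_projection(
                    pred, labels[sid], stacks[sid].channels,
                    d / f"projection_{sid}.png", channel_name="r1238",
                )
            _finish_stage(config, "evaluate")
            result["reports"] = {
                k: {"mean": v.mean, "sd": v.sd} for k, v in reports.items()
            }
        result["evaluate_dir"] = str(_stage_dir(config, "evaluate"))

    return result


def _load_models(config: PipelineConfig, modality_name: str) -> list:
    """Rebuild TrainedModel objects from a train-stage checkpoint directory."""
    from .model import ModalityConfig, TrainedModel, build_model

    d = _stage_dir(config, "train")
    modality = ModalityConfig(modality_name)
    models = []
    for path in sorted(d.glob(f"{modality_name}_rep*.npz")):
        meta = json.loads(path.with_suffix(".json").read_text())
        net = build_model(modality, n_classes=3, backbone=meta["backbone"], seed=0)
        with np.load(path) as npz:
            net.load_state_arrays(dict(npz))
        net.train(False)
        stats = ChannelStats(
            mean=np.asarray(meta["stats_mean"]), sd=np.asarray(meta["stats_sd"])
        )
        models.append(
            TrainedModel(
                network=net,
                modality=modality,
                train_config=config.train,
                stats=stats,
                history=meta["history"],
                replicate=meta["replicate"],
            )
        )
    return models
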