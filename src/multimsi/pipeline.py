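"""End-to-end orchestration: preprocess -> register -> assemble -> OnPLS
-> OPLS/VIP -> fuse, with config provenance, structured logging, seeding
and stage-level resume.
"""

from __future__ import annotations

import hashlib
import json
import logging
import uuid as uuid_mod
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from multimsi.chemometrics import assemble_multimodal, center_scale, fit_onpls
from multimsi.cube import SpectralImageCube, concat_pixel_matrices, restore_score_image
from multimsi.fusion import (
    downsample_hyperspectral,
    fit_opls,
    fuse,
    fusion_report,
    select_variables,
    vip,
)
from multimsi.imaging_io import read_imzml, read_tiff_cube, write_imzml, write_tiff_cube
from multimsi.phantom import PhantomSpec, make_phantom
from multimsi.preprocess import baseline_correct, peak_extract, rms_normalize
from multimsi.registration import register_modalities, resample_to_fixed
from multimsi.transform import AffineTransform2D

logger = logging.getLogger("multimsi.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


@dataclass
class PipelineConfig:
    """Serializable configuration of one pipeline run.

    All randomness flows from ``seed``; the effective config and its hash
    are written next to the outputs so every artifact is traceable.
    """

    output_dir: str = "pipeline_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict | None = None  # PhantomSpec-like mapping, or None
    inputs: dict = field(default_factory=dict)  # msi: [paths], microscopy: path
    preprocess: dict = field(default_factory=dict)
    register: dict = field(default_factory=lambda: {"enabled": True})
    decompose: dict = field(
        default_factory=lambda: {"n_global": 1, "n_local": {}, "n_unique": {}}
    )
    fuse: dict = field(
        default_factory=lambda: {
            "enabled": True,
            "vip_threshold": 1.0,
            "n_predictive": 2,
            "n_orthogonal": 1,
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "log_level": self.log_level,
            "simulate": self.simulate,
            "inputs": self.inputs,
            "preprocess": self.preprocess,
            "register": self.register,
            "decompose": self.decompose,
            "fuse": self.fuse,
        }

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage_done(out: Path, name: str) -> bool:
    return (out / f"{name}.done").exists()


def _mark_done(out: Path, name: str) -> None:
    (out / f"{name}.done").write_text("ok\n")


def _parse_subset_map(raw: dict) -> dict:
    """'0,1' -> (0, 1) keys for local-component maps; '0' -> 0 for unique."""
    out = {}
    for k, v in (raw or {}).items():
        if isinstance(k, str) and "," in k:
            out[tuple(int(s) for s in k.split(","))] = int(v)
        else:
            out[int(k)] = int(v)
    return out


def _load_stage_inputs(config: PipelineConfig, out: Path):
    if config.simulate is not None:
        spec_kwargs = dict(config.simulate)
        spec_kwargs.setdefault("seed", config.seed)
        for key in ("grid", "block_widths", "feature_diameter", "core_diameter"):
            if key in spec_kwargs:
                spec_kwargs[key] = tuple(spec_kwargs[key])
        spec = PhantomSpec(**spec_kwargs)
        cubes, hyper, truth = make_phantom(spec)
        sim_dir = out / "simulate"
        if not _stage_done(out, "simulate"):
            sim_dir.mkdir(parents=True, exist_ok=True)
            rng = np.random.default_rng(spec.seed)
            for cube in cubes:
                write_imzml(
                    cube,
                    sim_dir / f"{cube.modality_tag}.imzML",
                    file_uuid=uuid_mod.UUID(bytes=rng.bytes(16)),
                )
            write_tiff_cube(hyper, sim_dir / "lambda_stack.tiff")
            np.savetxt(
                sim_dir / "landmarks.csv",
                truth.landmarks(),
                delimiter=",",
                header="x,y",
                comments="",
            )
            _mark_done(out, "simulate")
        return cubes, hyper, truth
    msi_paths = config.inputs.get("msi", [])
    if not msi_paths:
        raise StageError("inputs: no MSI datasets configured and simulate disabled")
    tags = ("lipid_neg", "lipid_pos", "peptide")
    cubes = [read_imzml(p, modality_tag=tags[i % 3]) for i, p in enumerate(msi_paths)]
    hyper = None
    if config.inputs.get("microscopy"):
        hyper = read_tiff_cube(config.inputs["microscopy"])
    return cubes, hyper, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages in order; returns an artifact map.

    Completed stages (marked by ``<stage>.done``) are skipped on resume.
    Failures raise :class:`StageError` naming the stage; earlier outputs
    stay on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    cfg_hash = config.content_hash()
    summary_path = out / "pipeline.json"
    if summary_path.exists():
        prev = json.loads(summary_path.read_text())
        if prev.get("config_hash") == cfg_hash:
            logger.info("pipeline already complete for config %s; no recomputation", cfg_hash)
            return prev
    (out / "effective_config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    logger.info("pipeline start: config hash %s, seed %d", cfg_hash, config.seed)
    artifacts: dict = {"config_hash": cfg_hash, "output_dir": str(out)}

    try:
        cubes, hyper, truth = _load_stage_inputs(config, out)
    except Exception as exc:  # noqa: BLE001 - re-tag with stage name
        raise StageError(f"stage 'inputs': {exc}") from exc

    # ---- preprocess -------------------------------------------------
    try:
        pp = config.preprocess
        if pp.get("baseline_window"):
            cubes = [baseline_correct(c, int(pp["baseline_window"])) for c in cubes]
        if pp.get("rms_normalize", True):
            cubes = [rms_normalize(c) for c in cubes]
        if pp.get("peak_noise_factor") is not None:
            cubes = [peak_extract(c, float(pp["peak_noise_factor"])) for c in cubes]
        logger.info("preprocess done: %d blocks", len(cubes))
    except Exception as exc:
        raise StageError(f"stage 'preprocess': {exc}") from exc

    # ---- register ---------------------------------------------------
    reg_dir = out / "register"
    try:
        reg_cfg = config.register
        transforms = [AffineTransform2D.identity(c.modality_tag, cubes[0].modality_tag) for c in cubes]
        metrics_all = []
        if reg_cfg.get("enabled", True) and len(cubes) > 1:
            reg_dir.mkdir(parents=True, exist_ok=True)
            for i in range(1, len(cubes)):
                points = None
                if truth is not None and reg_cfg.get("use_truth_points", False):
                    lm = truth.landmarks()
                    points = (lm, truth.transforms[i].apply_points(lm))
                T, result = register_modalities(
                    cubes[0],
                    cubes[i],
                    control_points=points,
                    config={"seed": config.seed + i, **reg_cfg.get("options", {})},
                )
                transforms[i] = T
                metrics_all.append(result.final_metrics)
                cubes[i] = resample_to_fixed(cubes[i], cubes[0], T)
            (reg_dir / "transforms.json").write_text(
                json.dumps(
                    {
                        "transforms": [t.to_dict() for t in transforms],
                        "metrics": metrics_all,
                    },
                    indent=1,
                    sort_keys=True,
                )
            )
            _mark_done(out, "register")
        artifacts["transforms"] = [t.to_dict() for t in transforms]
    except Exception as exc:
        raise StageError(f"stage 'register': {exc}") from exc

    # ---- assemble + decompose --------------------------------------
    dec_dir = out / "decompose"
    try:
        dataset = assemble_multimodal(cubes)
        centered = center_scale(dataset, "mean_center")
        dcfg = config.decompose
        model = fit_onpls(
            centered,
            int(dcfg.get("n_global", 1)),
            {k: v for k, v in _parse_subset_map(dcfg.get("n_local")).items() if isinstance(k, tuple)},
            {k: v for k, v in _parse_subset_map(dcfg.get("n_unique")).items() if isinstance(k, int)},
        )
        dec_dir.mkdir(parents=True, exist_ok=True)
        summary = {}
        for b in range(model.n_blocks):
            summary[f"block_{b}"] = model.variance_fractions(b, centered.blocks[b].data)
            for k in range(model.global_scores[b].shape[1]):
                np.savetxt(
                    dec_dir / f"block{b}_global_t{k + 1}.csv",
                    model.score_image(b, "global", k, background=0.0),
                    delimiter=",",
                )
            for k in range(model.unique_scores[b].shape[1]):
                np.savetxt(
                    dec_dir / f"block{b}_unique_t{k + 1}.csv",
                    model.score_image(b, "unique", k, background=0.0),
                    delimiter=",",
                )
        (dec_dir / "variance_fractions.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True)
        )
        _mark_done(out, "decompose")
        artifacts["variance_fractions"] = summary
        logger.info("decompose done: %s", {k: round(v["global"], 3) for k, v in summary.items()})
    except Exception as exc:
        raise StageError(f"stage 'decompose': {exc}") from exc

    # ---- OPLS / VIP / fuse -----------------------------------------
    fuse_dir = out / "fusion"
    try:
        fcfg = config.fuse
        if fcfg.get("enabled", True) and hyper is not None:
            x = concat_pixel_matrices(dataset.blocks)
            y = downsample_hyperspectral(
                hyper,
                dataset.common_mask.shape,
                partition=dataset.common_mask,
            )
            opls = fit_opls(
                x,
                y,
                n_predictive=int(fcfg.get("n_predictive", 2)),
                n_orthogonal=int(fcfg.get("n_orthogonal", 1)),
            )
            vips = vip(opls, threshold=float(fcfg.get("vip_threshold", 1.0)))
            selected = select_variables(x, vips)
            fusion_model = fuse(selected, hyper, config=fcfg.get("options", {}))
            fuse_dir.mkdir(parents=True, exist_ok=True)
            np.savetxt(
                fuse_dir / "vip.csv",
                np.column_stack([x.variables, vips.vip]),
                delimiter=",",
                header="variable,vip",
                comments="",
            )
            table = fusion_report(fusion_model, fuse_dir)
            _mark_done(out, "fuse")
            artifacts["n_selected"] = selected.n_columns
            artifacts["reconstruction_scores"] = dict(
                zip(table["variable"], table["reconstruction_score"])
            )
            logger.info(
                "fusion done: %d/%d variables selected", selected.n_columns, x.n_columns
            )
    except Exception as exc:
        raise StageError(f"stage 'fuse': {exc}") from exc

    (out / "pipeline.json").write_text(
        json.dumps(artifacts, indent=1, sort_keys=True, default=str)
    )
    return artifacts
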