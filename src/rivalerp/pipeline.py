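"""End-to-end orchestration: simulate -> preprocess -> ERP stats -> sources.

``RunConfig`` aggregates every stage's parameters with the study's
values as defaults (sampling rate 500 Hz, 0.3-35 Hz / 1857-tap filter,
-100..2000 ms epochs, 60/150 µV rejection, 80-250 ms parieto-occipital
ROI at alpha .01, 170-190 and 380-420 ms windows, 11 participants).
``run_pipeline`` executes the whole chain for a simulated group and
writes every artifact under a run directory; results are reproducible
from (config, master_seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import erp as erp_mod
from .design import BehaviorParams, make_design, simulate_behavior
from .erp import (
    CENTRAL_CLUSTER,
    PO_CLUSTER,
    RoiSpec,
    WindowSpec,
    average_erps,
    count_chisq,
    permutation_tmap,
    pointwise_tmap,
    roi_count,
    window_anova,
)
from .forward import make_grid, make_leadfield
from .io_formats import save_epochs, write_brainvision, write_events_json
from .montage import default_montage
from .preprocessing import EpochSpec, FilterSpec, RejectionSpec, preprocess
from .simulate import EffectParams, NoiseParams, inject_blinks, simulate_recording
from .source import gcv_lambda, inverse_operator, localize_window, spm_condition_contrast, spm_hotelling

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every problem."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class DesignConfig:
    n_blocks: int = 16
    trials_per_block: int = 40


@dataclass
class RoiConfig:
    electrodes: list[str] | None = None  # None -> PO/O rows of the montage
    t_start_ms: float = 80.0
    t_end_ms: float = 250.0
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.t_start_ms < self.t_end_ms:
            raise ValueError("need t_start_ms < t_end_ms")


@dataclass
class WindowsConfig:
    n1_electrodes: list[str] = field(default_factory=lambda: list(PO_CLUSTER))
    n1_t_start_ms: float = 170.0
    n1_t_end_ms: float = 190.0
    lp_electrodes: list[str] = field(default_factory=lambda: list(CENTRAL_CLUSTER))
    lp_t_start_ms: float = 380.0
    lp_t_end_ms: float = 420.0


@dataclass
class SourceConfig:
    enabled: bool = True
    spacing_mm: float = 14.0
    brain_radius_mm: float = 75.0
    head_radius_mm: float = 100.0
    lam: float | None = None  # None -> generalized cross-validation
    smooth_weight: float = 1.0
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class OutputConfig:
    write_brainvision: bool = True
    write_plots: bool = True


@dataclass
class RunConfig:
    n_participants: int = 11
    master_seed: int = 0
    fs: float = 500.0
    design: DesignConfig = field(default_factory=DesignConfig)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    effects: EffectParams = field(default_factory=EffectParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    filter: FilterSpec = field(default_factory=FilterSpec)
    epochs: EpochSpec = field(default_factory=EpochSpec)
    rejection: RejectionSpec = field(default_factory=RejectionSpec)
    roi: RoiConfig = field(default_factory=RoiConfig)
    windows: WindowsConfig = field(default_factory=WindowsConfig)
    source: SourceConfig = field(default_factory=SourceConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [convert(v) for v in obj]
            if isinstance(obj, (list,)):
                return [convert(v) for v in obj]
            return obj

        return convert(self)


_SECTIONS = {
    "design": DesignConfig,
    "behavior": BehaviorParams,
    "effects": EffectParams,
    "noise": NoiseParams,
    "filter": FilterSpec,
    "epochs": EpochSpec,
    "rejection": RejectionSpec,
    "roi": RoiConfig,
    "windows": WindowsConfig,
    "source": SourceConfig,
    "output": OutputConfig,
}
_TUPLE_FIELDS = {"lp_window_ms", "baseline_ms"}
_SCALARS = {"n_participants", "master_seed", "fs"}


def config_from_dict(doc: dict | None) -> RunConfig:
    """Build a RunConfig from a (possibly empty) mapping.

    Unknown keys are errors; every error is reported with its path into
    the document.
    """
    doc = doc or {}
    errors: list[str] = []
    if not isinstance(doc, dict):
        raise ConfigError([f"config root must be a mapping, got {type(doc).__name__}"])
    kwargs = {}
    for key, value in doc.items():
        if key in _SCALARS:
            kwargs[key] = value
        elif key in _SECTIONS:
            cls = _SECTIONS[key]
            if not isinstance(value, dict):
                errors.append(f"{key}: expected a mapping")
                continue
            valid = {f.name for f in dataclasses.fields(cls)}
            sub = {}
            for k, v in value.items():
                if k not in valid:
                    errors.append(f"{key}.{k}: unknown key")
                    continue
                sub[k] = tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
            try:
                kwargs[key] = cls(**sub)
            except (ValueError, TypeError) as err:
                errors.append(f"{key}: {err}")
        else:
            errors.append(f"{key}: unknown key")
    if errors:
        raise ConfigError(errors)
    try:
        return RunConfig(**kwargs)
    except (ValueError, TypeError) as err:
        raise ConfigError([str(err)]) from err


def validate_config(path: str | Path | None) -> RunConfig:
    """Load and schema-check a YAML config file (empty file -> defaults)."""
    doc = None
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        doc = yaml.safe_load(text)
    return config_from_dict(doc)


def run_pipeline(
    config: RunConfig | None = None,
    out_dir: str | Path = "run",
    resume: bool = False,
) -> dict:
    """Execute the full chain and write all artifacts under ``out_dir``.

    Returns the summary report (also written as summary.json).
    """
    config = config or RunConfig()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not resume:
        raise FileExistsError(
            f"{out} exists and is not empty; pass resume=True to reuse it"
        )
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()), encoding="utf-8")

    montage = default_montage()
    master = np.random.SeedSequence(config.master_seed)
    epochs_by_participant = {}
    rejection_rows = []
    for p, child in enumerate(master.spawn(config.n_participants)):
        rng = np.random.default_rng(child)
        design = make_design(
            config.design.n_blocks,
            config.design.trials_per_block,
            seed=rng,
            first_condition="rivalry" if p % 2 == 0 else "fusion",
        )
        pb = config.behavior.draw_participant(rng)
        trials = simulate_behavior(design, pb, seed=rng)
        trials.to_csv(out / f"sub-{p:02d}_trials.tsv", sep="\t", index=False)

        raw = simulate_recording(
            trials, config.effects, config.noise, montage, seed=rng, fs=config.fs
        )
        raw, blink_samples = inject_blinks(raw, config.noise, seed=rng)
        if config.output.write_brainvision:
            write_brainvision(raw, out / f"sub-{p:02d}")
            write_events_json(raw, out / f"sub-{p:02d}_events.json")
            (out / f"sub-{p:02d}_blinks.json").write_text(
                json.dumps({"blink_samples": blink_samples})
            )

        ep = preprocess(
            raw, config.filter, config.epochs, config.rejection, trials=trials
        )
        save_epochs(ep, out / f"sub-{p:02d}_epochs.h5")
        rejection_rows.append({"participant": p, **ep.rejection_report})
        epochs_by_participant[p] = ep
        logger.info("participant %d: %s", p, ep.rejection_report)

    rejection = pd.DataFrame(rejection_rows)
    rejection.to_json(out / "rejection_report.json", orient="records", indent=1)

    erps = average_erps(epochs_by_participant)
    erps.n_trials.to_csv(out / "trial_counts.tsv", sep="\t")
    _write_erp_tsv(erps, out / "erps.tsv")

    roi = RoiSpec(
        electrodes=config.roi.electrodes or montage.channels_in_rows(["PO", "O"]),
        t_start_ms=config.roi.t_start_ms,
        t_end_ms=config.roi.t_end_ms,
        alpha=config.roi.alpha,
    )
    stats_report = {}
    maps = {}
    for label, (ca, cb) in {
        "rivalry": ("rivalry_changed", "rivalry_same"),
        "fusion": ("fusion_changed", "fusion_same"),
    }.items():
        tmap = pointwise_tmap(erps, ca, cb, alpha=roi.alpha)
        perm = permutation_tmap(erps, ca, cb, alpha=roi.alpha)
        tmap.to_frame().to_csv(out / f"tmap_{label}.tsv", sep="\t", index=False)
        count = roi_count(tmap, roi)
        chi2, df, p = count_chisq(count.count, count.n_cells, roi.alpha)
        pcount = roi_count(perm, roi)
        stats_report[label] = {
            "roi_sig_count": count.count,
            "roi_cells": count.n_cells,
            "roi_expected_null": count.n_cells * roi.alpha,
            "chi2": chi2,
            "chi2_df": df,
            "chi2_p": p,
            "permutation_roi_sig_count": pcount.count,
        }
        maps[label] = tmap
        if config.output.write_plots:
            from .viz import plot_tmap_raster

            plot_tmap_raster(tmap, montage, out / f"tmap_{label}.png")

    w_n1 = WindowSpec(
        config.windows.n1_electrodes,
        config.windows.n1_t_start_ms,
        config.windows.n1_t_end_ms,
    )
    w_lp = WindowSpec(
        config.windows.lp_electrodes,
        config.windows.lp_t_start_ms,
        config.windows.lp_t_end_ms,
    )
    anovas = {}
    for wname, w in (("n1_window", w_n1), ("late_positivity_window", w_lp)):
        for label, conds in (
            ("rivalry", ("rivalry_changed", "rivalry_same")),
            ("fusion", ("fusion_changed", "fusion_same")),
        ):
            res = window_anova(erps, w, conds)
            anovas[f"{wname}_{label}"] = dataclasses.asdict(res)
    (out / "anovas.json").write_text(json.dumps(anovas, indent=1))

    source_report = {}
    if config.source.enabled:
        grid = make_grid(
            config.source.spacing_mm,
            config.source.brain_radius_mm,
            config.source.head_radius_mm,
        )
        gain = make_leadfield(montage, grid)
        y = erps.data[
            :, :, erps.channel_indices(gain.channels)
        ][:, :, :, erps.sample_window(w_n1.t_start_ms, w_n1.t_end_ms)].mean(
            axis=(0, 1, 3)
        )
        lam = config.source.lam or gcv_lambda(gain, y, config.source.smooth_weight)
        inv = inverse_operator(gain, lam, config.source.smooth_weight)
        sols = localize_window(erps, w_n1, inv)
        spm = spm_hotelling(sols, "rivalry_changed", alpha=config.source.alpha)
        contrast = spm_condition_contrast(
            sols, "rivalry_changed", "rivalry_same", alpha=config.source.alpha
        )
        spm.to_frame().to_csv(out / "spm_rivalry_changed.tsv", sep="\t", index=False)
        contrast.to_frame().to_csv(out / "spm_contrast.tsv", sep="\t", index=False)
        source_report = {
            "lambda": lam,
            "n_voxels": grid.n_voxels,
            "hotelling_sig_voxels": int(spm.sig.sum()),
            "contrast_sig_voxels": int(contrast.sig.sum()),
        }
        if config.output.write_plots:
            from .viz import plot_glass_brain

            plot_glass_brain(contrast, out / "glass_brain_contrast.png")

    summary = {
        "n_participants_analyzed": len(erps.participants),
        "trial_counts_mean": erps.n_trials.mean().to_dict(),
        "stats": stats_report,
        "anovas": anovas,
        "source": source_report,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def _write_erp_tsv(erps, path: Path) -> None:
    frames = []
    for i, pid in enumerate(erps.participants):
        for j, cond in enumerate(erps.conditions):
            df = pd.DataFrame(erps.data[i, j].T, columns=erps.channels)
            df.insert(0, "time_ms", erps.times_ms)
            df.insert(0, "condition", cond)
            df.insert(0, "participant", pid)
            frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
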