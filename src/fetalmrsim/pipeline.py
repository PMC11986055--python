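"""Configuration-driven orchestration of the simulation pipeline.

One subject runs end to end as: load or generate the high-resolution
anatomy -> merge labels to GM/WM/CSF -> GHMRF partial-volume fit of the
WM mask -> reward maps and GA-dependent sigmoid modulation of sampled
reference T1/T2 -> six low-resolution series (three orientations, two
partially overlapping runs each) plus label stacks and brain masks ->
BIDS output.

Seeds follow a master -> per-subject -> per-series hierarchy derived
from ``numpy.random.SeedSequence`` so cohorts are reproducible and any
subject can be re-run in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from ._errors import ValidationError
from .anatomy import (
    HRAnatomy,
    extract_mask,
    load_hr_anatomy,
    merge_to_three_classes,
    write_bids_dataset,
)
from .fse import LRSeries, downsample_annotations, sequence_preset, simulate_lr_series
from .ghmrf import GHMRFConfig, fit_ghmrf
from .phantom import PhantomSpec, generate_phantom
from .relaxometry import (
    AlphaSchedule,
    build_alpha_schedule,
    build_quantitative_maps,
    default_alpha_schedule,
    read_sigma_table,
    sample_subject_properties,
)

ORIENTATIONS = ("axial", "coronal", "sagittal")
RUNS = (1, 2)


@dataclass
class SubjectSpec:
    subject_id: str
    ga_weeks: float
    condition: str = "unknown"
    groups: tuple[str, ...] = ("default",)
    image_path: str | None = None
    label_path: str | None = None
    phantom: Mapping[str, Any] = dc_field(default_factory=dict)

    @property
    def uses_phantom(self) -> bool:
        return self.image_path is None


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    preset_name: str = "HASTE"
    field_tesla: float = 1.5
    preset_overrides: Mapping[str, Any] = dc_field(default_factory=dict)
    sample_ranges: bool = False
    alpha_source: str = "default"       # default | sigma_csv | alpha_json
    alpha_path: str | None = None
    phantom_defaults: Mapping[str, Any] = dc_field(default_factory=dict)
    ghmrf: Mapping[str, Any] = dc_field(default_factory=dict)
    subjects: list[SubjectSpec] = dc_field(default_factory=list)
    overwrite: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        preset = raw.get("preset", {})
        alpha = raw.get("alpha", {})
        subjects = []
        for s in raw.get("subjects", []):
            subjects.append(SubjectSpec(
                subject_id=str(s["id"]),
                ga_weeks=float(s["ga_weeks"]),
                condition=s.get("condition", "unknown"),
                groups=tuple(s.get("groups", ["default"])),
                image_path=s.get("image"),
                label_path=s.get("labels"),
                phantom=s.get("phantom", {}),
            ))
        return cls(
            output_dir=raw.get("output_dir", "out"),
            seed=int(raw.get("seed", 0)),
            preset_name=preset.get("name", "HASTE"),
            field_tesla=float(preset.get("field_tesla", 1.5)),
            preset_overrides=preset.get("overrides", {}),
            sample_ranges=bool(raw.get("sample_ranges", False)),
            alpha_source=alpha.get("source", "default"),
            alpha_path=alpha.get("path"),
            phantom_defaults=raw.get("phantom_defaults", {}),
            ghmrf=raw.get("ghmrf", {}),
            subjects=subjects,
            overwrite=bool(raw.get("overwrite", False)),
        )


@dataclass
class SubjectResult:
    subject_id: str
    series: list[LRSeries]
    annotations: list[np.ndarray]
    masks: list[np.ndarray]
    log: dict


def _subject_seed_sequence(master_seed: int, subject_id: str):
    return np.random.SeedSequence(
        [int(master_seed), zlib.crc32(subject_id.encode("utf-8"))])


def _seed_from(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def load_alpha_schedule(config: RunConfig) -> AlphaSchedule:
    if config.alpha_source == "default":
        return default_alpha_schedule()
    if config.alpha_source == "sigma_csv":
        if not config.alpha_path:
            raise ValidationError("alpha.source sigma_csv needs alpha.path")
        return build_alpha_schedule(read_sigma_table(config.alpha_path),
                                    sigma_source=str(config.alpha_path))
    if config.alpha_source == "alpha_json":
        if not config.alpha_path:
            raise ValidationError("alpha.source alpha_json needs alpha.path")
        return AlphaSchedule.from_json(Path(config.alpha_path).read_text())
    raise ValidationError(f"unknown alpha source {config.alpha_source!r}")


def _subject_anatomy(config: RunConfig, subject: SubjectSpec,
                     seed: int) -> HRAnatomy:
    if not subject.uses_phantom:
        if subject.label_path is None:
            raise ValidationError(
                f"subject {subject.subject_id}: image without labels")
        return load_hr_anatomy(subject.image_path, subject.label_path,
                               subject.ga_weeks, subject.subject_id,
                               condition=subject.condition)
    kw = dict(config.phantom_defaults)
    kw.update(subject.phantom)
    kw.setdefault("seed", seed)
    kw["ga_weeks"] = subject.ga_weeks
    kw["subject_id"] = subject.subject_id
    kw["condition"] = subject.condition
    if "grid_shape" in kw:
        kw["grid_shape"] = tuple(kw["grid_shape"])
    if "spacing_mm" in kw:
        kw["spacing_mm"] = tuple(kw["spacing_mm"])
    return generate_phantom(PhantomSpec(**kw))


def run_subject(config: RunConfig, subject: SubjectSpec,
                schedule: AlphaSchedule | None = None) -> SubjectResult:
    """Simulate the full six-series protocol for one subject."""
    ss = _subject_seed_sequence(config.seed, subject.subject_id)
    anat_ss, prop_ss, series_parent = ss.spawn(3)
    try:
        anatomy = _subject_anatomy(config, subject, _seed_from(anat_ss))
        tcm = merge_to_three_classes(anatomy)
        wm_mask = extract_mask(tcm, "WM")
        ghmrf_cfg = GHMRFConfig(**dict(config.ghmrf))
        pv, bias, diag = fit_ghmrf(anatomy.intensity, wm_mask, ghmrf_cfg,
                                   spacing_mm=anatomy.spacing,
                                   affine=anatomy.affine)
        props = sample_subject_properties(config.field_tesla,
                                          _seed_from(prop_ss))
        schedule = schedule or load_alpha_schedule(config)
        qmaps = build_quantitative_maps(tcm, pv, props, schedule,
                                        anatomy.ga_weeks)
        base_params = sequence_preset(config.preset_name, config.field_tesla,
                                      **dict(config.preset_overrides))
        series, annotations, masks = [], [], []
        series_ss = series_parent.spawn(len(ORIENTATIONS) * len(RUNS))
        i = 0
        for orientation in ORIENTATIONS:
            for run in RUNS:
                seed = _seed_from(series_ss[i])
                params = base_params
                if config.sample_ranges:
                    params = base_params.sample(np.random.default_rng(seed))
                s = simulate_lr_series(qmaps, params, orientation, run, seed)
                s.subject_id = subject.subject_id
                labels_lr, mask_lr = downsample_annotations(anatomy.labels, s)
                series.append(s)
                annotations.append(labels_lr)
                masks.append(mask_lr)
                i += 1
        log = {
            "subject": subject.subject_id,
            "ga_weeks": subject.ga_weeks,
            "condition": subject.condition,
            "alpha": qmaps.provenance["alpha"],
            "properties": props.to_dict(),
            "ghmrf": {"iterations": diag["iterations"],
                      "converged": diag["converged"],
                      "class_means": diag["class_means"]},
            "series_seeds": [s.seed for s in series],
        }
        return SubjectResult(subject_id=subject.subject_id, series=series,
                             annotations=annotations, masks=masks, log=log)
    except Exception as exc:
        exc.args = (f"subject {subject.subject_id}: {exc}",) + exc.args[1:] \
            if exc.args else (f"subject {subject.subject_id}",)
        raise


def run_cohort(config: RunConfig):
    """Run every roster subject once and write a single BIDS dataset.

    A subject may belong to several instance groups; the summary reports
    both the instance-weighted series total (a subject's six series
    count once per group membership) and the unique-anatomy totals.
    Per-subject failures are collected and reported together.
    """
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise ValidationError(
            f"output dir {out} is not empty; pass overwrite to reuse it")
    schedule = load_alpha_schedule(config) if config.subjects else None
    all_series, all_ann, all_masks, logs = [], [], [], []
    errors: dict[str, str] = {}
    for subject in config.subjects:
        try:
            res = run_subject(config, subject, schedule=schedule)
        except Exception as exc:  # collected, reported together
            errors[subject.subject_id] = str(exc)
            continue
        all_series.extend(res.series)
        all_ann.extend(res.annotations)
        all_masks.extend(res.masks)
        logs.append(res.log)
    manifest = write_bids_dataset(all_series, out, annotations=all_ann,
                                  masks=all_masks)
    group_sizes: dict[str, int] = {}
    for subject in config.subjects:
        if subject.subject_id in errors:
            continue
        for g in subject.groups:
            group_sizes[g] = group_sizes.get(g, 0) + 1
    n_unique = len(config.subjects) - len(errors)
    per_subject = len(ORIENTATIONS) * len(RUNS)
    summary = {
        "unique_anatomies": n_unique,
        "series_files": n_unique * per_subject,
        "series_total_instances": sum(group_sizes.values()) * per_subject,
        "instances_by_group": group_sizes,
        "errors": errors,
    }
    out.mkdir(parents=True, exist_ok=True)
    (out / "cohort_summary.json").write_text(json.dumps(summary, indent=2))
    (out / "run_log.json").write_text(json.dumps(
        {"config_seed": config.seed, "subjects": logs}, indent=2))
    return manifest, summary
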