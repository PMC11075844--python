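"""End-to-end orchestration: cohort -> filters -> bicoherence -> images ->
classifier -> metrics -> muscle comparison.

One classifier is trained per muscle, plus an "ALL" condition formed by
averaging the per-muscle bicoherence maps of each trial before rendering.
Every run is driven by a single structured config that serializes to JSON;
the run log records the config, its hash and all seeds, so a log line is
enough to re-execute an identical run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import (
    EvaluationReport,
    METRIC_NAMES,
    SplitPlan,
    TrainConfig,
    compare_groups,
    run_protocol,
)
from .hosa import BicoherenceMap, HosaParams, average_maps, bicoherence
from .imaging import RenderConfig, render_map, write_image
from .preprocess import FilterConfig, preprocess_chain
from .records import EmgRecord, write_record
from .synth import CohortSpec, QpcSpec, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "config_from_dict"]


@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    filter: FilterConfig = field(default_factory=FilterConfig)
    hosa: HosaParams = field(default_factory=HosaParams)
    render: RenderConfig = field(default_factory=RenderConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    split: SplitPlan = field(default_factory=SplitPlan)
    output_dir: str = "emgbicoh_out"
    save_intermediates: str = "summary"  # none | summary | full
    log_level: str = "info"

    def validate(self) -> None:
        self.cohort.validate()
        self.filter.validate(self.cohort.fs)
        self.hosa.validate()
        self.render.validate()
        self.train.validate()
        self.split.validate()
        if self.save_intermediates not in ("none", "summary", "full"):
            raise ValueError(
                f"save_intermediates must be none|summary|full, "
                f"got {self.save_intermediates!r}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["class_qpc"] = {
            k: dataclasses.asdict(v) for k, v in self.cohort.class_qpc.items()
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def config_from_dict(d: dict) -> PipelineConfig:
    """Build a config from a (possibly partial) plain dict, with defaulting."""
    d = dict(d)
    cohort_d = dict(d.pop("cohort", {}))
    class_qpc = {
        k: QpcSpec(**{**v, "amplitudes": tuple(v.get("amplitudes", (1, 1, 1)))})
        for k, v in cohort_d.pop("class_qpc", {}).items()
    }
    if "muscles" in cohort_d:
        cohort_d["muscles"] = tuple(cohort_d["muscles"])
    cohort = CohortSpec(**cohort_d, **({"class_qpc": class_qpc} if class_qpc else {}))
    filt = FilterConfig(**d.pop("filter", {}))
    hosa = HosaParams(**d.pop("hosa", {}))
    render = RenderConfig(**d.pop("render", {}))
    train = TrainConfig(**d.pop("train", {}))
    split_d = dict(d.pop("split", {}))
    if "fractions" in split_d:
        split_d["fractions"] = tuple(split_d["fractions"])
    split = SplitPlan(**split_d)
    return PipelineConfig(
        cohort=cohort, filter=filt, hosa=hosa, render=render,
        train=train, split=split, **d,
    )


@dataclass
class PipelineResult:
    reports: dict[str, EvaluationReport]
    comparisons: dict[str, dict]
    config: PipelineConfig
    output_dir: Path


def _stage(name: str, fn, record_id: str = ""):
    try:
        return fn()
    except Exception as exc:
        where = f" (record {record_id})" if record_id else ""
        raise RuntimeError(f"pipeline stage {name!r} failed{where}: {exc}") from exc


def make_image_dataset(
    records: list[EmgRecord],
    manifest: pd.DataFrame,
    filter_config: FilterConfig,
    hosa_params: HosaParams,
    render_config: RenderConfig,
    out_dir: Path | None = None,
    save: str = "none",
) -> dict[str, dict]:
    """Preprocess, estimate bicoherence, and render one image per record,
    plus one averaged-map ("ALL") image per trial.

    Returns ``{group: {"images": (n,H,W,3), "labels": ..., "subjects": ...}}``
    with one group per muscle and one "ALL" group.
    """
    groups: dict[str, dict] = {
        m: {"images": [], "labels": [], "subjects": []}
        for m in list(manifest["muscle"].unique()) + ["ALL"]
    }
    img_rows = []
    trials = manifest.groupby(["class_label", "subject_id", "trial_id"], sort=True)
    for (cls, subj, trial), rows in trials:
        trial_maps: list[BicoherenceMap] = []
        for _, row in rows.sort_values("muscle").iterrows():
            rec = records[int(row["record_index"])]
            rid = f"{subj}/{trial}/{row['muscle']}"
            clean = _stage("preprocess", lambda: preprocess_chain(rec, filter_config), rid)
            bmap = _stage("bicoherence", lambda: bicoherence(clean, hosa_params), rid)
            trial_maps.append(bmap)
            img = render_map(
                bmap, render_config, class_label=cls, subject_id=subj,
                muscle=row["muscle"], source_id=rid,
            )
            g = groups[row["muscle"]]
            g["images"].append(img.pixels)
            g["labels"].append(cls)
            g["subjects"].append(subj)
            if out_dir is not None and save == "full":
                path = out_dir / "images" / f"{subj}_{trial}_{row['muscle']}.png"
                write_image(img, path)
                img_rows.append(img.manifest_row(str(path)))
        avg = _stage("average_maps", lambda: average_maps(trial_maps),
                     f"{subj}/{trial}")
        img = render_map(
            avg, render_config, class_label=cls, subject_id=subj,
            muscle="ALL", source_id=f"{subj}/{trial}/ALL",
        )
        groups["ALL"]["images"].append(img.pixels)
        groups["ALL"]["labels"].append(cls)
        groups["ALL"]["subjects"].append(subj)
        if out_dir is not None and save == "full":
            path = out_dir / "images" / f"{subj}_{trial}_ALL.png"
            write_image(img, path)
            img_rows.append(img.manifest_row(str(path)))
    for g in groups.values():
        g["images"] = np.stack(g["images"])
        g["labels"] = np.asarray(g["labels"])
        g["subjects"] = np.asarray(g["subjects"])
    if out_dir is not None and save == "full" and img_rows:
        pd.DataFrame(img_rows).to_csv(out_dir / "images" / "manifest.csv", index=False)
    return groups


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline per the config; artifacts under output_dir."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    records, manifest = _stage("generate", lambda: generate_cohort(config.cohort))
    save = config.save_intermediates
    if save != "none":
        manifest.to_csv(out / "cohort_manifest.csv", index=False)
    if save == "full":
        sig_dir = out / "signals"
        for rec, (_, row) in zip(records, manifest.iterrows()):
            write_record(
                rec,
                sig_dir / f"{row['subject_id']}_{row['trial_id']}_{row['muscle']}.txt",
            )

    groups = make_image_dataset(
        records, manifest, config.filter, config.hosa, config.render,
        out_dir=out, save=save,
    )

    reports: dict[str, EvaluationReport] = {}
    for group, data in groups.items():
        reports[group] = _stage(
            "train/evaluate",
            lambda d=data, g=group: run_protocol(
                d["images"], d["labels"], d["subjects"],
                plan=config.split, train_config=config.train, group=g,
            ),
            group,
        )

    comparisons: dict[str, dict] = {}
    positive = "KOA" if "KOA" in set(config.cohort.class_qpc) else None
    for metric in METRIC_NAMES:
        group_values = {}
        for g, rep in reports.items():
            pr = rep.per_run
            if positive is not None and "positive_class" in pr:
                pr = pr[pr["positive_class"] == positive]
            vals = pr[metric].to_numpy(dtype=float)
            if np.all(np.isfinite(vals)):
                group_values[g] = vals
        if len(group_values) >= 2:
            try:
                comparisons[metric] = compare_groups(group_values)
            except ValueError:
                pass  # degenerate (zero-variance) metric; skip comparison

    if save != "none":
        per_run = pd.concat(
            [r.per_run.assign(group=g) for g, r in reports.items()],
            ignore_index=True,
        )
        per_run.to_csv(out / "metrics_per_run.csv", index=False)
        summaries = []
        for g, r in reports.items():
            s = r.summary.copy()
            s.columns = ["_".join(c) for c in s.columns]
            s = s.reset_index().assign(group=g)
            summaries.append(s)
        pd.concat(summaries, ignore_index=True).to_csv(
            out / "metrics_summary.csv", index=False
        )
        comp_out = {
            m: {
                "f_statistic": c["f_statistic"],
                "p_value": c["p_value"],
                "alpha": c["alpha"],
                "tukey": c["tukey"].to_dict(orient="records"),
            }
            for m, c in comparisons.items()
        }
        with open(out / "comparisons.json", "w") as fh:
            json.dump(comp_out, fh, indent=2, default=str)
        log = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "elapsed_s": round(time.time() - t0, 2),
            "n_records": len(records),
            "groups": sorted(groups),
        }
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, default=str)

    return PipelineResult(
        reports=reports, comparisons=comparisons, config=config, output_dir=out
    )
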