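"""End-to-end reproducible runs: config, seeding, manifest, CSV outputs.

A run is described by a single YAML/dict config.  The ``fish`` stage
simulates one nucleus stack per scene per condition, measures %RD for every
territory, summarizes per condition x chromosome, tests each condition
against the reference (Mann-Whitney) and writes a shift table in the layout
of the study's radial-distance tables.  Optional ``dereg`` and ``linescan``
stages run the expression-table and envelope-profile simulations and their
summaries.  One global seed expands deterministically into per-scene seeds,
so a rerun with the same config produces identical CSVs.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .envelope import Section, average_profiles, extract_line_profile
from .io import measurements_to_frame, write_expression, write_scene
from .radial import SegConfig, compare, measure_scene, shift_table, summarize
from .synthetic import (
    EnvelopeSimParams,
    ExpressionSimParams,
    SceneParams,
    TerritorySpec,
    render_scene,
    simulate_envelope_sections,
    simulate_expression,
)
from .transcriptome import deregulation_summary

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "load_config", "demo_config"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass(frozen=True)
class ConditionSpec:
    name: str
    # chromosome -> mean fractional radial position of its territories
    positions: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class RunConfig:
    """Validated snapshot of every parameter of a run."""

    seed: int = 0
    reference: str = "glass"
    stages: tuple[str, ...] = ("fish",)
    n_scenes: int = 6
    # chromosome -> paint channel
    chromosomes: dict[str, str] = field(default_factory=lambda: {"CT18": "green", "CT19": "red"})
    conditions: tuple[ConditionSpec, ...] = ()
    position_jitter: float = 0.04
    pair: tuple[str, str] | None = None
    scene: dict = field(default_factory=dict)          # SceneParams overrides
    segmentation: dict = field(default_factory=dict)   # SegConfig overrides
    expression: dict = field(default_factory=dict)     # ExpressionSimParams overrides
    sections: dict = field(default_factory=dict)       # EnvelopeSimParams overrides
    save_scenes: bool = False

    def validate(self):
        if not self.conditions:
            raise ConfigError("at least one condition is required")
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ConfigError("condition names must be unique")
        if "fish" in self.stages and self.reference not in names:
            raise ConfigError(
                f"reference condition {self.reference!r} not among conditions {names}"
            )
        unknown = set(self.stages) - {"fish", "dereg", "linescan"}
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        if self.n_scenes < 1:
            raise ConfigError("n_scenes must be >= 1")
        if self.pair is not None:
            for chrom in self.pair:
                if chrom not in self.chromosomes:
                    raise ConfigError(f"pair chromosome {chrom!r} not declared")
        for cond in self.conditions:
            for chrom, f in cond.positions.items():
                if chrom not in self.chromosomes:
                    raise ConfigError(
                        f"condition {cond.name!r} places unknown chromosome {chrom!r}"
                    )
                if not 0.0 <= f <= 1.0:
                    raise ConfigError("fractional positions must be in [0, 1]")
        # constructing the dataclasses validates their fields/keys
        SceneParams(**self.scene).validate()
        SegConfig(**self.segmentation)
        if "dereg" in self.stages:
            ExpressionSimParams(**self.expression).validate()
        if "linescan" in self.stages:
            EnvelopeSimParams(**self.sections).validate()


def _strict_keys(d: dict, allowed, where: str):
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)} in {where}")


def load_config(source) -> RunConfig:
    """Build a RunConfig from a YAML path/string or a plain dict.

    Unknown keys anywhere in the document are rejected.
    """
    if isinstance(source, RunConfig):
        return source
    if isinstance(source, (str, Path)):
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text)
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")

    fields = {f for f in RunConfig.__dataclass_fields__}
    _strict_keys(data, fields, "config")
    data = dict(data)
    conds = []
    for entry in data.get("conditions", []):
        _strict_keys(entry, {"name", "positions"}, "condition entry")
        conds.append(ConditionSpec(name=entry["name"],
                                   positions=dict(entry.get("positions", {}))))
    data["conditions"] = tuple(conds)
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    if data.get("pair") is not None:
        data["pair"] = tuple(data["pair"])
    for key, cls in (("scene", SceneParams), ("segmentation", SegConfig),
                     ("expression", ExpressionSimParams), ("sections", EnvelopeSimParams)):
        if key in data:
            sub = dict(data[key])
            _strict_keys(sub, cls.__dataclass_fields__, key)
            for k, v in sub.items():
                if isinstance(v, list):
                    sub[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
            data[key] = sub
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def demo_config(seed: int = 11, n_scenes: int = 12) -> RunConfig:
    """Small two-condition demo emulating the peripheral-vs-interior shift
    of a gene-poor (CT18-like) and gene-rich (CT19-like) chromosome."""
    return RunConfig(
        seed=seed,
        reference="glass",
        n_scenes=n_scenes,
        chromosomes={"CT18": "green", "CT19": "red"},
        conditions=(
            ConditionSpec("glass", {"CT18": 0.66, "CT19": 0.55}),
            ConditionSpec("2kPa", {"CT18": 0.56, "CT19": 0.49}),
        ),
        pair=("CT18", "CT19"),
    )


def _scene_seed(global_seed: int, cond_idx: int, scene_idx: int) -> int:
    """Deterministic per-scene seed below 2^31 from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), cond_idx, scene_idx])
    return int(ss.generate_state(1)[0] % 2**31)


def run_pipeline(config, out_dir) -> Path:
    """Execute the configured stages and write CSV outputs plus a manifest.

    Returns the output directory.  Raises if any enabled stage produced
    zero outputs.
    """
    cfg = load_config(config)
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    channel_to_chrom = {ch: chrom for chrom, ch in cfg.chromosomes.items()}
    manifest: dict = {
        "version": __version__,
        "config": json.loads(json.dumps(asdict(cfg), default=list)),
        "started": datetime.datetime.now().isoformat(timespec="seconds"),
        "scenes": [],
    }

    if "fish" in cfg.stages:
        seg = SegConfig(**cfg.segmentation)
        frames = []
        for ci, cond in enumerate(cfg.conditions):
            for si in range(cfg.n_scenes):
                seed = _scene_seed(cfg.seed, ci, si)
                jitter_rng = np.random.default_rng([cfg.seed, ci, si, 1])
                territories = []
                for chrom, f in cond.positions.items():
                    fr = float(np.clip(
                        jitter_rng.normal(f, cfg.position_jitter), 0.02, 0.95
                    ))
                    territories.append(TerritorySpec(
                        channel=cfg.chromosomes[chrom],
                        fractional_radial_position=fr,
                    ))
                params = SceneParams(**{**cfg.scene,
                                        "territories": tuple(territories),
                                        "seed": seed})
                scene, truth = render_scene(params)
                scene.scene_id = f"{cond.name}_{si:03d}"
                if cfg.save_scenes:
                    write_scene(scene, out / "scenes" / f"{scene.scene_id}.tif",
                                truth=truth, seed=seed)
                measurements = measure_scene(scene, seg)
                frames.append(measurements_to_frame(
                    measurements, condition=cond.name,
                    chromosome_by_channel=channel_to_chrom,
                ))
                manifest["scenes"].append({
                    "scene_id": scene.scene_id,
                    "condition": cond.name,
                    "seed": seed,
                    "threshold_method": seg.threshold_method,
                    "n_territories": len(measurements),
                    "n_clamped": int(sum(m.clamped for m in measurements)),
                })
        measurements_df = pd.concat(frames, ignore_index=True)
        if measurements_df.empty:
            raise RuntimeError("fish stage produced zero measurements")
        measurements_df.to_csv(out / "measurements.csv", index=False)

        summaries = []
        for cond in cfg.conditions:
            for chrom in cfg.chromosomes:
                sel = (measurements_df["condition"] == cond.name) & (
                    measurements_df["chromosome"] == chrom
                )
                vals = measurements_df.loc[sel, "percent_rd"]
                if len(vals):
                    summaries.append(summarize(vals, cond.name, chrom))
        rows = []
        for s in summaries:
            row = {"condition": s.condition, "chromosome": s.chromosome,
                   "n": s.n, "median": round(s.median, 2)}
            row.update({f"bin_{int(lo)}_{int(lo) + 20}": freq
                        for lo, freq in zip(range(0, 100, 20), s.bin_frequencies)})
            if s.condition != cfg.reference:
                ref = next((r for r in summaries
                            if r.condition == cfg.reference
                            and r.chromosome == s.chromosome), None)
                if ref is not None:
                    u, p = compare(s, ref)
                    row["mw_u"], row["mw_p"] = u, p
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "summaries.csv", index=False)

        table = shift_table(
            pd.DataFrame([{"condition": s.condition, "chromosome": s.chromosome,
                           "median": round(s.median, 2)} for s in summaries]),
            reference=cfg.reference, pair=cfg.pair,
        )
        table.round(2).to_csv(out / "shift_table.csv")

    if "dereg" in cfg.stages:
        params = ExpressionSimParams(**{**cfg.expression, "seed": cfg.seed})
        table = simulate_expression(params)
        write_expression(table, out / "expression.tsv")
        for cond in params.conditions:
            if cond == params.reference:
                continue
            summary = deregulation_summary(table, cond,
                                           transcribing_condition=params.reference)
            summary.to_csv(out / f"deregulation_{cond}.csv")

    if "linescan" in cfg.stages:
        params = EnvelopeSimParams(**{**cfg.sections, "seed": cfg.seed})
        sections = simulate_envelope_sections(params)
        if not sections:
            raise RuntimeError("linescan stage produced zero sections")
        profiles = [
            extract_line_profile(Section(img, params.pixel_size, mask))
            for img, mask in sections
        ]
        summary = average_profiles(profiles, profiles)
        pd.DataFrame({
            "position": summary.positions,
            "normalized_intensity": summary.mean_profile,
        }).to_csv(out / "line_profile.csv", index=False)

    manifest["finished"] = datetime.datetime.now().isoformat(timespec="seconds")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
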