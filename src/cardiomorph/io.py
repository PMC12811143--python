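"""Readers/writers, run configuration, and the staged pipeline.

Volumes travel as multi-page TIFF plus a sidecar JSON carrying calibration
(missing calibration is an error, never a silent default); label stacks as
per-slice indexed PNGs plus a legend JSON; profiles, ensembles and counts
as UTF-8 comma-separated CSV with mandatory header row.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .exceptions import ConfigError, FormatError
from .morphometry import DEFAULT_LEGEND, SectionLabelStack
from .volume import MultiChannelVolume

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.9g"


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def write_volume(volume: MultiChannelVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF (pages = Z, channel axis) + sidecar."""
    path = Path(path)
    data = np.moveaxis(volume.data, 0, 1)  # (Z, C, Y, X)
    tifffile.imwrite(path, data.astype(np.float32), metadata={"axes": "ZCYX"})
    sidecar = {
        "axis_order": "ZCYX",
        "shape": list(data.shape),
        "voxel_size_um": list(volume.voxel_size_um),
        "channel_names": list(volume.channel_names),
        "axis_convention": volume.axis_convention,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_volume(path: str | Path) -> MultiChannelVolume:
    """Read a volume written by :func:`write_volume`, validating the sidecar."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar JSON for {path.name}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("shape", "voxel_size_um", "channel_names"):
        if key not in meta:
            raise FormatError(f"sidecar missing required key {key!r}")
    data = tifffile.imread(path)
    data = np.asarray(data).reshape(tuple(meta["shape"]))  # raises on mismatch
    expected = tuple(meta["shape"])
    if data.shape != expected:
        raise FormatError(f"TIFF shape {data.shape} != sidecar shape {expected}")
    if len(meta["channel_names"]) != expected[1]:
        raise FormatError("channel count mismatch between pages and sidecar")
    return MultiChannelVolume(
        data=np.moveaxis(data, 1, 0),
        voxel_size_um=tuple(meta["voxel_size_um"]),
        channel_names=tuple(meta["channel_names"]),
        axis_convention=meta.get("axis_convention", ""),
    )


# ---------------------------------------------------------------------------
# label stacks
# ---------------------------------------------------------------------------

def write_label_stack(stack: SectionLabelStack, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for z in range(stack.n_slices):
        iio.imwrite(directory / f"slice_{z:04d}.png", stack.labels[z].astype(np.uint8))
    legend = {
        "classes": stack.legend,
        "pixel_size_um": stack.pixel_size_um,
        "slice_thickness_um": stack.slice_thickness_um,
        "n_slices": stack.n_slices,
    }
    (directory / "legend.json").write_text(json.dumps(legend, indent=1, sort_keys=True))
    return directory


def read_label_stack(directory: str | Path) -> SectionLabelStack:
    """Read per-slice indexed PNGs + legend JSON; unknown class codes rejected."""
    directory = Path(directory)
    legend_path = directory / "legend.json"
    if not legend_path.exists():
        raise FormatError("missing legend.json")
    legend = json.loads(legend_path.read_text())
    files = sorted(directory.glob("slice_*.png"))
    if not files:
        raise FormatError("no slice images found")
    if "n_slices" in legend and legend["n_slices"] != len(files):
        raise FormatError("slice count does not match legend")
    slices = [np.asarray(iio.imread(f)) for f in files]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise FormatError(f"slices have unequal shapes: {sorted(shapes)}")
    labels = np.stack(slices)
    known = set(legend["classes"].values())
    used = set(np.unique(labels).tolist())
    if not used <= known:
        raise FormatError(f"label codes {sorted(used - known)} missing from legend")
    return SectionLabelStack(
        labels=labels,
        pixel_size_um=float(legend["pixel_size_um"]),
        slice_thickness_um=float(legend["slice_thickness_um"]),
        legend=legend["classes"],
    )


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def write_profile_csv(profile, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"position_um": profile.positions_um, "intensity": profile.intensities}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_ensemble_csv(ensemble, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "position_um": ensemble.positions_um,
            "mean": ensemble.mean,
            "sem": ensemble.sem,
            "n": ensemble.n,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_counts_csv(path: str | Path) -> pd.DataFrame:
    from .interaction import validate_counts_table

    return validate_counts_table(pd.read_csv(path))


def write_counts_csv(counts: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    counts.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

KNOWN_STAGES = ("simulate_boundary", "profiles", "summary", "simulate_sections",
                "morphometry", "vsd", "glm")

_CONFIG_KEYS = {"stages", "seed", "out", "log_level", "params"}


@dataclass
class RunConfig:
    """Pipeline configuration; unknown keys are rejected on load."""

    stages: list[str]
    out: str
    seed: int = 0
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in KNOWN_STAGES:
                raise ConfigError(f"unknown stage {s!r}; known: {KNOWN_STAGES}")
        unknown_param_stages = set(self.params) - set(KNOWN_STAGES)
        if unknown_param_stages:
            raise ConfigError(f"params for unknown stages: {sorted(unknown_param_stages)}")

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        payload = json.loads(text)
        unknown = set(payload) - _CONFIG_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stages" not in payload or "out" not in payload:
            raise ConfigError("config requires 'stages' and 'out'")
        return cls(**payload)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _provenance(config: RunConfig) -> dict:
    canonical = config.to_json()
    return {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in order; returns a result bundle dict.

    Deterministic given config + seed; every run writes a provenance record
    (config hash, seed, versions) alongside its outputs.
    """
    from . import interaction, morphometry, profiles as prof, synthetic

    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    state: dict = {}

    for stage in config.stages:
        params = dict(config.params.get(stage, {}))
        try:
            if stage == "simulate_boundary":
                spec = synthetic.BoundaryPhantomSpec(
                    **{**params, "seed": params.get("seed", config.seed)}
                )
                vol, truth = synthetic.make_boundary_volume(spec)
                write_volume(vol, out / "boundary_volume.tif")
                (out / "boundary_truth.json").write_text(truth.to_json())
                state["volume"], state["truth"] = vol, truth
                results[stage] = {"volume": str(out / "boundary_volume.tif")}

            elif stage == "profiles":
                vol = state.get("volume")
                if vol is None:
                    vol = read_volume(params.pop("volume"))
                channel = params.get("channel", "band")
                slab_um = params.get("slab_um", vol.voxel_size_um[0] * vol.data.shape[1])
                n_lines = int(params.get("n_lines", 3))
                projections = prof.slab_max_projection(vol, slab_um, channel)
                ny, nx = projections[0].shape
                px = vol.voxel_size_um[2]
                stats_rows = []
                all_profiles = []
                for proj in projections:
                    for row in np.linspace(ny * 0.25, ny * 0.75, n_lines):
                        line = prof.ProfileLine(
                            start=(float(row), 0.0),
                            end=(float(row), float(nx - 1)),
                            anchor_um=(nx - 1) / 2.0 * px,
                            sampling_step_um=params.get("step_um", px),
                        )
                        p = prof.sample_profile(proj, line, pixel_size_um=px)
                        p = prof.LinearProfile(
                            p.positions_um, np.clip(p.intensities, 0.0, None)
                        )
                        p = prof.normalize_profile(p)
                        all_profiles.append(p)
                        st = prof.boundary_stats(
                            p, baseline=float(params.get("baseline", 0.1))
                        )
                        stats_rows.append({"m_um": st.m, "s_um": st.s})
                ensemble = prof.aggregate_profiles(all_profiles)
                write_ensemble_csv(ensemble, out / "ensemble.csv")
                stats_df = pd.DataFrame(stats_rows)
                stats_df.to_csv(out / "boundary_stats.csv", index=False,
                                float_format=_FLOAT_FMT)
                state["boundary_stats"] = stats_df
                results[stage] = {"n_profiles": len(all_profiles)}

            elif stage == "summary":
                stats_df = state["boundary_stats"]
                summary = {
                    "mean_m_um": float(stats_df["m_um"].mean()),
                    "mean_s_um": float(stats_df["s_um"].mean()),
                }
                truth = state.get("truth")
                if truth is not None:
                    summary["true_center_um"] = truth.derived["boundary_center_um"]
                    summary["center_error_um"] = abs(
                        summary["mean_m_um"] - truth.derived["boundary_center_um"]
                    )
                (out / "summary.json").write_text(json.dumps(summary, sort_keys=True))
                results[stage] = summary

            elif stage == "simulate_sections":
                hole_specs = tuple(
                    synthetic.HoleSpec(**h) for h in params.pop("holes", [])
                )
                spec = synthetic.HeartPhantomSpec(
                    **{**params, "hole_specs": hole_specs,
                       "seed": params.get("seed", config.seed)}
                )
                stack, truth = synthetic.make_section_stack(spec)
                write_label_stack(stack, out / "sections")
                (out / "sections_truth.json").write_text(truth.to_json())
                state["stack"] = stack
                results[stage] = {"n_slices": stack.n_slices}

            elif stage == "morphometry":
                stack = state.get("stack")
                if stack is None:
                    stack = read_label_stack(params.pop("stack"))
                metrics = {
                    "ivs_fill": morphometry.ivs_fill(stack),
                    "trabeculation_fraction": morphometry.trabeculation_fraction(stack),
                }
                (out / "morphometry.json").write_text(json.dumps(metrics, sort_keys=True))
                results[stage] = metrics

            elif stage == "vsd":
                stack = state.get("stack")
                if stack is None:
                    stack = read_label_stack(params.pop("stack"))
                records = morphometry.detect_vsds(stack)
                rows = []
                for rec in records:
                    morphometry.vsd_area(stack, rec)
                    morphometry.classify_vsd(stack, rec)
                    rows.append(
                        {
                            "component_id": rec.component_id,
                            "slice_start": rec.slice_range[0],
                            "slice_end": rec.slice_range[1],
                            "area_um2": rec.area_um2,
                            "subtype": rec.subtype,
                        }
                    )
                pd.DataFrame(
                    rows,
                    columns=["component_id", "slice_start", "slice_end",
                             "area_um2", "subtype"],
                ).to_csv(out / "vsds.csv", index=False, float_format=_FLOAT_FMT)
                results[stage] = {"n_defects": len(records)}

            elif stage == "glm":
                counts = read_counts_csv(params["counts"])
                fit = interaction.fit_counts(counts)
                effects = interaction.reported_effects(fit)
                payload = dataclasses.asdict(effects)
                (out / "glm.json").write_text(json.dumps(payload, sort_keys=True))
                results[stage] = payload
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "provenance.json").write_text(
        json.dumps(_provenance(config), indent=1, sort_keys=True)
    )
    return results
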