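"""Shared I/O, run configuration, manifests, and arm orchestration.

Table formats are delimited text with documented headers:

* trace tables — ``#`` metadata lines (``fps``, ``n_frames``) followed by a
  TSV with a ``neuron_id`` column and one column per frame;
* interval tables — TSV with ``label``, ``start_s``, ``end_s``;
* spine tables — long-format TSV with ``protrusion_id``, ``session_index``,
  ``dendrite_id``, ``position_um``, ``class``, ``present``;
* frame stacks — multi-page TIFF (16-bit or float).

Times are seconds from recording start (frame = floor(t * fps)); intervals
are half-open [start, end); positions are micrometres.  ``run_pipeline``
executes one analysis arm in dependency order and records a manifest with
the config hash, output checksums and every exclusion warning, so a rerun
with the same config and seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import behavior, spines, synchrony, texture, traces, widefield
from ._validate import InvalidConfigError

__all__ = [
    "RunConfig",
    "RunManifest",
    "read_trace_table",
    "write_trace_table",
    "read_interval_table",
    "write_interval_table",
    "read_spine_table",
    "write_spine_table",
    "read_stack",
    "write_stack",
    "load_config",
    "run_pipeline",
]

ARMS = ("baseline", "whisking", "texture", "spines", "behavior")


# ----------------------------------------------------------------- tables


def write_trace_table(path, F: np.ndarray, fps: float, neuron_ids=None) -> None:
    F = np.atleast_2d(np.asarray(F, dtype=float))
    ids = neuron_ids or [f"n{i}" for i in range(F.shape[0])]
    with open(path, "w") as fh:
        fh.write(f"# fps={fps!r}\n# n_frames={F.shape[1]}\n")
        fh.write("neuron_id\t" + "\t".join(f"f{j}" for j in range(F.shape[1])) + "\n")
        for nid, row in zip(ids, F):
            fh.write(nid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_trace_table(path) -> tuple[np.ndarray, float, list[str]]:
    """Returns (matrix, fps, neuron_ids); full-precision round trip."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    if "fps" not in meta:
        raise ValueError(f"{path}: missing '# fps=' header")
    fps = float(meta["fps"])
    header = lines[body_start].rstrip("\n").split("\t")
    if header[0] != "neuron_id":
        raise ValueError(f"{path}: line {body_start + 1}: expected 'neuron_id' column")
    ids, rows = [], []
    for ln, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise ValueError(f"{path}: line {ln}: expected {len(header)} fields, got {len(parts)}")
        ids.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as e:
            raise ValueError(f"{path}: line {ln}: {e}") from None
    return np.asarray(rows), fps, ids


def write_interval_table(path, df: pd.DataFrame) -> None:
    df[["label", "start_s", "end_s"]].to_csv(path, sep="\t", index=False)


def read_interval_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("label", "start_s", "end_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad = df.index[df.end_s <= df.start_s]
    if len(bad):
        raise ValueError(f"{path}: line {bad[0] + 2}: interval end <= start")
    return df


def write_spine_table(path, df: pd.DataFrame) -> None:
    spines.validate_spine_table(df)
    df[spines.REQUIRED_COLUMNS].to_csv(path, sep="\t", index=False)


def read_spine_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["present"] = df["present"].astype(bool)
    return spines.validate_spine_table(df)


def write_stack(path, frames: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(frames))


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path)


# ------------------------------------------------------------ run config


@dataclass
class RunConfig:
    """One home for every stage parameter (defaults = stage defaults)."""

    arm: str = "baseline"
    inputs: dict = field(default_factory=dict)  # named input paths
    out_dir: str = "results/run"
    seed: int = 0
    fps: float = 10.0
    behavior_fps: int = 30
    # traces
    dff_window_s: float = 300.0
    dff_percentile: float = 50.0
    min_height_sd: float = 4.0
    min_ipi_s: float = 0.5
    min_width_s: float = 0.3
    # synchrony
    n_surrogates: int = 1000
    synchrony_percentile: float = 95.0
    # widefield
    mask_threshold: float = 0.95
    onset_threshold_mad: float = 3.0
    min_quiet_s: float = 0.5
    min_bout_s: float = 0.5
    delay_mode: str = "argmax_time"
    # texture
    min_touch_s: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.05
    paired_permutation: bool = False
    # behavior
    criterion_k: int = 8
    criterion_window: int = 10
    skip_omissions: bool = False
    min_total_approaches: int = 12
    max_time_bias: float = 0.60
    # spines
    reemergence_radius_um: float = 2.0

    def __post_init__(self):
        if self.arm not in ARMS:
            raise InvalidConfigError(f"unknown arm {self.arm!r}; expected one of {ARMS}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InvalidConfigError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    arm: str
    started_utc: str
    outputs: dict = field(default_factory=dict)  # name -> sha256 of file
    warnings: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# --------------------------------------------------------- orchestration


def _arm_baseline(cfg: RunConfig, out: Path) -> dict:
    F, fps, ids = read_trace_table(cfg.inputs["traces"])
    dffs, transient_rows, metric_rows = [], [], []
    for nid, row in zip(ids, F):
        d = traces.compute_dff(
            traces.RawTrace(row, fps, nid), cfg.dff_window_s, cfg.dff_percentile
        )
        ts = traces.detect_transients(
            d.dff, d.baseline_sd, fps, cfg.min_height_sd, cfg.min_ipi_s, cfg.min_width_s, nid
        )
        mean_size, freq = traces.activity_metrics(ts, d.duration_s)
        metric_rows.append(
            {"neuron_id": nid, "mean_transient_size": mean_size, "freq_per_min": freq,
             "baseline_sd": d.baseline_sd}
        )
        transient_rows.append(ts.to_frame())
        dffs.append(traces.denoise(d.dff, d.baseline_sd))
    denoised = np.asarray(dffs)
    pd.concat(transient_rows, ignore_index=True).to_csv(out / "transients.tsv", sep="\t", index=False)
    pd.DataFrame(metric_rows).to_csv(out / "activity_metrics.tsv", sep="\t", index=False)
    outputs = {"transients": out / "transients.tsv", "activity_metrics": out / "activity_metrics.tsv"}
    if len(ids) >= 2:
        raster = synchrony.binarize(denoised, fps)
        null = synchrony.build_null(raster, cfg.n_surrogates, cfg.synchrony_percentile, cfg.seed)
        ev = synchrony.detect_events(raster, null)
        ev.to_frame().to_csv(out / "synchrony_events.tsv", sep="\t", index=False)
        summary = pd.DataFrame(
            [
                {
                    "threshold": null.threshold,
                    "n_events": len(ev),
                    "mean_duration_s": ev.mean_duration_s,
                    "pct_time_in_synchrony": 100 * ev.fraction_time_in_synchrony,
                    "mean_participant_pct": 100 * ev.mean_participant_fraction,
                }
            ]
        )
        summary.to_csv(out / "synchrony_summary.tsv", sep="\t", index=False)
        outputs["synchrony_events"] = out / "synchrony_events.tsv"
        outputs["synchrony_summary"] = out / "synchrony_summary.tsv"
    return outputs


def _arm_whisking(cfg: RunConfig, out: Path) -> dict:
    wh = pd.read_csv(cfg.inputs["whisking"], sep="\t")["magnitude"].to_numpy()
    ca = pd.read_csv(cfg.inputs["ca_wf"], sep="\t")["ca_wf"].to_numpy()
    wh10 = widefield.resample_behavior(wh, cfg.behavior_fps, int(cfg.fps))
    n = min(wh10.size, ca.size)
    corr = widefield.whisking_correlation(ca[:n], wh10[:n], cfg.fps)
    onsets = widefield.detect_whisking_onsets(
        wh, cfg.behavior_fps, None, cfg.onset_threshold_mad, cfg.min_quiet_s, cfg.min_bout_s
    )
    summary = widefield.onset_locked_summary(ca, onsets, cfg.fps, delay_mode=cfg.delay_mode)
    pd.DataFrame(
        [
            {
                "r_zero_lag": corr["r_zero_lag"],
                "peak_r": corr["peak_r"],
                "peak_lag_s": corr["peak_lag_s"],
                "whisking_modulation": summary.modulation,
                "response_delay_s": summary.response_delay_s,
                "n_episodes": summary.n_episodes,
            }
        ]
    ).to_csv(out / "whisking_summary.tsv", sep="\t", index=False)
    return {"whisking_summary": out / "whisking_summary.tsv"}


def _arm_texture(cfg: RunConfig, out: Path) -> dict:
    F, fps, ids = read_trace_table(cfg.inputs["traces"])
    sched = texture.extract_touch_events(read_interval_table(cfg.inputs["schedule"]), cfg.min_touch_s)
    profile = texture.classify_population(
        F, fps, sched, cfg.n_perm, cfg.alpha, cfg.seed, ids, cfg.dff_window_s,
        paired=cfg.paired_permutation,
    )
    profile.table.to_csv(out / "texture_profile.tsv", sep="\t", index=False)
    return {"texture_profile": out / "texture_profile.tsv"}


def _arm_spines(cfg: RunConfig, out: Path) -> dict:
    table = read_spine_table(cfg.inputs["spine_table"])
    sessions = sorted(table["session_index"].unique())
    rows = []
    for s_prev, s_next in zip(sessions, sessions[1:]):
        t = spines.turnover(table, s_prev, s_next)
        rows.append(
            {"s_prev": s_prev, "s_next": s_next, **{k: v for k, v in t.items() if not k.endswith("_ids")}}
        )
    pd.DataFrame(rows).to_csv(out / "turnover.tsv", sep="\t", index=False)
    return {"turnover": out / "turnover.tsv"}


def _arm_behavior(cfg: RunConfig, out: Path) -> dict:
    trials = pd.read_csv(cfg.inputs["trials"], sep="\t")
    rows = []
    for (session, phase), grp in trials.groupby(["session_id", "phase"]):
        met = behavior.session_criterion(
            grp["outcome"].tolist(), cfg.criterion_k, cfg.criterion_window, cfg.skip_omissions
        )
        rows.append({"session_id": session, "phase": phase, "trials_to_criterion": met})
    pd.DataFrame(rows).to_csv(out / "criterion.tsv", sep="\t", index=False)
    return {"criterion": out / "criterion.tsv"}


_ARM_RUNNERS = {
    "baseline": _arm_baseline,
    "whisking": _arm_whisking,
    "texture": _arm_texture,
    "spines": _arm_spines,
    "behavior": _arm_behavior,
}


def run_pipeline(cfg: RunConfig, arm: str | None = None) -> RunManifest:
    """Execute one analysis arm; stages run in dependency order and every
    dropped-episode / excluded-neuron warning is logged to the manifest."""
    from . import __version__

    arm = arm or cfg.arm
    if arm not in _ARM_RUNNERS:
        raise InvalidConfigError(f"unknown arm {arm!r}")
    for name, path in cfg.inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"arm {arm!r}: missing input {name!r} at {path}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=cfg.content_hash(),
        package_version=__version__,
        arm=arm,
        started_utc=datetime.now(timezone.utc).isoformat(),
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        outputs = _ARM_RUNNERS[arm](cfg, out)
    manifest.warnings = [str(w.message) for w in caught]
    manifest.outputs = {name: _checksum(p) for name, p in outputs.items()}
    manifest.write(out / "manifest.json")
    return manifest
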