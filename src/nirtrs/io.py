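"""Readers and writers for the pipeline's text formats.

All formats are plain text (CSV/TSV/JSON/YAML); write-then-read is an
identity on values, and malformed input is refused with the offending
location rather than coerced.

Formats
-------
Hb CSV      ``time_s, channel, oxy_uM, deoxy_uM, total_uM``
RR CSV      ``event_time_s, interval_s``
VAS CSV     ``subject, condition, item, score``
TPSF TSV    see :mod:`nirtrs.optics`
RunConfig   hierarchical YAML, hashed into every analysis output
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .autonomic import IntervalSeries
from .design import CONDITIONS, ExperimentDesign
from .simulate import CHANNELS, HbChannelSeries, SyntheticExperiment, SimulationConfig

__all__ = [
    "RunConfig",
    "write_hb_csv",
    "read_hb_csv",
    "write_rr_csv",
    "read_rr_csv",
    "write_vas_csv",
    "read_vas_csv",
    "write_dataset",
    "read_dataset",
]

HB_COLUMNS = ["time_s", "channel", "oxy_uM", "deoxy_uM", "total_uM"]
RR_COLUMNS = ["event_time_s", "interval_s"]
VAS_COLUMNS = ["subject", "condition", "item", "score"]


@dataclass
class RunConfig:
    """Analysis parameters; round-trips losslessly through YAML."""

    # design
    period_duration_s: float = 60.0
    sampling_rate_hz: float = 0.33
    baseline_samples: int = 10
    # TPSF fit
    fit_rise_fraction: float = 0.10
    fit_fall_fraction: float = 0.01
    fit_init_mua: float = 0.01
    fit_init_musp: float = 1.0
    # HRV
    hrv_resample_hz: float = 4.0
    hrv_segment_s: float = 120.0
    # gates
    normality_alpha: float = 0.05
    outlier_k: float = 3.5
    seed: int = 0

    def design(self) -> ExperimentDesign:
        return ExperimentDesign(
            period_duration_s=self.period_duration_s,
            sampling_rate_hz=self.sampling_rate_hz,
            baseline_samples=self.baseline_samples,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _check_columns(df: pd.DataFrame, expected: list[str], path: Path) -> None:
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: header mismatch: expected {expected}, got {list(df.columns)}"
        )


def write_hb_csv(path: str | Path, channels: dict[str, HbChannelSeries]) -> None:
    rows = []
    for chan in sorted(channels):
        s = channels[chan]
        for t, o, d in zip(s.times, s.oxy_um, s.deoxy_um):
            rows.append((t, chan, o, d, o + d))
    df = pd.DataFrame(rows, columns=HB_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g")


def read_hb_csv(path: str | Path) -> dict[str, HbChannelSeries]:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, HB_COLUMNS, path)
    bad = df.index[~np.isfinite(df[["time_s", "oxy_uM", "deoxy_uM"]]).all(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: non-finite value at data row {bad[0] + 1}")
    out = {}
    for chan, grp in df.groupby("channel", sort=True):
        out[str(chan)] = HbChannelSeries(
            times=grp["time_s"].to_numpy(),
            oxy_um=grp["oxy_uM"].to_numpy(),
            deoxy_um=grp["deoxy_uM"].to_numpy(),
        )
    return out


def write_rr_csv(path: str | Path, series: IntervalSeries) -> None:
    df = pd.DataFrame(
        {"event_time_s": series.onsets, "interval_s": series.intervals}
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_rr_csv(path: str | Path) -> IntervalSeries:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, RR_COLUMNS, path)
    iv = df["interval_s"].to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(iv) | (iv <= 0))[0]
    if bad.size:
        raise ValueError(
            f"{path}: non-positive or non-finite interval at data row {bad[0] + 1}"
        )
    t0 = float(df["event_time_s"].iloc[0])
    return IntervalSeries.from_intervals(iv, start=t0)


def write_vas_csv(path: str | Path, vas: pd.DataFrame) -> None:
    vas.to_csv(path, index=False, float_format="%.9g", columns=VAS_COLUMNS)


def read_vas_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, VAS_COLUMNS, path)
    scores = df["score"].to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(scores) | (scores < 0) | (scores > 100))[0]
    if bad.size:
        raise ValueError(f"{path}: VAS score out of [0, 100] at data row {bad[0] + 1}")
    return df


# --- dataset directory -------------------------------------------------------

def write_dataset(outdir: str | Path, experiment: SyntheticExperiment) -> None:
    """Write a simulated study as a directory tree of the text formats
    (``hb/``, ``rr/``, ``vas.csv``, ``manifest.json``)."""
    outdir = Path(outdir)
    (outdir / "hb").mkdir(parents=True, exist_ok=True)
    (outdir / "rr").mkdir(parents=True, exist_ok=True)
    for (subj, cond), channels in sorted(experiment.hb.items()):
        write_hb_csv(outdir / "hb" / f"sub{subj:03d}_{cond}.csv", channels)
    for (subj, cond), series in sorted(experiment.rr.items()):
        write_rr_csv(outdir / "rr" / f"sub{subj:03d}_{cond}.csv", series)
    write_vas_csv(outdir / "vas.csv", experiment.vas)
    (outdir / "manifest.json").write_text(
        json.dumps(experiment.manifest, indent=2, sort_keys=True) + "\n"
    )


def read_dataset(indir: str | Path, design: ExperimentDesign | None = None) -> SyntheticExperiment:
    """Read a dataset directory written by :func:`write_dataset` (or
    assembled by hand in the same layout)."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    hb, rr = {}, {}
    for f in sorted((indir / "hb").glob("sub*_*.csv")):
        subj, cond = _parse_subject_file(f)
        hb[(subj, cond)] = read_hb_csv(f)
    for f in sorted((indir / "rr").glob("sub*_*.csv")):
        subj, cond = _parse_subject_file(f)
        rr[(subj, cond)] = read_rr_csv(f)
    vas = read_vas_csv(indir / "vas.csv")
    n_subjects = len({k[0] for k in hb})
    config = SimulationConfig(n_subjects=max(n_subjects, 1), seed=manifest.get("seed", 0))
    return SyntheticExperiment(
        config=config,
        design=design or ExperimentDesign(),
        hb=hb,
        rr=rr,
        vas=vas,
        manifest=manifest,
    )


def _parse_subject_file(path: Path) -> tuple[int, str]:
    stem = path.stem  # subNNN_condition
    try:
        subj_part, cond = stem.split("_", 1)
        subj = int(subj_part[3:])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: unrecognised dataset file name") from exc
    if cond not in CONDITIONS:
        raise ValueError(f"{path}: unknown condition {cond!r}")
    return subj, cond
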