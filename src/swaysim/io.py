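"""Plain-text file dialects and run configuration.

Series files are CSV with a single metadata header line of ``key=value``
tokens (quantity, unit, sample_rate, channels) followed by one column per
channel; missing samples are empty fields.  The manifest is a TSV with one
row per trial; the subject table a TSV with one row per participant.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import AngularSeries, ForceTrace, MarkerSet, SubjectProfile

__all__ = [
    "RunConfig",
    "write_angular",
    "read_angular",
    "write_force",
    "read_force",
    "write_markers",
    "read_markers",
    "write_manifest",
    "read_manifest",
    "write_subjects",
    "read_subjects",
]

_FLOAT_FMT = "%.9g"


def _write_table(path: Path, meta: dict, columns: dict[str, np.ndarray]) -> None:
    header = ",".join(f"{k}={v}" for k, v in meta.items())
    names = list(columns)
    arrs = [np.asarray(columns[c], dtype=float) for c in names]
    n = len(arrs[0])
    with open(path, "w") as fh:
        fh.write(header + "\n")
        fh.write(",".join(names) + "\n")
        for i in range(n):
            fh.write(",".join(
                "" if np.isnan(a[i]) else _FLOAT_FMT % a[i] for a in arrs
            ) + "\n")


def _read_table(path: Path) -> tuple[dict, pd.DataFrame]:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(tok.split("=", 1) for tok in header.split(",") if "=" in tok)
        df = pd.read_csv(fh)
    return meta, df


def write_angular(path, series: AngularSeries) -> None:
    _write_table(Path(path),
                 {"quantity": series.quantity, "unit": series.unit,
                  "sample_rate": series.sample_rate},
                 {"theta": series.values})


def read_angular(path) -> AngularSeries:
    meta, df = _read_table(Path(path))
    return AngularSeries(float(meta["sample_rate"]),
                         df["theta"].to_numpy(float), meta["quantity"])


def write_force(path, force: ForceTrace) -> None:
    meta = {"quantity": "force", "unit": "N", "sample_rate": force.sample_rate}
    _write_table(Path(path), meta, {"force": force.values})


def read_force(path) -> ForceTrace:
    meta, df = _read_table(Path(path))
    return ForceTrace(float(meta["sample_rate"]), df["force"].to_numpy(float))


def write_markers(path, m: MarkerSet) -> None:
    cols: dict[str, np.ndarray] = {}
    for name, xy in m.markers.items():
        bad = m.missing[name]
        x = np.where(bad, np.nan, xy[:, 0])
        y = np.where(bad, np.nan, xy[:, 1])
        cols[f"{name}_x"] = x
        cols[f"{name}_y"] = y
    _write_table(Path(path),
                 {"quantity": "markers", "unit": "m",
                  "sample_rate": m.sample_rate},
                 cols)


def read_markers(path) -> MarkerSet:
    meta, df = _read_table(Path(path))
    names = sorted({c[:-2] for c in df.columns if c.endswith("_x")})
    markers, missing = {}, {}
    for name in names:
        xy = df[[f"{name}_x", f"{name}_y"]].to_numpy(float)
        mask = np.isnan(xy).any(axis=1)
        markers[name] = xy
        missing[name] = mask
    return MarkerSet(float(meta["sample_rate"]), markers, missing)


MANIFEST_COLUMNS = ["subject_id", "group", "condition", "vision",
                    "trial_index", "file", "force_file"]


def write_manifest(path, rows: list[dict]) -> None:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS).fillna("")
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"force_file": str}, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    return df


def write_subjects(path, subjects: list[SubjectProfile]) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in subjects]).to_csv(
        path, sep="\t", index=False)


def read_subjects(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class RunConfig:
    """Fully resolved pipeline parameters.

    Defaults equal the protocol's stated values: 3.5 Hz static and 5 Hz
    dynamic filter cutoffs, 80 s clipping, 500 ms onset baseline with a
    4 SD threshold, the pooled ±1 SD force-exclusion rule and the
    five-perturbation minimum.
    """

    seed: int = 0
    design: str = "static_sim"
    n_pd: int = 20
    n_control: int = 22
    static_cutoff_hz: float = 3.5
    dynamic_cutoff_hz: float = 5.0
    clip_s: float = 80.0
    filter_order: int = 4
    mpf_band_lo_hz: float = 0.05
    welch_segment_s: float = 20.0
    max_gap_ms: float = 40.0
    onset_baseline_ms: float = 500.0
    onset_k_sd: float = 4.0
    onset_coarse_k: float = 6.0
    exclusion_measure: str = "impulse"
    min_events: int = 5
    response_window_s: float = 2.0
    alpha: float = 0.05
    device: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)
    controller_pd: dict = field(default_factory=dict)
    controller_control: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)
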