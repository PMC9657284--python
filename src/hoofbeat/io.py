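"""Trial bundles on disk: delimited text tables plus a JSON manifest.

A trial bundle is a directory of UTF-8 comma-separated tables with "." as
the decimal separator and all times in seconds:

* ``manifest.json`` — schema version, sampling rate, seed, and (for
  simulated trials) the full gait template;
* ``events.csv`` — columns (limb, event ∈ {on, off}, time_s);
* ``acceleration.csv`` — (time_s, head_mps2, withers_mps2, pelvis_mps2);
* ``displacement_truth.csv`` — (time_s, head_mm, withers_mm, pelvis_mm),
  simulated trials only;
* ``limb_signals.csv`` — (time_s, LF, RF, LH, RH), simulated trials only.

Numerics are written with 9 significant digits, so a write/read round trip
reproduces every table bit-exactly at that precision.  No community
standard binary format exists for this data class; CSV keeps fixtures
reviewable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AxialTrace, EventSeriesError, LimbEventSeries, LimbSignal
from .simulate import Trial
from .templates import GaitTemplate, LIMBS, SEGMENTS

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1
_FLOAT_FMT = "%.9g"


class BundleError(ValueError):
    """Malformed or inconsistent trial bundle."""


def _template_to_json(t: GaitTemplate) -> dict:
    d = dataclasses.asdict(t)
    d["extremum_phase"] = {f"{seg}:{kind}": v
                           for (seg, kind), v in t.extremum_phase.items()}
    return d


def _template_from_json(d: dict) -> GaitTemplate:
    d = dict(d)
    d["extremum_phase"] = {tuple(k.split(":")): v
                           for k, v in d["extremum_phase"].items()}
    return GaitTemplate(**d)


def write_trial(trial: Trial, path: str | Path) -> Path:
    """Write a trial bundle; returns the bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for limb, series in trial.events.items():
        for on, off in zip(series.hoof_on_s, series.hoof_off_s):
            rows.append((limb, "on", on))
            rows.append((limb, "off", off))
    ev = pd.DataFrame(rows, columns=["limb", "event", "time_s"])
    ev = ev.sort_values(["time_s", "limb"], ignore_index=True)
    ev.to_csv(path / "events.csv", index=False, float_format=_FLOAT_FMT)

    t = next(iter(trial.acceleration.values())).times()
    acc = pd.DataFrame({"time_s": t})
    for seg in SEGMENTS:
        acc[f"{seg}_mps2"] = trial.acceleration[seg].samples
    acc.to_csv(path / "acceleration.csv", index=False, float_format=_FLOAT_FMT)

    if trial.displacement_truth:
        disp = pd.DataFrame({"time_s": t})
        for seg in SEGMENTS:
            disp[f"{seg}_mm"] = trial.displacement_truth[seg].samples
        disp.to_csv(path / "displacement_truth.csv", index=False,
                    float_format=_FLOAT_FMT)
    if trial.limb_signals:
        sig = pd.DataFrame({"time_s": t})
        for limb in LIMBS:
            sig[limb] = trial.limb_signals[limb].samples
        sig.to_csv(path / "limb_signals.csv", index=False,
                   float_format=_FLOAT_FMT)

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "fs_hz": trial.fs_hz,
        "seed": trial.template.seed if trial.template else None,
        "template": (_template_to_json(trial.template)
                     if trial.template else None),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def read_events(path: str | Path) -> dict[str, LimbEventSeries]:
    """Read an event table, validating interleaving per limb."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"limb", "event", "time_s"} - set(df.columns)
    if missing:
        raise BundleError(f"{path.name}: missing columns {sorted(missing)}")
    out = {}
    for limb, sub in df.groupby("limb"):
        if limb not in LIMBS:
            raise BundleError(f"{path.name}: unknown limb {limb!r}")
        sub = sub.sort_values("time_s", kind="stable")
        kinds = sub["event"].to_list()
        times = sub["time_s"].to_numpy()
        expect = "on"
        ons, offs = [], []
        for row, (kind, tt) in zip(sub.index, zip(kinds, times)):
            if kind not in ("on", "off"):
                raise BundleError(f"{path.name}: row {row}: bad event {kind!r}")
            if kind != expect:
                raise BundleError(
                    f"{path.name}: limb {limb}, row {row}: expected "
                    f"{expect!r} event, found {kind!r}")
            (ons if kind == "on" else offs).append(tt)
            expect = "off" if kind == "on" else "on"
        if expect == "off":  # trailing unmatched hoof-on
            ons.pop()
        try:
            out[limb] = LimbEventSeries(limb, np.array(ons), np.array(offs))
        except EventSeriesError as exc:
            raise BundleError(f"{path.name}: {exc}") from exc
    return out


def _read_trace_table(path: Path, suffix: str, fs_hz: float,
                      kind: str) -> dict[str, AxialTrace]:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if (dt <= 0).any():
        row = int(np.nonzero(dt <= 0)[0][0]) + 1
        raise BundleError(f"{path.name}: non-monotone time at row {row}")
    if t.size > 1 and abs((t[1] - t[0]) - 1.0 / fs_hz) > 1e-6 / fs_hz:
        raise BundleError(f"{path.name}: sample spacing inconsistent with "
                          f"manifest fs_hz={fs_hz}")
    out = {}
    for seg in SEGMENTS:
        col = f"{seg}_{suffix}"
        if col not in df:
            raise BundleError(f"{path.name}: missing column {col}")
        out[seg] = AxialTrace(seg, kind, fs_hz, df[col].to_numpy(), t[0])
    return out


def read_trial(path: str | Path) -> Trial:
    """Read a trial bundle back into a :class:`Trial`."""
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise BundleError(f"{path}: manifest.json not found")
    manifest = json.loads(mpath.read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise BundleError(f"manifest.json: schema version "
                          f"{manifest.get('schema_version')!r} unsupported "
                          f"(expected {SCHEMA_VERSION})")
    fs = manifest.get("fs_hz")
    if not fs:
        raise BundleError("manifest.json: sampling rate required (fs_hz)")
    template = (None if manifest.get("template") is None
                else _template_from_json(manifest["template"]))

    events = read_events(path / "events.csv")
    accel = _read_trace_table(path / "acceleration.csv", "mps2", fs,
                              "acceleration_mps2")
    disp = {}
    if (path / "displacement_truth.csv").exists():
        disp = _read_trace_table(path / "displacement_truth.csv", "mm", fs,
                                 "displacement_mm")
    signals = {}
    spath = path / "limb_signals.csv"
    if spath.exists():
        df = pd.read_csv(spath)
        for limb in LIMBS:
            if limb in df:
                signals[limb] = LimbSignal(limb, fs, df[limb].to_numpy(),
                                           df["time_s"].iloc[0])
    return Trial(template=template, events=events, limb_signals=signals,
                 acceleration=accel, displacement_truth=disp,
                 truth_extrema=None)


def write_stride_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path
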