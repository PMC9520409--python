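"""Readers/writers for the package's plain-text formats and run manifests.

Conventions: times are serialized in milliseconds except trend/AFR
timestamps, which are in seconds; units are embedded in the column names.
Floats are written with Python's shortest-repr formatting, which makes a
read/write cycle byte-stable for files produced by this module.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .atrial_generator import AAParamTrend
from .av_network import ModelParams
from .rr_metrics import RRSeries, TrendSeries
from .tilt_pipeline import AfrTrend, TiltProtocol, TiltSegment


class ParseError(ValueError):
    """Malformed input file; message names the offending row/column."""


def _write_csv(path, header: list[str], rows) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in rows:
            w.writerow([repr(float(v)) if isinstance(v, float) else v
                        for v in row])


def _read_csv(path, expected: list[str]) -> list[list[str]]:
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        try:
            header = next(r)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if header != expected:
            raise ParseError(
                f"{path}: expected header {expected}, got {header}"
            )
        return list(r)


def _parse_float(path, row_no: int, col: str, value: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(
            f"{path}: row {row_no}, column {col!r}: not a number: {value!r}"
        ) from None


def write_aa_series(path, times_ms) -> None:
    _write_csv(path, ["time_ms"], ([float(t)] for t in np.asarray(times_ms)))


def read_aa_series(path) -> np.ndarray:
    rows = _read_csv(path, ["time_ms"])
    return np.array(
        [_parse_float(path, i + 2, "time_ms", r[0]) for i, r in enumerate(rows)]
    )


#: Ventricular activation series shares the AA format.
write_ventricular_series = write_aa_series
read_ventricular_series = read_aa_series


def write_rr_series(path, rr: RRSeries) -> None:
    _write_csv(
        path, ["rr_ms", "valid"],
        ([float(x), int(v)] for x, v in zip(rr.intervals, rr.valid)),
    )


def read_rr_series(path) -> RRSeries:
    rows = _read_csv(path, ["rr_ms", "valid"])
    vals, valid = [], []
    for i, r in enumerate(rows):
        vals.append(_parse_float(path, i + 2, "rr_ms", r[0]))
        flag = r[1].strip()
        if flag not in ("0", "1"):
            raise ParseError(
                f"{path}: row {i + 2}, column 'valid': expected 0/1, got {flag!r}"
            )
        valid.append(flag == "1")
    return RRSeries(np.array(vals), np.array(valid, dtype=bool))


def write_trend(path, trend: TrendSeries) -> None:
    _write_csv(
        path, ["time_s", "value"],
        ([float(t), float(v)] for t, v in zip(trend.time_s, trend.values)),
    )


def read_trend(path) -> TrendSeries:
    rows = _read_csv(path, ["time_s", "value"])
    t = [_parse_float(path, i + 2, "time_s", r[0]) for i, r in enumerate(rows)]
    v = [_parse_float(path, i + 2, "value", r[1]) for i, r in enumerate(rows)]
    return TrendSeries(np.array(t), np.array(v))


def write_aa_param_trend(path, trend: AAParamTrend) -> None:
    _write_csv(
        path, ["time_s", "mu_ms", "sigma_ms"],
        ([float(t), float(m), float(s)] for t, m, s in
         zip(trend.time_s, trend.mu_ms, trend.sigma_ms)),
    )


def read_aa_param_trend(path) -> AAParamTrend:
    rows = _read_csv(path, ["time_s", "mu_ms", "sigma_ms"])
    t, mu, sg = [], [], []
    for i, r in enumerate(rows):
        t.append(_parse_float(path, i + 2, "time_s", r[0]))
        mu.append(_parse_float(path, i + 2, "mu_ms", r[1]))
        sg.append(_parse_float(path, i + 2, "sigma_ms", r[2]))
    return AAParamTrend(np.array(t), np.array(mu), np.array(sg))


def write_afr_trend(path, afr: AfrTrend) -> None:
    _write_csv(
        path, ["time_s", "afr_hz"],
        ([float(t), float(a)] for t, a in zip(afr.time_s, afr.afr_hz)),
    )


def read_afr_trend(path) -> AfrTrend:
    rows = _read_csv(path, ["time_s", "afr_hz"])
    t = [_parse_float(path, i + 2, "time_s", r[0]) for i, r in enumerate(rows)]
    a = [_parse_float(path, i + 2, "afr_hz", r[1]) for i, r in enumerate(rows)]
    return AfrTrend(np.array(t), np.array(a))


def write_model_params(path, params: ModelParams) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model_params(path) -> ModelParams:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as e:
            raise ParseError(f"{path}: invalid JSON: {e}") from None
    try:
        return ModelParams.from_dict(d)
    except (KeyError, TypeError, ValueError) as e:
        raise ParseError(f"{path}: bad parameter file: {e}") from None


def write_protocol(path, protocol: TiltProtocol) -> None:
    doc = {"segments": [
        {"label": s.label, "duration_s": s.duration_s,
         "a_r": s.a_r, "a_d": s.a_d}
        for s in protocol.segments
    ]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_protocol(path) -> TiltProtocol:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        segs = tuple(
            TiltSegment(
                label=str(s["label"]),
                duration_s=float(s["duration_s"]),
                a_r=float(s.get("a_r", 1.0)),
                a_d=float(s.get("a_d", 1.0)),
            )
            for s in doc["segments"]
        )
    except (KeyError, TypeError, ValueError) as e:
        raise ParseError(f"{path}: bad protocol file: {e}") from None
    return TiltProtocol(segs)


def run_manifest(path, config: dict, seeds: dict, summary: dict) -> dict:
    """Write a JSON manifest of a completed run and return it.

    ``seeds`` must contain the master seed and any derived stream seeds;
    a missing master seed is an error for stochastic runs.
    """
    if "master" not in seeds:
        raise ValueError("manifest requires the master seed under seeds['master']")
    doc = {
        "software": {"name": "avnode", "version": __version__},
        "config": config,
        "seeds": seeds,
        "summary": summary,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return doc
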