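"""Delimited-text I/O for reference bands, trends and trial manifests.

Reference bands are stored one file per muscle per experiment with columns
``condition``, ``mean``, ``sd`` (tab-separated, header mandatory), matching
the format consumed by the comparison statistics and emitted by the
synthetic generator.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import ReferenceBand, ResponseTrend

__all__ = [
    "write_reference_band", "read_reference_band",
    "write_trend", "read_trend", "write_manifest", "read_manifest",
]


def write_reference_band(band: ReferenceBand, path, sep="\t"):
    df = pd.DataFrame({"condition": band.conditions, "mean": band.mean,
                       "sd": band.sd})
    df.to_csv(path, sep=sep, index=False)


def read_reference_band(path, sep="\t") -> ReferenceBand:
    df = pd.read_csv(path, sep=sep)
    missing = {"condition", "mean", "sd"} - set(df.columns)
    if missing:
        raise ValueError(f"reference band file {path} lacks columns {missing}")
    return ReferenceBand(df["condition"].to_numpy(), df["mean"].to_numpy(),
                         df["sd"].to_numpy())


def write_trend(trend: ResponseTrend, path, sep="\t"):
    df = pd.DataFrame({"condition": trend.conditions,
                       "response": trend.responses})
    df.to_csv(path, sep=sep, index=False)


def read_trend(path, muscle="", experiment="", sep="\t") -> ResponseTrend:
    df = pd.read_csv(path, sep=sep)
    return ResponseTrend(muscle, experiment, df["condition"].to_numpy(),
                         df["response"].to_numpy())


def write_manifest(trials, directory, prefix="trial"):
    """Write per-trial JSON manifests (protocol, condition, magnitudes,
    onset) plus the trajectory tables, one pair per trial."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, tr in enumerate(trials):
        base = directory / f"{prefix}_{i:03d}"
        man = {
            "protocol": tr.spec.protocol,
            "condition": tr.condition,
            "onset": tr.onset,
            "spec": tr.spec.manifest(),
            "trajectory": str(base) + ".tsv",
        }
        with open(str(base) + ".json", "w") as fh:
            json.dump(man, fh, indent=1)
        tr.disturbed.save_table(str(base) + ".tsv")
        paths.append(str(base) + ".json")
    return paths


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
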