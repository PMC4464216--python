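"""Reading and writing decay tables and fit reports.

Decay tables are CSV/TSV files with header columns
``condition,time_min,value,replicate``.  Values may be given as percent of
the initial amount (auto-detected when the maximum exceeds 2) and are
normalized per replicate on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .dataset import DecayDataset
from .fitting import FitResult

REQUIRED_COLUMNS = ("condition", "time_min", "value", "replicate")


class DecayTableError(ValueError):
    """Malformed decay table (missing column, bad value, duplicate row)."""


def read_decay_table(path: str | Path, *, normalize: bool = True) -> dict[str, DecayDataset]:
    """Parse a decay table into one DecayDataset per condition.

    Percent-scale values (max > 2) are divided by 100, then each replicate is
    scaled to 1 at its earliest time.  Errors carry 1-based data line numbers.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DecayTableError(f"{path.name}: missing required columns {missing}")
    df = df.loc[:, list(REQUIRED_COLUMNS)]
    bad = df.index[(df["value"] <= 0) | df["value"].isna()]
    if len(bad):
        raise DecayTableError(f"{path.name}: non-positive value at line {bad[0] + 2}")
    bad = df.index[df["time_min"] < 0]
    if len(bad):
        raise DecayTableError(f"{path.name}: negative time at line {bad[0] + 2}")
    dup = df.duplicated(["condition", "replicate", "time_min"])
    if dup.any():
        raise DecayTableError(
            f"{path.name}: duplicate (condition, replicate, time) at line {df.index[dup][0] + 2}"
        )
    out: dict[str, DecayDataset] = {}
    for cond, grp in df.groupby("condition", sort=False):
        grp = grp.drop(columns="condition")
        if grp["value"].max() > 2:  # percent scale
            grp = grp.assign(value=grp["value"] / 100.0)
        ds = DecayDataset(str(cond), grp)
        out[str(cond)] = ds.normalize() if normalize else ds
    return out


def write_decay_table(datasets: dict[str, DecayDataset], path: str | Path) -> Path:
    """Write datasets to a single CSV/TSV (12 significant digits, lossless round trip)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frames = []
    for cond, ds in datasets.items():
        frames.append(ds.observations.assign(condition=cond))
    table = pd.concat(frames, ignore_index=True).loc[:, list(REQUIRED_COLUMNS)]
    table.to_csv(path, sep=sep, index=False, float_format="%.12g")
    return path


def fit_report_dict(fit: FitResult) -> dict:
    """JSON-serializable summary of a fit."""
    return {
        "condition": fit.condition,
        "network": fit.network.name,
        "free_rates": list(fit.free),
        "estimates": fit.estimates,
        "fixed_rates": fit.fixed,
        "ci_95": {s: list(v) for s, v in (fit.ci or {}).items()},
        "ci_method": fit.ci_method,
        "rss": fit.rss,
        "n_obs": fit.n,
        "n_free": fit.k,
        "aic": fit.aic,
        "converged": fit.converged,
        "at_boundary": fit.at_boundary,
        "unidentifiable": fit.unidentifiable,
    }


def write_fit_reports(fits: dict[str, FitResult], directory: str | Path) -> list[Path]:
    """One JSON per condition plus a human-readable summary text file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for cond, fit in fits.items():
        p = directory / f"fit_{cond}.json"
        p.write_text(json.dumps(fit_report_dict(fit), indent=2) + "\n")
        paths.append(p)
    summary = directory / "fits_summary.txt"
    summary.write_text("\n\n".join(fits[c].summary() for c in fits) + "\n")
    paths.append(summary)
    return paths
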