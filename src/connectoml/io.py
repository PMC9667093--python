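"""Plain-text serialization of cohorts, graphs and results.

Everything is written as delimited text (TSV/CSV/JSON) with fixed float
formatting, so a run repeated with the same seed produces byte-identical
files — the reproducibility contract downstream analyses rely on.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasSpec
from .simulate import SyntheticCohort

_FLOAT_FMT = "%.6f"


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write a cohort as one time-series TSV per subject plus tables.

    Layout: ``sub-XXX.tsv`` (timepoints x nodes, tab-separated),
    ``manifest.csv`` (subject, file, group), ``covariates.csv``,
    ``truth.json`` (planted-effect record) and ``atlas.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, subject in enumerate(cohort.covariates["subject"]):
        fname = f"{subject}.tsv"
        np.savetxt(outdir / fname, cohort.timeseries[i].T, fmt=_FLOAT_FMT,
                   delimiter="\t")
        manifest.append(
            {"subject": subject, "file": fname,
             "group": int(cohort.covariates["group"].iloc[i])}
        )
    pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False)
    cohort.covariates.to_csv(outdir / "covariates.csv", index=False,
                             float_format=_FLOAT_FMT)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    cohort.atlas.to_frame().to_csv(outdir / "atlas.csv", index=False)
    with open(outdir / "seed.json", "w") as fh:
        json.dump({"seed": cohort.seed}, fh)
    return outdir


def read_timeseries(manifest_path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Load subject time series listed in a manifest.

    Returns (subjects x nodes x timepoints array, manifest frame).
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    series = []
    for fname in manifest["file"]:
        ts = np.loadtxt(manifest_path.parent / fname, delimiter="\t")
        series.append(ts.T)  # stored timepoints x nodes
    return np.stack(series), manifest


def read_atlas(path: str | Path) -> AtlasSpec:
    """Rebuild an AtlasSpec from an atlas.csv table."""
    df = pd.read_csv(path)
    names = list(dict.fromkeys(df["subnetwork"]))
    return AtlasSpec(
        n_nodes=len(df),
        subnetwork_of=tuple(names.index(s) + 1 for s in df["subnetwork"]),
        subnetwork_names=tuple(names),
        labels=tuple(df["label"]),
    )


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Symmetric matrix (connectivity or adjacency) as TSV."""
    np.savetxt(path, matrix, fmt=_FLOAT_FMT, delimiter="\t")


def write_loop_results(results, path: str | Path) -> None:
    """One JSON record per outer loop (JSON-lines)."""
    with open(path, "w") as fh:
        for r in results:
            fh.write(json.dumps({
                "loop": r.loop, "split_seed": r.split_seed,
                "selected": r.selected, "weights": r.weights,
                "models": r.models,
            }, sort_keys=True) + "\n")
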