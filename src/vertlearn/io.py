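"""Result writers: tidy CSV tables and JSON run manifests.

Every output directory receives a ``manifest.json`` recording the fully
resolved parameters, the base seed and the package version, which together
suffice to reproduce the run byte for byte.
"""

from __future__ import annotations

import json
import os
from typing import Any, Sequence

import pandas as pd

from . import __version__
from .config import SimParams
from .observables import RunSummary, aggregate_summaries, summaries_to_frame

__all__ = ["write_results", "write_manifest", "write_run_outputs"]


def write_results(df: pd.DataFrame, path: str) -> str:
    """Write a table as CSV (parent directories created as needed)."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_manifest(params: SimParams, path: str,
                   extra: dict[str, Any] | None = None) -> str:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    payload = {
        "version": __version__,
        "params": params.to_dict(),
        "seed": params.seed,
    }
    if extra:
        payload.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def write_run_outputs(summaries: Sequence[RunSummary], params: SimParams,
                      out_dir: str, *,
                      extra_manifest: dict[str, Any] | None = None) -> dict[str, str]:
    """Write per-replicate results, a one-row aggregate, and the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "results": write_results(summaries_to_frame(summaries),
                                 os.path.join(out_dir, "results.csv")),
        "aggregate": write_results(aggregate_summaries(summaries),
                                   os.path.join(out_dir, "aggregate.csv")),
        "manifest": write_manifest(params, os.path.join(out_dir,
                                                        "manifest.json"),
                                   extra_manifest),
    }
    return paths
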