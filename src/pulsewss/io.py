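"""CSV / JSON export of profiles, shear series, flow series and summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import HemoSummary, MethodComparison
from .womersley import ProfileSeries, ShearSeries

__all__ = [
    "profile_to_csv",
    "profile_to_long_csv",
    "shear_to_csv",
    "flow_to_csv",
    "summary_to_json",
]


def profile_to_csv(p: ProfileSeries, path: str | Path) -> None:
    """Matrix layout: first row the r-grid (m), first column the t-grid (s)."""
    header = np.concatenate([[np.nan], p.r_grid])
    body = np.column_stack([p.t_grid, p.U.T])
    out = np.vstack([header, body])
    df = pd.DataFrame(out)
    df.iloc[0, 0] = None
    df.to_csv(path, index=False, header=False, float_format="%.10g")


def profile_to_long_csv(p: ProfileSeries, path: str | Path) -> None:
    """Long form: one row per (t, r, U) triple."""
    t, r = np.meshgrid(p.t_grid, p.r_grid, indexing="ij")
    pd.DataFrame(
        {"t": t.ravel(), "r": r.ravel(), "U": p.U.T.ravel()}
    ).to_csv(path, index=False, float_format="%.10g")


def shear_to_csv(s: ShearSeries, path: str | Path) -> None:
    pd.DataFrame({"t": s.t_grid, "tau_w": s.tau_w}).to_csv(
        path, index=False, float_format="%.10g"
    )


def flow_to_csv(t_grid: np.ndarray, q: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"t": t_grid, "Q": q}).to_csv(
        path, index=False, float_format="%.10g"
    )


def summary_to_json(
    path: str | Path,
    summaries: dict[str, HemoSummary],
    comparison: MethodComparison | None = None,
    provenance: dict | None = None,
) -> None:
    """Per-method summaries plus optional method comparison and provenance."""
    doc: dict = {name: s.to_dict() for name, s in summaries.items()}
    if comparison is not None:
        doc["comparison"] = comparison.to_dict()
    if provenance is not None:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
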