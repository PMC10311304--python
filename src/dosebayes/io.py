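"""CSV readers/writers for dose-response data.

Two dialects:

* ``long`` - header ``dose1,dose2,response`` (the ``dose2`` column may be
  absent for monotherapy vectors), one measurement per row.
* ``wide`` - matrix layout: the first row holds the drug-1 doses, the first
  column the drug-2 doses, the body holds responses; the (0, 0) body cell at
  dose zero/zero is the base value and must appear exactly once.

Real-data ingestion rejects negative responses (screens containing them are
filtered out); synthetic data written by this package may legitimately
contain small negative values from the Gaussian noise, so the writers do not
enforce the rule.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import DoseResponseDataset

__all__ = ["LoadError", "read_matrix", "write_matrix"]


class LoadError(ValueError):
    """Malformed or rule-violating dose-response file."""


def _check_negative(responses: np.ndarray, where: list[str]) -> None:
    bad = np.flatnonzero(responses < 0)
    if bad.size:
        locs = ", ".join(where[i] for i in bad[:5])
        raise LoadError(
            f"negative responses are not accepted from data files ({locs}); "
            "screens with negative measurements are removed before modelling"
        )


def _read_long(path: Path, allow_negative: bool) -> DoseResponseDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "response" not in cols or "dose1" not in cols:
        raise LoadError(
            f"{path}: long format requires columns dose1[,dose2],response; got {cols}"
        )
    dose_cols = ["dose1", "dose2"] if "dose2" in cols else ["dose1"]
    doses = df[dose_cols].to_numpy(dtype=float)
    responses = df["response"].to_numpy(dtype=float)
    if not allow_negative:
        _check_negative(responses, [f"row {i + 2}" for i in range(len(df))])
    try:
        return DoseResponseDataset(doses, responses)
    except ValueError as exc:
        raise LoadError(f"{path}: {exc}") from exc


def _read_wide(path: Path, allow_negative: bool) -> DoseResponseDataset:
    # header=None keeps duplicate dose labels visible (pandas would mangle them)
    raw = pd.read_csv(path, header=None, dtype=str, float_precision="round_trip")
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise LoadError(f"{path}: wide format needs dose labels plus a response body")
    try:
        d1 = np.asarray([float(c) for c in raw.iloc[0, 1:]])
        d2 = np.asarray([float(r) for r in raw.iloc[1:, 0]])
        body = raw.iloc[1:, 1:].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise LoadError(f"{path}: wide format requires numeric dose labels") from exc
    if np.sum(d1 == 0) != 1 or np.sum(d2 == 0) != 1:
        raise LoadError(
            f"{path}: wide format requires exactly one zero dose per axis "
            "(the base cell must be present exactly once)"
        )
    doses, responses, where = [], [], []
    for i, x2 in enumerate(d2):
        for j, x1 in enumerate(d1):
            doses.append((x1, x2))
            responses.append(body[i, j])
            where.append(f"cell ({x1:g}, {x2:g})")
    responses = np.asarray(responses)
    if not allow_negative:
        _check_negative(responses, where)
    try:
        return DoseResponseDataset(np.asarray(doses), responses)
    except ValueError as exc:
        raise LoadError(f"{path}: {exc}") from exc


def read_matrix(
    path, dialect: str = "long", allow_negative: bool = False
) -> DoseResponseDataset:
    """Load a dose-response CSV in the given dialect ('long' or 'wide')."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    if dialect == "long":
        return _read_long(path, allow_negative)
    if dialect == "wide":
        return _read_wide(path, allow_negative)
    raise LoadError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")


def write_matrix(data: DoseResponseDataset, path, dialect: str = "long") -> None:
    """Write a dataset as CSV; round-trips exactly through :func:`read_matrix`."""
    path = Path(path)
    if dialect == "long":
        cols = {"dose1": data.doses[:, 0]}
        if data.is_combo:
            cols["dose2"] = data.doses[:, 1]
        cols["response"] = data.responses
        # %.17g round-trips IEEE doubles exactly
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
        return
    if dialect != "wide":
        raise ValueError(f"unknown dialect {dialect!r}")
    if not data.is_combo:
        raise ValueError("wide format is defined for combination matrices")
    d1 = np.unique(data.doses[:, 0])
    d2 = np.unique(data.doses[:, 1])
    body = np.full((len(d2), len(d1)), np.nan)
    for (x1, x2), y in zip(data.doses, data.responses):
        body[np.searchsorted(d2, x2), np.searchsorted(d1, x1)] = y
    if np.any(np.isnan(body)):
        raise ValueError("dataset is not a complete grid; use the long dialect")
    frame = pd.DataFrame(body, index=d2, columns=d1)
    frame.to_csv(path, index_label="dose2\\dose1", float_format="%.17g")
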