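"""File formats: scales (JSON/YAML), vectors/matrices/counts/pairs (CSV/TSV).

Conventions: aggregated counts are the canonical exchange format; probability
vectors are accepted with a tolerance-checked sum.  Unbounded upper limits are
spelled ``inf`` in scale files.  Writers round probabilities to 5 decimals by
default (the reporting convention) with a full-precision option.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .containers import (
    CountVector,
    PairedResponses,
    ProbVector,
    TransitionMatrix,
)
from .scales import Interval, IntervalScale
from .solver import SolverConfig

__all__ = [
    "ParseError",
    "read_scale",
    "write_scale",
    "read_counts",
    "read_pairs",
    "write_counts",
    "write_pairs",
    "read_vector",
    "write_vector",
    "read_matrix",
    "write_matrix",
    "load_solver_config",
]


class ParseError(ValueError):
    """A malformed input file; the message names the file and offending line."""


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


# -- scales -----------------------------------------------------------------


def _scale_to_dict(scale: IntervalScale) -> dict:
    options = []
    for i, iv in enumerate(scale.intervals):
        opt = {"lb": iv.lb, "ub": "inf" if math.isinf(iv.ub) else iv.ub}
        if scale.labels is not None:
            opt["label"] = scale.labels[i]
        options.append(opt)
    return {"version_id": scale.version_id, "options": options}


def _scale_from_dict(data: Mapping, source: str) -> IntervalScale:
    try:
        options = data["options"]
        intervals = []
        for opt in options:
            ub = opt["ub"]
            ub = math.inf if (isinstance(ub, str) and ub.lower() == "inf") else float(ub)
            intervals.append(Interval(float(opt["lb"]), ub))
        labels = tuple(o["label"] for o in options) if all("label" in o for o in options) else None
        return IntervalScale(str(data["version_id"]), tuple(intervals), labels)
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{source}: invalid scale specification: {exc}") from exc


def read_scale(path: str | Path) -> IntervalScale:
    """Read a scale from JSON or YAML (by extension)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return _scale_from_dict(data, str(path))


def write_scale(path: str | Path, scale: IntervalScale) -> None:
    path = Path(path)
    data = _scale_to_dict(scale)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# -- counts and pairs -------------------------------------------------------


def read_counts(
    path: str | Path, scale: IntervalScale
) -> CountVector | dict[str, CountVector]:
    """Read aggregated counts: header ``option,count`` plus optional ``time``.

    With a ``time`` column, returns a mapping from time label to CountVector.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    required = {"option", "count"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            opt, cnt = int(row["option"]), float(row["count"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{line}: non-numeric option/count") from exc
        if cnt < 0:
            raise ParseError(f"{path}:{line}: negative count {cnt}")
        if not 1 <= opt <= scale.d:
            raise ParseError(f"{path}:{line}: option {opt} outside 1..{scale.d}")

    def build(sub: pd.DataFrame) -> CountVector:
        counts = np.zeros(scale.d)
        np.add.at(counts, sub["option"].to_numpy(dtype=int) - 1, sub["count"].to_numpy(dtype=float))
        return CountVector(scale, counts)

    if "time" in df.columns:
        return {str(t): build(sub) for t, sub in df.groupby("time", sort=True)}
    return build(df)


def read_pairs(
    path: str | Path,
    scale1: IntervalScale,
    scale2: IntervalScale,
    t1: str = "t1",
    t2: str = "t2",
) -> PairedResponses:
    """Read individual-level cohort pairs: header ``id,t1_option,t2_option``."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    required = {"id", "t1_option", "t2_option"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            o1, o2 = int(row["t1_option"]), int(row["t2_option"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{line}: non-integer option index") from exc
        if not 1 <= o1 <= scale1.d:
            raise ParseError(f"{path}:{line}: t1 option {o1} outside 1..{scale1.d}")
        if not 1 <= o2 <= scale2.d:
            raise ParseError(f"{path}:{line}: t2 option {o2} outside 1..{scale2.d}")
    try:
        return PairedResponses(
            scale1=scale1,
            scale2=scale2,
            ids=df["id"].to_numpy(),
            options_t1=df["t1_option"].to_numpy(dtype=int),
            options_t2=df["t2_option"].to_numpy(dtype=int),
            t1=t1,
            t2=t2,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_counts(path: str | Path, counts: CountVector, time: str | None = None) -> None:
    """Write aggregated counts as ``option,count`` rows (plus ``time`` if given)."""
    df = pd.DataFrame(
        {"option": np.arange(1, counts.scale.d + 1), "count": counts.counts}
    )
    if time is not None:
        df.insert(0, "time", time)
    df.to_csv(path, index=False)


def write_pairs(path: str | Path, pairs: PairedResponses) -> None:
    """Write cohort pairs as ``id,t1_option,t2_option`` rows."""
    pd.DataFrame(
        {"id": pairs.ids, "t1_option": pairs.options_t1, "t2_option": pairs.options_t2}
    ).to_csv(path, index=False)


# -- vectors and matrices ---------------------------------------------------


def read_vector(path: str | Path, scale: IntervalScale, atol: float = 1e-4) -> ProbVector:
    """Read a probability vector: single ``prob`` column, one option per line."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    if "prob" not in df.columns:
        raise ParseError(f"{path}: expected a 'prob' column, got {list(df.columns)}")
    try:
        return ProbVector(scale, df["prob"].to_numpy(dtype=float), atol=atol)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_vector(
    path: str | Path, p: ProbVector, decimals: int | None = 5
) -> None:
    """Write a probability vector; ``decimals=None`` keeps full precision."""
    values = p.probs if decimals is None else p.rounded(decimals)
    pd.DataFrame({"prob": values}).to_csv(path, index=False)


def read_matrix(
    path: str | Path,
    from_scale: IntervalScale,
    to_scale: IntervalScale,
    atol: float = 1e-4,
) -> TransitionMatrix:
    """Read a transition matrix from a rectangular headerless CSV."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), header=None)
    try:
        return TransitionMatrix(from_scale, to_scale, df.to_numpy(dtype=float), atol=atol)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_matrix(
    path: str | Path, m: TransitionMatrix, decimals: int | None = 5
) -> None:
    values = m.entries if decimals is None else np.round(m.entries, decimals)
    pd.DataFrame(values).to_csv(path, index=False, header=False)


# -- solver configuration ---------------------------------------------------

_SOLVER_KEYS = {
    "theta",
    "slack_target",
    "max_alternations",
    "objective_rtol",
    "escalation_factor",
    "max_escalations",
    "n_starts",
    "init_perturbation",
    "seed",
}


def load_solver_config(path: str | Path) -> SolverConfig:
    """Read a solver configuration from YAML; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: solver config must be a mapping")
    unknown = set(data) - _SOLVER_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown solver-config keys {sorted(unknown)}")
    if "theta" in data:
        data["theta"] = tuple(float(t) for t in data["theta"])
    try:
        return SolverConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
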