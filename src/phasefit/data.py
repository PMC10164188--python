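"""Domain containers, CSV I/O and preprocessing for daily training data.

The package works on two kinds of input:

* a long-format training table (one row per subject per session, the score
  being the highest level reached that day), turned into one
  :class:`PerformanceSeries` per subject;
* a wide transfer-test panel (:class:`TransferPanel`): four tasks — the
  trained task ``Grid`` and the transfer tasks ``OOO`` (Odd One Out), ``FI``
  (Following Instructions) and ``Math`` — each measured at five test
  sessions T1..T5.

Preprocessing follows the cohort pipeline: drop subjects who missed six or
more transfer tests (two full test sessions), impute remaining gaps from the
k nearest neighbours, then standardize every task to its T1 mean and sd.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TASKS = ("Grid", "OOO", "FI", "Math")
TRANSFER_TASKS = ("OOO", "FI", "Math")
SESSIONS = (1, 2, 3, 4, 5)

TRAINING_COLUMNS = ("subject_id", "session", "level")
TRANSFER_COLUMNS = ("subject_id", "task", "session", "score")


class TrainingCSVError(ValueError):
    """Raised when a training CSV violates the expected dialect."""


class TransferCSVError(ValueError):
    """Raised when a transfer CSV violates the expected dialect."""


@dataclasses.dataclass(frozen=True)
class PerformanceSeries:
    """One subject's observed daily training levels over indexed sessions.

    ``times`` are session indices in day units (1-based, strictly
    increasing); ``levels`` is the performance score per session.
    """

    subject_id: str
    times: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        levels = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "levels", levels)
        if times.ndim != 1 or levels.ndim != 1 or times.shape != levels.shape:
            raise ValueError("times and levels must be 1-D arrays of equal length")
        if len(times) < 2:
            raise ValueError(f"subject {self.subject_id!r}: need at least 2 observations")
        if not np.all(np.diff(times) > 0):
            raise ValueError(f"subject {self.subject_id!r}: times must be strictly increasing")
        if not np.all(np.isfinite(levels)) or not np.all(levels > 0):
            raise ValueError(f"subject {self.subject_id!r}: levels must be finite and > 0")

    def __len__(self) -> int:
        return len(self.times)

    def scaled(self, c: float) -> "PerformanceSeries":
        """Return a copy with all levels multiplied by ``c`` (> 0)."""
        return PerformanceSeries(self.subject_id, self.times, self.levels * float(c))


def read_training_csv(path: str | Path) -> list[PerformanceSeries]:
    """Read a long-format training CSV into one series per subject.

    Expected header: ``subject_id,session,level``; lines starting with ``#``
    (artifact metadata) are ignored.  Duplicate (subject, session) rows and
    non-numeric values are reported as :class:`TrainingCSVError` naming the
    offending subject/row.
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in TRAINING_COLUMNS if c not in df.columns]
    if missing:
        raise TrainingCSVError(f"{path}: missing required columns {missing}")
    if df.empty:
        return []
    sessions = pd.to_numeric(df["session"], errors="coerce")
    levels = pd.to_numeric(df["level"], errors="coerce")
    for name, col in (("session", sessions), ("level", levels)):
        bad = col.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrainingCSVError(
                f"{path}: non-numeric {name} {df[name].iloc[row]!r} for subject "
                f"{df['subject_id'].iloc[row]!r} (data row {row + 1})"
            )
    df = df.assign(session=sessions.astype(float), level=levels.astype(float))
    dup = df.duplicated(subset=["subject_id", "session"], keep=False)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise TrainingCSVError(
            f"{path}: duplicate session {df['session'].iloc[row]:g} for subject "
            f"{df['subject_id'].iloc[row]!r}"
        )
    out: list[PerformanceSeries] = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("session")
        out.append(
            PerformanceSeries(str(sid), grp["session"].to_numpy(), grp["level"].to_numpy())
        )
    return out


def write_training_csv(
    path: str | Path,
    series: Iterable[PerformanceSeries],
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write series to the long CSV dialect, with ``#``-prefixed metadata lines."""
    rows = [
        {"subject_id": s.subject_id, "session": t, "level": y}
        for s in series
        for t, y in zip(s.times, s.levels)
    ]
    df = pd.DataFrame(rows, columns=list(TRAINING_COLUMNS))
    _write_csv_with_metadata(path, df, metadata)


def _write_csv_with_metadata(
    path: str | Path, df: pd.DataFrame, metadata: Mapping[str, object] | None
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


@dataclasses.dataclass(frozen=True)
class TransferPanel:
    """Subjects x (task, session) transfer-test score matrix.

    ``scores`` has the subject id as index and a (task, session) MultiIndex
    over the columns, exactly five sessions per task.  Missing entries are
    NaN — never silently zero.
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        cols = self.scores.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 2:
            raise ValueError("scores needs (task, session) MultiIndex columns")
        tasks = list(dict.fromkeys(cols.get_level_values(0)))
        unknown = [t for t in tasks if t not in TASKS]
        if unknown:
            raise ValueError(f"unknown tasks {unknown}; expected subset of {TASKS}")
        for task in tasks:
            got = sorted(int(s) for s in cols[cols.get_level_values(0) == task].get_level_values(1))
            if got != list(SESSIONS):
                raise ValueError(f"task {task!r} must have exactly sessions {SESSIONS}, got {got}")
        # canonical column order and index name
        ordered = pd.MultiIndex.from_tuples(
            [(t, s) for t in TASKS if t in tasks for s in SESSIONS],
            names=["task", "session"],
        )
        scores = self.scores.reindex(columns=ordered).astype(float)
        scores.index = scores.index.astype(str).rename("subject_id")
        object.__setattr__(self, "scores", scores)

    @property
    def subjects(self) -> list[str]:
        return list(self.scores.index)

    @property
    def tasks(self) -> list[str]:
        return list(dict.fromkeys(self.scores.columns.get_level_values(0)))

    @property
    def n_subjects(self) -> int:
        return len(self.scores)

    def missing_mask(self) -> pd.DataFrame:
        return self.scores.isna()

    def n_missing(self, tasks: Sequence[str] | None = None) -> pd.Series:
        """Missing-cell count per subject over ``tasks`` (default: transfer tasks)."""
        tasks = list(tasks) if tasks is not None else self._counting_tasks()
        cols = [c for c in self.scores.columns if c[0] in tasks]
        return self.scores[cols].isna().sum(axis=1)

    def _counting_tasks(self) -> list[str]:
        present = [t for t in TRANSFER_TASKS if t in self.tasks]
        return present if present else self.tasks

    def to_long(self) -> pd.DataFrame:
        long = self.scores.stack(["task", "session"], future_stack=True).rename("score")
        long = long.reset_index().rename(columns={"level_0": "subject_id"})
        return long[list(TRANSFER_COLUMNS)]

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "TransferPanel":
        missing = [c for c in TRANSFER_COLUMNS if c not in df.columns]
        if missing:
            raise TransferCSVError(f"missing required columns {missing}")
        dup = df.duplicated(subset=["subject_id", "task", "session"], keep=False)
        if dup.any():
            row = df[dup].iloc[0]
            raise TransferCSVError(
                f"duplicate cell for subject {row['subject_id']!r}, "
                f"task {row['task']!r}, session {row['session']}"
            )
        wide = df.pivot(index="subject_id", columns=["task", "session"], values="score")
        tasks = list(dict.fromkeys(df["task"]))
        full = pd.MultiIndex.from_tuples(
            [(t, s) for t in TASKS if t in tasks for s in SESSIONS],
            names=["task", "session"],
        )
        wide = wide.reindex(columns=full)
        wide.columns.names = ["task", "session"]
        return cls(wide)


def read_transfer_csv(path: str | Path) -> TransferPanel:
    """Read a long transfer CSV (empty score field = missing) into a panel."""
    df = pd.read_csv(path, comment="#", dtype={"subject_id": str, "task": str})
    if "session" in df.columns:
        df["session"] = pd.to_numeric(df["session"], errors="raise").astype(int)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="raise")
    return TransferPanel.from_long(df)


def write_transfer_csv(
    path: str | Path, panel: TransferPanel, metadata: Mapping[str, object] | None = None
) -> None:
    _write_csv_with_metadata(path, panel.to_long(), metadata)


def exclude_incomplete(panel: TransferPanel, max_missing: int = 6) -> TransferPanel:
    """Drop subjects with ``max_missing`` or more missing transfer cells.

    The count runs over the transfer tasks only (3 tasks x 5 sessions = 15
    cells; six missing corresponds to two full test sessions).  A subject is
    retained iff its missing count is strictly below ``max_missing``.
    """
    counts = panel.n_missing()
    keep = counts < max_missing
    return TransferPanel(panel.scores.loc[keep])


def knn_impute(panel: TransferPanel, k: int = 35) -> TransferPanel:
    """Fill each missing cell with the mean of the k nearest subjects' values.

    Distance between two subjects is the Euclidean distance over the cells
    observed in both, divided by the number of co-observed cells; only
    subjects with the target cell observed are candidate neighbours, and
    ties are broken by lower subject position.  Observed cells are never
    modified.
    """
    X = panel.scores.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    n = X.shape[0]
    if not obs.any(axis=1).all():
        bad = panel.scores.index[~obs.any(axis=1)][0]
        raise ValueError(f"subject {bad!r} has no observed cells; cannot impute")
    out = X.copy()
    Xz = np.where(obs, X, 0.0)
    for i in np.flatnonzero(~obs.all(axis=1)):
        diff = Xz - Xz[i]
        co = obs & obs[i]
        n_co = co.sum(axis=1)
        sq = np.where(co, diff**2, 0.0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            dist = np.sqrt(sq) / n_co
        dist[n_co == 0] = np.inf
        dist[i] = np.inf
        for j in np.flatnonzero(~obs[i]):
            cand = dist.copy()
            cand[~obs[:, j]] = np.inf
            n_cand = int(np.isfinite(cand).sum())
            if n_cand < k:
                cell = panel.scores.columns[j]
                raise ValueError(
                    f"only {n_cand} candidate neighbours for subject "
                    f"{panel.scores.index[i]!r}, cell {cell}; need k={k}"
                )
            # stable argsort => ties broken by lower subject position
            nearest = np.argsort(cand, kind="stable")[:k]
            out[i, j] = X[nearest, j].mean()
    return TransferPanel(pd.DataFrame(out, index=panel.scores.index, columns=panel.scores.columns))


def standardize_to_T1(panel: TransferPanel) -> TransferPanel:
    """Standardize every session of each task to that task's T1 mean and sd.

    Uses the sample sd (ddof=1).  The transform is affine per task, so
    applying it a second time is the identity (the standardized T1 column
    already has mean 0 and sd 1).
    """
    scores = panel.scores.copy()
    for task in panel.tasks:
        t1 = scores[(task, 1)]
        mean = t1.mean()
        sd = t1.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"task {task!r}: zero variance at T1; cannot standardize")
        for s in SESSIONS:
            scores[(task, s)] = (scores[(task, s)] - mean) / sd
    return TransferPanel(scores)
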