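"""Long-format trajectory dataset: per-individual irregular (time, score) series.

The on-disk format is a plain CSV with columns ``individual_id``,
``time_days`` (real days since baseline, 0 at the first observation) and
``sidas_total`` (integer 0..50).  Individuals need at least two completed
observations to be modelled; :func:`read_dataset` applies that inclusion
rule and validates every row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("individual_id", "time_days", "sidas_total")

# same-day repeat entries are nudged apart by this many days to keep
# strictly increasing times within an individual
_TIE_OFFSET = 1e-3


@dataclass
class TrajectoryDataset:
    """Validated per-individual sequences of (time, score) observations."""

    frame: pd.DataFrame
    score_max: int = 50
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        df = df.sort_values(["individual_id", "time_days"], kind="mergesort").reset_index(drop=True)
        self.frame = df
        self._index = {
            ind: (grp["time_days"].to_numpy(float), grp["sidas_total"].to_numpy(np.int64))
            for ind, grp in df.groupby("individual_id", sort=True)
        }

    @property
    def individuals(self) -> list:
        return list(self._index)

    @property
    def n_individuals(self) -> int:
        return len(self._index)

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def observations(self, individual_id) -> tuple[np.ndarray, np.ndarray]:
        """(times, scores) for one individual, sorted by time."""
        try:
            return self._index[individual_id]
        except KeyError:
            raise KeyError(f"unknown individual {individual_id!r}")

    def n_obs_of(self, individual_id) -> int:
        return self._index[individual_id][0].size

    def filter_min_obs(self, min_obs: int) -> "TrajectoryDataset":
        """Keep only individuals with at least ``min_obs`` observations."""
        keep = [i for i, (t, _) in self._index.items() if t.size >= min_obs]
        sub = self.frame[self.frame["individual_id"].isin(keep)].copy()
        return TrajectoryDataset(sub, self.score_max)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _validate_rows(df: pd.DataFrame, score_max: int) -> None:
    scores = df["sidas_total"]
    numeric = pd.to_numeric(scores, errors="coerce")
    bad = df.index[numeric.isna() | (numeric != numeric.round())]
    if len(bad):
        raise ValueError(f"non-integer sidas_total at rows {list(bad[:5])}")
    out_of_range = df.index[(numeric < 0) | (numeric > score_max)]
    if len(out_of_range):
        raise ValueError(
            f"sidas_total outside 0..{score_max} at rows {list(out_of_range[:5])}"
        )
    times = pd.to_numeric(df["time_days"], errors="coerce")
    bad_t = df.index[times.isna() | (times < 0)]
    if len(bad_t):
        raise ValueError(f"negative or non-numeric time_days at rows {list(bad_t[:5])}")


def from_frame(df: pd.DataFrame, min_obs: int = 2, score_max: int = 50) -> TrajectoryDataset:
    """Validate a long-format frame and apply the inclusion rule.

    Duplicate (individual, time) rows keep the last entry (interpreted as a
    corrected re-entry); repeated same-day times are offset by 1e-3 days to
    preserve strict ordering.  Individuals with fewer than ``min_obs``
    observations are dropped with a logged count.
    """
    df = df.reset_index(drop=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    _validate_rows(df, score_max)
    df = df.copy()
    df["time_days"] = pd.to_numeric(df["time_days"])
    df["sidas_total"] = pd.to_numeric(df["sidas_total"]).astype(np.int64)

    n_dup = df.duplicated(["individual_id", "time_days"]).sum()
    if n_dup:
        logger.warning("dropping %d duplicate (individual, time) rows, keeping last", n_dup)
        df = df.drop_duplicates(["individual_id", "time_days"], keep="last")

    df = df.sort_values(["individual_id", "time_days"], kind="mergesort").reset_index(drop=True)
    # strictify any residual ties within individual (distinct rows, same day)
    for _, idx in df.groupby("individual_id").groups.items():
        t = df.loc[idx, "time_days"].to_numpy(float)
        for i in range(1, t.size):
            if t[i] <= t[i - 1]:
                t[i] = t[i - 1] + _TIE_OFFSET
        df.loc[idx, "time_days"] = t

    counts = df.groupby("individual_id").size()
    keep = counts.index[counts >= min_obs]
    n_dropped = counts.size - keep.size
    if n_dropped:
        logger.info("dropped %d individuals with fewer than %d observations", n_dropped, min_obs)
    df = df[df["individual_id"].isin(keep)].reset_index(drop=True)
    return TrajectoryDataset(df, score_max)


def read_dataset(path, min_obs: int = 2, score_max: int = 50) -> TrajectoryDataset:
    """Read and validate a long-format observations CSV."""
    df = pd.read_csv(path)
    return from_frame(df, min_obs=min_obs, score_max=score_max)
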