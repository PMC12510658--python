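"""Tidy time-course dataset container.

Measurements are long-format records ``(time_s, species, replicate,
value)`` in molecules per platelet.  Fitting consumes the per-(time,
species) mean view — the experimental protocol reports means of three
experiments — while the replicates support noise-robustness checks.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import OBSERVED_SPECIES

__all__ = ["TimeCourseDataset"]

REQUIRED_COLUMNS = ("time_s", "species", "replicate", "value")


class TimeCourseDataset:
    """Replicate measurements of the six observed species on a time grid."""

    def __init__(self, frame: pd.DataFrame,
                 true_params: Mapping[str, float] | None = None,
                 variant_id: str | None = None):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset missing required columns: {missing}")
        frame = frame.loc[:, list(REQUIRED_COLUMNS)].copy()
        frame["time_s"] = frame["time_s"].astype(float)
        frame["value"] = frame["value"].astype(float)

        unknown = sorted(set(frame["species"]) - set(OBSERVED_SPECIES))
        if unknown:
            raise ValueError(f"unknown species labels: {unknown}")
        absent = sorted(set(OBSERVED_SPECIES) - set(frame["species"]))
        if absent:
            raise ValueError(f"dataset is missing species: {absent}")
        if (frame["value"] < 0).any():
            bad = frame.loc[frame["value"] < 0].iloc[0]
            raise ValueError(
                f"negative abundance for {bad['species']} at t={bad['time_s']}"
            )
        dup = frame.duplicated(subset=["time_s", "species", "replicate"])
        if dup.any():
            bad = frame.loc[dup].iloc[0]
            raise ValueError(
                "duplicate (time, species, replicate) row: "
                f"{bad['species']} t={bad['time_s']} rep={bad['replicate']}"
            )
        self.frame = frame.reset_index(drop=True)
        self.true_params = dict(true_params) if true_params else None
        self.variant_id = variant_id
        self._mean_view: pd.DataFrame | None = None

    @property
    def times(self) -> np.ndarray:
        return np.array(sorted(self.frame["time_s"].unique()))

    @property
    def species(self) -> tuple[str, ...]:
        return OBSERVED_SPECIES

    @property
    def mean_view(self) -> pd.DataFrame:
        """Replicate means: index time_s, one column per observed species."""
        if self._mean_view is None:
            pivot = (
                self.frame.groupby(["time_s", "species"])["value"].mean()
                .unstack("species")
                .loc[:, list(OBSERVED_SPECIES)]
                .sort_index()
            )
            if pivot.isna().any().any():
                cell = pivot.stack(future_stack=True)
                bad = cell[cell.isna()].index[0]
                raise ValueError(f"incomplete grid: no data for {bad}")
            self._mean_view = pivot
        return self._mean_view

    @property
    def n_cells(self) -> int:
        """Number of (time, species) mean cells; 42 on the default grid."""
        return int(self.mean_view.size)

    def mean_matrix(self) -> np.ndarray:
        """Mean view as a (time x species) array in canonical species order."""
        return self.mean_view.to_numpy()

    def to_csv(self, path) -> None:
        """Write tidy CSV (time_s [s], species, replicate, value
        [molecules platelet^-1])."""
        self.frame.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"TimeCourseDataset({len(self.times)} timepoints x "
                f"{len(self.species)} species, "
                f"{self.frame['replicate'].nunique()} replicates)")
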