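"""Longitudinal panel container shared by every analysis module.

A :class:`PanelDataset` holds a dense ``(subject, wave, variable)`` array of
severity scores together with an observation mask.  Waves are integer age
labels (the study design is annual assessment), not calendar dates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PanelDataset", "ScaleDefinition"]

DEFAULT_COMPOSITES = ("GAD", "MDD", "ADHD", "CDASPD", "ODD", "SUB")
INTERNALIZING = ("GAD", "MDD")
EXTERNALIZING = ("ADHD", "CDASPD", "ODD", "SUB")
NETWORK_NODES = ("ADHD", "CDASPD", "ODD", "GAD", "MDD", "FAU", "FMU", "FTU")


@dataclass
class PanelDataset:
    """Subjects x waves x variables array of scores with a missingness mask.

    Parameters
    ----------
    subject_ids
        Ordered, unique subject identifiers (length ``n``).
    waves
        Strictly increasing integer age labels (length ``W >= 2``).
    variables
        Ordered measure names (length ``m``).
    values
        Real array of shape ``(n, W, m)``; entries where ``observed_mask``
        is ``False`` are undefined (stored as NaN).
    observed_mask
        Boolean array of the same shape; ``True`` where a score was observed.
    """

    subject_ids: list
    waves: list
    variables: list
    values: np.ndarray
    observed_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.subject_ids = list(self.subject_ids)
        self.waves = [int(w) for w in self.waves]
        self.variables = [str(v) for v in self.variables]
        self.values = np.asarray(self.values, dtype=float)
        if self.observed_mask is None:
            self.observed_mask = np.isfinite(self.values)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        self._validate()

    def _validate(self):
        n, W, m = len(self.subject_ids), len(self.waves), len(self.variables)
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if W < 2:
            raise ValueError("a panel needs at least two waves")
        if any(b <= a for a, b in zip(self.waves, self.waves[1:])):
            raise ValueError("waves must be strictly increasing")
        if self.values.shape != (n, W, m):
            raise ValueError(
                f"values shape {self.values.shape} != {(n, W, m)}")
        if self.observed_mask.shape != self.values.shape:
            raise ValueError("observed_mask shape mismatch")
        if not np.all(np.isfinite(self.values[self.observed_mask])):
            raise ValueError("observed values must be finite")
        # keep unobserved cells at NaN so accidental use is loud
        self.values = np.where(self.observed_mask, self.values, np.nan)

    # -- basic accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_waves(self) -> int:
        return len(self.waves)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def wave_index(self, wave: int) -> int:
        return self.waves.index(int(wave))

    def var_index(self, name: str) -> int:
        return self.variables.index(name)

    def wave_matrix(self, wave: int, variables=None) -> np.ndarray:
        """Cross-section at one wave as an ``(n, m)`` array with NaN holes."""
        w = self.wave_index(wave)
        X = self.values[:, w, :]
        if variables is not None:
            idx = [self.var_index(v) for v in variables]
            X = X[:, idx]
        return X

    def wide_matrix(self, variables=None, waves=None) -> tuple[np.ndarray, list[str]]:
        """Flatten to an ``(n, W*m)`` matrix with ``var@wave`` column names."""
        waves = self.waves if waves is None else [int(w) for w in waves]
        variables = self.variables if variables is None else list(variables)
        cols, mats = [], []
        for w in waves:
            wi = self.wave_index(w)
            for v in variables:
                cols.append(f"{v}@{w}")
                mats.append(self.values[:, wi, self.var_index(v)])
        return np.column_stack(mats), cols

    def to_long(self) -> pd.DataFrame:
        """Long-format frame of observed cells only."""
        n, W, m = self.values.shape
        subj = np.repeat(self.subject_ids, W * m)
        wave = np.tile(np.repeat(self.waves, m), n)
        var = np.tile(self.variables, n * W)
        val = self.values.reshape(-1)
        obs = self.observed_mask.reshape(-1)
        df = pd.DataFrame(
            {"subject": subj, "wave": wave, "variable": var, "value": val})
        return df[obs].reset_index(drop=True)

    def select_variables(self, variables) -> "PanelDataset":
        idx = [self.var_index(v) for v in variables]
        return PanelDataset(self.subject_ids, self.waves, list(variables),
                            self.values[:, :, idx].copy(),
                            self.observed_mask[:, :, idx].copy())

    def copy(self) -> "PanelDataset":
        return PanelDataset(list(self.subject_ids), list(self.waves),
                            list(self.variables), self.values.copy(),
                            self.observed_mask.copy())


@dataclass
class ScaleDefinition:
    """Scoring recipe for one scale: which items, their Likert bounds, rule."""

    scale_name: str
    item_names: list
    response_min: dict
    response_max: dict
    scoring_rule: str = "sum"  # or "mean"

    def __post_init__(self):
        if not self.item_names:
            raise ValueError("item list must be non-empty")
        if self.scoring_rule not in ("sum", "mean"):
            raise ValueError("scoring_rule must be 'sum' or 'mean'")
        if np.isscalar(self.response_min):
            self.response_min = {i: float(self.response_min) for i in self.item_names}
        if np.isscalar(self.response_max):
            self.response_max = {i: float(self.response_max) for i in self.item_names}
        for item in self.item_names:
            lo, hi = self.response_min[item], self.response_max[item]
            if not hi > lo:
                raise ValueError(
                    f"item {item!r}: response_max ({hi}) must exceed "
                    f"response_min ({lo})")

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleDefinition":
        return cls(d["scale_name"], list(d["item_names"]),
                   d["response_min"], d["response_max"],
                   d.get("scoring_rule", "sum"))

    def to_dict(self) -> dict:
        return {"scale_name": self.scale_name,
                "item_names": list(self.item_names),
                "response_min": dict(self.response_min),
                "response_max": dict(self.response_max),
                "scoring_rule": self.scoring_rule}
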