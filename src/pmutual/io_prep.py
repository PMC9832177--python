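"""Panel I/O, proportion-of-maximum rescaling, composite scores, scale omega.

The measures in the target design mix response formats (0-3 symptom Likert
items, 0-7 use-frequency items), so items are put on a common 0-1 metric by
proportion-of-maximum scaling before composites are formed.  Composites are
sum scores except where the source scales differ in length across ages
(conduct/antisocial traits) or pool heterogeneous behaviours (substance-use
frequency), which use means.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PanelDataset, ScaleDefinition

__all__ = ["read_panel", "write_panel", "poms_rescale", "build_composites",
           "scale_omega"]


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_LONG_SCHEMA = {"subject": "subject", "wave": "wave",
                "variable": "variable", "value": "value"}


def read_panel(path, layout: str = "long", schema: dict | None = None) -> PanelDataset:
    """Read a CSV panel in long (canonical) or wide layout.

    Long layout needs columns ``subject, wave, variable, value`` (renamable
    through ``schema``).  Wide layout needs a subject column plus one column
    per ``variable@wave`` pair, e.g. ``GAD@14``.

    Raises on duplicate ``(subject, wave, variable)`` rows and on
    non-numeric value cells; empty cells become missing entries in the mask.
    """
    path = Path(path)
    if layout == "long":
        sch = dict(_LONG_SCHEMA)
        if schema:
            sch.update(schema)
        df = pd.read_csv(path, dtype={sch["subject"]: str},
                         float_precision="round_trip")
        df = df.rename(columns={v: k for k, v in sch.items()})
        return _panel_from_long(df)
    if layout == "wide":
        subject_col = (schema or {}).get("subject", "subject")
        df = pd.read_csv(path, dtype={subject_col: str},
                         float_precision="round_trip")
        long = df.melt(id_vars=[subject_col], var_name="_col", value_name="value")
        parts = long["_col"].str.rsplit("@", n=1, expand=True)
        if parts.shape[1] != 2 or parts[1].isna().any():
            raise ValueError("wide columns must be named 'variable@wave'")
        long["variable"] = parts[0]
        long["wave"] = parts[1]
        long = long.rename(columns={subject_col: "subject"})
        return _panel_from_long(long[["subject", "wave", "variable", "value"]])
    raise ValueError(f"unknown layout {layout!r}")


def _panel_from_long(df: pd.DataFrame) -> PanelDataset:
    df = df.copy()
    df["wave"] = pd.to_numeric(df["wave"], errors="raise").astype(int)
    dup = df.duplicated(subset=["subject", "wave", "variable"])
    if dup.any():
        first = df.loc[dup.idxmax(), ["subject", "wave", "variable"]]
        raise ValueError(
            "duplicate (subject, wave, variable) row: "
            f"({first['subject']}, {first['wave']}, {first['variable']})")
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = vals.isna() & df["value"].notna() & (df["value"].astype(str).str.strip() != "")
    if bad.any():
        raise ValueError(f"non-numeric value cell at input row {int(bad.idxmax())}")
    df["value"] = vals

    subjects = list(pd.unique(df["subject"]))
    waves = sorted(df["wave"].unique())
    variables = list(pd.unique(df["variable"]))
    cube = df.pivot_table(index="subject", columns=["wave", "variable"],
                          values="value", aggfunc="first", dropna=False)
    full_cols = pd.MultiIndex.from_product([waves, variables])
    cube = cube.reindex(index=subjects, columns=full_cols)
    values = cube.to_numpy().reshape(len(subjects), len(waves), len(variables))
    return PanelDataset(subjects, waves, variables, values)


def write_panel(panel: PanelDataset, path, layout: str = "long",
                options: dict | None = None) -> Path:
    """Write a panel as CSV plus a ``.provenance.json`` sidecar."""
    path = Path(path)
    if layout == "long":
        df = panel.to_long()
    elif layout == "wide":
        X, cols = panel.wide_matrix()
        df = pd.DataFrame(X, columns=cols)
        df.insert(0, "subject", panel.subject_ids)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    sidecar = {"file": path.name, "layout": layout, "sha256": digest,
               "n_subjects": panel.n_subjects, "waves": panel.waves,
               "variables": panel.variables, "options": options or {}}
    path.with_suffix(path.suffix + ".provenance.json").write_text(
        json.dumps(sidecar, indent=1))
    return path


# ---------------------------------------------------------------------------
# rescaling and composites
# ---------------------------------------------------------------------------

def poms_rescale(item_values, definition: ScaleDefinition,
                 item: str | None = None) -> np.ndarray:
    """Proportion-of-maximum rescaling: ``(x - min) / (max - min)`` -> [0, 1].

    Missing values (NaN) pass through; values outside the declared response
    bounds raise, since they signal a data-entry problem rather than a
    scaling one.
    """
    x = np.asarray(item_values, dtype=float)
    if item is None:
        if len(set(definition.response_min.values())) > 1 or \
           len(set(definition.response_max.values())) > 1:
            raise ValueError("heterogeneous bounds: pass item= explicitly")
        item = definition.item_names[0]
    lo = definition.response_min[item]
    hi = definition.response_max[item]
    obs = np.isfinite(x)
    if np.any((x[obs] < lo) | (x[obs] > hi)):
        bad = x[obs][(x[obs] < lo) | (x[obs] > hi)][0]
        raise ValueError(
            f"value {bad} outside declared bounds [{lo}, {hi}] for {item!r}")
    return (x - lo) / (hi - lo)


def build_composites(panel: PanelDataset, recipes: list[tuple[ScaleDefinition, str] | ScaleDefinition],
                     max_missing_frac: float = 0.25) -> PanelDataset:
    """Aggregate an item-level panel into composite severity scores.

    Each recipe is a :class:`ScaleDefinition` (its ``scoring_rule`` decides
    sum vs mean).  A composite at a wave is missing when more than
    ``max_missing_frac`` of its items are missing there; otherwise sums are
    taken over the observed items (mean rule averages observed items).
    """
    defs = []
    for r in recipes:
        defs.append(r[0] if isinstance(r, tuple) else r)
        if isinstance(r, tuple):
            defs[-1].scoring_rule = r[1]
    for d in defs:
        for item in d.item_names:
            if item not in panel.variables:
                raise ValueError(
                    f"recipe {d.scale_name!r} references unknown item {item!r}")

    n, W = panel.n_subjects, panel.n_waves
    out = np.full((n, W, len(defs)), np.nan)
    for k, d in enumerate(defs):
        idx = [panel.var_index(i) for i in d.item_names]
        vals = panel.values[:, :, idx]
        obs = panel.observed_mask[:, :, idx]
        n_items = len(idx)
        n_obs = obs.sum(axis=2)
        ok = (n_items - n_obs) <= max_missing_frac * n_items
        ok &= n_obs > 0
        with np.errstate(invalid="ignore"):
            if d.scoring_rule == "sum":
                agg = np.nansum(np.where(obs, vals, 0.0), axis=2)
            else:
                agg = np.nansum(np.where(obs, vals, 0.0), axis=2) / np.maximum(n_obs, 1)
        out[:, :, k] = np.where(ok, agg, np.nan)
    return PanelDataset(panel.subject_ids, panel.waves,
                        [d.scale_name for d in defs], out)


# ---------------------------------------------------------------------------
# scale reliability
# ---------------------------------------------------------------------------

def scale_omega(item_data) -> dict:
    """McDonald's omega for one scale from a one-factor ML fit.

    ``item_data`` is a complete-case ``(subjects, items)`` matrix (rows with
    any missing item are dropped).  Returns a dict with ``omega``, the
    fitted loadings/residuals, and a ``converged`` flag — non-convergence is
    reported, never a silent NaN.
    """
    from . import sem_core

    X = np.asarray(item_data, dtype=float)
    X = X[np.isfinite(X).all(axis=1)]
    n, p = X.shape
    if p < 3:
        raise ValueError("omega needs at least 3 items")
    if n < 50:
        raise ValueError("omega needs at least 50 complete rows")

    items = [f"item{i}" for i in range(p)]
    spec = sem_core.one_factor_spec(items)
    fit = sem_core.fit_ml(spec, pd.DataFrame(X, columns=items),
                          missing="listwise", compute_se=False)
    lam = np.array([fit.estimates[f"lam_{it}"] for it in items])
    th = np.array([fit.estimates[f"theta_{it}"] for it in items])
    # sign indeterminacy of the factor: report the positive orientation
    if lam.sum() < 0:
        lam = -lam
    s = lam.sum()
    omega = s ** 2 / (s ** 2 + th.sum())
    return {"omega": float(omega), "loadings": lam, "residuals": th,
            "converged": bool(fit.converged),
            "diagnostics": None if fit.converged else
            {"gradient_norm": fit.gradient_norm}}
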