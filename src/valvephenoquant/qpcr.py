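"""Relative transcript quantification from qPCR Cq tables.

Each sample's target Cq is normalised to the geometric mean of two
housekeeping genes (Gapdh and Actb in the study), giving
dCt = Cq_target - sqrt(Cq_hk1 * Cq_hk2); lower dCt means higher
expression. Fold changes 2^-ddCt are for presentation only; statistics
are run on untransformed dCt values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_HOUSEKEEPING",
    "delta_ct",
    "relative_expression",
    "stats_input",
]

log = logging.getLogger(__name__)

DEFAULT_HOUSEKEEPING = ("Gapdh", "Actb")

_REQUIRED = ("sample", "group", "target", "cq")


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"Cq table is missing columns {missing}")
    table = table.copy()
    undetermined = table["cq"].isna() | ~np.isfinite(table["cq"])
    if undetermined.any():
        log.warning("dropping %d undetermined (non-amplifying) wells", int(undetermined.sum()))
        table = table[~undetermined]
    if (table["cq"] <= 0).any():
        raise ValueError("Cq values must be positive")
    return table


def delta_ct(
    table: pd.DataFrame,
    housekeeping: tuple[str, str] = DEFAULT_HOUSEKEEPING,
) -> pd.DataFrame:
    """Per-sample/target dCt against the geometric mean of two housekeepers.

    `table` is long-format with columns sample, group, target, cq.
    Technical replicates (repeated sample/target rows) are arithmetically
    averaged before normalisation. Returns a long-format frame with
    columns sample, group, target, delta_ct for all non-housekeeping
    targets.
    """
    if len(housekeeping) != 2:
        raise ValueError("exactly two housekeeping targets are required")
    table = _check_table(table)
    mean_cq = (
        table.groupby(["sample", "group", "target"], sort=False)["cq"].mean().reset_index()
    )
    wide = mean_cq.pivot_table(index=["sample", "group"], columns="target", values="cq")
    for hk in housekeeping:
        if hk not in wide.columns:
            raise ValueError(f"housekeeping target {hk!r} absent from table")
        bad = wide.index[wide[hk].isna()].get_level_values("sample").tolist()
        if bad:
            raise ValueError(f"samples missing housekeeping target {hk!r}: {bad}")
    hk_ref = np.sqrt(wide[housekeeping[0]] * wide[housekeeping[1]])
    targets = [c for c in wide.columns if c not in housekeeping]
    out = wide[targets].sub(hk_ref, axis=0)
    out = out.reset_index().melt(
        id_vars=["sample", "group"], var_name="target", value_name="delta_ct"
    )
    return out.dropna(subset=["delta_ct"]).reset_index(drop=True)


def relative_expression(dct: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    """Fold change 2^-ddCt per sample/target against the reference-group
    mean dCt of that target (assumes amplification efficiency 2.0)."""
    ref = dct[dct["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")
    ref_mean = ref.groupby("target")["delta_ct"].mean()
    out = dct.copy()
    out["ddct"] = out["delta_ct"] - out["target"].map(ref_mean)
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out


def stats_input(dct: pd.DataFrame, target: str) -> list[tuple[str, np.ndarray]]:
    """Group-wise untransformed dCt values for one target, ready for the
    test-selection engine. Never pass fold changes to statistics."""
    sub = dct[dct["target"] == target]
    groups = [
        (str(name), grp["delta_ct"].to_numpy())
        for name, grp in sub.groupby("group", sort=False)
    ]
    if len(groups) < 2:
        raise ValueError("need at least two groups for a comparison")
    return groups
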