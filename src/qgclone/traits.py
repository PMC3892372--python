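"""Derived traits: intrinsic rate of increase, standardization, family means."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RM_CORRECTION = 0.74  # correction factor relating ln(ON)/AFR to the intrinsic rate


@dataclass
class StandardizationScope:
    """How to z-score trait columns: one global scale or one per population."""

    scope: str = "global"  # "global" | "per_population"
    columns: tuple[str, ...] = ("AFR", "body_mass", "size_at_birth")

    def __post_init__(self) -> None:
        if self.scope not in ("global", "per_population"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if not self.columns:
            raise ValueError("columns must be non-empty")
        self.columns = tuple(self.columns)


def compute_rm(AFR, ON):
    """Intrinsic rate of natural increase r_m = 0.74 ln(ON) / AFR (per day).

    AFR is the age at first reproduction in days; ON the offspring number
    produced over the following AFR days.  Vectorized; raises on AFR <= 0
    or ON < 1 (where the statistic is undefined).
    """
    AFR = np.asarray(AFR, dtype=float)
    ON = np.asarray(ON, dtype=float)
    if np.any(AFR <= 0):
        raise ValueError("r_m undefined: AFR must be > 0")
    if np.any(ON < 1):
        raise ValueError("r_m undefined: ON must be >= 1")
    out = RM_CORRECTION * np.log(ON) / AFR
    return out.item() if out.ndim == 0 else out


def standardize(table: pd.DataFrame, scope: StandardizationScope | None = None) -> pd.DataFrame:
    """Z-score trait columns (sample SD, ddof=1) to mean 0, variance 1.

    With scope="per_population" each population is scaled on its own;
    a zero-variance column in any group is an error naming both.
    """
    scope = scope or StandardizationScope()
    missing = [c for c in scope.columns if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    out = table.copy()
    if scope.scope == "global":
        groups = [("(all)", out.index)]
    else:
        groups = [(str(k), idx) for k, idx in out.groupby("population").groups.items()]
    for col in scope.columns:
        for gname, idx in groups:
            vals = out.loc[idx, col].astype(float)
            sd = vals.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(
                    f"cannot standardize column {col!r} in group {gname!r}: zero variance"
                )
            out.loc[idx, col] = (vals - vals.mean()) / sd
    return out


def family_means(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicates to one record per (population, clone_id).

    Numeric traits are averaged over replicates; a ``n_reps`` column keeps
    the replicate count.  Zone labels (constant within a clone) are kept.
    """
    if table.empty:
        raise ValueError("empty table")
    keys = ["population", "clone_id"]
    numeric = [
        c for c in table.columns
        if c not in keys + ["zone", "replicate_id"] and pd.api.types.is_numeric_dtype(table[c])
    ]
    agg = {c: "mean" for c in numeric}
    if "zone" in table.columns:
        agg["zone"] = "first"
    out = table.groupby(keys, as_index=False, sort=False).agg(agg)
    out["n_reps"] = table.groupby(keys, sort=False).size().to_numpy()
    return out


def mean_offspring_size(lengths) -> float:
    """Mean offspring tibia length (mm); protocol expects 3-5 measurements."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("no offspring measurements")
    if not 3 <= lengths.size <= 5:
        logger.warning(
            "offspring size from %d measurements (protocol expects 3-5)", lengths.size
        )
    return float(lengths.mean())
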