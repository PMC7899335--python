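"""Scoring of the four worm behavioral assays from trial-level tables.

The experimental unit is the worm (per-worm fraction or rate, then group
mean +/- SEM), except for the aldicarb paralysis assay where the plate of
20 worms is the unit and the fraction paralyzed is pooled per genotype.

Assays:

* nose touch / optoASH - binary reversal responses per trial (10 nose
  touch trials per worm; a configurable number of light pulses), scored
  as the per-worm response fraction;
* thrashing - thrashes counted over 30 s in liquid;
* spontaneous reversals - reversals counted over a 5 min period;
* aldicarb paralysis - fraction of fully paralyzed worms checked at
  15 min intervals, which must be non-decreasing per plate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError

__all__ = [
    "nose_touch_score",
    "opto_response",
    "rate_score",
    "paralysis_curve",
    "group_summary",
]


def group_summary(per_worm: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Group mean, SD, SEM and n over per-worm scores."""
    def _sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    g = per_worm.groupby("genotype")[value_col]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
                sem=_sem, n="count")
    return out.reset_index()


def _binary_fraction(table: pd.DataFrame, max_trials: int | None) -> pd.DataFrame:
    required = {"worm_id", "genotype", "response"}
    if not required.issubset(table.columns):
        raise ConfigurationError(f"table needs columns {sorted(required)}")
    resp = table["response"]
    if not resp.isin([0, 1]).all():
        raise ConfigurationError("responses must be binary (0/1)")
    counts = table.groupby(["genotype", "worm_id"])["response"].agg(["sum", "count"])
    if max_trials is not None and (counts["count"] > max_trials).any():
        raise ConfigurationError(f"a worm has more than {max_trials} trials")
    empty = counts["count"] == 0
    if empty.any():
        warnings.warn(f"excluding {int(empty.sum())} worm(s) with zero trials")
        counts = counts[~empty]
    counts["fraction"] = counts["sum"] / counts["count"]
    return counts.reset_index()[["worm_id", "genotype", "fraction"]]


def nose_touch_score(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-worm nose-touch response fraction (of up to 10 trials) and group summary."""
    per_worm = _binary_fraction(table, max_trials=10)
    return per_worm, group_summary(per_worm, "fraction")


def opto_response(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-worm fraction of light pulses answered with a reversal, plus group summary."""
    per_worm = _binary_fraction(table, max_trials=None)
    return per_worm, group_summary(per_worm, "fraction")


def rate_score(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-worm event count over the assay's stated period (no re-scaling).

    Expects columns worm_id, genotype, count, period, assay; the period
    must be identical within each assay (30 s for thrashing, 5 min for
    spontaneous reversals).
    """
    required = {"worm_id", "genotype", "count", "period", "assay"}
    if not required.issubset(table.columns):
        raise ConfigurationError(f"table needs columns {sorted(required)}")
    if (table["count"] < 0).any():
        raise ConfigurationError("counts must be non-negative")
    for assay, sub in table.groupby("assay"):
        if sub["period"].nunique() != 1:
            raise ConfigurationError(f"assay {assay!r} mixes different periods")
    per_worm = table[["worm_id", "genotype", "assay", "count", "period"]].copy()
    per_worm = per_worm.rename(columns={"count": "rate"})
    return per_worm, group_summary(per_worm, "rate")


def paralysis_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Pooled fraction paralyzed vs time per genotype, with binomial SE.

    Expects columns plate_id, genotype, time_min, n_paralyzed, n_total.
    Counts must be non-decreasing in time within each plate (worms do not
    recover); a violation is a data-integrity error naming the plate.
    """
    required = {"plate_id", "genotype", "time_min", "n_paralyzed", "n_total"}
    if not required.issubset(table.columns):
        raise ConfigurationError(f"table needs columns {sorted(required)}")
    if (table["n_paralyzed"] > table["n_total"]).any():
        raise DataIntegrityError("n_paralyzed exceeds n_total")
    for plate, sub in table.sort_values("time_min").groupby("plate_id"):
        if np.any(np.diff(sub["n_paralyzed"].to_numpy()) < 0):
            raise DataIntegrityError(f"plate {plate!r}: paralyzed count decreases over time")
    pooled = (table.groupby(["genotype", "time_min"])[["n_paralyzed", "n_total"]]
              .sum().reset_index())
    p = pooled["n_paralyzed"] / pooled["n_total"]
    pooled["fraction"] = p
    pooled["se"] = np.sqrt(p * (1 - p) / pooled["n_total"])
    return pooled.sort_values(["genotype", "time_min"]).reset_index(drop=True)
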