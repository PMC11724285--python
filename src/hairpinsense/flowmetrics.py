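"""Flow-cytometry readout: gating, GFP/BFP normalisation, fold activation.

Event tables are plain :class:`pandas.DataFrame` objects with numeric
columns ``FSC_A``, ``SSC_A``, ``SSC_H``, ``BFP``, ``GFP`` (one row per
event) — the contract is a CSV exported from any cytometry tool, never the
binary FCS file.  Gating follows the usual chain: a live-cell scatter
rectangle, a singlet band on the SSC area/height ratio, then BFP
positivity.  The reporter design makes BFP expression edit-independent, so
the per-cell GFP/BFP ratio normalises transfection dose; fold activation is
the summary ratio with target over the summary ratio without target.

The per-cell median summary is the default (robust to the lognormal tails
typical of cytometry); a population-mean variant is available because the
underlying protocol does not pin down which was used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError

REQUIRED_COLUMNS = ("FSC_A", "SSC_A", "SSC_H", "BFP", "GFP")
DEFAULT_MIN_EVENTS = 100


@dataclass(frozen=True)
class GateConfig:
    """Gate thresholds; build from a vector-only control table with
    :meth:`from_control`, or supply fixed numbers."""

    fsc_range: tuple[float, float]
    ssc_range: tuple[float, float]
    singlet_band: tuple[float, float]
    bfp_threshold: float
    gfp_threshold: float = 0.0
    min_bfp_events: int = DEFAULT_MIN_EVENTS
    statistic: str = "median"  # or "mean"

    def __post_init__(self) -> None:
        for lo, hi in (self.fsc_range, self.ssc_range, self.singlet_band):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise InputError("gate bounds must be finite with lo < hi")
        if self.statistic not in ("median", "mean"):
            raise InputError("statistic must be 'median' or 'mean'")

    @classmethod
    def from_control(
        cls,
        control: pd.DataFrame,
        live_quantiles: tuple[float, float] = (0.05, 0.999),
        singlet_quantiles: tuple[float, float] = (0.01, 0.99),
        bfp_quantile: float = 0.995,
        statistic: str = "median",
    ) -> "GateConfig":
        """Quantile-derived gates from a vector-only (reporter-free) control."""
        _check_columns(control)
        ratio = control["SSC_A"] / np.maximum(control["SSC_H"], 1e-12)
        return cls(
            fsc_range=(
                float(control["FSC_A"].quantile(live_quantiles[0])),
                float(control["FSC_A"].quantile(live_quantiles[1])),
            ),
            ssc_range=(
                float(control["SSC_A"].quantile(live_quantiles[0])),
                float(control["SSC_A"].quantile(live_quantiles[1])),
            ),
            singlet_band=(
                float(ratio.quantile(singlet_quantiles[0])),
                float(ratio.quantile(singlet_quantiles[1])),
            ),
            bfp_threshold=float(control["BFP"].quantile(bfp_quantile)),
            statistic=statistic,
        )


def _check_columns(table: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"event table is missing required column {col!r}")


def gate_events(table: pd.DataFrame, config: GateConfig) -> tuple[pd.DataFrame, dict]:
    """Apply live -> singlet -> BFP-positive gates in order; returns the
    gated table and per-stage retention counts."""
    _check_columns(table)
    if len(table) < 1:
        raise InputError("event table is empty")
    counts = {"input": len(table)}
    live = table[
        table["FSC_A"].between(*config.fsc_range)
        & table["SSC_A"].between(*config.ssc_range)
    ]
    counts["live"] = len(live)
    ratio = live["SSC_A"] / np.maximum(live["SSC_H"], 1e-12)
    singlet = live[ratio.between(*config.singlet_band)]
    counts["singlet"] = len(singlet)
    bfp_pos = singlet[singlet["BFP"] > config.bfp_threshold]
    counts["bfp_positive"] = len(bfp_pos)
    return bfp_pos, counts


def normalized_intensity(table: pd.DataFrame, config: GateConfig) -> float:
    """Summary of the per-cell GFP/BFP ratio (median by default)."""
    ratios = table["GFP"] / table["BFP"]
    if config.statistic == "median":
        return float(ratios.median())
    return float(ratios.mean())


def fold_activation(
    table_plus: pd.DataFrame, table_minus: pd.DataFrame, config: GateConfig
) -> dict:
    """Fold activation = summary(GFP/BFP | target) / summary(GFP/BFP | no
    target).  Both tables must already be gated."""
    for name, table in (("plus", table_plus), ("minus", table_minus)):
        _check_columns(table)
        if len(table) < config.min_bfp_events:
            raise InputError(
                f"{name} table has {len(table)} BFP-positive events; at least "
                f"{config.min_bfp_events} required"
            )
    norm_plus = normalized_intensity(table_plus, config)
    norm_minus = normalized_intensity(table_minus, config)
    if not np.isfinite(norm_minus) or abs(norm_minus) < 1e-12:
        raise InputError(
            "baseline normalized intensity is zero or undefined; apply an "
            "intensity floor or widen the BFP gate"
        )
    return {
        "normalized_plus": norm_plus,
        "normalized_minus": norm_minus,
        "fold": norm_plus / norm_minus,
        "n_plus": len(table_plus),
        "n_minus": len(table_minus),
        "statistic": config.statistic,
    }


def analyze(
    plus: pd.DataFrame,
    minus: pd.DataFrame,
    control: pd.DataFrame | None = None,
    config: GateConfig | None = None,
) -> dict:
    """Gate both condition tables (thresholds from the control when no
    explicit config is given) and compute fold activation."""
    if config is None:
        if control is None:
            raise InputError("either a control table or a GateConfig is required")
        config = GateConfig.from_control(control)
    gated_plus, counts_plus = gate_events(plus, config)
    gated_minus, counts_minus = gate_events(minus, config)
    out = fold_activation(gated_plus, gated_minus, config)
    out["gates_plus"] = counts_plus
    out["gates_minus"] = counts_minus
    return out
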