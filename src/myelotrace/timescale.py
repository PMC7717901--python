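"""Trajectories of blood composition and protein similarity versus lineage age.

Group-level summaries (myeloid composition percentages, or per-group mean
percent similarity to the human orthologue) are placed on a timescale at
the emergence time (MYA) of each group's earliest known ancestor, oldest
first.  The timescale is split into two evolutionary periods — the
fish-to-squamate transition and the squamate-to-mammal transition, sharing
squamata as the hinge — mirroring the two-panel reading of the
similarity-versus-time trend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .groups import EMERGENCE_MYA, assign_emergence

logger = logging.getLogger(__name__)

#: Early period: the fishes through the first reptiles.
PERIOD1_GROUPS = ("jawed_fish", "jawless_fish", "amphibia", "squamata")
#: Late period: squamata (shared hinge) through the mammals.
PERIOD2_GROUPS = ("squamata", "testudines", "crocodilia", "aves",
                  "monotremata", "marsupialia", "placentalia")

#: Groups dropped by default from similarity trajectories: the placental
#: similarities include the reference species' own group and sit far above
#: the other lineages.
DEFAULT_SIMILARITY_EXCLUDE = ("placentalia",)


@dataclass(frozen=True)
class TimescalePoint:
    group: str
    mya: float
    metric_name: str
    value: float
    spread_low: float
    spread_high: float

    def __post_init__(self) -> None:
        if not self.spread_low <= self.value <= self.spread_high:
            raise ValueError(
                f"spread must bracket the value: {self.spread_low} <= "
                f"{self.value} <= {self.spread_high} fails for {self.group}")


def build_trajectory(summaries: pd.DataFrame, metric: str,
                     value_col: str | None = None,
                     spread: str = "minmax",
                     mya_table: dict[str, float] | None = None,
                     exclude_groups: tuple[str, ...] = ()
                     ) -> list[TimescalePoint]:
    """Turn per-group summary rows into an ordered trajectory.

    Parameters
    ----------
    summaries
        Rows with a ``group`` column plus the metric columns.  Two layouts
        are understood: composition/similarity summaries carrying
        (``mean_pct``/``min_pct``/``max_pct``/``sd_pct`` or
        ``abs_mean``/``abs_min``/``abs_max``), optionally filtered by a
        selector column, or an explicit ``value_col``.
    metric
        Name recorded on the points and, when the table has a
        ``cell_type`` or ``protein`` column, the selector value
        (e.g. ``pct_neutrophil`` selects cell_type ``neutrophil`` of
        column ``pct_of_myeloid``; ``mean_similarity_CSF3`` selects
        protein ``CSF3`` of column ``mean_pct``).
    spread
        ``"minmax"`` floating-bar spread, ``"sd"`` mean +/- one standard
        deviation, or ``"none"``.

    Points are sorted oldest-first (descending MYA), ties broken by name.
    """
    mya_table = EMERGENCE_MYA if mya_table is None else mya_table
    df = summaries.copy()

    if metric.startswith("pct_") and "cell_type" in df.columns:
        df = df[df["cell_type"] == metric.removeprefix("pct_")]
        value_col = value_col or "pct_of_myeloid"
        lo_col = hi_col = sd_col = None
    elif metric.startswith("abs_") and "cell_type" in df.columns:
        df = df[df["cell_type"] == metric.removeprefix("abs_")]
        value_col = value_col or "abs_mean"
        lo_col, hi_col, sd_col = "abs_min", "abs_max", None
    elif metric.startswith("mean_similarity_") and "protein" in df.columns:
        df = df[df["protein"] == metric.removeprefix("mean_similarity_")]
        value_col = value_col or "mean_pct"
        lo_col, hi_col = "min_pct", "max_pct"
        sd_col = "sd_pct" if "sd_pct" in df.columns else None
    elif value_col is not None:
        lo_col = hi_col = sd_col = None
    else:
        raise ValueError(
            f"metric {metric!r} not resolvable against columns "
            f"{list(summaries.columns)}")
    if df.empty:
        raise ValueError(f"metric {metric!r} absent from summaries")
    if value_col not in df.columns:
        raise ValueError(f"value column {value_col!r} absent from summaries")

    df = df[~df["group"].isin(exclude_groups)]
    points = []
    for _, row in df.iterrows():
        value = float(row[value_col])
        if spread == "minmax" and lo_col and lo_col in df.columns:
            lo, hi = float(row[lo_col]), float(row[hi_col])
        elif spread == "sd" and sd_col:
            sd = float(row[sd_col])
            lo, hi = value - sd, value + sd
        else:
            lo = hi = value
        points.append(TimescalePoint(
            group=row["group"], mya=assign_emergence(row["group"], mya_table),
            metric_name=metric, value=value, spread_low=lo, spread_high=hi))
    points.sort(key=lambda p: (-p.mya, p.group))
    return points


def split_periods(trajectory: list[TimescalePoint]
                  ) -> tuple[list[TimescalePoint], list[TimescalePoint]]:
    """Split a trajectory into the two evolutionary periods.

    Period 1 covers the fishes, amphibia and squamata; period 2 runs from
    squamata to the placental mammals, squamata appearing in both.  A
    trajectory lacking squamata yields disjoint periods with a warning.
    """
    if not trajectory:
        raise ValueError("empty trajectory")
    p1 = [p for p in trajectory if p.group in PERIOD1_GROUPS]
    p2 = [p for p in trajectory if p.group in PERIOD2_GROUPS]
    if not any(p.group == "squamata" for p in trajectory):
        logger.warning("split_periods: squamata absent; periods do not overlap")
    return p1, p2


def trajectory_frame(points: list[TimescalePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"group": p.group, "mya": p.mya, "metric": p.metric_name,
          "value": p.value, "spread_low": p.spread_low,
          "spread_high": p.spread_high} for p in points])


def export_trajectory(points: list[TimescalePoint], tsv_path,
                      plot_path=None) -> pd.DataFrame:
    """Write the trajectory TSV (deterministic bytes) and optional plot."""
    if not points:
        raise ValueError("no points to export")
    frame = trajectory_frame(points)
    frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g",
                 lineterminator="\n")
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        ax.fill_between(frame["mya"], frame["spread_low"],
                        frame["spread_high"], alpha=0.25)
        ax.plot(frame["mya"], frame["value"], marker="o")
        for _, row in frame.iterrows():
            ax.annotate(row["group"], (row["mya"], row["value"]), fontsize=6,
                        textcoords="offset points", xytext=(3, 4))
        ax.set_xlabel("emergence time (MYA)")
        ax.set_ylabel(points[0].metric_name)
        ax.invert_xaxis()  # deep time on the left
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return frame
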