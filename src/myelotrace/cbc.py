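"""Blood-count meta-analysis: per-lineage absolute counts and myeloid composition.

Per-species complete blood counts (CBC, standardised to 1e9 cells/L) are
filtered to adult/sub-adult myeloid records, then summarised per lineage
group as floating-bar statistics (min/mean/max absolute count per cell
type) and as the percentage composition of the myeloid compartment.
"""

from __future__ import annotations

import logging

import pandas as pd

from .groups import CELL_TYPES, MYELOID_CELL_TYPES

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["species", "group", "sex", "life_stage", "cell_type", "count"]
_KEPT_STAGES = {"adult", "sub-adult"}
_VALID_STAGES = _KEPT_STAGES | {"juvenile", "unknown"}
_VALID_SEX = {"male", "female", "unspecified"}


class CompositionError(ValueError):
    """Raised when a myeloid composition is undefined (zero group total)."""


def read_records(path) -> pd.DataFrame:
    """Read a CBC table (CSV with a count_1e9_per_L or count column)."""
    df = pd.read_csv(path)
    if "count_1e9_per_L" in df.columns:
        df = df.rename(columns={"count_1e9_per_L": "count"})
    return validate_records(df)


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check the closed vocabularies and non-negativity of a record table."""
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"missing CBC columns: {sorted(missing)}")
    bad_ct = set(records["cell_type"]) - set(CELL_TYPES)
    if bad_ct:
        raise ValueError(f"unknown cell types: {sorted(bad_ct)}")
    bad_stage = set(records["life_stage"]) - _VALID_STAGES
    if bad_stage:
        raise ValueError(f"unknown life stages: {sorted(bad_stage)}")
    bad_sex = set(records["sex"]) - _VALID_SEX
    if bad_sex:
        raise ValueError(f"unknown sex values: {sorted(bad_sex)}")
    if (records["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    return records


def filter_records(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the meta-analysis inclusion rules.

    Retains adult and sub-adult records only, and drops all lymphoid
    counts; the analysis concerns the myeloid compartment.  Records flagged
    non-standardised at parse time (a ``standardised`` column set False)
    are dropped as well.

    Returns
    -------
    (kept, dropped)
        The retained records and a per-rule drop count
        (``life_stage``, ``lymphoid``, ``non_standardised``).
    """
    validate_records(records)
    dropped = {"life_stage": 0, "lymphoid": 0, "non_standardised": 0}

    keep = records["life_stage"].isin(_KEPT_STAGES)
    dropped["life_stage"] = int((~keep).sum())
    kept = records[keep]

    lymphoid = kept["cell_type"] == "lymphoid_other"
    dropped["lymphoid"] = int(lymphoid.sum())
    kept = kept[~lymphoid]

    if "standardised" in kept.columns:
        std = kept["standardised"].astype(bool)
        dropped["non_standardised"] = int((~std).sum())
        kept = kept[std]

    for rule, n in dropped.items():
        if n:
            logger.info("filter_records: dropped %d records (%s)", n, rule)
    return kept.reset_index(drop=True), dropped


def aggregate_counts(records: pd.DataFrame,
                     grouping: str = "group") -> pd.DataFrame:
    """Floating-bar statistics of absolute counts per group and cell type.

    Returns one row per (group, cell_type) with ``abs_min``, ``abs_mean``
    and ``abs_max`` across species records, in 1e9 cells/L.
    """
    if records.empty:
        logger.warning("aggregate_counts: no records after filtering")
        return pd.DataFrame(
            columns=[grouping, "cell_type", "n", "abs_min", "abs_mean",
                     "abs_max"])
    agg = (records.groupby([grouping, "cell_type"], sort=True)["count"]
           .agg(n="size", abs_min="min", abs_mean="mean", abs_max="max")
           .reset_index())
    return agg


def myeloid_composition(records: pd.DataFrame, grouping: str = "group",
                        mode: str = "group_mean") -> pd.DataFrame:
    """Percentage composition of the myeloid compartment per group.

    mode ``"group_mean"`` (default): each cell type's share is its
    per-group mean count over the sum of per-group mean counts of all
    recorded myeloid cell types.  mode ``"per_species"``: per-species
    compositions are computed first and then averaged, an alternative
    reading of group-level composition.  Unrecorded cell types contribute
    nothing to the denominator; an explicit zero count does.

    Returns rows (group, cell_type, pct_of_myeloid); percentages per group
    sum to 100 within 1e-6.
    """
    if mode not in {"group_mean", "per_species"}:
        raise ValueError(f"unknown composition mode {mode!r}")
    myeloid = records[records["cell_type"].isin(MYELOID_CELL_TYPES)]
    if myeloid.empty:
        raise CompositionError("no myeloid records to compose")

    rows = []
    for group, sub in myeloid.groupby(grouping, sort=True):
        if mode == "group_mean":
            means = sub.groupby("cell_type", sort=True)["count"].mean()
            total = means.sum()
            if total == 0:
                raise CompositionError(
                    f"group {group!r} has all-zero myeloid counts")
            pct = 100.0 * means / total
        else:
            per_sp = sub.pivot_table(index="species", columns="cell_type",
                                     values="count", aggfunc="mean")
            totals = per_sp.sum(axis=1)
            if (totals == 0).any():
                bad = totals.index[totals == 0].tolist()
                raise CompositionError(
                    f"species with all-zero myeloid counts in {group!r}: {bad}")
            pct = (100.0 * per_sp.div(totals, axis=0)).mean(axis=0)
            pct = 100.0 * pct / pct.sum()
        for ct, value in pct.items():
            rows.append({grouping: group, "cell_type": ct,
                         "pct_of_myeloid": float(value)})
    return pd.DataFrame(rows)


def summarize(records: pd.DataFrame, grouping: str = "group",
              mode: str = "group_mean") -> pd.DataFrame:
    """Filter then merge absolute and percentage summaries into one table."""
    kept, _ = filter_records(records)
    absolute = aggregate_counts(kept, grouping)
    pct = myeloid_composition(kept, grouping, mode=mode)
    return absolute.merge(pct, on=[grouping, "cell_type"], how="left")


def plot_composition(summary: pd.DataFrame, path, grouping: str = "group"
                     ) -> None:
    """Stacked-bar plot of myeloid composition per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = summary.pivot_table(index=grouping, columns="cell_type",
                                values="pct_of_myeloid", fill_value=0.0)
    ax = pivot.plot(kind="bar", stacked=True, figsize=(9, 4), width=0.8)
    ax.set_ylabel("% of myeloid cells")
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    plt.close(ax.figure)


def plot_floating_bars(summary: pd.DataFrame, path, grouping: str = "group"
                       ) -> None:
    """Floating-bar (min-max with mean line) plot of absolute counts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    labels, xs = [], []
    for x, (_, row) in enumerate(summary.iterrows()):
        ax.bar(x, row["abs_max"] - row["abs_min"], bottom=row["abs_min"],
               width=0.6, color="#9ecae1", edgecolor="black", linewidth=0.5)
        ax.hlines(row["abs_mean"], x - 0.3, x + 0.3, color="black")
        labels.append(f"{row[grouping]}\n{row['cell_type']}")
        xs.append(x)
    ax.set_xticks(xs, labels, rotation=90, fontsize=6)
    ax.set_ylabel("count (1e9/L)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
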