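"""Gene presence/absence matrix across species.

Builds the species x gene matrix for the CSF receptor/ligand families and
the C/EBP transcription factors, with three states: ``present``,
``absent``, and ``not_assessed`` (distinguishing missing annotation from
evidenced loss).  Species rows are ordered by lineage-group emergence time
(oldest first) and then by name, matching the tree-ordered heat-map layout.
"""

from __future__ import annotations

import pandas as pd

from .groups import EMERGENCE_MYA, GENE_PANEL, assign_emergence

STATUSES = ("present", "absent", "not_assessed")


def build_presence_matrix(calls: pd.DataFrame,
                          genes: tuple[str, ...] = GENE_PANEL,
                          emergence: dict[str, float] | None = None
                          ) -> pd.DataFrame:
    """Assemble the presence/absence matrix from a per-species call table.

    Parameters
    ----------
    calls
        Columns species, group, gene, status.  Statuses outside
        {present, absent, not_assessed} or genes outside the panel raise,
        listing the offending rows.  Unreported (species, gene) pairs
        become ``not_assessed``.
    genes
        Column panel, in display order.
    emergence
        Group -> MYA mapping used to order rows (default: built-in table).

    Returns
    -------
    DataFrame indexed by species (ordered by group emergence descending,
    then species name), one column per panel gene, values from
    :data:`STATUSES`; the species -> group mapping is kept in
    ``.attrs["groups"]``.
    """
    required = {"species", "group", "gene", "status"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"call table missing columns: {sorted(missing)}")
    if calls.empty:
        raise ValueError("empty call table")
    bad_gene = ~calls["gene"].isin(genes)
    if bad_gene.any():
        rows = calls[bad_gene].index.tolist()
        offenders = sorted(calls.loc[bad_gene, "gene"].unique())
        raise ValueError(
            f"unknown gene symbols {offenders} at rows {rows}")
    bad_status = ~calls["status"].isin(STATUSES)
    if bad_status.any():
        rows = calls[bad_status].index.tolist()
        raise ValueError(f"invalid statuses at rows {rows}")

    groups = dict(zip(calls["species"], calls["group"]))
    emergence = EMERGENCE_MYA if emergence is None else emergence
    species = sorted(
        groups,
        key=lambda sp: (-assign_emergence(groups[sp], emergence), sp))

    matrix = (calls.pivot_table(index="species", columns="gene",
                                values="status", aggfunc="last")
              .reindex(index=species, columns=list(genes))
              .fillna("not_assessed"))
    matrix.columns.name = None
    matrix.index.name = "species"
    matrix.attrs["groups"] = groups
    return matrix


def summarize_loss_by_group(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-group retention fraction of each gene among assessed species.

    Returns one row per (group, gene) with ``n_assessed``, ``n_present``
    and ``retention`` = present / assessed; the group with the most total
    absences is flagged ``max_loss_group``.
    """
    if matrix.empty:
        raise ValueError("empty presence matrix")
    groups = matrix.attrs.get("groups")
    if not groups:
        raise ValueError("matrix lacks species->group mapping (attrs['groups'])")
    long = (matrix.reset_index()
            .melt(id_vars="species", var_name="gene", value_name="status"))
    long["group"] = long["species"].map(groups)
    assessed = long[long["status"] != "not_assessed"]
    out = (assessed.assign(present=assessed["status"] == "present")
           .groupby(["group", "gene"], sort=True)
           .agg(n_assessed=("status", "size"), n_present=("present", "sum"))
           .reset_index())
    out["retention"] = out["n_present"] / out["n_assessed"]
    absences = (out["n_assessed"] - out["n_present"]).groupby(out["group"]).sum()
    max_loss = absences.idxmax() if absences.any() else None
    out["max_loss_group"] = out["group"] == max_loss
    return out


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write the matrix as TSV (species row index kept)."""
    matrix.to_csv(path, sep="\t")


def read_matrix(path, groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix`."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if groups is not None:
        matrix.attrs["groups"] = groups
    return matrix


def render_heatmap(matrix: pd.DataFrame, path) -> None:
    """Categorical heat map: present (blue), absent (light), not_assessed (grey)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    codes = {"absent": 0, "present": 1, "not_assessed": 2}
    colours = ["#f7fbff", "#2171b5", "#bdbdbd"]
    grid = matrix.apply(lambda col: col.map(codes)).to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(1 + 0.45 * matrix.shape[1], 1 + 0.22 * matrix.shape[0]))
    ax.pcolormesh(grid, cmap=ListedColormap(colours), vmin=-0.5, vmax=2.5,
                  edgecolors="white", linewidth=0.5)
    ax.set_xticks([i + 0.5 for i in range(matrix.shape[1])], matrix.columns,
                  rotation=90, fontsize=7)
    ax.set_yticks([i + 0.5 for i in range(matrix.shape[0])], matrix.index,
                  fontsize=6)
    ax.invert_yaxis()
    ax.legend(handles=[Patch(color=c, label=s) for s, c in
                       zip(("absent", "present", "not_assessed"), colours)],
              loc="upper left", bbox_to_anchor=(1.01, 1), fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
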