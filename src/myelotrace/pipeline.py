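"""End-to-end orchestration: simulate -> cbc -> homology -> presence -> synteny -> timescale.

A single YAML config drives one reproducible run: a simulation block (or
real input files per data stream), per-stage parameter overrides, stage
toggles, a seed, and an output directory.  Every run writes a manifest
listing each output file with its SHA-256 digest, the config hash and the
seed; re-running the same config reproduces the TSV outputs byte for byte.
A failing stage leaves a ``FAILED`` marker in its directory and aborts the
stages downstream of it, keeping partial outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import cbc as cbc_mod
from . import homology as hom
from . import presence as pres
from . import synteny as syn
from . import synthetic as sim
from . import timescale as ts
from .groups import DEFAULT_GROUPS, PROTEIN_FAMILIES

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "out_dir": "myelotrace_run",
    "simulation": {
        "groups": None,  # null = all ten lineage groups
        "species_per_group": 3,
        "substitution_rate": 0.002,
        "indel_rate": 0.0001,
        "gene_loss_rate": 0.03,
        "inversion_rate": 0.02,
        "translocation_rate": 0.02,
        "root_length": 250,
    },
    "stages": {"cbc": True, "homology": True, "presence": True,
               "synteny": True, "timescale": True},
    "cbc": {"input": None, "composition_mode": "group_mean"},
    "presence": {"input": None},
    "synteny": {"flank_size": 10, "anchors": 4, "window": 10,
                "presence_fraction": 0.8,
                "focal_genes": list(PROTEIN_FAMILIES)},
    "homology": {"similarity_mode": "identity", "min_query_coverage": 0.40,
                 "max_evalue": 1e-20, "gap_open": 11, "gap_extend": 1},
    "timescale": {"include_placentalia_similarity": False,
                  "mya_overrides": {}},
}

_STAGE_ORDER = ("simulate", "cbc", "homology", "presence", "synteny",
                "timescale")


def _merge(defaults: dict, overrides: dict, path: str,
           errors: list[tuple[str, str]]) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            errors.append((here, "unknown configuration key"))
            continue
        if isinstance(defaults[key], dict) and not key.endswith("_overrides"):
            if not isinstance(value, dict):
                errors.append((here, "expected a mapping"))
                continue
            out[key] = _merge(defaults[key], value, here, errors)
        else:
            out[key] = value
    return out


def validate_config(source: str | Path | dict
                    ) -> tuple[dict[str, Any], list[tuple[str, str]]]:
    """Validate a run configuration, injecting defaults.

    Returns the completed config and a list of (path, message) violations;
    an empty list means the config is usable.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = copy.deepcopy(source)
    errors: list[tuple[str, str]] = []
    cfg = _merge(DEFAULT_CONFIG, raw, "", errors)

    simblock = cfg["simulation"]
    for key in ("substitution_rate", "indel_rate", "gene_loss_rate",
                "inversion_rate", "translocation_rate"):
        if simblock[key] < 0:
            errors.append((f"simulation.{key}", "must be >= 0"))
    if simblock["species_per_group"] < 1:
        errors.append(("simulation.species_per_group", "must be >= 1"))
    if simblock["root_length"] < 50:
        errors.append(("simulation.root_length", "must be >= 50"))
    if simblock["groups"] is not None:
        known = {g.name for g in DEFAULT_GROUPS}
        for name in simblock["groups"]:
            if name not in known:
                errors.append(("simulation.groups", f"unknown group {name!r}"))
    if cfg["synteny"]["flank_size"] < 1:
        errors.append(("synteny.flank_size", "must be >= 1"))
    if not 3 <= cfg["synteny"]["anchors"] <= 5:
        errors.append(("synteny.anchors", "must be between 3 and 5"))
    if not 0 < cfg["homology"]["min_query_coverage"] <= 1:
        errors.append(("homology.min_query_coverage", "must be in (0, 1]"))
    if cfg["homology"]["max_evalue"] <= 0:
        errors.append(("homology.max_evalue", "must be positive"))
    for stream in ("cbc", "presence"):
        if cfg[stream]["input"] is not None and raw.get("simulation"):
            errors.append((f"{stream}.input",
                           "conflicts with an explicit simulation block: "
                           "give exactly one source per data stream"))
    return cfg, errors


def config_hash(cfg: dict[str, Any]) -> str:
    """Digest of the scientific configuration (output location excluded)."""
    hashed = {k: v for k, v in cfg.items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str).encode()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g",
                 lineterminator="\n")


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: dict[str, Any] | str | Path) -> dict[str, Any]:
    """Run all enabled stages in dependency order; return the manifest."""
    cfg, errors = validate_config(config)
    if errors:
        raise PipelineError(f"invalid configuration: {errors}")
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    manifest: dict[str, Any] = {"seed": seed, "config_hash": config_hash(cfg),
                                "stages": {}, "files": {}}
    ctx: dict[str, Any] = {}
    aborted = False
    for stage in _STAGE_ORDER:
        enabled = stage == "simulate" or cfg["stages"].get(stage, True)
        if not enabled:
            manifest["stages"][stage] = "disabled"
            continue
        if aborted:
            manifest["stages"][stage] = "skipped"
            continue
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        try:
            _STAGE_FUNCS[stage](cfg, ctx, stage_dir)
            manifest["stages"][stage] = "ok"
        except Exception as exc:  # noqa: BLE001 - marker + abort downstream
            logger.exception("stage %s failed", stage)
            (stage_dir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
            manifest["stages"][stage] = "failed"
            aborted = True
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest["files"][str(path.relative_to(out))] = digest
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: dict, ctx: dict, stage_dir: Path) -> None:
    s = cfg["simulation"]
    groups = DEFAULT_GROUPS
    if s["groups"] is not None:
        groups = tuple(g for g in DEFAULT_GROUPS if g.name in set(s["groups"]))
    sim_cfg = sim.SimulationConfig(
        seed=cfg["seed"], groups=groups,
        species_per_group=s["species_per_group"],
        substitution_rate=s["substitution_rate"],
        indel_rate=s["indel_rate"], gene_loss_rate=s["gene_loss_rate"],
        inversion_rate=s["inversion_rate"],
        translocation_rate=s["translocation_rate"])
    species, newick = sim.simulate_species_set(sim_cfg)
    _write_tsv(species, stage_dir / "species.tsv")
    (stage_dir / "tree.nwk").write_text(newick + "\n")

    reference = sim.default_reference_order()
    orders, order_truth = sim.simulate_genome_orders(reference, sim_cfg)
    frames = [sim.order_to_frame(reference, "reference")]
    frames += [sim.order_to_frame(o, sp) for sp, o in orders.items()]
    _write_tsv(pd.concat(frames, ignore_index=True), stage_dir / "orders.tsv")

    grouping = dict(zip(species["species"], species["group"]))
    rng = sim.stage_rng(cfg["seed"], "roots")
    families: dict[str, dict[str, str | None]] = {}
    divergence: dict[str, dict[str, float]] = {}
    for protein in PROTEIN_FAMILIES:
        root = sim.random_protein(s["root_length"], rng)
        seqs, truth = sim.evolve_protein_family(
            root, newick, sim_cfg, stage=f"protein:{protein}")
        families[protein] = seqs
        divergence[protein] = truth.divergence
        hom.write_panel_fasta(stage_dir / f"{protein}.fa", seqs, grouping,
                              protein)
        (stage_dir / f"{protein}.query.fa").write_text(
            f">human|placentalia|{protein}\n{root}\n")
        ctx.setdefault("roots", {})[protein] = root

    counts = sim.simulate_cbc(sim_cfg)
    counts.to_csv(stage_dir / "cbc.csv", index=False, float_format="%.6g",
                  lineterminator="\n")
    truth_log = {"order_events": order_truth.events,
                 "divergence": divergence,
                 "cbc_means": sim.true_cbc_means(sim_cfg)}
    (stage_dir / "truth.json").write_text(
        json.dumps(truth_log, indent=1, sort_keys=True) + "\n")

    ctx.update(sim_cfg=sim_cfg, species=species, grouping=grouping,
               newick=newick, reference=reference, orders=orders,
               order_truth=order_truth, families=families, counts=counts)


def _stage_cbc(cfg: dict, ctx: dict, stage_dir: Path) -> None:
    if cfg["cbc"]["input"]:
        records = cbc_mod.read_records(cfg["cbc"]["input"])
    else:
        records = ctx["counts"]
    summary = cbc_mod.summarize(records,
                                mode=cfg["cbc"]["composition_mode"])
    _write_tsv(summary, stage_dir / "summary.tsv")
    cbc_mod.plot_composition(summary, stage_dir / "composition.png")
    cbc_mod.plot_floating_bars(summary, stage_dir / "absolute_counts.png")
    ctx["cbc_summary"] = summary


def _stage_homology(cfg, ctx, stage_dir: Path) -> None:
    h = cfg["homology"]
    scheme = hom.ScoringScheme(gap_open=h["gap_open"],
                               gap_extend=h["gap_extend"])
    criteria = hom.HomologyCriteria(min_query_coverage=h["min_query_coverage"],
                                    max_evalue=h["max_evalue"])
    tables = []
    for protein, seqs in ctx["families"].items():
        table = hom.score_species_panel(ctx["roots"][protein], seqs, scheme,
                                        criteria, protein=protein)
        tables.append(table)
    scores = pd.concat(tables, ignore_index=True)
    _write_tsv(scores, stage_dir / "scores.tsv")
    value = ("percent_identity" if h["similarity_mode"] == "identity"
             else "percent_positives")
    summary = hom.aggregate_by_group(scores, ctx["grouping"], value=value)
    _write_tsv(summary, stage_dir / "group_summary.tsv")
    ctx["homology_scores"] = scores
    ctx["homology_summary"] = summary


def _stage_presence(cfg, ctx, stage_dir: Path) -> None:
    if cfg["presence"]["input"]:
        calls = pd.read_csv(cfg["presence"]["input"], sep="\t")
        genes = tuple(sorted(calls["gene"].unique()))
    elif "homology_scores" in ctx:
        scores = ctx["homology_scores"]
        calls = pd.DataFrame({
            "species": scores["species"],
            "group": scores["species"].map(ctx["grouping"]),
            "gene": scores["protein"],
            "status": scores["homolog"].map({True: "present",
                                             False: "absent"})})
        genes = PROTEIN_FAMILIES
    else:  # homology disabled: call presence from simulated gene survival
        rows = []
        for protein, seqs in ctx["families"].items():
            for sp, seq in seqs.items():
                rows.append({"species": sp, "group": ctx["grouping"][sp],
                             "gene": protein,
                             "status": "present" if seq else "absent"})
        calls = pd.DataFrame(rows)
        genes = PROTEIN_FAMILIES
    matrix = pres.build_presence_matrix(calls, genes=genes)
    pres.write_matrix(matrix, stage_dir / "matrix.tsv")
    _write_tsv(pres.summarize_loss_by_group(matrix),
               stage_dir / "retention.tsv")
    pres.render_heatmap(matrix, stage_dir / "heatmap.png")
    ctx["presence_matrix"] = matrix


def _stage_synteny(cfg, ctx, stage_dir: Path) -> None:
    s = cfg["synteny"]
    comparisons_all = []
    for focal in s["focal_genes"]:
        block = syn.select_anchors(
            syn.extract_block(ctx["reference"], focal, s["flank_size"]),
            ctx["orders"], k=s["anchors"],
            presence_fraction=s["presence_fraction"])
        comps = [syn.compare_locus(block, order, sp, window=s["window"])
                 for sp, order in ctx["orders"].items()]
        syn.render_synteny_map(comps, stage_dir / f"{focal}.svg")
        comparisons_all.append(syn.comparisons_to_frame(comps)
                               .assign(focal_gene=focal))
    _write_tsv(pd.concat(comparisons_all, ignore_index=True),
               stage_dir / "comparisons.tsv")


def _stage_timescale(cfg, ctx, stage_dir: Path) -> None:
    t = cfg["timescale"]
    mya = dict(ts.EMERGENCE_MYA, **(t["mya_overrides"] or {}))
    if "cbc_summary" in ctx:
        for cell_type in ("neutrophil", "heterophil", "monocyte"):
            sub = ctx["cbc_summary"]
            if not (sub["cell_type"] == cell_type).any():
                continue
            points = ts.build_trajectory(sub, f"pct_{cell_type}",
                                         spread="none", mya_table=mya)
            ts.export_trajectory(points, stage_dir / f"pct_{cell_type}.tsv",
                                 stage_dir / f"pct_{cell_type}.png")
    if "homology_summary" in ctx:
        exclude = (() if t["include_placentalia_similarity"]
                   else ts.DEFAULT_SIMILARITY_EXCLUDE)
        summary = ctx["homology_summary"]
        for protein in summary["protein"].unique():
            if not (~summary[summary["protein"] == protein]["group"]
                    .isin(exclude)).any():
                continue
            points = ts.build_trajectory(
                summary, f"mean_similarity_{protein}",
                spread="sd", mya_table=mya, exclude_groups=exclude)
            p1, p2 = ts.split_periods(points)
            ts.export_trajectory(points,
                                 stage_dir / f"similarity_{protein}.tsv",
                                 stage_dir / f"similarity_{protein}.png")
            for name, period in (("period1", p1), ("period2", p2)):
                if period:
                    ts.export_trajectory(
                        points=period,
                        tsv_path=stage_dir /
                        f"similarity_{protein}_{name}.tsv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cbc": _stage_cbc,
    "homology": _stage_homology,
    "presence": _stage_presence,
    "synteny": _stage_synteny,
    "timescale": _stage_timescale,
}
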