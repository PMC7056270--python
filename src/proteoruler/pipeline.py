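"""End-to-end pipeline: simulate -> quantify -> differential -> structure.

A :class:`RunConfig` (loadable from YAML) fixes every input, threshold and
seed; :func:`run_pipeline` executes the stages, writes all result tables
under the output directory and finishes with a JSON manifest listing every
artifact with its SHA-256 hash.  Identical configuration and seed produce
byte-identical artifacts, hence identical manifests.

The single seed is fanned out to the stages by fixed offsets so that, e.g.,
changing the noise realisation does not perturb the planted ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import differential as ds
from . import structure as st
from .io_tables import (
    condition_of,
    read_design,
    read_protein_groups,
    write_protein_groups,
    write_table,
)
from .ruler import (
    RulerConfig,
    detection_filter,
    estimate_copy_numbers,
    filter_groups,
    total_protein_content,
)
from .synthetic import SimulationParams, make_design, make_ground_truth, simulate_intensities

__all__ = ["RunConfig", "ContrastSpec", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class ContrastSpec:
    """One differential contrast: ``rule`` is 'activation' or 'genotype'."""

    name: str
    condition_a: str
    condition_b: str
    rule: str = "genotype"


def _default_contrasts() -> list[ContrastSpec]:
    out = []
    for ct in ("CD4", "CD8"):
        naive = condition_of("WT", ct, "naive")
        tcr_wt = condition_of("WT", ct, "TCR")
        tcr_ko = condition_of("Myc_cKO", ct, "TCR")
        out.append(ContrastSpec(f"tcr_{ct.lower()}", naive, tcr_wt, "activation"))
        out.append(ContrastSpec(f"myc_{ct.lower()}", tcr_wt, tcr_ko, "genotype"))
    return out


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    When ``protein_groups`` / ``design`` paths are given, those files are
    the input; otherwise a synthetic dataset of ``n_proteins`` proteins is
    generated (the ground truth is then written alongside the results).
    """

    out_dir: str = "proteoruler_run"
    seed: int = 0
    protein_groups: str | None = None
    design: str | None = None
    n_proteins: int = 2000
    genotypes: tuple[str, ...] = ("WT", "Myc_cKO")
    cell_types: tuple[str, ...] = ("CD4", "CD8")
    n_replicates: int = 3
    simulation: SimulationParams = field(default_factory=SimulationParams)
    ruler: RulerConfig = field(default_factory=RulerConfig)
    contrasts: list[ContrastSpec] = field(default_factory=_default_contrasts)
    overlap: tuple[str, str] | None = None  # two contrast names to intersect
    p_threshold: float = 0.05
    fold_threshold: float = 2.0
    heatmap_min_mean_copies: float = 500.0
    heatmap_min_reps: int = 2
    heatmap_reference_celltype: str = "CD8"
    gene_set: str | None = None  # path to a plain-text gene list
    rank_conditions: list[str] | None = None  # default: all conditions

    def __post_init__(self):
        if self.p_threshold <= 0 or self.fold_threshold <= 0:
            raise ValueError("thresholds must be positive")


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML, erroring on unknown or malformed fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"config: unknown fields {sorted(unknown)}")
    if "simulation" in raw:
        sim = dict(raw["simulation"])
        if "ruler_config" in sim:
            sim["ruler_config"] = RulerConfig(**sim["ruler_config"])
        elif "ruler" in raw:
            sim["ruler_config"] = RulerConfig(**raw["ruler"])
        raw["simulation"] = SimulationParams(**sim)
    elif "ruler" in raw:
        raw["simulation"] = SimulationParams(ruler_config=RulerConfig(**raw["ruler"]))
    if "ruler" in raw:
        raw["ruler"] = RulerConfig(**raw["ruler"])
    if "contrasts" in raw:
        raw["contrasts"] = [ContrastSpec(**c) for c in raw["contrasts"]]
    for fld in ("genotypes", "cell_types"):
        if fld in raw:
            raw[fld] = tuple(raw[fld])
    if "overlap" in raw and raw["overlap"] is not None:
        raw["overlap"] = tuple(raw["overlap"])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; return the artifact manifest (also written to disk).

    Any stage error aborts with a :class:`PipelineError` naming the stage;
    artifacts written so far are retained next to a ``FAILED`` marker file.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "setup"

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts.append(path)
        return path

    try:
        # ---- stage: input -------------------------------------------------
        stage = "simulate" if cfg.protein_groups is None else "load"
        if cfg.protein_groups is None:
            design = make_design(cfg.genotypes, cfg.cell_types, cfg.n_replicates)
            truth = make_ground_truth(
                cfg.n_proteins, params=cfg.simulation, seed=cfg.seed, design=design
            )
            groups = simulate_intensities(truth, design, seed=cfg.seed + 1, params=cfg.simulation)
            emit("design.tsv", lambda p: write_table(design, p))
            emit("protein_groups.tsv", lambda p: write_protein_groups(groups, p))
            emit("ground_truth.tsv", lambda p: write_table(truth.table, p))
        else:
            if cfg.design is None:
                raise PipelineError("config: field 'design' is required with 'protein_groups'")
            design = read_design(cfg.design)
            groups = read_protein_groups(cfg.protein_groups)

        # ---- stage: quantify ---------------------------------------------
        stage = "quantify"
        filtered = detection_filter(filter_groups(groups), design, cfg.ruler)
        result = estimate_copy_numbers(filtered, design, cfg.ruler)
        emit("copy_numbers.tsv", lambda p: write_table(result.to_frame(), p))
        content = total_protein_content(result)
        emit(
            "total_protein_content.tsv",
            lambda p: write_table(content.rename_axis("condition").reset_index(), p),
        )

        # ---- stage: differential -------------------------------------------
        stage = "differential"
        regulated_sets: dict[str, set] = {}
        for c in cfg.contrasts:
            table = ds.differential_table(result, c.condition_a, c.condition_b)
            table = ds.classify_regulation(
                table, c.rule, cfg.p_threshold, cfg.fold_threshold
            )
            regulated_sets[c.name] = set(table.loc[table["regulated"], "group_id"])
            emit(f"differential_{c.name}.tsv", lambda p, t=table: write_table(t, p))
            volcano = ds.volcano_table(table)
            if len(volcano):
                emit(f"volcano_{c.name}.tsv", lambda p, t=volcano: write_table(t, p))
        if cfg.overlap is not None:
            a, b = cfg.overlap
            if a not in regulated_sets or b not in regulated_sets:
                raise PipelineError(f"config: overlap names unknown contrasts {cfg.overlap}")
            only_a, shared, only_b = ds.regulated_overlap(regulated_sets[a], regulated_sets[b])
            venn = pd.DataFrame(
                {
                    "partition": [f"only_{a}", "shared", f"only_{b}"],
                    "count": [len(only_a), len(shared), len(only_b)],
                }
            )
            emit("venn_counts.tsv", lambda p: write_table(venn, p))

        # ---- stage: structure ----------------------------------------------
        stage = "structure"
        conditions = cfg.rank_conditions or list(result.mean_copies.columns)
        ranks = pd.concat(
            [st.mass_rank_profile(result, c).to_frame() for c in conditions],
            ignore_index=True,
        )
        emit("mass_rank_profiles.tsv", lambda p: write_table(ranks, p))
        if cfg.gene_set is not None:
            genes = [
                g.strip() for g in Path(cfg.gene_set).read_text().splitlines() if g.strip()
            ]
            summary, unmatched = st.pathway_mass_summary(result, genes)
            emit("pathway_mass.tsv", lambda p: write_table(summary.reset_index(), p))
            if unmatched:
                log.warning("gene set: %d unmatched names: %s", len(unmatched), unmatched[:10])
        heat = st.build_heatmap_matrix(
            result,
            min_mean_copies=cfg.heatmap_min_mean_copies,
            min_reps=cfg.heatmap_min_reps,
            reference_celltype=cfg.heatmap_reference_celltype,
        )
        emit(
            "heatmap_matrix.tsv",
            lambda p: write_table(
                heat.ordered().rename_axis("group_id").reset_index(), p
            ),
        )
        emit(
            "heatmap_orders.tsv",
            lambda p: write_table(
                pd.DataFrame(
                    {
                        "axis": ["row"] * len(heat.row_order) + ["col"] * len(heat.col_order),
                        "position": list(range(len(heat.row_order)))
                        + list(range(len(heat.col_order))),
                        "id": heat.row_order + heat.col_order,
                    }
                ),
                p,
            ),
        )
    except PipelineError:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        raise
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    return manifest
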