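"""End-to-end orchestration of the marker screen with provenance capture.

``run_screen`` composes the five stages — per-bait correlation, top-fraction
selection, intersection, compartment-enrichment filtering, contaminant
exclusion and GWAS cross-referencing — and emits, alongside the candidate
table, a JSON-serializable manifest recording every threshold and the gene
count surviving each stage.  The manifest is mandatory output: the screen's
conclusions hinge on a handful of cutoffs, so they are always written down.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import yaml

from . import __version__
from .errors import ParameterError, PodoscreenError
from .filters import (
    GwasCatalog,
    contaminant_exclusion,
    enrichment_records,
    filter_by_enrichment,
    gwas_crossref,
)
from .io import ExpressionMatrix, read_compartment_map, read_gct, read_tsv_matrix
from .genes import parse_gene_id
from .screen import (
    CandidateTable,
    MarkerPanel,
    build_candidate_table,
    correlate_bait,
)

log = logging.getLogger("podoscreen")


@dataclass
class ScreenConfig:
    """All parameters of one screen run."""

    q_bait: float = 0.02
    q_neg: float = 0.01
    enrichment_threshold: float = 1.5
    method: str = "pearson"
    log2_transform: bool = False
    pseudocount: float = 0.0
    compartments: Optional[Tuple[str, ...]] = ("cortex",)
    panel: MarkerPanel = field(default_factory=MarkerPanel)
    matrix_path: Optional[str] = None
    compartment_map_path: Optional[str] = None
    gwas_paths: Dict[str, str] = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self):
        for name, q in (("q_bait", self.q_bait), ("q_neg", self.q_neg)):
            if not (0.0 < q <= 1.0):
                raise ParameterError(f"{name} must be in (0, 1], got {q}")
        if self.enrichment_threshold <= 0:
            raise ParameterError("enrichment_threshold must be > 0")
        if self.compartments is not None:
            self.compartments = tuple(self.compartments)

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        panel_cfg = raw.pop("panel", None)
        cfg = cls(**raw)
        if panel_cfg:
            baits = tuple(parse_gene_id(b) for b in panel_cfg.get("baits", []))
            contaminants = {
                name: parse_gene_id(g)
                for name, g in panel_cfg.get("contaminants", {}).items()
            }
            default = MarkerPanel()
            cfg.panel = MarkerPanel(
                baits=baits or default.baits,
                contaminants=contaminants or default.contaminants,
            )
        return cfg

    def parameters(self) -> dict:
        return {
            "q_bait": self.q_bait,
            "q_neg": self.q_neg,
            "enrichment_threshold": self.enrichment_threshold,
            "method": self.method,
            "log2_transform": self.log2_transform,
            "pseudocount": self.pseudocount,
            "compartments": list(self.compartments) if self.compartments else None,
            "baits": [str(b) for b in self.panel.baits],
            "contaminants": {k: str(v) for k, v in self.panel.contaminants.items()},
            "seed": self.seed,
        }


def load_matrix(config: ScreenConfig) -> ExpressionMatrix:
    if not config.matrix_path:
        raise ParameterError("config has no matrix_path")
    path = Path(config.matrix_path)
    if path.suffix.lower() == ".gct":
        matrix = read_gct(path)
        if config.compartment_map_path:
            cmap = read_compartment_map(config.compartment_map_path)
            matrix.compartment = [
                cmap.get(s, "unassigned") for s in matrix.samples
            ]
        return matrix
    cmap = (
        read_compartment_map(config.compartment_map_path)
        if config.compartment_map_path
        else {}
    )
    return read_tsv_matrix(path, cmap)


def run_screen(
    config: ScreenConfig,
    matrix: Optional[ExpressionMatrix] = None,
    catalogs: Optional[Sequence[GwasCatalog]] = None,
) -> Tuple[CandidateTable, dict]:
    """Run the full screen; returns (candidate table, manifest)."""
    if matrix is None:
        matrix = load_matrix(config)
    if catalogs is None:
        catalogs = [
            GwasCatalog.from_file(trait, path)
            for trait, path in config.gwas_paths.items()
        ]
    config.panel.check_in_matrix(matrix)

    def _stage(name, fn):
        try:
            return fn()
        except PodoscreenError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    profiles = {}
    for bait in config.panel.baits:
        profiles[bait.key] = _stage(
            f"correlate:{bait.symbol or bait.key}",
            lambda b=bait: correlate_bait(
                matrix,
                b,
                compartments=config.compartments,
                method=config.method,
                log2_transform=config.log2_transform,
            ),
        )
    table = _stage(
        "intersect",
        lambda: build_candidate_table(matrix, profiles, config.q_bait, config.panel),
    )
    n_intersection = int(table.df["in_intersection"].sum())
    log.info("intersection: %d candidates", n_intersection)

    records = _stage(
        "enrichment",
        lambda: enrichment_records(matrix, pseudocount=config.pseudocount),
    )
    table = _stage(
        "enrichment",
        lambda: filter_by_enrichment(table, config.enrichment_threshold, records),
    )
    cand = table.candidates()
    n_enriched = int((cand["passes_enrichment"] == True).sum())  # noqa: E712
    log.info("pass enrichment (fold >= %.3g): %d", config.enrichment_threshold, n_enriched)

    table = _stage(
        "exclusion",
        lambda: contaminant_exclusion(
            matrix,
            table,
            config.panel,
            q_neg=config.q_neg,
            compartments=config.compartments,
            method=config.method,
            log2_transform=config.log2_transform,
        ),
    )
    cand = table.candidates()
    n_after_exclusion = int(
        ((cand["passes_enrichment"] == True) & (cand["excluded_by"] == "")).sum()  # noqa: E712
    )
    log.info("after contaminant exclusion: %d", n_after_exclusion)

    if catalogs:
        table = _stage("gwas", lambda: gwas_crossref(table, catalogs))
    n_gwas = int(
        (
            table.candidates()["gwas_traits"].ne("")
            & (table.candidates()["passes_enrichment"] == True)  # noqa: E712
            & table.candidates()["excluded_by"].eq("")
        ).sum()
    )

    universe = matrix.n_genes()
    per_bait_top = max(1, math.floor(config.q_bait * universe))
    manifest = {
        "software": "podoscreen",
        "version": __version__,
        "seed": config.seed,
        "parameters": config.parameters(),
        "n_genes": universe,
        "n_samples": len(matrix.samples),
        "n_cortex": int(sum(c == "cortex" for c in matrix.compartment)),
        "n_medulla": int(sum(c == "medulla" for c in matrix.compartment)),
        "stage_counts": {
            "per_bait_top": per_bait_top,
            "intersection": n_intersection,
            "pass_enrichment": n_enriched,
            "after_exclusion": n_after_exclusion,
            "gwas_annotated": n_gwas,
        },
    }
    return table, manifest


def write_outputs(
    table: CandidateTable, manifest: dict, out_dir, plot: bool = False
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_tsv(out / "candidates.tsv")
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if plot:
        plot_stage_counts(manifest, out / "stage_counts.png")


def plot_stage_counts(manifest: dict, path) -> None:
    """Bar chart of gene counts surviving each screen stage."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = manifest["stage_counts"]
    names = list(counts)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(range(len(names)), [counts[n] for n in names], color="#4878b0")
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("genes")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
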