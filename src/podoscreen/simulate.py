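"""Synthetic bulk kidney transcriptomes from a cell-type mixture model.

Bulk RNA-seq of a tissue averages the transcriptomes of its constituent
cell types, weighted by their (unknown, sample-varying) proportions.  The
marker screen exploits exactly this: genes specific to one cell type rise
and fall together across bulk samples because they share that cell type's
proportion.  The generator makes that structure explicit:

* each sample draws cell-type fractions from a Dirichlet whose
  concentration vector depends on the compartment — cortex samples contain
  a podocyte component, medulla samples essentially none (glomeruli reside
  in the cortex, emulated by a near-zero medulla podocyte alpha);
* each gene has a baseline mean drawn log-uniformly over four orders of
  magnitude; a signature gene is elevated ``signature_strength``-fold in
  its own cell type;
* expression = (fractions @ cell-type means) x multiplicative log-normal
  noise, then each sample column is rescaled to sum to 1e6 (TPM), which
  reproduces the compositional coupling of real TPM data.

Four podocyte signature genes are designated as analogs of the bait
markers NPHS1/NPHS2/PTPRO/PLA2R1 (carrying their real Ensembl ids and
symbols), and the first mesangial/endothelial/blood signature genes are
PDGFRB/PECAM1/ABO analogs, so the default :class:`~podoscreen.screen.MarkerPanel`
works on simulated matrices unchanged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genes import BAIT_GENES, CONTAMINANT_GENES, GeneId
from .io import ExpressionMatrix
from .screen import CandidateTable

CELL_TYPES = ("podocyte", "mesangial", "endothelial", "blood", "tubular", "background")

#: Cell types whose signature genes count as contaminant leak if they
#: survive the podocyte screen.
CONTAMINANT_CELL_TYPES = ("mesangial", "endothelial", "blood")

_DEFAULT_SIGNATURE_SIZES = {
    "podocyte": 300,
    "mesangial": 100,
    "endothelial": 100,
    "blood": 100,
    "tubular": 200,
}

_DEFAULT_ALPHA_CORTEX = {
    "podocyte": 1.0,
    "mesangial": 0.8,
    "endothelial": 0.8,
    "blood": 0.3,
    "tubular": 4.0,
    "background": 1.6,
}

_DEFAULT_ALPHA_MEDULLA = {
    "podocyte": 0.01,
    "mesangial": 0.5,
    "endothelial": 0.8,
    "blood": 0.3,
    "tubular": 5.0,
    "background": 1.6,
}


@dataclass
class MixtureModelSpec:
    """Generative parameters of the synthetic bulk transcriptome.

    Defaults mirror the screened study design: 85 cortex + 4 medulla
    samples, 300 planted podocyte signature genes (four of which are the
    bait analogs), 100 markers each for the mesangial/endothelial/blood
    contaminant types, tenfold signature elevation and log-normal noise
    with sigma 0.3 on the natural-log scale.
    """

    n_genes: int = 5000
    n_cortex: int = 85
    n_medulla: int = 4
    cell_types: Tuple[str, ...] = CELL_TYPES
    signature_genes: Optional[Dict[str, Tuple[int, ...]]] = None
    signature_strength: float = 10.0
    dirichlet_alpha_cortex: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ALPHA_CORTEX)
    )
    dirichlet_alpha_medulla: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ALPHA_MEDULLA)
    )
    noise_sigma: float = 0.3
    base_expression_range: Tuple[float, float] = (1.0, 1e4)
    seed: int = 0

    def __post_init__(self):
        if self.n_cortex < 3:
            raise ValidationError("n_cortex must be >= 3")
        if self.n_medulla < 0:
            raise ValidationError("n_medulla must be >= 0")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.signature_strength <= 1.0:
            raise ValidationError("signature_strength must be > 1")
        if self.noise_sigma < 0.0:
            raise ValidationError("noise_sigma must be >= 0")
        lo, hi = self.base_expression_range
        if not (0 < lo <= hi):
            raise ValidationError("base_expression_range must be 0 < lo <= hi")
        if self.signature_genes is None:
            self.signature_genes = self._default_signature_blocks()
        # invariants: disjoint signature sets, indices in range, alphas > 0
        seen: Set[int] = set()
        for ct, idx in self.signature_genes.items():
            if ct not in self.cell_types:
                raise ValidationError(f"signature for unknown cell type {ct!r}")
            s = set(idx)
            if s & seen:
                raise ValidationError("signature gene sets must be disjoint")
            if s and (min(s) < 0 or max(s) >= self.n_genes):
                raise ValidationError("signature gene index out of range")
            seen |= s
        for name, alphas in (
            ("cortex", self.dirichlet_alpha_cortex),
            ("medulla", self.dirichlet_alpha_medulla),
        ):
            for ct in self.cell_types:
                a = alphas.get(ct)
                if a is None or a <= 0.0:
                    raise ValidationError(
                        f"dirichlet_alpha_{name}[{ct!r}] must be > 0 "
                        "(use a tiny value such as 0.01 for a near-absent type)"
                    )

    def _default_signature_blocks(self) -> Dict[str, Tuple[int, ...]]:
        blocks: Dict[str, Tuple[int, ...]] = {}
        start = 0
        for ct in self.cell_types:
            size = _DEFAULT_SIGNATURE_SIZES.get(ct, 0)
            size = min(size, max(0, self.n_genes - start))
            blocks[ct] = tuple(range(start, start + size))
            start += size
        return blocks

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModelSpec":
        d = dict(d)
        if "cell_types" in d:
            d["cell_types"] = tuple(d["cell_types"])
        if d.get("signature_genes") is not None:
            d["signature_genes"] = {
                k: tuple(v) for k, v in d["signature_genes"].items()
            }
        if "base_expression_range" in d:
            d["base_expression_range"] = tuple(d["base_expression_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator planted: fractions, means and marker labels."""

    fractions: pd.DataFrame  # samples x cell types
    mu: np.ndarray  # genes x cell types
    gene_labels: List[str]  # cell type of each gene, or "background"
    markers: Dict[str, List[str]]  # cell type -> gene keys
    bait_keys: List[str]
    contaminant_keys: Dict[str, str]  # cell type -> marker gene key
    spec: MixtureModelSpec

    def podocyte_markers(self, exclude_baits: bool = True) -> Set[str]:
        keys = set(self.markers.get("podocyte", []))
        return keys - set(self.bait_keys) if exclude_baits else keys

    def contaminant_markers(self) -> Set[str]:
        out: Set[str] = set()
        for ct in CONTAMINANT_CELL_TYPES:
            out |= set(self.markers.get(ct, []))
        return out

    def to_json(self, path) -> None:
        payload = {
            "fractions": {
                s: [float(v) for v in row]
                for s, row in zip(self.fractions.index, self.fractions.to_numpy())
            },
            "cell_types": list(self.fractions.columns),
            "gene_labels": self.gene_labels,
            "markers": self.markers,
            "bait_keys": self.bait_keys,
            "contaminant_keys": self.contaminant_keys,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _gene_ids(spec: MixtureModelSpec) -> List[GeneId]:
    """Synthetic Ensembl-style ids, with real ids on the marker analogs."""
    ids: List[GeneId] = []
    for i in range(spec.n_genes):
        ids.append(GeneId(f"ENSG{90000000000 + i:011d}", 1, None))
    pod = spec.signature_genes.get("podocyte", ())
    for slot, (ensembl, version, symbol) in zip(pod[:4], BAIT_GENES):
        ids[slot] = GeneId(ensembl, version, symbol)
    for ct, (ensembl, version, symbol) in CONTAMINANT_GENES.items():
        block = spec.signature_genes.get(ct, ())
        if block:
            ids[block[0]] = GeneId(ensembl, version, symbol)
    return ids


def simulate_matrix(spec: MixtureModelSpec) -> Tuple[ExpressionMatrix, GroundTruth]:
    """Draw one synthetic TPM matrix and its ground truth, reproducibly."""
    rng = np.random.default_rng(spec.seed)
    C = len(spec.cell_types)
    lo, hi = spec.base_expression_range
    base = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), spec.n_genes)
    mu = np.repeat(base[:, None], C, axis=1)
    labels = ["background"] * spec.n_genes
    for ct, idx in spec.signature_genes.items():
        if not idx:
            continue
        col = spec.cell_types.index(ct)
        mu[list(idx), col] *= spec.signature_strength
        for i in idx:
            labels[i] = ct

    alpha_c = np.array([spec.dirichlet_alpha_cortex[ct] for ct in spec.cell_types])
    alpha_m = np.array([spec.dirichlet_alpha_medulla[ct] for ct in spec.cell_types])
    frac_cortex = rng.dirichlet(alpha_c, spec.n_cortex)
    frac_medulla = (
        rng.dirichlet(alpha_m, spec.n_medulla)
        if spec.n_medulla
        else np.zeros((0, C))
    )
    fractions = np.vstack([frac_cortex, frac_medulla])

    expr = mu @ fractions.T  # genes x samples
    if spec.noise_sigma > 0:
        expr = expr * np.exp(rng.normal(0.0, spec.noise_sigma, expr.shape))
    tpm = expr / expr.sum(axis=0, keepdims=True) * 1e6

    samples = [f"cortex_{i + 1:03d}" for i in range(spec.n_cortex)] + [
        f"medulla_{i + 1:03d}" for i in range(spec.n_medulla)
    ]
    compartment = ["cortex"] * spec.n_cortex + ["medulla"] * spec.n_medulla
    genes = _gene_ids(spec)
    matrix = ExpressionMatrix(genes, samples, tpm, compartment)

    keys = [g.key for g in genes]
    markers = {
        ct: [keys[i] for i in idx] for ct, idx in spec.signature_genes.items() if idx
    }
    pod = spec.signature_genes.get("podocyte", ())
    bait_keys = [keys[i] for i in pod[:4]]
    contaminant_keys = {
        ct: keys[spec.signature_genes[ct][0]]
        for ct in CONTAMINANT_CELL_TYPES
        if spec.signature_genes.get(ct)
    }
    truth = GroundTruth(
        fractions=pd.DataFrame(
            fractions, index=samples, columns=list(spec.cell_types)
        ),
        mu=mu,
        gene_labels=labels,
        markers=markers,
        bait_keys=bait_keys,
        contaminant_keys=contaminant_keys,
        spec=spec,
    )
    return matrix, truth


@dataclass(frozen=True)
class RecoveryReport:
    """How well the screen recovered the planted podocyte markers."""

    sensitivity: float
    precision: float
    precision_defined: bool
    contaminant_leak: int
    n_survivors: int
    survivors: frozenset


def recovery_report(table: CandidateTable, truth: GroundTruth) -> RecoveryReport:
    """Sensitivity / precision of the surviving set against planted truth.

    Sensitivity: fraction of planted podocyte signature genes (bait analogs
    excluded) that survive every filter.  Precision: fraction of survivors
    that are planted podocyte genes.  With no survivors the precision is
    undefined (NaN, flagged).  Contaminant leak counts survivors planted as
    mesangial/endothelial/blood signatures.
    """
    truth_keys = set()
    for ct, keys in truth.markers.items():
        truth_keys |= set(keys)
    table_keys = set(table.df.index)
    if not truth_keys <= table_keys:
        missing = sorted(truth_keys - table_keys)[:5]
        raise ValidationError(
            f"table does not cover the simulated gene universe (missing {missing})"
        )
    survivors = set(table.survivors())
    planted = truth.podocyte_markers(exclude_baits=True)
    hits = survivors & planted
    sensitivity = len(hits) / len(planted) if planted else math.nan
    if survivors:
        precision, defined = len(hits) / len(survivors), True
    else:
        precision, defined = math.nan, False
    leak = len(survivors & truth.contaminant_markers())
    return RecoveryReport(
        sensitivity=sensitivity,
        precision=precision,
        precision_defined=defined,
        contaminant_leak=leak,
        n_survivors=len(survivors),
        survivors=frozenset(survivors),
    )
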