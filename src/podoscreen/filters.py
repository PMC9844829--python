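"""Candidate filters: cortex/medulla enrichment, contaminant exclusion, GWAS.

Three independent filters mirror the screen's triage of intersection
candidates:

* **compartment enrichment** — mean TPM over cortex samples divided by mean
  TPM over medulla samples; podocytes live in glomeruli, which reside in the
  cortex, so genuine podocyte transcripts should be cortex-enriched.
  Candidates with fold >= threshold (default 1.5) pass; the rest are flagged
  out but retained.
* **contaminant exclusion** — candidates appearing in the top fraction
  (default 1%) of the correlation ranking of any contaminant cell-type
  marker (mesangial PDGFRB, endothelial PECAM1, blood ABO) are flagged with
  that cell type; exclusion by any one list suffices (union semantics).
* **GWAS cross-referencing** — candidates are annotated with every trait
  whose catalog contains them (case-insensitive symbol match, or Ensembl id).

The filters touch disjoint columns of the CandidateTable, so their
composition is order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np

from .errors import ConfigurationError, GeneLookupError, ParameterError, ValidationError
from .genes import GeneId, parse_gene_id
from .io import ExpressionMatrix
from .screen import (
    CandidateTable,
    MarkerPanel,
    correlate_bait,
    top_fraction,
)


@dataclass(frozen=True)
class EnrichmentRecord:
    """Cortex vs medulla mean-TPM ratio for one gene.

    ``fold`` is +inf when the medulla mean is 0 and the cortex mean is
    positive; when both means are 0 the fold is undefined and flagged.
    """

    gene: str
    cortex_mean_tpm: float
    medulla_mean_tpm: float
    fold: float
    undefined: bool = False


@dataclass(frozen=True)
class GwasCatalog:
    """A named trait with its associated gene symbols / Ensembl ids."""

    trait: str
    genes: frozenset

    @classmethod
    def from_symbols(cls, trait: str, symbols: Iterable[str]) -> "GwasCatalog":
        norm = frozenset(s.strip().upper() for s in symbols if s.strip())
        if not norm:
            raise ValidationError(f"GWAS catalog {trait!r} has no genes")
        return cls(trait, norm)

    @classmethod
    def from_file(cls, trait: str, path) -> "GwasCatalog":
        lines = Path(path).read_text().splitlines()
        return cls.from_symbols(trait, lines)

    def __contains__(self, item) -> bool:
        if isinstance(item, GeneId):
            return item.key.upper() in self.genes or (
                item.symbol or ""
            ).upper() in self.genes
        return str(item).strip().upper() in self.genes


# ---------------------------------------------------------------------------
# enrichment


def _compartment_means(matrix: ExpressionMatrix):
    cortex = matrix.sample_indices("cortex")
    medulla = matrix.sample_indices("medulla")
    if len(cortex) < 1 or len(medulla) < 1:
        raise ConfigurationError(
            f"enrichment needs >= 1 cortex and >= 1 medulla sample "
            f"(found {len(cortex)} cortex, {len(medulla)} medulla)"
        )
    return matrix.tpm[:, cortex].mean(axis=1), matrix.tpm[:, medulla].mean(axis=1)


def _fold(cortex_mean: float, medulla_mean: float, pseudocount: float):
    c, m = cortex_mean + pseudocount, medulla_mean + pseudocount
    if m > 0.0:
        return c / m, False
    if c > 0.0:
        return math.inf, False
    return math.nan, True


def compartment_enrichment(
    matrix: ExpressionMatrix,
    gene: Union[GeneId, str],
    pseudocount: float = 0.0,
) -> EnrichmentRecord:
    """Cortex-mean / medulla-mean TPM for one gene (plain arithmetic means).

    The medulla samples are few and unmatched to the cortex samples, so no
    pairing is attempted.  ``pseudocount`` (default 0) is added to both
    means before dividing, for callers who prefer finite folds.
    """
    if pseudocount < 0:
        raise ParameterError("pseudocount must be >= 0")
    i = matrix.gene_index(gene)
    cortex_means, medulla_means = _compartment_means(matrix)
    c, m = float(cortex_means[i]), float(medulla_means[i])
    fold, undefined = _fold(c, m, pseudocount)
    return EnrichmentRecord(matrix.genes[i].key, c, m, fold, undefined)


def enrichment_records(
    matrix: ExpressionMatrix,
    genes: Optional[Iterable] = None,
    pseudocount: float = 0.0,
) -> Dict[str, EnrichmentRecord]:
    """Enrichment records for many genes at once (all genes by default)."""
    if pseudocount < 0:
        raise ParameterError("pseudocount must be >= 0")
    cortex_means, medulla_means = _compartment_means(matrix)
    if genes is None:
        rows = range(matrix.n_genes())
    else:
        rows = [matrix.gene_index(g) for g in genes]
    out = {}
    for i in rows:
        c, m = float(cortex_means[i]), float(medulla_means[i])
        fold, undefined = _fold(c, m, pseudocount)
        key = matrix.genes[i].key
        out[key] = EnrichmentRecord(key, c, m, fold, undefined)
    return out


def filter_by_enrichment(
    table: CandidateTable,
    threshold: float,
    records: Dict[str, EnrichmentRecord],
) -> CandidateTable:
    """Flag candidates by cortex enrichment: pass iff fold >= threshold.

    Candidates failing the threshold stay in the table with
    ``passes_enrichment = False`` ("not considered further", not deleted).
    An infinite fold passes any finite threshold; an undefined fold
    (both means zero) fails and remains flagged on the record.
    """
    if threshold <= 0:
        raise ParameterError(f"enrichment threshold must be > 0, got {threshold}")
    out = table.copy()
    missing = [
        k for k in out.df.index[out.df["in_intersection"]] if k not in records
    ]
    if missing:
        raise ValidationError(
            f"no enrichment record for in-intersection candidates: {missing[:10]}"
        )
    for key, rec in records.items():
        if key not in out.df.index:
            continue
        out.df.at[key, "cortex_mean_tpm"] = rec.cortex_mean_tpm
        out.df.at[key, "medulla_mean_tpm"] = rec.medulla_mean_tpm
        out.df.at[key, "fold"] = rec.fold
        out.df.at[key, "passes_enrichment"] = bool(
            not rec.undefined and rec.fold >= threshold
        )
    out.params["enrichment_threshold"] = threshold
    return out


# ---------------------------------------------------------------------------
# contaminant exclusion


def contaminant_exclusion(
    matrix: ExpressionMatrix,
    table: CandidateTable,
    panel: MarkerPanel,
    q_neg: float = 0.01,
    compartments: Optional[Sequence[str]] = ("cortex",),
    method: Optional[str] = None,
    log2_transform: bool = False,
) -> CandidateTable:
    """Flag candidates co-ranking with contaminant cell-type markers.

    For each contaminant marker a correlation profile is computed with the
    same method and sample selection as the bait screen, and its top
    ``q_neg`` fraction (default 1%) is taken.  A candidate appearing in any
    such list gets that cell type appended to ``excluded_by``.
    """
    if not (0.0 < q_neg <= 1.0):
        raise ParameterError(f"q_neg must be in (0, 1], got {q_neg}")
    method = method or str(table.params.get("method", "pearson"))
    out = table.copy()
    universe = matrix.n_genes()
    exclusions: Dict[str, List[str]] = {}
    for cell_type, marker in panel.contaminants.items():
        if marker not in matrix:
            raise GeneLookupError(f"{marker} ({cell_type})")
        profile = correlate_bait(
            matrix, marker, compartments=compartments, method=method,
            log2_transform=log2_transform,
        )
        top = {g.key for g in top_fraction(profile, q_neg, universe)}
        for key in out.df.index[out.df["in_intersection"]]:
            if key in top:
                exclusions.setdefault(key, []).append(cell_type)
    for key, cell_types in exclusions.items():
        out.df.at[key, "excluded_by"] = ";".join(cell_types)
    out.params["q_neg"] = q_neg
    out.params["contaminants"] = list(panel.contaminants)
    return out


# ---------------------------------------------------------------------------
# GWAS cross-referencing


def gwas_crossref(
    table: CandidateTable, catalogs: Sequence[GwasCatalog]
) -> CandidateTable:
    """Annotate each gene with every trait whose catalog contains it.

    Matching is case-insensitive on upper-cased symbols, or exact on
    version-stripped Ensembl ids; unmatched genes simply stay unannotated.
    """
    out = table.copy()
    if not catalogs:
        return out
    symbols = out.df["symbol"].astype(str)
    for key in out.df.index:
        gid = GeneId(key) if key.startswith("ENSG") else parse_gene_id(key)
        sym = symbols.at[key]
        traits = [
            cat.trait
            for cat in catalogs
            if (key.upper() in cat.genes)
            or (sym and sym.upper() in cat.genes)
            or gid in cat
        ]
        if traits:
            out.df.at[key, "gwas_traits"] = ";".join(traits)
    out.params["gwas_traits"] = [c.trait for c in catalogs]
    return out
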