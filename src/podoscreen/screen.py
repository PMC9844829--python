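"""The marker-guided co-expression screen.

Each bait marker's TPM vector is correlated against every transcript over
the selected kidney-cortex samples, transcripts are ranked by descending
coefficient, the top fraction of each ranking is kept, and the per-bait
top lists are intersected.  Candidates are carried forward in a
:class:`CandidateTable` together with the full workflow state
(per-bait coefficients and ranks, intersection membership, enrichment
folds, exclusion flags, GWAS annotations).

Determinism: ties in coefficient are broken by ascending version-stripped
gene id; genes with undefined (zero-variance) coefficients rank after all
defined genes, again ordered lexicographically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    DegenerateBaitError,
    GeneLookupError,
    InsufficientSamplesError,
    ParameterError,
    ValidationError,
)
from .genes import BAIT_GENES, CONTAMINANT_GENES, GeneId, parse_gene_id
from .io import ExpressionMatrix

METHODS = ("pearson", "spearman")


@dataclass(frozen=True)
class MarkerPanel:
    """Bait (podocyte) and contaminant (other cell type) marker genes."""

    baits: Tuple[GeneId, ...] = tuple(
        GeneId(e, v, s) for e, v, s in BAIT_GENES
    )
    contaminants: Dict[str, GeneId] = field(
        default_factory=lambda: {
            name: GeneId(e, v, s) for name, (e, v, s) in CONTAMINANT_GENES.items()
        }
    )

    def __post_init__(self):
        if not self.baits:
            raise ValidationError("marker panel needs at least one bait")
        bait_keys = {b.key for b in self.baits}
        cont_keys = {g.key for g in self.contaminants.values()}
        if bait_keys & cont_keys:
            raise ValidationError(
                f"bait and contaminant sets overlap: {sorted(bait_keys & cont_keys)}"
            )

    def check_in_matrix(self, matrix: ExpressionMatrix) -> None:
        missing = [
            str(g)
            for g in (*self.baits, *self.contaminants.values())
            if g not in matrix
        ]
        if missing:
            raise GeneLookupError(", ".join(missing))


@dataclass
class CorrelationProfile:
    """Per-gene correlation coefficients and ranks against one bait.

    ``order`` lists gene row indices from rank 1 to rank G; ``ranks[i]`` is
    the rank of gene row ``i``.  Undefined coefficients are NaN and rank
    after every defined gene.
    """

    bait: GeneId
    method: str
    genes: List[GeneId]
    coefficients: np.ndarray
    ranks: np.ndarray
    order: np.ndarray

    def __len__(self) -> int:
        return len(self.genes)

    def coefficient_of(self, gene) -> float:
        key = gene.key if isinstance(gene, GeneId) else parse_gene_id(str(gene)).key
        for i, g in enumerate(self.genes):
            if g.key == key:
                return float(self.coefficients[i])
        raise GeneLookupError(key)


def _pearson_against(X: np.ndarray, bait_row: int) -> np.ndarray:
    """Row-wise Pearson r of every row of X against X[bait_row].

    Uses the n-1 (sample) convention in the variance terms; the convention
    cancels in the coefficient but is fixed here for the oracle tests.
    """
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", Xc, Xc) / (n - 1)
    x0 = Xc[bait_row]
    ss0 = ss[bait_row]
    cov = (Xc @ x0) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(ss * ss0)
    r[ss == 0.0] = np.nan
    return np.clip(r, -1.0, 1.0)


def correlate_bait(
    matrix: ExpressionMatrix,
    bait: Union[GeneId, str],
    compartments: Optional[Sequence[str]] = ("cortex",),
    method: str = "pearson",
    log2_transform: bool = False,
) -> CorrelationProfile:
    """Correlate every transcript with one bait over the selected samples.

    Parameters
    ----------
    compartments
        Sample labels to include; ``None`` selects every sample.  The
        default is cortex only — glomeruli (and podocytes) reside in the
        renal cortex, so that compartment carries the co-expression signal.
    method
        ``pearson`` on TPM values, or ``spearman`` (Pearson on within-gene
        sample ranks, average ties).
    log2_transform
        Apply log2(TPM + 1) before correlating.  Off by default: the screen
        operates on raw TPM.
    """
    if method not in METHODS:
        raise ParameterError(f"unknown correlation method: {method!r}")
    bait_idx = matrix.gene_index(bait)
    bait_gene = matrix.genes[bait_idx]
    if compartments is None:
        cols = np.arange(len(matrix.samples))
    else:
        cols = np.array(
            [j for j, c in enumerate(matrix.compartment) if c in compartments],
            dtype=int,
        )
    if len(cols) < 3:
        raise InsufficientSamplesError(
            f"correlation needs >= 3 samples, got {len(cols)} "
            f"(compartments={compartments})"
        )
    X = matrix.tpm[:, cols]
    if log2_transform:
        X = np.log2(X + 1.0)
    if np.ptp(X[bait_idx]) == 0.0:
        raise DegenerateBaitError(
            f"bait {bait_gene} has zero variance over the selected samples"
        )
    if method == "spearman":
        X = rankdata(X, axis=1)
    r = _pearson_against(np.ascontiguousarray(X, dtype=float), bait_idx)

    keys = np.array(matrix.gene_keys())
    primary = np.where(np.isnan(r), -np.inf, r)
    # lexsort: last key is primary -> descending coefficient, then id asc
    order = np.lexsort((keys, -primary))
    ranks = np.empty(len(r), dtype=int)
    ranks[order] = np.arange(1, len(r) + 1)
    return CorrelationProfile(
        bait=bait_gene,
        method=method,
        genes=list(matrix.genes),
        coefficients=r,
        ranks=ranks,
        order=order,
    )


def top_fraction(
    profile: CorrelationProfile, q: float, universe_size: int
) -> List[GeneId]:
    """The floor(q * universe_size) strongest-correlated genes, rank order.

    With the study's 56,200-transcript universe and q = 0.02 this retains
    exactly 1,124 transcripts per bait.  The list length is always
    floor(q * universe_size), with a minimum of 1.
    """
    if not (0.0 < q <= 1.0):
        raise ParameterError(f"top fraction q must be in (0, 1], got {q}")
    if universe_size != len(profile):
        raise ParameterError(
            f"universe_size {universe_size} != profile size {len(profile)}"
        )
    k = max(1, math.floor(q * universe_size))
    return [profile.genes[i] for i in profile.order[:k]]


def intersect_top_lists(lists: Sequence[Iterable]) -> set:
    """Genes present in every list (version-stripped identity)."""
    if len(lists) < 2:
        raise ParameterError("intersection needs >= 2 lists")
    sets = []
    for lst in lists:
        sets.append(
            {
                g.key if isinstance(g, GeneId) else parse_gene_id(str(g)).key
                for g in lst
            }
        )
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


# ---------------------------------------------------------------------------
# CandidateTable


@dataclass
class CandidateTable:
    """Workflow state for every gene in the screened matrix.

    ``df`` is indexed by version-stripped gene id with columns:
    symbol, is_bait, r_<bait>/rank_<bait> per bait, mean_rank,
    in_intersection, cortex_mean_tpm, medulla_mean_tpm, fold,
    passes_enrichment (nullable boolean until the filter runs),
    excluded_by (semicolon-joined cell types, '' = none),
    gwas_traits (semicolon-joined, '' = none).
    ``params`` records every threshold applied so far.
    """

    df: pd.DataFrame
    bait_keys: List[str]
    params: Dict[str, object] = field(default_factory=dict)

    def copy(self) -> "CandidateTable":
        return CandidateTable(self.df.copy(), list(self.bait_keys), dict(self.params))

    def candidates(self) -> pd.DataFrame:
        return self.df[self.df["in_intersection"]]

    def survivors(self) -> List[str]:
        """Non-bait candidates passing enrichment and no contaminant exclusion."""
        d = self.df
        mask = (
            d["in_intersection"]
            & (d["passes_enrichment"] == True)  # noqa: E712 (nullable boolean)
            & (d["excluded_by"] == "")
            & ~d["is_bait"]
        )
        return list(d.index[mask.fillna(False).astype(bool)])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="gene", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, bait_keys: Optional[List[str]] = None) -> "CandidateTable":
        df = pd.read_csv(path, sep="\t", index_col="gene", na_values=["NA"])
        if bait_keys is None:
            bait_keys = [c[len("rank_"):] for c in df.columns if c.startswith("rank_")]
        df["symbol"] = df["symbol"].fillna("").astype(str)
        for col in ("excluded_by", "gwas_traits"):
            df[col] = df[col].fillna("").astype(str)
        df["in_intersection"] = df["in_intersection"].astype(bool)
        df["is_bait"] = df["is_bait"].astype(bool)
        df["passes_enrichment"] = df["passes_enrichment"].astype("boolean")
        return cls(df, bait_keys)


def build_candidate_table(
    matrix: ExpressionMatrix,
    profiles: Dict[str, CorrelationProfile],
    q_bait: float,
    panel: Optional[MarkerPanel] = None,
) -> CandidateTable:
    """Assemble the per-gene table from per-bait profiles at fraction q_bait."""
    if len(profiles) < 2:
        raise ParameterError("the screen needs >= 2 bait profiles to intersect")
    universe = matrix.n_genes()
    top_lists = {
        key: top_fraction(p, q_bait, universe) for key, p in profiles.items()
    }
    intersection = intersect_top_lists(list(top_lists.values()))

    keys = matrix.gene_keys()
    data = {
        "symbol": [g.symbol or "" for g in matrix.genes],
        "is_bait": [k in profiles for k in keys],
    }
    rank_cols = []
    for bait_key, profile in profiles.items():
        data[f"r_{bait_key}"] = profile.coefficients
        data[f"rank_{bait_key}"] = profile.ranks
        rank_cols.append(f"rank_{bait_key}")
    df = pd.DataFrame(data, index=pd.Index(keys, name="gene"))
    df["mean_rank"] = df[rank_cols].mean(axis=1)
    df["in_intersection"] = [k in intersection for k in keys]
    df["cortex_mean_tpm"] = np.nan
    df["medulla_mean_tpm"] = np.nan
    df["fold"] = np.nan
    df["passes_enrichment"] = pd.array([pd.NA] * len(keys), dtype="boolean")
    df["excluded_by"] = ""
    df["gwas_traits"] = ""
    params: Dict[str, object] = {
        "q_bait": q_bait,
        "method": next(iter(profiles.values())).method,
        "universe_size": universe,
        "baits": list(profiles),
    }
    return CandidateTable(df, list(profiles), params)


def order_candidates(table: CandidateTable) -> List[str]:
    """Intersection candidates by ascending mean rank, ties by gene id."""
    cand = table.candidates()
    rank_cols = [f"rank_{b}" for b in table.bait_keys]
    missing = cand.index[cand[rank_cols].isna().any(axis=1)]
    if len(missing):
        raise ValidationError(
            f"candidates missing per-bait ranks: {sorted(missing)[:10]}"
        )
    # stable sort: index first, then mean_rank, so ties break lexicographically
    ordered = cand.sort_index(kind="mergesort").sort_values(
        "mean_rank", kind="mergesort"
    )
    return list(ordered.index)
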