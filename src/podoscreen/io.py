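"""Reading and writing TPM expression matrices (GCT 1.2 and plain TSV).

The in-memory container is :class:`ExpressionMatrix`: a genes x samples
array of TPM values plus a per-sample tissue-compartment label
(``cortex`` / ``medulla`` / ``unassigned``).  Missing values are not
permitted — the screen's rank cutoffs assume a fixed transcript universe,
so an absent gene must be an absent row, never a NaN cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    DuplicateGeneError,
    GeneLookupError,
    MatrixFormatError,
    ValidationError,
)
from .genes import GeneId, parse_gene_id

COMPARTMENTS = ("cortex", "medulla", "unassigned")

GeneLike = Union[GeneId, str]


@dataclass
class ExpressionMatrix:
    """A genes x samples TPM matrix with compartment labels."""

    genes: List[GeneId]
    samples: List[str]
    tpm: np.ndarray
    compartment: List[str]

    _index: Dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        self.tpm = np.asarray(self.tpm, dtype=float)
        if not self.genes or not self.samples:
            raise ValidationError("expression matrix must have >= 1 gene and sample")
        if self.tpm.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"tpm shape {self.tpm.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.compartment) != len(self.samples):
            raise ValidationError("compartment label list length != sample count")
        bad = set(self.compartment) - set(COMPARTMENTS)
        if bad:
            raise ValidationError(f"unknown compartment labels: {sorted(bad)}")
        if not np.isfinite(self.tpm).all():
            raise ValidationError("TPM matrix contains non-finite values")
        if (self.tpm < 0).any():
            raise ValidationError("TPM matrix contains negative values")
        keys = [g.key for g in self.genes]
        if len(set(keys)) != len(keys):
            seen, dups = set(), set()
            for k in keys:
                (dups if k in seen else seen).add(k)
            raise DuplicateGeneError(dups)
        self._index = {k: i for i, k in enumerate(keys)}

    # -- lookup helpers -------------------------------------------------

    def gene_index(self, gene: GeneLike) -> int:
        key = gene.key if isinstance(gene, GeneId) else parse_gene_id(str(gene)).key
        try:
            return self._index[key]
        except KeyError:
            raise GeneLookupError(key) from None

    def __contains__(self, gene: GeneLike) -> bool:
        key = gene.key if isinstance(gene, GeneId) else parse_gene_id(str(gene)).key
        return key in self._index

    def gene_keys(self) -> List[str]:
        return [g.key for g in self.genes]

    def sample_indices(self, label: str) -> np.ndarray:
        return np.array(
            [j for j, c in enumerate(self.compartment) if c == label], dtype=int
        )

    def n_genes(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.tpm, index=[g.versioned() for g in self.genes], columns=self.samples
        )


# ---------------------------------------------------------------------------
# parsing helpers


def _numeric_block(block: pd.DataFrame, path, gene_names: Sequence[str]) -> np.ndarray:
    """Convert a string DataFrame to floats, reporting the first bad cell."""
    converted = block.apply(pd.to_numeric, errors="coerce")
    bad = converted.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raw = block.iat[i, j]
        raise MatrixFormatError(
            f"{path}: non-numeric value {raw!r} at gene {gene_names[i]!r}, "
            f"sample {block.columns[j]!r} (row {i + 1}, column {j + 1} of the body)"
        )
    return converted.to_numpy(dtype=float)


def read_gct(path) -> ExpressionMatrix:
    """Read a GCT 1.2 file (the GTEx distribution format).

    Line 1 is the version tag, line 2 declares ``<rows>\\t<cols>``, and the
    body header is ``Name\\tDescription\\t<samples...>``.  Gene versions are
    parsed from dotted or comma-suffixed identifiers.  All compartments are
    initialized to ``unassigned``.
    """
    path = Path(path)
    with path.open() as fh:
        tag = fh.readline().rstrip("\n")
        if not tag.startswith("#1."):
            raise MatrixFormatError(
                f"{path}: line 1 is not a GCT version tag (found {tag!r})"
            )
        dims = fh.readline().rstrip("\n").split("\t")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except (ValueError, IndexError):
            raise MatrixFormatError(
                f"{path}: line 2 must declare '<#rows>\\t<#cols>'"
            ) from None
        body = pd.read_csv(fh, sep="\t", dtype=str)
    if list(body.columns[:2]) != ["Name", "Description"]:
        raise MatrixFormatError(
            f"{path}: body header must start with 'Name\\tDescription'"
        )
    samples = list(body.columns[2:])
    if len(body) != n_rows or len(samples) != n_cols:
        raise MatrixFormatError(
            f"{path}: dimension mismatch — header declares {n_rows} genes x "
            f"{n_cols} samples, body has {len(body)} genes x {len(samples)} samples"
        )
    names = body["Name"].tolist()
    descriptions = body["Description"].tolist()
    genes = [
        parse_gene_id(n, symbol=(d if isinstance(d, str) and d else None))
        for n, d in zip(names, descriptions)
    ]
    values = _numeric_block(body[samples], path, names)
    return ExpressionMatrix(genes, samples, values, ["unassigned"] * len(samples))


def read_tsv_matrix(
    path, compartment_map: Optional[Mapping[str, str]] = None
) -> ExpressionMatrix:
    """Read a plain TSV matrix: header of sample ids, first column gene ids.

    Samples named in ``compartment_map`` receive their label; all others
    are ``unassigned``.
    """
    path = Path(path)
    body = pd.read_csv(path, sep="\t", dtype=str)
    if body.shape[1] < 2:
        raise MatrixFormatError(f"{path}: expected gene column plus >= 1 sample")
    gene_col = body.columns[0]
    samples = list(body.columns[1:])
    names = body[gene_col].tolist()
    genes = [parse_gene_id(n) for n in names]
    values = _numeric_block(body[samples], path, names)
    compartment_map = dict(compartment_map or {})
    unknown = set(compartment_map.values()) - set(COMPARTMENTS)
    if unknown:
        raise ValidationError(f"unknown compartment labels: {sorted(unknown)}")
    compartment = [compartment_map.get(s, "unassigned") for s in samples]
    return ExpressionMatrix(genes, samples, values, compartment)


def write_tsv_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV; versioned gene ids serialize as ``ensembl.version``."""
    path = Path(path)
    try:
        matrix.to_frame().to_csv(path, sep="\t", index_label="gene")
    except OSError as exc:
        raise OSError(f"failed writing expression matrix to {path}: {exc}") from exc


def read_compartment_map(path) -> Dict[str, str]:
    """Read a two-column TSV of (sample_id, label)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise MatrixFormatError(f"{path}: compartment map needs two columns")
    # tolerate an optional header row
    if df.iloc[0, 1] not in COMPARTMENTS:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_compartment_map(matrix: ExpressionMatrix, path) -> None:
    with Path(path).open("w") as fh:
        for sample, label in zip(matrix.samples, matrix.compartment):
            fh.write(f"{sample}\t{label}\n")
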