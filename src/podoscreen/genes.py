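"""Gene identifiers with version-insensitive equality.

GTEx distributes Ensembl gene ids with a dotted version suffix
(``ENSG00000161270.19``); some published tables print the separator as a
comma instead.  Screening logic must treat all versions of a gene as the
same entity, so :class:`GeneId` hashes and compares on the version-stripped
accession only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import ValidationError

_ENSG_RE = re.compile(r"^(ENSG\d{11})(?:[.,](\d+))?$")

#: Bait podocyte markers used throughout (Ensembl id, version, symbol).
BAIT_GENES = (
    ("ENSG00000161270", 19, "NPHS1"),
    ("ENSG00000116218", 12, "NPHS2"),
    ("ENSG00000151490", 13, "PTPRO"),
    ("ENSG00000153246", 12, "PLA2R1"),
)

#: Contaminant cell-type markers: mesangial, endothelial, blood.
CONTAMINANT_GENES = {
    "mesangial": ("ENSG00000113721", None, "PDGFRB"),
    "endothelial": ("ENSG00000261371", None, "PECAM1"),
    "blood": ("ENSG00000175164", None, "ABO"),
}


@dataclass(frozen=True)
class GeneId:
    """An Ensembl (or free-form) gene identifier.

    Equality and hashing ignore ``version`` and ``symbol``: two GeneIds are
    the same gene iff their version-stripped accessions match.  This is the
    identity used for every membership test in the screen.
    """

    ensembl_id: str
    version: Optional[int] = None
    symbol: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        if not self.ensembl_id:
            raise ValidationError("empty gene identifier")
        if self.ensembl_id.startswith("ENSG") and not re.fullmatch(
            r"ENSG\d{11}", self.ensembl_id
        ):
            raise ValidationError(
                f"malformed Ensembl gene id: {self.ensembl_id!r} "
                "(expected ENSG followed by 11 digits)"
            )

    def __eq__(self, other):
        if isinstance(other, GeneId):
            return self.ensembl_id == other.ensembl_id
        return NotImplemented

    def __hash__(self):
        return hash(self.ensembl_id)

    @property
    def key(self) -> str:
        """Version-stripped accession, the canonical dictionary key."""
        return self.ensembl_id

    def versioned(self) -> str:
        """Serialize as ``accession.version`` (dot separator, always)."""
        if self.version is None:
            return self.ensembl_id
        return f"{self.ensembl_id}.{self.version}"

    def __str__(self):
        return self.versioned()


def parse_gene_id(text: str, symbol: Optional[str] = None) -> GeneId:
    """Parse a gene identifier, accepting ``.`` or ``,`` version separators.

    Non-Ensembl identifiers (anything not starting with ``ENSG``) are kept
    verbatim with no version.
    """
    text = text.strip()
    m = _ENSG_RE.match(text)
    if m:
        version = int(m.group(2)) if m.group(2) is not None else None
        return GeneId(m.group(1), version, symbol)
    if text.startswith("ENSG"):
        raise ValidationError(f"malformed Ensembl gene id: {text!r}")
    return GeneId(text, None, symbol)


def strip_keys(genes: Iterable) -> list[str]:
    """Version-stripped keys for a mixed iterable of GeneId / strings."""
    out = []
    for g in genes:
        if isinstance(g, GeneId):
            out.append(g.key)
        else:
            out.append(parse_gene_id(str(g)).key)
    return out
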