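"""Gene signatures: the 11-gene HNF panel, AR target panels, and GMT I/O.

The HNF signature captures the gastrointestinal (GI) lineage transcription
program aberrantly activated in a subset of castration-resistant prostate
cancer (CRPC).  It comprises the two master transcription factors *HNF1A*
and *HNF4G* together with nine strong, direct downstream targets.

The AR (androgen receptor) score is computed over the union of two
published AR target-gene signatures.  The exact membership of those two
source lists is not redistributable here, so this module ships editable
synthetic placeholder lists of canonical AR target genes; replace them with
the published lists via GMT files for production use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GeneSignature",
    "hnf_signature",
    "ar_signature_10gene",
    "ar_signature_hieronymus",
    "ar_signature",
    "combine_signatures",
    "read_gmt",
    "write_gmt",
]

# Master regulators + 9 strong direct downstream targets of the GI program.
HNF_SIGNATURE_GENES = (
    "HNF1A",
    "HNF4G",
    "AKR1C3",
    "ANG",
    "APOH",
    "CLRN3",
    "GAS2",
    "METTL7B",
    "MUC13",
    "SGK2",
    "UGT2B15",
)

# Synthetic placeholder for a published 10-gene AR activity signature:
# canonical androgen-responsive genes, editable via GMT.
AR_10GENE_PLACEHOLDER = (
    "KLK3",
    "KLK2",
    "TMPRSS2",
    "FKBP5",
    "NKX3-1",
    "PLPP1",
    "PMEPA1",
    "ABCC4",
    "NALCN",
    "EAF2",
)

# Synthetic placeholder for the Hieronymus-style AR target signature:
# a broader curated AR target list overlapping the 10-gene panel, editable
# via GMT.
AR_HIERONYMUS_PLACEHOLDER = (
    "KLK3",
    "KLK2",
    "TMPRSS2",
    "FKBP5",
    "NKX3-1",
    "PMEPA1",
    "ABCC4",
    "ZBTB10",
    "EAF2",
    "HERC3",
    "PTGER4",
    "MAF",
    "ADAM7",
    "CENPN",
    "ELL2",
    "MED28",
    "MPHOSPH9",
    "ACSL3",
    "GNMT",
    "TNK1",
)


def _dedup(genes: Iterable[str]) -> tuple[str, ...]:
    """De-duplicate preserving first-seen order; trim whitespace."""
    seen: dict[str, None] = {}
    for g in genes:
        g = g.strip()
        if g and g not in seen:
            seen[g] = None
    return tuple(seen)


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered, de-duplicated list of gene symbols."""

    name: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        genes = _dedup(self.genes)
        if not genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def hnf_signature() -> GeneSignature:
    """The 11-gene HNF/GI-lineage signature (HNF1A, HNF4G + 9 targets)."""
    return GeneSignature("HNF", HNF_SIGNATURE_GENES)


def ar_signature_10gene() -> GeneSignature:
    """Placeholder 10-gene AR activity signature (editable stand-in)."""
    return GeneSignature("AR_10gene", AR_10GENE_PLACEHOLDER)


def ar_signature_hieronymus() -> GeneSignature:
    """Placeholder Hieronymus-style AR target signature (editable stand-in)."""
    return GeneSignature("AR_Hieronymus", AR_HIERONYMUS_PLACEHOLDER)


def combine_signatures(a: GeneSignature, b: GeneSignature, name: str) -> GeneSignature:
    """De-duplicated union of two signatures, preserving first-seen order."""
    return GeneSignature(name, (*a.genes, *b.genes))


def ar_signature() -> GeneSignature:
    """Combined AR panel: union of the two AR target signatures."""
    return combine_signatures(ar_signature_10gene(), ar_signature_hieronymus(), "AR")


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT file (name, description, then tab-separated symbols).

    Empty gene fields are skipped; duplicate symbols within a line are
    dropped.  Raises ``ValueError`` naming the offending line on malformed
    input (fewer than three tab-separated fields).
    """
    signatures = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} tab-separated "
                    "fields; GMT requires name, description and >=1 gene"
                )
            name, _desc, *genes = fields
            signatures.append(GeneSignature(name, genes))
    return signatures


def write_gmt(
    signatures: Sequence[GeneSignature],
    path: str | Path,
    descriptions: Sequence[str] | None = None,
) -> None:
    """Write signatures to a GMT file (one per line)."""
    if descriptions is None:
        descriptions = ["na"] * len(signatures)
    with open(path, "w") as fh:
        for sig, desc in zip(signatures, descriptions):
            fh.write("\t".join([sig.name, desc, *sig.genes]) + "\n")
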