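"""IUPAC motif scanning over pre-windowed promoter / 3'UTR sequences.

A motif's regulon is the set of genes whose supplied 1 kb window carries at
least one instance of the motif on the given strand. Sequences arrive
pre-extracted (FASTA keyed by gene or transcript id); no genome coordinate
arithmetic happens here.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Union

from Bio import SeqIO

from pcmkit.io import GeneModule, ModuleCategory

__all__ = ["MotifRegion", "MotifKind", "IupacMotif", "scan_motif", "iupac_to_regex"]

# IUPAC nucleotide codes (DNA alphabet; U is normalized to T on input).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


class MotifRegion(str, Enum):
    promoter_1kb = "promoter_1kb"
    utr3_1kb = "utr3_1kb"


class MotifKind(str, Enum):
    dna = "dna"
    rna_linear = "rna_linear"


@dataclass(frozen=True)
class IupacMotif:
    pattern: str
    region: MotifRegion = MotifRegion.promoter_1kb
    kind: MotifKind = MotifKind.dna

    def __post_init__(self) -> None:
        pat = self.pattern.upper().replace("U", "T")
        object.__setattr__(self, "pattern", pat)
        if len(pat) < 4:
            raise ValueError(f"motif {pat!r} shorter than 4 characters")
        for i, ch in enumerate(pat):
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC code {ch!r} at position {i} of {pat!r}")


def iupac_to_regex(pattern: str) -> str:
    """Expand an IUPAC pattern into a plain character-class regex."""
    parts = []
    for ch in pattern.upper().replace("U", "T"):
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def _load_sequences(sequences) -> dict[str, str]:
    if isinstance(sequences, Mapping):
        return {str(k): str(v) for k, v in sequences.items()}
    # anything else is treated as a FASTA path / handle
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(sequences, "fasta")}
    return records


def scan_motif(
    motif: IupacMotif,
    sequences: Union[Mapping[str, str], str],
    name: str | None = None,
) -> GeneModule | None:
    """Build the motif's regulon: genes with ≥1 match in their window.

    Scanning is single-strand on the provided sequence. RNA motifs are
    matched with U/T treated as equivalent. A motif matching nothing yields
    ``None`` with a warning (such empty regulons are dropped before
    scoring).
    """
    seqs = _load_sequences(sequences)
    if not seqs:
        raise ValueError("no sequences supplied (empty FASTA)")
    rx = re.compile(iupac_to_regex(motif.pattern))
    hits = {gid for gid, seq in seqs.items() if rx.search(seq.upper().replace("U", "T"))}
    if not hits:
        warnings.warn(f"motif {motif.pattern} matched no sequence; empty regulon dropped")
        return None
    category = (
        ModuleCategory.dna_motif if motif.kind == MotifKind.dna
        else ModuleCategory.rna_motif_linear
    )
    return GeneModule(
        name or f"{motif.kind.value}:{motif.pattern}",
        frozenset(hits),
        category,
        source=f"{motif.region.value}",
    )
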