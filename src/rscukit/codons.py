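"""Standard genetic code, CDS parsing, codon counting, and gene-list filtering.

Codon usage is represented as a length-64 vector over the DNA codons in
alphabetical order (AAA, AAC, ..., TTT).  Amino acids use one-letter symbols
with ``*`` for stop; display helpers use three-letter names (``Leu-CTG``)
as codon-usage tables conventionally do.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

#: All 64 DNA codons in alphabetical order.
CODONS: tuple[str, ...] = tuple("".join(p) for p in product("ACGT", repeat=3))

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

AA_THREE: dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Stop",
}


class MalformedCDSError(ValueError):
    """CDS length is not a multiple of three, or the sequence is empty."""


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T}."""


class EmptyCollectionError(ValueError):
    """No coding sequences remain after filtering."""


@dataclass(frozen=True)
class GeneticCode:
    """Mapping from codons to amino acids plus synonymous-family structure.

    Attributes
    ----------
    codon_to_aa
        All 64 codons mapped to a one-letter amino-acid symbol (``*`` = stop).
    degeneracy
        Number of synonymous codons per amino acid (stops excluded).
    families
        Amino acid -> tuple of its synonymous codons, alphabetical.
    """

    codon_to_aa: dict[str, str]
    degeneracy: dict[str, int] = field(default_factory=dict)
    families: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.codon_to_aa[c] == "*")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.codon_to_aa[c] != "*")


def standard_genetic_code() -> GeneticCode:
    """Return the standard genetic code (NCBI translation table 1).

    61 sense codons encode the 20 standard amino acids; TGA, TAG and TAA
    are stops; Met (ATG) and Trp (TGG) are the only single-codon families.
    """
    table = CodonTable.unambiguous_dna_by_id[1]
    codon_to_aa = {c: "*" for c in table.stop_codons}
    codon_to_aa.update(table.forward_table)
    codon_to_aa = {c: codon_to_aa[c] for c in CODONS}
    families: dict[str, list[str]] = {}
    for codon in CODONS:
        aa = codon_to_aa[codon]
        if aa != "*":
            families.setdefault(aa, []).append(codon)
    fam = {aa: tuple(sorted(cs)) for aa, cs in families.items()}
    degeneracy = {aa: len(cs) for aa, cs in fam.items()}
    return GeneticCode(codon_to_aa=codon_to_aa, degeneracy=degeneracy, families=fam)


@dataclass(frozen=True)
class CodingSequence:
    """A pre-extracted CDS: in-frame, DNA alphabet, length divisible by 3."""

    gene_id: str
    sequence: str


def count_codons(cds: CodingSequence | str, gene_id: str = "") -> np.ndarray:
    """Count non-overlapping triplets of a CDS from frame 0.

    Returns a length-64 float vector in :data:`CODONS` order summing to
    ``len(sequence) / 3``.  Lowercase input is uppercased; ``U`` (RNA) is
    rejected — inputs are DNA by convention.
    """
    seq = cds.sequence if isinstance(cds, CodingSequence) else cds
    name = cds.gene_id if isinstance(cds, CodingSequence) else gene_id
    seq = seq.upper()
    if len(seq) == 0 or len(seq) % 3 != 0:
        raise MalformedCDSError(
            f"CDS {name!r}: length {len(seq)} is empty or not a multiple of 3"
        )
    bad = set(seq) - set("ACGT")
    if bad:
        raise AlphabetError(f"CDS {name!r}: non-ACGT characters {sorted(bad)}")
    counts = np.zeros(64, dtype=float)
    for i in range(0, len(seq), 3):
        counts[CODON_INDEX[seq[i : i + 3]]] += 1.0
    return counts


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list: one id per line, ``#`` comments allowed."""
    ids: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return ids


def load_cds_collection(
    fasta_path: str | Path,
    pseudogene_blacklist: set[str] | frozenset[str] = frozenset(),
) -> dict[str, np.ndarray]:
    """Load a CDS FASTA into per-gene codon-count vectors.

    The gene id is the first whitespace-separated token of each header.
    Blacklisted (pseudogene) ids are dropped; for duplicated ids only the
    first record is kept (with a warning).  Raises
    :class:`EmptyCollectionError` if nothing survives filtering.
    """
    counts: dict[str, np.ndarray] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        gene_id = record.id
        if gene_id in pseudogene_blacklist:
            continue
        if gene_id in counts:
            warnings.warn(f"duplicate gene id {gene_id!r}: keeping first record")
            continue
        counts[gene_id] = count_codons(str(record.seq), gene_id=gene_id)
    if not counts:
        raise EmptyCollectionError(
            f"no coding sequences retained from {fasta_path} after filtering"
        )
    return counts
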