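"""Alignments, supermatrices and missing-data accounting.

A supermatrix is the concatenation of single-gene alignments into one
matrix with named, contiguous gene partitions.  Taxa absent from a gene
are padded with ``'?'``, so missing data are a first-class property of
the container: :func:`missing_fraction` and :func:`per_taxon_missing`
quantify them, and :func:`subset_taxa` supports taxon-sampling
experiments.

File parsing and writing delegate to Biopython (FASTA, relaxed PHYLIP,
NEXUS character matrices); this module adds validation with informative
errors and the partition bookkeeping Biopython does not track.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PsqcError",
    "FormatError",
    "Alignment",
    "Partition",
    "SuperMatrix",
    "read_alignment",
    "write_alignment",
    "read_partition_table",
    "write_partition_table",
    "concatenate",
    "missing_fraction",
    "per_taxon_missing",
    "subset_taxa",
]


class PsqcError(Exception):
    """Base class for errors raised by this package."""


class FormatError(PsqcError):
    """A file or matrix violates the expected format."""


#: Residue symbols accepted per alphabet (beyond the missing symbols).
NT_CHARS = frozenset("ACGTURYSWKMBDHV")
AA_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYBZJ")

#: Symbols treated as missing data.  Gaps count as missing: the
#: missing-data statistics do not distinguish indels from absent
#: sequence, since incomplete sequences and gaps erode signal alike.
MISSING_SYMBOLS = {
    "nt": frozenset("-?N"),
    "aa": frozenset("-?X"),
    "mixed": frozenset("-?XN"),
}

_VALID_CHARS = {
    "nt": NT_CHARS | MISSING_SYMBOLS["nt"],
    "aa": AA_CHARS | MISSING_SYMBOLS["aa"],
    "mixed": NT_CHARS | AA_CHARS | MISSING_SYMBOLS["mixed"],
}

ALPHABETS = ("nt", "aa", "mixed")


def _infer_alphabet(chars: frozenset) -> str:
    for alphabet in ("nt", "aa", "mixed"):
        if chars <= _VALID_CHARS[alphabet]:
            return alphabet
    bad = sorted(chars - _VALID_CHARS["mixed"])
    raise FormatError(f"characters not in any supported alphabet: {bad}")


@dataclass(frozen=True)
class Alignment:
    """A rectangular multiple sequence alignment.

    Parameters
    ----------
    taxa:
        Ordered, unique, non-empty taxon names.
    data:
        Character matrix of shape ``(len(taxa), length)``, dtype ``<U1``,
        uppercase.
    alphabet:
        ``'nt'``, ``'aa'`` or ``'mixed'`` (a concatenation of both).
    """

    taxa: tuple[str, ...]
    data: np.ndarray
    alphabet: str

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if len(self.taxa) != len(set(self.taxa)):
            seen, dup = set(), None
            for t in self.taxa:
                if t in seen:
                    dup = t
                    break
                seen.add(t)
            raise FormatError(f"duplicate taxon name {dup!r}")
        if any(not t for t in self.taxa):
            raise FormatError("empty taxon name")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise FormatError("data shape does not match taxa")
        present = frozenset(np.unique(self.data).tolist())
        bad = present - _VALID_CHARS[self.alphabet]
        if bad:
            raise FormatError(
                f"characters {sorted(bad)} invalid for alphabet {self.alphabet!r}"
            )

    # -- construction ------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str]],
        alphabet: str | None = None,
    ) -> "Alignment":
        """Build an alignment from ``(taxon, sequence)`` pairs.

        Sequences are uppercased; all rows must have equal length.  The
        alphabet is inferred when not given (nucleotide if every symbol
        fits the nucleotide set, else amino acid, else mixed).
        """
        records = list(records)
        if not records:
            raise FormatError("empty alignment: no sequences")
        taxa = tuple(name for name, _ in records)
        length = len(records[0][1])
        for name, seq in records:
            if len(seq) != length:
                raise FormatError(
                    f"ragged alignment: row for taxon {name!r} has length "
                    f"{len(seq)}, expected {length}"
                )
        if length == 0:
            raise FormatError("empty alignment: zero columns")
        data = np.array(
            [list(seq.upper()) for _, seq in records], dtype="<U1"
        )
        if alphabet is None:
            alphabet = _infer_alphabet(frozenset(np.unique(data).tolist()))
        return cls(taxa=taxa, data=data, alphabet=alphabet)

    # -- basic queries -----------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        """Number of columns (sites), 1-based inclusive in reports."""
        return self.data.shape[1]

    def row(self, taxon: str) -> str:
        return "".join(self.data[self.taxa.index(taxon)])

    def to_records(self) -> list[tuple[str, str]]:
        return [(t, "".join(r)) for t, r in zip(self.taxa, self.data)]

    def missing_mask(self) -> np.ndarray:
        """Boolean matrix marking missing cells under this alphabet."""
        symbols = sorted(MISSING_SYMBOLS[self.alphabet])
        return np.isin(self.data, symbols)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.alphabet == other.alphabet
            and self.data.shape == other.data.shape
            and bool((self.data == other.data).all())
        )

    def __hash__(self) -> int:  # frozen dataclass with ndarray field
        return hash((self.taxa, self.alphabet, self.data.tobytes()))


@dataclass(frozen=True)
class Partition:
    """A contiguous gene block: 1-based inclusive column range."""

    name: str
    start: int
    end: int
    alphabet: str = "aa"
    model_hint: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("partition name must be non-empty")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"partition {self.name!r}: invalid range {self.start}-{self.end}"
            )
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"partition {self.name!r}: unknown alphabet")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def columns(self) -> slice:
        """0-based column slice into the supermatrix data."""
        return slice(self.start - 1, self.end)


@dataclass(frozen=True)
class SuperMatrix:
    """A concatenated alignment with named gene partitions.

    ``events`` records provenance annotations such as implanted
    transfers (see the synthetic-data module); it does not affect any
    computation.
    """

    alignment: Alignment
    partitions: tuple[Partition, ...]
    events: tuple[dict, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        length = self.alignment.length
        covered = np.zeros(length, dtype=bool)
        names = set()
        for p in self.partitions:
            if p.name in names:
                raise FormatError(f"duplicate partition name {p.name!r}")
            names.add(p.name)
            if p.end > length:
                raise FormatError(
                    f"partition {p.name!r} ends at {p.end}, matrix has "
                    f"{length} columns"
                )
            block = covered[p.columns]
            if block.any():
                raise FormatError(f"partition {p.name!r} overlaps another")
            covered[p.columns] = True
        if not covered.all():
            raise FormatError("partitions do not cover every column")

    @property
    def taxa(self) -> tuple[str, ...]:
        return self.alignment.taxa

    def partition(self, name: str) -> Partition:
        for p in self.partitions:
            if p.name == name:
                return p
        raise KeyError(f"no partition named {name!r}")

    def extract_partition(
        self, name: str, drop_all_missing_taxa: bool = False
    ) -> Alignment:
        """The single-gene alignment for one partition.

        With ``drop_all_missing_taxa``, taxa whose whole block is
        missing (the concatenation fill) are removed, recovering the
        original gene alignment.
        """
        p = self.partition(name)
        data = self.alignment.data[:, p.columns]
        taxa = self.alignment.taxa
        if drop_all_missing_taxa:
            symbols = sorted(MISSING_SYMBOLS[p.alphabet])
            keep = ~np.isin(data, symbols).all(axis=1)
            data = data[keep]
            taxa = tuple(t for t, k in zip(taxa, keep) if k)
        return Alignment(taxa=taxa, data=data.copy(), alphabet=p.alphabet)

    def missing_mask(self) -> np.ndarray:
        """Missing-cell mask, evaluated per partition's own alphabet.

        ``'N'`` is a valid amino acid but missing as a nucleotide, so
        the mask must respect each gene's alphabet in mixed matrices.
        """
        mask = np.zeros(self.alignment.data.shape, dtype=bool)
        for p in self.partitions:
            symbols = sorted(MISSING_SYMBOLS[p.alphabet])
            mask[:, p.columns] = np.isin(self.alignment.data[:, p.columns], symbols)
        return mask


# ----------------------------------------------------------------------
# Reading and writing
# ----------------------------------------------------------------------

_FORMATS = ("fasta", "phylip", "nexus")


def read_alignment(path, format: str, alphabet: str | None = None) -> Alignment:
    """Read an alignment file (``fasta``, ``phylip`` or ``nexus``).

    PHYLIP may be sequential or interleaved with relaxed names; NEXUS
    reading covers the DATA/CHARACTERS matrix only (SETS/ASSUMPTIONS
    blocks are ignored with a warning).  Interleaved and sequential
    layouts of the same matrix yield identical alignments.
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    if format == "fasta":
        records = [
            (rec.id, str(rec.seq)) for rec in SeqIO.parse(io.StringIO(text), "fasta")
        ]
        if not records:
            raise FormatError(f"{path}: no FASTA records found")
        return Alignment.from_records(records, alphabet=alphabet)
    if format == "nexus":
        lowered = text.lower()
        if "begin sets" in lowered or "begin assumptions" in lowered:
            logger.warning(
                "%s: NEXUS SETS/ASSUMPTIONS blocks are ignored", path
            )
        try:
            msa = AlignIO.read(io.StringIO(text), "nexus")
        except Exception as exc:  # Bio.Nexus raises assorted exceptions
            raise FormatError(f"{path}: NEXUS parse failed: {exc}") from exc
        return Alignment.from_records(
            [(rec.id, str(rec.seq)) for rec in msa], alphabet=alphabet
        )
    # relaxed PHYLIP: try interleaved/relaxed first, then sequential
    last_error: Exception | None = None
    for dialect in ("phylip-relaxed", "phylip-sequential", "phylip"):
        try:
            msa = AlignIO.read(io.StringIO(text), dialect)
            return Alignment.from_records(
                [(rec.id, str(rec.seq)) for rec in msa], alphabet=alphabet
            )
        except Exception as exc:
            last_error = exc
    raise FormatError(f"{path}: PHYLIP parse failed: {last_error}") from last_error


def _molecule_type(alphabet: str) -> str:
    return "DNA" if alphabet == "nt" else "protein"


def write_alignment(aln: Alignment, path, format: str) -> None:
    """Write an alignment in ``fasta``, ``phylip`` or ``nexus`` format."""
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    records = [
        SeqRecord(
            Seq(seq),
            id=name,
            description="",
            annotations={"molecule_type": _molecule_type(aln.alphabet)},
        )
        for name, seq in aln.to_records()
    ]
    if format == "fasta":
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
        return
    msa = MultipleSeqAlignment(records)
    bio_format = "phylip-relaxed" if format == "phylip" else "nexus"
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, bio_format)


_PARTITION_LINE = re.compile(
    r"^\s*(?P<name>\S+)\s*=\s*(?P<start>\d+)\s*-\s*(?P<end>\d+)"
    r"(?:\s+(?P<alphabet>\S+))?\s*$"
)


def read_partition_table(path) -> tuple[Partition, ...]:
    """Parse a plain-text partition table: ``name = start-end [alphabet]``."""
    parts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = _PARTITION_LINE.match(line)
            if m is None:
                raise FormatError(f"{path}:{lineno}: cannot parse {line!r}")
            parts.append(
                Partition(
                    name=m.group("name"),
                    start=int(m.group("start")),
                    end=int(m.group("end")),
                    alphabet=m.group("alphabet") or "aa",
                )
            )
    if not parts:
        raise FormatError(f"{path}: no partitions found")
    return tuple(parts)


def write_partition_table(partitions: Sequence[Partition], path) -> None:
    with open(path, "w") as fh:
        for p in partitions:
            fh.write(f"{p.name} = {p.start}-{p.end} {p.alphabet}\n")


# ----------------------------------------------------------------------
# Concatenation and missing data
# ----------------------------------------------------------------------


def concatenate(
    genes: Mapping[str, Alignment] | Sequence[tuple[str, Alignment]],
) -> SuperMatrix:
    """Concatenate named gene alignments into a supermatrix.

    The taxon set is the union of the genes' taxa (in order of first
    appearance); absent gene-by-taxon blocks are filled with ``'?'``.
    One partition is created per gene, in input order.
    """
    if isinstance(genes, Mapping):
        items = list(genes.items())
    else:
        items = list(genes)
    if not items:
        raise FormatError("no genes to concatenate")
    names = [name for name, _ in items]
    if len(names) != len(set(names)):
        raise FormatError("duplicate gene names in concatenation")

    taxa: list[str] = []
    for _, gene in items:
        for t in gene.taxa:
            if t not in taxa:
                taxa.append(t)
    total = sum(gene.length for _, gene in items)
    data = np.full((len(taxa), total), "?", dtype="<U1")
    index = {t: i for i, t in enumerate(taxa)}

    partitions = []
    offset = 0
    for name, gene in items:
        rows = [index[t] for t in gene.taxa]
        data[rows, offset : offset + gene.length] = gene.data
        partitions.append(
            Partition(
                name=name,
                start=offset + 1,
                end=offset + gene.length,
                alphabet=gene.alphabet,
            )
        )
        offset += gene.length

    alphabets = {gene.alphabet for _, gene in items}
    alphabet = alphabets.pop() if len(alphabets) == 1 else "mixed"
    aln = Alignment(taxa=tuple(taxa), data=data, alphabet=alphabet)
    return SuperMatrix(alignment=aln, partitions=tuple(partitions))


def missing_fraction(sm: SuperMatrix | Alignment) -> float:
    """Fraction of cells holding a missing symbol, in [0, 1]."""
    mask = sm.missing_mask()
    return float(mask.sum()) / mask.size


def per_taxon_missing(sm: SuperMatrix) -> pd.DataFrame:
    """Per-taxon missing-data profile.

    Returns a table indexed by taxon with the fraction of missing cells
    and the number of partitions whose block is entirely missing for
    that taxon.
    """
    mask = sm.missing_mask()
    frac = mask.mean(axis=1)
    whole = np.zeros(len(sm.taxa), dtype=int)
    for p in sm.partitions:
        whole += mask[:, p.columns].all(axis=1)
    return pd.DataFrame(
        {"missing_fraction": frac, "partitions_missing": whole},
        index=pd.Index(sm.taxa, name="taxon"),
    )


def subset_taxa(sm: SuperMatrix, keep: Iterable[str]) -> SuperMatrix:
    """Restrict a supermatrix to a subset of taxa.

    Row order is preserved, partitions are unchanged and no columns are
    removed (columns may become entirely missing).
    """
    keep = set(keep)
    unknown = keep - set(sm.taxa)
    if unknown:
        raise KeyError(f"unknown taxa: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to keep")
    rows = [i for i, t in enumerate(sm.taxa) if t in keep]
    aln = Alignment(
        taxa=tuple(sm.taxa[i] for i in rows),
        data=sm.alignment.data[rows].copy(),
        alphabet=sm.alignment.alphabet,
    )
    return SuperMatrix(alignment=aln, partitions=sm.partitions, events=sm.events)
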