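"""Protein and peptide sequence records, FASTA I/O and the storage-protein manifest.

Conventions used throughout the package:

* residue coordinates are 1-based and inclusive, matching the ``start–end``
  style in which peptide locations within precursor proteins are reported;
* sequences are uppercase strings over the 20 canonical one-letter codes.
  Ambiguous codes (X, B, Z, U) are rejected by default; a lenient mode maps
  them to the sentinel ``X``, which never matches a cleavage rule or a
  database fragment because both are validated to be canonical-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, EmptyInputError

#: The 20 canonical amino acids, one-letter codes.
CANONICAL_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity/rare codes accepted only in lenient mode.
NONCANONICAL = frozenset("XBZU")

#: Sentinel every non-canonical residue maps to in lenient mode.  It is not a
#: member of :data:`CANONICAL_ALPHABET`, so it can never satisfy a cleavage
#: rule or match a bioactive fragment.
SENTINEL = "X"


def normalize_sequence(raw: str, *, lenient: bool = False) -> str:
    """Uppercase, strip whitespace and validate a residue string.

    Parameters
    ----------
    raw:
        Residue string, possibly lowercase or containing whitespace.
    lenient:
        When true, the ambiguity codes X/B/Z/U are mapped to :data:`SENTINEL`
        instead of raising.

    Raises
    ------
    AlphabetError
        If a character is outside the accepted alphabet; the error names the
        1-based position of the first offending character.
    """
    seq = "".join(raw.split()).upper()
    if not seq:
        raise EmptyInputError("sequence is empty")
    out = []
    for i, ch in enumerate(seq, start=1):
        if ch in CANONICAL_ALPHABET:
            out.append(ch)
        elif lenient and ch in NONCANONICAL:
            out.append(SENTINEL)
        else:
            raise AlphabetError(
                f"illegal residue {ch!r} at position {i}", position=i
            )
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein to digest: accession plus one-letter residue sequence."""

    accession: str
    sequence: str
    name: str = ""
    gene: str | None = None
    source_note: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        # the sentinel is tolerated here so lenient-mode records stay valid
        for i, ch in enumerate(self.sequence, start=1):
            if ch not in CANONICAL_ALPHABET and ch != SENTINEL:
                raise AlphabetError(
                    f"illegal residue {ch!r} at position {i} in {self.accession}",
                    position=i,
                )
        if not self.sequence:
            raise EmptyInputError("sequence is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideSequence:
    """A peptide with optional residue modifications.

    ``modifications`` is a list of ``(position, modification_id)`` pairs with
    1-based positions into ``residues``.
    """

    residues: str
    modifications: tuple[tuple[int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_sequence(self.residues))
        object.__setattr__(self, "modifications", tuple(
            (int(p), str(m)) for p, m in self.modifications
        ))
        n = len(self.residues)
        for pos, mod in self.modifications:
            if not 1 <= pos <= n:
                raise ValueError(
                    f"modification {mod!r} position {pos} outside [1, {n}]"
                )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def _parse_accession(header: str) -> str:
    """First whitespace-delimited token, with the UniProt ``sp|ACC|NAME`` and
    ``tr|ACC|NAME`` dialects unwrapped to the bare accession."""
    token = header.split()[0] if header.split() else ""
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in {"sp", "tr"}:
        return parts[1]
    return token


def read_fasta(path: str | Path, *, lenient: bool = False) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`, in file order.

    Sequences are uppercased and whitespace-stripped.  An empty file raises
    :class:`~legumepep.errors.EmptyInputError`; an illegal residue raises
    :class:`~legumepep.errors.AlphabetError` naming the position.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = _parse_accession(rec.description or rec.id)
        if not accession:
            raise EmptyInputError(f"record with empty header in {path}")
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        seq = normalize_sequence(str(rec.seq), lenient=lenient)
        name = " ".join(rec.description.split()[1:]) if rec.description else ""
        records.append(ProteinRecord(accession=accession, sequence=seq, name=name))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, sequence lines wrapped at 60 columns."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.name)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecords)


def _data_path(name: str):
    return resources.files("legumepep.data").joinpath(name)


def load_accession_manifest() -> pd.DataFrame:
    """The study's storage-protein manifest: 25 UniProtKB accessions of the
    main faba bean, pea and soy storage proteins (11S legumins/glycinins and
    7S vicilins/conglycinins), as a DataFrame with columns
    ``species, protein_family, protein, gene, accession``."""
    with resources.as_file(_data_path("storage_protein_accessions.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str).fillna("")
    return df


def load_identified_peptides() -> pd.DataFrame:
    """The LC-MS/MS-identified peptide set used for mass verification:
    sequence, fraction, observed and calculated neutral monoisotopic masses
    (Da), precursor protein/accession, 1-based location, and modifications
    (``pos:mod_id`` entries separated by ``;``)."""
    with resources.as_file(_data_path("identified_peptides.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"sequence": str, "modifications": str})
    df["modifications"] = df["modifications"].fillna("")
    return df


def parse_modifications(spec: str) -> tuple[tuple[int, str], ...]:
    """Parse a ``pos:mod_id;pos:mod_id`` annotation string."""
    if not spec or not spec.strip():
        return ()
    out = []
    for part in spec.split(";"):
        pos, mod = part.strip().split(":")
        out.append((int(pos), mod))
    return tuple(out)
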