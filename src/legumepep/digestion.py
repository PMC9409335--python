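"""Rule-based in silico proteolysis with several enzymes acting at once.

Gastrointestinal digestion is emulated by applying pepsin, trypsin and
chymotrypsin *simultaneously*: the cleavage-site set of the mixture is the
union of the per-enzyme site sets, and digestion is exhaustive (every site is
cut, no missed cleavages), which is the regime under which the release
frequency A_E is defined.

A cleavage rule is a pure P1/P1' predicate: bond *i* (between residues *i*
and *i+1*, 1-based) is cut when residue *i* is in the rule's P1 set and
residue *i+1* is not in its P1' blocker set.  Specificity tables are data,
not code — the packaged defaults follow the ExPASy-PeptideCutter-style
conventions (trypsin K/R blocked by P; chymotrypsin high-specificity F/Y/W
blocked by P; pepsin at pH > 2 after F/L) and can be replaced by a user file.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import AlphabetError
from .sequences import CANONICAL_ALPHABET, SENTINEL, ProteinRecord


@dataclass(frozen=True)
class CleavageRule:
    """P1/P1' cleavage specificity of one protease."""

    enzyme_id: str
    ec_number: str
    p1_residues: frozenset[str]
    p1prime_blockers: frozenset[str] = frozenset()
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "p1_residues", frozenset(self.p1_residues))
        object.__setattr__(self, "p1prime_blockers", frozenset(self.p1prime_blockers))
        if not self.p1_residues:
            raise ValueError(f"{self.enzyme_id}: P1 residue set is empty")
        for s, label in ((self.p1_residues, "P1"), (self.p1prime_blockers, "P1'")):
            bad = s - CANONICAL_ALPHABET
            if bad:
                raise ValueError(
                    f"{self.enzyme_id}: non-canonical {label} residues {sorted(bad)}"
                )


@dataclass(frozen=True)
class Fragment:
    """One released peptide with 1-based inclusive coordinates in its parent."""

    sequence: str
    start: int
    end: int


@dataclass(frozen=True)
class DigestResult:
    parent_accession: str
    fragments: tuple[Fragment, ...]
    cleavage_sites: tuple[int, ...]
    enzymes_used: tuple[str, ...]

    def fragment_sequences(self) -> list[str]:
        return [f.sequence for f in self.fragments]


def _check_sequence(sequence: str) -> None:
    for i, ch in enumerate(sequence, start=1):
        if ch not in CANONICAL_ALPHABET and ch != SENTINEL:
            raise AlphabetError(f"illegal residue {ch!r} at position {i}", position=i)


def cleavage_sites(sequence: str, rule: CleavageRule) -> list[int]:
    """Sorted bond indices cut by one rule.

    Site *i* (1-based, ``1 <= i < len(sequence)``) is the bond between
    residues *i* and *i+1*; it is included iff ``sequence[i-1]`` is a P1
    residue and ``sequence[i]`` is not a P1' blocker.  There is never a site
    after the final residue.
    """
    _check_sequence(sequence)
    sites = [
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in rule.p1_residues
        and sequence[i] not in rule.p1prime_blockers
    ]
    return sites


def digest(protein: ProteinRecord, rules: Sequence[CleavageRule]) -> DigestResult:
    """Exhaustive simultaneous digestion of one protein.

    The site set is the union over rules; fragments are the maximal runs
    between consecutive sites.  With no rules the whole sequence is returned
    as a single fragment.
    """
    seq = protein.sequence
    sites: set[int] = set()
    for rule in rules:
        sites.update(cleavage_sites(seq, rule))
    ordered = sorted(sites)
    bounds = [0] + ordered + [len(seq)]
    fragments = tuple(
        Fragment(sequence=seq[a:b], start=a + 1, end=b)
        for a, b in zip(bounds[:-1], bounds[1:])
    )
    return DigestResult(
        parent_accession=protein.accession,
        fragments=fragments,
        cleavage_sites=tuple(ordered),
        enzymes_used=tuple(r.enzyme_id for r in rules),
    )


def load_enzyme_rules(path: str | Path | None = None) -> dict[str, CleavageRule]:
    """Load cleavage rules from a tab-delimited file (columns ``enzyme_id,
    ec_number, p1_residues, p1prime_blockers, description``); with no path,
    the packaged default table (pepsin pH > 2, trypsin, chymotrypsin)."""
    if path is None:
        ref = resources.files("legumepep.data").joinpath("enzymes.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str).fillna("")
    else:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    rules = {}
    for row in df.itertuples(index=False):
        rules[row.enzyme_id] = CleavageRule(
            enzyme_id=row.enzyme_id,
            ec_number=row.ec_number,
            p1_residues=frozenset(row.p1_residues),
            p1prime_blockers=frozenset(row.p1prime_blockers),
            description=row.description,
        )
    return rules


def gastrointestinal_rules() -> list[CleavageRule]:
    """The default three-enzyme set emulating gastrointestinal digestion."""
    rules = load_enzyme_rules()
    return [rules["pepsin"], rules["trypsin"], rules["chymotrypsin"]]


def digest_table(results: Iterable[DigestResult]) -> pd.DataFrame:
    """Flatten digestion results to a tidy table (accession, start, end, fragment)."""
    rows = [
        {"accession": r.parent_accession, "start": f.start, "end": f.end,
         "fragment": f.sequence}
        for r in results
        for f in r.fragments
    ]
    return pd.DataFrame(rows, columns=["accession", "start", "end", "fragment"])
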