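"""Screening peptides against a bioactive-fragment database.

Implements the occurrence-frequency parameter

    A = a / N

where *a* is the total number of occurrences in the peptide of database
fragments annotated with the activity of interest (overlapping occurrences
all counted) and *N* is the peptide length, and the potency parameter

    B = ( Σ_i a_i / EC50_i ) / N

summed over the *k* distinct matched fragments *i* that carry an EC50 (µM);
B is undefined (missing) when no matched fragment has an EC50.  Overlap
counting matters: for EEEDEDEPR against the "stimulating" fragments
{EEE, EE}, EE occurs at positions 1 and 2 inside the EEE run, giving a = 3
and A = 3/9 = 0.33.

The post-digestion release frequency

    A_E = (number of released fragments exactly equal to an active database
           fragment, with multiplicity) / N_protein

scores a whole protein under a stated enzyme set: the protein is digested
exhaustively and only whole released peptides count (substring credit would
double-count with A).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .digestion import CleavageRule, digest
from .sequences import CANONICAL_ALPHABET, PeptideSequence, ProteinRecord

#: Activity classes pre-declared by the screening vocabulary; the vocabulary
#: itself is open (any string is accepted).
KNOWN_ACTIVITIES = (
    "ACE inhibitor",
    "DPP-IV inhibitor",
    "DPP-III inhibitor",
    "alpha-glucosidase inhibitor",
    "renin inhibitor",
    "antioxidant",
    "anti-amnestic",
    "antithrombotic",
    "regulating",
    "stimulating",
)


@dataclass(frozen=True)
class BioactiveFragment:
    """One database record: a short fragment with a known bioactivity."""

    sequence: str
    activity: str
    ec50_uM: float | None = None
    reference: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.strip().upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("fragment sequence must be non-empty")
        bad = set(seq) - CANONICAL_ALPHABET
        if bad:
            raise ValueError(f"fragment {seq!r}: non-canonical residues {sorted(bad)}")
        if self.ec50_uM is not None and not self.ec50_uM > 0:
            raise ValueError(f"fragment {seq!r}: EC50 must be positive")


class BioactiveFragmentDB:
    """In-memory fragment database with unique (sequence, activity) pairs."""

    def __init__(self, records: Iterable[BioactiveFragment]):
        self.records: list[BioactiveFragment] = []
        seen: set[tuple[str, str]] = set()
        for rec in records:
            key = (rec.sequence, rec.activity)
            if key in seen:
                raise ValueError(f"duplicate (sequence, activity) pair {key}")
            seen.add(key)
            self.records.append(rec)

    @property
    def activities(self) -> set[str]:
        return {r.activity for r in self.records}

    def fragments_for(self, activity: str) -> list[BioactiveFragment]:
        return [r for r in self.records if r.activity == activity]

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_table(cls, path: str | Path) -> "BioactiveFragmentDB":
        """Read a tab-delimited database file with columns ``sequence,
        activity, ec50_uM, reference`` (blank EC50 = missing)."""
        # keep_default_na: the dipeptides NA and (in user files) NN etc. are
        # sequences, not missing values
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        records = []
        for row in df.itertuples(index=False):
            ec50 = getattr(row, "ec50_uM", "")
            ec50 = float(ec50) if str(ec50).strip() else None
            ref = str(getattr(row, "reference", "") or "")
            records.append(
                BioactiveFragment(row.sequence, row.activity, ec50, ref)
            )
        return cls(records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"sequence": r.sequence, "activity": r.activity,
                 "ec50_uM": r.ec50_uM, "reference": r.reference}
                for r in self.records
            ],
            columns=["sequence", "activity", "ec50_uM", "reference"],
        )


@dataclass(frozen=True)
class ActivityProfile:
    """Screening result for one peptide and one activity class."""

    peptide: PeptideSequence
    activity: str
    matches: tuple[tuple[str, tuple[int, ...]], ...]
    a: int
    A: float
    B: float | None
    k: int


def count_occurrences(peptide: str, fragment: str) -> int:
    """Number of start positions at which ``fragment`` occurs in ``peptide``
    as a contiguous substring; overlapping occurrences all count."""
    if not fragment:
        raise ValueError("fragment must be non-empty")
    if not peptide:
        raise ValueError("peptide must be non-empty")
    count = 0
    start = peptide.find(fragment)
    while start != -1:
        count += 1
        start = peptide.find(fragment, start + 1)
    return count


def occurrence_positions(peptide: str, fragment: str) -> tuple[int, ...]:
    """1-based start positions of all (overlapping) occurrences."""
    positions = []
    start = peptide.find(fragment)
    while start != -1:
        positions.append(start + 1)
        start = peptide.find(fragment, start + 1)
    return tuple(positions)


def parameter_A(
    peptide: PeptideSequence | str,
    db: BioactiveFragmentDB,
    activity: str,
) -> ActivityProfile:
    """Match one peptide against the database fragments of one activity and
    return the full profile (a, A, B, k and per-fragment positions)."""
    pep = peptide if isinstance(peptide, PeptideSequence) else PeptideSequence(peptide)
    n = len(pep)
    matches: list[tuple[str, tuple[int, ...]]] = []
    b_sum = 0.0
    k = 0
    for frag in db.fragments_for(activity):
        pos = occurrence_positions(pep.residues, frag.sequence)
        if pos:
            matches.append((frag.sequence, pos))
            if frag.ec50_uM is not None:
                b_sum += len(pos) / frag.ec50_uM
                k += 1
    a = sum(len(pos) for _, pos in matches)
    return ActivityProfile(
        peptide=pep,
        activity=activity,
        matches=tuple(matches),
        a=a,
        A=a / n,
        B=(b_sum / n) if k > 0 else None,
        k=k,
    )


def parameter_B(
    peptide: PeptideSequence | str,
    db: BioactiveFragmentDB,
    activity: str,
) -> float | None:
    """Potency parameter B, or None when no matched fragment carries an EC50."""
    return parameter_A(peptide, db, activity).B


def profile_peptide(
    peptide: PeptideSequence | str, db: BioactiveFragmentDB
) -> list[ActivityProfile]:
    """Profiles for every activity with at least one match, sorted by
    activity name."""
    profiles = [
        parameter_A(peptide, db, activity) for activity in sorted(db.activities)
    ]
    return [p for p in profiles if p.matches]


def parameter_AE(
    protein: ProteinRecord,
    rules: Sequence[CleavageRule],
    db: BioactiveFragmentDB,
    activity: str,
) -> float:
    """Release frequency of active fragments under exhaustive digestion.

    Counts released fragments whose full sequence equals a database fragment
    of the given activity (with multiplicity over the fragment list), divided
    by the protein length.
    """
    result = digest(protein, rules)
    active = {f.sequence for f in db.fragments_for(activity)}
    released = sum(1 for frag in result.fragments if frag.sequence in active)
    return released / len(protein)


def round_reported(value: float, decimals: int = 2) -> float:
    """Round half away from zero, the convention used for reported A/B values
    (Python's built-in round is half-to-even and would turn 0.625 into 0.62)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def load_study_fragments() -> BioactiveFragmentDB:
    """The packaged fragment database: the bioactive fragments reported for
    the identified peptides (EC50s are not part of the published record and
    are left missing).  This is a small study-specific fixture, not a
    redistribution of any external database."""
    ref = resources.files("legumepep.data").joinpath("bioactive_fragments.tsv")
    with resources.as_file(ref) as p:
        return BioactiveFragmentDB.from_table(p)


def load_screening_reference() -> pd.DataFrame:
    """Published per-peptide screening reference: peptide, activity, the
    matched fragment list and the occurrence frequency A as printed (kept as
    a string to preserve its printed precision)."""
    ref = resources.files("legumepep.data").joinpath("screening_reference.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    return df


def screen_table(
    peptides: Iterable[PeptideSequence | str],
    db: BioactiveFragmentDB,
    activity: str | None = None,
) -> pd.DataFrame:
    """Tidy screening report: one row per (peptide, activity) with matched
    fragments, a, A and B.  ``activity`` restricts to one class."""
    rows = []
    for pep in peptides:
        profiles = profile_peptide(pep, db)
        if activity is not None:
            profiles = [p for p in profiles if p.activity == activity]
        for p in profiles:
            rows.append(
                {
                    "peptide": p.peptide.residues,
                    "activity": p.activity,
                    "fragments": ",".join(f for f, _ in p.matches),
                    "a": p.a,
                    "A": p.A,
                    "B": p.B,
                }
            )
    return pd.DataFrame(
        rows, columns=["peptide", "activity", "fragments", "a", "A", "B"]
    )
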