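"""Seeded generators for every input the pipeline consumes.

One global seed fans out into independent per-generator substreams (a fixed
stream id per generator family), so adding a new generator never perturbs
the outputs of existing ones and a fixed :class:`SimulationConfig` yields
byte-identical outputs across runs.

What is emulated, with known ground truth:

* random protein sequences with a chosen residue composition;
* bioactive-fragment databases with known EC50s and a controlled fraction of
  records lacking EC50;
* 4PL dose–response readouts with additive Gaussian noise (plate replicates
  reported as mean ± SD are consistent with an additive error model);
* monotone fluorescein-decay kinetics for ORAC/CAA: the trace holds its
  initial fluorescence for a lag period (the antioxidant-protected phase)
  and then decays exponentially — the minimal shape that produces the
  antioxidant-dependent AUC behaviour the assay assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assays import DoseResponseDataset, KineticTrace, fourpl
from .screening import KNOWN_ACTIVITIES, BioactiveFragment, BioactiveFragmentDB
from .sequences import ProteinRecord

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# fixed substream ids: one per generator family
_STREAMS = {"protein": 11, "fragment_db": 23, "dose_response": 37, "kinetic": 53}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class FourPLTruth:
    bottom: float = 0.0
    top: float = 100.0
    hill_slope: float = 1.2
    midpoint: float = 500.0


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for a full synthetic study."""

    seed: int = 0
    n_proteins: int = 5
    protein_length: int = 300
    db_size: int = 50
    ec50_range_uM: tuple[float, float] = (1.0, 500.0)
    missing_ec50_fraction: float = 0.5
    fourpl_truth: FourPLTruth = field(default_factory=FourPLTruth)
    concentrations: tuple[float, ...] = (100.0, 200.0, 400.0, 800.0, 1500.0, 3000.0, 4500.0, 6000.0)
    replicates: int = 3
    noise_sd: float = 3.0
    trace_rfu0: float = 1000.0
    trace_lag_min: float = 20.0
    trace_decay_rate: float = 0.1
    trace_duration_min: int = 90

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.protein_length <= 0 or self.db_size <= 0:
            raise ValueError("sizes must be positive")
        lo, hi = self.ec50_range_uM
        if not (0 < lo <= hi):
            raise ValueError("EC50 range must be positive")


def gen_protein(
    length: int,
    weights: Mapping[str, float] | None = None,
    seed: int = 0,
    accession: str = "SYN0001",
) -> ProteinRecord:
    """A reproducible random protein with residues drawn from ``weights``
    (uniform over the 20 canonical residues when omitted)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if weights is None:
        p = np.full(len(_ALPHABET), 1.0 / len(_ALPHABET))
    else:
        p = np.array([float(weights.get(ch, 0.0)) for ch in _ALPHABET])
        if p.sum() <= 0:
            raise ValueError("composition weights sum to zero")
        p = p / p.sum()
    rng = _rng(seed, "protein")
    seq = "".join(rng.choice(list(_ALPHABET), size=length, p=p))
    return ProteinRecord(accession=accession, sequence=seq, name="synthetic protein")


def gen_fragment_db(
    n: int,
    activities: Sequence[str] = KNOWN_ACTIVITIES,
    ec50_range: tuple[float, float] = (1.0, 500.0),
    missing_ec50_fraction: float = 0.5,
    seed: int = 0,
    fragment_lengths: tuple[int, ...] = (2, 3),
) -> BioactiveFragmentDB:
    """A synthetic fragment database of ``n`` unique (sequence, activity)
    records; exactly ``round(n × missing_ec50_fraction)`` records lack an
    EC50, the rest draw log-uniformly from ``ec50_range`` (µM)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed, "fragment_db")
    lo, hi = ec50_range
    seen: set[tuple[str, str]] = set()
    keys: list[tuple[str, str]] = []
    while len(keys) < n:
        length = int(rng.choice(fragment_lengths))
        seq = "".join(rng.choice(list(_ALPHABET), size=length))
        activity = str(rng.choice(list(activities)))
        if (seq, activity) not in seen:
            seen.add((seq, activity))
            keys.append((seq, activity))
    n_missing = round(n * missing_ec50_fraction)
    missing = np.zeros(n, dtype=bool)
    missing[rng.choice(n, size=n_missing, replace=False)] = True
    records = []
    for (seq, activity), miss in zip(keys, missing):
        ec50 = None if miss else float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        records.append(BioactiveFragment(seq, activity, ec50, reference="synthetic"))
    return BioactiveFragmentDB(records)


def gen_dose_response(
    truth: FourPLTruth,
    concentrations: Sequence[float],
    replicates: int = 3,
    noise_sd: float = 3.0,
    seed: int = 0,
    assay_kind: str = "DPPH",
    sample_id: str = "synthetic",
) -> DoseResponseDataset:
    """Replicate responses on the 4PL curve defined by ``truth`` plus
    additive Gaussian noise with standard deviation ``noise_sd``."""
    if truth.midpoint <= 0:
        raise ValueError("truth midpoint must be positive")
    rng = _rng(seed, "dose_response")
    conc = np.asarray(concentrations, dtype=float)
    responses = []
    for c in conc:
        mean = fourpl(c, truth.bottom, truth.top, truth.hill_slope, truth.midpoint)
        noise = rng.normal(0.0, noise_sd, size=replicates) if noise_sd > 0 else np.zeros(replicates)
        responses.append(mean + noise)
    return DoseResponseDataset(
        assay_kind=assay_kind, concentrations=conc, responses=responses,
        sample_id=sample_id,
    )


def gen_kinetic_trace(
    rfu0: float,
    lag_min: float,
    decay_rate: float,
    duration: int = 90,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KineticTrace:
    """A monotone (in expectation) fluorescence-decay trace read every minute:
    constant at ``rfu0`` through the lag, then exponential decay at
    ``decay_rate`` per minute.  Optional Gaussian noise, clipped at zero."""
    if rfu0 <= 0:
        raise ValueError("rfu0 must be positive")
    if duration < 1:
        raise ValueError("duration must be >= 1 minute")
    times = np.arange(0, duration + 1, dtype=float)
    expected = rfu0 * np.exp(-decay_rate * np.clip(times - lag_min, 0.0, None))
    if noise_sd > 0:
        rng = _rng(seed, "kinetic")
        expected = np.clip(expected + rng.normal(0.0, noise_sd, size=len(times)), 0.0, None)
        expected[0] = rfu0  # the time-0 reference reading is noise-free
    return KineticTrace(times=times, rfu=expected)


def gen_study(config: SimulationConfig) -> dict:
    """Generate one coherent synthetic study from a single config: proteins,
    a fragment database, a dose–response dataset per assay family and an
    ORAC-style kinetic trace.  Deterministic in ``config.seed``."""
    proteins = [
        gen_protein(
            config.protein_length, seed=config.seed + i,
            accession=f"SYN{i + 1:04d}",
        )
        for i in range(config.n_proteins)
    ]
    db = gen_fragment_db(
        config.db_size,
        ec50_range=config.ec50_range_uM,
        missing_ec50_fraction=config.missing_ec50_fraction,
        seed=config.seed,
    )
    dose = gen_dose_response(
        config.fourpl_truth, config.concentrations, config.replicates,
        config.noise_sd, seed=config.seed,
    )
    trace = gen_kinetic_trace(
        config.trace_rfu0, config.trace_lag_min, config.trace_decay_rate,
        config.trace_duration_min, seed=config.seed,
    )
    return {"proteins": proteins, "db": db, "dose_response": dose, "trace": trace}
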