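"""Assay-level computations: percent transforms, 4PL dose–response fitting,
ORAC kinetic integration and cellular antioxidant activity.

Percent transforms
------------------
Radical-scavenging (DPPH/ABTS) and iron-chelation readouts are expressed as
``(1 − A_sample/A_control) × 100`` of background-subtracted absorbances.
ACE inhibition uses the substrate (HHL) peak areas of the control reaction
(no enzyme, 100 % inhibition), the sample and the uninhibited blank.  DPP-IV
inhibition is ``(1 − RFU_sample/RFU_control) × 100``; cell viability is the
plain luminescence ratio ``L_sample/L_control × 100``; CAA is
``(1 − ∫SA/∫CA) × 100`` on blank- and baseline-corrected fluorescence areas.

Dose–response model
-------------------
EC50/IC50 values are the midpoint of a four-parameter logistic fitted by
least squares:

    y(x) = bottom + (top − bottom) / (1 + (x / midpoint)^(−hill_slope))

The reported EC50/IC50 is the fitted midpoint parameter (not the absolute
50 %-crossing when top/bottom deviate from 100/0).

ORAC integration
----------------
The fluorescein-decay area under the curve is the per-minute rectangular sum

    AUC = 1 + Σ_{t=1..T} RFU_t / RFU_0

net AUC = AUC − AUC_blank, and sample antioxidant capacity is read off a
straight-line Trolox standard curve of net AUC against µM Trolox.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateControlError, DegenerateTraceError, FitError

ASSAY_KINDS = (
    "DPPH",
    "ABTS",
    "iron_chelation",
    "ACE",
    "DPPIV_invitro",
    "DPPIV_cell",
    "viability",
    "CAA",
)


# ---------------------------------------------------------------------------
# containers


@dataclass
class DoseResponseDataset:
    """Replicate percent responses measured over a concentration series.

    ``responses[i]`` holds the replicate values observed at
    ``concentrations[i]`` (µg peptide/mL).
    """

    assay_kind: str
    concentrations: np.ndarray
    responses: list[np.ndarray]
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = [np.atleast_1d(np.asarray(r, dtype=float)) for r in self.responses]
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(self.responses) != len(self.concentrations):
            raise ValueError("responses must align with concentrations")

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All replicate points, pooled (no pre-averaging)."""
        x = np.concatenate(
            [np.full(len(r), c) for c, r in zip(self.concentrations, self.responses)]
        )
        y = np.concatenate(self.responses)
        return x, y


@dataclass(frozen=True)
class FourPLFit:
    top: float
    bottom: float
    hill_slope: float
    midpoint: float
    rss: float
    converged: bool


@dataclass
class KineticTrace:
    """Per-minute fluorescence readings, times in minutes starting at 0."""

    times: np.ndarray
    rfu: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if len(self.times) != len(self.rfu):
            raise ValueError("times and rfu must have equal length")
        if len(self.times) == 0 or self.times[0] != 0:
            raise ValueError("trace must start at time 0")
        if np.any(self.rfu < 0):
            raise ValueError("fluorescence readings must be non-negative")

    @property
    def rfu0(self) -> float:
        return float(self.rfu[0])


@dataclass(frozen=True)
class TroloxCurve:
    """Straight-line standard curve of net AUC against µM Trolox."""

    standard_concentrations: tuple[float, ...]
    net_aucs: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float


# ---------------------------------------------------------------------------
# percent transforms


def _require_positive_control(control: float, label: str = "control") -> None:
    if not control > 0:
        raise DegenerateControlError(f"{label} signal must be positive, got {control}")


def percent_scavenging(sample_abs: float, control_abs: float) -> float:
    """Radical-scavenging capacity (%) from background-subtracted absorbances."""
    _require_positive_control(control_abs, "control absorbance")
    return (1.0 - sample_abs / control_abs) * 100.0


def percent_chelation(sample_abs: float, control_abs: float) -> float:
    """Iron-chelating activity (%); control is the iron–ferrozine complex
    without chelating peptides."""
    return percent_scavenging(sample_abs, control_abs)


def ace_inhibition(pa_control: float, pa_sample: float, pa_blank: float) -> float:
    """ACE inhibition (%) from HHL peak areas.

    ``pa_control`` — substrate alone (100 % inhibition); ``pa_sample`` —
    substrate + enzyme + peptides; ``pa_blank`` — uninhibited reaction
    (0 % inhibition).
    """
    denom = pa_control - pa_blank
    if denom == 0:
        raise DegenerateControlError("control and blank peak areas coincide")
    return (1.0 - (pa_control - pa_sample) / denom) * 100.0


def dppiv_inhibition(rfu_sample: float, rfu_control: float) -> float:
    """DPP-IV inhibition (%) from background-subtracted fluorescence."""
    _require_positive_control(rfu_control, "control fluorescence")
    return (1.0 - rfu_sample / rfu_control) * 100.0


def cell_viability(lum_sample: float, lum_control: float) -> float:
    """Cell viability (%) — a plain luminescence ratio, not an inhibition."""
    _require_positive_control(lum_control, "control luminescence")
    return lum_sample / lum_control * 100.0


def caa_value(sample_area: float, control_area: float) -> float:
    """Cellular antioxidant activity (%) from integrated DCF fluorescence."""
    _require_positive_control(control_area, "control area")
    return (1.0 - sample_area / control_area) * 100.0


# ---------------------------------------------------------------------------
# kinetic integration


def orac_auc(trace: KineticTrace) -> float:
    """Fluorescein-decay AUC: ``1 + Σ RFU_t/RFU_0`` over the per-minute
    readings after time 0 (rectangular sum, no trapezoid)."""
    if trace.rfu0 <= 0:
        raise DegenerateTraceError("initial fluorescence must be positive")
    return 1.0 + float(np.sum(trace.rfu[1:] / trace.rfu0))


def net_auc(sample_auc: float, blank_auc: float) -> float:
    """AUC of a sample or standard minus the blank AUC."""
    return sample_auc - blank_auc


def trolox_fit(
    standard_concentrations: Sequence[float], net_aucs: Sequence[float]
) -> TroloxCurve:
    """Least-squares straight line of net AUC against µM Trolox (≥ 3
    standards); raises :class:`~legumepep.errors.FitError` on a singular
    design (all standards at one concentration)."""
    x = np.asarray(standard_concentrations, dtype=float)
    y = np.asarray(net_aucs, dtype=float)
    if len(x) < 3:
        raise FitError("at least 3 Trolox standards are required")
    if np.allclose(x, x[0]):
        raise FitError("all standards at the same concentration: singular design")
    res = stats.linregress(x, y)
    return TroloxCurve(
        standard_concentrations=tuple(x),
        net_aucs=tuple(y),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def trolox_equivalent_uM(sample_net_auc: float, curve: TroloxCurve) -> float:
    """Trolox concentration (µM) whose net AUC equals the sample's, read off
    the standard curve."""
    if curve.slope == 0:
        raise FitError("standard curve has zero slope")
    return (sample_net_auc - curve.intercept) / curve.slope


def orac_value(
    sample_net_auc: float,
    curve: TroloxCurve,
    protein_mg: float,
    assay_volume_uL: float = 200.0,
    dilution: float = 1.0,
) -> float:
    """Antioxidant capacity as µmol Trolox equivalent per mg protein.

    The sample's Trolox-equivalent concentration (µM) in the well is
    converted to µmol via the reaction volume (default 200 µL: sample +
    fluorescein + radical initiator), scaled by any pre-dilution of the
    sample and divided by the mg of protein loaded.
    """
    if not protein_mg > 0:
        raise ValueError("protein amount must be positive")
    te_uM = trolox_equivalent_uM(sample_net_auc, curve)
    umol_te = te_uM * assay_volume_uL * 1e-6  # µM × L = µmol
    return umol_te * dilution / protein_mg


def caa_from_traces(
    sample: KineticTrace,
    control: KineticTrace,
    blank: KineticTrace,
    window_min: float = 60.0,
) -> float:
    """CAA (%) from raw kinetic traces.

    Sample and control traces are corrected by subtracting the blank trace
    pointwise and then each trace's own initial (time-0) reading, and
    integrated by rectangular summation over ``[0, window_min]``.  Negative
    intermediate areas are kept (not clipped)."""
    def corrected_area(trace: KineticTrace) -> float:
        if not np.array_equal(trace.times, blank.times):
            raise ValueError("trace and blank time grids differ")
        corr = trace.rfu - blank.rfu
        corr = corr - corr[0]
        mask = trace.times <= window_min
        return float(np.sum(corr[mask]))

    sa = corrected_area(sample)
    ca = corrected_area(control)
    return caa_value(sa, ca)


def percent_transform(
    assay_kind: str, signal: float, control: float, blank: float = 0.0
) -> float:
    """Dispatch a raw signal to the percent formula of its assay family.

    Signals are assumed background-subtracted except for ACE, whose formula
    consumes the blank peak area explicitly.
    """
    if assay_kind in ("DPPH", "ABTS"):
        return percent_scavenging(signal, control)
    if assay_kind == "iron_chelation":
        return percent_chelation(signal, control)
    if assay_kind == "ACE":
        return ace_inhibition(control, signal, blank)
    if assay_kind in ("DPPIV_invitro", "DPPIV_cell"):
        return dppiv_inhibition(signal, control)
    if assay_kind == "viability":
        return cell_viability(signal, control)
    if assay_kind == "CAA":
        return caa_value(signal, control)
    raise ValueError(f"unknown assay kind {assay_kind!r}")


def datasets_from_tables(signals, controls) -> list[DoseResponseDataset]:
    """Build per-sample dose–response datasets from tidy tables.

    ``signals`` columns: sample, assay_kind, concentration, replicate,
    signal.  ``controls`` columns: sample, assay_kind, control and
    (optionally) blank; joined on (sample, assay_kind).  Percent transforms
    apply per replicate and replicates are kept pooled for fitting.
    """
    import pandas as pd

    signals = pd.DataFrame(signals)
    controls = pd.DataFrame(controls)
    if "blank" not in controls.columns:
        controls = controls.assign(blank=0.0)
    merged = signals.merge(controls, on=["sample", "assay_kind"], how="left")
    if merged["control"].isna().any():
        missing = merged.loc[merged["control"].isna(), ["sample", "assay_kind"]]
        raise ValueError(f"missing control rows for {missing.drop_duplicates().to_dict('records')}")
    datasets = []
    for (sample, kind), grp in merged.groupby(["sample", "assay_kind"], sort=True):
        concs = sorted(grp["concentration"].unique())
        responses = []
        for c in concs:
            sub = grp[grp["concentration"] == c]
            responses.append(
                np.array(
                    [
                        percent_transform(kind, row.signal, row.control, row.blank)
                        for row in sub.itertuples(index=False)
                    ]
                )
            )
        datasets.append(
            DoseResponseDataset(
                assay_kind=kind,
                concentrations=np.array(concs, dtype=float),
                responses=responses,
                sample_id=str(sample),
            )
        )
    return datasets


def read_kinetic_traces(path, well_map=None) -> dict[str, KineticTrace]:
    """Read a wide kinetic table (first column ``time`` in minutes, one
    column per well) into per-well traces; ``well_map`` (well → label)
    optionally renames wells to roles such as sample/control/blank."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    time_col = df.columns[0]
    traces = {}
    for col in df.columns[1:]:
        label = well_map.get(col, col) if well_map else col
        traces[label] = KineticTrace(times=df[time_col].to_numpy(), rfu=df[col].to_numpy())
    return traces


# ---------------------------------------------------------------------------
# four-parameter logistic


def fourpl(
    x: np.ndarray | float,
    bottom: float,
    top: float,
    hill_slope: float,
    midpoint: float,
) -> np.ndarray | float:
    """Four-parameter logistic response at concentration ``x``."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / midpoint) ** (-hill_slope))


def fit_4pl(dataset: DoseResponseDataset) -> FourPLFit:
    """Least-squares 4PL fit on pooled replicate points.

    Initialisation: bottom = min response, top = max response, midpoint = the
    concentration whose mean response is nearest halfway between them,
    slope = 1; the midpoint is constrained positive.  Non-convergence (and
    unidentifiable flat data) yields ``converged=False`` rather than an
    exception.
    """
    if len(np.unique(dataset.concentrations)) < 4:
        raise ValueError("at least 4 distinct concentrations are required")
    x, y = dataset.pooled()
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")

    if np.ptp(y) == 0:  # flat data: all four parameters unidentifiable
        return FourPLFit(
            top=float(y[0]), bottom=float(y[0]), hill_slope=np.nan,
            midpoint=np.nan, rss=0.0, converged=False,
        )

    means = np.array(
        [np.mean(r) for r in dataset.responses]
    )
    bottom0, top0 = float(np.min(y)), float(np.max(y))
    half = 0.5 * (bottom0 + top0)
    mid0 = float(dataset.concentrations[np.argmin(np.abs(means - half))])
    p0 = [bottom0, top0, 1.0, mid0]
    bounds = ([-np.inf, -np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf, np.inf])

    def model(xx, bottom, top, hill, mid):
        return fourpl(xx, bottom, top, hill, mid)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, x, y, p0=p0, bounds=bounds, maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
    except (RuntimeError, ValueError):
        return FourPLFit(
            top=np.nan, bottom=np.nan, hill_slope=np.nan, midpoint=np.nan,
            rss=np.nan, converged=False,
        )

    bottom, top, hill, mid = (float(v) for v in popt)
    resid = y - fourpl(x, bottom, top, hill, mid)
    rss = float(np.sum(resid**2))
    converged = bool(np.isfinite(mid) and mid > 0 and np.isfinite(rss))
    return FourPLFit(
        top=top, bottom=bottom, hill_slope=hill, midpoint=mid,
        rss=rss, converged=converged,
    )


def bootstrap_midpoint_ci(
    dataset: DoseResponseDataset,
    n_boot: int = 199,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile residual-bootstrap confidence interval for the midpoint.

    Centred residuals from the full fit are resampled onto the fitted curve
    and the model is refitted; resampling residuals rather than cases keeps
    the interval usable with the few (often 3) replicates per concentration
    typical of plate assays, where within-group case resampling is too
    discrete to approximate the sampling distribution.
    """
    rng = np.random.default_rng(seed)
    fit = fit_4pl(dataset)
    if not fit.converged:
        raise FitError("cannot bootstrap an unconverged fit")
    x, y = dataset.pooled()
    fitted = fourpl(x, fit.bottom, fit.top, fit.hill_slope, fit.midpoint)
    resid = y - fitted
    resid = resid - resid.mean()
    sizes = [len(r) for r in dataset.responses]
    mids = []
    for _ in range(n_boot):
        yb = fitted + rng.choice(resid, size=len(resid), replace=True)
        responses, k = [], 0
        for size in sizes:
            responses.append(yb[k:k + size])
            k += size
        boot = DoseResponseDataset(
            assay_kind=dataset.assay_kind,
            concentrations=dataset.concentrations,
            responses=responses,
            sample_id=dataset.sample_id,
        )
        bf = fit_4pl(boot)
        if bf.converged:
            mids.append(bf.midpoint)
    if not mids:
        raise FitError("no bootstrap replicate converged")
    alpha = 1.0 - level
    lo, hi = np.quantile(mids, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
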