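"""Synthetic MALDI-IM-MS/MS acquisition generator.

Emulates the signal structure of a 60-s spot analysis on a Q-IMS-TOF
instrument operated in MS/MS mode: the analyte fragment (m/z ~185.11) and
the internal-standard fragment (m/z ~189.13) appear as 2D Gaussian peaks
in (m/z, drift time), together with an endogenous interfering fragment
offset by dm/z 0.03 and dDT 0.04 ms whose intensity is independent of the
analyte concentration.  The TOF resolution mode controls the m/z peak
width: in sensitivity ("V") mode the interferent merges with the analyte
peak, in resolution ("W") mode it is mass-resolved.

Signal chain per spot (expected peak volume)::

    analyte = response_slope * conc * prep_factor * matrix_factor
              * spot_factor * replicate_factor

where ``prep_factor`` encodes the preparation route of the sample's role
(extraction recovery, post-extraction dilution, post-extraction spiking),
``spot_factor`` is a crystallization-quality multiplier shared by analyte
and IS within a spot (so IS normalization cancels it), and
``replicate_factor`` is multiplicative log-normal replicate noise.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import ndtr

from .design import QC_LEVELS_NG_PER_ML, SampleRecord, SampleRole

__all__ = [
    "InstrumentModel",
    "SignalModel",
    "Scan",
    "Acquisition",
    "simulate_spot",
    "simulate_batch",
    "simulate_tic_profile",
    "MZ_GRID_STEP",
]

#: Absolute m/z comb on which centroids are rendered (and spectra binned).
MZ_GRID_STEP = 0.005

_V_MODE_FWHM = 0.060
_W_MODE_FWHM = 0.018
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class InstrumentModel(BaseModel):
    """Acquisition geometry and resolution mode of the simulated instrument."""

    model_config = ConfigDict(extra="forbid")

    resolution_mode: Literal["V", "W"] = "W"
    #: m/z FWHM at m/z 185; None resolves to the mode default (V: 0.060, W: 0.018).
    mz_fwhm_at_185: float | None = Field(None, gt=0)
    dt_fwhm: float = Field(0.10, gt=0)  # mobility peak FWHM, ms
    dt_min: float = 0.0
    dt_max: float = 4.0
    dt_bins: int = Field(200, ge=2)
    scans_per_spot: int = Field(30, ge=1)  # IMS cycles over the spot analysis
    acquisition_seconds: float = Field(60.0, gt=0)

    @model_validator(mode="after")
    def _check_axis(self) -> "InstrumentModel":
        if not self.dt_max > self.dt_min:
            raise ValueError("dt axis must be strictly increasing (dt_max > dt_min)")
        return self

    @property
    def mz_fwhm(self) -> float:
        if self.mz_fwhm_at_185 is not None:
            return self.mz_fwhm_at_185
        return _V_MODE_FWHM if self.resolution_mode == "V" else _W_MODE_FWHM

    @property
    def mz_sigma(self) -> float:
        return self.mz_fwhm * _FWHM_TO_SIGMA

    @property
    def dt_sigma(self) -> float:
        return self.dt_fwhm * _FWHM_TO_SIGMA

    @property
    def dt_edges(self) -> np.ndarray:
        return np.linspace(self.dt_min, self.dt_max, self.dt_bins + 1)

    @property
    def dt_centers(self) -> np.ndarray:
        edges = self.dt_edges
        return 0.5 * (edges[:-1] + edges[1:])


class SignalModel(BaseModel):
    """Concentration-response and noise structure of the generator.

    Defaults reproduce the assay's reported operating point: extraction
    recovery 53.6%, matrix factors ~1, replicate CV 8% (within the 5-10%
    range of the reported within-batch CVs), and an interferent whose
    m/z-window leakage is <1% of the LLOQ signal in W mode but large in V
    mode.
    """

    model_config = ConfigDict(extra="forbid")

    analyte_mz: float = 185.1075
    is_mz: float = 189.1325
    interferent_delta_mz: float = 0.03
    interferent_delta_dt: float = 0.04  # ms
    analyte_dt: float = 1.85  # ms
    is_dt: float = 1.86  # ms
    response_slope: float = Field(200.0, gt=0)  # analyte peak volume per ng/mL
    is_response_slope: float | None = Field(None, gt=0)  # defaults to response_slope
    is_virtual_conc: float = Field(200.0, gt=0)  # fixed IS spike, virtual ng/mL
    extraction_recovery: float = Field(0.536, gt=0, le=1)
    matrix_factor_analyte: float = Field(1.0, gt=0)
    matrix_factor_is: float = Field(1.0, gt=0)
    replicate_cv: float = Field(0.08, ge=0)
    spot_heterogeneity: float = Field(0.25, ge=0)
    baseline_noise: float = Field(1.0, ge=0)  # a.u. per rendered point
    interferent_area: float = Field(250.0, ge=0)  # concentration-independent volume
    carryover_analyte_fraction: float = Field(0.05, ge=0)  # of the LLOQ-level signal
    carryover_is_fraction: float = Field(0.002, ge=0)  # of the nominal IS signal
    freeze_thaw_loss_per_cycle: float = Field(0.0, ge=0, lt=1)
    tic_burst_probability: float = Field(0.25, gt=0, le=1)

    @property
    def is_slope(self) -> float:
        return self.is_response_slope if self.is_response_slope is not None else self.response_slope


@dataclass
class Scan:
    """One drift-bin spectrum: centroided (m/z, intensity) pairs."""

    drift_bin: int
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class Acquisition:
    """One 60-s spot analysis, stored as flat centroid arrays.

    ``scan_ids`` orders centroids by acquisition time (IMS cycle) and then
    drift bin; the :attr:`scans` view groups them into per-drift-bin scans.
    """

    scan_ids: np.ndarray
    drift_bins: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    dt_centers: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.scan_ids)
        if not (len(self.drift_bins) == len(self.mz) == len(self.intensity) == n):
            raise ValueError("centroid arrays must have equal length")
        if n and (self.intensity < 0).any():
            raise ValueError("intensities must be >= 0")
        if n and ((self.drift_bins < 0) | (self.drift_bins >= len(self.dt_centers))).any():
            raise ValueError("drift bins outside the drift-time axis")

    @property
    def n_centroids(self) -> int:
        return len(self.mz)

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    @property
    def scans(self) -> list[Scan]:
        """Time-ordered scans, one per (cycle, drift bin) with any signal."""
        if self.n_centroids == 0:
            return []
        order = np.lexsort((self.mz, self.scan_ids))
        sid = self.scan_ids[order]
        boundaries = np.flatnonzero(np.diff(sid)) + 1
        out = []
        for chunk in np.split(order, boundaries):
            out.append(
                Scan(
                    drift_bin=int(self.drift_bins[chunk[0]]),
                    mz=self.mz[chunk],
                    intensity=self.intensity[chunk],
                )
            )
        return out

    @classmethod
    def from_scans(cls, scans: Sequence[Scan], dt_centers: np.ndarray, metadata: dict | None = None):
        ids, bins, mzs, ints = [], [], [], []
        for i, sc in enumerate(scans):
            mz = np.asarray(sc.mz, dtype=float)
            ids.append(np.full(len(mz), i, dtype=np.int64))
            bins.append(np.full(len(mz), sc.drift_bin, dtype=np.int64))
            mzs.append(mz)
            ints.append(np.asarray(sc.intensity, dtype=float))
        cat = lambda parts, dt: np.concatenate(parts) if parts else np.empty(0, dtype=dt)
        return cls(
            scan_ids=cat(ids, np.int64),
            drift_bins=cat(bins, np.int64),
            mz=cat(mzs, float),
            intensity=cat(ints, float),
            dt_centers=np.asarray(dt_centers, dtype=float),
            metadata=metadata or {},
        )


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 multiplicative log-normal noise; exactly 1 when cv == 0."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def simulate_tic_profile(
    prespotted: bool,
    instrument: InstrumentModel,
    seed,
    signal: SignalModel | None = None,
) -> np.ndarray:
    """Per-IMS-cycle total-ion-current multipliers for one spot.

    Pre-spotted matrix gives a homogeneous recrystallized deposit: a
    stable profile (mean ~1, CV = ``spot_heterogeneity``).  Depositing the
    matrix after the extract leaves sparse crystals: the laser only
    intermittently hits them, producing sparse high-variance bursts with a
    lower mean.  Both profiles are strictly non-negative.
    """
    signal = signal or SignalModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = instrument.scans_per_spot
    if prespotted:
        return _lognormal_factor(rng, max(signal.spot_heterogeneity, 1e-12), size=n) \
            if signal.spot_heterogeneity > 0 else np.ones(n)
    hits = rng.random(n) < signal.tic_burst_probability
    bursts = _lognormal_factor(rng, 1.0, size=n)
    return np.where(hits, bursts, 0.0)


def _gaussian_bin_weights(center: float, sigma: float, edges: np.ndarray) -> np.ndarray:
    """Integral of a unit Gaussian over each bin defined by ``edges``."""
    return np.diff(ndtr((edges - center) / sigma))


def _render_component(
    volume: float,
    mz_center: float,
    dt_center: float,
    instrument: InstrumentModel,
    shares: np.ndarray,
):
    """Render one 2D Gaussian peak onto (cycle, drift bin, m/z comb) points.

    Returns flat (scan_id, drift_bin, mz, intensity) arrays; the peak
    volume is split across IMS cycles in proportion to ``shares``.
    """
    if volume <= 0:
        return None
    dt_edges = instrument.dt_edges
    dt_sigma = instrument.dt_sigma
    lo = int(np.searchsorted(dt_edges, dt_center - 4.5 * dt_sigma)) - 1
    hi = int(np.searchsorted(dt_edges, dt_center + 4.5 * dt_sigma)) + 1
    lo = max(lo, 0)
    hi = min(hi, instrument.dt_bins)
    if hi <= lo:
        return None
    dt_w = _gaussian_bin_weights(dt_center, dt_sigma, dt_edges[lo : hi + 1])
    bin_idx = np.arange(lo, hi, dtype=np.int64)

    mz_sigma = instrument.mz_sigma
    j_lo = int(np.floor((mz_center - 4.5 * mz_sigma) / MZ_GRID_STEP))
    j_hi = int(np.ceil((mz_center + 4.5 * mz_sigma) / MZ_GRID_STEP))
    mz_edges = np.arange(j_lo, j_hi + 1, dtype=float) * MZ_GRID_STEP
    mz_w = _gaussian_bin_weights(mz_center, mz_sigma, mz_edges)
    mz_centers = mz_edges[:-1] + 0.5 * MZ_GRID_STEP

    nc, nb, nm = len(shares), len(bin_idx), len(mz_centers)
    inten = (volume * shares)[:, None, None] * dt_w[None, :, None] * mz_w[None, None, :]
    bins = np.tile(np.repeat(bin_idx, nm), nc)
    cycles = np.repeat(np.arange(nc, dtype=np.int64), nb * nm)
    scan_ids = cycles * instrument.dt_bins + bins
    mzs = np.tile(mz_centers, nc * nb)
    return scan_ids, bins, mzs, inten.ravel()


def _effective_concentration(sample: SampleRecord) -> float:
    role = sample.role
    if role is SampleRole.CLINICAL:
        if sample.true_conc is None:
            raise ValueError(
                f"clinical sample {sample.sample_id!r} needs true_conc for simulation"
            )
        return float(sample.true_conc)
    if role in (SampleRole.QC_EL, SampleRole.QC_MAT):
        if sample.nominal_conc and sample.nominal_conc > 0:
            return float(sample.nominal_conc)
        if sample.level in QC_LEVELS_NG_PER_ML:
            return QC_LEVELS_NG_PER_ML[sample.level]
        raise ValueError(f"{role.value} sample {sample.sample_id!r} has no resolvable level")
    if sample.nominal_conc is None:
        raise ValueError(f"sample {sample.sample_id!r} has unknown nominal_conc")
    return float(sample.nominal_conc)


def simulate_spot(
    sample: SampleRecord,
    instrument: InstrumentModel,
    signal: SignalModel,
    seed,
    include_interferent: bool = True,
) -> Acquisition:
    """Simulate one spot analysis and return its acquisition.

    The preparation route of the sample's role decides which signal
    factors apply: normal samples co-extract analyte and IS (both see the
    extraction recovery and the plasma matrix factors); QC DIL adds a 1:1
    post-extraction dilution; QC REC spikes the analyte *after* extraction
    of a CAL0 (100% analyte recovery, IS still extracted); QC MAT / QC EL
    are post-extraction spikes into matrix extract / neat eluent.  The
    endogenous interferent is present whenever plasma extract is present.
    """
    rng = np.random.default_rng(seed)
    role = sample.role
    conc = _effective_concentration(sample)

    tic = simulate_tic_profile(sample.prespotted_matrix, instrument, rng, signal)
    total = tic.sum()
    shares = tic / total if total > 0 else np.full(len(tic), 1.0 / len(tic))
    spot_factor = _lognormal_factor(rng, signal.spot_heterogeneity) * (
        float(tic.mean()) if total > 0 else 0.0
    )
    # Independent per-compound replicate noise; cv/sqrt(2) each so the
    # analyte/IS response ratio has CV ~= replicate_cv.
    cv_each = signal.replicate_cv / np.sqrt(2.0)
    rep_a = _lognormal_factor(rng, cv_each)
    rep_i = _lognormal_factor(rng, cv_each)
    rep_x = _lognormal_factor(rng, cv_each)

    recovery = signal.extraction_recovery
    has_matrix = role not in (SampleRole.QC_EL, SampleRole.CARRYOVER_BLANK)
    if role is SampleRole.QC_DIL:
        prep_a, prep_i = recovery * 0.5, recovery * 0.5
    elif role is SampleRole.QC_REC:
        prep_a, prep_i = 0.5, recovery * 0.5
    elif role in (SampleRole.QC_MAT, SampleRole.QC_EL):
        prep_a, prep_i = 0.5, 0.5
    else:
        prep_a, prep_i = recovery, recovery

    mf_a = signal.matrix_factor_analyte if has_matrix else 1.0
    mf_i = signal.matrix_factor_is if has_matrix else 1.0
    ft = (1.0 - signal.freeze_thaw_loss_per_cycle) ** sample.freeze_thaw_cycles

    if role is SampleRole.CARRYOVER_BLANK:
        v_analyte = (
            signal.carryover_analyte_fraction
            * signal.response_slope * QC_LEVELS_NG_PER_ML["LLOQ"] * recovery
            * spot_factor * rep_a
        )
        v_is = (
            signal.carryover_is_fraction
            * signal.is_slope * signal.is_virtual_conc * recovery
            * spot_factor * rep_i
        )
    else:
        has_is = role is not SampleRole.BV
        v_analyte = (
            signal.response_slope * conc * prep_a * mf_a * ft * spot_factor * rep_a
        )
        v_is = (
            signal.is_slope * signal.is_virtual_conc * prep_i * mf_i * spot_factor * rep_i
            if has_is
            else 0.0
        )
    v_interf = (
        signal.interferent_area * spot_factor * rep_x
        if (include_interferent and has_matrix)
        else 0.0
    )

    parts = []
    for vol, mz0, dt0 in (
        (v_analyte, signal.analyte_mz, signal.analyte_dt),
        (v_is, signal.is_mz, signal.is_dt),
        (v_interf, signal.analyte_mz + signal.interferent_delta_mz,
         signal.analyte_dt + signal.interferent_delta_dt),
    ):
        rendered = _render_component(vol, mz0, dt0, instrument, shares)
        if rendered is not None:
            parts.append(rendered)

    if signal.baseline_noise > 0:
        parts.append(_render_noise_floor(instrument, signal, rng))

    if parts:
        scan_ids = np.concatenate([p[0] for p in parts])
        bins = np.concatenate([p[1] for p in parts])
        mzs = np.concatenate([p[2] for p in parts])
        ints = np.concatenate([p[3] for p in parts])
        keep = ints > 0
        scan_ids, bins, mzs, ints = scan_ids[keep], bins[keep], mzs[keep], ints[keep]
        order = np.lexsort((mzs, scan_ids))
        scan_ids, bins, mzs, ints = scan_ids[order], bins[order], mzs[order], ints[order]
    else:
        scan_ids = np.empty(0, dtype=np.int64)
        bins = np.empty(0, dtype=np.int64)
        mzs = np.empty(0, dtype=float)
        ints = np.empty(0, dtype=float)

    metadata = {
        "sample": json.loads(sample.model_dump_json()),
        "instrument": json.loads(instrument.model_dump_json()),
        "seed": np.asarray(seed).tolist() if not isinstance(seed, int) else seed,
    }
    return Acquisition(
        scan_ids=scan_ids, drift_bins=bins, mz=mzs, intensity=ints,
        dt_centers=instrument.dt_centers, metadata=metadata,
    )


def _render_noise_floor(instrument: InstrumentModel, signal: SignalModel, rng):
    """Chemical/detector baseline: truncated-Gaussian points on the m/z
    combs around the analyte and IS fragments, across the whole DT axis
    (attributed to the first IMS cycle)."""
    combs = []
    for mz0, half in ((signal.analyte_mz, 0.035), (signal.is_mz, 0.025)):
        j_lo = int(np.floor((mz0 - half) / MZ_GRID_STEP))
        j_hi = int(np.ceil((mz0 + half) / MZ_GRID_STEP))
        combs.append((np.arange(j_lo, j_hi, dtype=float) + 0.5) * MZ_GRID_STEP)
    mz_points = np.concatenate(combs)
    nb = instrument.dt_bins
    nm = len(mz_points)
    bins = np.repeat(np.arange(nb, dtype=np.int64), nm)
    mzs = np.tile(mz_points, nb)
    ints = np.clip(rng.normal(0.0, signal.baseline_noise, nb * nm), 0.0, None)
    return bins.copy(), bins, mzs, ints  # scan_id = 0 * dt_bins + bin


def _child_seed(seed, sample_id: str) -> list[int]:
    base = [int(s) & 0x7FFFFFFF for s in (seed if isinstance(seed, (list, tuple)) else [seed])]
    return base + [zlib.crc32(sample_id.encode()) & 0x7FFFFFFF]


def simulate_batch(
    layout: Sequence[SampleRecord],
    instrument: InstrumentModel,
    signal: SignalModel,
    seed,
    include_interferent: bool = True,
) -> list[Acquisition]:
    """One acquisition per layout record, bit-reproducible for a given seed.

    Per-spot seeds are derived from (seed, sample_id), so the result is
    independent of layout ordering and of which subset is simulated.
    """
    if not layout:
        raise ValueError("layout must be non-empty")
    ids = [r.sample_id for r in layout]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_ids in layout: {dupes}")
    return [
        simulate_spot(
            r, instrument, signal, _child_seed(seed, r.sample_id),
            include_interferent=include_interferent,
        )
        for r in layout
    ]
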