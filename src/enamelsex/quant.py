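"""Targeted MS1 label-free quantification of marker peptides.

For each marker the module extracts per-isotopologue ion chromatograms (XICs)
at the configured ppm tolerance, picks and integrates the chromatographic
peak, scores the observed isotopic envelope against theory (normalized dot
product), and optionally validates identity from DDA MS2 fragments. The
tolerance defaults — 10 ppm at MS1, 20 ppm at MS2 — are the acquisition-level
settings the method was developed with.

Detection is a conjunction: integrated area above a relative noise floor
(10x the out-of-peak baseline by default), envelope score >= 0.90, and MS2
validation passing wherever MS2 evidence for the precursor exists. Every
failed criterion is recorded in ``reasons`` so a call is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem
from .panel import MarkerPeptide
from .spectra import Run


class QuantError(ValueError):
    pass


@dataclass
class QuantParams:
    tol_ppm_ms1: float = 10.0
    tol_ppm_ms2: float = 20.0
    n_peaks: int = 4
    min_envelope_score: float = 0.90
    floor_multiplier: float = 10.0
    min_area: float = 0.0
    min_ions: int = 4
    rt_window: float = 30.0  # apex search half-window around expected RT, s
    expected_rt: dict[str, float] | None = None
    use_ms2: bool = True


@dataclass
class Chromatogram:
    target_mz: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.rt = np.asarray(self.rt, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.rt.shape != self.intensity.shape:
            raise QuantError("chromatogram rt/intensity length mismatch")
        if self.rt.size > 1 and np.any(np.diff(self.rt) < 0):
            raise QuantError("chromatogram rt not ascending")
        if np.any(self.intensity < 0):
            raise QuantError("negative chromatogram intensity")


@dataclass
class PeakIntegration:
    apex_rt: float | None
    apex_index: int | None
    rt_start: float | None
    rt_end: float | None
    index_bounds: tuple[int, int] | None
    iso_areas: np.ndarray
    area: float


@dataclass
class MarkerQuantResult:
    marker_id: str
    area: float
    apex_rt: float | None
    rt_start: float | None
    rt_end: float | None
    iso_areas: list[float]
    envelope_score: float
    ms2_matched_ions: int
    ms2_evaluated: bool
    detected: bool
    reasons: list[str] = field(default_factory=list)


def extract_xic(run: Run, targets: list[float], tol_ppm: float = 10.0,
                competing_mz: list[float] | None = None) -> list[Chromatogram]:
    """Per-scan summed intensity within +/- tol_ppm of each target m/z.

    ``competing_mz`` resolves near-isobaric interference: when given, an
    observed centroid inside a target's tolerance window contributes only if
    that target is the nearest member of the competing set (e.g. the +1
    isotopologue of a peptide form sits ~14 ppm below the monoisotopic peak
    of its once-deamidated form at z=2; nearest-target assignment keeps the
    two channels from bleeding into each other when mass error spreads the
    centroids)."""
    ms1 = run.ms1()
    if not ms1:
        raise QuantError(f"run {run.sample_id} contains no MS1 scans")
    rt = np.array([s.rt for s in ms1])
    competitors = None
    if competing_mz is not None:
        competitors = np.sort(np.asarray(competing_mz, dtype=np.float64))
    out = []
    for target in targets:
        half = target * tol_ppm * 1e-6
        lo, hi = target - half, target + half
        trace = np.empty(len(ms1))
        for i, s in enumerate(ms1):
            a = np.searchsorted(s.mz_array, lo, side="left")
            b = np.searchsorted(s.mz_array, hi, side="right")
            if b <= a:
                trace[i] = 0.0
                continue
            mz_hits = s.mz_array[a:b]
            int_hits = s.intensity_array[a:b]
            if competitors is not None and competitors.size > 1:
                idx = np.clip(np.searchsorted(competitors, mz_hits), 1,
                              competitors.size - 1)
                nearest = np.where(
                    np.abs(mz_hits - competitors[idx - 1])
                    <= np.abs(mz_hits - competitors[idx]),
                    competitors[idx - 1], competitors[idx])
                keep = np.abs(nearest - target) < 1e-9
                trace[i] = int_hits[keep].sum()
            else:
                trace[i] = int_hits.sum()
        out.append(Chromatogram(target, rt, trace))
    return out


def detect_and_integrate(
    chromatograms: list[Chromatogram],
    expected_rt: float | None = None,
    rt_window: float = 30.0,
    boundary_fraction: float = 0.01,
) -> PeakIntegration:
    """Pick the apex on the monoisotopic (first) trace and integrate all traces.

    The apex is the global maximum of the A0 trace, restricted to
    ``expected_rt +/- rt_window`` when an expected retention time is given.
    Peak bounds extend from the apex until intensity drops below 1% of the
    apex (or the trace ends); each isotopologue trace is integrated by the
    trapezoid rule over those bounds and areas are summed. Ties at equal apex
    intensity resolve to the earliest retention time.
    """
    if not chromatograms:
        raise QuantError("no chromatograms to integrate")
    a0 = chromatograms[0]
    n_iso = len(chromatograms)
    empty = PeakIntegration(None, None, None, None, None, np.zeros(n_iso), 0.0)
    if a0.rt.size == 0:
        return empty

    mask = np.ones(a0.rt.size, dtype=bool)
    if expected_rt is not None:
        mask = np.abs(a0.rt - expected_rt) <= rt_window
        if not mask.any():
            return empty
    masked = np.where(mask, a0.intensity, -np.inf)
    apex_idx = int(np.argmax(masked))  # argmax returns the first (earliest) maximum
    apex_int = a0.intensity[apex_idx]
    if apex_int <= 0:
        return empty

    floor = boundary_fraction * apex_int
    i0 = apex_idx
    while i0 > 0 and a0.intensity[i0 - 1] >= floor:
        i0 -= 1
    i1 = apex_idx
    while i1 < a0.intensity.size - 1 and a0.intensity[i1 + 1] >= floor:
        i1 += 1

    iso_areas = np.array([
        np.trapezoid(c.intensity[i0:i1 + 1], c.rt[i0:i1 + 1]) if i1 > i0 else 0.0
        for c in chromatograms
    ])
    return PeakIntegration(
        apex_rt=float(a0.rt[apex_idx]), apex_index=apex_idx,
        rt_start=float(a0.rt[i0]), rt_end=float(a0.rt[i1]),
        index_bounds=(i0, i1), iso_areas=iso_areas, area=float(iso_areas.sum()))


def envelope_score(observed: np.ndarray, theoretical: np.ndarray) -> float:
    """Cosine similarity of observed vs theoretical isotopologue intensities.

    1 for proportional vectors, 0 for orthogonal or all-zero observations.
    """
    observed = np.asarray(observed, dtype=np.float64)
    theoretical = np.asarray(theoretical, dtype=np.float64)
    if observed.shape != theoretical.shape:
        raise QuantError("envelope vectors differ in length")
    n_obs = np.linalg.norm(observed)
    n_theo = np.linalg.norm(theoretical)
    if n_obs == 0 or n_theo == 0:
        return 0.0
    return float(np.dot(observed, theoretical) / (n_obs * n_theo))


def ms2_validate(run: Run, marker: MarkerPeptide, tol_ppm: float = 20.0,
                 min_ions: int = 4) -> tuple[int, bool | None]:
    """Count matched b/y fragments in MS2 spectra targeting the marker.

    Considers MS2 spectra whose precursor m/z lies within the isolation
    half-width of the marker m/z; counts distinct theoretical b/y ions
    (charges 1-2) matched within the ppm tolerance. Returns ``(max matched
    over spectra, passed)``; if no MS2 spectrum targets the marker the result
    is ``(0, None)`` (not evaluated — MS1-only mode).
    """
    frags = chem.fragment_ions(marker.peptide, ("b", "y"), max_charge=2)
    target = marker.mz
    best = 0
    evaluated = False
    for s in run.ms2():
        if s.precursor is None:
            continue
        if abs(s.precursor.mz - target) > s.precursor.isolation_half_width:
            continue
        evaluated = True
        matched = 0
        for _, fmz in frags:
            half = fmz * tol_ppm * 1e-6
            a = np.searchsorted(s.mz_array, fmz - half, side="left")
            b = np.searchsorted(s.mz_array, fmz + half, side="right")
            if b > a:
                matched += 1
        best = max(best, matched)
    if not evaluated:
        return 0, None
    return best, best >= min_ions


def quantify_marker(run: Run, marker: MarkerPeptide,
                    params: QuantParams | None = None) -> MarkerQuantResult:
    """Full targeted quantification of one marker in one run."""
    params = params or QuantParams()
    env = chem.isotope_envelope(
        chem.elemental_composition(marker.peptide), marker.charge, params.n_peaks)
    targets = [m for m, _ in env]
    theoretical = np.array([a for _, a in env])

    chroms = extract_xic(run, targets, params.tol_ppm_ms1)
    expected = (params.expected_rt or {}).get(marker.id)
    peak = detect_and_integrate(chroms, expected_rt=expected, rt_window=params.rt_window)
    score = envelope_score(peak.iso_areas, theoretical)

    reasons: list[str] = []
    # relative noise floor: median out-of-peak intensity of the summed trace,
    # scaled by the peak duration
    if peak.index_bounds is not None:
        i0, i1 = peak.index_bounds
        summed = np.sum([c.intensity for c in chroms], axis=0)
        outside = np.concatenate([summed[:i0], summed[i1 + 1:]])
        baseline = float(np.median(outside)) if outside.size else 0.0
        duration = peak.rt_end - peak.rt_start
        floor = params.floor_multiplier * baseline * duration
    else:
        floor = 0.0

    if peak.area <= max(floor, params.min_area):
        reasons.append("area below floor")
    if score < params.min_envelope_score:
        reasons.append("envelope_score")

    matched, ms2_pass = 0, None
    if params.use_ms2:
        matched, ms2_pass = ms2_validate(run, marker, params.tol_ppm_ms2, params.min_ions)
        if ms2_pass is False:
            reasons.append("ms2_validation")

    detected = not reasons
    return MarkerQuantResult(
        marker_id=marker.id, area=peak.area, apex_rt=peak.apex_rt,
        rt_start=peak.rt_start, rt_end=peak.rt_end,
        iso_areas=[float(a) for a in peak.iso_areas],
        envelope_score=score, ms2_matched_ions=matched,
        ms2_evaluated=ms2_pass is not None, detected=detected, reasons=reasons)
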