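"""Synthetic DDA run generator with known ground truth.

Emulates, at desk scale, the structure of the study design this package
targets: data-dependent acquisition runs over an MS1 range of 350-1650 m/z in
which the four amelogenin marker peptides elute as Gaussian chromatographic
peaks — AmelY signal present only in male samples — alongside partially
deamidated AmelX-like background peptides whose deamidation occupancy is
elevated in "archaeological" samples, plus uniform random decoy peaks.

Every run is produced from a :class:`SampleSpec` and is deterministic given
its seed; the paired :class:`GroundTruth` records the injected chromatographic
area of each species (closed-form Gaussian integral, apex * sigma * sqrt(2pi))
so downstream quantification can be scored against what was actually emitted.

Scale defaults: 600 s run, one MS1 scan per second, 6 s FWHM elution peaks —
a compact stand-in for a 50-minute gradient that preserves every property the
pipeline depends on (peak shape, isotopic structure, DDA triggering, dynamic
exclusion) at a fraction of the size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from math import comb
from typing import Literal, Sequence

import numpy as np

from . import chem
from .panel import MarkerPanel, load_panel
from .spectra import Precursor, Run, Spectrum

MS1_RANGE = (350.0, 1650.0)
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: default apex ion intensities (arbitrary counts) for a male sample, echoing
#: the order of magnitude of reported male XIC intensities
DEFAULT_MARKER_APEX = {"Y1": 1.0e8, "Y2": 8.0e7, "X1": 3.0e8, "X2": 2.0e8}
#: default elution apex retention times, seconds
DEFAULT_MARKER_RT = {"Y1": 150.0, "Y2": 230.0, "X1": 310.0, "X2": 390.0}

#: default AmelX-like background peptides (sequence, apex intensity, RT s).
#: Each carries deamidatable sites of a single residue class so that MS1
#: count-channels attribute unambiguously to N or Q.
DEFAULT_BACKGROUND = (
    ("HPLQPLQPLAPQ", 5.0e7, 180.0),
    ("SPLNPHLNGLAS", 6.0e7, 260.0),
)

DEFAULT_OCCUPANCY = {"modern": (0.20, 0.10), "archaeological": (0.60, 0.50)}

DEAMIDATION_DELTA = 0.984016


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class BackgroundPeptide:
    sequence: str
    apex_intensity: float
    rt_center: float
    charge: int = 2


@dataclass
class SampleSpec:
    """Full description of one synthetic sample run."""

    sample_id: str
    sex: Literal["male", "female"]
    era: Literal["modern", "archaeological"] = "modern"
    marker_apex: dict[str, float] = None
    marker_rt: dict[str, float] = None
    rt_sigma: float = 6.0 * FWHM_TO_SIGMA  # 6 s FWHM elution peaks
    scan_interval: float = 1.0
    run_length: float = 600.0
    mass_jitter_ppm: float = 3.0
    baseline_intensity: float = 0.0
    noise_cv: float = 0.05
    p_N: float = None
    p_Q: float = None
    background_peptides: tuple[BackgroundPeptide, ...] = None
    decoy_density: float = 20.0
    decoy_intensity_scale: float = 1.0e4
    n_peaks: int = 4
    top_n: int = 10
    dynamic_exclusion: float = 20.0
    ms2_min_intensity: float = 1.0e5
    ms2_enabled: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise SimulationError(f"sex must be male or female, got {self.sex!r}")
        if self.era not in ("modern", "archaeological"):
            raise SimulationError(f"era must be modern or archaeological, got {self.era!r}")
        if self.marker_apex is None:
            self.marker_apex = dict(DEFAULT_MARKER_APEX)
        if self.marker_rt is None:
            self.marker_rt = dict(DEFAULT_MARKER_RT)
        p_n_default, p_q_default = DEFAULT_OCCUPANCY[self.era]
        if self.p_N is None:
            self.p_N = p_n_default
        if self.p_Q is None:
            self.p_Q = p_q_default
        if not (0.0 <= self.p_N <= 1.0 and 0.0 <= self.p_Q <= 1.0):
            raise SimulationError("deamidation occupancies must lie in [0, 1]")
        if self.background_peptides is None:
            self.background_peptides = tuple(
                BackgroundPeptide(s, a, rt) for s, a, rt in DEFAULT_BACKGROUND
            )
        for v in self.marker_apex.values():
            if v < 0:
                raise SimulationError("negative marker apex intensity")


@dataclass
class GroundTruth:
    """What was injected into a synthetic run, by construction."""

    sample_id: str
    sex: str
    era: str
    p_N: float
    p_Q: float
    marker_area: dict[str, float]  # intensity * s, closed-form Gaussian integral
    background_forms: list[dict]  # sequence, n_deam_N, n_deam_Q, weight, area


@dataclass(frozen=True)
class _Species:
    label: str
    kind: str  # "marker" | "background"
    peptide: chem.ModifiedPeptide
    charge: int
    apex: float
    rt_center: float
    iso_mz: tuple[float, ...]
    iso_abundance: tuple[float, ...]


def _deamidated_form(sequence: str, n_deam_n: int, n_deam_q: int,
                     registry: chem.ModificationRegistry) -> chem.ModifiedPeptide:
    """A representative positional isomer with the requested per-class
    deamidation counts (isomers are isobaric; the lowest positions are used)."""
    pos_n = [i + 1 for i, aa in enumerate(sequence) if aa == "N"]
    pos_q = [i + 1 for i, aa in enumerate(sequence) if aa == "Q"]
    mods = tuple((p, "Deamidation") for p in pos_n[:n_deam_n] + pos_q[:n_deam_q])
    return chem.ModifiedPeptide(sequence, mods, registry=registry)


def _build_species(spec: SampleSpec, panel: MarkerPanel,
                   registry: chem.ModificationRegistry,
                   prune_weight: float = 1e-3) -> tuple[list[_Species], GroundTruth]:
    area_factor = spec.rt_sigma * math.sqrt(2.0 * math.pi)
    species: list[_Species] = []
    marker_area: dict[str, float] = {}

    marker_apex = dict(spec.marker_apex)
    if spec.sex == "female":
        for m in panel.by_source("AmelY"):
            marker_apex[m.id] = 0.0

    for marker in panel:
        apex = marker_apex.get(marker.id, 0.0)
        marker_area[marker.id] = apex * area_factor
        if apex <= 0:
            continue
        rt = spec.marker_rt.get(marker.id)
        if rt is None or not (0.0 <= rt <= spec.run_length):
            raise SimulationError(f"marker {marker.id}: RT {rt} outside run length")
        env = chem.isotope_envelope(
            chem.elemental_composition(marker.peptide), marker.charge, spec.n_peaks)
        species.append(_Species(
            label=marker.id, kind="marker", peptide=marker.peptide,
            charge=marker.charge, apex=apex, rt_center=rt,
            iso_mz=tuple(m for m, _ in env), iso_abundance=tuple(a for _, a in env)))

    background_forms: list[dict] = []
    for bg in spec.background_peptides:
        if not (0.0 <= bg.rt_center <= spec.run_length):
            raise SimulationError(f"background {bg.sequence}: RT outside run length")
        k_n = bg.sequence.count("N")
        k_q = bg.sequence.count("Q")
        for j_n in range(k_n + 1):
            w_n = comb(k_n, j_n) * spec.p_N ** j_n * (1 - spec.p_N) ** (k_n - j_n)
            for j_q in range(k_q + 1):
                w_q = comb(k_q, j_q) * spec.p_Q ** j_q * (1 - spec.p_Q) ** (k_q - j_q)
                w = w_n * w_q
                if w < prune_weight:
                    continue
                pep = _deamidated_form(bg.sequence, j_n, j_q, registry)
                env = chem.isotope_envelope(
                    chem.elemental_composition(pep), bg.charge, spec.n_peaks)
                apex = bg.apex_intensity * w
                species.append(_Species(
                    label=f"{bg.sequence}/dN{j_n}dQ{j_q}", kind="background",
                    peptide=pep, charge=bg.charge, apex=apex, rt_center=bg.rt_center,
                    iso_mz=tuple(m for m, _ in env),
                    iso_abundance=tuple(a for _, a in env)))
                background_forms.append({
                    "sequence": bg.sequence, "n_deam_N": j_n, "n_deam_Q": j_q,
                    "weight": w, "area": apex * area_factor,
                })

    truth = GroundTruth(
        sample_id=spec.sample_id, sex=spec.sex, era=spec.era,
        p_N=spec.p_N, p_Q=spec.p_Q, marker_area=marker_area,
        background_forms=background_forms)
    return species, truth


def _merge_peaks(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort by m/z and coalesce peaks closer than 1e-5 (required for strictly
    ascending centroid arrays)."""
    if mz.size == 0:
        return mz, intensity
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    keep_mz, keep_int = [mz[0]], [intensity[0]]
    for m, i in zip(mz[1:], intensity[1:]):
        if m - keep_mz[-1] < 1e-5:
            keep_int[-1] += i
        else:
            keep_mz.append(m)
            keep_int.append(i)
    return np.array(keep_mz), np.array(keep_int)


def simulate_run(spec: SampleSpec,
                 panel: MarkerPanel | None = None) -> tuple[Run, GroundTruth]:
    """Simulate one DDA run per the sample spec; deterministic given its seed."""
    panel = panel or load_panel()
    registry = chem.ModificationRegistry.default()
    rng = np.random.default_rng(spec.seed)
    species, truth = _build_species(spec, panel, registry)

    frag_cache: dict[str, list[tuple[str, float]]] = {}
    scan_times = np.arange(0.0, spec.run_length, spec.scan_interval)
    spectra: list[Spectrum] = []
    exclusion: list[tuple[float, float]] = []  # (m/z, trigger time)
    scan_counter = 0

    for t in scan_times:
        mz_list: list[float] = []
        int_list: list[float] = []
        owner: list[int] = []  # index into species, -1 for decoy/baseline
        for si, sp in enumerate(species):
            elut = sp.apex * math.exp(-((t - sp.rt_center) ** 2) / (2.0 * spec.rt_sigma ** 2))
            if elut < max(1e-6 * sp.apex, 1e-3):
                continue
            n = len(sp.iso_mz)
            jitter = rng.normal(0.0, spec.mass_jitter_ppm * 1e-6, size=n) \
                if spec.mass_jitter_ppm > 0 else np.zeros(n)
            noise = rng.normal(0.0, spec.noise_cv, size=n) \
                if spec.noise_cv > 0 else np.zeros(n)
            for k in range(n):
                inten = elut * sp.iso_abundance[k] * max(0.0, 1.0 + noise[k])
                if inten <= 0:
                    continue
                mz_list.append(sp.iso_mz[k] * (1.0 + jitter[k]))
                int_list.append(inten + spec.baseline_intensity)
                owner.append(si)
        if spec.decoy_density > 0:
            n_decoy = rng.poisson(spec.decoy_density)
            if n_decoy:
                dmz = rng.uniform(*MS1_RANGE, size=n_decoy)
                dint = rng.exponential(spec.decoy_intensity_scale, size=n_decoy)
                mz_list.extend(dmz.tolist())
                int_list.extend(dint.tolist())
                owner.extend([-1] * n_decoy)

        mz_arr = np.array(mz_list)
        int_arr = np.array(int_list)
        merged_mz, merged_int = _merge_peaks(mz_arr, int_arr)
        scan_counter += 1
        spectra.append(Spectrum(
            scan_id=str(scan_counter), ms_level=1, rt=float(t),
            mz_array=merged_mz, intensity_array=merged_int))

        if not spec.ms2_enabled or merged_mz.size == 0:
            continue

        # DDA cycle: top-N precursors by intensity (tie-break: m/z ascending),
        # skipping anything on the 20 s dynamic-exclusion list.
        exclusion = [(m, t0) for m, t0 in exclusion if t - t0 < spec.dynamic_exclusion]
        order = np.lexsort((merged_mz, -merged_int))
        selected = 0
        for idx in order:
            if selected >= spec.top_n:
                break
            pmz = float(merged_mz[idx])
            pint = float(merged_int[idx])
            if pint < spec.ms2_min_intensity:
                break
            if any(abs(pmz - em) / em <= 10e-6 for em, _ in exclusion):
                continue
            exclusion.append((pmz, float(t)))
            selected += 1
            # which species (if any) sits inside the isolation window?
            best = None
            for sp in species:
                if abs(sp.iso_mz[0] - pmz) <= 0.85:
                    if best is None or abs(sp.iso_mz[0] - pmz) < abs(best.iso_mz[0] - pmz):
                        best = sp
            fmz: list[float] = []
            fint: list[float] = []
            charge = None
            if best is not None:
                charge = best.charge
                key = str(best.peptide)
                if key not in frag_cache:
                    frag_cache[key] = chem.fragment_ions(best.peptide, ("b", "y"), 1)
                frags = frag_cache[key]
                for _, fm in frags:
                    fmz.append(fm * (1.0 + rng.normal(0.0, spec.mass_jitter_ppm * 1e-6)))
                    fint.append(pint * rng.uniform(0.02, 0.2))
            n_frag_decoys = rng.poisson(5)
            if n_frag_decoys:
                fmz.extend(rng.uniform(100.0, 1300.0, size=n_frag_decoys).tolist())
                fint.extend(rng.exponential(
                    spec.decoy_intensity_scale, size=n_frag_decoys).tolist())
            if not fmz:
                continue
            m_arr, i_arr = _merge_peaks(np.array(fmz), np.array(fint))
            scan_counter += 1
            spectra.append(Spectrum(
                scan_id=str(scan_counter), ms_level=2,
                rt=float(t) + spec.scan_interval * (0.05 + 0.9 * selected / (spec.top_n + 1)),
                mz_array=m_arr, intensity_array=i_arr,
                precursor=Precursor(pmz, charge, 0.85)))

    spectra.sort(key=lambda s: s.rt)
    run = Run(sample_id=spec.sample_id, spectra=spectra,
              metadata={"sex_truth": spec.sex, "era": spec.era, "seed": spec.seed})
    return run, truth


def _subseed(master_seed: int, k: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(k,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def simulate_cohort(
    n_samples: int,
    sexes: Sequence[str] | None = None,
    eras: Sequence[str] | str = "modern",
    seed: int = 0,
    panel: MarkerPanel | None = None,
    base_spec: SampleSpec | None = None,
    p_N: float | None = None,
    p_Q: float | None = None,
) -> list[tuple[Run, GroundTruth]]:
    """Simulate a cohort with per-sample sub-seeds derived from the master seed.

    ``sexes`` defaults to alternating male/female; ``eras`` may be one label
    for the whole cohort or a per-sample sequence. Occupancies follow each
    sample's era defaults unless ``p_N``/``p_Q`` are given explicitly.
    Sub-seeds are independent: each sample's randomness depends only on
    (master seed, sample index).
    """
    if n_samples < 1:
        raise SimulationError("cohort size must be >= 1")
    if sexes is None:
        sexes = ["male" if i % 2 == 0 else "female" for i in range(n_samples)]
    if len(sexes) != n_samples:
        raise SimulationError("sex assignment length mismatch")
    if isinstance(eras, str):
        eras = [eras] * n_samples
    if len(eras) != n_samples:
        raise SimulationError("era assignment length mismatch")

    out = []
    for k in range(n_samples):
        era_p_n, era_p_q = DEFAULT_OCCUPANCY[eras[k]]
        occ = {"p_N": p_N if p_N is not None else era_p_n,
               "p_Q": p_Q if p_Q is not None else era_p_q}
        if base_spec is not None:
            spec = replace(base_spec, sample_id=f"S{k + 1:03d}", sex=sexes[k],
                           era=eras[k], seed=_subseed(seed, k), **occ)
        else:
            spec = SampleSpec(sample_id=f"S{k + 1:03d}", sex=sexes[k], era=eras[k],
                              seed=_subseed(seed, k), **occ)
        out.append(simulate_run(spec, panel=panel))
    return out
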