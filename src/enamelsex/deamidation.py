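"""Bulk deamidation occupancy as a diagenesis / authenticity statistic.

Deamidation converts Asn and Gln to Asp and Glu (+0.984016 Da per site) and
accumulates with sample age, so the intensity-weighted fraction of deamidated
sites in the enamel background peptidome separates ancient from modern
material. Occupancy is computed per residue class X in {N, Q} as

    occupancy(X) = sum_i area_i * n_deamidated_i(X) / sum_i area_i * n_sites_i(X)

over quantified peptide forms i — a site-level, intensity-weighted fraction
that is unbiased when forms carry unequal site counts. Arginine deamidation
(citrullination) is excluded from the bulk statistic by default.

At MS1 resolution, forms of one peptide that share a total deamidation count
are isobaric, so quantification from a run can only attribute a count channel
to a residue class when the peptide's deamidatable sites are all of one
class; :func:`occupancy_from_run` therefore requires single-class background
peptides (the simulator defaults comply) and raises otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import chem, quant
from .simulate import BackgroundPeptide, DEAMIDATION_DELTA
from .spectra import Run

CLASSES = ("N", "Q")


class DeamidationError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideFormQuant:
    """One quantified peptide form with its deamidation bookkeeping."""

    sequence: str
    area: float
    n_deamidated: dict  # class -> count of deamidated sites
    source: str = "AmelX"

    def __post_init__(self):
        if self.area < 0:
            raise DeamidationError("negative area")
        for cls in self.n_deamidated:
            if not 0 <= self.n_deamidated[cls] <= self.n_sites(cls):
                raise DeamidationError(
                    f"{self.sequence}: {self.n_deamidated[cls]} deamidated "
                    f"{cls} sites but only {self.n_sites(cls)} present")

    def n_sites(self, cls: str) -> int:
        return self.sequence.count(cls)


@dataclass
class OccupancyResult:
    occupancy: dict  # class -> float | None (missing when no eligible signal)
    total_area: dict  # class -> summed weighting intensity
    n_forms: dict  # class -> number of forms used


def bulk_occupancy(forms: list[PeptideFormQuant], cls: str) -> float | None:
    """Intensity-weighted site-level deamidation fraction for one class.

    Returns None (missing, not zero) when no form contributes weight.
    """
    if cls not in CLASSES:
        raise DeamidationError(f"class must be one of {CLASSES}, got {cls!r}")
    num = sum(f.area * f.n_deamidated.get(cls, 0) for f in forms)
    den = sum(f.area * f.n_sites(cls) for f in forms)
    if den == 0:
        return None
    return num / den


def occupancy_from_forms(forms: list[PeptideFormQuant]) -> OccupancyResult:
    occ, tot, nf = {}, {}, {}
    for cls in CLASSES:
        eligible = [f for f in forms if f.n_sites(cls) > 0]
        occ[cls] = bulk_occupancy(forms, cls)
        tot[cls] = sum(f.area * f.n_sites(cls) for f in eligible)
        nf[cls] = len(eligible)
    return OccupancyResult(occ, tot, nf)


def occupancy_from_run(
    run: Run,
    background_peptides: list[BackgroundPeptide],
    params: quant.QuantParams | None = None,
) -> OccupancyResult:
    """Quantify every deamidation count-channel of each background peptide by
    XIC and convert to bulk occupancies.

    Channels whose observed isotopic envelope scores below the configured
    threshold are excluded (score gating keeps chance XIC hits out of the
    statistic). Peptides containing both N and Q sites are rejected — their
    count channels are isobaric across classes.
    """
    params = params or quant.QuantParams()
    registry = chem.ModificationRegistry.default()
    forms: list[PeptideFormQuant] = []
    for bg in background_peptides:
        k_n, k_q = bg.sequence.count("N"), bg.sequence.count("Q")
        if k_n > 0 and k_q > 0:
            raise DeamidationError(
                f"{bg.sequence}: peptides with both N and Q sites cannot be "
                "class-attributed from MS1 count channels")
        cls = "N" if k_n else "Q"
        k = max(k_n, k_q)
        if k == 0:
            continue
        base = chem.ModifiedPeptide(bg.sequence, registry=registry)
        base_mass = chem.monoisotopic_mass(base)
        comp = chem.elemental_composition(base)
        deam_delta_comp = registry["Deamidation"].composition_delta
        # isotopologue positions of every count channel; used as competing
        # targets so adjacent channels (~14 ppm apart at z=2) do not bleed
        channel_targets = {}
        for j in range(k + 1):
            mono_mz = chem.mz(base_mass + j * DEAMIDATION_DELTA, bg.charge)
            channel_targets[j] = [mono_mz + i * chem.ISOTOPE_SPACING / bg.charge
                                  for i in range(params.n_peaks)]
        all_targets = [t for ts in channel_targets.values() for t in ts]
        for j in range(k + 1):
            env = chem.isotope_envelope(comp + deam_delta_comp * j,
                                        bg.charge, params.n_peaks)
            theoretical = np.array([a for _, a in env])
            targets = channel_targets[j]
            chroms = quant.extract_xic(run, targets, params.tol_ppm_ms1,
                                       competing_mz=all_targets)
            peak = quant.detect_and_integrate(
                chroms, expected_rt=bg.rt_center, rt_window=params.rt_window)
            if peak.area <= 0:
                continue
            score = quant.envelope_score(peak.iso_areas, theoretical)
            if score < params.min_envelope_score:
                continue
            forms.append(PeptideFormQuant(
                sequence=bg.sequence, area=peak.area,
                n_deamidated={cls: j}))
    return occupancy_from_forms(forms)


@dataclass
class GroupComparison:
    mean_a: dict
    mean_b: dict
    fold_change: dict  # class -> mean_B / mean_A; inf flagged when mean_A == 0
    n_a: dict
    n_b: dict


def compare_groups(group_a: list[OccupancyResult],
                   group_b: list[OccupancyResult]) -> GroupComparison:
    """Per-class group means and fold change (mean_B / mean_A), skipping
    missing occupancies."""
    mean_a, mean_b, fold, n_a, n_b = {}, {}, {}, {}, {}
    for cls in CLASSES:
        vals_a = [r.occupancy[cls] for r in group_a if r.occupancy[cls] is not None]
        vals_b = [r.occupancy[cls] for r in group_b if r.occupancy[cls] is not None]
        if not vals_a or not vals_b:
            raise DeamidationError(f"class {cls}: a group has no defined occupancy")
        mean_a[cls] = float(np.mean(vals_a))
        mean_b[cls] = float(np.mean(vals_b))
        n_a[cls], n_b[cls] = len(vals_a), len(vals_b)
        fold[cls] = math.inf if mean_a[cls] == 0 else mean_b[cls] / mean_a[cls]
    return GroupComparison(mean_a, mean_b, fold, n_a, n_b)
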