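"""Exact peptide mass, elemental composition, isotopic envelopes and b/y fragments.

All masses are monoisotopic, in daltons. Physical constants are pinned in one
place so that every printed four-decimal m/z in the marker panel is reproduced
bit-for-bit from sequence + modification tables:

* proton mass 1.0072765 Da
* water (condensation) mass 18.0105646 Da
* average isotopologue spacing 1.0033548 Da (the C13-C12 mass difference)

Residue monoisotopic masses come from the standard amino-acid table, stated to
five decimal places. I and L are distinct letters with identical mass; no
implicit interconversion is ever performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

PROTON = 1.0072765
WATER = 18.0105646
ISOTOPE_SPACING = 1.0033548

#: residue (amino acid minus water) monoisotopic masses, Da
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: residue elemental formulas (C, H, N, O, S, P)
RESIDUE_FORMULA = {
    "G": (2, 3, 1, 1, 0, 0), "A": (3, 5, 1, 1, 0, 0),
    "S": (3, 5, 1, 2, 0, 0), "P": (5, 7, 1, 1, 0, 0),
    "V": (5, 9, 1, 1, 0, 0), "T": (4, 7, 1, 2, 0, 0),
    "C": (3, 5, 1, 1, 1, 0), "L": (6, 11, 1, 1, 0, 0),
    "I": (6, 11, 1, 1, 0, 0), "N": (4, 6, 2, 2, 0, 0),
    "D": (4, 5, 1, 3, 0, 0), "Q": (5, 8, 2, 2, 0, 0),
    "K": (6, 12, 2, 1, 0, 0), "E": (5, 7, 1, 3, 0, 0),
    "M": (5, 9, 1, 1, 1, 0), "H": (6, 7, 3, 1, 0, 0),
    "F": (9, 9, 1, 1, 0, 0), "R": (6, 12, 4, 1, 0, 0),
    "Y": (9, 9, 1, 2, 0, 0), "W": (11, 10, 2, 1, 0, 0),
}

ELEMENTS = ("C", "H", "N", "O", "S", "P")

#: monoisotopic mass of the lightest isotope of each element
ELEMENT_MASS = {
    "C": 12.0, "H": 1.0078250, "N": 14.0030740,
    "O": 15.9949146, "S": 31.9720707, "P": 30.9737615,
}

#: natural isotope abundances indexed by nominal mass shift (A, A+1, A+2, ...)
ISOTOPE_ABUNDANCE = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "P": (1.0,),
}


class PeptideChemistryError(ValueError):
    """Raised for invalid sequences or disallowed modification placements."""


@dataclass(frozen=True)
class ElementalComposition:
    """Element counts (C, H, N, O, S, P). Deltas may be negative; a full
    peptide composition must be non-negative."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0
    P: int = 0

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(*(getattr(self, e) + getattr(other, e) for e in ELEMENTS))

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition(*(getattr(self, e) * k for e in ELEMENTS))

    def as_dict(self) -> dict[str, int]:
        return {e: getattr(self, e) for e in ELEMENTS if getattr(self, e) != 0}

    @property
    def n_atoms(self) -> int:
        return sum(getattr(self, e) for e in ELEMENTS)

    def mass(self) -> float:
        """Monoisotopic mass reconstructed from element counts."""
        return sum(getattr(self, e) * ELEMENT_MASS[e] for e in ELEMENTS)


WATER_COMPOSITION = ElementalComposition(H=2, O=1)


@dataclass(frozen=True)
class Modification:
    name: str
    mass_delta: float
    composition_delta: ElementalComposition
    allowed_residues: frozenset[str]  # one-letter codes; "N-term" allows N-terminal placement

    def __post_init__(self):
        if abs(self.mass_delta - self.composition_delta.mass()) > 1e-4:
            raise PeptideChemistryError(
                f"modification {self.name}: mass delta {self.mass_delta} inconsistent "
                f"with composition delta ({self.composition_delta.mass():.6f})"
            )


class ModificationRegistry:
    """Named post-translational modifications with mass and composition deltas.

    The shipped registry carries the modifications relevant to acid-etched
    enamel peptidomes: oxidation, di-oxidation, deamidation, phosphorylation,
    N-terminal acetylation and the two pyro-Glu conversions.
    """

    def __init__(self, mods: Iterable[Modification] = ()):
        self._mods: dict[str, Modification] = {}
        for m in mods:
            self.add(m)

    def add(self, mod: Modification) -> None:
        self._mods[mod.name] = mod

    def __getitem__(self, name: str) -> Modification:
        try:
            return self._mods[name]
        except KeyError:
            raise PeptideChemistryError(f"unknown modification: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._mods

    def names(self) -> list[str]:
        return sorted(self._mods)

    @classmethod
    def default(cls) -> "ModificationRegistry":
        """Registry shipped with the package (see data/modifications.tsv)."""
        path = resources.files("enamelsex.data").joinpath("modifications.tsv")
        return cls.from_tsv(path.read_text())

    @classmethod
    def from_tsv(cls, text: str) -> "ModificationRegistry":
        """Parse the key-value registry format: name, mass delta, composition
        delta as e.g. ``O:1,H:-1,N:-1``, allowed residues as letters (``Nterm``
        marks N-terminal placement)."""
        reg = cls()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, delta, comp, residues = [f.strip() for f in line.split("\t")]
            counts = {}
            if comp:
                for item in comp.split(","):
                    el, n = item.split(":")
                    counts[el.strip()] = int(n)
            allowed = frozenset(
                "N-term" if r == "Nterm" else r for r in residues.split(",") if r
            )
            reg.add(Modification(name, float(delta), ElementalComposition(**counts), allowed))
        return reg


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with positioned modifications.

    ``modifications`` is a tuple of ``(position, name)`` where position is a
    1-based residue index or the string ``"N-term"``.
    """

    sequence: str
    modifications: tuple[tuple[int | str, str], ...] = ()
    registry: ModificationRegistry = field(default=None, compare=False, hash=False)

    def __post_init__(self):
        if not self.sequence:
            raise PeptideChemistryError("empty peptide sequence")
        for aa in self.sequence:
            if aa not in RESIDUE_MASS:
                raise PeptideChemistryError(f"unknown residue letter {aa!r}")
        reg = self.registry or ModificationRegistry.default()
        object.__setattr__(self, "registry", reg)
        seen = set()
        for pos, name in self.modifications:
            mod = reg[name]
            if "N-term" in mod.allowed_residues:
                # N-terminal-only modification; residue letters, if present,
                # constrain the first residue (pyro-Glu conversions).
                if pos != "N-term":
                    raise PeptideChemistryError(f"{name} is N-terminal only")
                letters = mod.allowed_residues - {"N-term"}
                if letters and self.sequence[0] not in letters:
                    raise PeptideChemistryError(
                        f"{name} requires N-terminal residue in {sorted(letters)}, "
                        f"got {self.sequence[0]!r}"
                    )
            elif pos == "N-term":
                raise PeptideChemistryError(f"{name} is not an N-terminal modification")
            else:
                if not (1 <= pos <= len(self.sequence)):
                    raise PeptideChemistryError(
                        f"modification position {pos} outside 1..{len(self.sequence)}"
                    )
                aa = self.sequence[pos - 1]
                if aa not in mod.allowed_residues:
                    raise PeptideChemistryError(
                        f"{name} not allowed on residue {aa!r} at position {pos}"
                    )
            key = (pos, name)
            if key in seen:
                raise PeptideChemistryError(f"duplicate modification {key}")
            seen.add(key)

    def mod_objects(self) -> list[tuple[int | str, Modification]]:
        return [(pos, self.registry[name]) for pos, name in self.modifications]

    def __str__(self) -> str:
        if not self.modifications:
            return self.sequence
        tags = ";".join(f"{p}:{n}" for p, n in self.modifications)
        return f"{self.sequence}[{tags}]"


def monoisotopic_mass(peptide: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas."""
    mass = sum(RESIDUE_MASS[aa] for aa in peptide.sequence) + WATER
    for _, mod in peptide.mod_objects():
        mass += mod.mass_delta
    return mass


def mz(mass: float, z: int) -> float:
    """m/z of the z-fold protonated ion [M+zH]^z+."""
    if z < 1:
        raise PeptideChemistryError(f"charge must be >= 1, got {z}")
    return (mass + z * PROTON) / z


def neutral_mass(mz_value: float, z: int) -> float:
    """Inverse of :func:`mz`."""
    if z < 1:
        raise PeptideChemistryError(f"charge must be >= 1, got {z}")
    return mz_value * z - z * PROTON


def elemental_composition(peptide: ModifiedPeptide) -> ElementalComposition:
    """Summed elemental composition: residues + H2O + modification deltas."""
    comp = WATER_COMPOSITION
    for aa in peptide.sequence:
        comp = comp + ElementalComposition(*RESIDUE_FORMULA[aa])
    for _, mod in peptide.mod_objects():
        comp = comp + mod.composition_delta
    if any(getattr(comp, e) < 0 for e in ELEMENTS):
        raise PeptideChemistryError(f"negative element count in composition of {peptide}")
    return comp


def isotope_envelope(
    composition: ElementalComposition, z: int, n_peaks: int = 4
) -> list[tuple[float, float]]:
    """Theoretical isotopic envelope as ``(m/z, relative abundance)`` pairs.

    Isotopologues are aggregated by nominal mass shift (A0, A+1, ...), computed
    by per-element convolution of natural-abundance distributions, truncated to
    ``n_peaks`` and renormalized to sum to 1. Consecutive peaks are spaced by
    ISOTOPE_SPACING / z.
    """
    if n_peaks < 1:
        raise PeptideChemistryError("n_peaks must be >= 1")
    if composition.n_atoms == 0:
        raise PeptideChemistryError("empty composition")
    if z < 1:
        raise PeptideChemistryError(f"charge must be >= 1, got {z}")
    dist = np.array([1.0])
    for el in ELEMENTS:
        n = getattr(composition, el)
        if n == 0:
            continue
        base = np.asarray(ISOTOPE_ABUNDANCE[el], dtype=float)
        # exponentiation by squaring over convolution
        power = base
        k = n
        elem_dist = np.array([1.0])
        while k:
            if k & 1:
                elem_dist = np.convolve(elem_dist, power)
            k >>= 1
            if k:
                power = np.convolve(power, power)
        dist = np.convolve(dist, elem_dist)
    out = dist[:n_peaks]
    if out.size < n_peaks:
        out = np.pad(out, (0, n_peaks - out.size))
    out = out / out.sum()
    mono_mz = mz(composition.mass(), z)
    return [(mono_mz + i * ISOTOPE_SPACING / z, float(a)) for i, a in enumerate(out)]


def fragment_ions(
    peptide: ModifiedPeptide,
    series: Sequence[str] = ("b", "y"),
    max_charge: int = 1,
) -> list[tuple[str, float]]:
    """Singly/multiply protonated b and y fragment ions.

    Position-resolved modifications are assigned to the fragment that contains
    their residue; N-terminal modifications travel with the b series (and the
    full-length y ion).
    """
    if not series:
        raise PeptideChemistryError("empty ion series selection")
    bad = set(series) - {"b", "y"}
    if bad:
        raise PeptideChemistryError(f"unsupported ion series {sorted(bad)}")
    if len(peptide.sequence) < 2:
        raise PeptideChemistryError("fragmentation requires length >= 2")
    n = len(peptide.sequence)
    residue = [RESIDUE_MASS[aa] for aa in peptide.sequence]
    mod_at = [0.0] * (n + 1)  # index 0 = N-term
    for pos, mod in peptide.mod_objects():
        mod_at[0 if pos == "N-term" else pos] += mod.mass_delta

    prefix = np.cumsum([mod_at[0]] + [residue[i] + mod_at[i + 1] for i in range(n)])
    total = prefix[-1]

    out: list[tuple[str, float]] = []
    for z in range(1, max_charge + 1):
        for i in range(1, n + 1):  # incl. full-length b_n / y_n ions
            if "b" in series:
                m = prefix[i]  # residues 1..i with their mods, + N-term mod
                label = f"b{i}" if z == 1 else f"b{i}^{z}"
                out.append((label, (m + z * PROTON) / z))
            if "y" in series:
                m = total - prefix[n - i] + WATER  # residues n-i+1..n
                label = f"y{i}" if z == 1 else f"y{i}^{z}"
                out.append((label, (m + z * PROTON) / z))
    return out
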