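"""The diagnostic amelogenin marker panel.

Four native enamel peptides distinguish the X- and Y-chromosome amelogenin
copies in cattle through single amino acid variants (SAAVs): two AmelY-unique
peptides (LRYPYP, LRYPYPSY) whose presence indicates a male, and two
AmelX-unique peptides (SM(ox)IRHPYP, IRHPYPSY) that double as an
enamel-recovery control present in both sexes. Each marker carries the charge
state and reference [M+zH]z+ value it is quantified at; the panel loader
recomputes every m/z from sequence + modifications and refuses to load if it
disagrees with the reference beyond 0.002.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO

from . import chem

MZ_CHECK_TOL = 0.002


class PanelError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerPeptide:
    id: str
    peptide: chem.ModifiedPeptide
    source: str  # "AmelX" | "AmelY"
    charge: int
    reference_mz: float
    saav_positions: tuple[int, ...] = ()  # 1-based coordinates in the source protein

    def __post_init__(self):
        if self.source not in ("AmelX", "AmelY"):
            raise PanelError(f"marker {self.id}: source must be AmelX or AmelY")
        if abs(self.mz - self.reference_mz) > MZ_CHECK_TOL:
            raise PanelError(
                f"marker {self.id}: computed m/z {self.mz:.4f} differs from "
                f"reference {self.reference_mz:.4f} by more than {MZ_CHECK_TOL}"
            )

    @property
    def mz(self) -> float:
        return chem.mz(chem.monoisotopic_mass(self.peptide), self.charge)

    @property
    def sequence(self) -> str:
        return self.peptide.sequence


@dataclass(frozen=True)
class MarkerPanel:
    markers: tuple[MarkerPeptide, ...]

    def __post_init__(self):
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate marker ids")
        if not any(m.source == "AmelY" for m in self.markers):
            raise PanelError("panel needs at least one AmelY marker")
        if not any(m.source == "AmelX" for m in self.markers):
            raise PanelError("panel needs at least one AmelX marker")

    def __iter__(self):
        return iter(self.markers)

    def __len__(self):
        return len(self.markers)

    def __getitem__(self, marker_id: str) -> MarkerPeptide:
        for m in self.markers:
            if m.id == marker_id:
                return m
        raise KeyError(marker_id)

    def by_source(self, source: str) -> list[MarkerPeptide]:
        return [m for m in self.markers if m.source == source]


def _parse_mods(text: str) -> tuple[tuple[int | str, str], ...]:
    mods = []
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        pos, name = item.split(":")
        pos = pos.strip()
        mods.append(("N-term" if pos == "N-term" else int(pos), name.strip()))
    return tuple(mods)


def load_panel(path: str | Path | None = None,
               registry: chem.ModificationRegistry | None = None) -> MarkerPanel:
    """Load a marker panel from the tab-separated panel format.

    Columns: id, sequence, mods ("pos:name" semicolon-separated, may be
    empty), charge, reference_mz, source, saav_positions (comma-separated,
    may be empty). Invariants (m/z agreement, source balance, unique ids)
    are enforced at load; a violation is a hard error naming the marker.
    """
    if path is None:
        text = resources.files("enamelsex.data").joinpath("default_panel.tsv").read_text()
    else:
        text = Path(path).read_text()
    registry = registry or chem.ModificationRegistry.default()
    markers = []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 7:
            raise PanelError(f"panel line needs 7 tab-separated fields: {line!r}")
        mid, seq, mods, charge, ref_mz, source, saav = fields
        peptide = chem.ModifiedPeptide(seq.strip(), _parse_mods(mods), registry=registry)
        saav_positions = tuple(int(p) for p in saav.split(",") if p.strip())
        markers.append(MarkerPeptide(
            id=mid.strip(), peptide=peptide, source=source.strip(),
            charge=int(charge), reference_mz=float(ref_mz),
            saav_positions=saav_positions,
        ))
    return MarkerPanel(tuple(markers))


def default_protein_fasta() -> Path:
    """Path of the shipped synthetic AmelX/AmelY stand-in sequences."""
    return Path(str(resources.files("enamelsex.data").joinpath("synthetic_amelogenin.fasta")))


def _occurrences(needle: str, haystack: str, max_mismatches: int = 0) -> list[int]:
    """1-based start positions of needle in haystack, allowing up to
    ``max_mismatches`` substitutions."""
    hits = []
    n, m = len(haystack), len(needle)
    for i in range(n - m + 1):
        window = haystack[i:i + m]
        if max_mismatches == 0:
            if window == needle:
                hits.append(i + 1)
        else:
            mism = sum(a != b for a, b in zip(window, needle))
            if mism <= max_mismatches:
                hits.append(i + 1)
    return hits


def validate_uniqueness(panel: MarkerPanel, fasta_path: str | Path,
                        max_mismatches: int = 0) -> dict[str, dict]:
    """Check that each marker sequence occurs in its source protein and not in
    the homologous one.

    The FASTA must contain one record whose id mentions AmelX and one
    mentioning AmelY (case-insensitive). Returns per marker id a report with
    ``found_in_source``, ``found_in_other``, the occurrence positions, and a
    ``passes`` flag (found in source, absent from the other protein).
    """
    records = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        label = (rec.id + " " + rec.description).lower()
        if "amely" in label:
            records["AmelY"] = str(rec.seq).upper()
        elif "amelx" in label:
            records["AmelX"] = str(rec.seq).upper()
    for needed in ("AmelX", "AmelY"):
        if needed not in records:
            raise PanelError(f"FASTA lacks an {needed} record")

    report = {}
    for marker in panel:
        other = "AmelX" if marker.source == "AmelY" else "AmelY"
        pos_source = _occurrences(marker.sequence, records[marker.source], max_mismatches)
        pos_other = _occurrences(marker.sequence, records[other], max_mismatches)
        report[marker.id] = {
            "found_in_source": bool(pos_source),
            "found_in_other": bool(pos_other),
            "positions_in_source": pos_source,
            "positions_in_other": pos_other,
            "passes": bool(pos_source) and not pos_other,
        }
    return report
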