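"""Diagnostic oxonium-ion checking and isobaric composition reassignment.

NeuGc (N-glycolylneuraminic acid) is a non-human sialic acid, so a putative
NeuGc-containing urinary glycoform is suspect.  Two mass coincidences make
such assignments easy for a search engine to get wrong:

* Fuc + NeuGc is isobaric with Hex + NeuAc (within 1e-4 Da), so
  HexNAc(a)Hex(b)Fuc(c)NeuAc(d)NeuGc(1) collides with
  HexNAc(a)Hex(b+1)Fuc(c-1)NeuAc(d+1);
* NeuGc is isobaric with NeuAc + one oxidation (+15.9949 Da) of the peptide.

The HCD spectrum settles it: NeuAc yields oxonium ions at m/z 292.1027 /
274.0921, NeuGc at 308.0976 / 290.0870.  When a nominally NeuGc-bearing
composition shows only NeuAc diagnostics, a mass-conserving rewrite is
proposed, preferring the pure-glycan rewrite (no extra modification
hypothesis) over adding a peptide oxidation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glycans import (
    MODIFICATION_MASSES,
    GlycanComposition,
    composition_mass,
    oxonium_ions,
)

__all__ = [
    "SpectrumPeaks",
    "ValidationReport",
    "check_diagnostic_ions",
    "reassign_composition",
    "read_peak_list",
]

NEUAC_IONS = tuple(mz for _, mz in oxonium_ions("NeuAc"))
NEUGC_IONS = tuple(mz for _, mz in oxonium_ions("NeuGc"))


@dataclass
class SpectrumPeaks:
    """An MS/MS peak list: (m/z, intensity) pairs plus a match tolerance."""

    mz: np.ndarray
    intensity: np.ndarray
    tol_ppm: float = 10.0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size != self.intensity.size:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.mz <= 0) or np.any(self.intensity < 0):
            raise ValueError("m/z must be positive and intensities nonnegative")

    def match(self, target_mz: float) -> np.ndarray:
        """Indices of peaks within tol_ppm of a target m/z."""
        return np.flatnonzero(np.abs(self.mz - target_mz) / target_mz * 1e6 <= self.tol_ppm)


@dataclass
class ValidationReport:
    neuac_evidence: bool
    neugc_evidence: bool
    matched_peaks: dict[str, list[float]]
    conflict: bool
    proposed_composition: GlycanComposition | None = None
    proposed_extra_modifications: list[str] = field(default_factory=list)
    resolved: bool = False


def check_diagnostic_ions(
    spectrum: SpectrumPeaks,
    comp: GlycanComposition,
    require_both: bool = False,
) -> ValidationReport:
    """Check a spectrum for NeuAc/NeuGc diagnostic oxonium ions.

    Sialic-species evidence means at least one (or, with ``require_both``,
    both) of the species' two diagnostic ions matches a peak within the
    spectrum tolerance.  A conflict is flagged when the nominal composition
    contains NeuGc but the spectrum shows NeuAc evidence without NeuGc
    evidence.
    """
    matched: dict[str, list[float]] = {"NeuAc": [], "NeuGc": []}
    hits = {"NeuAc": 0, "NeuGc": 0}
    for species, targets in (("NeuAc", NEUAC_IONS), ("NeuGc", NEUGC_IONS)):
        for target in targets:
            idx = spectrum.match(target)
            if idx.size:
                hits[species] += 1
                matched[species].extend(spectrum.mz[idx].tolist())
    needed = 2 if require_both else 1
    neuac = hits["NeuAc"] >= needed
    neugc = hits["NeuGc"] >= needed
    conflict = comp.neugc > 0 and neuac and not neugc
    return ValidationReport(
        neuac_evidence=neuac, neugc_evidence=neugc, matched_peaks=matched, conflict=conflict
    )


def reassign_composition(
    comp: GlycanComposition,
    report: ValidationReport,
    peptide_modifications: tuple[str, ...] = (),
) -> ValidationReport:
    """Propose a mass-conserving NeuGc -> NeuAc rewrite for a flagged conflict.

    Preference order: (a) Fuc(-1) NeuGc(-1) -> Hex(+1) NeuAc(+1) when a
    fucose is available (pure glycan rewrite); else (b) NeuGc(-1) ->
    NeuAc(+1) with one added peptide oxidation.  The corrected precursor mass
    equals the original within 1e-3 Da; if no rewrite applies the report is
    returned unresolved.
    """
    if not report.conflict or comp.neugc == 0:
        return report
    original_mass = composition_mass(comp)
    if comp.fuc >= comp.neugc:
        corrected = GlycanComposition(
            comp.hexnac, comp.hex + comp.neugc, comp.fuc - comp.neugc, comp.neuac + comp.neugc, 0
        )
        extra: list[str] = []
    else:
        corrected = GlycanComposition(comp.hexnac, comp.hex, comp.fuc, comp.neuac + comp.neugc, 0)
        extra = ["Oxidation@peptide"] * comp.neugc
    new_mass = composition_mass(corrected) + len(extra) * MODIFICATION_MASSES["Oxidation"]
    if abs(new_mass - original_mass) > 1e-3:
        raise AssertionError(
            f"reassignment not mass conserving: {original_mass} -> {new_mass}"
        )
    report.proposed_composition = corrected
    report.proposed_extra_modifications = list(peptide_modifications) + extra
    report.resolved = True
    return report


def read_peak_list(path) -> SpectrumPeaks:
    """Read a two-column (m/z, intensity) text file or a single MGF-style
    block (BEGIN IONS / END IONS with m/z-intensity body lines)."""
    mzs, intens = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" in line or line[0].isalpha():
                continue
            parts = line.split()
            mzs.append(float(parts[0]))
            intens.append(float(parts[1]) if len(parts) > 1 else 1.0)
    return SpectrumPeaks(np.array(mzs), np.array(intens))
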