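"""Glycan composition algebra for intact-glycopeptide analysis.

A glycan composition is a multiset of monosaccharide residues -- HexNAc
(N-acetylhexosamine), Hex (hexose), Fuc (deoxyhexose/fucose), NeuAc
(N-acetylneuraminic acid) and NeuGc (N-glycolylneuraminic acid) -- written in
the search-engine dialect ``HexNAc(5)Hex(6)Fuc(1)NeuAc(3)``.  This module
provides parsing/formatting, monoisotopic mass arithmetic, glycopeptide m/z,
the five-way glycan classification used for class-level abundance summaries,
oxonium (diagnostic) ion tables, isobaric-collision enumeration and
N-glycosylation sequon detection.

Two near-isobaric identities drive the composition-validation chemistry:

* ``mass(NeuGc) - mass(NeuAc) = mass(Met oxidation)`` within 1e-4 Da, so a
  NeuGc assignment can masquerade as NeuAc on an oxidized peptide;
* ``mass(Fuc) + mass(NeuGc) = mass(Hex) + mass(NeuAc)`` within 1e-4 Da, so
  Fuc+NeuGc-containing compositions collide with Hex+NeuAc alternatives.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Iterator

from pyteomics import mass as _pmass

__all__ = [
    "GlycanComposition",
    "GlycanClass",
    "MONOSACCHARIDE_MASSES",
    "MODIFICATION_MASSES",
    "PROTON",
    "WATER",
    "parse_composition",
    "composition_mass",
    "peptide_mass",
    "glycopeptide_mz",
    "classify_glycan",
    "oxonium_ions",
    "find_isobaric_collisions",
    "find_sequons",
    "mass_table_tsv",
]

# Monoisotopic residue masses (Da) of the glycan building blocks as they occur
# in a glycosidic chain (i.e. dehydrated residues).
MONOSACCHARIDE_MASSES: dict[str, float] = {
    "HexNAc": 203.079373,
    "Hex": 162.052824,
    "Fuc": 146.057909,
    "NeuAc": 291.095417,
    "NeuGc": 307.090331,
}

PROTON: float = 1.007276466879
WATER: float = _pmass.calculate_mass(formula="H2O")

# Peptide modification delta masses, computed from elemental composition.
# TMT 10/11-plex reporter+balancer tag: C8 13C4 H20 N 15N O2.
MODIFICATION_MASSES: dict[str, float] = {
    "TMT": _pmass.calculate_mass(formula="C[12]8C[13]4H20N[14]1N[15]1O2"),
    "Carbamidomethyl": _pmass.calculate_mass(formula="C2H3NO"),
    "Oxidation": _pmass.calculate_mass(formula="O"),
    "Deamidated": _pmass.calculate_mass(formula="O") - _pmass.calculate_mass(formula="NH"),
    "Acetyl": _pmass.calculate_mass(formula="C2H2O"),
}

_MONO_ORDER = ("HexNAc", "Hex", "Fuc", "NeuAc", "NeuGc")
_FIELD_BY_NAME = {"HexNAc": "hexnac", "Hex": "hex", "Fuc": "fuc", "NeuAc": "neuac", "NeuGc": "neugc"}
_TOKEN_RE = re.compile(r"([A-Za-z]+)\((\-?\d+)\)")

#: The five glycan classes reported for class-level group comparisons.
GLYCAN_CLASSES = ("high-mannose", "C/H", "C/H+Fuc", "C/H+NeuAc", "C/H+Fuc/Sia")


class GlycanParseError(ValueError):
    """Raised for malformed composition strings."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Nonnegative monosaccharide counts with mass semantics.

    Immutable and hashable so compositions can key feature tables.
    """

    hexnac: int = 0
    hex: int = 0
    fuc: int = 0
    neuac: int = 0
    neugc: int = 0

    def __post_init__(self) -> None:
        for name in _MONO_ORDER:
            count = getattr(self, _FIELD_BY_NAME[name])
            if not isinstance(count, int) or count < 0:
                raise GlycanParseError(f"negative or non-integer count for {name}: {count!r}")

    @property
    def counts(self) -> tuple[int, int, int, int, int]:
        return (self.hexnac, self.hex, self.fuc, self.neuac, self.neugc)

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def sialic(self) -> int:
        return self.neuac + self.neugc

    @property
    def mass(self) -> float:
        return composition_mass(self)

    def is_empty(self) -> bool:
        return self.total == 0

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(*(a + b for a, b in zip(self.counts, other.counts)))

    def __str__(self) -> str:
        # Canonical order HexNAc, Hex, Fuc, NeuAc, NeuGc; zero counts omitted.
        parts = [
            f"{name}({getattr(self, _FIELD_BY_NAME[name])})"
            for name in _MONO_ORDER
            if getattr(self, _FIELD_BY_NAME[name]) > 0
        ]
        return "".join(parts)


def parse_composition(text: str) -> GlycanComposition:
    """Parse a ``Name(count)`` concatenation into a :class:`GlycanComposition`.

    Order-insensitive; absent names mean zero.  Unknown names, malformed
    tokens, negative counts and duplicated names are rejected.  A composition
    whose counts are all zero (e.g. ``"Hex(0)"``) is rejected as an empty
    glycan: a glycan-bearing feature must carry at least one residue.
    """
    if not isinstance(text, str) or not text.strip():
        raise GlycanParseError(f"empty composition string: {text!r}")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    for match in _TOKEN_RE.finditer(text):
        if match.start() != pos:
            raise GlycanParseError(f"malformed token near {text[pos:match.start()]!r} in {text!r}")
        name, value = match.group(1), int(match.group(2))
        if name not in MONOSACCHARIDE_MASSES:
            raise GlycanParseError(f"unknown monosaccharide {name!r} in {text!r}")
        if name in counts:
            raise GlycanParseError(f"duplicated monosaccharide {name!r} in {text!r}")
        if value < 0:
            raise GlycanParseError(f"negative count in token {match.group(0)!r}")
        counts[name] = value
        pos = match.end()
    if pos != len(text) or not counts:
        raise GlycanParseError(f"malformed token near {text[pos:]!r} in {text!r}")
    comp = GlycanComposition(**{_FIELD_BY_NAME[k]: v for k, v in counts.items()})
    if comp.is_empty():
        raise GlycanParseError(f"empty glycan (all counts zero): {text!r}")
    return comp


def composition_mass(comp: GlycanComposition) -> float:
    """Monoisotopic mass of a composition: the count-weighted residue sum."""
    return sum(c * MONOSACCHARIDE_MASSES[n] for n, c in zip(_MONO_ORDER, comp.counts))


def _parse_mod_token(token: str) -> tuple[str, str]:
    """Split a ``Name@site`` modification token into (name, site)."""
    name, _, site = token.partition("@")
    name = name.strip()
    if name not in MODIFICATION_MASSES:
        raise ValueError(f"unknown modification {name!r}")
    return name, site.strip()


def peptide_mass(peptide: str, modifications: Iterable[str] = ()) -> float:
    """Neutral monoisotopic mass of a (modified) peptide.

    ``modifications`` are ``Name@site`` tokens (site = 1-based residue index,
    ``N-term`` or ``C-term``); only the name contributes to the mass.
    """
    if not peptide:
        raise ValueError("empty peptide sequence")
    total = WATER
    for residue in peptide:
        try:
            total += _pmass.std_aa_mass[residue]
        except KeyError:
            raise ValueError(f"unknown residue letter {residue!r} in {peptide!r}") from None
    for token in modifications:
        name, _ = _parse_mod_token(token)
        total += MODIFICATION_MASSES[name]
    return total


def glycopeptide_mz(
    peptide: str,
    modifications: Iterable[str] = (),
    comp: GlycanComposition | None = None,
    charge: int = 1,
) -> float:
    """m/z of a glycopeptide: (peptide + mods + glycan + z protons) / z."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    neutral = peptide_mass(peptide, modifications)
    if comp is not None:
        neutral += composition_mass(comp)
    return (neutral + charge * PROTON) / charge


def classify_glycan(comp: GlycanComposition) -> str:
    """Assign one of the five glycan classes (a total partition).

    High-mannose requires exactly two HexNAc (the chitobiose core), >= 5 Hex
    and no fucose or sialic acid.  Everything else is complex/hybrid (C/H),
    subdivided by terminal fucosylation and sialylation.  Paucimannosidic and
    truncated compositions fall into plain C/H.
    """
    if comp.is_empty():
        raise ValueError("cannot classify an empty glycan composition")
    if comp.hexnac == 2 and comp.hex >= 5 and comp.fuc == 0 and comp.sialic == 0:
        return "high-mannose"
    fucosylated = comp.fuc > 0
    sialylated = comp.sialic > 0
    if fucosylated and sialylated:
        return "C/H+Fuc/Sia"
    if fucosylated:
        return "C/H+Fuc"
    if sialylated:
        return "C/H+NeuAc"
    return "C/H"


def oxonium_ions(unit: str | GlycanComposition) -> list[tuple[str, float]]:
    """Diagnostic oxonium ions for a monosaccharide or a whole composition.

    For each residue present, returns the singly protonated residue ion
    ``[X+H]+`` and its water loss ``[X+H-H2O]+``.  For NeuAc these are m/z
    292.1027 and 274.0921; for NeuGc, 308.0976 and 290.0870.
    """
    if isinstance(unit, GlycanComposition):
        names = [n for n, c in zip(_MONO_ORDER, unit.counts) if c > 0]
        if not names:
            raise ValueError("empty composition has no oxonium ions")
        ions: list[tuple[str, float]] = []
        for name in names:
            ions.extend(oxonium_ions(name))
        return ions
    if unit not in MONOSACCHARIDE_MASSES:
        raise ValueError(f"unsupported monosaccharide {unit!r}")
    residue = MONOSACCHARIDE_MASSES[unit]
    return [
        (f"{unit}+H", residue + PROTON),
        (f"{unit}+H-H2O", residue + PROTON - WATER),
    ]


#: Default composition search space for collision enumeration.
DEFAULT_SEARCH_SPACE: dict[str, int] = {"HexNAc": 9, "Hex": 10, "Fuc": 3, "NeuAc": 4, "NeuGc": 1}


def _iter_space(space: dict[str, int]) -> Iterator[GlycanComposition]:
    ranges = [range(space.get(name, 0) + 1) for name in _MONO_ORDER]
    for counts in itertools.product(*ranges):
        if sum(counts) > 0:
            yield GlycanComposition(*counts)


def find_isobaric_collisions(
    comp: GlycanComposition,
    space: dict[str, int] | None = None,
    tol_ppm: float = 10.0,
) -> list[GlycanComposition]:
    """Enumerate compositions in ``space`` isobaric with ``comp`` within ppm.

    The relation is symmetric: ``b in collisions(a)`` iff ``a in
    collisions(b)`` (ppm measured against the mean of the two masses so the
    tolerance window is identical from either side).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if space is None:
        space = DEFAULT_SEARCH_SPACE
    target = composition_mass(comp)
    hits = []
    for other in _iter_space(space):
        if other == comp:
            continue
        m = composition_mass(other)
        if abs(m - target) / ((m + target) / 2) * 1e6 <= tol_ppm:
            hits.append(other)
    return sorted(hits)


_SEQUON_RE = re.compile(r"N(?=[^P][STC])")


def find_sequons(peptide: str) -> list[int]:
    """1-based positions of N-glycosylation sequons N-X-[S/T/C], X != P."""
    return [m.start() + 1 for m in _SEQUON_RE.finditer(peptide)]


def mass_table_tsv() -> str:
    """Monosaccharide and modification mass tables as tab-separated text."""
    lines = ["kind\tname\tmonoisotopic_mass_da"]
    for name in _MONO_ORDER:
        lines.append(f"monosaccharide\t{name}\t{MONOSACCHARIDE_MASSES[name]:.6f}")
    for name, delta in MODIFICATION_MASSES.items():
        lines.append(f"modification\t{name}\t{delta:.6f}")
    lines.append(f"constant\tproton\t{PROTON:.6f}")
    lines.append(f"constant\twater\t{WATER:.6f}")
    return "\n".join(lines) + "\n"
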