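"""The hexaphyrin meso-substitution chemical compound space.

Hexaphyrins carry six meso (methine-bridge) substitution sites, R1..R6,
numbered clockwise around the macrocycle.  A substitution *pattern* partitions
the sites into ordered groups that always carry the same substituent (e.g.
A2B2C2 ties the diagonally facing pairs R1/R4, R2/R5 and R3/R6), an
*assignment* picks one fragment per group from a substituent library, and a
*switch structure* adds the macrocycle state label (26R, 28R, 28M, 26D —
redox state + conformation).  Canonical keys like ``26R(NH2_OH_NH2)`` join
assignments to fixture records.

Centrosymmetry matters because an inversion center forces β_HRS = 0: an
unsubstituted rectangular Hückel 28R macrocycle is C_i, and a 28R whose
per-site map is invariant under the diagonal pairing R1↔R4, R2↔R5, R3↔R6 is
*formally* predicted centrosymmetric.  The prediction is geometric bookkeeping
only — bulky or strongly interacting substituents (e.g. NO2) can relax the
real structure to C2/C1, which fixture records override.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from typing import Iterator

import yaml

__all__ = [
    "SITES",
    "STATES",
    "Substituent",
    "SubstitutionPattern",
    "Assignment",
    "SwitchStructure",
    "load_substituent_library",
    "default_library",
    "fixture_library",
    "load_patterns",
    "get_pattern",
    "expand_assignment",
    "compress_site_map",
    "space_size",
    "enumerate_space",
    "is_formally_centrosymmetric",
    "ChemSpaceError",
]

SITES = ("R1", "R2", "R3", "R4", "R5", "R6")
STATES = ("26D", "26R", "28R", "28M")

# diagonal site pairing of the rectangular conformations
_INVERSION_PAIRING = {"R1": "R4", "R2": "R5", "R3": "R6",
                      "R4": "R1", "R5": "R2", "R6": "R3"}


class ChemSpaceError(ValueError):
    """Invalid pattern, library or assignment."""


@dataclass(frozen=True)
class Substituent:
    label: str
    electronic_class: str  # EWG | EDG | neutral
    character: str  # mesomeric | inductive | none


@dataclass(frozen=True)
class SubstitutionPattern:
    """Ordered partition of the six sites into same-substituent groups."""

    name: str
    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        flat = [s for g in self.groups for s in g]
        if sorted(flat) != sorted(SITES):
            raise ChemSpaceError(
                f"pattern {self.name!r}: groups must partition {SITES}, got {flat}"
            )

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class Assignment:
    """One point of the compound space: a substituent label per group."""

    pattern: SubstitutionPattern
    choices: tuple[str, ...]

    def __post_init__(self):
        if len(self.choices) != self.pattern.n_groups:
            raise ChemSpaceError(
                f"pattern {self.pattern.name!r} needs {self.pattern.n_groups} "
                f"choices, got {len(self.choices)}"
            )

    @property
    def key_body(self) -> str:
        return "_".join(self.choices)


@dataclass(frozen=True)
class SwitchStructure:
    """An assignment in a given macrocycle state, with its canonical key."""

    state: str
    assignment: Assignment
    key: str = field(init=False)

    def __post_init__(self):
        if self.state not in STATES:
            raise ChemSpaceError(f"unknown state {self.state!r}; expected {STATES}")
        object.__setattr__(self, "key", f"{self.state}({self.assignment.key_body})")


def _data_text(name: str) -> str:
    return (resources.files("hexanlo") / "data" / name).read_text()


def load_substituent_library(text: str | None = None) -> dict[str, Substituent]:
    """Load the full substituent catalogue (YAML), keyed by label."""
    doc = yaml.safe_load(text if text is not None else _data_text("substituents.yaml"))
    lib: dict[str, Substituent] = {}
    for row in doc["substituents"]:
        if row["label"] in lib:
            raise ChemSpaceError(f"duplicate substituent label {row['label']!r}")
        lib[row["label"]] = Substituent(
            row["label"], row["electronic_class"], row["character"]
        )
    return lib


def default_library() -> tuple[str, ...]:
    """The seven-fragment optimization library (PhF5 excluded)."""
    doc = yaml.safe_load(_data_text("substituents.yaml"))
    return tuple(r["label"] for r in doc["substituents"] if r["in_default_library"])


def fixture_library() -> tuple[str, ...]:
    """All catalogued fragments, including fixture-only ones (PhF5)."""
    doc = yaml.safe_load(_data_text("substituents.yaml"))
    return tuple(r["label"] for r in doc["substituents"])


def load_patterns(text: str | None = None) -> dict[str, SubstitutionPattern]:
    doc = yaml.safe_load(text if text is not None else _data_text("patterns.yaml"))
    return {
        name: SubstitutionPattern(name, tuple(tuple(g) for g in spec["groups"]))
        for name, spec in doc["patterns"].items()
    }


def get_pattern(name: str) -> SubstitutionPattern:
    patterns = load_patterns()
    try:
        return patterns[name]
    except KeyError:
        raise ChemSpaceError(
            f"unknown pattern {name!r}; available: {sorted(patterns)}"
        ) from None


def expand_assignment(a: Assignment, library=None) -> dict[str, str]:
    """Per-site map {R1..R6 -> substituent label} of an assignment."""
    if library is not None:
        bad = [c for c in a.choices if c not in library]
        if bad:
            raise ChemSpaceError(f"choices {bad} not in active library {list(library)}")
    site_map: dict[str, str] = {}
    for group, choice in zip(a.pattern.groups, a.choices):
        for site in group:
            site_map[site] = choice
    return {s: site_map[s] for s in SITES}


def compress_site_map(pattern: SubstitutionPattern, site_map: dict[str, str]) -> Assignment:
    """Inverse of :func:`expand_assignment`; fails if the map breaks the pattern."""
    choices = []
    for group in pattern.groups:
        labels = {site_map[s] for s in group}
        if len(labels) != 1:
            raise ChemSpaceError(
                f"site map not constant on group {group} of {pattern.name}: {labels}"
            )
        choices.append(next(iter(labels)))
    return Assignment(pattern, tuple(choices))


def space_size(pattern: SubstitutionPattern, library) -> int:
    """|library| ** n_groups — the combinatorial size of the compound space."""
    if not library:
        raise ChemSpaceError("library must be non-empty")
    return len(library) ** pattern.n_groups


def enumerate_space(pattern: SubstitutionPattern, library) -> Iterator[Assignment]:
    """All assignments in lexicographic order by library index.

    The first element is the all-first-fragment assignment; the count equals
    :func:`space_size`.
    """
    if not library:
        raise ChemSpaceError("library must be non-empty")
    for combo in product(tuple(library), repeat=pattern.n_groups):
        yield Assignment(pattern, combo)


def is_formally_centrosymmetric(state: str, site_map: dict[str, str]) -> bool:
    """Formal C_i prediction: 28R with a diagonal-symmetric substituent map.

    This is a geometric bookkeeping rule, not a guarantee: fixture records may
    override it where the relaxed structure breaks to C2/C1 (e.g. NO2 on
    R1/R4).
    """
    if state != "28R":
        return False
    return all(site_map[s] == site_map[_INVERSION_PAIRING[s]] for s in SITES)
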