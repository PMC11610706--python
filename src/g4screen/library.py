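"""Enumeration and rule-based classification of the G-quadruplex variant library.

The library is built around a 17-nt reference oligonucleotide that folds into
a monomeric, three-tetrad parallel G-quadruplex.  Four sub-libraries are
combined:

* the *tetrad* sub-library: every substitution pattern (4^4 = 256) at the four
  positions forming the central tetrad of the reference structure
  (positions 2, 6, 11 and 15, 1-based);
* three *loop* sub-libraries: every loop pattern over {A, C, T} (3^4 = 81) at
  the four loop positions (4, 8, 9 and 13) in three tetrad backgrounds —
  the unmutated reference (GGGG), a representative dimer-former (G→A at
  position 2) and a representative tetramer-former (G→A at position 11).

The raw enumeration has 499 entries; the three loop sub-libraries each contain
one sequence (the all-reference-loop member) that duplicates a tetrad
sub-library entry, leaving 496 unique sequences.

Spectral classes are assigned from the mutational signature of the central
tetrad (and, for the dimer-background loop sub-library, from the adenosine
content of the first three loop positions).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ReferenceTopology",
    "LibrarySequence",
    "SpectralClass",
    "ClassLabel",
    "InvalidReferenceError",
    "MalformedSequenceError",
    "PatternError",
    "enumerate_library",
    "annotate",
    "count_by_tetrad_mutations",
    "match_tetrad_pattern",
    "assign_rule_class",
    "assign_rule_classes",
    "library_table",
    "write_fasta",
]

DNA_ALPHABET = frozenset("ACGT")

#: IUPAC degenerate codes accepted by :func:`match_tetrad_pattern`.
IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "N": frozenset("ACGT"),
    "H": frozenset("ACT"),
    "Y": frozenset("CT"),
}


class InvalidReferenceError(ValueError):
    """Reference topology violates its invariants."""


class MalformedSequenceError(ValueError):
    """Sequence has the wrong length or contains non-DNA characters."""


class PatternError(ValueError):
    """Degenerate pattern contains an unsupported code."""


class SpectralClass(str, enum.Enum):
    """Major spectral classes of the library.

    Class names follow the screen's convention of naming a class after a
    representative library member (17.3 is the monomeric reference).
    """

    C17_3 = "17.3"
    C17_4 = "17.4"
    C17_4s26 = "17.4s26"
    C17_4_plus_17_4s26 = "17.4+17.4s26"
    C17_63 = "17.63"
    C17_36 = "17.36"
    C17_28 = "17.28"
    C17_49 = "17.49"
    C17_180 = "17.180"
    C17_154 = "17.154"
    no_pattern = "no_pattern"
    no_G4_signals = "no_G4_signals"


@dataclass(frozen=True)
class ClassLabel:
    """A class assignment with any ambiguous alternatives recorded.

    Exactly one ``major`` class is assigned per sequence; when the mutational
    signature is claimed by more than one class, the non-chosen candidates are
    kept in ``ambiguous_alternatives`` rather than silently dropped.
    """

    major: SpectralClass
    ambiguous_alternatives: frozenset[SpectralClass] = frozenset()


@dataclass(frozen=True)
class ReferenceTopology:
    """Position conventions of the 17-nt reference scaffold (1-based).

    The three stacked tetrads of the reference structure are formed by the
    position quadruples in ``tetrad_layers``; the middle layer is the central
    tetrad whose mutation pattern drives class assignment.
    """

    sequence: str = "GGGTGGGTTGGGTGGGA"
    tetrad_layers: tuple[tuple[int, int, int, int], ...] = (
        (1, 5, 10, 14),
        (2, 6, 11, 15),
        (3, 7, 12, 16),
    )
    central_tetrad_positions: tuple[int, int, int, int] = (2, 6, 11, 15)
    loop_positions: tuple[int, int, int, int] = (4, 8, 9, 13)
    tail_position: int = 17

    def __post_init__(self) -> None:
        if len(self.sequence) != 17 or not set(self.sequence) <= DNA_ALPHABET:
            raise InvalidReferenceError(
                f"reference must be a 17-nt A/C/G/T string, got {self.sequence!r}"
            )
        tetrad_pos = {p for layer in self.tetrad_layers for p in layer}
        for p in sorted(tetrad_pos):
            if self.sequence[p - 1] != "G":
                raise InvalidReferenceError(
                    f"tetrad position {p} must be G in the reference, "
                    f"found {self.sequence[p - 1]}"
                )
        if self.central_tetrad_positions != self.tetrad_layers[1]:
            raise InvalidReferenceError(
                "central tetrad must be the middle tetrad layer"
            )
        if tetrad_pos & set(self.loop_positions):
            raise InvalidReferenceError("tetrad and loop positions overlap")
        covered = tetrad_pos | set(self.loop_positions) | {self.tail_position}
        if covered != set(range(1, 18)):
            raise InvalidReferenceError("positions do not cover 1..17")

    @property
    def loop_pattern(self) -> str:
        return "".join(self.sequence[p - 1] for p in self.loop_positions)


@dataclass
class LibrarySequence:
    """One annotated 17-nt library variant.

    ``tetrad_pattern`` holds the bases at the central-tetrad positions
    (2, 6, 11, 15) and ``loop_pattern`` the bases at the loop positions
    (4, 8, 9, 13).  A sequence produced by more than one sub-library keeps
    every sub-library tag in ``sublibraries``.
    """

    seq_id: str
    sequence: str
    sublibraries: tuple[str, ...]
    tetrad_pattern: str
    loop_pattern: str
    n_tetrad_mutations: int
    mutated_tetrad_positions: frozenset[int]
    n_loop_adenosines_489: int
    class_label: ClassLabel | None = field(default=None)

    @property
    def sublibrary(self) -> str:
        """Primary sub-library tag (tetrad tag wins for merged duplicates)."""
        return self.sublibraries[0]


def annotate(
    sequence: str,
    ref: ReferenceTopology | None = None,
    *,
    seq_id: str | None = None,
    sublibraries: tuple[str, ...] = (),
) -> LibrarySequence:
    """Annotate a 17-nt sequence with its mutational signature.

    Raises :class:`MalformedSequenceError` for wrong length or alphabet.
    """
    ref = ref or ReferenceTopology()
    if len(sequence) != 17 or not set(sequence) <= DNA_ALPHABET:
        raise MalformedSequenceError(
            f"expected a 17-nt A/C/G/T string, got {sequence!r}"
        )
    tet = "".join(sequence[p - 1] for p in ref.central_tetrad_positions)
    loop = "".join(sequence[p - 1] for p in ref.loop_positions)
    mutated = frozenset(
        p for p in ref.central_tetrad_positions if sequence[p - 1] != "G"
    )
    n_a = sum(1 for p in ref.loop_positions[:3] if sequence[p - 1] == "A")
    return LibrarySequence(
        seq_id=seq_id or sequence,
        sequence=sequence,
        sublibraries=sublibraries,
        tetrad_pattern=tet,
        loop_pattern=loop,
        n_tetrad_mutations=len(mutated),
        mutated_tetrad_positions=mutated,
        n_loop_adenosines_489=n_a,
    )


def _substitute(ref: ReferenceTopology, positions: tuple[int, ...], bases: str) -> str:
    s = list(ref.sequence)
    for p, b in zip(positions, bases):
        s[p - 1] = b
    return "".join(s)


#: tetrad backgrounds of the three loop sub-libraries
_LOOP_BACKGROUNDS = {
    "loop_17_3": "GGGG",  # unmutated reference
    "loop_17_4": "AGGG",  # G→A at position 2, dimer-forming background
    "loop_17_10": "GGAG",  # G→A at position 11, tetramer-forming background
}


def enumerate_library(
    ref: ReferenceTopology | None = None,
    *,
    classify: bool = True,
    tggt_to_17_36: bool = True,
) -> list[LibrarySequence]:
    """Enumerate the full deduplicated variant library.

    Generates the 256-member tetrad sub-library and the three 81-member loop
    sub-libraries (H = A/C/T at positions 4, 8, 9, 13), then merges exact
    string duplicates keeping all sub-library tags; 499 raw records collapse
    to 496 unique sequences.  When ``classify`` is true each record also gets
    its rule-based :class:`ClassLabel`.
    """
    ref = ref or ReferenceTopology()

    raw: list[tuple[str, str, str]] = []  # (sublibrary, seq_id, sequence)
    for i, bases in enumerate(itertools.product("ACGT", repeat=4)):
        tet = "".join(bases)
        seq = _substitute(ref, ref.central_tetrad_positions, tet)
        raw.append(("tetrad", f"tet_{i:03d}_{tet}", seq))
    for sub, background in _LOOP_BACKGROUNDS.items():
        base_seq = _substitute(ref, ref.central_tetrad_positions, background)
        for i, bases in enumerate(itertools.product("ACT", repeat=4)):
            loop = "".join(bases)
            s = list(base_seq)
            for p, b in zip(ref.loop_positions, loop):
                s[p - 1] = b
            raw.append((sub, f"{sub}_{i:02d}_{loop}", "".join(s)))

    merged: dict[str, LibrarySequence] = {}
    for sub, seq_id, seq in raw:
        if seq in merged:
            rec = merged[seq]
            rec.sublibraries = rec.sublibraries + (sub,)
        else:
            merged[seq] = annotate(seq, ref, seq_id=seq_id, sublibraries=(sub,))

    library = list(merged.values())
    if classify:
        for rec in library:
            rec.class_label = assign_rule_class(rec, tggt_to_17_36=tggt_to_17_36)
    return library


def count_by_tetrad_mutations(
    library: list[LibrarySequence], k: int | set[int]
) -> int:
    """Number of library sequences with a central-tetrad mutation count in ``k``."""
    ks = {k} if isinstance(k, int) else set(k)
    return sum(1 for rec in library if rec.n_tetrad_mutations in ks)


def _pattern_matches(pattern: str, tetrad: str) -> bool:
    return all(b in IUPAC[c] for c, b in zip(pattern, tetrad))


def match_tetrad_pattern(
    library: list[LibrarySequence], *patterns: str
) -> list[LibrarySequence]:
    """Sequences whose central-tetrad pattern matches any degenerate pattern.

    Patterns are 4-character strings over the IUPAC codes A/C/G/T/N/H/Y and
    are OR-combined.  Raises :class:`PatternError` on an unsupported code.
    """
    if not patterns:
        raise PatternError("at least one pattern required")
    for pat in patterns:
        if len(pat) != 4:
            raise PatternError(f"pattern must have length 4: {pat!r}")
        bad = set(pat) - set(IUPAC)
        if bad:
            raise PatternError(f"unsupported IUPAC code(s) {sorted(bad)} in {pat!r}")
    return [
        rec
        for rec in library
        if any(_pattern_matches(p, rec.tetrad_pattern) for p in patterns)
    ]


def assign_rule_class(
    seq: LibrarySequence, *, tggt_to_17_36: bool = True
) -> ClassLabel:
    """Assign the spectral class implied by the mutational signature.

    The ruleset (total and deterministic):

    1. unmutated tetrad (GGGG) → 17.3, the monomeric fold;
    2. first half intact (positions 2, 6 both G) with ≥1 mutation in the
       second half → 17.63, the tetramer-forming class;
    3. second half intact (positions 11, 15 both G) with ≥1 mutation in the
       first half → the dimer-forming 17.4 family; within the dimer-background
       loop sub-library the adenosine count at loop positions 4, 8, 9 refines
       this: 0–1 A → 17.4s26, 2 A → the mixed class 17.4+17.4s26
       (with 17.4 as ambiguous alternative), 3 A → 17.4;
    4. cross-half double mutants: GHHG → 17.49, HGGH → 17.28 (17.36 recorded
       as an ambiguous alternative; TGGT reassigned to 17.36 when
       ``tggt_to_17_36``), GHGH → 17.36;
    5. NAAA / AAAN → 17.180; HAHG → 17.154;
    6. any other sequence with 3–4 tetrad mutations → no G4 signals;
       everything remaining → no clear pattern.
    """
    tet = seq.tetrad_pattern
    first_intact = tet[0] == "G" and tet[1] == "G"
    second_intact = tet[2] == "G" and tet[3] == "G"

    if tet == "GGGG":
        return ClassLabel(SpectralClass.C17_3)
    if first_intact:
        return ClassLabel(SpectralClass.C17_63)
    if second_intact:
        # loop-adenosine refinement applies to the dimer-background loop
        # sub-library proper; a merged duplicate keeps the tetrad tag first
        # and is classified as plain 17.4
        if seq.sublibraries and seq.sublibraries[0] == "loop_17_4":
            n_a = seq.n_loop_adenosines_489
            if n_a == 0:
                return ClassLabel(SpectralClass.C17_4s26)
            if n_a == 1:
                # one adenosine sits in the overlap of the 17.4s26 (0-1 A)
                # and mixed-class (1-2 A) signatures
                return ClassLabel(
                    SpectralClass.C17_4s26,
                    frozenset({SpectralClass.C17_4_plus_17_4s26}),
                )
            if n_a == 2:
                return ClassLabel(
                    SpectralClass.C17_4_plus_17_4s26,
                    frozenset({SpectralClass.C17_4}),
                )
            return ClassLabel(SpectralClass.C17_4)
        return ClassLabel(SpectralClass.C17_4)
    # cross-half double mutants
    if _pattern_matches("GHHG", tet):
        return ClassLabel(SpectralClass.C17_49)
    if _pattern_matches("HGGH", tet):
        if tggt_to_17_36 and tet == "TGGT":
            return ClassLabel(
                SpectralClass.C17_36, frozenset({SpectralClass.C17_28})
            )
        return ClassLabel(
            SpectralClass.C17_28, frozenset({SpectralClass.C17_36})
        )
    if _pattern_matches("GHGH", tet):
        return ClassLabel(SpectralClass.C17_36)
    if _pattern_matches("NAAA", tet) or _pattern_matches("AAAN", tet):
        return ClassLabel(SpectralClass.C17_180)
    if _pattern_matches("HAHG", tet):
        return ClassLabel(SpectralClass.C17_154)
    if seq.n_tetrad_mutations >= 3:
        return ClassLabel(SpectralClass.no_G4_signals)
    return ClassLabel(SpectralClass.no_pattern)


def assign_rule_classes(
    library: list[LibrarySequence], *, tggt_to_17_36: bool = True
) -> list[ClassLabel]:
    return [assign_rule_class(s, tggt_to_17_36=tggt_to_17_36) for s in library]


def library_table(library: list[LibrarySequence]) -> pd.DataFrame:
    """Annotation table, one row per unique sequence."""
    rows = []
    for rec in library:
        rows.append(
            {
                "seq_id": rec.seq_id,
                "sequence": rec.sequence,
                "sublibraries": "+".join(rec.sublibraries),
                "tetrad_pattern": rec.tetrad_pattern,
                "loop_pattern": rec.loop_pattern,
                "n_tetrad_mutations": rec.n_tetrad_mutations,
                "mutated_tetrad_positions": ",".join(
                    str(p) for p in sorted(rec.mutated_tetrad_positions)
                ),
                "n_loop_adenosines_489": rec.n_loop_adenosines_489,
                "rule_class": rec.class_label.major.value if rec.class_label else "",
                "ambiguous_alternatives": "+".join(
                    sorted(a.value for a in rec.class_label.ambiguous_alternatives)
                )
                if rec.class_label
                else "",
            }
        )
    return pd.DataFrame(rows)


def write_fasta(library: list[LibrarySequence], path) -> None:
    """Write the library as FASTA (seq_id in header, 17-nt records)."""
    with open(path, "w") as fh:
        for rec in library:
            fh.write(f">{rec.seq_id} sublibraries={'+'.join(rec.sublibraries)}\n")
            fh.write(rec.sequence + "\n")
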