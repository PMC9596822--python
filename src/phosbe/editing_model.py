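"""Genetic-code machinery for base-editing outcome enumeration.

A cytosine base editor (CBE) deaminates C→T and an adenine base editor
(ABE) deaminates A→G on the protospacer strand, within an editing window
measured from the PAM-distal end of the protospacer.  This module knows
nothing about protospacers or PAMs: it answers the codon-level question
"which amino-acid substitutions can an editor produce from this codon?",
enumerating every nonempty combination of editable bases on one strand
at a time (a single deaminase acts on the displaced strand of a single
R-loop, so sense- and antisense-strand edits never mix in one outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

STOP = "*"
PHOSPHO_RESIDUES = frozenset("STY")

#: Default residue sets used by the charge filter: substitutions into
#: acidic (phosphomimetic) or basic residues change the local charge of
#: the site and are excluded from phospho-disrupting libraries.
ACIDIC = frozenset("DE")
BASIC = frozenset("KRH")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = STOP

#: Codons of the standard genetic code, per amino acid.
CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_CODON_TABLE.items()):
    CODONS_BY_AA.setdefault(_aa, ())
    CODONS_BY_AA[_aa] += (_codon,)

Strand = Literal["sense", "antisense"]


class InvalidCodonError(ValueError):
    """Raised for codons that are not 3-letter A/C/G/T strings."""


def translate(codon: str) -> str:
    """Translate one codon under the standard genetic code.

    Returns the one-letter amino acid, or ``"*"`` for a stop codon.
    """
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise InvalidCodonError(f"not a valid A/C/G/T codon: {codon!r}")
    return _CODON_TABLE[codon]


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    if any(b not in "ACGT" for b in seq):
        raise ValueError(f"non-ACGT character in sequence: {seq!r}")
    return str(Seq(seq).reverse_complement())


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def pam_matches(pattern: str, seq: str) -> bool:
    """Does an A/C/G/T string match an IUPAC PAM pattern of equal length?"""
    if len(seq) != len(pattern):
        return False
    return all(b in _IUPAC[p] for p, b in zip(pattern, seq))


@dataclass(frozen=True)
class EditorSpec:
    """A base editor's chemistry and targeting rule.

    Parameters
    ----------
    name:
        Display label, e.g. ``"CBE"`` or ``"ABE"``.
    source_base, product_base:
        The conversion performed on the protospacer strand (C→T for a
        cytosine editor, A→G for an adenine editor).
    window:
        Inclusive 1-based positions on the protospacer where the
        deaminase edits; position 1 is the PAM-distal (5') end.
    pam:
        IUPAC pattern required immediately 3' of the protospacer.
    """

    name: str
    source_base: str
    product_base: str
    window: tuple[int, int] = (4, 8)
    pam: str = "NGG"
    protospacer_length: int = 20

    def __post_init__(self) -> None:
        if self.source_base == self.product_base:
            raise ValueError("source and product base must differ")
        for b in (self.source_base, self.product_base):
            if b not in "ACGT":
                raise ValueError(f"invalid base: {b!r}")
        lo, hi = self.window
        if not (1 <= lo <= hi <= self.protospacer_length):
            raise ValueError(f"window {self.window} outside protospacer")
        if any(c not in _IUPAC for c in self.pam):
            raise ValueError(f"invalid IUPAC PAM pattern: {self.pam!r}")

    def window_positions(self) -> range:
        """1-based protospacer positions inside the editing window."""
        return range(self.window[0], self.window[1] + 1)

    def editable_base(self, strand: Strand) -> str:
        """The sense-sequence base this editor can edit via a guide on `strand`."""
        if strand == "sense":
            return self.source_base
        return complement_base(self.source_base)

    def edited_base(self, strand: Strand) -> str:
        """The sense-sequence base produced by an edit via a guide on `strand`."""
        if strand == "sense":
            return self.product_base
        return complement_base(self.product_base)


#: Editor presets: the canonical CBE (C→T) and ABE (A→G) with an NGG PAM
#: and a position 4–8 activity window.
PRESETS: dict[str, EditorSpec] = {
    "CBE": EditorSpec("CBE", "C", "T"),
    "ABE": EditorSpec("ABE", "A", "G"),
}


def get_editor(name: str, **overrides) -> EditorSpec:
    """Look up a preset editor by name, optionally overriding fields."""
    try:
        preset = PRESETS[name.upper()]
    except KeyError:
        raise KeyError(f"unknown editor preset {name!r}; known: {sorted(PRESETS)}")
    if overrides:
        from dataclasses import replace

        return replace(preset, **overrides)
    return preset


@dataclass(frozen=True)
class CodonEditOutcome:
    """One possible edited state of a codon.

    ``edited_positions`` are 1-based offsets within the codon (subset of
    {1,2,3}) changed simultaneously; ``is_primary`` marks the
    complete-edit outcome in which every editable base was converted.
    """

    edited_positions: frozenset[int]
    edited_codon: str
    ref_aa: str
    alt_aa: str
    strand_of_edit: Strand
    is_primary: bool = False

    @property
    def is_silent(self) -> bool:
        return self.alt_aa == self.ref_aa

    @property
    def is_nonsense(self) -> bool:
        return self.alt_aa == STOP


def editable_codon_offsets(codon: str, editor: EditorSpec, strand: Strand) -> frozenset[int]:
    """Codon offsets (1-based) carrying a base editable on the given strand."""
    target = editor.editable_base(strand)
    return frozenset(i + 1 for i, b in enumerate(codon) if b == target)


def codon_edit_outcomes(
    codon: str,
    editor: EditorSpec,
    strand_of_edit: Strand,
    editable_offsets: Iterable[int],
) -> list[CodonEditOutcome]:
    """Enumerate edited codons for every nonempty subset of editable offsets.

    The codon is given in sense (coding) orientation.  A guide on the
    sense strand converts ``source→product`` directly; a guide on the
    antisense strand converts the complement pair, which appears on the
    sense codon as ``complement(source)→complement(product)``.  The
    outcome with all offsets edited is flagged primary.
    """
    ref_aa = translate(codon)
    offsets = frozenset(editable_offsets)
    if not offsets <= {1, 2, 3}:
        raise ValueError(f"offsets must be within {{1,2,3}}: {sorted(offsets)}")
    legal = editable_codon_offsets(codon, editor, strand_of_edit)
    if not offsets <= legal:
        raise ValueError(
            f"offsets {sorted(offsets - legal)} of codon {codon} do not carry "
            f"{editor.editable_base(strand_of_edit)} (editable via {strand_of_edit} guide)"
        )
    new_base = editor.edited_base(strand_of_edit)
    outcomes = []
    for r in range(1, len(offsets) + 1):
        for subset in combinations(sorted(offsets), r):
            bases = list(codon)
            for off in subset:
                bases[off - 1] = new_base
            edited = "".join(bases)
            outcomes.append(
                CodonEditOutcome(
                    edited_positions=frozenset(subset),
                    edited_codon=edited,
                    ref_aa=ref_aa,
                    alt_aa=translate(edited),
                    strand_of_edit=strand_of_edit,
                    is_primary=(len(subset) == len(offsets)),
                )
            )
    return outcomes


def complete_edit(codon: str, editor: EditorSpec, strand_of_edit: Strand) -> CodonEditOutcome | None:
    """The primary (all editable bases converted) outcome, or None if the
    codon carries no editable base on that strand."""
    offsets = editable_codon_offsets(codon, editor, strand_of_edit)
    if not offsets:
        return None
    for out in codon_edit_outcomes(codon, editor, strand_of_edit, offsets):
        if out.is_primary:
            return out
    raise AssertionError("unreachable")


def accessible_substitutions(
    residue: str,
    editor: EditorSpec,
    include_charge_altering: bool = True,
    acidic_set: frozenset[str] = ACIDIC,
    basic_set: frozenset[str] = BASIC,
) -> frozenset[str]:
    """Amino acids reachable from a phospho-residue by one editor.

    Union over every codon of ``residue``, both strands of edit, and
    every nonempty same-strand combination of editable codon bases, of
    the resulting amino acids — excluding Ser/Thr/Tyr (still
    phosphorylatable), silent outcomes, and stops.  With
    ``include_charge_altering=False`` the acidic/basic set is excluded
    too, matching the library-design charge filter.
    """
    if residue not in PHOSPHO_RESIDUES:
        raise ValueError(f"residue must be one of S/T/Y, got {residue!r}")
    reachable: set[str] = set()
    for codon in CODONS_BY_AA[residue]:
        for strand in ("sense", "antisense"):
            offsets = editable_codon_offsets(codon, editor, strand)
            if not offsets:
                continue
            for out in codon_edit_outcomes(codon, editor, strand, offsets):
                if out.is_silent or out.is_nonsense:
                    continue
                if out.alt_aa in PHOSPHO_RESIDUES:
                    continue
                reachable.add(out.alt_aa)
    if not include_charge_altering:
        reachable -= set(acidic_set) | set(basic_set)
    return frozenset(reachable)


def conversion_space(
    editors: Iterable[EditorSpec] = (),
    include_charge_altering: bool = True,
) -> frozenset[str]:
    """Union of accessible substitutions over S/T/Y and the given editors
    (defaults to the CBE and ABE presets)."""
    eds = tuple(editors) or (PRESETS["CBE"], PRESETS["ABE"])
    space: set[str] = set()
    for residue in sorted(PHOSPHO_RESIDUES):
        for ed in eds:
            space |= accessible_substitutions(residue, ed, include_charge_altering)
    return frozenset(space)
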