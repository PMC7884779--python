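"""Edit-encoded sequence grammar and coordinate plumbing.

A single input string encodes both the reference and the desired edited
sequence.  Plain bases are shared context; parenthesised tokens describe
edits:

* ``(REF/ALT)`` — substitution (or complex replacement when lengths differ),
* ``(+SEQ)``    — insertion of ``SEQ``,
* ``(-SEQ)``    — deletion of ``SEQ``.

``parse_edit_input`` materialises the reference and edited sequences and the
per-edit coordinates on the reference; everything downstream (spacer search,
extension construction, nicking-guide classification) works off the
resulting :class:`EditSpec`.

Coordinates are 0-based, half-open throughout this package; user-facing
tables convert to 1-based inclusive at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "Edit",
    "EditSpec",
    "StrandedInterval",
    "GrammarError",
    "DELETED",
    "parse_edit_input",
    "reverse_complement",
    "ref_to_edited_coordinate",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# IUPAC codes tolerated in flanking context; design windows containing
# anything outside ACGT are discarded upstream with a warning.
_IUPAC = set("ACGTRYSWKMBDHVN")
_ACGT = set("ACGT")

#: Sentinel returned by coordinate mapping for positions inside a deleted
#: reference allele.
DELETED = "deleted"


class GrammarError(ValueError):
    """Malformed edit-encoded input; carries the offending string offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at input offset {offset})")
        self.offset = offset


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over the IUPAC DNA alphabet."""
    seq = seq.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-nucleotide character(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class StrandedInterval:
    """0-based half-open interval with strand, on some named frame."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "StrandedInterval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Edit:
    """One edit anchored on the reference sequence.

    ``ref_start`` is the 0-based offset of the first reference base the edit
    touches; for a pure insertion it is the offset of the reference base
    immediately 3' of the insertion point.
    """

    ref_start: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if not self.ref_allele and not self.alt_allele:
            raise ValueError("edit with empty reference and alternate allele")

    @property
    def edit_type(self) -> str:
        if not self.ref_allele:
            return "insertion"
        if not self.alt_allele:
            return "deletion"
        if len(self.ref_allele) == len(self.alt_allele):
            return "substitution"
        return "complex"

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.ref_allele)

    def token(self) -> str:
        if self.edit_type == "insertion":
            return f"(+{self.alt_allele})"
        if self.edit_type == "deletion":
            return f"(-{self.ref_allele})"
        return f"({self.ref_allele}/{self.alt_allele})"


@dataclass
class EditSpec:
    """Parsed edit-encoded input: both sequences plus edit coordinates."""

    raw_input: str
    reference_sequence: str
    edited_sequence: str
    edits: list[Edit]
    _ref_to_ed: list = field(default=None, repr=False, compare=False)
    _ed_to_ref: list = field(default=None, repr=False, compare=False)
    _rc_cache: "EditSpec" = field(default=None, repr=False, compare=False)

    # -- coordinate maps -------------------------------------------------
    def _build_maps(self) -> None:
        ref_to_ed: list = [None] * len(self.reference_sequence)
        ed_to_ref: list = [None] * len(self.edited_sequence)
        r = e = 0
        for edit in self.edits:
            while r < edit.ref_start:  # shared context
                ref_to_ed[r] = e
                ed_to_ref[e] = r
                r += 1
                e += 1
            lr, la = len(edit.ref_allele), len(edit.alt_allele)
            for i in range(lr):
                # substituted bases map pairwise while both alleles last;
                # the overhang of a deletion/complex edit maps to DELETED
                ref_to_ed[r + i] = e + i if i < la else DELETED
            for j in range(la):
                ed_to_ref[e + j] = r + j if j < lr else None
            r += lr
            e += la
        while r < len(self.reference_sequence):
            ref_to_ed[r] = e
            ed_to_ref[e] = r
            r += 1
            e += 1
        self._ref_to_ed = ref_to_ed
        self._ed_to_ref = ed_to_ref

    def ref_to_edited(self, pos: int):
        """Map a reference offset to the edited sequence (or ``DELETED``)."""
        if not 0 <= pos < len(self.reference_sequence):
            raise IndexError(f"reference offset {pos} out of range")
        if self._ref_to_ed is None:
            self._build_maps()
        return self._ref_to_ed[pos]

    def edited_to_ref(self, pos: int):
        """Map an edited offset back to the reference (None for inserted bases)."""
        if not 0 <= pos < len(self.edited_sequence):
            raise IndexError(f"edited offset {pos} out of range")
        if self._ed_to_ref is None:
            self._build_maps()
        return self._ed_to_ref[pos]

    # -- edit span helpers ----------------------------------------------
    def edited_span(self) -> tuple[int, int]:
        """[start, end) interval of edited bases in edited coordinates.

        For a pure deletion the interval is empty and marks the junction.
        Returns (0, 0) when there are no edits.
        """
        if not self.edits:
            return (0, 0)
        starts, ends = [], []
        shift = 0
        for edit in self.edits:
            e_start = edit.ref_start + shift
            starts.append(e_start)
            ends.append(e_start + len(edit.alt_allele))
            shift += len(edit.alt_allele) - len(edit.ref_allele)
        return (min(starts), max(ends))

    def ref_span(self) -> tuple[int, int]:
        """[start, end) reference interval touched by the edits (junction for
        a pure insertion)."""
        if not self.edits:
            return (0, 0)
        return (
            min(e.ref_start for e in self.edits),
            max(e.ref_end for e in self.edits),
        )

    # -- serialisation ---------------------------------------------------
    def serialize(self) -> str:
        """Canonical edit-encoded form (upper case, canonical tokens)."""
        out, prev = [], 0
        for edit in self.edits:
            out.append(self.reference_sequence[prev:edit.ref_start])
            out.append(edit.token())
            prev = edit.ref_end
        out.append(self.reference_sequence[prev:])
        return "".join(out)

    def reverse_complemented(self) -> "EditSpec":
        """The same design problem viewed from the opposite strand (cached)."""
        if self._rc_cache is not None:
            return self._rc_cache
        ref_rc = reverse_complement(self.reference_sequence)
        ed_rc = reverse_complement(self.edited_sequence)
        n = len(self.reference_sequence)
        flipped = [
            Edit(
                ref_start=n - e.ref_end,
                ref_allele=reverse_complement(e.ref_allele) if e.ref_allele else "",
                alt_allele=reverse_complement(e.alt_allele) if e.alt_allele else "",
            )
            for e in reversed(self.edits)
        ]
        spec = EditSpec(
            raw_input="",
            reference_sequence=ref_rc,
            edited_sequence=ed_rc,
            edits=flipped,
        )
        spec.raw_input = spec.serialize()
        self._rc_cache = spec
        return spec


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    """Yield ('seq', bases, offset) and ('token', body, offset) chunks."""
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c == "(":
            j = text.find(")", i + 1)
            if j == -1:
                raise GrammarError("unbalanced parentheses", i)
            body = text[i + 1 : j]
            if not body:
                raise GrammarError("empty edit token", i)
            if "(" in body:
                raise GrammarError("nested edit token", i + 1 + body.index("("))
            yield ("token", body, i)
            i = j + 1
        elif c == ")":
            raise GrammarError("unbalanced parentheses", i)
        else:
            j = i
            while j < n and text[j] not in "()":
                j += 1
            yield ("seq", text[i:j], i)
            i = j


def _check_token_allele(allele: str, offset: int) -> None:
    bad = set(allele) - _IUPAC
    if bad:
        raise GrammarError(f"non-DNA character(s) {sorted(bad)} in edit token", offset)
    ambiguous = set(allele) - _ACGT
    if ambiguous:
        raise GrammarError(
            f"ambiguous IUPAC code(s) {sorted(ambiguous)} inside an edit token; "
            "expand ambiguity codes before single-sequence design",
            offset,
        )


def parse_edit_input(text: str) -> EditSpec:
    """Parse one edit-encoded string into an :class:`EditSpec`.

    Raises :class:`GrammarError` (with the offending offset) on malformed
    tokens, non-DNA characters, or ambiguous codes inside tokens.
    """
    raw = text.strip()
    upper = raw.upper()
    ref_parts: list[str] = []
    ed_parts: list[str] = []
    edits: list[Edit] = []
    ref_len = 0
    for kind, chunk, offset in _tokenize(upper):
        if kind == "seq":
            bad = set(chunk) - _IUPAC
            if bad:
                raise GrammarError(
                    f"non-DNA character(s) {sorted(bad)} in sequence", offset
                )
            ref_parts.append(chunk)
            ed_parts.append(chunk)
            ref_len += len(chunk)
            continue
        if chunk.startswith("+"):
            allele = chunk[1:]
            if not allele:
                raise GrammarError("empty insertion token", offset)
            _check_token_allele(allele, offset)
            edits.append(Edit(ref_start=ref_len, ref_allele="", alt_allele=allele))
            ed_parts.append(allele)
        elif chunk.startswith("-"):
            allele = chunk[1:]
            if not allele:
                raise GrammarError("empty deletion token", offset)
            _check_token_allele(allele, offset)
            edits.append(Edit(ref_start=ref_len, ref_allele=allele, alt_allele=""))
            ref_parts.append(allele)
            ref_len += len(allele)
        elif "/" in chunk:
            ref_a, sep, alt_a = chunk.partition("/")
            if "/" in alt_a:
                raise GrammarError("multiple '/' in substitution token", offset)
            if not ref_a or not alt_a:
                raise GrammarError("substitution token needs REF and ALT", offset)
            _check_token_allele(ref_a, offset)
            _check_token_allele(alt_a, offset)
            if ref_a == alt_a:
                raise GrammarError("substitution token with REF == ALT", offset)
            edits.append(Edit(ref_start=ref_len, ref_allele=ref_a, alt_allele=alt_a))
            ref_parts.append(ref_a)
            ed_parts.append(alt_a)
            ref_len += len(ref_a)
        else:
            raise GrammarError(
                "edit token must be (REF/ALT), (+SEQ) or (-SEQ)", offset
            )
    return EditSpec(
        raw_input=raw,
        reference_sequence="".join(ref_parts),
        edited_sequence="".join(ed_parts),
        edits=edits,
    )


def ref_to_edited_coordinate(spec: EditSpec, pos: int):
    """Functional wrapper around :meth:`EditSpec.ref_to_edited`."""
    return spec.ref_to_edited(pos)
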