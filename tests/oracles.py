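"""Independent brute-force oracles used to validate the design pipeline.

Everything here is written from the design rules directly — plain loops and
string surgery, no imports from the package's design modules — so agreement
between these functions and the pipeline is a meaningful check.
"""

from __future__ import annotations

import re

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_ACGT = set("ACGT")


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def splice(reference: str, edits) -> str:
    """Apply (ref_start, ref_allele, alt_allele) edits by direct splicing."""
    out, prev = [], 0
    for start, ref_allele, alt_allele in sorted(edits):
        out.append(reference[prev:start])
        out.append(alt_allele)
        prev = start + len(ref_allele)
    out.append(reference[prev:])
    return "".join(out)


_TOKEN_RE = re.compile(r"\(([^)]*)\)")


def parse_edit_string(text: str):
    """(reference, edited, edits) by independent regex surgery."""
    text = text.strip().upper()
    ref_parts, edits = [], []
    pos = 0
    ref_len = 0
    for m in _TOKEN_RE.finditer(text):
        plain = text[pos : m.start()]
        ref_parts.append(plain)
        ref_len += len(plain)
        body = m.group(1)
        if body.startswith("+"):
            edits.append((ref_len, "", body[1:]))
        elif body.startswith("-"):
            edits.append((ref_len, body[1:], ""))
            ref_parts.append(body[1:])
            ref_len += len(body) - 1
        else:
            ref_a, alt_a = body.split("/")
            edits.append((ref_len, ref_a, alt_a))
            ref_parts.append(ref_a)
            ref_len += len(ref_a)
        pos = m.end()
    ref_parts.append(text[pos:])
    reference = "".join(ref_parts)
    return reference, splice(reference, edits), edits


def rc_edit_string(text: str) -> str:
    """Reverse-complement an edit-encoded string, token-aware."""
    pieces = re.split(r"(\([^)]*\))", text.strip().upper())
    out = []
    for piece in reversed(pieces):
        if not piece:
            continue
        if piece.startswith("("):
            body = piece[1:-1]
            if body.startswith("+"):
                out.append(f"(+{rc(body[1:])})")
            elif body.startswith("-"):
                out.append(f"(-{rc(body[1:])})")
            else:
                ref_a, alt_a = body.split("/")
                out.append(f"({rc(ref_a)}/{rc(alt_a)})")
        else:
            out.append(rc(piece))
    return "".join(out)


def scan_protospacers(seq: str):
    """All (strand, ref_spacer_start) NGG sites, both strands, ACGT-only."""
    seq = seq.upper()
    sites = []
    for i in range(len(seq) - 22):
        window = seq[i : i + 23]
        if window[21:23] == "GG" and not set(window) - _ACGT:
            sites.append(("+", i))
        if window[0:2] == "CC" and not set(window) - _ACGT:
            sites.append(("-", i + 3))
    return sites


def _flip_edits(edits, n):
    return sorted(
        (n - (start + len(ref_a)), rc(ref_a), rc(alt_a))
        for start, ref_a, alt_a in edits
    )


def edited_span(edits):
    """(first, last_end) of edited bases in edited coordinates."""
    starts, ends, shift = [], [], 0
    for start, ref_a, alt_a in sorted(edits):
        starts.append(start + shift)
        ends.append(start + shift + len(alt_a))
        shift += len(alt_a) - len(ref_a)
    return min(starts), max(ends)


def enumerate_designs(reference, edited, edits, params):
    """Brute-force design set as tuples.

    Returns a set of (strand, ref_spacer_start, pbs, rtt, extension,
    nick_to_edit_distance, downstream_homology).
    """
    designs = set()
    n = len(reference)
    min_hom = params.min_downstream_homology
    max_rtt = max(params.rtt_lengths)
    for strand in "+-":
        if strand == "+":
            R, E, eds = reference, edited, sorted(edits)
        else:
            R, E = rc(reference), rc(edited)
            eds = _flip_edits(edits, n)
        e0, e1 = edited_span(eds)
        first_ref = min(s for s, _, _ in eds)
        for i in range(len(R) - 22):
            window = R[i : i + 23]
            if window[21:23] != "GG" or set(window) - _ACGT:
                continue
            nick = i + 17
            if nick > first_ref:
                continue
            dist = e0 - nick
            span = e1 - e0
            if dist + span + min_hom > max_rtt:
                continue
            ref_start = i if strand == "+" else n - 20 - i
            for pbs in params.pbs_lengths:
                if nick - pbs < 0:
                    continue
                for rtt in params.rtt_lengths:
                    if nick + rtt > len(E) or nick + rtt < e1:
                        continue
                    hom = rtt - dist - span
                    if hom < min_hom:
                        continue
                    pbs_seq = rc(R[nick - pbs : nick])
                    rtt_seq = rc(E[nick : nick + rtt])
                    if set(pbs_seq + rtt_seq) - _ACGT:
                        continue
                    designs.add(
                        (strand, ref_start, pbs, rtt, rtt_seq + pbs_seq, dist, hom)
                    )
    return designs


def edited_to_ref_map(reference, edited, edits):
    """Per edited base: the reference offset it descends from (None if
    inserted)."""
    mapping = [None] * len(edited)
    r = e = 0
    for start, ref_a, alt_a in sorted(edits):
        while r < start:
            mapping[e] = r
            r += 1
            e += 1
        for j in range(len(alt_a)):
            mapping[e + j] = r + j if j < len(ref_a) else None
        r += len(ref_a)
        e += len(alt_a)
    while r < len(reference):
        mapping[e] = r
        r += 1
        e += 1
    return mapping


def enumerate_ngrna_tuples(reference, edited, edits, peg_strand, peg_nick_ref, params):
    """Brute-force opposite-strand guide set.

    Returns a set of (ng_strand, edited_spacer_start, spacer, category,
    mismatch_positions, abs_distance).
    """
    mapping = edited_to_ref_map(reference, edited, edits)
    m = len(edited)
    lo, hi = params.ngrna_distance_range
    peg_bond = peg_nick_ref if peg_strand == "+" else peg_nick_ref + 1
    ng_strand = "-" if peg_strand == "+" else "+"
    search = edited if ng_strand == "+" else rc(edited)
    out = set()
    for i in range(len(search) - 22):
        window = search[i : i + 23]
        if window[21:23] != "GG" or set(window) - _ACGT:
            continue
        spacer = window[:20]
        if ng_strand == "+":
            ed_positions = list(range(i, i + 20))
            nick_bond_ed = i + 17
            start_ed = i
        else:
            start_ed = m - 20 - i
            ed_positions = list(range(start_ed + 19, start_ed - 1, -1))
            nick_bond_ed = m - (i + 17)
        mismatches = []
        for idx, (base, ed_pos) in enumerate(zip(spacer, ed_positions)):
            r = mapping[ed_pos]
            if r is None:
                mismatches.append(20 - idx)
                continue
            ref_base = reference[r] if ng_strand == "+" else _COMP[reference[r]]
            if base != ref_base:
                mismatches.append(20 - idx)
        mismatches = tuple(sorted(mismatches))
        if not mismatches:
            category = "PE3"
        elif any(p <= 10 for p in mismatches):
            category = "PE3b_seed"
        else:
            category = "PE3b_non_seed"
        # project the ngRNA nick bond onto the reference
        ref_bond = len(reference)
        for p in range(nick_bond_ed, m):
            if mapping[p] is not None:
                ref_bond = mapping[p]
                break
        ng_bond = ref_bond
        signed = ng_bond - peg_bond
        if peg_strand == "-":
            signed = -signed
        if not lo <= abs(signed) <= hi:
            continue
        out.add((ng_strand, start_ed, spacer, category, mismatches, abs(signed)))
    return out
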