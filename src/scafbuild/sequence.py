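"""Pure nucleotide-string operations and the deterministic scaffold builder.

All operations are pure functions on plain strings over the IUPAC
nucleotide alphabet (ACGTU plus ambiguity codes RYSWKMBDHVN), in either
case. Coordinates are 1-based and inclusive. Case is preserved
throughout so soft-masking in the input survives into the built
scaffold; unresolved regions are emitted as uppercase 'N'.
"""

from __future__ import annotations

from scafbuild.model import (
    BuildError,
    Insert,
    ScaffoldError,
    ScaffoldPlan,
    SequenceEntry,
    UnresolvedEntry,
    resolve_insert_bounds,
    validate_plan,
)

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "U": "A",
    "R": "Y", "Y": "R",
    "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B",
    "D": "H", "H": "D",
    "N": "N",
}
_COMPLEMENT.update({k.lower(): v.lower() for k, v in _COMPLEMENT.items()})

IUPAC_ALPHABET = frozenset(_COMPLEMENT)

_RC_TABLE = str.maketrans(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet, case-preserving.

    ``U`` complements to ``A`` (no T/U normalisation of the rest of the
    string). Raises :class:`ScaffoldError` (``invalid-character``)
    naming the 1-based position of the first character outside the
    alphabet.
    """
    for pos, ch in enumerate(seq, 1):
        if ch not in IUPAC_ALPHABET:
            raise ScaffoldError(
                "invalid-character",
                f"character {ch!r} at position {pos} is not an IUPAC nucleotide code",
            )
    return seq.translate(_RC_TABLE)[::-1]


def subsequence(seq: str, start: int, stop: int) -> str:
    """Characters ``start..stop`` inclusive (1-based); length stop-start+1."""
    if not (1 <= start <= stop <= len(seq)):
        raise ScaffoldError(
            "coordinate-out-of-bounds",
            f"subsequence ({start}, {stop}) outside [1, {len(seq)}]",
        )
    return seq[start - 1 : stop]


def splice(seq: str, open: int, close: int, replacement: str) -> str:
    """Replace positions ``open..close`` inclusive with ``replacement``."""
    if not (1 <= open <= close <= len(seq)):
        raise ScaffoldError(
            "coordinate-out-of-bounds",
            f"splice range ({open}, {close}) outside [1, {len(seq)}]",
        )
    return seq[: open - 1] + replacement + seq[close:]


def resolve_insert(insert: Insert, index) -> str:
    """The insert's patch sequence: source record, trimmed, then RC'd if asked."""
    if insert.source not in index:
        raise ScaffoldError(
            "unknown-source", f"no FASTA record named {insert.source!r}"
        )
    record = index[insert.source]
    start = insert.start if insert.start is not None else 1
    stop = insert.stop if insert.stop is not None else len(record)
    patch = subsequence(record, start, stop)
    return reverse_complement(patch) if insert.reverse else patch


def resolve_sequence_entry(entry: SequenceEntry, index) -> str:
    """Resolve one sequence entry to its contribution to the scaffold.

    Normative processing order:

    1. fetch the source record;
    2. splice in every insert, with open/close interpreted against the
       original forward-strand record — splices are applied in strictly
       descending ``open`` order so earlier coordinates are untouched by
       length changes downstream;
    3. trim with start/stop, interpreted against the *post-insertion*
       sequence (defaults: 1 and its full length);
    4. reverse complement if ``reverse``.
    """
    if entry.source not in index:
        raise ScaffoldError(
            "unknown-source", f"no FASTA record named {entry.source!r}"
        )
    seq = index[entry.source]
    resolved = []
    for insert in entry.inserts:
        patch = resolve_insert(insert, index)
        open_, close = resolve_insert_bounds(insert, len(patch))
        resolved.append((open_, close, patch))
    spans = sorted((o, c) for o, c, _ in resolved)
    for (o1, c1), (o2, c2) in zip(spans, spans[1:]):
        if o2 <= c1:
            raise ScaffoldError(
                "overlapping-inserts",
                f"insert ranges ({o1}, {c1}) and ({o2}, {c2}) overlap",
            )
    for open_, close, patch in sorted(resolved, key=lambda t: t[0], reverse=True):
        seq = splice(seq, open_, close, patch)
    start = entry.start if entry.start is not None else 1
    stop = entry.stop if entry.stop is not None else len(seq)
    seq = subsequence(seq, start, stop)
    return reverse_complement(seq) if entry.reverse else seq


def resolve_unresolved_entry(entry: UnresolvedEntry) -> str:
    """``entry.length`` uppercase 'N' characters."""
    if entry.length < 1:
        raise ScaffoldError(
            "non-positive-length",
            f"unresolved length must be >= 1, got {entry.length}",
        )
    return "N" * entry.length


def build_scaffold(plan: ScaffoldPlan, index) -> str:
    """Build the scaffold super-sequence: validate, then concatenate.

    Runs :func:`~scafbuild.model.validate_plan` first and raises
    :class:`~scafbuild.model.BuildError` carrying the full issue list if
    anything is wrong; a plan that validates cleanly always builds.
    Output is byte-identical for identical inputs across runs and
    platforms.
    """
    issues = validate_plan(plan, index)
    if issues:
        raise BuildError(issues)
    parts = []
    for entry in plan.entries:
        if isinstance(entry, UnresolvedEntry):
            parts.append(resolve_unresolved_entry(entry))
        else:
            parts.append(resolve_sequence_entry(entry, index))
    return "".join(parts)
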