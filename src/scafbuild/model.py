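"""Scaffold plan data model, YAML parsing, and validation.

A plan document is a YAML list in which every element is a single-key
mapping — ``{"sequence": {...}}`` or ``{"unresolved": {...}}``. All
coordinates throughout the model are 1-based and inclusive at both
ends, matching the convention biologists use when reading alignments
and feature tables.

Parsing is purely structural and never consults FASTA data;
:func:`validate_plan` performs every cross-check against a
:class:`~scafbuild.io.SequenceIndex` and returns a list of
:class:`ValidationIssue` rather than raising, so a caller can report
all problems in one pass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Union

import yaml

#: Machine-readable diagnostic codes emitted by parsing and validation.
ISSUE_CODES = frozenset(
    {
        "unknown-entry-type",
        "unknown-attribute",
        "missing-attribute",
        "unknown-source",
        "coordinate-out-of-bounds",
        "inverted-range",
        "overlapping-inserts",
        "non-positive-length",
        "empty-plan",
        "malformed-document",
        "duplicate-fasta-id",
        "invalid-character",
    }
)


@dataclass(frozen=True)
class ValidationIssue:
    """One problem found in a plan, located by entry index and attribute path."""

    entry_index: int
    path: str
    code: str
    message: str

    def __post_init__(self) -> None:
        if self.code not in ISSUE_CODES:
            raise ValueError(f"unknown issue code: {self.code!r}")

    def __str__(self) -> str:
        return f"entry {self.entry_index} {self.path}: {self.code}: {self.message}"


class ScaffoldError(Exception):
    """Base class for all scaffold-plan errors; carries a diagnostic code."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code
        self.message = message


class ParseError(ScaffoldError):
    """Structural problem in the plan document itself.

    Carries a single :class:`ValidationIssue`-equivalent description:
    the code, a location path, and the entry index (or -1 when the
    problem is document-level).
    """

    def __init__(self, code: str, message: str, entry_index: int = -1, path: str = ""):
        super().__init__(code, message)
        self.entry_index = entry_index
        self.path = path

    @property
    def issue(self) -> ValidationIssue:
        return ValidationIssue(self.entry_index, self.path, self.code, self.message)


class BuildError(ScaffoldError):
    """Raised when building a plan that fails validation.

    ``issues`` holds the complete issue list from :func:`validate_plan`;
    ``code`` is the first issue's code.
    """

    def __init__(self, issues: list[ValidationIssue]):
        if not issues:
            raise ValueError("BuildError requires at least one issue")
        super().__init__(issues[0].code, "; ".join(str(i) for i in issues))
        self.issues = list(issues)


@dataclass
class Insert:
    """A patch sequence replacing an inclusive coordinate range of its host.

    ``open``/``close`` address the *forward strand of the original host
    record*; the region between them (inclusive) is replaced by this
    insert's resolved sequence. When only one of the pair is given, the
    other is derived from the insert's post-trim length (see
    :func:`resolve_insert_bounds`). ``start``/``stop`` trim the insert's
    own source record before placement; ``reverse`` reverse-complements
    the trimmed insert.
    """

    source: str
    open: Optional[int] = None
    close: Optional[int] = None
    start: Optional[int] = None
    stop: Optional[int] = None
    reverse: bool = False


@dataclass
class SequenceEntry:
    """A scaffold region drawn from a named FASTA record.

    Inserts are applied first (coordinates anchored to the original
    record), then ``start``/``stop`` trim the post-insertion sequence,
    then ``reverse`` reverse-complements the result.
    """

    source: str
    start: Optional[int] = None
    stop: Optional[int] = None
    reverse: bool = False
    inserts: list[Insert] = field(default_factory=list)


@dataclass
class UnresolvedEntry:
    """A run of 'N' characters: sequence unknown, length (approximately) known."""

    length: int


Entry = Union[SequenceEntry, UnresolvedEntry]


@dataclass
class ScaffoldPlan:
    """An ordered, non-empty list of entries defining one super-sequence."""

    entries: list[Entry]


# --- YAML loading -----------------------------------------------------------
#
# YAML 1.1 resolves yes/no/on/off (and case variants) as booleans. Plans
# accept only true/false, so typo'd flags fail loudly instead of silently
# flipping a strand. The restricted loader below narrows the implicit bool
# resolver; everything else is stock SafeLoader.


class _StrictBoolLoader(yaml.SafeLoader):
    pass


# Rebuild implicit resolvers without the stock YAML-1.1 bool rule, then
# register a true/false-only rule in its place.
_StrictBoolLoader.yaml_implicit_resolvers = {
    key: [(tag, regexp) for tag, regexp in resolvers if tag != "tag:yaml.org,2002:bool"]
    for key, resolvers in yaml.SafeLoader.yaml_implicit_resolvers.items()
}
_StrictBoolLoader.add_implicit_resolver(
    "tag:yaml.org,2002:bool",
    re.compile(r"^(?:true|True|TRUE|false|False|FALSE)$"),
    list("tTfF"),
)


_SEQUENCE_KEYS = frozenset({"source", "start", "stop", "reverse", "inserts"})
_UNRESOLVED_KEYS = frozenset({"length"})
_INSERT_KEYS = frozenset({"source", "open", "close", "start", "stop", "reverse"})


def _require_int(value: object, entry_index: int, path: str) -> int:
    if isinstance(value, bool) or not isinstance(value, int):
        raise ParseError(
            "malformed-document",
            f"attribute {path!r} must be an integer, got {value!r}",
            entry_index,
            path,
        )
    return value


def _require_str(value: object, entry_index: int, path: str) -> str:
    if not isinstance(value, str) or not value:
        raise ParseError(
            "malformed-document",
            f"attribute {path!r} must be a non-empty string, got {value!r}",
            entry_index,
            path,
        )
    return value


def _require_bool(value: object, entry_index: int, path: str) -> bool:
    if not isinstance(value, bool):
        raise ParseError(
            "malformed-document",
            f"attribute {path!r} accepts only true/false, got {value!r}",
            entry_index,
            path,
        )
    return value


def _check_keys(
    mapping: dict, allowed: frozenset, entry_index: int, prefix: str
) -> None:
    for key in mapping:
        if not isinstance(key, str) or key not in allowed:
            raise ParseError(
                "unknown-attribute",
                f"unknown attribute {key!r} (allowed: {', '.join(sorted(allowed))})",
                entry_index,
                f"{prefix}{key}",
            )


def _parse_insert(raw: object, entry_index: int, path: str) -> Insert:
    if not isinstance(raw, dict):
        raise ParseError(
            "malformed-document", f"insert at {path!r} must be a mapping", entry_index, path
        )
    _check_keys(raw, _INSERT_KEYS, entry_index, f"{path}.")
    if "source" not in raw:
        raise ParseError(
            "missing-attribute", "insert requires a source", entry_index, f"{path}.source"
        )
    if "open" not in raw and "close" not in raw:
        raise ParseError(
            "missing-attribute",
            "insert requires at least one of open/close",
            entry_index,
            f"{path}.open",
        )
    return Insert(
        source=_require_str(raw["source"], entry_index, f"{path}.source"),
        open=_require_int(raw["open"], entry_index, f"{path}.open") if "open" in raw else None,
        close=_require_int(raw["close"], entry_index, f"{path}.close") if "close" in raw else None,
        start=_require_int(raw["start"], entry_index, f"{path}.start") if "start" in raw else None,
        stop=_require_int(raw["stop"], entry_index, f"{path}.stop") if "stop" in raw else None,
        reverse=_require_bool(raw["reverse"], entry_index, f"{path}.reverse")
        if "reverse" in raw
        else False,
    )


def _parse_entry(raw: object, entry_index: int) -> Entry:
    if not isinstance(raw, dict) or len(raw) != 1:
        raise ParseError(
            "malformed-document",
            "each entry must be a mapping with exactly one key "
            "(sequence or unresolved)",
            entry_index,
            "",
        )
    (kind, body), = raw.items()
    if kind == "sequence":
        if body is None:
            body = {}
        if not isinstance(body, dict):
            raise ParseError(
                "malformed-document", "sequence body must be a mapping", entry_index, "sequence"
            )
        _check_keys(body, _SEQUENCE_KEYS, entry_index, "")
        if "source" not in body:
            raise ParseError(
                "missing-attribute", "sequence entry requires a source", entry_index, "source"
            )
        raw_inserts = body.get("inserts", [])
        if not isinstance(raw_inserts, list):
            raise ParseError(
                "malformed-document", "inserts must be a list", entry_index, "inserts"
            )
        inserts = [
            _parse_insert(ins, entry_index, f"inserts[{i}]")
            for i, ins in enumerate(raw_inserts)
        ]
        return SequenceEntry(
            source=_require_str(body["source"], entry_index, "source"),
            start=_require_int(body["start"], entry_index, "start") if "start" in body else None,
            stop=_require_int(body["stop"], entry_index, "stop") if "stop" in body else None,
            reverse=_require_bool(body["reverse"], entry_index, "reverse")
            if "reverse" in body
            else False,
            inserts=inserts,
        )
    if kind == "unresolved":
        if not isinstance(body, dict):
            raise ParseError(
                "malformed-document",
                "unresolved body must be a mapping",
                entry_index,
                "unresolved",
            )
        _check_keys(body, _UNRESOLVED_KEYS, entry_index, "")
        if "length" not in body:
            raise ParseError(
                "missing-attribute", "unresolved entry requires a length", entry_index, "length"
            )
        return UnresolvedEntry(length=_require_int(body["length"], entry_index, "length"))
    raise ParseError(
        "unknown-entry-type",
        f"unknown entry type {kind!r} (expected sequence or unresolved)",
        entry_index,
        str(kind),
    )


def parse_scaffold(text: str) -> ScaffoldPlan:
    """Parse a scaffold plan document into a :class:`ScaffoldPlan`.

    The document must be a single YAML document whose root is a
    non-empty list; each element is a one-key mapping selecting the
    entry type. Attribute defaults are applied here (``reverse`` false,
    ``inserts`` empty, coordinates absent). Structural violations raise
    :class:`ParseError`; no FASTA data is consulted.
    """
    try:
        docs = list(yaml.load_all(text, Loader=_StrictBoolLoader))
    except yaml.YAMLError as exc:
        raise ParseError("malformed-document", f"not valid YAML: {exc}") from exc
    if not docs:
        raise ParseError("empty-plan", "plan document is empty")
    if len(docs) > 1:
        raise ParseError(
            "malformed-document",
            f"expected exactly one document per plan file, found {len(docs)} "
            "(separate scaffolds belong in separate files)",
        )
    root = docs[0]
    if root is None or (isinstance(root, list) and not root):
        raise ParseError("empty-plan", "plan contains no entries")
    if not isinstance(root, list):
        raise ParseError("malformed-document", "plan document root must be a list of entries")
    return ScaffoldPlan(entries=[_parse_entry(raw, i) for i, raw in enumerate(root)])


def resolve_insert_bounds(insert: Insert, effective_insert_length: int) -> tuple[int, int]:
    """Return the (open, close) range an insert replaces in its host.

    Both coordinates present: returned unchanged. One present: the
    other is derived so the replaced span exactly equals
    ``effective_insert_length`` — the insert's length *after* its own
    start/stop trimming (reverse complementing never changes length) —
    making the net length change of a single-coordinate insert zero.
    """
    if insert.open is not None and insert.close is not None:
        return insert.open, insert.close
    if insert.open is not None:
        return insert.open, insert.open + effective_insert_length - 1
    if insert.close is not None:
        open_ = insert.close - effective_insert_length + 1
        if open_ < 1:
            raise ScaffoldError(
                "coordinate-out-of-bounds",
                f"derived open coordinate {open_} < 1 "
                f"(close={insert.close}, insert length {effective_insert_length})",
            )
        return open_, insert.close
    raise ScaffoldError("missing-attribute", "insert has neither open nor close")


def _insert_effective_length(insert: Insert, record_length: int) -> int:
    start = insert.start if insert.start is not None else 1
    stop = insert.stop if insert.stop is not None else record_length
    return stop - start + 1


def _validate_insert(
    insert: Insert,
    entry_index: int,
    prefix: str,
    host_length: int,
    index,
    issues: list[ValidationIssue],
) -> Optional[tuple[int, int]]:
    """Check one insert; append issues; return resolved bounds if clean."""
    if insert.source not in index:
        issues.append(
            ValidationIssue(
                entry_index,
                f"{prefix}.source",
                "unknown-source",
                f"no FASTA record named {insert.source!r}",
            )
        )
        return None
    record_length = len(index[insert.source])
    ok = True
    start = insert.start if insert.start is not None else 1
    stop = insert.stop if insert.stop is not None else record_length
    if insert.start is not None and not (1 <= insert.start <= record_length):
        issues.append(
            ValidationIssue(
                entry_index,
                f"{prefix}.start",
                "coordinate-out-of-bounds",
                f"start {insert.start} outside [1, {record_length}] of {insert.source!r}",
            )
        )
        ok = False
    if insert.stop is not None and not (1 <= insert.stop <= record_length):
        issues.append(
            ValidationIssue(
                entry_index,
                f"{prefix}.stop",
                "coordinate-out-of-bounds",
                f"stop {insert.stop} outside [1, {record_length}] of {insert.source!r}",
            )
        )
        ok = False
    if ok and start > stop:
        issues.append(
            ValidationIssue(
                entry_index,
                f"{prefix}.start",
                "inverted-range",
                f"insert trim start {start} > stop {stop}",
            )
        )
        ok = False
    if not ok:
        return None
    if insert.open is not None and insert.close is not None and insert.open > insert.close:
        issues.append(
            ValidationIssue(
                entry_index,
                f"{prefix}.open",
                "inverted-range",
                f"open {insert.open} > close {insert.close}",
            )
        )
        return None
    try:
        open_, close = resolve_insert_bounds(insert, stop - start + 1)
    except ScaffoldError as exc:
        issues.append(ValidationIssue(entry_index, f"{prefix}.open", exc.code, exc.message))
        return None
    if not (1 <= open_ <= close <= host_length):
        issues.append(
            ValidationIssue(
                entry_index,
                f"{prefix}.open",
                "coordinate-out-of-bounds",
                f"insert range ({open_}, {close}) outside [1, {host_length}] "
                f"of the enclosing sequence",
            )
        )
        return None
    return open_, close


def validate_plan(plan: ScaffoldPlan, index) -> list[ValidationIssue]:
    """Check a parsed plan against a sequence index; return all issues.

    An empty return value guarantees :func:`scafbuild.sequence.build_scaffold`
    succeeds on the same inputs. Checks run in entry order and are
    side-effect free; identical inputs always yield the identical issue
    list. Per entry the order is: entry source resolution, per-insert
    checks (source, own trim, resolved placement bounds), pairwise
    insert disjointness, then entry trim against the post-insertion
    length (skipped when an insert already failed, since that length is
    then undefined).
    """
    issues: list[ValidationIssue] = []
    for i, entry in enumerate(plan.entries):
        if isinstance(entry, UnresolvedEntry):
            if entry.length < 1:
                issues.append(
                    ValidationIssue(
                        i,
                        "length",
                        "non-positive-length",
                        f"unresolved length must be >= 1, got {entry.length}",
                    )
                )
            continue
        if entry.source not in index:
            issues.append(
                ValidationIssue(
                    i, "source", "unknown-source", f"no FASTA record named {entry.source!r}"
                )
            )
            continue
        host_length = len(index[entry.source])
        bounds: list[tuple[int, int]] = []
        inserts_clean = True
        for j, insert in enumerate(entry.inserts):
            resolved = _validate_insert(
                insert, i, f"inserts[{j}]", host_length, index, issues
            )
            if resolved is None:
                inserts_clean = False
            else:
                bounds.append(resolved)
        # closed intervals: sharing even a single position is an overlap
        sorted_bounds = sorted(bounds)
        for (o1, c1), (o2, c2) in zip(sorted_bounds, sorted_bounds[1:]):
            if o2 <= c1:
                issues.append(
                    ValidationIssue(
                        i,
                        "inserts",
                        "overlapping-inserts",
                        f"insert ranges ({o1}, {c1}) and ({o2}, {c2}) overlap",
                    )
                )
                inserts_clean = False
        if not inserts_clean:
            continue
        built_length = host_length + sum(
            _insert_effective_length(ins, len(index[ins.source])) - (c - o + 1)
            for ins, (o, c) in zip(entry.inserts, bounds)
        )
        if built_length < 1:
            # an empty FASTA record (or inserts deleting everything) yields
            # a zero-length region: nothing a coordinate could address
            issues.append(
                ValidationIssue(
                    i,
                    "source",
                    "coordinate-out-of-bounds",
                    f"entry resolves to an empty sequence ({entry.source!r})",
                )
            )
            continue
        start = entry.start if entry.start is not None else 1
        stop = entry.stop if entry.stop is not None else built_length
        trim_ok = True
        if entry.start is not None and not (1 <= entry.start <= built_length):
            issues.append(
                ValidationIssue(
                    i,
                    "start",
                    "coordinate-out-of-bounds",
                    f"start {entry.start} outside [1, {built_length}] "
                    f"(post-insertion length of {entry.source!r})",
                )
            )
            trim_ok = False
        if entry.stop is not None and not (1 <= entry.stop <= built_length):
            issues.append(
                ValidationIssue(
                    i,
                    "stop",
                    "coordinate-out-of-bounds",
                    f"stop {entry.stop} outside [1, {built_length}] "
                    f"(post-insertion length of {entry.source!r})",
                )
            )
            trim_ok = False
        if trim_ok and start > stop:
            issues.append(
                ValidationIssue(
                    i, "start", "inverted-range", f"trim start {start} > stop {stop}"
                )
            )
    return issues
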