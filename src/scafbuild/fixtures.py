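"""Synthetic scaffold cases and an independent brute-force builder.

The generator emits random *valid* plan/FASTA pairs whose expected
output is computed by :func:`oracle_build` — a deliberately different
construction from the production builder: post-insertion sequences are
assembled by a single left-to-right walk over the source (never by
in-place splicing), and reverse complementing uses per-character
dictionary lookup rather than ``str.translate``. Agreement between the
two routes over many seeds is the package's central correctness check.

:func:`worked_example_case` reconstructs the canonical worked example: a
three-entry scaffold (plain sequence, 20-N unresolved region, trimmed
reverse-complemented sequence carrying two inserts) with synthetic
nucleotide content.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass

import yaml

from scafbuild.io import SequenceIndex, write_fasta
from scafbuild.model import (
    Insert,
    ScaffoldPlan,
    SequenceEntry,
    UnresolvedEntry,
    parse_scaffold,
    resolve_insert_bounds,
    validate_plan,
)


@dataclass(frozen=True)
class FixtureCase:
    """A plan/FASTA pair with its oracle-computed expected scaffold."""

    plan_text: str
    fasta_text: str
    expected_sequence: str
    seed: int
    description: str


def random_nucleotides(length: int, seed: int) -> str:
    """Uniform random string over {A,C,G,T}; same (length, seed) → same string."""
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    rng = random.Random(seed)
    return "".join(rng.choices("ACGT", k=length))


def _oracle_rc(seq: str) -> str:
    # dictionary-lookup complement, independent of the production table
    comp = {
        "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
        "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
        "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    }
    out = []
    for ch in reversed(seq):
        if ch.islower():
            out.append(comp[ch.upper()].lower())
        else:
            out.append(comp[ch])
    return "".join(out)


def oracle_build(plan: ScaffoldPlan, index: SequenceIndex) -> str:
    """Rebuild the scaffold by an independent method (valid plans only).

    Each sequence entry's post-insertion sequence is produced by walking
    the source left to right, emitting unreplaced segments and patches
    in turn; trimming is plain slicing; reverse complement is
    dictionary-based. Must equal the production builder on every valid
    input.
    """
    regions = []
    for entry in plan.entries:
        if isinstance(entry, UnresolvedEntry):
            regions.append("N" * entry.length)
            continue
        source = index[entry.source]
        patches = []
        for ins in entry.inserts:
            record = index[ins.source]
            start = ins.start if ins.start is not None else 1
            stop = ins.stop if ins.stop is not None else len(record)
            patch = record[start - 1 : stop]
            if ins.reverse:
                patch = _oracle_rc(patch)
            open_, close = resolve_insert_bounds(ins, len(patch))
            patches.append((open_, close, patch))
        patches.sort(key=lambda t: t[0])
        pieces = []
        cursor = 1  # 1-based position of the next unemitted source character
        for open_, close, patch in patches:
            pieces.append(source[cursor - 1 : open_ - 1])
            pieces.append(patch)
            cursor = close + 1
        pieces.append(source[cursor - 1 :])
        built = "".join(pieces)
        start = entry.start if entry.start is not None else 1
        stop = entry.stop if entry.stop is not None else len(built)
        built = built[start - 1 : stop]
        if entry.reverse:
            built = _oracle_rc(built)
        regions.append(built)
    return "".join(regions)


def _entry_to_raw(entry) -> dict:
    if isinstance(entry, UnresolvedEntry):
        return {"unresolved": {"length": entry.length}}
    body: dict = {"source": entry.source}
    if entry.start is not None:
        body["start"] = entry.start
    if entry.stop is not None:
        body["stop"] = entry.stop
    if entry.reverse:
        body["reverse"] = True
    if entry.inserts:
        raws = []
        for ins in entry.inserts:
            raw = {"source": ins.source}
            for attr in ("open", "close", "start", "stop"):
                value = getattr(ins, attr)
                if value is not None:
                    raw[attr] = value
            if ins.reverse:
                raw["reverse"] = True
            raws.append(raw)
        body["inserts"] = raws
    return {"sequence": body}


def plan_to_yaml(plan: ScaffoldPlan) -> str:
    """Serialize a plan back to a document parse_scaffold accepts (round-trip helper)."""
    return "---\n" + yaml.safe_dump(
        [_entry_to_raw(e) for e in plan.entries], sort_keys=False
    )


def _index_to_fasta(index: SequenceIndex, wrap: int = 60) -> str:
    sink = io.StringIO()
    for ident in index:
        write_fasta(index.header(ident), index[ident], wrap, stream=sink)
    return sink.getvalue()


def generate_case(seed: int, max_entries: int = 4, max_inserts: int = 3) -> FixtureCase:
    """Generate one random valid scaffold case, expected output included.

    Sequence sources are 10–200 nt over {A,C,G,T}; entries mix sequence
    and unresolved types; sequence entries carry optional trims,
    optional reversal, and up to ``max_inserts`` pairwise-disjoint
    inserts using one- or two-coordinate placement. Deterministic in
    ``seed``; every case validates with zero issues.
    """
    rng = random.Random(seed)
    index = SequenceIndex()
    entries = []
    counter = 0

    def new_record(length: int) -> str:
        nonlocal counter
        counter += 1
        ident = f"rec{counter}"
        index.add(ident, "".join(rng.choices("ACGT", k=length)))
        return ident

    for _ in range(rng.randint(1, max_entries)):
        if rng.random() < 0.25:
            entries.append(UnresolvedEntry(length=rng.randint(1, 50)))
            continue
        source_len = rng.randint(10, 200)
        source = new_record(source_len)
        inserts = []
        spans: list[tuple[int, int]] = []
        for _ in range(rng.randint(0, max_inserts)):
            placed = None
            for _attempt in range(25):
                open_ = rng.randint(1, source_len)
                close = open_ + rng.randint(0, min(9, source_len - open_))
                if all(close < o or c < open_ for o, c in spans):
                    placed = (open_, close)
                    break
            if placed is None:
                continue
            open_, close = placed
            spans.append(placed)
            span = close - open_ + 1
            mode = rng.choice(("both", "open", "close"))
            # one-coordinate placement derives the other bound from the
            # insert's effective length, so that length must equal the span
            patch_len = rng.randint(1, 12) if mode == "both" else span
            pad_left = rng.randint(0, 5)
            pad_right = rng.randint(0, 5)
            ins_source = new_record(pad_left + patch_len + pad_right)
            start = stop = None
            if pad_left or pad_right or rng.random() < 0.3:
                start = pad_left + 1
                stop = pad_left + patch_len
            inserts.append(
                Insert(
                    source=ins_source,
                    open=open_ if mode in ("both", "open") else None,
                    close=close if mode in ("both", "close") else None,
                    start=start,
                    stop=stop,
                    reverse=rng.random() < 0.5,
                )
            )
        built_len = source_len + sum(
            (ins.stop - ins.start + 1 if ins.start is not None else len(index[ins.source]))
            - (c - o + 1)
            for ins, (o, c) in zip(inserts, spans)
        )
        start = stop = None
        if rng.random() < 0.5 and built_len >= 1:
            start = rng.randint(1, built_len)
            stop = rng.randint(start, built_len)
        entries.append(
            SequenceEntry(
                source=source,
                start=start,
                stop=stop,
                reverse=rng.random() < 0.5,
                inserts=inserts,
            )
        )

    plan = ScaffoldPlan(entries=entries)
    issues = validate_plan(plan, index)
    if issues:  # pragma: no cover - generator contract
        raise AssertionError(f"generated case is invalid: {issues}")
    plan_text = plan_to_yaml(plan)
    # the YAML round trip must reproduce the plan we built
    assert parse_scaffold(plan_text) == plan
    return FixtureCase(
        plan_text=plan_text,
        fasta_text=_index_to_fasta(index),
        expected_sequence=oracle_build(plan, index),
        seed=seed,
        description=f"random case seed={seed}",
    )


def worked_example_case() -> FixtureCase:
    """The canonical three-entry worked example, with synthetic nucleotides.

    Entry 1: plain sequence 'sequence1'. Entry 2: unresolved region of
    length 20. Entry 3: 'sequence2' trimmed, reverse complemented, and
    patched with two inserts — 'insert1' fully specified (open, close,
    start, stop, reverse) and 'insert2' placed by its open coordinate
    alone. Nucleotide content is generated from fixed seeds; only the
    structure mirrors the published example.
    """
    index = SequenceIndex()
    index.add("sequence1 first contig", random_nucleotides(40, seed=101))
    index.add("sequence2 second contig", random_nucleotides(60, seed=202))
    index.add("insert1 pcr product", random_nucleotides(8, seed=303))
    index.add("insert2 pcr product", random_nucleotides(6, seed=404))
    plan_text = """---
- sequence:
    source: sequence1
- unresolved:
    length: 20
- sequence:
    source: sequence2
    start: 5
    stop: 55
    reverse: true
    inserts:
      - source: insert1
        open: 10
        close: 14
        start: 2
        stop: 6
        reverse: true
      - source: insert2
        open: 30
"""
    plan = parse_scaffold(plan_text)
    return FixtureCase(
        plan_text=plan_text,
        fasta_text=_index_to_fasta(index),
        expected_sequence=oracle_build(plan, index),
        seed=0,
        description="reconstruction of the canonical worked example",
    )
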