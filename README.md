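# scafbuild

Declarative, reproducible genome finishing: describe a scaffold as a
small YAML file, keep the contigs in a plain FASTA file, and let the
tool validate the plan and build the scaffold super-sequence.

## The problem

Finishing a draft genome means ordering and orienting contigs, marking
gaps of estimated size, and patching in extra sequence (for example
PCR-derived inserts that close a gap). Doing this by copy-pasting
blocks of nucleotide text into an editor is error-prone and leaves no
record of what was done. `scafbuild` replaces the hand edits with a
human-editable plan file: the plan *is* the documentation of how the
scaffold was constructed, and rebuilding from the same plan and the
same FASTA always produces byte-identical output.

## The model

A scaffold plan is a YAML list of entries; each entry contributes one
region, in order, to the final super-sequence `S`:

- `sequence` — a region taken from the FASTA record named by `source`
  (records are addressed by the first word of their header). The
  record may be patched with `inserts`, trimmed with `start`/`stop`,
  and reverse complemented with `reverse: true`. Per entry the
  contribution is

  `region = rc?( trim_{start..stop}( splice_inserts( source ) ) )`

- `unresolved` — a gap of unknown sequence but known length `L`,
  rendered as `N^L`.

All coordinates are 1-based and inclusive at both ends. An insert
replaces the closed interval `[open, close]` of its host record with
its own (optionally trimmed and reverse-complemented) sequence; if only
one of `open`/`close` is given, the other is derived from the insert's
effective length so the replaced span equals the insert. Insert
coordinates always address the original forward-strand record; entry
`start`/`stop` address the post-insertion sequence; reversal is applied
last. The built scaffold is the concatenation of all regions in plan
order.

Validation checks every cross-reference and coordinate before any
sequence is assembled and reports *all* problems with machine-readable
codes (`unknown-source`, `coordinate-out-of-bounds`, `inverted-range`,
`overlapping-inserts`, ...). A plan that validates cleanly is
guaranteed to build.

## Worked example

`scaffold.yml` — three entries: a plain contig, a 20-base gap, and a
trimmed, reverse-complemented contig carrying two inserts (the second
placed by its `open` coordinate alone):

```yaml
---
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
```

with `records.fa` holding `sequence1` (40 nt), `sequence2` (60 nt),
`insert1` (8 nt) and `insert2` (6 nt). Then:

```
$ scafbuild validate scaffold.yml records.fa   # silent, exit 0
$ scafbuild build scaffold.yml records.fa
>scaffold
GATTCGAACGATAAATCCCGCACCATGGTCCCCGACGCAGNNNNNNNNNNNNNNNNNNNNGCCGTTGTAA
GTCGATATTTGCTTGTATGAGGTTCCGTGACTATTCTAGAC
```

The 111 nt output is: the 40 nt of `sequence1` verbatim, the 20 `N`
gap, then 51 nt from `sequence2` — positions 10–14 replaced by the
reverse complement of `insert1[2..6]`, positions 30–35 replaced by
`insert2` (its `close` derived as 30 + 6 − 1 = 35), trimmed to 5–55 and
reverse complemented. Rerunning the command reproduces these bytes
exactly. This exact fixture is available programmatically as
`scafbuild.fixtures.worked_example_case()`.

`build` supports `--output PATH` (atomic write; an invalid plan never
leaves a partial file), `--header NAME` (default `scaffold`) and
`--wrap N` (default 70). Exit codes: 0 success, 1 validation failure
(one diagnostic line per issue on stderr), 2 unreadable/unparseable
input.

## Library use

```python
from scafbuild import parse_scaffold, read_fasta_index, build_scaffold

plan = parse_scaffold(open("scaffold.yml").read())
index = read_fasta_index(open("records.fa"))
sequence = build_scaffold(plan, index)   # raises BuildError with all issues if invalid
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch: it builds the worked example
above and checks its structure and 20-`N` gap, performs ten repeated
CLI builds to confirm byte-identical output, and builds 500 seeded
random scaffolds, comparing each against an independent brute-force
builder (`scafbuild.fixtures.oracle_build`) that assembles every entry
by a left-to-right walk instead of in-place splicing. It writes its
JSON results object to `--out`.

See `docs/methods.md` for the full semantics, numerical conventions and
known limitations.
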