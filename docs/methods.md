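# Methods

## The plan format and its semantics

A scaffold plan is a single YAML document whose root is a non-empty
list. Each element is a mapping with exactly one key — `sequence` or
`unresolved` — whose value holds that entry type's attributes. One
plan describes one scaffold; multiple documents in a file are rejected
(separate scaffolds belong in separate files). Entry order in the file
is the region order in the built super-sequence.

Attributes:

| entry | attribute | meaning | default |
|---|---|---|---|
| sequence | `source` | FASTA record identifier (first header word) | required |
| sequence | `start`, `stop` | inclusive trim range on the post-insertion sequence | full range |
| sequence | `reverse` | reverse complement the final region | `false` |
| sequence | `inserts` | ordered list of insert mappings | `[]` |
| insert | `source` | FASTA record supplying the patch | required |
| insert | `open`, `close` | inclusive host range the patch replaces | at least one required |
| insert | `start`, `stop` | inclusive trim range on the insert's own record | full range |
| insert | `reverse` | reverse complement the patch | `false` |
| unresolved | `length` | number of `N` characters (≥ 1) | required |

All coordinates are 1-based and inclusive at both ends — the
convention biologists use in feature tables and alignment viewers; the
format never states a base explicitly, so this is a deliberate,
documented choice and all arithmetic below depends on it.

Strictness is a design stance, not an accident: unknown attribute
names (`revrse`) are hard errors, because a silently ignored typo
would silently change a genome build. For the same reason `reverse`
accepts only `true`/`false`: the YAML 1.1 spellings `yes`/`no`/`on`/`off`
are *not* booleans here (the loader's implicit bool resolver is
narrowed to true/false), so a stray `reverse: yes` fails loudly as a
malformed document instead of flipping a strand depending on parser
dialect.

## Entry resolution

For a `sequence` entry the processing order is normative:

1. fetch the source record;
2. resolve each insert: trim its record by its own `start`/`stop`,
   reverse complement if asked, derive the missing `open`/`close`
   bound if only one was given (see below), then splice all patches
   into the host **in strictly descending `open` order**, so earlier
   coordinates are never shifted by downstream length changes;
3. trim with the entry's `start`/`stop`, interpreted against the
   **post-insertion** sequence;
4. reverse complement the result if `reverse`.

Consequences of this ordering, each deliberate:

- Insert `open`/`close` always address the original forward-strand
  record, even when the entry is reversed — insert coordinates stay
  stable when a user toggles `reverse` or edits other inserts.
- Entry trims address the sequence the user would see after patching;
  the alternative (pre-insertion trims) would make a trim silently
  shift whenever an insert changes length.

A single-coordinate insert derives its other bound from the insert's
**post-trim** length `L`: `close = open + L − 1` or
`open = close − L + 1`. The derived span therefore always equals the
patch length (net length change zero). Using the raw record length
instead would make trimming and single-coordinate placement compose
inconsistently; post-trim length is the choice that keeps
`trim ∘ place` order-independent. A derived `open < 1`, or any
resolved range not inside `[1, host length]`, is an error — an insert
may not bridge past the end of its entry into a neighbouring gap
region; model such cases with explicit `open`/`close` instead.

Inserts are replacements of **closed** intervals: two inserts whose
resolved ranges share even a single position overlap and are rejected;
ranges that merely touch (`close` of one = `open` of the next − 1) are
legal.

`unresolved` entries render as uppercase `N` repeated `length` times;
`length ≥ 1` is enforced (a zero-length gap carries no information and
is almost certainly an editing mistake).

## Validation

`validate_plan(plan, index)` returns a list of issues, each with the
entry index, an attribute path (`inserts[1].open`), a machine-readable
code and a human message; an empty list guarantees the build succeeds.
All issues are collected in one pass, in entry order, so a user fixes
a plan in one round trip rather than one error at a time. Within an
entry the order is: entry source resolution; per-insert checks
(source, own trim bounds, resolved placement bounds); pairwise
disjointness of resolved insert ranges; finally the entry trim checked
against the post-insertion length — last because that length is only
defined once every insert has resolved cleanly (if an insert failed,
the trim check is skipped; the entry already has issues). Validation
is pure and order-stable: identical inputs give the identical issue
list.

`build_scaffold` re-runs validation internally and raises with the
full issue list on any problem, so the guarantee holds regardless of
whether the caller validated first.

## FASTA handling

Records are read into an insertion-ordered index keyed by the first
whitespace-delimited word of the header. Record splitting uses
Biopython's `SimpleFastaParser`; on top of it the reader strips all
whitespace inside sequence bodies (line wrapping never matters),
accepts LF and CRLF, tolerates blank lines, and rejects duplicate
identifiers, empty identifiers, content before the first `>`, and any
character outside the IUPAC nucleotide alphabet (with record and
position named). Empty records are legal in the file; referencing one
from a plan fails validation, since no 1-based coordinate can address
it.

Letter case is preserved end to end, so soft-masking in the inputs
survives into the scaffold. `U` is accepted and complements to `A`;
no T/U normalisation is applied to anything else — which means strict
involution (`rc(rc(s)) = s`) holds on the DNA alphabet, while on
RNA-containing strings `rc ∘ rc` is exactly T/U normalisation. The
written FASTA record is bit-exact: `>` + header, sequence wrapped to a
fixed width (default 70 columns, common FASTA practice), LF newlines,
trailing newline.

## Determinism and the CLI

Building is a pure function of (plan text, FASTA text): no clocks, no
randomness, no environment lookups. Ten repeated builds of the same
fixture are asserted byte-identical in the test suite. The CLI writes
output files atomically (temporary file in the destination directory,
then rename), so an invalid plan or a crash never leaves a partial
scaffold on disk. Exit codes are exactly 0 (success), 1 (validation
failure, one diagnostic line per issue on stderr) and 2 (usage, I/O or
parse failure); the built record is the only thing ever written to
stdout.

## Synthetic cases and the oracle

The generator (`scafbuild.fixtures.generate_case`) emits random valid
plan/FASTA pairs: 1–4 entries mixing sequence regions (sources 10–200
nt over {A,C,G,T}, optional trims and reversal, up to 3
pairwise-disjoint inserts with one- or two-coordinate placement,
insert records padded so their own trims are exercised) and unresolved
gaps of 1–50 nt. Sizes were chosen once as desk-scale values that
exercise every code path — inserts at region boundaries, single-base
spans, derived bounds — while keeping a 500-case sweep under a few
seconds; they are not tuned to any empirical genome. The generator is
deterministic in its seed.

Expected outputs come from `oracle_build`, a deliberately different
implementation: post-insertion sequences are assembled by a single
left-to-right walk emitting unreplaced source segments and patches
(never by in-place splicing), and reverse complementing uses
per-character dictionary lookup rather than the production
`str.translate` table. Agreement of the two routes, byte-exact, over
hundreds of seeds is the central correctness check; a corruption suite
additionally verifies that each single mutation of a valid plan
(renamed source, inverted range, overlapping inserts, zeroed gap
length, misspelled attribute) yields its specific issue code and a
build refusal.

What a green suite does not establish: the generator draws only
{A,C,G,T} sources (ambiguity codes and case handling are covered by
dedicated unit tests, not randomly), sequences are far shorter than
real contigs (correctness here is length-independent string algebra,
but performance on chromosome-scale inputs is untested), and the
worked-example fixture reproduces the canonical example's *structure*
(three entries, two inserts, a 20-N gap) with synthetic nucleotide
content, since no published nucleotides exist for it.

## Known limitations

- One scaffold per plan file; no AGP import/export.
- No inference of contig order, orientation or gap sizes — the plan
  states them, the tool executes them.
- Inserts cannot extend beyond their entry or bridge across entry
  boundaries into gap regions; resolved bounds must lie inside the
  host record.
- No quality values and no per-base provenance in the output record.
- Plans and FASTA are read fully into memory; suitable for
  finishing-scale inputs (megabases), not for streaming terabase data.
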