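"""Plan parsing, insert-bound resolution, and validation diagnostics."""

import pytest
from hypothesis import given, settings, strategies as st

from scafbuild.fixtures import generate_case, plan_to_yaml
from scafbuild.io import SequenceIndex, read_fasta_index
from scafbuild.model import (
    Insert,
    ParseError,
    ScaffoldError,
    ScaffoldPlan,
    SequenceEntry,
    UnresolvedEntry,
    parse_scaffold,
    resolve_insert_bounds,
    validate_plan,
)


class TestParseScaffold:
    def test_simple_sequence_entry(self):
        plan = parse_scaffold("--- \n- sequence:\n    source: sequence1")
        assert plan.entries == [
            SequenceEntry(source="sequence1", reverse=False, inserts=[])
        ]

    def test_unresolved_entry(self):
        plan = parse_scaffold("--- \n- unresolved:\n    length: 20")
        assert plan.entries == [UnresolvedEntry(length=20)]

    def test_insert_defaults(self):
        plan = parse_scaffold(
            "- sequence:\n"
            "    source: a\n"
            "    inserts:\n"
            "      - source: b\n"
            "        open: 3\n"
        )
        (entry,) = plan.entries
        assert entry.inserts == [Insert(source="b", open=3)]

    @pytest.mark.parametrize(
        "doc,code",
        [
            ("--- []", "empty-plan"),
            ("", "empty-plan"),
            ("- sequnce:\n    source: a", "unknown-entry-type"),
            ("sequence: {source: a}", "malformed-document"),
            ("- sequence:\n    source: a\n    revrse: true", "unknown-attribute"),
            ("- sequence: {}", "missing-attribute"),
            ("- unresolved: {}", "missing-attribute"),
            ("- sequence:\n    source: a\n    inserts:\n      - open: 1", "missing-attribute"),
            # insert with neither open nor close
            ("- sequence:\n    source: a\n    inserts:\n      - source: b", "missing-attribute"),
            # truthy spellings other than true/false are not booleans
            ("- sequence:\n    source: a\n    reverse: yes", "malformed-document"),
            ("- sequence:\n    source: a\n    reverse: 1", "malformed-document"),
            ("- unresolved:\n    length: twenty", "malformed-document"),
            # two documents in one file: one scaffold per file
            ("---\n- unresolved:\n    length: 1\n---\n- unresolved:\n    length: 2\n",
             "malformed-document"),
            ("not: [valid", "malformed-document"),
        ],
    )
    def test_structural_errors(self, doc, code):
        with pytest.raises(ParseError) as exc:
            parse_scaffold(doc)
        assert exc.value.code == code

    def test_error_carries_entry_location(self):
        with pytest.raises(ParseError) as exc:
            parse_scaffold("- unresolved:\n    length: 1\n- sequnce:\n    source: a")
        assert exc.value.entry_index == 1

    def test_entry_order_preserved(self):
        plan = parse_scaffold(
            "- unresolved:\n    length: 5\n"
            "- sequence:\n    source: a\n"
            "- unresolved:\n    length: 7\n"
        )
        kinds = [type(e).__name__ for e in plan.entries]
        assert kinds == ["UnresolvedEntry", "SequenceEntry", "UnresolvedEntry"]


class TestResolveInsertBounds:
    @pytest.mark.parametrize(
        "insert,length,expected",
        [
            (Insert(source="x", open=4, close=7), 99, (4, 7)),  # both given: identity
            (Insert(source="x", open=3), 3, (3, 5)),
            (Insert(source="x", close=10), 4, (7, 10)),
        ],
    )
    def test_resolution(self, insert, length, expected):
        assert resolve_insert_bounds(insert, length) == expected

    def test_neither_coordinate_is_an_error(self):
        with pytest.raises(ScaffoldError) as exc:
            resolve_insert_bounds(Insert(source="x"), 5)
        assert exc.value.code == "missing-attribute"

    def test_derived_open_below_one_is_an_error(self):
        with pytest.raises(ScaffoldError) as exc:
            resolve_insert_bounds(Insert(source="x", close=3), 10)
        assert exc.value.code == "coordinate-out-of-bounds"

    @given(
        coord=st.integers(min_value=1, max_value=1000),
        length=st.integers(min_value=1, max_value=1000),
        use_open=st.booleans(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_single_coordinate_span_equals_insert_length(self, coord, length, use_open):
        """A one-coordinate insert replaces exactly its own length (net change 0)."""
        insert = (
            Insert(source="x", open=coord)
            if use_open
            else Insert(source="x", close=coord + length)  # keep derived open >= 1
        )
        open_, close = resolve_insert_bounds(insert, length)
        assert close - open_ + 1 == length


class TestValidatePlan:
    def test_valid_plan_has_no_issues(self, simple_index):
        plan = parse_scaffold("- sequence:\n    source: s1\n- unresolved:\n    length: 3")
        assert validate_plan(plan, simple_index) == []

    def test_unknown_source(self, simple_index):
        plan = ScaffoldPlan([SequenceEntry(source="ghost")])
        (issue,) = validate_plan(plan, simple_index)
        assert (issue.code, issue.path, issue.entry_index) == ("unknown-source", "source", 0)

    def test_stop_beyond_record_end(self):
        index = SequenceIndex.from_dict({"a": "ACGTACGTAC"})  # length 10
        plan = ScaffoldPlan([SequenceEntry(source="a", stop=11)])
        (issue,) = validate_plan(plan, index)
        assert (issue.code, issue.path) == ("coordinate-out-of-bounds", "stop")

    def test_touching_closed_intervals_overlap(self, simple_index):
        plan = ScaffoldPlan(
            [
                SequenceEntry(
                    source="long",
                    inserts=[
                        Insert(source="patch", open=3, close=5),
                        Insert(source="patch", open=5, close=8),
                    ],
                )
            ]
        )
        issues = validate_plan(plan, simple_index)
        assert [i.code for i in issues] == ["overlapping-inserts"]

    def test_adjacent_inserts_are_legal(self, simple_index):
        plan = ScaffoldPlan(
            [
                SequenceEntry(
                    source="long",
                    inserts=[
                        Insert(source="patch", open=3, close=4),
                        Insert(source="patch", open=5, close=6),
                    ],
                )
            ]
        )
        assert validate_plan(plan, simple_index) == []

    def test_overlap_oracle_brute_force(self, simple_index):
        """Pairwise closed-interval intersection agrees with a brute-force check."""
        import itertools

        spans = [(1, 2), (2, 4), (5, 5), (6, 8), (4, 6)]
        for a, b in itertools.combinations(spans, 2):
            overlap_by_enumeration = bool(
                set(range(a[0], a[1] + 1)) & set(range(b[0], b[1] + 1))
            )
            plan = ScaffoldPlan(
                [
                    SequenceEntry(
                        source="long",
                        inserts=[
                            Insert(source="patch", open=a[0], close=a[1]),
                            Insert(source="patch", open=b[0], close=b[1]),
                        ],
                    )
                ]
            )
            codes = {i.code for i in validate_plan(plan, simple_index)}
            assert ("overlapping-inserts" in codes) == overlap_by_enumeration

    @pytest.mark.parametrize(
        "entry,code",
        [
            (UnresolvedEntry(length=0), "non-positive-length"),
            (UnresolvedEntry(length=-3), "non-positive-length"),
            (SequenceEntry(source="s1", start=3, stop=2), "inverted-range"),
            (SequenceEntry(source="s1", start=0), "coordinate-out-of-bounds"),
            (SequenceEntry(source="s1", inserts=[Insert(source="ghost", open=1)]),
             "unknown-source"),
            (SequenceEntry(source="s1", inserts=[Insert(source="patch", open=3, close=2)]),
             "inverted-range"),
            (SequenceEntry(source="s1", inserts=[Insert(source="patch", open=4, close=5)]),
             "coordinate-out-of-bounds"),  # close beyond s1 (length 4)
            (SequenceEntry(source="s1", inserts=[Insert(source="patch", open=1, start=2, stop=1)]),
             "inverted-range"),
            (SequenceEntry(source="s1", inserts=[Insert(source="patch", open=1, stop=9)]),
             "coordinate-out-of-bounds"),  # insert trim beyond its own record
        ],
    )
    def test_single_issue_cases(self, simple_index, entry, code):
        issues = validate_plan(ScaffoldPlan([entry]), simple_index)
        assert [i.code for i in issues] == [code]

    def test_empty_record_referenced(self):
        index = SequenceIndex.from_dict({"empty": ""})
        plan = ScaffoldPlan([SequenceEntry(source="empty")])
        (issue,) = validate_plan(plan, index)
        assert issue.code == "coordinate-out-of-bounds"

    def test_trim_checked_against_post_insertion_length(self, simple_index):
        # host length 8, insert replaces (4,5) with 2 nt -> still 8; stop=8 ok
        plan = ScaffoldPlan(
            [
                SequenceEntry(
                    source="host",
                    stop=8,
                    inserts=[Insert(source="patch", open=4, close=5)],
                )
            ]
        )
        assert validate_plan(plan, simple_index) == []
        # replacing (3,6) [4 nt] with 2 nt shortens to 6; stop=8 now invalid
        plan = ScaffoldPlan(
            [
                SequenceEntry(
                    source="host",
                    stop=8,
                    inserts=[Insert(source="patch", open=3, close=6)],
                )
            ]
        )
        assert [i.code for i in validate_plan(plan, simple_index)] == [
            "coordinate-out-of-bounds"
        ]

    def test_issues_reported_for_all_entries(self, simple_index):
        plan = ScaffoldPlan(
            [
                SequenceEntry(source="ghost"),
                UnresolvedEntry(length=0),
                SequenceEntry(source="s1", stop=99),
            ]
        )
        issues = validate_plan(plan, simple_index)
        assert [i.entry_index for i in issues] == [0, 1, 2]

    def test_deterministic_and_order_stable(self, simple_index):
        plan = ScaffoldPlan(
            [SequenceEntry(source="ghost"), SequenceEntry(source="s1", start=9, stop=2)]
        )
        first = validate_plan(plan, simple_index)
        second = validate_plan(plan, simple_index)
        assert first == second


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(25))
    def test_parse_serialize_parse(self, seed):
        case = generate_case(seed)
        plan = parse_scaffold(case.plan_text)
        assert parse_scaffold(plan_to_yaml(plan)) == plan
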