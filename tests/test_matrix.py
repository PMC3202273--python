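"""Matrix assembly, colour binning, transposition, rendering, tables."""

import pytest

from famexmatrix.expression import CoDirectionSpec, ExpressionRecord
from famexmatrix.families import Member
from famexmatrix.matrix import (
    ColourScale,
    DEFAULT_COLOUR_SCALE,
    MISSING_EVALUE_COLOUR,
    SimilarityTable,
    assemble_matrix,
    emit_table,
    evalue_to_bin,
    parse_table,
    render_batches,
    transpose,
)


def rec(mid, org, log2, call, probes=()):
    return ExpressionRecord(Member(mid, org), log2, call, tuple(probes))


def runx_like_matrix(codirection="none"):
    """3x3 two-organism family with one clearly most-similar pair."""
    members = {
        "Hs": [Member(f"HsP{i}", "Hs") for i in range(3)],
        "Mm": [Member(f"MmP{i}", "Mm") for i in range(3)],
    }
    records = {
        "Hs": {
            "HsP0": rec("HsP0", "Hs", -1.2, "down", [("pr1", -1.2)]),
            "HsP1": rec("HsP1", "Hs", 0.9, "up"),
            "HsP2": rec("HsP2", "Hs", 0.1, "ns"),
        },
        "Mm": {
            "MmP0": rec("MmP0", "Mm", -0.8, "down"),
            "MmP1": rec("MmP1", "Mm", -0.5, "down"),
            "MmP2": rec("MmP2", "Mm", 1.4, "up"),
        },
    }
    sim = SimilarityTable()
    for h in range(3):
        for m in range(3):
            ev = 1e-120 if (h, m) == (0, 0) else 1e-40
            sim.set(f"HsP{h}", f"MmP{m}", ev)
    gene_of = lambda mem: mem.member_id[:3] + "G" + mem.member_id[-1]  # noqa: E731
    return assemble_matrix(
        "FAM1",
        members,
        records,
        sim=sim,
        codirection=CoDirectionSpec(codirection),
        gene_of=gene_of,
    )


class TestSimilarityTable:
    def test_symmetric_lookup(self):
        t = SimilarityTable()
        t.set("b", "a", 1e-5)
        assert t.get("a", "b") == 1e-5

    def test_best_evalue_wins_on_duplicates(self):
        t = SimilarityTable()
        t.set("a", "b", 1e-5)
        t.set("b", "a", 1e-9)
        assert t.get("a", "b") == 1e-9

    def test_negative_evalue_rejected(self):
        with pytest.raises(ValueError):
            SimilarityTable().set("a", "b", -1.0)


class TestEvalueBins:
    def test_zero_hits_top_bin(self):
        assert evalue_to_bin(0.0) == "violet"

    def test_above_all_bounds_hits_weakest_bin(self):
        assert evalue_to_bin(5.0) == "whitesmoke"

    def test_default_scale_mid_bin(self):
        # 1e-50 lies in the (1e-100, 1e-30] bin of the default scale
        assert evalue_to_bin(1e-50) == DEFAULT_COLOUR_SCALE.evalue_bins[1][1]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            evalue_to_bin(-1e-3)

    def test_custom_scale_must_end_with_inf(self):
        with pytest.raises(ValueError):
            ColourScale(evalue_bins=((1e-5, "red"), (1e-2, "blue")))


class TestAssemble:
    def test_most_similar_pair_gets_top_bin(self):
        m = runx_like_matrix()
        i = next(i for i, r in enumerate(m.rows) if r.member.member_id == "HsP0")
        j = next(j for j, c in enumerate(m.cols) if c.member.member_id == "MmP0")
        assert m.cells[i][j].colour == "violet"
        others = {
            m.cells[a][b].colour
            for a in range(3)
            for b in range(3)
            if (a, b) != (i, j)
        }
        assert others == {"mediumpurple"}

    def test_member_without_expression_excluded(self):
        members = {
            "Hs": [Member("HsP0", "Hs"), Member("HsP1", "Hs")],
            "Mm": [Member("MmP0", "Mm")],
        }
        records = {
            "Hs": {"HsP0": rec("HsP0", "Hs", 1.0, "up")},
            "Mm": {"MmP0": rec("MmP0", "Mm", 1.0, "up")},
        }
        m = assemble_matrix("F", members, records)
        assert [r.member.member_id for r in m.rows] == ["HsP0"]

    def test_family_without_any_expression_skipped(self):
        members = {"Hs": [Member("HsP0", "Hs")], "Mm": [Member("MmP0", "Mm")]}
        records = {"Hs": {}, "Mm": {}}
        assert assemble_matrix("F", members, records) is None

    def test_axes_sorted_by_gene_then_member(self):
        m = runx_like_matrix()
        assert [r.member.member_id for r in m.rows] == ["HsP0", "HsP1", "HsP2"]
        assert [c.gene for c in m.cols] == ["MmPG0", "MmPG1", "MmPG2"]

    def test_missing_evalue_renders_neutral(self):
        members = {"Hs": [Member("HsP0", "Hs")], "Mm": [Member("MmP0", "Mm")]}
        records = {
            "Hs": {"HsP0": rec("HsP0", "Hs", 1.0, "up")},
            "Mm": {"MmP0": rec("MmP0", "Mm", 1.0, "up")},
        }
        m = assemble_matrix("F", members, records, sim=SimilarityTable())
        assert m.cells[0][0].evalue is None
        assert m.cells[0][0].colour == MISSING_EVALUE_COLOUR

    def test_selection_flags_follow_codirection(self):
        m = runx_like_matrix("co_both")
        selected = {
            (m.rows[i].member.member_id, m.cols[j].member.member_id)
            for i in range(3)
            for j in range(3)
            if m.cells[i][j].selected
        }
        assert selected == {
            ("HsP0", "MmP0"), ("HsP0", "MmP1"), ("HsP1", "MmP2"),
        }
        assert m.selected


class TestTranspose:
    def test_involution(self):
        m = runx_like_matrix("co_both")
        assert transpose(transpose(m)) == m

    def test_cell_symmetry_and_label_swap(self):
        m = runx_like_matrix()
        t = transpose(m)
        assert t.object_labels == (m.object_labels[1], m.object_labels[0])
        for i in range(len(m.rows)):
            for j in range(len(m.cols)):
                assert t.cells[j][i] == m.cells[i][j]

    def test_ora_labels_preserved(self):
        from famexmatrix.ora import ora_family

        calls = {"Hs": {"g1": "up"}, "Mm": {"g1": "down"}}
        res = ora_family(
            "FAM1", {"Hs": {"g1"}, "Mm": {"g1"}}, calls, {"Hs": 10, "Mm": 10}
        )
        m = runx_like_matrix()
        m.ora = res
        t = transpose(m)
        assert t.ora.p_values == res.p_values


class TestRenderBatches:
    def make_many(self, n):
        return [runx_like_matrix() for _ in range(n)]

    def test_batching_of_50(self, tmp_path):
        for n, pages in [(120, 3), (50, 1), (0, 1)]:
            out = tmp_path / f"n{n}"
            paths = render_batches(self.make_many(n), out)
            assert len(paths) == pages
            total = sum(
                p.read_text(encoding="utf-8").count("<h2>Family ")
                for p in paths
            )
            assert total == n

    def test_batch_sizes_per_page(self, tmp_path):
        paths = render_batches(self.make_many(120), tmp_path / "b")
        counts = [
            p.read_text(encoding="utf-8").count("<h2>Family ") for p in paths
        ]
        assert counts == [50, 50, 20]

    def test_loss_report_in_footer(self, tmp_path):
        from famexmatrix.annotation import StageTally, tally_losses

        report = tally_losses([StageTally("s", 3, {"no_family": 1}, 2)])
        (path,) = render_batches([], tmp_path / "empty", loss_report=report)
        assert "no_family: 1" in path.read_text(encoding="utf-8")


class TestTables:
    def test_mode_all_is_cartesian(self, tmp_path):
        members = {
            "Hs": [Member(f"HsP{i}", "Hs") for i in range(2)],
            "Mm": [Member(f"MmP{i}", "Mm") for i in range(3)],
        }
        records = {
            "Hs": {f"HsP{i}": rec(f"HsP{i}", "Hs", 1.0, "up") for i in range(2)},
            "Mm": {f"MmP{i}": rec(f"MmP{i}", "Mm", 0.0, "ns") for i in range(3)},
        }
        m = assemble_matrix("F", members, records)
        rows = parse_table(emit_table([m], "all", tmp_path / "all.tsv"))
        assert len(rows) == 6

    def test_mode_significant_filters_ns(self, tmp_path):
        m = runx_like_matrix()
        rows = parse_table(emit_table([m], "significant", tmp_path / "s.tsv"))
        pairs = {(r["member1"], r["member2"]) for r in rows}
        # HsP2 is ns; every pair with it must be absent
        assert pairs == {
            ("HsP0", "MmP0"), ("HsP0", "MmP1"), ("HsP0", "MmP2"),
            ("HsP1", "MmP0"), ("HsP1", "MmP1"), ("HsP1", "MmP2"),
        }

    def test_mode_selection_empty_gives_header_only(self, tmp_path):
        members = {"Hs": [Member("HsP0", "Hs")], "Mm": [Member("MmP0", "Mm")]}
        records = {
            "Hs": {"HsP0": rec("HsP0", "Hs", 1.0, "up")},
            "Mm": {"MmP0": rec("MmP0", "Mm", 0.0, "ns")},
        }
        m = assemble_matrix(
            "F", members, records, codirection=CoDirectionSpec("co_up")
        )
        assert m.n_selected() == 0
        path = emit_table([m], "selection", tmp_path / "sel.tsv")
        lines = path.read_text(encoding="utf-8").splitlines()
        assert len(lines) == 1 and lines[0].startswith("#family_id")

    def test_roundtrip_bit_exact(self, tmp_path):
        m = runx_like_matrix()
        rows = parse_table(emit_table([m], "all", tmp_path / "rt.tsv"))
        by_pair = {(r["member1"], r["member2"]): r for r in rows}
        for i, r in enumerate(m.rows):
            for j, c in enumerate(m.cols):
                got = by_pair[(r.member.member_id, c.member.member_id)]
                assert got["log2_ratio1"] == r.log2_ratio
                assert got["log2_ratio2"] == c.log2_ratio
                assert got["evalue"] == m.cells[i][j].evalue

    def test_bad_mode_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            emit_table([], "everything", tmp_path / "x.tsv")
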