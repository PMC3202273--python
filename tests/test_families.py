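"""Family ingestion, connected-component construction, and filters."""

import random

import pytest

from famexmatrix.annotation import AnnotationGraph
from famexmatrix.families import (
    FamilyFilterSpec,
    FamilySet,
    Member,
    OrthologRelationSet,
    apply_family_filter,
    attach_star_mirnas,
    build_families_from_relations,
    derive_paralog_subset,
    load_preclustered,
    load_relations,
)
from _oracles import brute_force_components


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


def m(mid, org="Hs", fc="protein"):
    return Member(mid, org, fc)


class TestLoadPreclustered:
    def test_basic_parse(self, tmp_path):
        p = write(
            tmp_path,
            "fam.tsv",
            "# comment\nmember_id\torganism\tfamily_id\n"
            "P1\tHs\tFA\nP2\tHs\tFA\nP3\tMm\tFB\n",
        )
        fs = load_preclustered(p, "test")
        assert len(fs) == 2
        assert fs.n_members() == 3
        assert fs.families["FA"] == {m("P1"), m("P2")}
        assert fs.organisms == ("Hs", "Mm")

    def test_duplicate_member_in_two_families_errors(self, tmp_path):
        p = write(tmp_path, "fam.tsv", "P1\tHs\tFA\nP1\tHs\tFB\n")
        with pytest.raises(ValueError, match="P1"):
            load_preclustered(p, "test")

    def test_empty_file(self, tmp_path):
        fs = load_preclustered(write(tmp_path, "fam.tsv", ""), "test")
        assert len(fs) == 0

    def test_unknown_organism_errors(self, tmp_path):
        p = write(tmp_path, "fam.tsv", "P1\tXx\tFA\n")
        with pytest.raises(ValueError, match="Xx"):
            load_preclustered(p, "test")


class TestBuildFromRelations:
    def test_shared_partner_merges_into_one_family(self):
        rel = OrthologRelationSet()
        rel.add(m("a1"), m("b1", "Mm"))
        rel.add(m("a2"), m("b1", "Mm"), direction="reciprocal")
        fs = build_families_from_relations(rel, "FAM")
        assert len(fs) == 1
        (members,) = fs.families.values()
        assert {x.member_id for x in members} == {"a1", "a2", "b1"}
        assert fs.approach_granularity == "pairwise_derived"

    def test_disjoint_pairs_stay_separate(self):
        rel = OrthologRelationSet()
        rel.add(m("a1"), m("b1", "Mm"))
        rel.add(m("a2"), m("b2", "Mm"))
        fs = build_families_from_relations(rel, "FAM")
        assert sorted(len(ms) for ms in fs.families.values()) == [2, 2]

    def test_empty_relations(self):
        fs = build_families_from_relations(OrthologRelationSet(), "FAM")
        assert len(fs) == 0

    def test_self_pair_rejected(self):
        rel = OrthologRelationSet()
        with pytest.raises(ValueError, match="self-pair"):
            rel.add(m("a1"), m("a1"))

    def test_forward_and_reciprocal_merge_to_both(self):
        rel = OrthologRelationSet()
        rel.add(m("a1"), m("b1", "Mm"), "forward")
        rel.add(m("b1", "Mm"), m("a1"), "reciprocal")
        assert len(rel) == 1
        assert list(rel.direction_tags.values()) == ["both"]

    def test_matches_bruteforce_closure_on_random_graphs(self):
        rng = random.Random(1234)
        for _ in range(200):
            n_nodes = rng.randint(2, 30)
            nodes = [f"n{i:02d}" for i in range(n_nodes)]
            pairs = set()
            for _ in range(rng.randint(1, 2 * n_nodes)):
                a, b = rng.sample(nodes, 2)
                pairs.add((a, b))
            rel = OrthologRelationSet()
            for a, b in sorted(pairs):
                rel.add(m(a), m(b))
            fs = build_families_from_relations(rel, "F")
            got = {
                frozenset(x.member_id for x in ms)
                for ms in fs.families.values()
            }
            assert got == brute_force_components(sorted(pairs))

    def test_numbering_byte_stable_under_row_shuffle(self, tmp_path):
        rows = [
            ("a3", "Hs", "b1", "Mm"),
            ("a1", "Hs", "b2", "Mm"),
            ("a2", "Hs", "b2", "Mm"),
            ("c1", "Hs", "d1", "Mm"),
        ]
        texts = []
        rng = random.Random(5)
        for i in range(4):
            shuffled = rows[:]
            rng.shuffle(shuffled)
            p = write(
                tmp_path,
                f"rel{i}.tsv",
                "".join("\t".join(r) + "\n" for r in shuffled),
            )
            fs = build_families_from_relations(load_relations(p), "FAM")
            texts.append(fs.to_table_text())
        assert len(set(texts)) == 1
        assert "FAM000001" in texts[0]

    def test_partition_property(self):
        rng = random.Random(99)
        nodes = [f"n{i}" for i in range(25)]
        rel = OrthologRelationSet()
        pairs = set()
        while len(pairs) < 30:
            a, b = rng.sample(nodes, 2)
            pairs.add((a, b))
        for a, b in sorted(pairs):
            rel.add(m(a), m(b))
        fs = build_families_from_relations(rel, "F")
        all_members = [x for ms in fs.families.values() for x in ms]
        # union covers every related node exactly once (disjointness)
        assert len(all_members) == len(set(all_members))
        assert {x.member_id for x in all_members} == {
            x for p in pairs for x in p
        }


class TestParalogSubset:
    def make_fs(self):
        return FamilySet(
            "t",
            "pre_clustered",
            {
                "FA": frozenset({m("h1"), m("h2"), m("m1", "Mm")}),
                "FB": frozenset({m("m2", "Mm")}),
            },
            ("Hs", "Mm"),
        )

    def test_subset_keeps_own_organism_only(self):
        sub = derive_paralog_subset(self.make_fs(), "Hs")
        assert set(sub.families) == {"FA"}
        assert sub.families["FA"] == {m("h1"), m("h2")}
        assert sub.organisms == ("Hs",)

    def test_emptied_family_dropped_singleton_flagged(self):
        sub = derive_paralog_subset(self.make_fs(), "Mm")
        assert set(sub.families) == {"FA", "FB"}
        assert sub.singleton_flags == {"FA": True, "FB": True}

    def test_uncovered_organism_errors(self):
        with pytest.raises(ValueError, match="not covered"):
            derive_paralog_subset(self.make_fs(), "Sc")

    def test_bruteforce_filter_on_mixed_families(self):
        fs = FamilySet(
            "t",
            "pre_clustered",
            {
                f"F{i}": frozenset(
                    {m(f"h{i}a"), m(f"h{i}b"), m(f"m{i}", "Mm")}
                    if i % 2
                    else {m(f"m{i}", "Mm")}
                )
                for i in range(5)
            },
            ("Hs", "Mm"),
        )
        sub = derive_paralog_subset(fs, "Hs")
        expected = {
            fid: {x for x in ms if x.organism == "Hs"}
            for fid, ms in fs.families.items()
            if any(x.organism == "Hs" for x in ms)
        }
        assert {fid: set(ms) for fid, ms in sub.families.items()} == expected


class TestFamilyFilter:
    def two_isoform_family(self):
        # two proteins (splicing isoforms) of ONE human gene
        fs = FamilySet(
            "t",
            "pre_clustered",
            {"FA": frozenset({m("P1"), m("P2")})},
            ("Hs",),
        )
        graph = AnnotationGraph(
            organism="Hs",
            transcript_to_protein={"T1": "P1", "T2": "P2"},
            transcript_to_gene={"T1": "G1", "T2": "G1"},
        )
        return fs, {"Hs": graph}

    def test_multi_gene_excludes_single_gene_isoform_family(self):
        fs, annot = self.two_isoform_family()
        spec = FamilyFilterSpec(exclude_singletons=True, mode="multi_gene")
        assert len(apply_family_filter(fs, spec, annot)) == 0

    def test_multi_protein_keeps_isoform_family(self):
        fs, annot = self.two_isoform_family()
        spec = FamilyFilterSpec(exclude_singletons=True, mode="multi_protein")
        assert set(apply_family_filter(fs, spec, annot).families) == {"FA"}

    def test_multi_gene_without_mapping_errors(self):
        fs, _ = self.two_isoform_family()
        spec = FamilyFilterSpec(exclude_singletons=True, mode="multi_gene")
        with pytest.raises(ValueError, match="gene mapping"):
            apply_family_filter(fs, spec, None)

    def test_all_none_is_identity(self):
        fs, _ = self.two_isoform_family()
        out = apply_family_filter(fs, FamilyFilterSpec())
        assert out.families == fs.families

    def test_restrict_gene_ids_keeps_full_families_only(self):
        fs, annot = self.two_isoform_family()
        fs.families["FB"] = frozenset({m("P9")})
        spec = FamilyFilterSpec(restrict_gene_ids=("G1",))
        out = apply_family_filter(fs, spec, annot)
        # whole family of the matching gene, nothing else
        assert set(out.families) == {"FA"}
        assert out.families["FA"] == fs.families["FA"]

    def test_filter_never_adds_members(self, small_bundle):
        from famexmatrix.families import load_preclustered as load

        fs = load(small_bundle.paths["families"], "synthetic")
        out = apply_family_filter(
            fs, FamilyFilterSpec(exclude_singletons=True, mode="multi_protein")
        )
        for fid, ms in out.families.items():
            assert ms == fs.families[fid]


class TestStarMirnas:
    def mirna_fs(self):
        return FamilySet(
            "mir",
            "pre_clustered",
            {"MF1": frozenset({m("miR-1", fc="mature_mirna")})},
            ("Hs",),
        )

    def test_include_adds_star_to_partner_family(self):
        fs = attach_star_mirnas(self.mirna_fs(), {"miR-1": "miR-1*"}, "include")
        assert {x.member_id for x in fs.families["MF1"]} == {"miR-1", "miR-1*"}

    def test_ignore_returns_unchanged(self):
        fs0 = self.mirna_fs()
        fs = attach_star_mirnas(fs0, {"miR-1": "miR-1*"}, "ignore")
        assert fs.families == fs0.families

    def test_empty_star_map_identity(self):
        fs0 = self.mirna_fs()
        assert attach_star_mirnas(fs0, {}, "include").families == fs0.families

    def test_star_in_other_family_violates_disjointness(self):
        fs = FamilySet(
            "mir",
            "pre_clustered",
            {
                "MF1": frozenset({m("miR-1", fc="mature_mirna")}),
                "MF2": frozenset({m("miR-1*", fc="mature_mirna")}),
            },
            ("Hs",),
        )
        with pytest.raises(ValueError, match="disjoint|already belongs"):
            attach_star_mirnas(fs, {"miR-1": "miR-1*"}, "include")

    def test_protein_family_set_rejected(self):
        fs = FamilySet(
            "t", "pre_clustered", {"FA": frozenset({m("P1")})}, ("Hs",)
        )
        with pytest.raises(ValueError, match="mature_mirna"):
            attach_star_mirnas(fs, {"a": "b"}, "include")
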