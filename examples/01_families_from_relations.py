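"""Derive gene families from a pairwise ortholog relation list.

Pairwise resources report ortholog relations per query direction but no
family identifiers.  Merging forward and reciprocal relations and taking
connected components yields disjoint families with a deterministic numbering.
"""

from famexmatrix import Member, OrthologRelationSet, build_families_from_relations

rel = OrthologRelationSet()
# forward queries (human -> mouse) ...
rel.add(Member("HsRUNX1", "Hs"), Member("MmRunx1", "Mm"), "forward")
rel.add(Member("HsRUNX2", "Hs"), Member("MmRunx1", "Mm"), "forward")
rel.add(Member("HsPIK3CD", "Hs"), Member("MmPik3cd", "Mm"), "forward")
# ... and reciprocal ones (mouse -> human); duplicates merge to "both"
rel.add(Member("MmRunx1", "Mm"), Member("HsRUNX1", "Hs"), "reciprocal")
rel.add(Member("MmRunx3", "Mm"), Member("HsRUNX1", "Hs"), "reciprocal")

families = build_families_from_relations(rel, "FAM")
for fid, members in families.families.items():
    ids = sorted(m.member_id for m in members)
    print(f"{fid}: {', '.join(ids)}")

# Two families: the RUNX-like members form one connected component (RUNX2 and
# Runx3 join through their shared partner RUNX1), the PIK3CD pair another.
# Numbering follows the lexicographically smallest member of each component,
# so shuffled input rows give byte-identical results.
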