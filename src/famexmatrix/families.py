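"""Gene and microRNA family sets.

A *family* is a disjoint cluster of member identifiers (Ensembl protein IDs or
mature microRNA IDs) produced by one of the established family-inference
approaches.  Two kinds of association input are supported:

* pre-clustered member -> family-ID tables (SYSTERS, Ensembl Family,
  InParanoid, miRBase, TargetScan style), loaded verbatim with the original
  family identifiers conserved; and
* pairwise ortholog/paralog relation lists (EnsemblCompara style), from which
  families are derived as connected components of the relation graph, merging
  forward and reciprocal query directions, with a deterministic default
  numbering.

Filters mirror the display restrictions of the original web tool: singleton
exclusion at multi-gene or multi-protein granularity, restriction to explicit
family IDs, and restriction to the full families of a gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx

from .registry import check_organism

FEATURE_CLASSES = ("protein", "mature_mirna")

PRE_CLUSTERED = "pre_clustered"
PAIRWISE_DERIVED = "pairwise_derived"

#: Canonical header of a pre-clustered family file (skipped if present).
FAMILY_FILE_HEADER = ("member_id", "organism", "family_id")
RELATION_FILE_HEADER = ("member_a", "organism_a", "member_b", "organism_b")


@dataclass(frozen=True, order=True)
class Member:
    """One family member: a protein (or gene, for gene-keyed approaches) or a
    mature microRNA, belonging to exactly one organism."""

    member_id: str
    organism: str
    feature_class: str = "protein"

    def __post_init__(self) -> None:
        if not self.member_id:
            raise ValueError("member_id must be non-empty")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature_class must be one of {FEATURE_CLASSES}, "
                f"got {self.feature_class!r}"
            )


@dataclass
class FamilySet:
    """A disjoint partition of members into identified families.

    ``families`` maps family_id -> frozenset of :class:`Member`.  Disjointness
    (each member_id in at most one family) and non-emptiness are enforced at
    construction.  ``singleton_flags`` marks families consisting of a single
    member after a paralog subset; the exclude-singletons filter, not the
    loader, controls their visibility.
    """

    approach_name: str
    approach_granularity: str
    families: dict[str, frozenset[Member]]
    organisms: tuple[str, ...]
    singleton_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.approach_granularity not in (PRE_CLUSTERED, PAIRWISE_DERIVED):
            raise ValueError(
                f"approach_granularity must be {PRE_CLUSTERED!r} or "
                f"{PAIRWISE_DERIVED!r}"
            )
        self.validate()

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for fid, members in self.families.items():
            if not members:
                raise ValueError(f"family {fid!r} is empty")
            for m in members:
                other = seen.get(m.member_id)
                if other is not None and other != fid:
                    raise ValueError(
                        f"member {m.member_id!r} appears in families "
                        f"{other!r} and {fid!r}; families must be disjoint"
                    )
                seen[m.member_id] = fid

    # -- convenience accessors -------------------------------------------------

    def member_index(self) -> dict[str, str]:
        """member_id -> family_id."""
        return {
            m.member_id: fid for fid, ms in self.families.items() for m in ms
        }

    def all_members(self) -> set[Member]:
        return {m for ms in self.families.values() for m in ms}

    def n_members(self) -> int:
        return sum(len(ms) for ms in self.families.values())

    def __len__(self) -> int:
        return len(self.families)

    def to_table_text(self) -> str:
        """Canonical tab-delimited serialization (sorted); used both for
        export and for byte-stability checks."""
        lines = ["#" + "\t".join(FAMILY_FILE_HEADER)]
        for fid in sorted(self.families):
            for m in sorted(self.families[fid]):
                lines.append(f"{m.member_id}\t{m.organism}\t{fid}")
        return "\n".join(lines) + "\n"


@dataclass
class OrthologRelationSet:
    """De-duplicated unordered member pairs from pairwise ortholog queries.

    ``direction_tags`` records whether each pair was seen in the forward
    query direction, the reciprocal one, or both.  Self-pairs are rejected.
    """

    relations: set[frozenset[Member]] = field(default_factory=set)
    direction_tags: dict[frozenset[Member], str] = field(default_factory=dict)

    def add(self, a: Member, b: Member, direction: str = "forward") -> None:
        if direction not in ("forward", "reciprocal"):
            raise ValueError(f"bad direction {direction!r}")
        if a.member_id == b.member_id:
            raise ValueError(f"self-pair for member {a.member_id!r}")
        pair = frozenset((a, b))
        if pair in self.relations:
            if self.direction_tags[pair] != direction:
                self.direction_tags[pair] = "both"
        else:
            self.relations.add(pair)
            self.direction_tags[pair] = direction

    def __len__(self) -> int:
        return len(self.relations)


@dataclass(frozen=True)
class FamilyFilterSpec:
    """Display restriction switches.

    ``exclude_singletons`` activates the singleton filter; ``mode`` selects
    its granularity: ``multi_gene`` keeps families where at least one organism
    contributes two or more distinct genes (paralogous genes), ``multi_protein``
    keeps families with two or more members (splicing isoforms count) for at
    least one organism, ``none`` drops only size-1 families.  ``restrict_*``
    lists reduce the output to explicit families, expanding gene IDs to their
    full families.
    """

    exclude_singletons: bool = False
    mode: str = "none"
    restrict_family_ids: tuple[str, ...] | None = None
    restrict_gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "multi_gene", "multi_protein"):
            raise ValueError(f"bad filter mode {self.mode!r}")
        for name in ("restrict_family_ids", "restrict_gene_ids"):
            val = getattr(self, name)
            if val is not None and len(val) == 0:
                raise ValueError(f"{name} must be non-empty when given")


# -- file parsing helpers ------------------------------------------------------


def _read_tsv(path: str | Path, n_cols: int, header: tuple[str, ...]):
    """Yield stripped field tuples from a tab-delimited file, skipping blank
    lines, '#' comments, and an optional header row matching ``header``."""
    first = True
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = tuple(f.strip() for f in line.split("\t"))
            if first and tuple(f.lower() for f in fields) == header:
                first = False
                continue
            first = False
            if len(fields) < n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} tab-delimited "
                    f"columns, got {len(fields)}"
                )
            yield fields[:n_cols]


# -- loading and construction --------------------------------------------------


def load_preclustered(
    path: str | Path,
    approach_name: str,
    feature_class: str = "protein",
    registry: Mapping[str, str] | None = None,
) -> FamilySet:
    """Load a pre-clustered family file (member_id, organism, family_id),
    conserving the original family identifiers.

    A member listed under two different family IDs violates disjointness and
    raises; unknown organism codes raise.  An empty file yields an empty
    FamilySet.
    """
    families: dict[str, set[Member]] = {}
    for member_id, organism, family_id in _read_tsv(path, 3, FAMILY_FILE_HEADER):
        check_organism(organism, registry)
        m = Member(member_id, organism, feature_class)
        families.setdefault(family_id, set()).add(m)
    frozen = {fid: frozenset(ms) for fid, ms in sorted(families.items())}
    organisms = tuple(sorted({m.organism for ms in frozen.values() for m in ms}))
    return FamilySet(approach_name, PRE_CLUSTERED, frozen, organisms)


def load_relations(
    path: str | Path,
    feature_class: str = "protein",
    registry: Mapping[str, str] | None = None,
    direction: str = "forward",
) -> OrthologRelationSet:
    """Load a 4-column pairwise relation file
    (member_a, organism_a, member_b, organism_b)."""
    rel = OrthologRelationSet()
    for ma, oa, mb, ob in _read_tsv(path, 4, RELATION_FILE_HEADER):
        check_organism(oa, registry)
        check_organism(ob, registry)
        rel.add(
            Member(ma, oa, feature_class),
            Member(mb, ob, feature_class),
            direction,
        )
    return rel


def build_families_from_relations(
    rel: OrthologRelationSet, id_prefix: str
) -> FamilySet:
    """Derive families as connected components of the pairwise relation graph.

    Relations of both query directions are merged into one undirected graph;
    each connected component becomes one family.  Family IDs are the prefix
    followed by a zero-padded sequential integer, assigned in lexicographic
    order of each component's smallest member_id, so identical relation sets
    yield byte-identical family sets regardless of input row order.
    """
    graph: nx.Graph = nx.Graph()
    for pair in rel.relations:
        a, b = tuple(pair)
        graph.add_edge(a, b)
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(graph)),
        key=lambda comp: comp[0].member_id,
    )
    families = {
        f"{id_prefix}{i:06d}": frozenset(comp)
        for i, comp in enumerate(components, start=1)
    }
    organisms = tuple(
        sorted({m.organism for ms in families.values() for m in ms})
    )
    return FamilySet(id_prefix, PAIRWISE_DERIVED, families, organisms)


def derive_paralog_subset(fs: FamilySet, organism: str) -> FamilySet:
    """Restrict each family to the members of one organism (its paralogs).

    Families emptied by the restriction are dropped; families reduced to a
    single member are retained but flagged singleton, so the singleton filter
    (not this subset) decides their visibility.
    """
    if organism not in fs.organisms:
        raise ValueError(
            f"organism {organism!r} not covered by family set "
            f"{fs.approach_name!r} (covers {fs.organisms})"
        )
    families: dict[str, frozenset[Member]] = {}
    flags: dict[str, bool] = {}
    for fid in sorted(fs.families):
        sub = frozenset(m for m in fs.families[fid] if m.organism == organism)
        if not sub:
            continue
        families[fid] = sub
        flags[fid] = len(sub) == 1
    return FamilySet(
        f"{fs.approach_name}.{organism}.paralogs",
        fs.approach_granularity,
        families,
        (organism,),
        flags,
    )


def _gene_of_member(m: Member, annot) -> str:
    """Map a member to its gene through an annotation graph (or a mapping of
    organism -> graph).  Members without a recorded gene fall back to their
    own identifier; mature microRNAs are their own gene unit."""
    if m.feature_class == "mature_mirna" or annot is None:
        return m.member_id
    graph = annot.get(m.organism) if isinstance(annot, Mapping) else annot
    if graph is None:
        return m.member_id
    return graph.protein_to_gene.get(m.member_id, m.member_id)


def apply_family_filter(
    fs: FamilySet, spec: FamilyFilterSpec, annot=None
) -> FamilySet:
    """Apply display restrictions; never adds members or alters families.

    ``restrict_gene_ids`` keeps the *full* family of any member whose gene is
    listed.  ``multi_gene`` requires an annotation graph to resolve members to
    genes and raises without one.
    """
    fams = {fid: fs.families[fid] for fid in sorted(fs.families)}
    if spec.restrict_family_ids is not None:
        wanted = set(spec.restrict_family_ids)
        fams = {fid: ms for fid, ms in fams.items() if fid in wanted}
    if spec.restrict_gene_ids is not None:
        genes = set(spec.restrict_gene_ids)
        fams = {
            fid: ms
            for fid, ms in fams.items()
            if any(_gene_of_member(m, annot) in genes for m in ms)
        }
    if spec.exclude_singletons:
        if spec.mode == "multi_gene":
            if annot is None:
                raise ValueError(
                    "multi_gene singleton filter requires a gene mapping "
                    "(annotation graph)"
                )
            kept = {}
            for fid, ms in fams.items():
                per_org: dict[str, set[str]] = {}
                for m in ms:
                    per_org.setdefault(m.organism, set()).add(
                        _gene_of_member(m, annot)
                    )
                if any(len(g) >= 2 for g in per_org.values()):
                    kept[fid] = ms
            fams = kept
        elif spec.mode == "multi_protein":
            kept = {}
            for fid, ms in fams.items():
                per_org: dict[str, int] = {}
                for m in ms:
                    per_org[m.organism] = per_org.get(m.organism, 0) + 1
                if any(n >= 2 for n in per_org.values()):
                    kept[fid] = ms
            fams = kept
        else:  # plain size-1 exclusion
            fams = {
                fid: ms
                for fid, ms in fams.items()
                if len(ms) >= 2 and not fs.singleton_flags.get(fid, False)
            }
    flags = {fid: fs.singleton_flags[fid] for fid in fams if fid in fs.singleton_flags}
    return FamilySet(
        fs.approach_name, fs.approach_granularity, fams, fs.organisms, flags
    )


def load_star_map(path: str | Path) -> dict[str, str]:
    """Load a 2-column mature -> star microRNA map."""
    out: dict[str, str] = {}
    for mature, star in _read_tsv(path, 2, ("mature_id", "star_id")):
        out[mature] = star
    return out


def attach_star_mirnas(
    fs: FamilySet, star_map: Mapping[str, str], policy: str = "include"
) -> FamilySet:
    """Add star microRNAs to their mature partner's family (miRBase-style
    sets) or ignore them (TargetScan-style sets).

    ``policy='include'`` inserts each star ID into the family of its mature
    partner; a star ID already present in a *different* family violates
    disjointness and raises.  ``policy='ignore'`` returns the set unchanged.
    """
    if policy not in ("include", "ignore"):
        raise ValueError(f"bad star policy {policy!r}")
    if any(
        m.feature_class != "mature_mirna"
        for ms in fs.families.values()
        for m in ms
    ):
        raise ValueError("star microRNAs apply only to mature_mirna family sets")
    if policy == "ignore" or not star_map:
        return fs
    index = fs.member_index()
    fams = {fid: set(ms) for fid, ms in fs.families.items()}
    for mature in sorted(star_map):
        star = star_map[mature]
        fid = index.get(mature)
        if fid is None:
            continue
        star_fid = index.get(star)
        if star_fid is not None and star_fid != fid:
            raise ValueError(
                f"star microRNA {star!r} already belongs to family "
                f"{star_fid!r}, cannot add to {fid!r}"
            )
        organism = next(
            m.organism for m in fams[fid] if m.member_id == mature
        )
        fams[fid].add(Member(star, organism, "mature_mirna"))
        index[star] = fid
    frozen = {fid: frozenset(ms) for fid, ms in sorted(fams.items())}
    return FamilySet(
        fs.approach_name,
        fs.approach_granularity,
        frozen,
        fs.organisms,
        dict(fs.singleton_flags),
    )
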