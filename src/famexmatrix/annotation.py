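"""Probe-set -> transcript -> protein -> gene annotation cascade.

Expression features arrive at one of five levels (probe set, gene, transcript,
protein, mature microRNA) and are resolved to family members through an
annotation graph.  Resolution follows two rules of the original engine:

* ambiguity is retained, never resolved — a probe mapping to several
  transcripts contributes to all downstream members and is flagged ambiguous;
* nothing is dropped silently — every feature that resolves to no member is
  attributed to exactly one loss category, and per-stage tallies satisfy the
  conservation invariant input = surviving + sum(losses).

Transcripts and proteins stand in a 1-to-1 correlation; a transcript mapped to
two proteins is a hard error at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .families import Member, _read_tsv
from .registry import check_organism

# Loss categories.  The first four mirror the engine's data-loss report;
# UNRESOLVED covers input records that map to no known feature at all, and
# NONPOSITIVE covers expression values unusable for ratio computation.
NO_FAMILY = "no_family"
NON_CODING = "non_coding_transcript"
NOT_COVERED = "gene_not_covered"
NOT_SIGNIFICANT = "failed_significance"
UNRESOLVED = "unresolvable"
NONPOSITIVE = "nonpositive_value"

INPUT_LEVELS = ("probe_set", "gene", "transcript", "protein", "mirna")

LAYER_HEADERS = {
    "probe_to_transcript": ("probe_id", "transcript_id"),
    "transcript_to_protein": ("transcript_id", "protein_id"),
    "transcript_to_gene": ("transcript_id", "gene_id"),
}


@dataclass
class AnnotationGraph:
    """Annotation layers for one organism.

    ``probe_to_transcript`` is many-to-many (microarray probe designs are
    fixed while transcript catalogues grow); ``transcript_to_protein`` is 1:1
    where present (non-protein-coding transcripts are simply absent);
    ``transcript_to_gene`` is many-to-one.  ``protein_to_gene`` is derived by
    composition.
    """

    organism: str
    probe_to_transcript: dict[str, frozenset[str]] = field(default_factory=dict)
    transcript_to_protein: dict[str, str] = field(default_factory=dict)
    transcript_to_gene: dict[str, str] = field(default_factory=dict)
    protein_to_gene: dict[str, str] = field(default_factory=dict)
    gene_to_transcripts: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # 1:1 check in the protein->transcript direction.
        rev: dict[str, str] = {}
        for t, p in self.transcript_to_protein.items():
            if p in rev and rev[p] != t:
                raise ValueError(
                    f"protein {p!r} mapped from transcripts {rev[p]!r} and "
                    f"{t!r}; transcript/protein correlation must be 1-to-1"
                )
            rev[p] = t
        if not self.protein_to_gene:
            self.protein_to_gene = {
                p: self.transcript_to_gene[t]
                for t, p in self.transcript_to_protein.items()
                if t in self.transcript_to_gene
            }
        if not self.gene_to_transcripts:
            g2t: dict[str, set[str]] = {}
            for t, g in self.transcript_to_gene.items():
                g2t.setdefault(g, set()).add(t)
            self.gene_to_transcripts = {
                g: frozenset(ts) for g, ts in g2t.items()
            }

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_transcripts)

    @property
    def proteins(self) -> set[str]:
        return set(self.protein_to_gene)

    @property
    def probes(self) -> set[str]:
        return set(self.probe_to_transcript)


def load_annotation(
    paths: Mapping[str, str | Path],
    organism: str,
    registry: Mapping[str, str] | None = None,
) -> AnnotationGraph:
    """Build an :class:`AnnotationGraph` from 2-column tab-delimited layer
    files keyed by layer name (``probe_to_transcript``,
    ``transcript_to_protein``, ``transcript_to_gene``).

    Layers may be omitted (e.g. no protein layer for microRNA or gene-level
    use).  A transcript listed with two different proteins raises.
    """
    check_organism(organism, registry)
    unknown = set(paths) - set(LAYER_HEADERS)
    if unknown:
        raise ValueError(f"unknown annotation layers: {sorted(unknown)}")

    p2t: dict[str, set[str]] = {}
    if "probe_to_transcript" in paths:
        for probe, transcript in _read_tsv(
            paths["probe_to_transcript"], 2, LAYER_HEADERS["probe_to_transcript"]
        ):
            p2t.setdefault(probe, set()).add(transcript)

    t2p: dict[str, str] = {}
    if "transcript_to_protein" in paths:
        for transcript, protein in _read_tsv(
            paths["transcript_to_protein"],
            2,
            LAYER_HEADERS["transcript_to_protein"],
        ):
            if transcript in t2p and t2p[transcript] != protein:
                raise ValueError(
                    f"transcript {transcript!r} mapped to proteins "
                    f"{t2p[transcript]!r} and {protein!r}; the transcript/"
                    f"protein correlation must be 1-to-1"
                )
            t2p[transcript] = protein

    t2g: dict[str, str] = {}
    if "transcript_to_gene" in paths:
        for transcript, gene in _read_tsv(
            paths["transcript_to_gene"], 2, LAYER_HEADERS["transcript_to_gene"]
        ):
            if transcript in t2g and t2g[transcript] != gene:
                raise ValueError(
                    f"transcript {transcript!r} mapped to genes "
                    f"{t2g[transcript]!r} and {gene!r}"
                )
            t2g[transcript] = gene

    return AnnotationGraph(
        organism=organism,
        probe_to_transcript={p: frozenset(ts) for p, ts in p2t.items()},
        transcript_to_protein=t2p,
        transcript_to_gene=t2g,
    )


@dataclass(frozen=True)
class ResolvedFeature:
    """Resolution of one input feature to family members.

    ``resolved_members`` may be empty — the feature is then reportable under
    ``empty_reason`` ('unmapped' or 'non_coding'), never silently discarded.
    ``ambiguous`` is set when any mapping hop fans out to more than one
    target.
    """

    input_id: str
    input_level: str
    resolved_members: frozenset[Member]
    ambiguous: bool
    empty_reason: str | None = None


def resolve_features(
    ids: Sequence[str],
    level: str,
    graph: AnnotationGraph | None,
    organism: str | None = None,
) -> list[ResolvedFeature]:
    """Resolve input identifiers to members at the family namespace.

    Probe sets walk probe -> transcript(s) -> protein(s); genes fan out to
    all their coding isoforms; transcripts hop to their single protein;
    proteins are members themselves; mature microRNA IDs are terminal members
    with no transcript hop.  When ``graph`` is None, identifiers are treated
    as terminal members of ``organism`` (gene-keyed or microRNA analyses).

    Input IDs are whitespace-trimmed and case-sensitive.  No failure raises:
    unresolvable features come back with an empty member set and a reason.
    """
    if level not in INPUT_LEVELS:
        raise ValueError(f"bad input level {level!r}; expected {INPUT_LEVELS}")
    org = organism or (graph.organism if graph is not None else None)
    if org is None:
        raise ValueError("organism required when no annotation graph is given")
    feature_class = "mature_mirna" if level == "mirna" else "protein"

    out: list[ResolvedFeature] = []
    for raw in ids:
        fid = raw.strip()
        members: set[Member] = set()
        ambiguous = False
        reason: str | None = None
        if level == "mirna" or graph is None:
            members = {Member(fid, org, feature_class)}
        elif level == "probe_set":
            transcripts = graph.probe_to_transcript.get(fid, frozenset())
            if not transcripts:
                reason = "unmapped"
            else:
                proteins = {
                    graph.transcript_to_protein[t]
                    for t in transcripts
                    if t in graph.transcript_to_protein
                }
                ambiguous = len(transcripts) > 1 or len(proteins) > 1
                if not proteins:
                    reason = "non_coding"
                members = {Member(p, org) for p in proteins}
        elif level == "gene":
            transcripts = graph.gene_to_transcripts.get(fid)
            if transcripts is None:
                reason = "unmapped"
            else:
                proteins = {
                    graph.transcript_to_protein[t]
                    for t in transcripts
                    if t in graph.transcript_to_protein
                }
                ambiguous = len(proteins) > 1
                if not proteins:
                    reason = "non_coding"
                members = {Member(p, org) for p in proteins}
        elif level == "transcript":
            if fid in graph.transcript_to_protein:
                members = {Member(graph.transcript_to_protein[fid], org)}
            elif fid in graph.transcript_to_gene:
                reason = "non_coding"
            else:
                reason = "unmapped"
        else:  # protein
            if fid in graph.protein_to_gene:
                members = {Member(fid, org)}
            else:
                reason = "unmapped"
        out.append(
            ResolvedFeature(fid, level, frozenset(members), ambiguous, reason)
        )
    return out


# -- standalone identifier conversion -------------------------------------------


@dataclass
class MappedIds:
    """Result of a namespace conversion: translated IDs in input order, plus
    the IDs dropped because their translation was absent or conflicting."""

    translated: list[str]
    dropped: list[str]


def load_identifier_map(path: str | Path) -> dict[str, set[str]]:
    """Load a 2-column source -> target identifier map (targets accumulate,
    so conflicting rows are visible to the conversion policy)."""
    table: dict[str, set[str]] = {}
    for src, dst in _read_tsv(path, 2, ("source_id", "target_id")):
        table.setdefault(src, set()).add(dst)
    return table


def apply_identifier_map(
    ids: Sequence[str],
    map_table: Mapping[str, set[str] | str],
    conflict_policy: str = "drop_conflicts",
) -> MappedIds:
    """Convert identifiers between namespaces (e.g. UniProt -> Ensembl).

    An ID whose translation lands in more than one target — typically a
    fragmentary sequence associated with multiple genes — would break family
    disjointness, so it is dropped and counted rather than guessed.
    """
    if conflict_policy != "drop_conflicts":
        raise ValueError(f"unknown conflict policy {conflict_policy!r}")
    translated: list[str] = []
    dropped: list[str] = []
    for i in ids:
        targets = map_table.get(i)
        if isinstance(targets, str):
            targets = {targets}
        if targets and len(targets) == 1:
            translated.append(next(iter(targets)))
        else:
            dropped.append(i)
    return MappedIds(translated, dropped)


# -- data-loss accounting --------------------------------------------------------


@dataclass
class StageTally:
    """Record accounting for one pipeline stage: every input record is either
    surviving or attributed to exactly one loss category."""

    stage: str
    n_input: int
    losses: dict[str, int]
    n_surviving: int

    def check(self) -> None:
        total = self.n_surviving + sum(self.losses.values())
        if total != self.n_input:
            raise ValueError(
                f"stage {self.stage!r}: {self.n_input} input records but "
                f"{self.n_surviving} surviving + {sum(self.losses.values())} "
                f"lost = {total}"
            )


@dataclass
class LossReport:
    """Per-stage data-loss report, appended to every run's output."""

    stages: list[StageTally]

    def totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for st in self.stages:
            for cat, n in st.losses.items():
                out[cat] = out.get(cat, 0) + n
        return out

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage": st.stage,
                    "input": st.n_input,
                    "surviving": st.n_surviving,
                    "losses": dict(sorted(st.losses.items())),
                }
                for st in self.stages
            ],
            "totals": dict(sorted(self.totals().items())),
        }

    def to_text(self) -> str:
        lines = ["Data loss report", "================"]
        for st in self.stages:
            lines.append(
                f"{st.stage}: {st.n_input} in, {st.n_surviving} surviving"
            )
            for cat in sorted(st.losses):
                if st.losses[cat]:
                    lines.append(f"  - {cat}: {st.losses[cat]}")
        lines.append("totals:")
        for cat, n in sorted(self.totals().items()):
            lines.append(f"  - {cat}: {n}")
        return "\n".join(lines) + "\n"


def tally_losses(stages: Iterable[StageTally]) -> LossReport:
    """Assemble and validate a loss report; raises if any stage breaks the
    conservation invariant."""
    stages = list(stages)
    for st in stages:
        st.check()
    return LossReport(stages)
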