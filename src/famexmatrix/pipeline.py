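"""Run configuration and pipeline orchestration.

``run_pipeline`` wires the stages together in order: annotation loading ->
family ingestion/construction and filtering -> expression normalization and
feature resolution -> per-family four-way over-representation analysis ->
matrix assembly, HTML batches, relation tables and the data-loss report.
Record counts are logged at every stage and always reconciled: input records =
surviving + sum of loss categories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .annotation import (
    NO_FAMILY,
    NON_CODING,
    NONPOSITIVE,
    NOT_COVERED,
    NOT_SIGNIFICANT,
    UNRESOLVED,
    AnnotationGraph,
    LossReport,
    StageTally,
    load_annotation,
    resolve_features,
    tally_losses,
)
from .expression import (
    CoDirectionSpec,
    ExpressionRecord,
    ThresholdSpec,
    call_significance,
    collapse_redundant,
    load_expression,
    normalize,
)
from .families import (
    FamilyFilterSpec,
    FamilySet,
    Member,
    apply_family_filter,
    attach_star_mirnas,
    build_families_from_relations,
    load_preclustered,
    load_relations,
    load_star_map,
)
from .matrix import (
    ColourScale,
    DEFAULT_COLOUR_SCALE,
    FamilyMatrix,
    SimilarityTable,
    assemble_matrix,
    emit_table,
    load_similarity,
    render_batches,
    transpose,
)
from .ora import ORAResult, bh_qvalues, ora_family

log = logging.getLogger("famexmatrix")

#: user-facing annotation level -> internal ORA counting unit
_ORA_UNIT = {
    "probe_set": "feature",
    "gene": "gene",
    "transcript": "member",
    "protein": "member",
    "mirna": "member",
}

#: URL templates emitted with each gene (no network access is ever made).
DEFAULT_LINK_TEMPLATES = {
    "gene": "https://www.ensembl.org/Gene/Summary?g={gene}",
    "kegg": "https://www.genome.jp/dbget-bin/www_bget?{gene}",
    "atlas": "https://www.ebi.ac.uk/gxa/genes/{gene}",
}


@dataclass
class RunConfig:
    """Every pipeline choice, mirroring the selection features of the web
    form.  Defaults: fold-change thresholds 4/3 and 3/4, batches of 50
    families, gene-level ORA background, all three table modes."""

    organisms: tuple[str, str]
    expr_paths: tuple[str | Path, str | Path]
    out_dir: str | Path = "famexmatrix_out"
    form: str = "values_pair"
    input_level: str = "probe_set"
    annotation_paths: dict[str, dict[str, str | Path]] = field(default_factory=dict)
    family_file: str | Path | None = None
    approach: str = "families"
    relations_file: str | Path | None = None
    relation_prefix: str = "FAM"
    feature_class: str = "protein"
    star_map_file: str | Path | None = None
    star_policy: str = "include"
    similarity_file: str | Path | None = None
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    codirection: CoDirectionSpec = field(default_factory=CoDirectionSpec)
    family_filter: FamilyFilterSpec = field(default_factory=FamilyFilterSpec)
    ora_level: str = "gene"
    batch_size: int = 50
    table_modes: tuple[str, ...] = ("all", "significant", "selection")
    transpose: bool = False
    colour_scale: ColourScale = field(default_factory=lambda: DEFAULT_COLOUR_SCALE)
    object_labels: tuple[str, str] | None = None
    link_templates: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_LINK_TEMPLATES)
    )
    emit_qvalues: bool = False

    def __post_init__(self) -> None:
        if (self.family_file is None) == (self.relations_file is None):
            raise ValueError(
                "exactly one of family_file and relations_file must be given"
            )
        if self.ora_level not in _ORA_UNIT:
            raise ValueError(
                f"bad ora_level {self.ora_level!r}; expected one of "
                f"{tuple(_ORA_UNIT)}"
            )
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def resolved_labels(self) -> tuple[str, str]:
        if self.object_labels is not None:
            return self.object_labels
        o1, o2 = self.organisms
        if o1 == o2:
            return (f"{o1}:1", f"{o2}:2")
        return (o1, o2)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a declarative YAML configuration; relative paths resolve
        against the config file's directory."""
        path = Path(path)
        base = path.parent
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}

        def _p(v):
            return None if v is None else (base / v)

        kwargs: dict = {}
        kwargs["organisms"] = tuple(raw["organisms"])
        expr = raw["expression"]
        kwargs["expr_paths"] = (_p(expr[0]["path"]), _p(expr[1]["path"]))
        kwargs["form"] = raw.get("form", "values_pair")
        kwargs["input_level"] = raw.get("level", "probe_set")
        kwargs["annotation_paths"] = {
            org: {layer: _p(f) for layer, f in layers.items()}
            for org, layers in (raw.get("annotation") or {}).items()
        }
        fam = raw.get("families")
        if fam:
            kwargs["family_file"] = _p(fam["file"])
            kwargs["approach"] = fam.get("approach", "families")
        rel = raw.get("relations")
        if rel:
            kwargs["relations_file"] = _p(rel["file"])
            kwargs["relation_prefix"] = rel.get("prefix", "FAM")
        kwargs["feature_class"] = raw.get("feature_class", "protein")
        star = raw.get("star_map")
        if star:
            kwargs["star_map_file"] = _p(star.get("file"))
            kwargs["star_policy"] = star.get("policy", "include")
        if raw.get("similarity"):
            kwargs["similarity_file"] = _p(raw["similarity"])
        thr = raw.get("threshold")
        if thr:
            kwargs["threshold"] = ThresholdSpec(
                upper_ratio=parse_ratio(thr.get("upper", "4/3")),
                lower_ratio=parse_ratio(thr.get("lower", "3/4")),
            )
        if raw.get("codirection"):
            kwargs["codirection"] = CoDirectionSpec(
                raw["codirection"].replace("-", "_")
            )
        filt = raw.get("filter")
        if filt:
            kwargs["family_filter"] = FamilyFilterSpec(
                exclude_singletons=bool(filt.get("exclude_singletons", False)),
                mode=filt.get("mode", "none").replace("-", "_"),
                restrict_family_ids=(
                    tuple(filt["family_ids"]) if filt.get("family_ids") else None
                ),
                restrict_gene_ids=(
                    tuple(filt["gene_ids"]) if filt.get("gene_ids") else None
                ),
            )
        kwargs["ora_level"] = raw.get("ora_level", "gene")
        kwargs["batch_size"] = int(raw.get("batch_size", 50))
        if raw.get("tables"):
            kwargs["table_modes"] = tuple(raw["tables"])
        kwargs["transpose"] = bool(raw.get("transpose", False))
        kwargs["out_dir"] = _p(raw.get("out", "famexmatrix_out"))
        kwargs["emit_qvalues"] = bool(raw.get("qvalues", False))
        return cls(**kwargs)


def parse_ratio(text) -> float:
    """Parse a threshold that may be written as a fraction ('4/3') or a
    decimal ('1.5')."""
    if isinstance(text, (int, float)):
        return float(text)
    if "/" in text:
        num, den = text.split("/", 1)
        return float(num) / float(den)
    return float(text)


@dataclass
class ObjectData:
    """Per-object intermediate results."""

    label: str
    organism: str
    stages: list[StageTally]
    records: dict[str, ExpressionRecord]  # member_id -> record
    unit_calls: dict[str, str]  # counting unit -> call
    population: int
    feature_members: dict[str, set[str]]  # member_id -> input features


@dataclass
class RunResult:
    family_set: FamilySet
    matrices: list[FamilyMatrix]
    ora_results: dict[str, ORAResult]
    loss_report: LossReport
    selected_family_ids: list[str]
    table_paths: dict[str, Path]
    html_paths: list[Path]
    out_dir: Path
    qvalues: dict | None = None


def _unit_of_member(m: Member, graph: AnnotationGraph | None, unit_kind: str) -> str:
    if (
        unit_kind != "gene"
        or m.feature_class == "mature_mirna"
        or graph is None
    ):
        return m.member_id
    return graph.protein_to_gene.get(m.member_id, m.member_id)


def _process_object(
    label: str,
    organism: str,
    expr_path: str | Path,
    cfg: RunConfig,
    graph: AnnotationGraph | None,
    member_to_family: Mapping[str, str],
    unit_kind: str,
    family_unit_universe: set[str],
) -> ObjectData:
    inp = load_expression(expr_path, cfg.form, label)
    normed, dropped = normalize(inp)
    stages = [
        StageTally(
            f"{label}:normalize",
            len(inp.records),
            {NONPOSITIVE: len(dropped)},
            len(normed),
        )
    ]

    feats = resolve_features(
        [fid for fid, _ in normed], cfg.input_level, graph, organism
    )
    surviving: list[tuple[str, float, frozenset[Member]]] = []
    n_unresolved = n_noncoding = 0
    for (fid, x), rf in zip(normed, feats):
        if rf.resolved_members:
            surviving.append((fid, x, rf.resolved_members))
        elif rf.empty_reason == "non_coding":
            n_noncoding += 1
        else:
            n_unresolved += 1
    stages.append(
        StageTally(
            f"{label}:annotate",
            len(normed),
            {UNRESOLVED: n_unresolved, NON_CODING: n_noncoding},
            len(surviving),
        )
    )

    in_family = sum(
        1
        for _, _, members in surviving
        if any(m.member_id in member_to_family for m in members)
    )
    stages.append(
        StageTally(
            f"{label}:family_assignment",
            len(surviving),
            {NO_FAMILY: len(surviving) - in_family},
            in_family,
        )
    )

    # member-level records: ambiguity retained — every resolved member gets
    # the probe's value; redundant probes averaged on the log2 scale.
    per_member: dict[Member, list[tuple[str, float]]] = {}
    feature_members: dict[str, set[str]] = {}
    for fid, x, members in surviving:
        for m in sorted(members):
            per_member.setdefault(m, []).append((fid, x))
            feature_members.setdefault(m.member_id, set()).add(fid)
    records: dict[str, ExpressionRecord] = {}
    for m, probes in per_member.items():
        avg = collapse_redundant([x for _, x in probes])
        records[m.member_id] = ExpressionRecord(
            m, avg, call_significance(avg, cfg.threshold), tuple(probes)
        )

    # counting units for ORA, collapsed per unit before calling
    unit_values: dict[str, dict[str, float]] = {}
    for fid, x, members in surviving:
        if unit_kind == "feature":
            unit_values.setdefault(fid, {})[fid] = x
        else:
            for m in members:
                u = _unit_of_member(m, graph, unit_kind)
                unit_values.setdefault(u, {})[fid] = x
    unit_calls = {
        u: call_significance(
            collapse_redundant(list(vals.values())), cfg.threshold
        )
        for u, vals in unit_values.items()
    }

    n_significant = sum(1 for c in unit_calls.values() if c != "ns")
    stages.append(
        StageTally(
            f"{label}:significance",
            len(unit_calls),
            {NOT_SIGNIFICANT: len(unit_calls) - n_significant},
            n_significant,
        )
    )

    # population background: all units at the counting level, including units
    # never observed and units unmapped to any family
    if graph is not None:
        base = {
            "gene": graph.genes,
            "member": graph.proteins,
            "feature": graph.probes,
        }[unit_kind]
    else:
        base = set(family_unit_universe)
    universe = set(base) | set(unit_calls)
    stages.append(
        StageTally(
            f"{label}:platform_coverage",
            len(universe),
            {NOT_COVERED: len(universe) - len(unit_calls)},
            len(unit_calls),
        )
    )

    for st in stages:
        log.info(
            "%s: %d in, %d surviving, losses %s",
            st.stage,
            st.n_input,
            st.n_surviving,
            {k: v for k, v in st.losses.items() if v},
        )
    return ObjectData(
        label, organism, stages, records, unit_calls, len(universe), feature_members
    )


def _family_units_for_object(
    fs: FamilySet,
    organism: str,
    graph: AnnotationGraph | None,
    unit_kind: str,
    feature_members: Mapping[str, set[str]],
) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for fid, members in fs.families.items():
        units: set[str] = set()
        for m in members:
            if m.organism != organism:
                continue
            if unit_kind == "feature":
                units |= feature_members.get(m.member_id, set())
            else:
                units.add(_unit_of_member(m, graph, unit_kind))
        out[fid] = units
    return out


def load_family_set(cfg: RunConfig) -> FamilySet:
    """Load or derive the family set named by the configuration, apply the
    star-microRNA policy and the display filter."""
    if cfg.family_file is not None:
        fs = load_preclustered(cfg.family_file, cfg.approach, cfg.feature_class)
    else:
        rel = load_relations(cfg.relations_file, cfg.feature_class)
        fs = build_families_from_relations(rel, cfg.relation_prefix)
    if cfg.feature_class == "mature_mirna" and cfg.star_map_file is not None:
        fs = attach_star_mirnas(
            fs, load_star_map(cfg.star_map_file), cfg.star_policy
        )
    return fs


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full analysis and write all outputs under ``cfg.out_dir``.

    Outputs: ``page_NNNN.html`` matrix batches, one ``table_<mode>.tsv`` per
    configured mode, ``ora.tsv`` with the four p-values per family, and the
    loss report as both text and JSON.  Hard errors (missing files, invariant
    violations) raise with the stage name; per-record failures are only ever
    counted.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = cfg.resolved_labels()
    unit_kind = _ORA_UNIT[cfg.ora_level]

    annots: dict[str, AnnotationGraph] = {
        org: load_annotation(layers, org)
        for org, layers in cfg.annotation_paths.items()
    }

    fs = load_family_set(cfg)
    fs = apply_family_filter(fs, cfg.family_filter, annots or None)
    member_to_family = fs.member_index()
    log.info(
        "family set %s: %d families, %d members",
        fs.approach_name,
        len(fs),
        fs.n_members(),
    )

    family_unit_universe = {
        _unit_of_member(m, None, unit_kind) for m in fs.all_members()
    }
    objects: dict[str, ObjectData] = {}
    for label, organism, path in zip(labels, cfg.organisms, cfg.expr_paths):
        objects[label] = _process_object(
            label,
            organism,
            path,
            cfg,
            annots.get(organism),
            member_to_family,
            unit_kind,
            {u for u in family_unit_universe},
        )

    # four-way ORA per family
    ora_results: dict[str, ORAResult] = {}
    units_by_label = {
        label: _family_units_for_object(
            fs,
            obj.organism,
            annots.get(obj.organism),
            unit_kind,
            obj.feature_members,
        )
        for label, obj in objects.items()
    }
    calls = {label: obj.unit_calls for label, obj in objects.items()}
    population = {label: obj.population for label, obj in objects.items()}
    for fid in sorted(fs.families):
        ora_results[fid] = ora_family(
            fid,
            {label: units_by_label[label][fid] for label in labels},
            calls,
            population,
        )

    # matrices
    sim = (
        load_similarity(cfg.similarity_file)
        if cfg.similarity_file is not None
        else SimilarityTable()
    )

    def gene_of(m: Member) -> str | None:
        g = annots.get(m.organism)
        if g is None or m.feature_class == "mature_mirna":
            return None
        return g.protein_to_gene.get(m.member_id)

    matrices: list[FamilyMatrix] = []
    for fid in sorted(fs.families):
        members_by_object = {
            label: sorted(
                m for m in fs.families[fid] if m.organism == obj.organism
            )
            for label, obj in objects.items()
        }
        m = assemble_matrix(
            fid,
            members_by_object,
            {label: obj.records for label, obj in objects.items()},
            sim=sim,
            ora=ora_results[fid],
            scale=cfg.colour_scale,
            codirection=cfg.codirection,
            gene_of=gene_of,
            link_templates=cfg.link_templates,
        )
        if m is None:
            continue
        if cfg.transpose:
            m = transpose(m)
        matrices.append(m)
    selected = [m.family_id for m in matrices if m.selected]
    log.info(
        "%d families displayed, %d selected by co-direction mode %r",
        len(matrices),
        len(selected),
        cfg.codirection.mode,
    )

    loss_report = tally_losses(
        [st for label in labels for st in objects[label].stages]
    )
    (out_dir / "loss_report.txt").write_text(
        loss_report.to_text(), encoding="utf-8"
    )
    (out_dir / "loss_report.json").write_text(
        json.dumps(loss_report.to_dict(), indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )

    table_paths = {
        mode: emit_table(matrices, mode, out_dir / f"table_{mode}.tsv")
        for mode in cfg.table_modes
    }
    html_paths = render_batches(
        matrices, out_dir, batch_size=cfg.batch_size, loss_report=loss_report
    )

    qvalues = None
    if cfg.emit_qvalues:
        flat = {
            (fid,) + key: p
            for fid, res in ora_results.items()
            for key, p in res.p_values.items()
        }
        qvalues = bh_qvalues(flat)

    _write_ora_table(out_dir / "ora.tsv", ora_results, labels, qvalues)
    return RunResult(
        fs,
        matrices,
        ora_results,
        loss_report,
        selected,
        table_paths,
        html_paths,
        out_dir,
        qvalues,
    )


def _write_ora_table(
    path: Path,
    ora_results: Mapping[str, ORAResult],
    labels: tuple[str, str],
    qvalues: Mapping | None,
) -> None:
    cols = ["#family_id"]
    for label in labels:
        for direction in ("up", "down"):
            cols.append(f"p_{label}_{direction}")
            if qvalues is not None:
                cols.append(f"q_{label}_{direction}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for fid in sorted(ora_results):
            res = ora_results[fid]
            row = [fid]
            for label in labels:
                for direction in ("up", "down"):
                    row.append(repr(res.p_values[(label, direction)]))
                    if qvalues is not None:
                        row.append(repr(qvalues[(fid, label, direction)]))
            fh.write("\t".join(row) + "\n")
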