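"""Deterministic synthetic input generator.

Emulates the pre-generated data background of a two-organism family analysis
at desk scale: an annotation cascade (probe set -> transcript -> protein ->
gene) per organism, a disjoint family partition over the two gene sets (also
expressible as a pairwise relation list whose connected components reproduce
the same partition), within-family BLAST e-values, and differential-expression
tables in any of the four input dialects.

Expression is simulated as per-probe log2-ratios drawn Gaussian around a
gene-level effect: 0 for null genes, ±``effect_size`` for genes of planted
co-up / co-down / anti-directed families.  Planted effects are placed only in
families with at least two genes in each organism (a one-gene axis cannot
express a co-directed paralog pattern).  A ground-truth manifest records the
planted classes and the planted loss-category records so that every pipeline
stage is testable without any external download.

The generator is fixture machinery: the Gaussian noise model, the uniform
e-value decades and the synthetic identifier scheme are not claims about real
data (see the methods note for what passing tests do and do not show).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .expression import ThresholdSpec, _LOG2_10

_CONTROL = 100.0


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic input bundle.

    Defaults describe the standard desk-scale scenario: two organisms with
    2,000 genes each partitioned into 400 families, planted log2 effect 2.0
    with per-probe noise SD 0.2, 5% of families planted in each co-direction
    class, and a small number of planted loss records per category.
    """

    seed: int = 0
    organisms: tuple[str, str] = ("Hs", "Mm")
    n_genes: int = 2000
    n_families: int = 400
    family_size_choices: tuple[int, ...] = (1, 2, 3, 4)
    family_size_weights: tuple[float, ...] = (0.30, 0.30, 0.25, 0.15)
    max_isoforms: int = 3
    noncoding_rate: float = 0.05
    probe_ambiguity_rate: float = 0.05
    frac_co_up: float = 0.05
    frac_co_down: float = 0.05
    frac_anti: float = 0.05
    effect_size: float = 2.0
    noise_sd: float = 0.2
    frac_missing_evalue: float = 0.10
    n_uncovered_genes: int = 10
    n_unresolvable: int = 5
    expression_level: str = "probe_set"  # "probe_set" or "gene"
    form: str = "values_pair"

    def __post_init__(self) -> None:
        for name in (
            "noncoding_rate",
            "probe_ambiguity_rate",
            "frac_co_up",
            "frac_co_down",
            "frac_anti",
            "frac_missing_evalue",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.organisms[0] == self.organisms[1]:
            raise ValueError("the two organisms must be distinct codes")
        if self.expression_level not in ("probe_set", "gene"):
            raise ValueError("expression_level must be 'probe_set' or 'gene'")
        if len(self.family_size_choices) != len(self.family_size_weights):
            raise ValueError("family size choices and weights differ in length")
        if min(self.family_size_choices) < 1:
            raise ValueError("family sizes must be >= 1")


@dataclass
class FixtureBundle:
    """Generated input bundle: file paths plus the ground-truth manifest."""

    spec: FixtureSpec
    out_dir: Path
    paths: dict[str, Path]
    manifest: dict
    # per-organism per-feature true log2-ratios, kept so the same underlying
    # data can be re-emitted in any input dialect
    _log2_by_feature: dict[str, list[tuple[str, float]]] = field(repr=False, default_factory=dict)

    def write_expression(self, organism: str, form: str, out: str | Path) -> Path:
        """Re-emit one organism's expression table in another dialect from
        the same underlying per-feature log2-ratios."""
        out = Path(out)
        lines = []
        for fid, x in self._log2_by_feature[organism]:
            if form == "values_pair":
                lines.append(f"{fid}\t{_CONTROL * 2.0 ** x!r}\t{_CONTROL!r}")
            elif form == "ratio":
                lines.append(f"{fid}\t{2.0 ** x!r}")
            elif form == "log2_ratio":
                lines.append(f"{fid}\t{x!r}")
            elif form == "log10_ratio":
                lines.append(f"{fid}\t{x / _LOG2_10!r}")
            else:
                raise ValueError(f"bad expression form {form!r}")
        out.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return out


def _write_tsv(path: Path, rows: Sequence[Sequence[str]]) -> Path:
    path.write_text(
        "\n".join("\t".join(r) for r in rows) + ("\n" if rows else ""),
        encoding="utf-8",
    )
    return path


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureBundle:
    """Generate a complete, deterministic input bundle under ``out_dir``.

    Files written: per-organism annotation layers, a pre-clustered family
    file, an equivalent pairwise relation file, a within-family similarity
    table, per-organism expression tables in ``spec.form``, and
    ``manifest.json`` with the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    org1, org2 = spec.organisms

    # -- family skeleton: per-organism gene counts per family ------------------
    sizes = {
        org: rng.choice(
            spec.family_size_choices,
            size=spec.n_families,
            p=np.asarray(spec.family_size_weights)
            / sum(spec.family_size_weights),
        ).astype(int)
        for org in spec.organisms
    }
    for org in spec.organisms:
        needed = int(sizes[org].sum())
        if needed + spec.n_uncovered_genes > spec.n_genes:
            raise ValueError(
                f"infeasible spec: families need {needed} genes for {org} "
                f"plus {spec.n_uncovered_genes} uncovered, but n_genes="
                f"{spec.n_genes}"
            )

    family_ids = [f"F{i + 1:05d}" for i in range(spec.n_families)]
    eligible = [
        i
        for i in range(spec.n_families)
        if sizes[org1][i] >= 2 and sizes[org2][i] >= 2
    ]
    n_up = round(spec.frac_co_up * spec.n_families)
    n_down = round(spec.frac_co_down * spec.n_families)
    n_anti = round(spec.frac_anti * spec.n_families)
    if n_up + n_down + n_anti > len(eligible):
        raise ValueError(
            f"infeasible spec: {n_up + n_down + n_anti} planted families "
            f"requested but only {len(eligible)} families have >=2 genes in "
            f"both organisms"
        )
    order = rng.permutation(len(eligible))
    chosen = [eligible[j] for j in order[: n_up + n_down + n_anti]]
    family_class = {fid: "null" for fid in family_ids}
    for idx in chosen[:n_up]:
        family_class[family_ids[idx]] = "co_up"
    for idx in chosen[n_up : n_up + n_down]:
        family_class[family_ids[idx]] = "co_down"
    for idx in chosen[n_up + n_down :]:
        family_class[family_ids[idx]] = "anti"

    # -- genes, effects, annotation cascade ------------------------------------
    genes = {org: [f"{org}G{i:05d}" for i in range(spec.n_genes)] for org in spec.organisms}
    family_genes: dict[str, dict[str, list[str]]] = {fid: {} for fid in family_ids}
    gene_effect: dict[str, dict[str, float]] = {org: {} for org in spec.organisms}
    cursor = {org: 0 for org in spec.organisms}
    for i, fid in enumerate(family_ids):
        cls = family_class[fid]
        for org in spec.organisms:
            n = int(sizes[org][i])
            gs = genes[org][cursor[org] : cursor[org] + n]
            cursor[org] += n
            family_genes[fid][org] = gs
            if cls == "co_up":
                eff = spec.effect_size
            elif cls == "co_down":
                eff = -spec.effect_size
            elif cls == "anti":
                eff = spec.effect_size if org == org1 else -spec.effect_size
            else:
                eff = 0.0
            for g in gs:
                gene_effect[org][g] = eff
    familyless = {org: genes[org][cursor[org] :] for org in spec.organisms}
    for org in spec.organisms:
        for g in familyless[org]:
            gene_effect[org][g] = 0.0
    uncovered = {
        org: set(familyless[org][: spec.n_uncovered_genes])
        for org in spec.organisms
    }

    gene_proteins: dict[str, dict[str, list[str]]] = {org: {} for org in spec.organisms}
    annotation_rows: dict[str, dict[str, list]] = {
        org: {"p2t": [], "t2p": [], "t2g": []} for org in spec.organisms
    }
    gene_probes: dict[str, dict[str, list[tuple[str, str, bool]]]] = {
        org: {} for org in spec.organisms
    }  # gene -> [(probe, transcript, coding)]
    for org in spec.organisms:
        n_iso = rng.integers(1, spec.max_isoforms + 1, size=spec.n_genes)
        noncoding_draw = rng.random(spec.n_genes) < spec.noncoding_rate
        ambiguity_draw = rng.random(spec.n_genes * spec.max_isoforms)
        for i, g in enumerate(genes[org]):
            transcripts = []
            proteins = []
            for j in range(int(n_iso[i])):
                t = f"{org}T{i:05d}x{j}"
                p = f"{org}P{i:05d}x{j}"
                transcripts.append(t)
                proteins.append(p)
                annotation_rows[org]["t2p"].append((t, p))
                annotation_rows[org]["t2g"].append((t, g))
            gene_proteins[org][g] = proteins
            probes = []
            for j, t in enumerate(transcripts):
                pr = f"{org}PR{i:05d}x{j}"
                annotation_rows[org]["p2t"].append((pr, t))
                if (
                    len(transcripts) > 1
                    and ambiguity_draw[i * spec.max_isoforms + j]
                    < spec.probe_ambiguity_rate
                ):
                    other = transcripts[(j + 1) % len(transcripts)]
                    annotation_rows[org]["p2t"].append((pr, other))
                probes.append((pr, t, True))
            if noncoding_draw[i]:
                t_nc = f"{org}T{i:05d}xN"
                pr_nc = f"{org}PR{i:05d}xN"
                annotation_rows[org]["t2g"].append((t_nc, g))
                annotation_rows[org]["p2t"].append((pr_nc, t_nc))
                probes.append((pr_nc, t_nc, False))
            gene_probes[org][g] = probes

    # -- family and relation files ---------------------------------------------
    family_rows = [("member_id", "organism", "family_id")]
    relation_rows = [("member_a", "organism_a", "member_b", "organism_b")]
    family_members: dict[str, list[tuple[str, str]]] = {}
    for fid in family_ids:
        members: list[tuple[str, str]] = []
        for org in spec.organisms:
            for g in family_genes[fid][org]:
                members.extend((p, org) for p in gene_proteins[org][g])
        members.sort()
        family_members[fid] = members
        for m, org in members:
            family_rows.append((m, org, fid))
        for (ma, oa), (mb, ob) in zip(members, members[1:]):
            relation_rows.append((ma, oa, mb, ob))

    # -- similarity table --------------------------------------------------------
    sim_rows = [("member_a", "member_b", "evalue")]
    n_missing_evalue = 0
    for fid in family_ids:
        members = family_members[fid]
        best_pair = None
        first1 = next((m for m, o in members if o == org1), None)
        first2 = next((m for m, o in members if o == org2), None)
        if first1 is not None and first2 is not None:
            best_pair = tuple(sorted((first1, first2)))
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                a, b = members[a_i][0], members[b_i][0]
                pair = tuple(sorted((a, b)))
                if pair == best_pair:
                    ev = 10.0 ** -float(rng.uniform(110.0, 150.0))
                elif rng.random() < spec.frac_missing_evalue:
                    n_missing_evalue += 1
                    continue
                else:
                    ev = 10.0 ** -float(rng.uniform(20.0, 80.0))
                sim_rows.append((pair[0], pair[1], repr(ev)))

    # -- expression tables --------------------------------------------------------
    log2_by_feature: dict[str, list[tuple[str, float]]] = {}
    planted_losses: dict[str, dict[str, int]] = {}
    for org in spec.organisms:
        feats: list[tuple[str, float]] = []
        n_noncoding_records = 0
        for g in genes[org]:
            if g in uncovered[org]:
                continue
            eff = gene_effect[org][g]
            if spec.expression_level == "gene":
                feats.append((g, eff + float(rng.normal(0.0, spec.noise_sd))))
            else:
                for pr, _t, coding in gene_probes[org][g]:
                    feats.append(
                        (pr, eff + float(rng.normal(0.0, spec.noise_sd)))
                    )
                    if not coding:
                        n_noncoding_records += 1
        for i in range(spec.n_unresolvable):
            feats.append((f"{org}JUNK{i:03d}", 0.0))
        log2_by_feature[org] = feats
        planted_losses[org] = {
            "gene_not_covered": len(uncovered[org]),
            "unresolvable": spec.n_unresolvable,
            "non_coding_records": n_noncoding_records,
            "n_expression_records": len(feats),
        }

    # -- write files ----------------------------------------------------------------
    paths: dict[str, Path] = {}
    for org in spec.organisms:
        paths[f"probe_to_transcript_{org}"] = _write_tsv(
            out_dir / f"annot_{org}_probe_to_transcript.tsv",
            annotation_rows[org]["p2t"],
        )
        paths[f"transcript_to_protein_{org}"] = _write_tsv(
            out_dir / f"annot_{org}_transcript_to_protein.tsv",
            annotation_rows[org]["t2p"],
        )
        paths[f"transcript_to_gene_{org}"] = _write_tsv(
            out_dir / f"annot_{org}_transcript_to_gene.tsv",
            annotation_rows[org]["t2g"],
        )
    paths["families"] = _write_tsv(out_dir / "families.tsv", family_rows)
    paths["relations"] = _write_tsv(out_dir / "relations.tsv", relation_rows)
    paths["similarity"] = _write_tsv(out_dir / "similarity.tsv", sim_rows)

    manifest = {
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(spec).items()
        },
        "organisms": list(spec.organisms),
        "family_class": family_class,
        "planted": {
            cls: sorted(f for f, c in family_class.items() if c == cls)
            for cls in ("co_up", "co_down", "anti")
        },
        "family_genes": family_genes,
        "family_n_genes": {
            fid: {org: len(family_genes[fid][org]) for org in spec.organisms}
            for fid in family_ids
        },
        "losses": planted_losses,
        "n_familyless_genes": {
            org: len(familyless[org]) for org in spec.organisms
        },
        "uncovered_genes": {org: sorted(uncovered[org]) for org in spec.organisms},
    }

    bundle = FixtureBundle(
        spec, out_dir, paths, manifest, _log2_by_feature=log2_by_feature
    )
    for org in spec.organisms:
        paths[f"expression_{org}"] = bundle.write_expression(
            org, spec.form, out_dir / f"expression_{org}.tsv"
        )
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    paths["manifest"] = out_dir / "manifest.json"
    return bundle


# -- analytic expectations for null fixtures ----------------------------------------


def null_call_rate(noise_sd: float, threshold: ThresholdSpec | None = None) -> float:
    """Probability that a null unit (true log2-ratio 0, Gaussian noise) is
    called significant in one given direction."""
    t = threshold or ThresholdSpec()
    return float(norm.sf(t.log2_upper / noise_sd))


def expected_null_selection(
    family_sizes: Sequence[tuple[int, int]], q: float
) -> tuple[float, float]:
    """Mean and variance of the number of families with at least one
    co-directed pair (mode co_both) when every unit is independently up with
    probability ``q`` and down with probability ``q``.

    For a family with (n1, n2) units per object, selection = (an up unit on
    both axes) or (a down unit on both axes); the two axes are independent,
    the two directions on one axis are not, hence inclusion–exclusion with
    P(>=1 up and >=1 down among n) = 1 - 2(1-q)^n + (1-2q)^n.
    """
    mean = 0.0
    var = 0.0
    for n1, n2 in family_sizes:
        p_dir = (1 - (1 - q) ** n1) * (1 - (1 - q) ** n2)
        both = lambda n: 1 - 2 * (1 - q) ** n + (1 - 2 * q) ** n  # noqa: E731
        p_sel = 2 * p_dir - both(n1) * both(n2)
        mean += p_sel
        var += p_sel * (1 - p_sel)
    return mean, var
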