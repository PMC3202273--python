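"""Per-family matrix assembly, HTML batch rendering, and table output.

Each family is displayed as a two-dimensional grid: rows are the members of
object 1 that carry expression values, columns those of object 2.  The matrix
border encodes differential expression (green / black / red for down / ns /
up, averaged over redundant probes, with per-probe detail retained); each cell
encodes the pairwise BLAST e-value of the two sequences, binned to a colour
ramp whose top (most similar, typically the closest orthologs) is violet.
Families are rendered in batches of 50 self-contained HTML pages; three
tab-delimited table modes export the pairwise relations.
"""

from __future__ import annotations

import html
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import LossReport
from .expression import CoDirectionSpec, ExpressionRecord, classify_codirection
from .families import Member, _read_tsv
from .ora import ORAResult


@dataclass
class SimilarityTable:
    """Symmetric pairwise BLAST e-values between family members.

    E-values are consumed, never computed, by the engine.  Stored under the
    sorted ID pair; self-pairs (identity hits) are allowed.  When the same
    pair is listed more than once, the best (smallest) e-value wins.
    """

    evalues: dict[tuple[str, str], float] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, evalue: float) -> None:
        if evalue < 0:
            raise ValueError(f"negative e-value for pair ({a!r}, {b!r})")
        key = self._key(a, b)
        prev = self.evalues.get(key)
        self.evalues[key] = evalue if prev is None else min(prev, evalue)

    def get(self, a: str, b: str) -> float | None:
        return self.evalues.get(self._key(a, b))

    def __len__(self) -> int:
        return len(self.evalues)


def load_similarity(path: str | Path) -> SimilarityTable:
    """Load a 3-column (member_a, member_b, evalue) similarity table."""
    table = SimilarityTable()
    for a, b, ev in _read_tsv(path, 3, ("member_a", "member_b", "evalue")):
        table.set(a, b, float(ev))
    return table


#: Default e-value colour bins: (inclusive upper bound, colour), ordered and
#: exhaustive over [0, inf).  The exact bounds of the original display are not
#: published; this decade-binned ramp with a violet top bin (most similar
#: sequence pairs) is the package default and fully user-overridable.
DEFAULT_EVALUE_BINS: tuple[tuple[float, str], ...] = (
    (1e-100, "violet"),
    (1e-30, "mediumpurple"),
    (1e-10, "cornflowerblue"),
    (1e-5, "lightsteelblue"),
    (1e-2, "lightcyan"),
    (math.inf, "whitesmoke"),
)

#: Border colours for the three-state differential expression call.
DE_COLOURS: dict[str, str] = {"down": "green", "ns": "black", "up": "red"}

MISSING_EVALUE_COLOUR = "white"


@dataclass(frozen=True)
class ColourScale:
    """Colour coding of the matrix: three DE border colours plus the ordered
    e-value bins."""

    de_colours: Mapping[str, str] = field(default_factory=lambda: dict(DE_COLOURS))
    evalue_bins: tuple[tuple[float, str], ...] = DEFAULT_EVALUE_BINS

    def __post_init__(self) -> None:
        bounds = [b for b, _ in self.evalue_bins]
        if bounds != sorted(bounds) or not bounds or bounds[-1] != math.inf:
            raise ValueError(
                "evalue_bins must be ordered by bound and end with inf"
            )


DEFAULT_COLOUR_SCALE = ColourScale()


def evalue_to_bin(e: float, scale: ColourScale = DEFAULT_COLOUR_SCALE) -> str:
    """Map an e-value to the colour of the first bin whose bound >= e."""
    if e < 0:
        raise ValueError(f"negative e-value: {e}")
    for bound, colour in scale.evalue_bins:
        if e <= bound:
            return colour
    raise AssertionError("unreachable: bins are exhaustive")  # pragma: no cover


@dataclass(frozen=True)
class AxisEntry:
    """One matrix border entry: the member, its gene, the averaged log2-ratio
    with its call, and the per-probe detail column."""

    member: Member
    gene: str | None
    log2_ratio: float
    call: str
    probes: tuple[tuple[str, float], ...] = ()


@dataclass(frozen=True)
class Cell:
    evalue: float | None
    colour: str
    selected: bool


@dataclass
class FamilyMatrix:
    """Assembled per-family grid joining expression and similarity."""

    family_id: str
    object_labels: tuple[str, str]
    rows: list[AxisEntry]
    cols: list[AxisEntry]
    cells: list[list[Cell]]  # indexed [row][col]
    ora: ORAResult | None = None
    link_templates: dict[str, str] = field(default_factory=dict)

    def n_selected(self) -> int:
        return sum(c.selected for row in self.cells for c in row)

    @property
    def selected(self) -> bool:
        return self.n_selected() > 0


def _axis_entries(
    members: Iterable[Member],
    records: Mapping[str, ExpressionRecord],
    gene_of,
) -> list[AxisEntry]:
    entries = []
    for m in members:
        rec = records.get(m.member_id)
        if rec is None:
            continue  # members without expression values are excluded
        entries.append(
            AxisEntry(m, gene_of(m), rec.log2_ratio, rec.call, tuple(rec.source_probes))
        )
    entries.sort(key=lambda e: (e.gene or "", e.member.member_id))
    return entries


def assemble_matrix(
    family_id: str,
    members_by_object: Mapping[str, Iterable[Member]],
    records_by_object: Mapping[str, Mapping[str, ExpressionRecord]],
    sim: SimilarityTable | None = None,
    ora: ORAResult | None = None,
    scale: ColourScale = DEFAULT_COLOUR_SCALE,
    codirection: CoDirectionSpec = CoDirectionSpec("none"),
    gene_of=None,
    link_templates: Mapping[str, str] | None = None,
) -> FamilyMatrix | None:
    """Assemble one family's matrix.

    Rows come from the first object label, columns from the second; members
    without expression values are excluded from the display.  Axes are sorted
    by gene then member ID for deterministic output.  Missing e-values render
    in a neutral colour.  Returns None when no member of the family carries
    expression on either axis (the matrix is skipped entirely).
    """
    labels = tuple(members_by_object)
    if len(labels) != 2:
        raise ValueError("exactly two object labels are required")
    if gene_of is None:
        gene_of = lambda m: None  # noqa: E731
    rows = _axis_entries(members_by_object[labels[0]], records_by_object[labels[0]], gene_of)
    cols = _axis_entries(members_by_object[labels[1]], records_by_object[labels[1]], gene_of)
    if not rows and not cols:
        return None
    cells: list[list[Cell]] = []
    for r in rows:
        row_cells = []
        for c in cols:
            ev = sim.get(r.member.member_id, c.member.member_id) if sim else None
            colour = MISSING_EVALUE_COLOUR if ev is None else evalue_to_bin(ev, scale)
            row_cells.append(
                Cell(ev, colour, classify_codirection(r.call, c.call, codirection))
            )
        cells.append(row_cells)
    return FamilyMatrix(
        family_id,
        labels,
        rows,
        cols,
        cells,
        ora,
        dict(link_templates or {}),
    )


def transpose(m: FamilyMatrix) -> FamilyMatrix:
    """Exchange rows and columns (mutually swapping the two objects).

    Cell content is preserved under pair symmetry and the ORA p-values keep
    their object labels, which now annotate the opposite axis.
    """
    cells = [
        [m.cells[i][j] for i in range(len(m.rows))] for j in range(len(m.cols))
    ]
    return FamilyMatrix(
        m.family_id,
        (m.object_labels[1], m.object_labels[0]),
        list(m.cols),
        list(m.rows),
        cells,
        m.ora,
        dict(m.link_templates),
    )


# -- HTML rendering ---------------------------------------------------------------

_PAGE_CSS = """
body { font-family: sans-serif; font-size: 13px; }
table.fam { border-collapse: collapse; margin: 1em 0; }
table.fam td, table.fam th { border: 1px solid #999; padding: 3px 6px; }
td.de-up { color: white; background: red; }
td.de-down { color: white; background: green; }
td.de-ns { color: white; background: black; }
td.sel { font-weight: bold; }
.probes { color: #555; font-size: 11px; }
.ora { margin: 0.3em 0 1.2em 0; color: #333; }
pre.loss { background: #f5f5f5; padding: 0.6em; }
"""


def _fmt(x: float) -> str:
    return format(x, ".4g")


def _entry_cell(e: AxisEntry, link_templates: Mapping[str, str]) -> str:
    title = f"averaged log2-ratio {e.log2_ratio!r}"
    gene = html.escape(e.gene or "-")
    if e.gene and "gene" in link_templates:
        url = link_templates["gene"].format(gene=e.gene)
        gene = f'<a href="{html.escape(url)}">{gene}</a>'
    probes = "; ".join(f"{p}:{_fmt(v)}" for p, v in e.probes)
    return (
        f'<td class="de-{e.call}" title="{html.escape(title)}">'
        f"{html.escape(e.member.member_id)}<br>{gene}<br>{_fmt(e.log2_ratio)}"
        f'<br><span class="probes">{html.escape(probes)}</span></td>'
    )


def _family_html(m: FamilyMatrix) -> str:
    parts = [f"<h2>Family {html.escape(m.family_id)}</h2>"]
    parts.append('<table class="fam">')
    head = [f"<th>{html.escape(m.object_labels[0])} \\ {html.escape(m.object_labels[1])}</th>"]
    for c in m.cols:
        head.append(_entry_cell(c, m.link_templates).replace("<td", "<th", 1).replace("</td>", "</th>"))
    parts.append("<tr>" + "".join(head) + "</tr>")
    for i, r in enumerate(m.rows):
        row = [_entry_cell(r, m.link_templates)]
        for j in range(len(m.cols)):
            cell = m.cells[i][j]
            ev = "n/a" if cell.evalue is None else repr(cell.evalue)
            mark = "&#10003;" if cell.selected else "&nbsp;"
            cls = ' class="sel"' if cell.selected else ""
            row.append(
                f'<td{cls} style="background:{cell.colour}" '
                f'title="e-value {ev}">{mark}</td>'
            )
        parts.append("<tr>" + "".join(row) + "</tr>")
    parts.append("</table>")
    if m.ora is not None:
        bits = []
        for (label, direction), p in sorted(m.ora.p_values.items()):
            N, K, n, k = m.ora.counts[(label, direction)]
            bits.append(
                f"{html.escape(label)}/{direction}: p={_fmt(p)} "
                f"(k={k}, n={n}, K={K}, N={N})"
            )
        parts.append(
            '<div class="ora">over-representation: ' + "; ".join(bits) + "</div>"
        )
    return "\n".join(parts)


def render_batches(
    matrices: Sequence[FamilyMatrix],
    out_dir: str | Path,
    batch_size: int = 50,
    loss_report: LossReport | None = None,
    title: str = "Family expression/similarity matrices",
) -> list[Path]:
    """Render families to self-contained HTML pages in batches (default 50
    families per page, ``page_0001.html`` ...).  With no families a single
    page carrying only the loss report is written.  Returns the page paths."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_pages = max(1, -(-len(matrices) // batch_size))
    loss_html = ""
    if loss_report is not None:
        loss_html = f'<pre class="loss">{html.escape(loss_report.to_text())}</pre>'
    paths: list[Path] = []
    for page in range(n_pages):
        batch = matrices[page * batch_size : (page + 1) * batch_size]
        body = "\n".join(_family_html(m) for m in batch)
        doc = (
            "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            f"<title>{html.escape(title)} — page {page + 1}/{n_pages}</title>"
            f"<style>{_PAGE_CSS}</style></head><body>"
            f"<h1>{html.escape(title)}</h1>"
            f"<p>page {page + 1} of {n_pages}; "
            f"families {page * batch_size + 1}–{page * batch_size + len(batch)}"
            f" of {len(matrices)}</p>\n{body}\n{loss_html}</body></html>\n"
        )
        path = out_dir / f"page_{page + 1:04d}.html"
        path.write_text(doc, encoding="utf-8")
        paths.append(path)
    return paths


# -- table output -------------------------------------------------------------------

TABLE_MODES = ("selection", "all", "significant")
TABLE_COLUMNS = (
    "family_id",
    "gene1",
    "member1",
    "gene2",
    "member2",
    "log2_ratio1",
    "log2_ratio2",
    "evalue",
)


def emit_table(
    matrices: Sequence[FamilyMatrix], mode: str, out: str | Path
) -> Path:
    """Write one of the three tab-delimited relation tables.

    One row per (row member, column member) pair: ``all`` exports every pair,
    ``significant`` only pairs where both calls are significant, ``selection``
    only pairs carrying the selected flag.  Floats are written with ``repr``
    so they re-parse bit-exactly; missing e-values are 'NA'.
    """
    if mode not in TABLE_MODES:
        raise ValueError(f"bad table mode {mode!r}; expected {TABLE_MODES}")
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(TABLE_COLUMNS) + "\n")
        for m in matrices:
            for i, r in enumerate(m.rows):
                for j, c in enumerate(m.cols):
                    cell = m.cells[i][j]
                    if mode == "selection" and not cell.selected:
                        continue
                    if mode == "significant" and "ns" in (r.call, c.call):
                        continue
                    ev = "NA" if cell.evalue is None else repr(cell.evalue)
                    fh.write(
                        "\t".join(
                            (
                                m.family_id,
                                r.gene or "",
                                r.member.member_id,
                                c.gene or "",
                                c.member.member_id,
                                repr(r.log2_ratio),
                                repr(c.log2_ratio),
                                ev,
                            )
                        )
                        + "\n"
                    )
    return out


def parse_table(path: str | Path) -> list[dict]:
    """Re-parse an emitted relation table (inverse of :func:`emit_table`)."""
    rows: list[dict] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            rows.append(
                {
                    "family_id": f[0],
                    "gene1": f[1] or None,
                    "member1": f[2],
                    "gene2": f[3] or None,
                    "member2": f[4],
                    "log2_ratio1": float(f[5]),
                    "log2_ratio2": float(f[6]),
                    "evalue": None if f[7] == "NA" else float(f[7]),
                }
            )
    return rows
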