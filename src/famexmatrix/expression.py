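"""Differential-expression normalization, probe collapsing, significance
calls, and co-direction classification.

All input dialects — raw treatment/control value pairs, plain ratios,
log2-ratios, log10-ratios — are re-calculated to log2-ratios on ingestion.
Redundant probes for one member are averaged by arithmetic mean *on the log2
scale*, while the individual probe values are kept for display.  Significance
is a three-state call (up / down / not significant) from a strict fold-change
threshold, default ratio > 4/3 or < 3/4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .families import Member

FORMS = ("values_pair", "ratio", "log2_ratio", "log10_ratio")
CALLS = ("up", "down", "ns")
CODIRECTION_MODES = ("co_up", "co_down", "co_both", "anti", "none")

_LOG2_10 = math.log2(10.0)
# log2-ratios are quantized to this many decimals so that the four input
# dialects, which agree only to floating-point rounding after text parsing,
# yield identical downstream values and identical table output.
_DECIMALS = 9
# Guard band on the log2 scale: ratios within ~1e-9 of a threshold do not
# flip a strict inequality (e.g. a ratio of exactly 4/3 is never "up").
_EPS = 1e-9


@dataclass(frozen=True)
class ThresholdSpec:
    """Fold-change significance threshold, strict on both sides.

    Defaults: ratio > 4/3 calls up, ratio < 3/4 calls down, anything between
    (inclusive) is not significant.
    """

    upper_ratio: float = 4.0 / 3.0
    lower_ratio: float = 3.0 / 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.lower_ratio < 1.0 < self.upper_ratio):
            raise ValueError(
                "thresholds must satisfy 0 < lower_ratio < 1 < upper_ratio; "
                f"got lower={self.lower_ratio}, upper={self.upper_ratio}"
            )

    @property
    def log2_upper(self) -> float:
        return math.log2(self.upper_ratio)

    @property
    def log2_lower(self) -> float:
        return math.log2(self.lower_ratio)


DEFAULT_THRESHOLD = ThresholdSpec()


@dataclass(frozen=True)
class CoDirectionSpec:
    """Co-direction filter across the two compared objects.

    ``co_up`` selects pairs over-expressed in both, ``co_down`` repressed in
    both, ``co_both`` either, ``anti`` opposite significant directions, and
    ``none`` applies no co-direction restriction.
    """

    mode: str = "none"

    def __post_init__(self) -> None:
        if self.mode not in CODIRECTION_MODES:
            raise ValueError(
                f"bad co-direction mode {self.mode!r}; "
                f"expected one of {CODIRECTION_MODES}"
            )


def to_log2(value_or_pair, form: str) -> float | None:
    """Re-calculate one expression record to a log2-ratio.

    ``values_pair`` takes ``(treatment, control)`` and returns
    log2(treatment/control); ``ratio`` returns log2(value); ``log10_ratio``
    rescales by log2(10); ``log2_ratio`` is the identity.  Records violating
    positivity (zero or negative value where a ratio is required) return
    ``None`` so the caller can route them to the loss report instead of
    raising.
    """
    if form not in FORMS:
        raise ValueError(f"bad expression form {form!r}; expected {FORMS}")
    if form == "values_pair":
        treatment, control = value_or_pair
        if treatment <= 0 or control <= 0:
            return None
        x = math.log2(treatment / control)
    elif form == "ratio":
        if value_or_pair <= 0:
            return None
        x = math.log2(value_or_pair)
    elif form == "log10_ratio":
        x = value_or_pair * _LOG2_10
    else:
        x = float(value_or_pair)
    if not math.isfinite(x):
        return None
    return round(x, _DECIMALS)


def collapse_redundant(probes: Sequence[float]) -> float:
    """Arithmetic mean of per-probe log2-ratios (the averaging happens on the
    log2 scale, not on the ratio scale)."""
    if not probes:
        raise ValueError("cannot collapse an empty probe list")
    return round(math.fsum(probes) / len(probes), _DECIMALS)


def call_significance(
    log2_ratio: float, t: ThresholdSpec = DEFAULT_THRESHOLD
) -> str:
    """Three-state significance call: 'up' iff the ratio strictly exceeds the
    upper threshold, 'down' iff strictly below the lower one, else 'ns'."""
    if log2_ratio > t.log2_upper + _EPS:
        return "up"
    if log2_ratio < t.log2_lower - _EPS:
        return "down"
    return "ns"


def classify_codirection(call1: str, call2: str, spec: CoDirectionSpec) -> bool:
    """Decide whether a member pair with the given calls is selected.

    Pairs involving a not-significant call are never selected by the four
    directional modes; mode 'none' selects every pair.
    """
    for c in (call1, call2):
        if c not in CALLS:
            raise ValueError(f"bad call {c!r}")
    mode = spec.mode
    if mode == "none":
        return True
    if "ns" in (call1, call2):
        return False
    if mode == "co_up":
        return call1 == "up" and call2 == "up"
    if mode == "co_down":
        return call1 == "down" and call2 == "down"
    if mode == "co_both":
        return call1 == call2
    return call1 != call2  # anti


@dataclass(frozen=True)
class ExpressionRecord:
    """One member's differential expression for one object: the averaged
    log2-ratio, its significance call, and the contributing per-probe values
    retained for display."""

    member: Member
    log2_ratio: float
    call: str
    source_probes: tuple[tuple[str, float], ...] = ()


@dataclass
class ExpressionInput:
    """Raw expression table for one object before normalization.

    ``records`` preserves input order and duplicates: a feature listed twice
    contributes two redundant probes to be averaged later, not one.
    """

    object_label: str
    form: str
    records: list[tuple[str, tuple[float, ...]]]


def load_expression(
    path: str | Path,
    form: str,
    object_label: str,
    header: str | bool = "auto",
) -> ExpressionInput:
    """Read a tab-delimited expression table.

    ``values_pair`` expects three columns (feature, treatment, control); the
    ratio dialects expect two (feature, value).  ``header='auto'`` skips the
    first row when its value column does not parse as a number; '#' comment
    lines are always skipped.
    """
    if form not in FORMS:
        raise ValueError(f"bad expression form {form!r}; expected {FORMS}")
    n_values = 2 if form == "values_pair" else 1
    records: list[tuple[str, tuple[float, ...]]] = []
    first = True
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 1 + n_values:
                raise ValueError(
                    f"{path}:{lineno}: expected {1 + n_values} columns, "
                    f"got {len(fields)}"
                )
            try:
                values = tuple(float(v) for v in fields[1 : 1 + n_values])
            except ValueError:
                if first and (header == "auto" or header is True):
                    first = False
                    continue
                raise ValueError(
                    f"{path}:{lineno}: non-numeric expression value in "
                    f"{fields[1:1 + n_values]!r}"
                ) from None
            if first and header is True:
                first = False
                continue
            first = False
            records.append((fields[0], values))
    return ExpressionInput(object_label, form, records)


def normalize(
    inp: ExpressionInput,
) -> tuple[list[tuple[str, float]], list[str]]:
    """Normalize every record to a log2-ratio.

    Returns the surviving ``(feature_id, log2_ratio)`` list in input order and
    the feature IDs dropped for nonpositive/non-finite values (to be counted
    in the loss report).
    """
    surviving: list[tuple[str, float]] = []
    dropped: list[str] = []
    for fid, values in inp.records:
        arg = values if inp.form == "values_pair" else values[0]
        x = to_log2(arg, inp.form)
        if x is None:
            dropped.append(fid)
        else:
            surviving.append((fid, x))
    return surviving, dropped
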