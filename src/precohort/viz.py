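"""Scale charts: one patient's profile against a reference cohort.

A scale chart draws one horizontal track per similarity variable.  For a
continuous variable the track shows the reference cohort's minimum, lower
quartile, median, upper quartile and maximum as four graded segments; for a
categorical or binary variable the track is split into segments
proportional to category relative frequencies.  The index patient's own
value is overlaid as a contrasting vertical marker, so a glance shows where
the patient sits inside — or outside — the reference distribution.

Summarization (:func:`summarize_reference`) and rendering
(:func:`draw_scale_chart`) are strictly separated: the chart draws only
what the profile contains.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .features import FeatureMatrix

# quartile shades (outer..inner) and categorical shade cycle
_CONT_SHADES = ["#c6dbef", "#6baed6", "#2171b5", "#c6dbef"]
_CAT_SHADES = ["#2171b5", "#6baed6", "#c6dbef", "#deebf7", "#eff3ff"]
_INDEX_COLOR = "#d62728"


@dataclass
class VariableSummary:
    """Distribution summary of one variable plus the index patient's value."""

    name: str
    kind: str
    index_value: object
    # continuous: five-number summary (linear-interpolation quartiles)
    minimum: float | None = None
    q1: float | None = None
    median: float | None = None
    q3: float | None = None
    maximum: float | None = None
    # categorical/binary: category -> relative frequency
    frequencies: dict | None = None


@dataclass
class SummaryProfile:
    """Per-variable summaries of a reference cohort for one index case."""

    variables: list[VariableSummary]


def summarize_reference(matrix: FeatureMatrix, index_case: Mapping) -> SummaryProfile:
    """Summarize the reference cohort variable-by-variable.

    Continuous variables get the five-number summary with
    linear-interpolation quartiles; categorical and binary variables get
    relative category frequencies.  The index case's values are carried
    through untouched.
    """
    if len(matrix) == 0:
        raise ValueError("cannot summarize an empty reference cohort")
    out = []
    for var in matrix.spec.variables:
        col = matrix.data[var.name]
        idx_val = index_case.get(var.name) if hasattr(index_case, "get") else index_case[var.name]
        if var.kind == "continuous":
            vals = col.astype(float).dropna().to_numpy()
            mn, q1, med, q3, mx = np.percentile(vals, [0, 25, 50, 75, 100])
            out.append(VariableSummary(
                var.name, var.kind, idx_val,
                minimum=float(mn), q1=float(q1), median=float(med),
                q3=float(q3), maximum=float(mx),
            ))
        else:
            freqs = col.value_counts(normalize=True, dropna=True)
            out.append(VariableSummary(
                var.name, var.kind, idx_val,
                frequencies={k: float(v) for k, v in freqs.items()},
            ))
    return SummaryProfile(out)


def _draw_continuous(ax, y, vs: VariableSummary) -> None:
    span = vs.maximum - vs.minimum
    if span == 0:  # degenerate: single-valued reference
        ax.barh(y, 1.0, left=0.0, height=0.6, color=_CONT_SHADES[1])
        marker_x = 0.5
        clamped = vs.index_value != vs.minimum
    else:
        edges = [vs.minimum, vs.q1, vs.median, vs.q3, vs.maximum]
        for i in range(4):
            left = (edges[i] - vs.minimum) / span
            width = (edges[i + 1] - edges[i]) / span
            ax.barh(y, width, left=left, height=0.6, color=_CONT_SHADES[i],
                    edgecolor="white", linewidth=0.5)
        x = (float(vs.index_value) - vs.minimum) / span
        clamped = x < 0 or x > 1
        marker_x = min(max(x, 0.0), 1.0)
    ax.plot([marker_x, marker_x], [y - 0.4, y + 0.4], color=_INDEX_COLOR, lw=2.5)
    if clamped:
        ax.annotate("out of range", (marker_x, y + 0.42), fontsize=7,
                    color=_INDEX_COLOR, ha="center")


def _draw_categorical(ax, y, vs: VariableSummary) -> None:
    # segments ordered by descending frequency, ties by category label
    cats = sorted(vs.frequencies, key=lambda c: (-vs.frequencies[c], str(c)))
    left = 0.0
    marker_x = None
    for i, cat in enumerate(cats):
        width = vs.frequencies[cat]
        ax.barh(y, width, left=left, height=0.6,
                color=_CAT_SHADES[i % len(_CAT_SHADES)],
                edgecolor="white", linewidth=0.5)
        if width > 0.04:
            ax.annotate(f"{cat}", (left + width / 2, y), fontsize=7,
                        ha="center", va="center")
        if cat == vs.index_value or str(cat) == str(vs.index_value):
            marker_x = left + width / 2
        left += width
    if marker_x is None:  # index value not present in the reference
        marker_x = 1.0
        ax.annotate("out of range", (marker_x, y + 0.42), fontsize=7,
                    color=_INDEX_COLOR, ha="center")
    ax.plot([marker_x, marker_x], [y - 0.4, y + 0.4], color=_INDEX_COLOR, lw=2.5)


def draw_scale_chart(
    profile: SummaryProfile, output: str | Path, title: str | None = None
) -> Path:
    """Render a scale chart to ``output`` (format from the file suffix).

    One track per variable; continuous tracks are scaled to the reference
    [min, max], an index value outside it is clamped to the track edge and
    annotated.  Returns the written path.
    """
    n = len(profile.variables)
    fig, ax = plt.subplots(figsize=(7, 0.8 * n + 1.2))
    for y, vs in enumerate(reversed(profile.variables)):
        if vs.kind == "continuous":
            _draw_continuous(ax, y, vs)
        else:
            _draw_categorical(ax, y, vs)
    ax.set_yticks(range(n))
    ax.set_yticklabels([vs.name for vs in reversed(profile.variables)])
    ax.set_xlim(-0.02, 1.05)
    ax.set_xticks([])
    for side in ("top", "right", "bottom"):
        ax.spines[side].set_visible(False)
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    output = Path(output)
    output.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(output, dpi=150)
    plt.close(fig)
    return output
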