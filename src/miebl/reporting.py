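"""Criterion reports and multi-criterion comparisons.

``build_report`` turns one row of a criterion table into the five-statement
practitioner report (the ``miebl_re`` output); ``compare`` overlays the
posterior densities of 2-5 criteria on the same trial count (the
``miebl_cp`` output).  This module only formats quantities computed by
:mod:`miebl.posterior` -- it performs no inference of its own.

Display rounding is frozen so the reports match the published wording
byte-for-byte: probabilities are rounded to 4 decimals with trailing zeros
trimmed ("0.143", "0.4665"), percentages to 2 decimals with trailing zeros
trimmed ("54.75%", "90%"), and the separate whole-percent point estimate to
0 decimals ("86%").
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .posterior import (
    CriterionSpec,
    CriterionTable,
    MasterySummary,
    TrialCount,
    posterior_density_grid,
    posterior_from_counts,
)

__all__ = [
    "CriterionReport",
    "ComparisonSet",
    "build_report",
    "compare",
    "render_text",
    "report_to_json",
    "format_probability",
    "format_percent",
    "format_point_percent",
]

DEFAULT_GRID_POINTS = 1025


def format_probability(p: float) -> str:
    """Probability at 4 dp with trailing zeros trimmed: 0.143, 0.4665."""
    s = f"{p:.4f}".rstrip("0").rstrip(".")
    return s if s else "0"


def format_percent(p: float) -> str:
    """Proportion as a percent at 2 dp, trailing zeros trimmed: 54.75, 90."""
    s = f"{100 * p:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def format_point_percent(p: float) -> str:
    """Proportion as a whole percent (point-estimate display): 86."""
    return f"{100 * p:.0f}"


@dataclass(frozen=True)
class CriterionReport:
    """The five-statement report for one performance criterion.

    ``mc`` is the criterion as an integer percent, ``x_required`` the
    matching number of correct items, ``summary`` the posterior quantities,
    ``density`` the posterior density grid for plotting, and ``statements``
    the five display strings (1-indexed in the published output; stored
    0-indexed here).
    """

    n: int
    mc: int
    x_required: int
    summary: MasterySummary
    density: np.ndarray
    statements: tuple[str, str, str, str, str]

    @property
    def label(self) -> str:
        return f"{self.mc}%"


@dataclass(frozen=True)
class ComparisonSet:
    """2-5 criterion reports on the same n, with labelled density overlays."""

    reports: tuple[CriterionReport, ...]

    def __post_init__(self) -> None:
        if not 2 <= len(self.reports) <= 5:
            raise ValueError(
                f"comparison requires 2 to 5 reports, got {len(self.reports)}"
            )
        ns = {r.n for r in self.reports}
        if len(ns) > 1:
            raise ValueError(
                f"all compared reports must share the same number of trials, "
                f"got n values {sorted(ns)}"
            )

    @property
    def n(self) -> int:
        return self.reports[0].n

    @property
    def overlay(self) -> list[tuple[str, np.ndarray]]:
        return [(r.label, r.density) for r in self.reports]

    def to_long_records(self) -> list[tuple[str, float, float]]:
        """(label, mastery, density) rows for a long-format TSV dump."""
        return [
            (label, float(m), float(d))
            for label, grid in self.overlay
            for m, d in grid
        ]


def _normalize_mc(mc: float) -> int:
    """Accept 80 (percent) or 0.8 (fraction); values <= 1 are fractions."""
    pct = mc * 100.0 if mc <= 1.0 else mc
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"criterion must be within [0, 100]%, got {mc!r}")
    if abs(pct - round(pct)) > 1e-9:
        raise ValueError(f"criterion percent must be an integer, got {pct}")
    return round(pct)


def build_report(
    table: CriterionTable,
    mc: float,
    npoints: int = DEFAULT_GRID_POINTS,
) -> CriterionReport:
    """Five-statement report for criterion ``mc`` (integer percent) on ``table``.

    The quantities come from the table row with x = mc/100 * n; a criterion
    that does not correspond to a whole number of items (85% of 10 trials)
    is rejected with the attainable alternatives listed.
    """
    mc_pct = _normalize_mc(mc)
    spec = CriterionSpec.from_percent(mc_pct, table.n)  # validates integrality
    row = table.row(spec.x_required)
    post = posterior_from_counts(TrialCount(n=table.n, x=spec.x_required), table.prior)
    density = posterior_density_grid(post, npoints)
    report = CriterionReport(
        n=table.n,
        mc=mc_pct,
        x_required=spec.x_required,
        summary=row.summary,
        density=density,
        statements=_statements(table.n, mc_pct, spec.x_required, row.summary),
    )
    return report


def _statements(
    n: int, mc: int, x: int, s: MasterySummary
) -> tuple[str, str, str, str, str]:
    return (
        f"Performance criterion of {mc}% ({x} out of {n} items)",
        "If the student meets this criterion, then:",
        f"The probability that the true mastery is at least "
        f"{format_percent(s.p_star)}% is {format_probability(s.b)}.",
        f"There is a {format_percent(1 - s.a)}% chance that the true mastery "
        f"is at least {format_percent(s.lower_bound)}%.",
        f"The average mastery of comparable students reaching this criterion "
        f"is {format_percent(s.mean)}%.",
    )


def render_text(report: CriterionReport) -> str:
    """The report as five numbered lines, one per statement."""
    return "\n".join(
        f"[{i}] \"{stmt}\"" for i, stmt in enumerate(report.statements, start=1)
    )


def report_to_json(report: CriterionReport) -> str:
    """JSON rendering with unrounded values for programmatic use."""
    s = report.summary
    return json.dumps(
        {
            "n": report.n,
            "mc": report.mc,
            "x": report.x_required,
            "p_star": s.p_star,
            "a": s.a,
            "b": s.b,
            "lower_bound": s.lower_bound,
            "mean": s.mean,
            "statements": list(report.statements),
        },
        indent=2,
    )


def compare(*reports: CriterionReport) -> ComparisonSet:
    """Overlay 2-5 criterion reports sharing the same n (Fig. 2-style)."""
    return ComparisonSet(reports=tuple(reports))


def plot_comparison(cmp: ComparisonSet, path: str | None = None):
    """Render the density overlay with matplotlib (thin optional layer).

    The tested surface is the grid data; this helper only draws it.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, grid in cmp.overlay:
        ax.plot(grid[:, 0], grid[:, 1], label=label)
    ax.set_xlabel("True mastery level")
    ax.set_ylabel("Posterior density")
    ax.set_title(f"Posterior of true mastery by performance criterion (n={cmp.n})")
    ax.legend(title="Criterion")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
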