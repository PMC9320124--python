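"""Markdown rendering of the pipeline's reporting surfaces.

Mirrors the analysis's three tables and substitution curves: cohort
descriptives (M (SD) or %), geometric-mean band minutes with their share of
the 960-min day, per-band beta_ILR1 with CI and p per stratum, and the
substitution curves.  All numbers are rounded here, at render time only;
machine outputs carry full precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bands import BAND_LABELS
from .composition import DAY_MINUTES, geometric_mean_composition

__all__ = ["composition_table", "render_report"]


def composition_table(records: pd.DataFrame, band_labels=BAND_LABELS) -> pd.DataFrame:
    """Geometric-mean minutes and percentage of the day per band, by stratum."""
    out = {}
    strata = [("all", records)] + [
        (s, g) for s, g in records.groupby("sex") if len(g) >= 2
    ]
    for name, g in strata:
        gm = geometric_mean_composition(g[list(band_labels)].to_numpy(float))
        out[f"{name}_min"] = gm
        out[f"{name}_pct"] = 100.0 * gm / DAY_MINUTES
    return pd.DataFrame(out, index=list(band_labels))


def _fmt(df: pd.DataFrame, dp: int = 1) -> str:
    return df.round(dp).to_markdown()


def render_report(
    cohort: pd.DataFrame | None = None,
    cascade: dict | None = None,
    descriptives: pd.DataFrame | None = None,
    scan_tables: dict | None = None,
    omnibus: dict | None = None,
    curves: dict | None = None,
    diagnostics: dict | None = None,
) -> str:
    """Assemble a Markdown summary; missing stages are noted, not hidden."""
    lines = ["# Intensity-spectrum compositional analysis report", ""]

    if cascade is not None:
        lines += ["## Exclusion cascade", ""]
        for k, v in cascade.items():
            lines.append(f"- {k.replace('_', ' ')}: {v}")
        lines.append("")
    else:
        lines += ["*(no exclusion-cascade stage output)*", ""]

    if descriptives is not None:
        lines += ["## Cohort descriptives (M / SD / %)", "", _fmt(descriptives, 2), ""]

    if cohort is not None:
        lines += [
            "## Geometric-mean band minutes (closed to 960 min/day)",
            "",
            _fmt(composition_table(cohort)),
            "",
        ]
    else:
        lines += ["*(no cohort stage output; composition table omitted)*", ""]

    if scan_tables:
        lines += ["## Per-band first-pivot-coordinate associations", ""]
        if omnibus:
            lines.append(
                f"Omnibus ILR block test: F({omnibus['df1']}, {omnibus['df2']}) = "
                f"{omnibus['F']:.1f}, p = {omnibus['p']:.3g}"
            )
            lines.append("")
        for stratum, table in scan_tables.items():
            lines += [f"### {stratum}", "", _fmt(table.set_index("band"), 2), ""]
    else:
        lines += ["*(no model stage output)*", ""]

    if curves:
        lines += ["## One-for-remaining substitution curves", ""]
        for key, curve in curves.items():
            lines += [f"### {key}", "", _fmt(curve.set_index("minutes"), 2), ""]
    else:
        lines += ["*(no substitution stage output)*", ""]

    if diagnostics:
        lines += ["## Diagnostics", ""]
        if "vif" in diagnostics:
            v = diagnostics["vif"]
            lines.append(
                f"- VIF range: {np.min(v):.2f} to {np.max(v):.2f}"
            )
        if "icc_school" in diagnostics:
            lines.append(f"- School ICC (one-way): {diagnostics['icc_school']:.2f}")
        lines.append("")

    return "\n".join(lines)
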