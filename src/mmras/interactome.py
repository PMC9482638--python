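"""BioID2 SILAC interactome processing and CRISPR integration.

Proximity-labeling (BioID2) baits biotinylate their neighbors; SILAC MS
quantifies each protein's log2 enrichment over an empty-vector control.
Combining that enrichment with per-gene essentiality (CSS) defines the
"essential interactome": proteins both proximal to the bait and required
for growth.  Knockdown-vs-control comparisons across cell lines define the
differential interactome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "filter_silac",
    "combine_baits",
    "essential_interactome",
    "venn_intersect",
    "differential_interactome",
]

VENN_REGIONS = ("A_only", "B_only", "C_only", "AB_only", "AC_only", "BC_only", "ABC")


def filter_silac(
    table: pd.DataFrame, min_ratio_count: int = 2, flag_column: str | None = "flagged"
) -> pd.DataFrame:
    """Drop low-confidence rows: ratio_count below threshold, and any rows
    marked in the contaminant/decoy flag column (if present)."""
    if "ratio_count" not in table.columns:
        raise ValueError("SILAC table must have a ratio_count column")
    keep = table["ratio_count"] >= min_ratio_count
    if flag_column and flag_column in table.columns:
        keep &= ~table[flag_column].astype(bool)
    return table[keep].reset_index(drop=True)


def combine_baits(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average log2 enrichment per protein across bait/cell-line tables.

    Proteins absent from a table contribute no value there (mean over
    observed values only); ``n_observed`` records coverage.
    """
    if not tables:
        raise ValueError("combine_baits requires at least one table")
    stacked = pd.concat([t[["protein", "log2fc"]] for t in tables], ignore_index=True)
    out = (
        stacked.groupby("protein", sort=True)["log2fc"]
        .agg(log2fc="mean", n_observed="size")
        .reset_index()
    )
    out["n_observed"] = out["n_observed"].astype(int)
    return out


def essential_interactome(
    enrichment: pd.DataFrame,
    css_table: pd.DataFrame,
    css_max: float = -1.0,
    fc_min: float = 1.0,
) -> pd.DataFrame:
    """Proteins with CSS <= css_max and log2 enrichment >= fc_min.

    Thresholds are inclusive.  Proteins without a CSS (no matching gene
    symbol) are excluded; their count is recorded in ``.attrs['n_no_css']``.
    """
    css = css_table.set_index("gene")["css"]
    merged = enrichment.merge(
        css.rename("css"), left_on="protein", right_index=True, how="left"
    )
    n_no_css = int(merged["css"].isna().sum())
    scored = merged.dropna(subset=["css"])
    if scored.empty:
        raise ValueError("no proteins share a symbol with the CSS table")
    members = scored[(scored["css"] <= css_max) & (scored["log2fc"] >= fc_min)]
    out = members.reset_index(drop=True)
    out.attrs["css_max"] = css_max
    out.attrs["fc_min"] = fc_min
    out.attrs["n_no_css"] = n_no_css
    return out


def venn_intersect(set_a: set, set_b: set, set_c: set) -> dict:
    """Three-way Venn decomposition: the 7 disjoint region memberships.

    Region counts always sum to \\|A ∪ B ∪ C\\|.
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    regions = {
        "A_only": a - b - c,
        "B_only": b - a - c,
        "C_only": c - a - b,
        "AB_only": (a & b) - c,
        "AC_only": (a & c) - b,
        "BC_only": (b & c) - a,
        "ABC": a & b & c,
    }
    return {
        "memberships": regions,
        "counts": {k: len(v) for k, v in regions.items()},
        "triple_intersection": regions["ABC"],
    }


def differential_interactome(
    control_tables: dict[str, pd.DataFrame],
    knockdown_tables: dict[str, pd.DataFrame],
    delta: float = 0.5,
    min_lines: int = 2,
) -> pd.DataFrame:
    """Proteins whose bait enrichment shifts on knockdown in >= min_lines
    cell lines with consistent sign.

    Tables are dicts keyed by cell line; each line must appear in both.
    Per protein per line, the change is log2fc(knockdown) - log2fc(control);
    a protein is reported when \\|change\\| >= delta in at least ``min_lines``
    lines all in the same direction.
    """
    if set(control_tables) != set(knockdown_tables):
        raise ValueError(
            "control and knockdown tables must cover the same cell lines; got "
            f"{sorted(control_tables)} vs {sorted(knockdown_tables)}"
        )
    per_line = {}
    for line in control_tables:
        ctrl = control_tables[line].set_index("protein")["log2fc"]
        kd = knockdown_tables[line].set_index("protein")["log2fc"]
        shared = ctrl.index.intersection(kd.index)
        per_line[line] = (kd.loc[shared] - ctrl.loc[shared]).rename(line)
    deltas = pd.concat(per_line.values(), axis=1)

    rows = []
    for protein, row in deltas.iterrows():
        vals = row.dropna()
        dec = vals[vals <= -delta]
        inc = vals[vals >= delta]
        # sign consistency: any opposite-direction change >= delta disqualifies
        if len(dec) >= min_lines and len(inc) == 0:
            rows.append((protein, dict(dec), len(dec), "decreased"))
        elif len(inc) >= min_lines and len(dec) == 0:
            rows.append((protein, dict(inc), len(inc), "increased"))
    out = pd.DataFrame(
        rows, columns=["protein", "delta_log2fc", "n_lines_changed", "direction"]
    )
    out.attrs["delta"] = delta
    out.attrs["min_lines"] = min_lines
    return out
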