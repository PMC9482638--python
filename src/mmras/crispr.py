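"""CRISPR screen score (CSS) computation from sgRNA count tables.

The CSS is a per-gene essentiality statistic: guide-level log2 fold changes
(Day 21 vs Day 0 for growth screens, low vs high for FACS-sort screens,
condition vs control for modifier screens) are averaged per gene, then the
gene-level distribution is centered on its kernel-density mode and scaled
by the root-mean-square deviation (RMSD) from that mode.  Mode-centering
(rather than mean/median) is robust to the asymmetric dropout tail that
essential genes create: the bulk of genes are inert and their density peak
defines zero.

Counts are normalized with median-of-ratios size factors before the log
ratio; replicates are averaged on the normalized-count scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "size_factors",
    "guide_log2fc",
    "apply_blocklist",
    "gene_level_lfc",
    "kde_mode",
    "css_normalize",
    "score_screen",
    "sorted_screen_score",
    "modifier_delta",
    "read_count_table",
    "read_blocklist",
]

META_COLS = ("guide_id", "gene")
MIN_GENES_FOR_MODE = 50
KDE_GRID_POINTS = 2048


class NormalizationError(ValueError):
    pass


class ScoringError(ValueError):
    pass


def read_count_table(path) -> pd.DataFrame:
    """Read a tab-delimited guide count table (guide_id, gene, samples...)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing required columns: {missing}")
    return table


def read_blocklist(path) -> set[str]:
    """Read a plain-text blocklist, one guide_id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def _sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


def size_factors(table: pd.DataFrame, samples: list[str] | None = None) -> pd.Series:
    """Median-of-ratios size factors (one positive scalar per sample).

    factor_j = median over guides of count_ij / geometric_mean_i(counts),
    computed over guides with nonzero counts in every sample.
    """
    samples = samples if samples is not None else _sample_columns(table)
    if len(samples) < 2:
        raise NormalizationError("size factors require >= 2 samples")
    counts = table[samples].to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise NormalizationError("no guide has nonzero counts in all samples")
    c = counts[all_nonzero]
    log_geomean = np.log(c).mean(axis=1)
    factors = np.exp(np.median(np.log(c) - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=samples, name="size_factor")


def guide_log2fc(
    table: pd.DataFrame,
    numerator: list[str],
    denominator: list[str],
    pseudocount: float = 0.5,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-guide log2 fold change between two sample groups.

    Counts are divided by size factors, replicates averaged within each
    group on the normalized scale, and the pseudocount added to both group
    means before the log2 ratio.
    """
    for group, name in ((numerator, "numerator"), (denominator, "denominator")):
        absent = [s for s in group if s not in table.columns]
        if not group or absent:
            raise ValueError(f"{name} group missing from table: {absent or group}")
    if factors is None:
        factors = size_factors(table, sorted(set(numerator) | set(denominator)))
    norm = table[list(factors.index)].to_numpy(dtype=float) / factors.to_numpy()
    norm = pd.DataFrame(norm, columns=list(factors.index), index=table.index)
    mean_num = norm[numerator].mean(axis=1)
    mean_den = norm[denominator].mean(axis=1)
    lfc = np.log2((mean_num + pseudocount) / (mean_den + pseudocount))
    return pd.DataFrame(
        {"guide_id": table["guide_id"], "gene": table["gene"], "lfc": lfc}
    ).reset_index(drop=True)


def apply_blocklist(
    guides: pd.DataFrame, blocklist: set[str]
) -> tuple[pd.DataFrame, dict]:
    """Remove blocklisted guides; report how many and what fraction.

    Unknown blocklist ids (not in the table) are reported, not fatal.
    """
    present = set(guides["guide_id"])
    unknown = sorted(blocklist - present)
    keep = ~guides["guide_id"].isin(blocklist)
    n_total = len(guides)
    n_removed = int((~keep).sum())
    report = {
        "n_total": n_total,
        "n_removed": n_removed,
        "fraction_removed": n_removed / n_total if n_total else 0.0,
        "unknown_ids": unknown,
    }
    return guides[keep].reset_index(drop=True), report


def gene_level_lfc(guides: pd.DataFrame) -> pd.DataFrame:
    """Average guide log2fc per gene (plain arithmetic mean)."""
    grouped = guides.groupby("gene", sort=True)["lfc"]
    out = grouped.agg(raw_lfc="mean", n_guides_used="size").reset_index()
    out["n_guides_used"] = out["n_guides_used"].astype(int)
    return out


def kde_mode(values: np.ndarray) -> tuple[float, float]:
    """Mode of a sample as the argmax of a Gaussian KDE on a fixed grid.

    Silverman's rule sets the bandwidth; the grid has 2,048 points spanning
    the data range +/- 3 bandwidths.  Argmax ties break toward the grid
    point nearest the sample median.  Returns (mode, grid_spacing).
    """
    values = np.asarray(values, dtype=float)
    kde = stats.gaussian_kde(values, bw_method="silverman")
    bw = np.sqrt(float(kde.covariance[0, 0]))
    lo = values.min() - 3.0 * bw
    hi = values.max() + 3.0 * bw
    grid = np.linspace(lo, hi, KDE_GRID_POINTS)
    density = kde(grid)
    best = np.flatnonzero(density == density.max())
    if len(best) > 1:
        med = np.median(values)
        best = best[np.argmin(np.abs(grid[best] - med))]
    else:
        best = best[0]
    return float(grid[best]), float(grid[1] - grid[0])


def css_normalize(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Normalize gene-level LFCs to CRISPR screen scores (CSS).

    css = (raw_lfc - mode) / RMSD, where mode is the KDE mode of the
    raw_lfc distribution and RMSD = sqrt(mean((raw_lfc - mode)^2)) over all
    scored genes (1/n denominator).  The result has KDE mode ~0 and
    RMSD-from-mode exactly 1.
    """
    if len(gene_table) < MIN_GENES_FOR_MODE:
        raise ScoringError(
            f"css_normalize needs >= {MIN_GENES_FOR_MODE} genes for mode estimation, "
            f"got {len(gene_table)}"
        )
    raw = gene_table["raw_lfc"].to_numpy(dtype=float)
    if not np.isfinite(raw).all():
        raise ScoringError("raw_lfc contains non-finite values")
    mode, _ = kde_mode(raw)
    rmsd = np.sqrt(np.mean((raw - mode) ** 2))
    if rmsd == 0:
        raise ScoringError("raw_lfc distribution is degenerate (RMSD = 0)")
    out = gene_table.copy()
    out["css"] = (raw - mode) / rmsd
    out.attrs["mode"] = mode
    out.attrs["rmsd"] = rmsd
    return out


@dataclass
class ScreenResult:
    """Full screen scoring output: gene table plus processing report."""

    genes: pd.DataFrame
    blocklist_report: dict
    size_factors: pd.Series


def score_screen(
    table: pd.DataFrame,
    numerator: list[str],
    denominator: list[str],
    blocklist: set[str] | None = None,
    pseudocount: float = 0.5,
) -> ScreenResult:
    """End-to-end CSS pipeline: blocklist, normalize, LFC, average, CSS.

    The blocklist is applied to the count table before size-factor
    estimation, so removed guides never influence any downstream number.
    """
    table, report = apply_blocklist(table, blocklist or set())
    factors = size_factors(table, sorted(set(numerator) | set(denominator)))
    guides = guide_log2fc(table, numerator, denominator, pseudocount, factors)
    genes = css_normalize(gene_level_lfc(guides))
    return ScreenResult(genes=genes, blocklist_report=report, size_factors=factors)


def sorted_screen_score(
    table: pd.DataFrame,
    low: list[str],
    high: list[str],
    blocklist: set[str] | None = None,
    pseudocount: float = 0.5,
) -> ScreenResult:
    """CSS for a FACS-sort screen: numerator = low population, denominator =
    high, so positive CSS marks guides enriched in the low-signal sort (genes
    required for the sorted phenotype)."""
    return score_screen(table, low, high, blocklist, pseudocount)


def modifier_delta(
    css_condition: pd.DataFrame, css_control: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene change in CSS between a modifier condition and its control.

    Genes missing in either table are dropped (recorded in .attrs).
    """
    a = css_condition.set_index("gene")["css"]
    b = css_control.set_index("gene")["css"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between condition and control tables")
    out = pd.DataFrame(
        {
            "gene": shared,
            "css_condition": a.loc[shared].to_numpy(),
            "css_control": b.loc[shared].to_numpy(),
        }
    )
    out["delta_css"] = out["css_condition"] - out["css_control"]
    out.attrs["n_dropped"] = (len(a) - len(shared)) + (len(b) - len(shared))
    return out
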