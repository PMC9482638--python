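"""Drug-combination synergy scoring and drug-target set enrichment (DTSEA).

A combination screen measures viability on an n x m dose grid whose first
row and column are the single agents.  The highest-single-agent (HSA) null
says a combination well should kill no more than the stronger of its two
single agents; ExcessHSA is the observed effect minus that expectation, so
positive excess is synergy and negative is antagonism.  Aggregating
per-well excess over the combination wells scores each drug pair; ranking
a drug library by that score and running a weighted pre-ranked enrichment
over sets of drugs sharing an annotated target (DTSEA) asks which targets
are over-represented among the synergizers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "normalize_plate",
    "matrix_from_long",
    "excess_hsa",
    "rank_partners",
    "build_target_sets",
    "read_gmt",
    "preranked_enrichment",
    "SynergyResult",
    "EnrichmentResult",
]


@dataclass
class SynergyResult:
    drug_a: str
    drug_b: str
    cell_line: str
    excess_matrix: pd.DataFrame  # per-well excess effect, percent units
    aggregate: float  # sum over combination wells, percent units
    n_combination_wells: int


@dataclass
class EnrichmentResult:
    target: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    n_drugs: int
    leading_edge: list[str]


def normalize_plate(raw: np.ndarray, dmso_wells: np.ndarray) -> np.ndarray:
    """Convert raw luminescence to fraction-of-control viability.

    viability = raw / mean(DMSO control wells).
    """
    dmso_wells = np.asarray(dmso_wells, dtype=float)
    if dmso_wells.size == 0:
        raise ValueError("at least one DMSO control well is required")
    dmso_mean = dmso_wells.mean()
    if dmso_mean <= 0:
        raise ValueError("DMSO control mean must be positive")
    return np.asarray(raw, dtype=float) / dmso_mean


def matrix_from_long(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long-format well table into a doses_a x doses_b viability
    grid (rows = dose_a ascending, cols = dose_b ascending)."""
    grid = table.pivot_table(index="dose_a", columns="dose_b", values="viability")
    return grid.sort_index(axis=0).sort_index(axis=1)


def excess_hsa(viability: pd.DataFrame, agg: str = "sum") -> SynergyResult | pd.DataFrame:
    """Per-well and aggregate Excess-over-HSA for one viability grid.

    Effect E = 1 - V.  The HSA expectation for well (i, j) is
    max(E(i, 0), E(0, j)); excess = E(i, j) - HSA, reported in percent
    units (x100).  The aggregate is the sum (default; ``agg='mean'``
    available) of per-well excess over wells with both doses > 0.

    ``viability`` must be a doses_a x doses_b grid whose first row and
    column (dose 0) are the single-agent margins.
    """
    v = viability.to_numpy(dtype=float)
    if viability.index[0] != 0 or viability.columns[0] != 0:
        raise ValueError("viability grid must include zero-dose single-agent margins")
    if np.isnan(v).any():
        raise ValueError("viability grid has missing wells")
    effect = 1.0 - v
    hsa = np.maximum.outer(effect[:, 0], effect[0, :])
    excess = (effect - hsa) * 100.0
    combo = np.zeros_like(excess, dtype=bool)
    combo[1:, 1:] = True
    if agg == "sum":
        aggregate = float(excess[combo].sum())
    elif agg == "mean":
        aggregate = float(excess[combo].mean())
    else:
        raise ValueError("agg must be 'sum' or 'mean'")
    excess_df = pd.DataFrame(excess, index=viability.index, columns=viability.columns)
    return SynergyResult(
        drug_a=viability.attrs.get("drug_a", ""),
        drug_b=viability.attrs.get("drug_b", ""),
        cell_line=viability.attrs.get("cell_line", ""),
        excess_matrix=excess_df,
        aggregate=aggregate,
        n_combination_wells=int(combo.sum()),
    )


def rank_partners(aggregates: pd.DataFrame) -> pd.DataFrame:
    """Rank combination partners by mean aggregate ExcessHSA across lines.

    ``aggregates`` has columns ``drug, cell_line, aggregate``.  Drugs not
    scored in every cell line are excluded (count in .attrs).  Ties break
    lexicographically by drug name; descending score order.
    """
    if aggregates.empty:
        raise ValueError("no synergy results to rank")
    n_lines = aggregates["cell_line"].nunique()
    per_drug = aggregates.groupby("drug")["aggregate"].agg(["mean", "size"])
    complete = per_drug[per_drug["size"] == n_lines]
    out = (
        complete["mean"]
        .rename("score")
        .reset_index()
        .sort_values(["score", "drug"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["n_excluded"] = int(len(per_drug) - len(complete))
    return out


def build_target_sets(
    annotations: pd.DataFrame, min_set_size: int = 3
) -> dict[str, set[str]]:
    """Invert a drug -> target annotation to target -> drug sets, keeping
    targets covered by at least ``min_set_size`` drugs.

    ``annotations`` has columns ``drug, target`` (one row per pair).
    """
    sets: dict[str, set[str]] = {}
    for target, group in annotations.groupby("target"):
        drugs = set(group["drug"])
        if len(drugs) >= min_set_size:
            sets[target] = drugs
    return sets


def read_gmt(path) -> dict[str, set[str]]:
    """Read set-per-line GMT: name <tab> description <tab> members..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def _running_es(
    ranked_drugs: np.ndarray, scores: np.ndarray, members: set[str], weight: float
) -> tuple[float, int]:
    """Weighted KS running-sum enrichment score and index of the extremum.

    Hits increment by |score|^weight normalized to sum 1 over set members;
    misses decrement by 1/(N - N_hit).
    """
    is_hit = np.isin(ranked_drugs, list(members))
    n = len(ranked_drugs)
    n_hit = int(is_hit.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("set must hit a strict subset of the ranked universe")
    w = np.abs(scores) ** weight
    hit_sum = w[is_hit].sum()
    if hit_sum == 0:  # all member scores zero at weight > 0: fall back to equal
        steps = np.where(is_hit, 1.0 / n_hit, -1.0 / (n - n_hit))
    else:
        steps = np.where(is_hit, w / hit_sum, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx


def preranked_enrichment(
    ranked_scores: pd.Series,
    sets: dict[str, set[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Pre-ranked set enrichment (GSEA-style) over drug-target sets.

    ``ranked_scores`` maps drug -> ranking score; drugs are ordered by
    score descending (ties by name for determinism).  The null distribution
    comes from permuting set-membership labels: for each permutation a
    random same-size subset of the universe replaces the true set.  NES is
    ES divided by the mean |null ES| of the same sign; p_nominal is the
    same-sign null tail fraction; FDR q follows the standard same-sign NES
    tail-ratio procedure.  The leading edge is the member drugs at or
    before the running-sum extremum (after it for negative ES).
    """
    scores = ranked_scores.sort_index()
    order = np.lexsort((scores.index.to_numpy(), -scores.to_numpy()))
    ranked_drugs = scores.index.to_numpy()[order]
    ranked_vals = scores.to_numpy()[order]
    if not np.isfinite(ranked_vals).all():
        raise ValueError("ranking scores must be finite")
    n = len(ranked_drugs)
    rng = np.random.default_rng(seed)

    rows = []
    null_nes_all: list[np.ndarray] = []
    for target in sorted(sets):
        members = sets[target] & set(ranked_drugs)
        if len(members) < min_set_size:
            continue
        es, idx = _running_es(ranked_drugs, ranked_vals, members, weight)
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            perm = set(rng.choice(ranked_drugs, size=len(members), replace=False))
            null_es[b], _ = _running_es(ranked_drugs, ranked_vals, perm, weight)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if len(same_sign) == 0:
            p_nom, nes, null_nes = 0.0, np.inf * np.sign(es), np.array([])
        else:
            p_nom = float(np.mean(np.abs(same_sign) >= abs(es)))
            mean_abs = np.abs(same_sign).mean()
            nes = es / mean_abs
            null_nes = same_sign / mean_abs
        null_nes_all.append(null_nes)

        is_hit = np.isin(ranked_drugs, list(members))
        if es >= 0:
            leading = list(ranked_drugs[: idx + 1][is_hit[: idx + 1]])
        else:
            leading = list(ranked_drugs[idx:][is_hit[idx:]])
        rows.append(
            {
                "target": target,
                "es": es,
                "nes": nes,
                "p_nominal": p_nom,
                "n_drugs": len(members),
                "leading_edge": leading,
            }
        )

    out = pd.DataFrame(rows)
    if out.empty:
        return out
    # FDR q: same-sign tail ratio of pooled null NES vs observed NES
    pooled_null = np.concatenate(null_nes_all) if null_nes_all else np.array([])
    obs_nes = out["nes"].to_numpy()
    q_vals = np.empty(len(out))
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            q_vals[i] = 0.0
            continue
        same_null = pooled_null[np.sign(pooled_null) == np.sign(nes)]
        same_obs = obs_nes[np.sign(obs_nes) == np.sign(nes)]
        null_tail = np.mean(np.abs(same_null) >= abs(nes)) if len(same_null) else 0.0
        obs_tail = np.mean(np.abs(same_obs) >= abs(nes))
        q_vals[i] = min(null_tail / obs_tail, 1.0) if obs_tail > 0 else 0.0
    out["fdr_q"] = q_vals
    return out.sort_values("nes", ascending=False, kind="mergesort").reset_index(drop=True)
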