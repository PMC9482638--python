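"""Synthetic-data generators with planted ground truth.

Every analysis stage in this package (CRISPR screen scoring, SILAC
interactome filtering, dose-matrix synergy, signature/survival modeling,
PLA statistics) has a generator here that emulates its input format and
emits truth labels alongside the data, so each stage can be exercised
end-to-end as a parameter-recovery problem.

All generators are pure functions of their configuration: the same config
(including its seed) produces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScreenSimConfig",
    "SilacSimConfig",
    "MatrixSimConfig",
    "SurvivalSimConfig",
    "simulate_crispr_screen",
    "simulate_silac_table",
    "simulate_dose_matrix",
    "simulate_pla_table",
    "simulate_expression_survival",
]


class ConfigurationError(ValueError):
    """Raised when a simulation config violates its invariants."""


def _negbin(rng: np.random.Generator, mean, dispersion, size=None):
    """Negative binomial draws parameterized by mean and dispersion alpha,
    with Var = mu + alpha * mu^2 (the convention used by count-model GLMs)."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


# ---------------------------------------------------------------------------
# CRISPR dropout screens
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSimConfig:
    """Configuration for a pooled CRISPR dropout screen (Day 0 vs Day 21).

    ``essential_effect`` is the per-gene log2 dropout over the 21-day screen
    (negative for essential genes).  ``library_mean_count`` emulates screens
    run at deep guide coverage (hundreds of reads per guide).
    """

    n_genes: int = 1000
    guides_per_gene: int = 4
    n_essential: int = 50
    essential_effect: float = -2.0
    guide_efficiency_sd: float = 0.3
    library_mean_count: float = 500.0
    dispersion: float = 0.05
    replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.guides_per_gene < 1:
            raise ConfigurationError("n_genes and guides_per_gene must be >= 1")
        if not 0 <= self.n_essential <= self.n_genes:
            raise ConfigurationError("n_essential must be in [0, n_genes]")
        if self.library_mean_count <= 0:
            raise ConfigurationError("library_mean_count must be > 0")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")


def simulate_crispr_screen(cfg: ScreenSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a guide-count table for a growth (dropout) screen.

    Day 0 counts are negative binomial around the library mean.  Day 21
    counts are generated by Poisson thinning of each replicate's own Day 0
    abundance scaled by ``2**(gene effect + guide-level Gaussian jitter)``,
    so guide-level correlation between timepoints matches real screens.
    Non-essential genes have effect exactly 0.

    Returns
    -------
    counts : DataFrame with columns ``guide_id``, ``gene`` and one column
        per sample labeled ``day{0,21}_rep{r}``.
    truth : DataFrame with columns ``gene``, ``is_essential``, ``effect``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = np.array([f"GENE{i:05d}" for i in range(cfg.n_genes)])
    essential_idx = rng.choice(cfg.n_genes, size=cfg.n_essential, replace=False)
    effect = np.zeros(cfg.n_genes)
    effect[essential_idx] = cfg.essential_effect

    n_guides = cfg.n_genes * cfg.guides_per_gene
    guide_gene_idx = np.repeat(np.arange(cfg.n_genes), cfg.guides_per_gene)
    guide_ids = np.array(
        [f"{genes[g]}_sg{k + 1}" for g, k in
         zip(guide_gene_idx, np.tile(np.arange(cfg.guides_per_gene), cfg.n_genes))]
    )
    # guide-level efficacy jitter on the log2 dropout, fixed per guide
    jitter = rng.normal(0.0, cfg.guide_efficiency_sd, size=n_guides)
    guide_effect = effect[guide_gene_idx] + np.where(
        effect[guide_gene_idx] != 0.0, jitter, 0.0
    )

    data = {"guide_id": guide_ids, "gene": genes[guide_gene_idx]}
    scale = np.power(2.0, guide_effect)
    for rep in range(1, cfg.replicates + 1):
        day0 = _negbin(rng, cfg.library_mean_count, cfg.dispersion, size=n_guides)
        day21 = rng.poisson(day0 * scale)
        data[f"day0_rep{rep}"] = day0
        data[f"day21_rep{rep}"] = day21

    counts = pd.DataFrame(data)
    truth = pd.DataFrame(
        {"gene": genes, "is_essential": effect != 0.0, "effect": effect}
    )
    return counts, truth


# ---------------------------------------------------------------------------
# BioID2 SILAC enrichment tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SilacSimConfig:
    """Configuration for a bait-vs-empty-vector SILAC enrichment table."""

    n_proteins: int = 1000
    n_true_interactors: int = 50
    interactor_log2fc_mean: float = 3.0
    interactor_log2fc_sd: float = 0.5
    background_sd: float = 0.5
    ratio_count_weights: tuple[float, ...] = (0.15, 0.25, 0.3, 0.2, 0.1)
    bait: str = "BAIT"
    cell_line: str = "LINE1"
    condition: str = "shCTRL"
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if not 0 <= self.n_true_interactors <= self.n_proteins:
            raise ConfigurationError("n_true_interactors must be in [0, n_proteins]")
        if self.background_sd <= 0:
            raise ConfigurationError("background_sd must be > 0")
        w = np.asarray(self.ratio_count_weights, dtype=float)
        if w.ndim != 1 or len(w) == 0 or (w < 0).any() or w.sum() <= 0:
            raise ConfigurationError("ratio_count_weights must be non-negative and sum > 0")


def simulate_silac_table(cfg: SilacSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a per-protein SILAC log2 bait/control enrichment table.

    True interactors draw log2fc around ``interactor_log2fc_mean``; the
    background is centered on 0 with ``background_sd``.  Ratio counts
    (number of quantified peptide ratios) are drawn from the categorical
    distribution over 1..len(weights); every row has ratio_count >= 1.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    proteins = np.array([f"PROT{i:05d}" for i in range(cfg.n_proteins)])
    interactor_idx = rng.choice(cfg.n_proteins, size=cfg.n_true_interactors, replace=False)
    is_interactor = np.zeros(cfg.n_proteins, dtype=bool)
    is_interactor[interactor_idx] = True

    log2fc = rng.normal(0.0, cfg.background_sd, size=cfg.n_proteins)
    log2fc[is_interactor] = rng.normal(
        cfg.interactor_log2fc_mean, cfg.interactor_log2fc_sd, size=cfg.n_true_interactors
    )
    w = np.asarray(cfg.ratio_count_weights, dtype=float)
    ratio_count = rng.choice(np.arange(1, len(w) + 1), size=cfg.n_proteins, p=w / w.sum())

    table = pd.DataFrame(
        {
            "protein": proteins,
            "log2fc": log2fc,
            "ratio_count": ratio_count,
            "bait": cfg.bait,
            "cell_line": cfg.cell_line,
            "condition": cfg.condition,
        }
    )
    truth = pd.DataFrame({"protein": proteins, "is_interactor": is_interactor})
    return table, truth


# ---------------------------------------------------------------------------
# Dose-response viability matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatrixSimConfig:
    """Configuration for an n x m combination viability matrix.

    Single agents follow a Hill dose-response; combination wells sit at the
    highest-single-agent (HSA) expectation minus the planted per-well
    ``synergy_excess`` (on the viability scale), plus plate noise. Dose
    vectors start at 0 (the untreated margin); the defaults use the 6-point
    layout of a 5-dose range with constant 1:4 dilution plus the zero dose.
    """

    doses_a: tuple[float, ...] = (0.0, 1.0, 4.0, 16.0, 64.0, 256.0)
    doses_b: tuple[float, ...] = (0.0, 1.0, 4.0, 16.0, 64.0, 256.0)
    hill_params_a: tuple[float, float, float] = (16.0, 1.0, 0.6)  # ec50, slope, max_effect
    hill_params_b: tuple[float, float, float] = (16.0, 1.0, 0.6)
    synergy_excess: float = 0.0
    noise_sd: float = 0.0
    drug_a: str = "drugA"
    drug_b: str = "drugB"
    cell_line: str = "LINE1"
    seed: int = 0

    def validate(self) -> None:
        for doses in (self.doses_a, self.doses_b):
            d = np.asarray(doses, dtype=float)
            if len(d) < 2 or d[0] != 0.0 or (np.diff(d) <= 0).any():
                raise ConfigurationError(
                    "dose vectors must start at 0 and be strictly increasing"
                )
        for ec50, slope, emax in (self.hill_params_a, self.hill_params_b):
            if ec50 <= 0 or slope <= 0:
                raise ConfigurationError("ec50 and slope must be > 0")
            if not 0.0 <= emax <= 1.0:
                raise ConfigurationError("max_effect must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def _hill_effect(dose, ec50, slope, max_effect):
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ds = np.power(dose, slope)
    return max_effect * ds / (ec50**slope + ds)


def simulate_dose_matrix(cfg: MatrixSimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a combination viability matrix with planted synergy.

    Returns a long-format well table (``drug_a, dose_a, drug_b, dose_b,
    cell_line, viability``) and the matrix of true per-well excess effect
    (positive in combination wells when synergy is planted, 0 elsewhere).
    Viability is clipped to [0, 1.2] to mimic plate noise above control.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    da = np.asarray(cfg.doses_a, dtype=float)
    db = np.asarray(cfg.doses_b, dtype=float)
    ea = _hill_effect(da, *cfg.hill_params_a)  # fraction killed, single agent A
    eb = _hill_effect(db, *cfg.hill_params_b)

    hsa_effect = np.maximum.outer(ea, eb)  # rows = doses_a, cols = doses_b
    combo = np.zeros_like(hsa_effect, dtype=bool)
    combo[1:, 1:] = True
    true_excess = np.where(combo, cfg.synergy_excess, 0.0)

    viability = 1.0 - hsa_effect - true_excess
    if cfg.noise_sd > 0:
        viability = viability + rng.normal(0.0, cfg.noise_sd, size=viability.shape)
    viability = np.clip(viability, 0.0, 1.2)

    ii, jj = np.meshgrid(np.arange(len(da)), np.arange(len(db)), indexing="ij")
    table = pd.DataFrame(
        {
            "drug_a": cfg.drug_a,
            "dose_a": da[ii.ravel()],
            "drug_b": cfg.drug_b,
            "dose_b": db[jj.ravel()],
            "cell_line": cfg.cell_line,
            "viability": viability.ravel(),
        }
    )
    return table, true_excess


# ---------------------------------------------------------------------------
# PLA per-cell spot-count tables
# ---------------------------------------------------------------------------

def simulate_pla_table(
    n_cells: int,
    conditions: dict[str, float],
    dispersion: float = 0.3,
    nucleus_area_mean: float = 1500.0,
    nucleus_area_sd: float = 400.0,
    n_experiments: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-cell PLA spot-count table.

    Parameters
    ----------
    n_cells : cells per condition per experiment.
    conditions : mapping condition label -> mean spot count (>= 0).
    dispersion : negative-binomial dispersion of spot counts.
    nucleus_area_mean, nucleus_area_sd : normal nucleus-area distribution in
        pixels, truncated at 1 (image segmentation never yields area <= 0).
    """
    if not conditions:
        raise ConfigurationError("conditions must be a non-empty mapping")
    if any(m < 0 for m in conditions.values()):
        raise ConfigurationError("condition mean spot counts must be >= 0")
    if n_cells < 1 or n_experiments < 1:
        raise ConfigurationError("n_cells and n_experiments must be >= 1")

    rng = np.random.default_rng(seed)
    rows = []
    cell_no = 0
    for exp in range(1, n_experiments + 1):
        for cond, mean in conditions.items():
            if mean > 0:
                spots = _negbin(rng, mean, dispersion, size=n_cells)
            else:
                spots = np.zeros(n_cells, dtype=int)
            areas = np.maximum(
                rng.normal(nucleus_area_mean, nucleus_area_sd, size=n_cells), 1.0
            )
            for s, a in zip(spots, areas):
                cell_no += 1
                rows.append((f"cell{cell_no:06d}", cond, f"exp{exp}", int(s), float(a)))
    return pd.DataFrame(
        rows, columns=["cell_id", "condition", "experiment", "spot_count", "nucleus_area"]
    )


# ---------------------------------------------------------------------------
# Expression + survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalSimConfig:
    """Configuration for an expression matrix with exponential survival.

    Event hazard is ``base_hazard * exp(log_hazard_per_unit * score)`` where
    ``score`` is the per-sample latent signature activity (standard normal).
    Signature genes express ``score`` plus gene-level noise; all other genes
    are pure noise.  Censoring is independent exponential, with rate chosen
    so the null (beta = 0) censoring fraction equals ``censor_rate``.
    """

    n_samples: int = 500
    n_genes: int = 200
    n_signature_genes: int = 50
    log_hazard_per_unit: float = 0.8
    censor_rate: float = 0.3
    gene_noise_sd: float = 0.5
    base_hazard: float = 1.0 / 365.0  # per day; median survival ~1 year at score 0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.censor_rate < 1:
            raise ConfigurationError("censor_rate must be in [0, 1)")
        if not 1 <= self.n_signature_genes <= self.n_genes:
            raise ConfigurationError("n_signature_genes must be in [1, n_genes]")
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if self.base_hazard <= 0:
            raise ConfigurationError("base_hazard must be > 0")


def simulate_expression_survival(
    cfg: SurvivalSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (expression matrix, survival records, truth).

    Returns
    -------
    expression : genes x samples DataFrame (log-scale values).
    survival : DataFrame ``sample, time, event`` (time in days, event 1/0).
    truth : DataFrame ``sample, true_score`` plus attribute-free signature
        membership column in expression index order (``gene, in_signature``)
        exposed via ``truth.attrs['signature_genes']``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    samples = np.array([f"S{i:04d}" for i in range(cfg.n_samples)])
    genes = np.array([f"GENE{i:05d}" for i in range(cfg.n_genes)])
    sig_genes = genes[: cfg.n_signature_genes]

    score = rng.normal(0.0, 1.0, size=cfg.n_samples)
    expr = rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_samples))
    expr[: cfg.n_signature_genes, :] = (
        score[None, :]
        + rng.normal(0.0, cfg.gene_noise_sd, size=(cfg.n_signature_genes, cfg.n_samples))
    )

    hazard = cfg.base_hazard * np.exp(cfg.log_hazard_per_unit * score)
    event_time = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        # Exponential censoring at rate r*c/(1-c) gives P(censored) = c at beta = 0.
        censor_hazard = cfg.base_hazard * cfg.censor_rate / (1.0 - cfg.censor_rate)
        censor_time = rng.exponential(1.0 / censor_hazard, size=cfg.n_samples)
    else:
        censor_time = np.full(cfg.n_samples, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    expression = pd.DataFrame(expr, index=genes, columns=samples)
    survival = pd.DataFrame({"sample": samples, "time": time, "event": event})
    truth = pd.DataFrame({"sample": samples, "true_score": score})
    truth.attrs["signature_genes"] = list(sig_genes)
    return expression, survival, truth
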