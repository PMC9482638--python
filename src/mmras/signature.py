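"""mTORC1-inhibition gene signature: derivation, scoring, survival tests.

A drug-response signature is the set of genes consistently down-regulated
(average log2 fold change at or below a cutoff in every cell line tested)
after mTORC1 inhibition.  Each tumor sample is scored by the mean
log-scale expression of the signature genes; the association between that
continuous score and survival is tested with a Cox proportional-hazards
likelihood-ratio test, and visualized by tertile Kaplan-Meier curves.

The Cox fit maximizes the partial likelihood with Breslow tie handling by
Newton-Raphson; the likelihood-ratio statistic 2*(l(beta_hat) - l(0)) is
referred to chi-square with 1 df.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "derive_signature",
    "score_samples",
    "tertile_groups",
    "cox_partial_loglik",
    "cox_lr_test",
    "km_estimate",
]


class ScoringError(ValueError):
    pass


class EstimationError(RuntimeError):
    pass


def derive_signature(
    changes: pd.DataFrame, fc_cutoff: float = -0.5, strict: bool = False
) -> list[str]:
    """Genes down-regulated in every cell line.

    ``changes`` has columns ``gene, cell_line, log2fc`` with one row per
    (gene, cell line, timepoint).  Per cell line, log2fc is averaged across
    timepoints; a gene is a member iff that average is <= fc_cutoff (or
    strictly < with ``strict=True``) in every cell line.  Genes missing
    from any cell line are excluded.
    """
    lines = changes["cell_line"].unique()
    if len(lines) < 2:
        raise ValueError("signature derivation requires >= 2 cell lines")
    per_line = (
        changes.groupby(["gene", "cell_line"])["log2fc"].mean().unstack("cell_line")
    )
    complete = per_line.dropna()
    if strict:
        member = (complete < fc_cutoff).all(axis=1)
    else:
        member = (complete <= fc_cutoff).all(axis=1)
    return sorted(complete.index[member])


def score_samples(
    expression: pd.DataFrame, signature: list[str], min_coverage: float = 0.5
) -> pd.Series:
    """Per-sample signature score = mean expression of member genes.

    ``expression`` is genes x samples on a log scale.  Signature genes
    missing from the matrix are skipped; if fewer than ``min_coverage`` of
    them are present the score is not meaningful and an error is raised.
    """
    present = [g for g in signature if g in expression.index]
    if len(signature) == 0:
        raise ScoringError("empty signature")
    coverage = len(present) / len(signature)
    if coverage < min_coverage:
        raise ScoringError(
            f"only {coverage:.0%} of signature genes present (minimum {min_coverage:.0%})"
        )
    scores = expression.loc[present].mean(axis=0)
    scores.name = "signature_score"
    scores.attrs["coverage"] = coverage
    return scores


def tertile_groups(scores: pd.Series) -> pd.Series:
    """Split samples into low/mid/high tertiles of the score.

    Cuts at the 1/3 and 2/3 empirical quantiles (linear interpolation);
    samples exactly at a cut go to the lower group, so ties resolve
    deterministically.
    """
    if len(scores) < 3:
        raise ValueError("tertile grouping requires >= 3 samples")
    vals = scores.to_numpy(dtype=float)
    q1, q2 = np.quantile(vals, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(vals <= q1, "low", np.where(vals <= q2, "mid", "high"))
    return pd.Series(labels, index=scores.index, name="tertile")


def _cox_arrays(records: pd.DataFrame):
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    z = records["signature_score"].to_numpy(dtype=float)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    order = np.argsort(time, kind="mergesort")
    return time[order], event[order], z[order]


def cox_partial_loglik(records: pd.DataFrame, beta: float) -> float:
    """Breslow partial log-likelihood for a single continuous covariate."""
    time, event, z = _cox_arrays(records)
    eta = beta * z
    # risk set at t_i = all subjects with time >= t_i (ascending sort -> suffix sums)
    rev_cumsum = np.cumsum(np.exp(eta)[::-1])[::-1]
    ll = 0.0
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d_idx = [k for k in range(i, j) if event[k] == 1]
        if d_idx:
            ll += eta[d_idx].sum() - len(d_idx) * np.log(rev_cumsum[i])
        i = j
    return float(ll)


def _cox_derivatives(time, event, z, beta):
    """Gradient and negative Hessian of the Breslow partial log-likelihood."""
    w = np.exp(beta * z)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * z)[::-1])[::-1]
    s2 = np.cumsum((w * z * z)[::-1])[::-1]
    grad = 0.0
    info = 0.0
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d = sum(1 for k in range(i, j) if event[k] == 1)
        if d:
            zd = sum(z[k] for k in range(i, j) if event[k] == 1)
            zbar = s1[i] / s0[i]
            grad += zd - d * zbar
            info += d * (s2[i] / s0[i] - zbar**2)
        i = j
    return grad, info


def cox_lr_test(
    records: pd.DataFrame, max_iter: int = 100, tol: float = 1e-8
) -> dict:
    """Cox PH fit and likelihood-ratio test for the signature score.

    ``records`` has columns ``sample, time, event, signature_score``.
    Returns dict with ``beta``, ``se``, ``lr_stat``, ``p_value``,
    ``n_events`` and a ``separation`` flag for monotone likelihoods.
    """
    if records["event"].sum() < 2:
        raise EstimationError("Cox fit requires >= 2 events")
    if records["signature_score"].nunique() <= 1:
        raise EstimationError("signature score is constant: no information")
    time, event, z = _cox_arrays(records)

    beta = 0.0
    separation = False
    for _ in range(max_iter):
        grad, info = _cox_derivatives(time, event, z, beta)
        if info <= 0:
            raise EstimationError("non-positive information; cannot update")
        step = grad / info
        beta += np.clip(step, -5.0, 5.0)
        if abs(grad) < tol:
            break
        if abs(beta) > 50:
            separation = True
            break
    else:
        raise EstimationError("Newton-Raphson did not converge in max_iter iterations")

    _, info = _cox_derivatives(time, event, z, beta)
    se = float(1.0 / np.sqrt(info))
    ll_hat = cox_partial_loglik(records, beta)
    ll_null = cox_partial_loglik(records, 0.0)
    lr = 2.0 * (ll_hat - ll_null)
    p = float(stats.chi2.sf(lr, df=1))
    return {
        "beta": float(beta),
        "se": se,
        "lr_stat": float(lr),
        "p_value": p,
        "n_events": int(records["event"].sum()),
        "separation": separation,
    }


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate for one group.

    ``records`` needs columns ``time, event``.  Returns a table of event
    times with at-risk counts, event counts and the survival estimate.
    """
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    n = len(time)
    rows = []
    surv = 1.0
    i = 0
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            j += 1
        d = int(event[i:j].sum())
        at_risk = n - i
        if d > 0:
            surv *= 1.0 - d / at_risk
            rows.append((t, at_risk, d, surv))
        i = j
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])
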