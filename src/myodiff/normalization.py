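"""Trimmed mean of M-values (TMM) normalization and log2-CPM transformation.

The factor for each sample is computed against a reference sample (the one
whose upper-quartile count-per-million is closest to the mean upper
quartile). Per gene positive in both sample and reference,

    M_g = log2((y_gj / N_j) / (y_gr / N_r))        (log ratio)
    A_g = 0.5 * log2((y_gj / N_j) * (y_gr / N_r))  (log abundance)
    w_g = (N_j - y_gj)/(N_j y_gj) + (N_r - y_gr)/(N_r y_gr)

Genes in the extreme 30% tails of M and 5% tails of A are trimmed, the
factor is 2**(weighted mean of the retained M_g) with inverse-variance
weights 1/w_g, and factors are rescaled to geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import CountMatrix, ValidationError


@dataclass
class NormalizationResult:
    tmm_factor: np.ndarray          # per sample, geometric mean 1
    effective_library: np.ndarray   # N_j * f_j
    log_cpm: pd.DataFrame           # genes x samples
    parameters: dict


def _pick_reference(counts: np.ndarray) -> int:
    lib = counts.sum(axis=0).astype(float)
    uq = np.quantile(counts / lib, 0.75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair(
    y: np.ndarray,
    y_ref: np.ndarray,
    n: float,
    n_ref: float,
    m_trim: float,
    a_trim: float,
    weighted: bool,
) -> float:
    """Single-sample TMM factor against the reference (unrescaled)."""
    ok = (y > 0) & (y_ref > 0)
    if not ok.any():
        raise ValidationError("sample shares no positive gene with the reference")
    yj, yr = y[ok].astype(float), y_ref[ok].astype(float)
    m = np.log2((yj / n) / (yr / n_ref))
    a = 0.5 * np.log2((yj / n) * (yr / n_ref))
    w = (n - yj) / (n * yj) + (n_ref - yr) / (n_ref * yr)
    if np.allclose(m, 0):  # e.g. sample vs itself / pure rescaling
        return 1.0
    # double trim: drop the extreme m_trim tails of M and a_trim tails of A
    ng = m.size
    lo_m, hi_m = np.floor(ng * m_trim) + 1, ng - np.floor(ng * m_trim)
    lo_a, hi_a = np.floor(ng * a_trim) + 1, ng - np.floor(ng * a_trim)
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        raise ValidationError("trimming removed every gene; lower m_trim/a_trim")
    if weighted:
        weights = 1.0 / w[keep]
    else:
        weights = np.ones(keep.sum())
    return float(2 ** (np.sum(weights * m[keep]) / np.sum(weights)))


def tmm_factors(
    counts: CountMatrix,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
    weighted: bool = True,
    reference: str | None = None,
) -> np.ndarray:
    """Per-sample TMM factors, rescaled to geometric mean 1."""
    if not (0 <= m_trim < 0.5 and 0 <= a_trim < 0.5):
        raise ValidationError("trim fractions must lie in [0, 0.5)")
    y = counts.counts
    lib = y.sum(axis=0).astype(float)
    ref = (
        counts.sample_index()[reference]
        if reference is not None
        else _pick_reference(y)
    )
    factors = np.empty(counts.n_samples)
    for j in range(counts.n_samples):
        try:
            factors[j] = _tmm_pair(
                y[:, j], y[:, ref], lib[j], lib[ref], m_trim, a_trim, weighted
            )
        except ValidationError as exc:
            raise ValidationError(f"sample {counts.sample_ids[j]!r}: {exc}") from exc
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def log_cpm(
    counts: CountMatrix,
    factors: np.ndarray | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes.

    The prior count is scaled per sample proportionally to its effective
    library so zero counts map to a finite, library-consistent floor:
    log2((y + pc_j) / (L_j + 2 pc_j) * 1e6) with pc_j = prior * L_j / mean(L).
    """
    if factors is None:
        factors = tmm_factors(counts)
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.n_samples,):
        raise ValidationError("factors must be one per sample")
    eff = counts.counts.sum(axis=0) * factors
    if (eff <= 0).any():
        j = int(np.argmax(eff <= 0))
        raise ValidationError(
            f"nonpositive effective library for sample {counts.sample_ids[j]!r}"
        )
    pc = prior_count * eff / eff.mean()
    vals = np.log2((counts.counts + pc) / (eff + 2 * pc) * 1e6)
    return pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids)


def normalize(
    counts: CountMatrix,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
    prior_count: float = 0.5,
) -> NormalizationResult:
    """TMM factors plus log-CPM in one pass."""
    ref = _pick_reference(counts.counts)
    factors = tmm_factors(counts, m_trim=m_trim, a_trim=a_trim)
    return NormalizationResult(
        tmm_factor=factors,
        effective_library=counts.counts.sum(axis=0) * factors,
        log_cpm=log_cpm(counts, factors, prior_count=prior_count),
        parameters={
            "reference_sample": counts.sample_ids[ref],
            "m_trim": m_trim,
            "a_trim": a_trim,
            "prior_count": prior_count,
        },
    )
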