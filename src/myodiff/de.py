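"""Two-group differential expression on normalized log-expression with
empirical-Bayes variance moderation and Benjamini-Hochberg adjustment.

Each analyzed group gets two contrasts: the group versus all other samples
(one-vs-rest, background and control samples included in the rest) and the
group versus the normal-tissue controls. Gene-wise residual variances are
shrunk toward a prior (d0, s0^2) estimated by moment-matching the
distribution of log sample variances, and the moderated t is referred to a
t distribution on d0 + d_g degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .types import GroupHierarchy, SampleAnnotation, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    group_samples: frozenset[str]
    reference_samples: frozenset[str]
    kind: str  # "vs_rest" | "vs_nt"

    def __post_init__(self) -> None:
        if self.kind not in ("vs_rest", "vs_nt"):
            raise ValidationError(f"unknown contrast kind {self.kind!r}")
        if self.group_samples & self.reference_samples:
            raise ValidationError(f"contrast {self.name!r}: sides overlap")
        if len(self.group_samples) < 2 or len(self.reference_samples) < 2:
            raise ValidationError(
                f"contrast {self.name!r}: both sides need >= 2 samples "
                f"(got {len(self.group_samples)} vs {len(self.reference_samples)})"
            )


def build_contrasts(
    annotations: Sequence[SampleAnnotation],
    hierarchy: GroupHierarchy,
    target_group: str,
) -> tuple[ContrastSpec, Optional[ContrastSpec]]:
    """The (vs_rest, vs_nt) contrast pair for a group; (vs_rest, None) for NT.

    The rest side of vs_rest is every sample outside the target group,
    including background-group and control samples. A subgroup's contrast
    keeps the remainder of its own clinical group in the rest side.
    """
    known = set(hierarchy.analyzed_groups) | {hierarchy.control_group}
    if target_group not in known:
        raise ValidationError(f"{target_group!r} is not an analyzed group or control")
    all_ids = [a.sample_id for a in annotations]
    group_ids = frozenset(hierarchy.group_members(annotations, target_group))
    if len(group_ids) < 2:
        raise ValidationError(
            f"group {target_group!r} has {len(group_ids)} samples; need >= 2"
        )
    rest = frozenset(all_ids) - group_ids
    vs_rest = ContrastSpec(
        name=f"{target_group}_vs_rest",
        group_samples=group_ids,
        reference_samples=rest,
        kind="vs_rest",
    )
    if target_group == hierarchy.control_group:
        return vs_rest, None
    nt_ids = frozenset(
        a.sample_id for a in annotations if a.clinical_group == hierarchy.control_group
    )
    vs_nt = ContrastSpec(
        name=f"{target_group}_vs_NT",
        group_samples=group_ids,
        reference_samples=nt_ids,
        kind="vs_nt",
    )
    return vs_rest, vs_nt


@dataclass
class DEResult:
    """Per-gene statistics for one two-group contrast."""

    contrast: str
    genes: list[str]
    log2fc: np.ndarray
    s2: np.ndarray
    df_residual: float
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    prior_df: float = 0.0
    prior_var: float = 1.0
    n_group: int = 0
    n_reference: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "log2FC": self.log2fc,
                "t": self.t,
                "p": self.p,
                "q": self.q,
                "contrast": self.contrast,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DEResult":
        name = str(df["contrast"].iloc[0]) if len(df) else ""
        return cls(
            contrast=name,
            genes=[str(g) for g in df["gene"]],
            log2fc=df["log2FC"].to_numpy(float),
            s2=np.full(len(df), np.nan),
            df_residual=np.nan,
            t=df["t"].to_numpy(float),
            p=df["p"].to_numpy(float),
            q=df["q"].to_numpy(float),
        )


def bh_adjust(pvals: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from gene-wise variances with common df.

    Works on z = log(s2): E[z] and Var[z] have closed digamma/trigamma
    forms under the scaled-F hierarchical model; the trigamma equation is
    inverted by Newton iteration. Returns (inf, exp(mean)) when the observed
    spread of log-variances is no larger than expected under a common
    variance.
    """
    ok = np.isfinite(s2) & (s2 > 0)
    if not ok.any():
        raise ValidationError("all gene-wise residual variances are zero (degenerate input)")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    try:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    except Exception:  # pragma: no cover - defensive fallback
        logger.warning("prior df estimation failed; falling back to d0 = 0")
        return 0.0, float(np.exp(emean))
    return d0, s02


def fit_moderated(
    log_cpm: pd.DataFrame,
    contrast: ContrastSpec,
    prior_df: float | None = None,
) -> DEResult:
    """Moderated two-group t-test per gene on log-expression.

    ``prior_df`` overrides the estimated d0 (0 disables moderation; inf
    pools every gene's variance to s0^2).
    """
    cols = set(log_cpm.columns)
    missing = (contrast.group_samples | contrast.reference_samples) - cols
    if missing:
        raise ValidationError(f"samples missing from expression matrix: {sorted(missing)[:5]}")
    g_ids = sorted(contrast.group_samples)
    r_ids = sorted(contrast.reference_samples)
    x1 = log_cpm[g_ids].to_numpy(float)
    x2 = log_cpm[r_ids].to_numpy(float)
    if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
        raise ValidationError("log expression must be finite")
    n1, n2 = x1.shape[1], x2.shape[1]
    beta = x1.mean(axis=1) - x2.mean(axis=1)
    rss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df_res = float(n1 + n2 - 2)
    s2 = rss / df_res
    if np.all(s2 == 0):
        raise ValidationError("zero residual variance in all genes (degenerate input)")

    if prior_df is None:
        d0, s02 = estimate_prior(s2, df_res)
    else:
        d0 = float(prior_df)
        _, s02 = estimate_prior(s2, df_res)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    return DEResult(
        contrast=contrast.name,
        genes=[str(g) for g in log_cpm.index],
        log2fc=beta,
        s2=s2,
        df_residual=df_res,
        t=t,
        p=p,
        q=q,
        prior_df=d0,
        prior_var=s02,
        n_group=n1,
        n_reference=n2,
    )
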