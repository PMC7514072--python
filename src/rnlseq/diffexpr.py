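"""Negative-binomial differential expression for two-condition contrasts.

The model is the standard bulk RNA-seq NB formulation: counts K_gj ~
NB(mean = s_j * q_g(condition), variance = mu + alpha_g * mu^2) with
median-of-ratios size factors s_j, a per-gene method-of-moments
dispersion alpha_g shrunk toward a 1/mu trend, per-group mean fits by
Newton iteration on the log mean, and a Wald test on the log2 fold
change.  DEGs are called at FDR-adjusted p < alpha and fold change >
threshold (both strict), matching the study's thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import (
    ContrastSpec,
    CountMatrix,
    RunConfig,
    SampleMeta,
    ValidationError,
)

__all__ = [
    "size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "call_degs",
    "vst_zscore",
    "DirectionalGeneSet",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class DirectionalGeneSet:
    """A DEG set for one contrast and one direction of change."""

    label: str
    direction: str  # "up" | "down"
    genes: frozenset[str]
    contrast: ContrastSpec | None = None
    alpha_fdr: float = 0.05
    fc_threshold: float = 2.0

    def __len__(self) -> int:
        return len(self.genes)


def size_factors(cm: CountMatrix, pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios library-size factors.

    Reference genes are those with nonzero counts in every sample; each
    sample's factor is the median ratio of its counts to the per-gene
    geometric mean over those genes.  ``pseudo_reference=True`` relaxes
    the reference to genes nonzero in at least half the samples, using
    a geometric mean over nonzero entries.
    """
    counts = cm.counts
    if counts.shape[1] < 2:
        raise ValidationError("size factors need >= 2 samples")
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        if not pseudo_reference:
            raise ValidationError(
                "no gene has nonzero counts in every sample; re-run with "
                "pseudo_reference=True to use a pseudo-reference over "
                "partially observed genes"
            )
        mostly = (counts > 0).sum(axis=1) >= counts.shape[1] / 2
        if not mostly.any():
            raise ValidationError("matrix too sparse even for pseudo-reference")
        sub = counts[mostly].astype(float)
        logc = np.where(sub > 0, np.log(np.where(sub > 0, sub, 1.0)), np.nan)
        geo = np.exp(np.nanmean(logc, axis=1))
        ratios = sub / geo[:, None]
        factors = np.nanmedian(np.where(sub > 0, ratios, np.nan), axis=0)
    else:
        ref = counts[all_nonzero].astype(float)
        geo = np.exp(np.mean(np.log(ref), axis=1))
        factors = np.median(ref / geo[:, None], axis=0)
    if (factors <= 0).any() or not np.isfinite(factors).all():
        raise ValidationError("degenerate size factors")
    return factors


def _condition_groups(
    design: Sequence[SampleMeta], sample_ids: Sequence[str]
) -> dict[tuple, np.ndarray]:
    """Map condition -> column indices, in count-matrix column order."""
    pos = {sid: j for j, sid in enumerate(sample_ids)}
    groups: dict[tuple, list[int]] = {}
    for s in design:
        if s.sample_id not in pos:
            raise ValidationError(f"design sample {s.sample_id!r} absent from counts")
        groups.setdefault(s.condition, []).append(pos[s.sample_id])
    return {k: np.array(v) for k, v in groups.items()}


def estimate_dispersion(
    cm: CountMatrix,
    design: Sequence[SampleMeta],
    factors: np.ndarray,
    shrink: float = 0.5,
) -> np.ndarray:
    """Per-gene NB dispersion (variance = mu + alpha mu^2).

    Method-of-moments estimates pooled across within-condition replicate
    groups, then shrunk toward a fitted trend alpha(mu) = a0 + a1/mu by
    weight ``shrink`` (0 = raw estimates, 1 = pure trend).
    """
    groups = [ix for ix in _condition_groups(design, cm.sample_ids).values() if len(ix) >= 2]
    if not groups:
        raise ValidationError(
            "dispersion estimation needs >= 2 replicates in at least one condition"
        )
    norm = cm.counts / factors[None, :]
    n_g = norm.shape[0]
    num = np.zeros(n_g)  # sum over groups of df * (s^2 - mean)
    den = np.zeros(n_g)  # sum over groups of df * mean^2
    mu_acc = np.zeros(n_g)
    w_acc = 0.0
    for ix in groups:
        sub = norm[:, ix]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        df = len(ix) - 1
        num += df * (v - m)
        den += df * m**2
        mu_acc += df * m
        w_acc += df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(den > 0, num / den, 0.0)
    alpha_raw = np.clip(alpha_raw, 0.0, None)
    mu_bar = mu_acc / w_acc

    alpha = alpha_raw
    if shrink > 0:
        trend = _fit_dispersion_trend(mu_bar, alpha_raw)
        alpha = (1 - shrink) * alpha_raw + shrink * trend
    return np.clip(alpha, 0.0, None)


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha ~ a0 + a1/mu over informative genes."""
    ok = (mu > 1) & (alpha > 0)
    if ok.sum() < 10:
        # too few informative genes: flat trend at the mean estimate
        level = float(alpha[ok].mean()) if ok.any() else 0.0
        return np.full_like(mu, level)
    x = 1.0 / mu[ok]
    A = np.column_stack([np.ones(ok.sum()), x])
    coef, *_ = np.linalg.lstsq(A, alpha[ok], rcond=None)
    a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.clip(mu, 1e-8, None)
    return np.clip(trend, 0.0, None)


def _fit_group_mean(
    counts: np.ndarray, sf: np.ndarray, alpha: np.ndarray, n_iter: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """NB MLE of the normalized group mean q (counts: genes x samples).

    Newton iteration on beta = log q with score sum_j (K - mu)/(1 + alpha mu)
    and expected information sum_j mu/(1 + alpha mu), mu_j = s_j e^beta.
    Returns (q_hat, information).
    """
    q = (counts.sum(axis=1) + 0.5) / sf.sum()
    beta = np.log(q)
    a = alpha[:, None]
    for _ in range(n_iter):
        mu = sf[None, :] * np.exp(beta)[:, None]
        score = ((counts - mu) / (1.0 + a * mu)).sum(axis=1)
        info = (mu / (1.0 + a * mu)).sum(axis=1)
        step = np.clip(score / np.clip(info, 1e-12, None), -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = sf[None, :] * np.exp(beta)[:, None]
    info = (mu / (1.0 + a * mu)).sum(axis=1)
    return np.exp(beta), info


def nb_wald_test(
    cm: CountMatrix,
    design: Sequence[SampleMeta],
    factors: np.ndarray,
    dispersions: np.ndarray,
    contrast: ContrastSpec,
    min_count_filter: float = 5.0,
) -> pd.DataFrame:
    """Wald test of the contrast's numerator vs denominator condition.

    Returns a per-gene table (index = gene id) with base_mean, log2_fc,
    se_log2_fc, stat, p_value, p_adjusted, dispersion and tested.  Genes
    with mean normalized count below ``min_count_filter`` are excluded
    from testing and from the BH family (tested = False, NaN p values).
    """
    groups = _condition_groups(design, cm.sample_ids)
    for name, cond in (
        ("numerator", contrast.numerator_condition),
        ("denominator", contrast.denominator_condition),
    ):
        if cond not in groups:
            raise ValidationError(
                f"contrast {contrast.label!r}: {name} condition "
                f"({cond[0].value}, {cond[1].value}, {cond[2]:g} hpi) not in design"
            )
        if len(groups[cond]) < 2:
            raise ValidationError(
                f"contrast {contrast.label!r}: {name} condition has < 2 samples"
            )
    ix_num = groups[contrast.numerator_condition]
    ix_den = groups[contrast.denominator_condition]
    alpha = np.asarray(dispersions, dtype=float)

    norm = cm.counts / factors[None, :]
    base_mean = norm[:, np.concatenate([ix_num, ix_den])].mean(axis=1)
    tested = base_mean >= min_count_filter

    q_num, info_num = _fit_group_mean(cm.counts[:, ix_num], factors[ix_num], alpha)
    q_den, info_den = _fit_group_mean(cm.counts[:, ix_den], factors[ix_den], alpha)

    # +0.5 normalized-count moderation keeps the ratio finite at zero
    log2_fc = np.log2(q_num + 0.5) - np.log2(q_den + 0.5)
    # delta method on beta = ln q, scaled to log2; moderation factor
    # q/(q+0.5) propagates the +0.5 shift into the SE
    var_beta_num = q_num**2 / (q_num + 0.5) ** 2 / np.clip(info_num, 1e-12, None)
    var_beta_den = q_den**2 / (q_den + 0.5) ** 2 / np.clip(info_den, 1e-12, None)
    se = np.sqrt(var_beta_num + var_beta_den) / _LN2
    se = np.clip(se, 1e-12, None)
    stat = log2_fc / se
    p = 2.0 * stats.norm.sf(np.abs(stat))

    p_value = np.where(tested, p, np.nan)
    p_adj = np.full_like(p_value, np.nan)
    if tested.any():
        p_adj[tested] = bh_adjust(p_value[tested])

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fc": log2_fc,
            "se_log2_fc": se,
            "stat": np.where(tested, stat, np.nan),
            "p_value": p_value,
            "p_adjusted": p_adj,
            "dispersion": alpha,
            "tested": tested,
        },
        index=pd.Index(cm.gene_ids, name="gene_id"),
    )


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    table: pd.DataFrame, config: RunConfig, label: str = "", contrast: ContrastSpec | None = None
) -> tuple[DirectionalGeneSet, DirectionalGeneSet]:
    """Call up/down DEG sets at adjusted p < alpha and |FC| > threshold."""
    lfc_cut = np.log2(config.fc_threshold)
    sig = table["p_adjusted"] < config.alpha_fdr
    up = frozenset(table.index[sig & (table["log2_fc"] > lfc_cut)])
    down = frozenset(table.index[sig & (table["log2_fc"] < -lfc_cut)])
    mk = lambda d, genes: DirectionalGeneSet(
        label=label, direction=d, genes=genes, contrast=contrast,
        alpha_fdr=config.alpha_fdr, fc_threshold=config.fc_threshold,
    )
    return mk("up", up), mk("down", down)


def vst_zscore(cm: CountMatrix, factors: np.ndarray) -> pd.DataFrame:
    """Variance-stabilized (shifted-log) counts, z-scored per gene.

    t = log2(count/sf + 1); each gene is standardized along samples.
    Constant genes map to all-zero rows.
    """
    if cm.counts.shape[1] < 2:
        raise ValidationError("vst_zscore needs >= 2 samples")
    t = np.log2(cm.counts / factors[None, :] + 1.0)
    mean = t.mean(axis=1, keepdims=True)
    sd = t.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (t - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=pd.Index(cm.gene_ids, name="gene_id"), columns=cm.sample_ids)
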