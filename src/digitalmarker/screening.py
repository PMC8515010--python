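"""Gene filters and scoring for digital-marker screening.

The screen reduces a whole transcriptome to a short ranked candidate
list, per cancer type and drug:

* cell-line path: mean-expression filter on log10(1+TPM), Pearson
  correlation filter against the Z-scores of log IC50, then a univariate
  Fisher linear-discriminant score contrasting the extreme IC50 tails;
* patient path: mean-expression filter on log10(TPM), then a
  Mann-Whitney U score (-log10 p) contrasting the effective and
  ineffective outcome groups.

For paired cell-line cohorts the two datasets are screened separately
and their per-gene scores added; the sum orders the final candidate
list.  All filter inequalities are strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    EFFECTIVE,
    INEFFECTIVE,
    CohortPair,
    DrugResponse,
    ExpressionMatrix,
    ValidationError,
    align_expression_response,
)

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds of the screening stage.

    Defaults: mean log10(1+TPM) > 1 for cell lines, mean log10(TPM) > 0
    for patients, Pearson |r| > 0.25 against the IC50 Z-scores,
    extreme-tail fraction 0.15, and a strict > 20 occurrence cut for
    stable-gene selection.  All comparisons are strict.
    """

    expr_threshold_cell: float = 1.0
    expr_threshold_patient: float = 0.0
    corr_threshold: float = 0.25
    extreme_fraction: float = 0.15
    use_abs_correlation: bool = True
    log_correlation: bool = False  # correlate log10(1+TPM) instead of raw TPM
    occurrence_threshold: int = 20
    synthesis_mode: str = "sum"

    def __post_init__(self) -> None:
        for name in ("expr_threshold_cell", "expr_threshold_patient",
                     "corr_threshold", "extreme_fraction"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if not 0 < self.extreme_fraction <= 0.5:
            raise ValidationError("extreme_fraction must be in (0, 0.5]")


def filter_by_expression(x: ExpressionMatrix, threshold: float,
                         pseudo: int) -> list[str]:
    """Genes whose mean log10(pseudo + TPM) strictly exceeds ``threshold``.

    ``pseudo=1`` is the cell-line rule (log10(1+TPM) > threshold);
    ``pseudo=0`` is the patient rule, under which any zero TPM makes the
    gene fail (its log is -inf).
    """
    if pseudo not in (0, 1):
        raise ValidationError("pseudo must be 0 or 1")
    vals = x.values.to_numpy(dtype=float)
    if pseudo == 0:
        has_zero = np.any(vals <= 0, axis=1)
        with np.errstate(divide="ignore"):
            mean_log = np.where(has_zero, -np.inf,
                                np.log10(np.where(vals > 0, vals, 1.0)).mean(axis=1))
    else:
        mean_log = np.log10(1.0 + vals).mean(axis=1)
    keep = mean_log > threshold
    return [g for g, k in zip(x.genes, keep) if k]


def _pearson_by_gene(vals: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r of ``vals`` (genes x samples) against ``y``.

    Rows with zero variance get NaN.
    """
    xc = vals - vals.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r[sx == 0] = np.nan
    if sy == 0:
        r[:] = np.nan
    return r


def filter_by_correlation(x: ExpressionMatrix, r: DrugResponse,
                          threshold: float = 0.25, use_abs: bool = True,
                          log_transform: bool = False) -> list[str]:
    """Genes whose Pearson correlation with the IC50 Z-scores passes the cut.

    Correlation is computed between TPM (or log10(1+TPM) when
    ``log_transform``) and the response Z over the samples shared by
    matrix and response; |r| is compared when ``use_abs``, signed r
    otherwise; strictly greater than ``threshold``.  Zero-variance genes
    are dropped.
    """
    if r.mode != "continuous":
        raise ValidationError("correlation filter needs a continuous response")
    vals, rr = align_expression_response(x, r)
    if vals.shape[1] < 3:
        raise ValidationError(
            f"only {vals.shape[1]} overlapping samples; need >= 3"
        )
    arr = vals.to_numpy(dtype=float)
    if log_transform:
        arr = np.log10(1.0 + arr)
    cor = _pearson_by_gene(arr, rr.z)
    stat = np.abs(cor) if use_abs else cor
    with np.errstate(invalid="ignore"):
        keep = stat > threshold
    keep &= ~np.isnan(cor)
    return [g for g, k in zip(vals.index, keep) if k]


def extreme_groups(r: DrugResponse, extreme_fraction: float = 0.15
                   ) -> tuple[list[str], list[str]]:
    """Sample IDs of the lowest and highest IC50 tails.

    Samples are ordered by Z-score (ties broken by sample identifier)
    and the first/last ``max(2, floor(extreme_fraction * n))`` taken.
    """
    if r.mode != "continuous":
        raise ValidationError("extreme groups need a continuous response")
    n = len(r.samples)
    if n < 4:
        raise ValidationError(f"need >= 4 samples to form extreme groups, got {n}")
    n_ext = max(2, int(np.floor(extreme_fraction * n)))
    order = sorted(range(n), key=lambda i: (r.z[i], r.samples[i]))
    low = [r.samples[i] for i in order[:n_ext]]
    high = [r.samples[i] for i in order[-n_ext:]]
    return low, high


def fisher_ld(low: np.ndarray, high: np.ndarray) -> np.ndarray:
    """Univariate Fisher linear-discriminant magnitude per gene (rows).

    |mean_high - mean_low| / sqrt(var_high + var_low) with unbiased
    variances.  Both variances zero: 0 when means agree, +inf otherwise.
    """
    mu_l, mu_h = low.mean(axis=1), high.mean(axis=1)
    v_l = low.var(axis=1, ddof=1)
    v_h = high.var(axis=1, ddof=1)
    denom = np.sqrt(v_l + v_h)
    num = np.abs(mu_h - mu_l)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = num / denom
    zero = denom == 0
    score[zero & (num == 0)] = 0.0
    score[zero & (num > 0)] = np.inf
    return score


def score_fisher_ld(x: ExpressionMatrix, r: DrugResponse,
                    extreme_fraction: float = 0.15) -> pd.Series:
    """Score each gene by the Fisher LD between the IC50 extreme tails.

    Expression enters on the log10(1+TPM) scale.  Returns a Series
    indexed by gene, higher = more discriminative.
    """
    vals, rr = align_expression_response(x, r)
    low_ids, high_ids = extreme_groups(rr, extreme_fraction)
    logv = np.log10(1.0 + vals.to_numpy(dtype=float))
    col = {s: j for j, s in enumerate(vals.columns)}
    low = logv[:, [col[s] for s in low_ids]]
    high = logv[:, [col[s] for s in high_ids]]
    return pd.Series(fisher_ld(low, high), index=vals.index, name="fisher_ld")


def score_mannwhitney(x: ExpressionMatrix, r: DrugResponse) -> pd.Series:
    """Score each gene by -log10 p of a two-sided Mann-Whitney U test.

    TPM values are compared between the effective and ineffective
    outcome groups.  The exact null distribution is used when
    min(n1, n2) <= 8 and the gene has no tied values; otherwise the
    normal approximation with tie correction.
    """
    if r.mode != "binary":
        raise ValidationError("Mann-Whitney scoring needs a binary response")
    vals, rr = align_expression_response(x, r)
    labels = rr.label
    g1 = vals.to_numpy(dtype=float)[:, labels == EFFECTIVE]
    g2 = vals.to_numpy(dtype=float)[:, labels == INEFFECTIVE]
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 == 0 or n2 == 0:
        raise ValidationError("both outcome classes must be non-empty")
    small = min(n1, n2) <= 8
    p = np.empty(vals.shape[0])
    if not small:
        p[:] = stats.mannwhitneyu(g1, g2, axis=1, alternative="two-sided",
                                  method="asymptotic").pvalue
    else:
        for i in range(vals.shape[0]):
            row = np.concatenate([g1[i], g2[i]])
            method = "exact" if len(np.unique(row)) == len(row) else "asymptotic"
            p[i] = stats.mannwhitneyu(g1[i], g2[i], alternative="two-sided",
                                      method=method).pvalue
    score = -np.log10(np.clip(p, 1e-300, 1.0))
    return pd.Series(score, index=vals.index, name="mannwhitney")


def synthesize_scores(scores_a: pd.Series, scores_b: pd.Series,
                      mode: str = "sum") -> pd.DataFrame:
    """Combine per-dataset gene scores into a ranked score table.

    The gene universe is the intersection of the two (already filtered)
    score tables.  ``mode="sum"`` adds raw scores; ``"rank_percentile_sum"``
    maps each dataset's scores to percentile ranks in (0, 1] first.
    Ranks are 1-based by descending combined score, ties broken
    lexicographically by gene identifier.
    """
    shared = scores_a.index.intersection(scores_b.index)
    if len(shared) == 0:
        raise ValidationError(
            "no genes pass the filters in both datasets; relax the thresholds"
        )
    a = scores_a.loc[shared].astype(float)
    b = scores_b.loc[shared].astype(float)
    if mode == "rank_percentile_sum":
        a = a.rank(method="average") / len(a)
        b = b.rank(method="average") / len(b)
    elif mode != "sum":
        raise ValidationError(f"unknown synthesis mode {mode!r}")
    combined = a + b
    # descending combined score, ascending gene ID on ties
    order = sorted(shared, key=lambda g: (-_sort_val(combined.loc[g]), g))
    table = pd.DataFrame({
        "score_a": scores_a.loc[order],
        "score_b": scores_b.loc[order],
        "score_combined": combined.loc[order],
    })
    table["rank"] = np.arange(1, len(table) + 1)
    table.index.name = "gene"
    return table


def _sort_val(v: float) -> float:
    # +inf sentinels rank first; NaN should never occur here
    return float(v)


def rank_single(scores: pd.Series,
                tiebreak: pd.Series | None = None) -> pd.DataFrame:
    """Rank a single dataset's scores into a score table.

    ``score_combined`` equals the single score.  Equal scores break by
    descending ``tiebreak`` value (e.g. |median difference| on the
    patient path) and then by gene identifier.
    """
    if len(scores) == 0:
        raise ValidationError("no genes to rank")
    tb = tiebreak if tiebreak is not None else pd.Series(0.0, index=scores.index)
    order = sorted(scores.index,
                   key=lambda g: (-_sort_val(scores.loc[g]),
                                  -float(tb.get(g, 0.0)), g))
    table = pd.DataFrame({
        "score_a": scores.loc[order],
        "score_b": np.nan,
        "score_combined": scores.loc[order],
    })
    table["rank"] = np.arange(1, len(table) + 1)
    table.index.name = "gene"
    return table


def screen_cell_line_dataset(x: ExpressionMatrix, r: DrugResponse,
                             cfg: FilterConfig | None = None
                             ) -> tuple[pd.Series, dict]:
    """Run the cell-line filter/score cascade on one dataset.

    Returns the Fisher LD scores of the genes surviving both the
    expression and correlation filters, plus a stage-count log record.
    """
    cfg = cfg or FilterConfig()
    expr_pass = filter_by_expression(x, cfg.expr_threshold_cell, pseudo=1)
    sub = ExpressionMatrix(x.values.loc[expr_pass], x.cancer_type, x.dataset_tag)
    corr_pass = filter_by_correlation(sub, r, cfg.corr_threshold,
                                      use_abs=cfg.use_abs_correlation,
                                      log_transform=cfg.log_correlation)
    sub = ExpressionMatrix(x.values.loc[corr_pass], x.cancer_type, x.dataset_tag)
    scores = score_fisher_ld(sub, r, cfg.extreme_fraction)
    stages = {"total": x.n_genes, "expression_filter": len(expr_pass),
              "correlation_filter": len(corr_pass)}
    logger.info("%s: %s", x.dataset_tag or "dataset", stages)
    return scores, stages


def screen_cell_line_pair(pair: CohortPair, cfg: FilterConfig | None = None
                          ) -> pd.DataFrame:
    """Screen both paired datasets and synthesize their scores.

    Filters and Fisher LD scoring run on each dataset separately; the
    per-gene scores are then combined (sum by default) over the genes
    surviving the filters in both datasets and ranked.
    """
    cfg = cfg or FilterConfig()
    scores_a, _ = screen_cell_line_dataset(pair.expression_a, pair.response_a, cfg)
    scores_b, _ = screen_cell_line_dataset(pair.expression_b, pair.response_b, cfg)
    return synthesize_scores(scores_a, scores_b, mode=cfg.synthesis_mode)


def screen_patient_cohort(x: ExpressionMatrix, r: DrugResponse,
                          cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Run the patient-path screen: expression filter then Mann-Whitney rank.

    Equal p-values break by descending absolute difference of group
    medians (TPM), then by gene identifier.
    """
    cfg = cfg or FilterConfig()
    expr_pass = filter_by_expression(x, cfg.expr_threshold_patient, pseudo=0)
    sub = ExpressionMatrix(x.values.loc[expr_pass], x.cancer_type, x.dataset_tag)
    scores = score_mannwhitney(sub, r)
    vals, rr = align_expression_response(sub, r)
    arr = vals.to_numpy(dtype=float)
    med_eff = np.median(arr[:, rr.label == EFFECTIVE], axis=1)
    med_ineff = np.median(arr[:, rr.label == INEFFECTIVE], axis=1)
    tiebreak = pd.Series(np.abs(med_eff - med_ineff), index=vals.index)
    return rank_single(scores, tiebreak=tiebreak)


def count_stable_genes(lists_a: Mapping[str, Sequence[str]],
                       lists_b: Mapping[str, Sequence[str]],
                       occurrence_threshold: int = 20) -> pd.DataFrame:
    """Count gene occurrences across per-drug screened lists in two datasets.

    A gene qualifies when it occurs in strictly more than
    ``occurrence_threshold`` drug lists in *each* dataset; genes
    screened in only one dataset are excluded.  Returns a table indexed
    by gene with columns ``count_a``/``count_b``, sorted by total count
    descending then gene identifier.
    """
    def counts(lists: Mapping[str, Sequence[str]]) -> dict[str, int]:
        c: dict[str, int] = {}
        for genes in lists.values():
            for g in set(genes):
                c[g] = c.get(g, 0) + 1
        return c

    ca, cb = counts(lists_a), counts(lists_b)
    qual = [g for g in ca
            if g in cb and ca[g] > occurrence_threshold
            and cb[g] > occurrence_threshold]
    qual.sort(key=lambda g: (-(ca[g] + cb[g]), g))
    out = pd.DataFrame({"count_a": [ca[g] for g in qual],
                        "count_b": [cb[g] for g in qual]},
                       index=pd.Index(qual, name="gene"))
    return out


def write_gene_scores(table: pd.DataFrame, path, delimiter: str = "\t") -> None:
    table.to_csv(path, sep=delimiter)
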