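"""Synthetic cohorts with planted drug-sensitivity signal.

The generators emulate the three kinds of training data the pipeline
consumes, with known ground truth so every stage is testable offline:

* paired cell-line cohorts (two datasets profiling the same cancer
  type/drug, sharing signal genes but separated by a batch shift);
* patient cohorts with binary effective/ineffective outcomes;
* qPCR Cq readouts consistent with the linear dCq <-> log10(TPM+1)
  calibration.

The model is intentionally simple: per-sample latent sensitivity
z ~ N(0,1); a signal gene's log10(1+TPM) moves linearly with z
(directions alternate +-1), decoys are pure noise around a log-normal
background; IC50 = exp(sigma*z + mu) so standardized log IC50 recovers
z.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .conversion import ConversionModel, tpm_to_dcq
from .datamodel import (
    EFFECTIVE,
    INEFFECTIVE,
    CohortPair,
    CqTable,
    DrugResponse,
    ExpressionMatrix,
    ValidationError,
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohorts.

    Expression scales are log10(1+TPM).  ``effect_size`` is the mean
    log-expression shift per unit of latent sensitivity z (cell lines)
    or between the two outcome classes (patients); the default is 1.5x
    the within-gene noise SD.  Background baselines are Normal(0.7,
    0.7) so roughly a third of decoy genes clear the cell-line
    expression filter; signal baselines are Normal(1.8, 0.3) — a marker
    must be robustly expressed to be measurable.  ``batch_shift`` is a
    dataset-B additive offset on the log scale.  ``ic50_cut`` (uM) is
    the effective/ineffective boundary used when labelling by IC50.
    """

    n_genes: int = 2000
    n_signal_genes: int = 10
    n_samples_a: int = 60
    n_samples_b: int = 60
    n_patients: int = 60
    noise_sd: float = 0.4
    effect_size: float = 0.6
    base_mu: float = 0.7
    base_sigma: float = 0.7
    signal_base_mu: float = 1.8
    signal_base_sigma: float = 0.3
    batch_shift: float = 0.3
    ic50_ln_mu: float = 2.0
    ic50_ln_sigma: float = 1.0
    ic50_cut: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_genes > self.n_genes:
            raise ValidationError("n_signal_genes cannot exceed n_genes")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        for n in (self.n_genes, self.n_samples_a, self.n_samples_b,
                  self.n_patients):
            if n < 1:
                raise ValidationError("cohort sizes must be positive")
        if self.ic50_cut <= 0:
            raise ValidationError("ic50_cut must be positive")


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _truth(cfg: GeneratorConfig, rng: np.random.Generator) -> dict:
    genes = _gene_names(cfg.n_genes)
    signal_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.n_signal_genes,
                                    replace=False))
    directions = [1 if i % 2 == 0 else -1 for i in range(cfg.n_signal_genes)]
    return {
        "genes": genes,
        "signal_genes": [genes[i] for i in signal_idx],
        "signal_idx": signal_idx,
        "directions": directions,
    }


def _baselines(cfg: GeneratorConfig, truth: dict,
               rng: np.random.Generator) -> np.ndarray:
    base = rng.normal(cfg.base_mu, cfg.base_sigma, size=cfg.n_genes)
    base[truth["signal_idx"]] = rng.normal(
        cfg.signal_base_mu, cfg.signal_base_sigma, size=cfg.n_signal_genes)
    return base


def _expression(cfg: GeneratorConfig, baselines: np.ndarray, truth: dict,
                z: np.ndarray, shift: float, rng: np.random.Generator,
                strictly_positive: bool = False) -> np.ndarray:
    """log-scale model -> TPM matrix (genes x samples).

    Cell-line cohorts use TPM = 10^logv - 1 floored at 0 (zeros occur, as
    in real data, and exercise the pseudo-count filter path); patient
    cohorts use TPM = 10^logv so every gene is detected in every sample
    and the strict log10(TPM) > 0 filter reduces to mean logv > 0.
    """
    n = len(z)
    logv = baselines[:, None] + shift \
        + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n))
    for idx, d in zip(truth["signal_idx"], truth["directions"]):
        logv[idx] += cfg.effect_size * d * z
    if strictly_positive:
        return 10.0 ** logv
    return np.maximum(10.0 ** logv - 1.0, 0.0)


def _cell_line_dataset(cfg: GeneratorConfig, baselines, truth, n: int,
                       prefix: str, tag: str, shift: float,
                       rng: np.random.Generator
                       ) -> tuple[ExpressionMatrix, DrugResponse]:
    z = rng.standard_normal(n)
    tpm = _expression(cfg, baselines, truth, z, shift, rng)
    samples = [f"{prefix}{i:03d}" for i in range(1, n + 1)]
    x = ExpressionMatrix(pd.DataFrame(tpm, index=truth["genes"],
                                      columns=samples),
                         cancer_type="synthetic", dataset_tag=tag)
    ic50 = np.exp(cfg.ic50_ln_sigma * z + cfg.ic50_ln_mu)
    r = DrugResponse.from_ic50("drugX", samples, ic50, scale="ln")
    return x, r


def generate_cell_line_pair(cfg: GeneratorConfig | None = None,
                            shared_signal: bool = True
                            ) -> tuple[CohortPair, dict]:
    """Paired cell-line cohorts with planted sensitivity-associated genes.

    Both datasets draw independent samples from the same gene model;
    dataset B adds ``batch_shift`` on the log scale.  With
    ``shared_signal=False`` dataset B plants a disjoint signal-gene set
    (a null construction for cross-prediction tests).  Returns the pair
    and a truth record listing signal genes and directions per dataset.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    truth_a = _truth(cfg, rng)
    if shared_signal:
        truth_b = truth_a
    else:
        free = np.setdiff1d(np.arange(cfg.n_genes), truth_a["signal_idx"])
        if len(free) < cfg.n_signal_genes:
            raise ValidationError("not enough genes for a disjoint signal set")
        idx_b = np.sort(rng.choice(free, size=cfg.n_signal_genes,
                                   replace=False))
        truth_b = dict(truth_a)
        truth_b["signal_idx"] = idx_b
        truth_b["signal_genes"] = [truth_a["genes"][i] for i in idx_b]
    baselines = _baselines(cfg, truth_a, rng)
    if not shared_signal:
        # give dataset B's signal genes marker-grade baselines too
        baselines[truth_b["signal_idx"]] = rng.normal(
            cfg.signal_base_mu, cfg.signal_base_sigma, size=cfg.n_signal_genes)
    xa, ra = _cell_line_dataset(cfg, baselines, truth_a, cfg.n_samples_a,
                                "A", "dataset_a", 0.0, rng)
    xb, rb = _cell_line_dataset(cfg, baselines, truth_b, cfg.n_samples_b,
                                "B", "dataset_b", cfg.batch_shift, rng)
    truth = {
        "signal_genes_a": truth_a["signal_genes"],
        "signal_genes_b": truth_b["signal_genes"],
        "directions": truth_a["directions"],
        "shared_signal": shared_signal,
    }
    return CohortPair(xa, ra, xb, rb), truth


def generate_patient_cohort(cfg: GeneratorConfig | None = None
                            ) -> tuple[ExpressionMatrix, DrugResponse, dict]:
    """Patient cohort with binary outcomes and class-shifted signal genes.

    Outcomes are assigned first (balanced: |n_eff - n_ineff| <= 1, order
    shuffled); each signal gene's log expression shifts by
    ``effect_size`` (alternating direction) in the effective class.
    """
    cfg = cfg or GeneratorConfig()
    if cfg.n_patients < 4:
        raise ValidationError("need at least 2 patients per outcome class")
    rng = np.random.default_rng(cfg.seed)
    truth = _truth(cfg, rng)
    baselines = _baselines(cfg, truth, rng)
    n = cfg.n_patients
    labels = np.array([EFFECTIVE] * (n - n // 2) + [INEFFECTIVE] * (n // 2),
                      dtype=object)
    rng.shuffle(labels)
    # class indicator plays the role of z: effective = +1, ineffective = 0
    z = (labels == EFFECTIVE).astype(float)
    tpm = _expression(cfg, baselines, truth, z, 0.0, rng,
                      strictly_positive=True)
    samples = [f"P{i:03d}" for i in range(1, n + 1)]
    x = ExpressionMatrix(pd.DataFrame(tpm, index=truth["genes"],
                                      columns=samples),
                         cancer_type="synthetic", dataset_tag="patients")
    r = DrugResponse("drugX", samples, "binary", label=labels)
    return x, r, {
        "signal_genes": truth["signal_genes"],
        "directions": truth["directions"],
    }


def generate_qpcr_readout(x: ExpressionMatrix,
                          model: ConversionModel | None = None,
                          cq_noise_sd: float = 0.0,
                          reference_cq: float = 20.0,
                          seed: int = 0) -> CqTable:
    """Cq table consistent with the linear conversion model.

    Cq(gene, sample) = reference_cq + tpm_to_dcq(TPM) + Gaussian noise;
    the reference gene column is the constant ``reference_cq``.  With
    ``cq_noise_sd = 0`` the readout inverts exactly back to the input
    TPM.
    """
    model = model or ConversionModel()
    if model.slope >= 0:
        raise ValidationError("conversion slope must be negative")
    if cq_noise_sd < 0:
        raise ValidationError("cq_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    dcq = tpm_to_dcq(x.values.to_numpy(dtype=float), model)
    cq = reference_cq + dcq
    if cq_noise_sd > 0:
        cq = cq + rng.normal(0.0, cq_noise_sd, size=cq.shape)
    df = pd.DataFrame(cq.T, index=x.samples, columns=x.genes)
    if model.reference_gene in df.columns:
        raise ValidationError(
            f"expression matrix already contains {model.reference_gene!r}")
    df[model.reference_gene] = reference_cq
    return CqTable(cq=df, reference_gene=model.reference_gene)
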