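"""Synthetic paired FF/FFPE expression data.

The generator produces every input the REO pipeline consumes, with the
statistical structure the analysis assumes:

* **FF cohorts** — log-linear expression: gene g in sample s is
  ``exp(mu_g + eps_gs)`` with per-gene log-means ``mu_g ~
  Uniform(-mu_log_spread, +mu_log_spread)`` and within-sample noise
  ``eps ~ N(0, sample_sd^2)``.  The uniform log-mean spread keeps the
  rank density constant across the expression range, so implanted
  effects translate into rank differences the same way wherever they
  sit, and it is wide enough relative to the noise that most gene-pair
  orderings are stable across samples.
* **FFPE degradation** — a gene-specific log-scale shift ``delta_g ~
  N(0, deg_shift_sd^2)`` drawn once per gene universe (so two "tissues"
  built on the same universe share it — degradation is a property of the
  gene, not the tissue) plus per-measurement FFPE noise
  ``eta ~ N(0, deg_noise_sd^2)``.  Large ``|delta_g|`` produces the
  multi-fold expression shifts seen in archival material while leaving
  most pair orderings intact, since flipping a pair requires the shift
  difference to overcome the pair's log-mean separation.  Storage time
  optionally inflates the noise: ``sd_eff = deg_noise_sd * (1 +
  storage_slope * storage_years)``.
* **Two-phenotype cohorts** — class-invariant means for all genes except
  a set of implanted reversal pairs: for pair (a, b) with effect size
  ``delta`` and centre c, class 0 gets log-means ``c ± delta/2`` (a above
  b) and class 1 the mirror image, flipping the pair's expected ordering.
  Default pair centres are spaced ``1.2 * delta`` apart: because each
  implanted gene sweeps only the interval ``[c - delta/2, c + delta/2]``,
  centre separation beyond ``delta`` guarantees that no cross-pair
  between two different implants reverses, and any incidental reversal
  against a background gene inside the interval has at most a quarter of
  the implanted pair's avgRij (the sub-spans on either side of the
  background gene multiply to at most ``(delta/2)^2``).  The implanted
  pairs are therefore the unique top-scoring reversal pairs by design.

All randomness flows from ``seed`` through named substreams, so an
identical config reproduces bit-identical matrices.  ``noise_seed``
(when set) reseeds only the sampling noise, yielding fresh "patients"
from the same gene universe, degradation profile and implanted effects —
the way an independent validation cohort relates to a training cohort.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, PairedCohort
from .ranking import ReoError

__all__ = [
    "GeneratorConfig",
    "gene_means",
    "degradation_shifts",
    "make_ff_cohort",
    "degrade_to_ffpe",
    "make_two_class_cohort",
    "TwoClassCohort",
]

# substream keys (structural draws reuse `seed` even when noise_seed is set)
_K_MU = 0
_K_FF_NOISE = 1
_K_DEG_SHIFT = 2
_K_FFPE_NOISE = 3
_K_CLASS0_NOISE = 4
_K_CLASS1_NOISE = 5


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic paired FF/FFPE generator.

    Defaults are the package's reference study conditions: 2,000 genes,
    80 samples per cohort, uniform log-mean spread of +/-4.5 (natural
    log), sample noise 0.4, degradation shift sd 0.45 (~12% of genes
    past 2-fold), FFPE noise 0.3 (expected FF/FFPE pair consistency
    around 90%, mirroring archival-material observations), five
    implanted reversal pairs at log effect size 1.5.
    """

    n_genes: int = 2000
    n_samples: int = 80
    seed: int = 0
    noise_seed: int | None = None
    mu_log_spread: float = 4.5
    sample_sd: float = 0.4
    deg_shift_sd: float = 0.45
    deg_noise_sd: float = 0.3
    storage_years: float = 0.0
    storage_slope: float = 0.0
    n_reversal_pairs: int = 5
    reversal_delta: float = 1.5
    reversal_pairs: tuple[tuple[str, str, float], ...] | None = None

    def __post_init__(self):
        if self.n_genes < 2:
            raise ReoError("n_genes must be >= 2")
        if self.n_samples < 1:
            raise ReoError("n_samples must be >= 1")
        for name in ("mu_log_spread", "sample_sd", "deg_shift_sd", "deg_noise_sd"):
            if getattr(self, name) < 0:
                raise ReoError(f"{name} must be >= 0")
        if self.reversal_pairs is not None:
            ids = set(gene_ids(self.n_genes))
            for a, b, _ in self.reversal_pairs:
                if a == b:
                    raise ReoError(f"implanted pair references one gene: {a}")
                if a not in ids or b not in ids:
                    raise ReoError(f"implanted pair gene not in universe: {a},{b}")

    @property
    def effective_deg_noise_sd(self) -> float:
        return self.deg_noise_sd * (1.0 + self.storage_slope * self.storage_years)

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


def gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def _rng(cfg: GeneratorConfig, key: int, structural: bool) -> np.random.Generator:
    seed = cfg.seed if structural or cfg.noise_seed is None else cfg.noise_seed
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def gene_means(cfg: GeneratorConfig) -> np.ndarray:
    """Per-gene log-scale means mu_g, fixed by the structural seed."""
    return _rng(cfg, _K_MU, True).uniform(
        -cfg.mu_log_spread, cfg.mu_log_spread, cfg.n_genes
    )


def degradation_shifts(cfg: GeneratorConfig) -> np.ndarray:
    """Gene-specific log-scale degradation shifts delta_g, drawn once per
    gene universe and shared by every cohort built on it."""
    return _rng(cfg, _K_DEG_SHIFT, True).normal(
        0.0, cfg.deg_shift_sd, cfg.n_genes
    )


def _sample_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:03d}" for i in range(n)]


def make_ff_cohort(cfg: GeneratorConfig, sample_prefix: str = "S") -> ExpressionMatrix:
    """A fresh-frozen cohort: exp(mu_g + eps_gs), eps ~ N(0, sample_sd^2)."""
    mu = gene_means(cfg)
    eps = _rng(cfg, _K_FF_NOISE, False).normal(
        0.0, cfg.sample_sd, (cfg.n_genes, cfg.n_samples)
    )
    values = np.exp(mu[:, None] + eps)
    return ExpressionMatrix.from_arrays(
        values, gene_ids(cfg.n_genes), _sample_ids(sample_prefix, cfg.n_samples)
    )


def degrade_to_ffpe(ff: ExpressionMatrix, cfg: GeneratorConfig) -> PairedCohort:
    """Degrade an FF matrix into its paired FFPE profile.

    FFPE value = exp(log FF + delta_g + eta_gs); the pairing is the
    identity on sample order.  Log-space construction keeps values
    strictly positive, so degradation can never create zeros or flip a
    value's sign.
    """
    if ff.n_genes != cfg.n_genes:
        raise ReoError("FF matrix gene count does not match the config")
    delta = degradation_shifts(cfg)
    eta = _rng(cfg, _K_FFPE_NOISE, False).standard_normal(
        (ff.n_genes, ff.n_samples)
    )
    values = np.exp(
        np.log(ff.values) + delta[:, None] + cfg.effective_deg_noise_sd * eta
    )
    ffpe_ids = [f"{s}_FFPE" for s in ff.sample_ids]
    ffpe = ExpressionMatrix.from_arrays(values, ff.gene_ids, ffpe_ids)
    pairing = tuple(zip(ff.sample_ids, ffpe_ids))
    return PairedCohort(ff=ff, ffpe=ffpe, pairing=pairing)


@dataclass(frozen=True)
class TwoClassCohort:
    """Two phenotype cohorts plus the implanted reversal-pair truth
    (gene_a, gene_b, delta) with gene_a the class-0-high gene."""

    class0: ExpressionMatrix
    class1: ExpressionMatrix
    implanted: tuple[tuple[str, str, float], ...]


def _default_reversal_pairs(cfg: GeneratorConfig, mu: np.ndarray):
    """Implant centres spaced 1.2 * delta apart around the middle of the
    log-mean range; each pair takes the two unused genes nearest its
    centre.  Centre separation beyond delta prevents reversals between
    genes of different implants, so the implants stay the unique
    top-scoring pairs (see module docstring).  Returns ((gene_a, gene_b,
    centre, delta), ...) with gene_a the class-0-high gene."""
    m = cfg.n_reversal_pairs
    spacing = 1.2 * cfg.reversal_delta
    centres = (np.arange(m) - (m - 1) / 2.0) * spacing
    ids = gene_ids(cfg.n_genes)
    used: set[int] = set()
    pairs = []
    for c in centres:
        order = np.argsort(np.abs(mu - c), kind="stable")
        picked = [int(i) for i in order if int(i) not in used][:2]
        if len(picked) < 2:
            raise ReoError("not enough genes to implant the requested pairs")
        used.update(picked)
        pairs.append((ids[picked[0]], ids[picked[1]], float(c), cfg.reversal_delta))
    return tuple(pairs)


def make_two_class_cohort(cfg: GeneratorConfig) -> TwoClassCohort:
    """Two cohorts sharing class-invariant means except at the implanted
    reversal pairs, whose expected ordering flips between classes."""
    mu = gene_means(cfg)
    ids = gene_ids(cfg.n_genes)
    idx = {g: i for i, g in enumerate(ids)}
    if cfg.reversal_pairs is not None:
        # explicit pairs: centre at the midpoint of the two genes' means
        pairs = tuple(
            (a, b, 0.5 * (mu[idx[a]] + mu[idx[b]]), delta)
            for a, b, delta in cfg.reversal_pairs
        )
    else:
        pairs = _default_reversal_pairs(cfg, mu)
    if not pairs:
        raise ReoError("two-class generation needs at least one implanted pair")

    flat = [g for a, b, _, _ in pairs for g in (a, b)]
    if len(set(flat)) != len(flat):
        logging.getLogger(__name__).info(
            "implanted reversal pairs share genes: %s",
            sorted({g for g in flat if flat.count(g) > 1}),
        )

    mu0 = mu.copy()
    mu1 = mu.copy()
    implanted: list[tuple[str, str, float]] = []
    for a, b, c, delta in pairs:
        ia, ib = idx[a], idx[b]
        mu0[ia], mu0[ib] = c + delta / 2.0, c - delta / 2.0
        mu1[ia], mu1[ib] = c - delta / 2.0, c + delta / 2.0
        implanted.append((a, b, float(delta)))

    eps0 = _rng(cfg, _K_CLASS0_NOISE, False).normal(
        0.0, cfg.sample_sd, (cfg.n_genes, cfg.n_samples)
    )
    eps1 = _rng(cfg, _K_CLASS1_NOISE, False).normal(
        0.0, cfg.sample_sd, (cfg.n_genes, cfg.n_samples)
    )
    class0 = ExpressionMatrix.from_arrays(
        np.exp(mu0[:, None] + eps0), ids, _sample_ids("C0S", cfg.n_samples)
    )
    class1 = ExpressionMatrix.from_arrays(
        np.exp(mu1[:, None] + eps1), ids, _sample_ids("C1S", cfg.n_samples)
    )
    return TwoClassCohort(class0, class1, tuple(implanted))
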