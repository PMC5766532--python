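"""Synthetic metabolomics matrices with realistic statistical structure.

Metabolite abundances are positive and right-skewed, with strong
between-metabolite correlation (shared pathways, shared sample physiology).
The generator reproduces this with an exponentiated low-rank factor model on
the log scale:

    log X = scores @ loadings + group_shift + noise

where the first latent factor carries per-metabolite baseline offsets with
near-unit per-sample scores (dilution-like variability; metabolites span
concentration ranges and the noiseless log-matrix has rank exactly
``latent_rank``), the remaining
factors induce between-metabolite correlation, an optional mean shift on a
subset of metabolites distinguishes two balanced phenotype groups, and the
residual is i.i.d. Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._types import AbundanceMatrix, GroupLabels

__all__ = ["SynthSpec", "generate_complete"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the log-normal factor model.

    noise_sd and effect_size are on the natural-log scale; effect_size is
    the mean shift applied to the first ``n_affected`` metabolites in the
    second group.
    """

    n_samples: int = 100
    n_metabolites: int = 50
    latent_rank: int = 5
    noise_sd: float = 0.1
    n_affected: int = 0
    effect_size: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_metabolites < 1:
            raise ValueError("need at least 2 samples and 1 metabolite")
        if not 1 <= self.latent_rank <= min(self.n_samples, self.n_metabolites):
            raise ValueError(
                "latent_rank must be in [1, min(n_samples, n_metabolites)]"
            )
        if not 0 <= self.n_affected <= self.n_metabolites:
            raise ValueError("n_affected must be in [0, n_metabolites]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_complete(spec: SynthSpec) -> tuple[AbundanceMatrix, GroupLabels]:
    """Draw one complete (no missing values) matrix plus balanced labels.

    Fully reproducible from ``spec.seed``. Values are strictly positive.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, r = spec.n_samples, spec.n_metabolites, spec.latent_rank

    # The baseline log-abundance offsets ride on the first latent factor,
    # whose per-sample score is near 1 (dilution-like variability), so the
    # noiseless log-matrix has rank exactly latent_rank and columns span
    # distinct concentration ranges.
    offsets = rng.uniform(1.0, 5.0, size=p)
    scores = np.column_stack(
        [rng.normal(1.0, 0.2, size=n), rng.standard_normal((n, r - 1))]
    )
    loadings = np.vstack([offsets, rng.standard_normal((r - 1, p))])

    # balanced case/control split, first half control
    labels = np.array(["control"] * (n - n // 2) + ["case"] * (n // 2))
    indicator = (labels == "case").astype(float)

    shift = np.zeros(p)
    shift[: spec.n_affected] = spec.effect_size

    log_x = (
        scores @ loadings
        + np.outer(indicator, shift)
        + rng.normal(0.0, spec.noise_sd, size=(n, p))
    )

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    metabolite_ids = [f"M{j + 1:04d}" for j in range(p)]
    matrix = AbundanceMatrix(np.exp(log_x), sample_ids, metabolite_ids)
    return matrix, GroupLabels(labels)
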