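"""Synthetic grouped expression data with tunable inter-sample heterogeneity.

The generator emulates a normalised log2-scale expression matrix with a
modular correlation structure and two equal-size sample groups, one of
which ("case") carries inflated within-group dispersion.  It exists so
that every downstream stage — dissimilarities, persistence, permutation
tests, Mahalanobis analysis — has a ground-truthed input whose
heterogeneity is known by construction.

Generative model (fixed)
------------------------
Genes are assigned round-robin to ``n_modules`` co-expression modules.
For gene *i* in module *m* and sample *s*::

    x[i, s] = baseline[i] + module_strength * z[m, s] + sigma[i, s] * e[i, s]

with ``baseline[i] ~ Normal(8, 1)`` (a plausible log2 intensity),
module latent factors ``z[m, s] ~ Normal(0, 1)`` drawn independently
per sample, and residuals ``e[i, s] ~ Normal(0, noise_sd)``.  The
dispersion multiplier ``sigma`` is 1 everywhere except in the case
group, where it equals ``heterogeneity`` — for all genes, or only for
the affected subset when ``restricted`` is on.  Group means are equal
by construction, so heterogeneity enlarges inter-sample distances
without creating differential-expression signal.

Three independent sub-streams (gene layout, factors, noise) are derived
deterministically from the seed, so changing ``n_per_group`` does not
reshuffle gene baselines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleMetadata,
    write_expression,
    write_gmt,
    write_metadata,
)

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "write_fixture",
           "CONTROL_LABEL", "CASE_LABEL"]

CONTROL_LABEL = "control"
CASE_LABEL = "case"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic expression generator.

    With ``heterogeneity == 1`` the two groups are exchangeable
    (identical generative law), which is the null condition used for
    type-I calibration.
    """

    n_genes: int = 200
    n_per_group: int = 20
    n_modules: int = 5
    module_strength: float = 0.5
    noise_sd: float = 0.5
    heterogeneity: float = 1.0
    affected_fraction: float = 0.0
    restricted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_per_group < 1 or self.n_modules < 1:
            raise ValidationError("n_genes, n_per_group, n_modules must be >= 1")
        if not 0.0 <= self.module_strength < 1.0:
            raise ValidationError("module_strength must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.heterogeneity < 1:
            raise ValidationError("heterogeneity must be >= 1")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValidationError("affected_fraction must be in [0, 1]")
        if self.restricted and self.affected_fraction == 0.0:
            raise ValidationError("restricted mode needs affected_fraction > 0")


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    metadata: SampleMetadata
    affected_genes: tuple[str, ...]
    truth: SyntheticConfig = field(repr=False)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset from the generative model (deterministic in seed).

    The affected-gene count in restricted mode is
    ``floor(affected_fraction * n_genes)``.
    """
    ss = np.random.SeedSequence(config.seed)
    gene_stream, factor_stream, noise_stream = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )
    g, n = config.n_genes, config.n_per_group
    gene_ids = tuple(f"G{i:05d}" for i in range(g))
    sample_ids = tuple(
        [f"{CONTROL_LABEL}_{j:03d}" for j in range(n)]
        + [f"{CASE_LABEL}_{j:03d}" for j in range(n)]
    )
    assignment = {s: (CONTROL_LABEL if j < n else CASE_LABEL)
                  for j, s in enumerate(sample_ids)}

    module_of = np.arange(g) % config.n_modules
    baseline = gene_stream.normal(8.0, 1.0, size=g)
    if config.restricted:
        n_aff = math.floor(config.affected_fraction * g)
        aff_idx = np.sort(gene_stream.choice(g, size=n_aff, replace=False))
    else:
        aff_idx = np.array([], dtype=int)
    affected = tuple(gene_ids[i] for i in aff_idx)

    z = factor_stream.normal(0.0, 1.0, size=(config.n_modules, 2 * n))
    e = noise_stream.normal(0.0, config.noise_sd, size=(g, 2 * n))

    sigma = np.ones((g, 2 * n))
    case_cols = np.arange(n, 2 * n)
    if config.restricted:
        sigma[np.ix_(aff_idx, case_cols)] = config.heterogeneity
    else:
        sigma[:, case_cols] = config.heterogeneity

    values = baseline[:, None] + config.module_strength * z[module_of, :] + sigma * e
    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    return SyntheticDataset(expr, SampleMetadata(assignment), affected,
                            replace(config))


def write_fixture(dataset: SyntheticDataset, directory: str | Path,
                  n_decoys: int = 5, decoy_seed: int = 0) -> dict[str, Path]:
    """Write a dataset as the TSV/CSV/GMT files the readers consume.

    The GMT (written only when the dataset has affected genes) contains
    one set named ``"affected"`` plus ``n_decoys`` decoy sets of the
    same size drawn from the unaffected genes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": write_expression(dataset.expression,
                                       directory / "expression.tsv"),
        "metadata": write_metadata(dataset.metadata, directory / "metadata.csv"),
    }
    if dataset.affected_genes:
        rng = np.random.default_rng(decoy_seed)
        unaffected = [gid for gid in dataset.expression.gene_ids
                      if gid not in set(dataset.affected_genes)]
        size = len(dataset.affected_genes)
        sets = {"affected": GeneSet("affected", "genes with extra case dispersion",
                                    tuple(dataset.affected_genes))}
        for k in range(n_decoys):
            picked = rng.choice(len(unaffected), size=min(size, len(unaffected)),
                                replace=False)
            sets[f"decoy_{k}"] = GeneSet(
                f"decoy_{k}", "size-matched unaffected genes",
                tuple(unaffected[i] for i in np.sort(picked)))
        paths["gmt"] = write_gmt(GeneSetCollection(sets), directory / "genesets.gmt")
    return paths
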