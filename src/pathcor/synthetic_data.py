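"""Synthetic multi-experiment expression backgrounds with known structure.

The generator plants coexpression modules with a Gaussian latent-factor
model: per experiment and sample, module factors are drawn from a zero-mean
normal with a user-supplied correlation matrix, and each gene is

    x_g = loading_m * f_m + eps_g          (gene g in module m)
    x_g = eps_g                            (background gene)

with eps_g ~ N(0, noise_sd^2) independent.  Because the downstream pipeline
works on within-array ranks, no attempt is made to mimic microarray intensity
distributions; Gaussian margins are sufficient.  Confounded-pair fixtures
plant two annotations whose only generative dependence is a coexpressed
shared gene block, the situation the shared-gene adjustment is meant to null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ExperimentGrouping, GeneSet, GeneSetCollection


@dataclass
class SyntheticSpec:
    """Description of a synthetic expression background.

    n_genes : size K of the gene universe.
    experiments : samples per experiment, e.g. ``[30] * 10``.
    modules : ``(start, stop, loading)`` half-open gene-index blocks; one
        latent factor (and one emitted gene set) per block.
    module_correlation_matrix : target correlation among the module factors
        (symmetric PSD, unit diagonal); identity when omitted.
    noise_sd : standard deviation of the independent gene-level noise.
    seed : seed for every random draw.
    """

    n_genes: int
    experiments: Sequence[int]
    modules: Sequence[tuple[int, int, float]] = field(default_factory=list)
    module_correlation_matrix: np.ndarray | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        for start, stop, _ in self.modules:
            if not (0 <= start < stop <= self.n_genes):
                raise ValueError(f"module block [{start}, {stop}) outside 0..{self.n_genes}")
        m = len(self.modules)
        if self.module_correlation_matrix is not None:
            C = np.asarray(self.module_correlation_matrix, float)
            if C.shape != (m, m):
                raise ValueError(f"correlation matrix shape {C.shape} != ({m}, {m})")
            if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
                raise ValueError("correlation matrix must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ValueError("module correlation matrix is not positive semi-definite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        return self


def _factor_root(C: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root used to impose the factor correlation."""
    w, v = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w) @ v.T


def gene_ids(n_genes: int) -> list[str]:
    width = len(str(n_genes))
    return [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]


def generate_background(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, ExperimentGrouping, GeneSetCollection]:
    """Draw an expression background, its grouping, and module gene sets."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    K = spec.n_genes
    m = len(spec.modules)
    genes = gene_ids(K)

    C = (
        np.eye(m)
        if spec.module_correlation_matrix is None
        else np.asarray(spec.module_correlation_matrix, float)
    )
    root = _factor_root(C) if m else None

    columns: list[str] = []
    mapping: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    ewidth = len(str(len(spec.experiments)))
    for e_idx, n_i in enumerate(spec.experiments, start=1):
        exp_id = f"e{e_idx:0{ewidth}d}"
        X = rng.normal(0.0, spec.noise_sd, size=(K, n_i))
        if m:
            F = rng.standard_normal(size=(n_i, m)) @ root  # factors, corr C
            for j, (start, stop, loading) in enumerate(spec.modules):
                X[start:stop] += loading * F[:, j][None, :]
        blocks.append(X)
        for s_idx in range(1, n_i + 1):
            sid = f"{exp_id}_s{s_idx:03d}"
            columns.append(sid)
            mapping[sid] = exp_id

    expr = pd.DataFrame(np.hstack(blocks), index=genes, columns=columns)
    sets = [
        GeneSet(f"module_{j + 1}", f"planted module {j + 1}", tuple(genes[start:stop]))
        for j, (start, stop, _) in enumerate(spec.modules)
    ]
    return expr, ExperimentGrouping(mapping), GeneSetCollection(sets)


def generate_confounded_pair(
    n_unique: int = 10,
    n_shared: int = 10,
    n_background: int = 200,
    experiments: Sequence[int] = (30,) * 5,
    loading: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, ExperimentGrouping, GeneSetCollection]:
    """Two annotations whose association is driven purely by shared genes.

    Each pathway is ``n_unique`` pure-noise genes plus a common coexpressed
    block of ``n_shared`` genes (a single latent factor with the given
    loading).  The unadjusted summary correlation is large because both
    summaries contain the same shared-block signal, while the generative
    dependence between the unique parts is exactly zero -- conditioning on
    the shared-gene summary should null the association.
    """
    K = 2 * n_unique + n_shared + n_background
    spec = SyntheticSpec(
        n_genes=K,
        experiments=list(experiments),
        modules=[(2 * n_unique, 2 * n_unique + n_shared, loading)] if n_shared else [],
        noise_sd=noise_sd,
        seed=seed,
    )
    expr, grouping, _ = generate_background(spec)
    genes = list(expr.index)
    unique_a = genes[:n_unique]
    unique_b = genes[n_unique : 2 * n_unique]
    shared = genes[2 * n_unique : 2 * n_unique + n_shared]
    collection = GeneSetCollection(
        [
            GeneSet("pathway_A", "unique noise block A + shared block", tuple(unique_a + shared)),
            GeneSet("pathway_B", "unique noise block B + shared block", tuple(unique_b + shared)),
        ]
    )
    return expr, grouping, collection
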