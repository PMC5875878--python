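"""Run configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class RunConfig:
    """Tunable parameters of a network build / benchmark run.

    alpha : FDR cutoff for edge significance (on BH-adjusted combined p).
    min_experiment_size : experiments with fewer samples are excluded so the
        conditioned t-test keeps at least 2 degrees of freedom.
    min_genes_measured : gene sets with fewer measured members are excluded
        (a single-gene set makes shared-gene conditioning degenerate).
    collapse : probe-collapse rule, 'mean' or 'max_mean'.
    shrink : 'pre' (analytic shrinkage before conditioning) or 'off'.
    bin_step : bin-size increment of the enrichment-proportion curve.
    steps : stepping-overlap indices exercised by the validation benchmark;
        None selects the three canonical configurations (t = 33, 78, 123 on a
        126-gene set, overlap coefficients 0.8532 / 0.5517 / 0.0469), scaled
        proportionally to the structured set's size.
    """

    alpha: float = 0.05
    min_experiment_size: int = 5
    min_genes_measured: int = 2
    collapse: str = "mean"
    shrink: str = "pre"
    bin_step: int = 10
    steps: tuple[int, ...] | None = None
    seed: int = 0

    def validate(self) -> "RunConfig":
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.min_experiment_size < 4:
            raise ValueError("min_experiment_size must be >= 4 (df = n-3 >= 1)")
        if self.min_genes_measured < 1:
            raise ValueError("min_genes_measured must be >= 1")
        if self.collapse not in ("mean", "max_mean"):
            raise ValueError(f"unknown collapse rule {self.collapse!r}")
        if self.shrink not in ("pre", "off"):
            raise ValueError(f"unknown shrink mode {self.shrink!r}")
        if self.bin_step < 1:
            raise ValueError("bin_step must be >= 1")
        if self.steps is not None and any(t < 1 for t in self.steps):
            raise ValueError("step indices must be >= 1")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["steps"] = None if self.steps is None else list(self.steps)
        return d
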