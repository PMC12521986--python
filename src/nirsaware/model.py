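"""Model-style front end: build a responsiveness model from recordings,
fit it, and inspect the results.

`ResponsivenessModel` wraps the full diagnostic procedure behind a fit/
results interface: the model is constructed from the raw runs of one
participant-state, ``fit()`` runs preprocessing, the hyperparameter search
and the permutation tests, and the returned :class:`ResponsivenessResults`
carries per-chromophore accuracies, null distributions, p-values, the
min-P diagnosis, and a text ``summary()``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .diagnose import (
    CHROMOPHORES,
    DEFAULT_ALPHA,
    DEFAULT_N_PERMUTATIONS,
    DiagnosisResult,
    run_full_diagnosis,
)
from .io import RawRecording, read_snirf
from .preprocess import PreprocessConfig

__all__ = ["ResponsivenessModel", "ResponsivenessResults"]


class ResponsivenessModel:
    """Awareness-detection model for one participant-state dataset.

    Parameters
    ----------
    runs
        The raw two-wavelength recordings (typically two runs) to pool.
    config
        Preprocessing parameters; defaults follow the standard chain.
    alpha
        Decision threshold on the minimum empirical p-value.
    """

    def __init__(self, runs: list[RawRecording],
                 config: PreprocessConfig | None = None,
                 alpha: float = DEFAULT_ALPHA) -> None:
        if not runs:
            raise ValueError("need at least one run")
        self.runs = list(runs)
        self.config = config or PreprocessConfig()
        self.alpha = alpha

    @classmethod
    def from_snirf(cls, paths: list[str | Path], **kwargs) -> "ResponsivenessModel":
        return cls([read_snirf(p) for p in paths], **kwargs)

    def fit(self, n_permutations: int = DEFAULT_N_PERMUTATIONS,
            seed: int = 0) -> "ResponsivenessResults":
        """Run the full diagnosis and return the results object."""
        diag = run_full_diagnosis(
            self.runs, config=self.config, n_permutations=n_permutations,
            alpha=self.alpha, seed=seed,
        )
        return ResponsivenessResults(self, diag)


class ResponsivenessResults:
    """Fitted diagnosis: accuracies, p-values and the responsiveness label."""

    def __init__(self, model: ResponsivenessModel,
                 diagnosis: DiagnosisResult) -> None:
        self.model = model
        self.diagnosis = diagnosis

    @property
    def label(self) -> str:
        return self.diagnosis.label

    @property
    def p_min(self) -> float:
        return self.diagnosis.p_min

    @property
    def accuracies(self) -> dict[str, float]:
        return {c: r.observed_accuracy
                for c, r in self.diagnosis.chromophore_results.items()}

    @property
    def p_values(self) -> dict[str, float]:
        return {c: r.p_value
                for c, r in self.diagnosis.chromophore_results.items()}

    def summary(self) -> str:
        """Human-readable report of the fitted diagnosis."""
        d = self.diagnosis
        lines = [
            "Responsiveness diagnosis",
            "=" * 61,
            f"{'feature set':<12}{'model':<14}{'CV accuracy':>12}"
            f"{'null mean':>11}{'p-value':>10}",
            "-" * 61,
        ]
        for c in CHROMOPHORES:
            r = d.chromophore_results[c]
            ms = (f"f={r.modelspec.n_filters}, C={r.modelspec.C:g}"
                  if r.modelspec else "-")
            lines.append(
                f"{c:<12}{ms:<14}{r.observed_accuracy:>12.1%}"
                f"{np.mean(r.null_accuracies):>11.1%}{r.p_value:>10.4f}"
            )
        lines += [
            "-" * 61,
            f"min p-value: {d.p_min:.4f}   threshold: {d.alpha:g}",
            f"diagnosis:   {d.label}",
        ]
        return "\n".join(lines)

    def plot_null_distributions(self, ax=None):
        """Histogram of the permutation nulls with the observed accuracies."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for c in CHROMOPHORES:
            r = self.diagnosis.chromophore_results[c]
            ax.hist(r.null_accuracies, bins=20, alpha=0.4, label=f"{c} null")
            ax.axvline(r.observed_accuracy, linestyle="--")
        ax.set_xlabel("cross-validation accuracy")
        ax.set_ylabel("permutations")
        ax.legend()
        return ax

    def save_json(self, path: str | Path) -> None:
        self.diagnosis.save_json(path)
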