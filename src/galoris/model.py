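"""Model-style front end to the genetic-algorithm feature selector.

:class:`GALoRIS` is built from a feature matrix and binary workload
labels; :meth:`GALoRIS.fit` runs the evolutionary search and returns a
:class:`GALoRISResults` carrying the selected feature set, the fitted
logistic coefficients with their Wald p-values, the per-generation search
history, and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import BandFeatureMatrix
from .ga import Chromosome, GaConfig, StructuredDataset, decode_chromosome, run_galoris
from .screening import SearchSpace, build_search_space

__all__ = ["GALoRIS", "GALoRISResults"]


class GALoRIS:
    """Wrapper feature-selection model over a band-power feature matrix.

    Parameters
    ----------
    features
        Samples x features table (``BandFeatureMatrix`` or DataFrame with
        ``Band_Channel`` columns).
    labels
        Binary workload labels, 1 = high workload.
    search_space
        Columns the search may select from.  When omitted, the per-column
        two-task t-test screen at ``screen_alpha`` defines it from the
        data.
    config
        Genetic-algorithm parameters; defaults to the study configuration.
    """

    def __init__(
        self,
        features: BandFeatureMatrix | pd.DataFrame,
        labels: np.ndarray,
        search_space: SearchSpace | None = None,
        config: GaConfig | None = None,
        screen_alpha: float = 0.05,
    ) -> None:
        if isinstance(features, pd.DataFrame):
            features = BandFeatureMatrix(features)
        self.features = features
        self.labels = np.asarray(labels, dtype=int)
        if len(self.labels) != features.n_samples:
            raise ValueError("labels and features disagree on sample count")
        if search_space is None:
            search_space = build_search_space(features, self.labels, alpha=screen_alpha)
        self.search_space = search_space
        self.config = config if config is not None else GaConfig()

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        label_column: str = "label",
        **kwargs,
    ) -> "GALoRIS":
        """Build from one table whose ``label_column`` holds the labels."""
        if label_column not in frame.columns:
            raise KeyError(f"no {label_column!r} column in the frame")
        labels = frame[label_column].to_numpy(dtype=int)
        features = frame.drop(columns=[label_column])
        return cls(features, labels, **kwargs)

    def fit(self) -> "GALoRISResults":
        """Run the evolutionary search and package the outcome."""
        best, structured, history = run_galoris(
            self.features, self.labels, self.search_space, self.config
        )
        return GALoRISResults(self, best, structured, history)


class GALoRISResults:
    """Outcome of a fitted :class:`GALoRIS` search."""

    def __init__(
        self,
        model: GALoRIS,
        best_chromosome: Chromosome,
        structured_dataset: StructuredDataset,
        history: pd.DataFrame,
    ) -> None:
        self.model = model
        self.best_chromosome = best_chromosome
        self.structured_dataset = structured_dataset
        self.history = history

    @property
    def selected_features(self) -> list[str]:
        return decode_chromosome(self.best_chromosome.genes, self.model.search_space)

    @property
    def n_features_in(self) -> int:
        return len(self.model.search_space)

    @property
    def n_features_selected(self) -> int:
        return self.best_chromosome.ap_n_genes

    @property
    def reduction_percent(self) -> float:
        """Percent of search-space columns discarded by the selection."""
        return 100.0 * (1.0 - self.n_features_selected / self.n_features_in)

    @property
    def accuracy(self) -> float:
        return self.best_chromosome.ap_accuracy

    @property
    def error_rate(self) -> float:
        return self.best_chromosome.ap_error_rate

    @property
    def params(self) -> pd.Series:
        """Intercept and per-selected-feature logistic coefficients."""
        best = self.best_chromosome
        index = ["intercept"] + self.selected_features
        values = np.concatenate([[best.intercept], best.coefficients])
        return pd.Series(values, index=index, name="coef")

    @property
    def pvalues(self) -> pd.Series:
        """Wald p-values of the selected features' coefficients (NaN when
        the fit needed ridge stabilization)."""
        return pd.Series(
            self.best_chromosome.p_values, index=self.selected_features, name="p_value"
        )

    def summary(self) -> str:
        """Plain-text report in the spirit of a regression results table."""
        best = self.best_chromosome
        alpha = self.model.config.alpha
        lines = [
            "GALoRIS feature-selection results",
            "=" * 54,
            f"Search space:        {self.n_features_in} features",
            f"Selected:            {self.n_features_selected} features "
            f"({self.reduction_percent:.0f}% reduction)",
            f"Fit accuracy:        {best.ap_accuracy:.4f}",
            f"Fit error rate:      {best.ap_error_rate:.4f}",
            f"Generations run:     {int(self.history['generation'].iloc[-1])}",
            f"Ridge fallback:      {best.ridge_fallback}",
            "-" * 54,
            f"{'feature':<16}{'coef':>12}{'p-value':>14}  sig",
            "-" * 54,
        ]
        pvals = self.pvalues
        for name, coef in self.params.items():
            if name == "intercept":
                lines.append(f"{name:<16}{coef:>12.4f}{'':>14}")
                continue
            p = pvals[name]
            flag = "*" if np.isfinite(p) and p <= alpha else ""
            p_txt = f"{p:.3e}" if np.isfinite(p) else "nan"
            lines.append(f"{name:<16}{coef:>12.4f}{p_txt:>14}  {flag}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Best and mean fitness accuracy per generation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["generation"], self.history["best_accuracy"], label="best")
        ax.plot(self.history["generation"], self.history["mean_accuracy"], label="mean")
        ax.set_xlabel("generation")
        ax.set_ylabel("fit accuracy")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax
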