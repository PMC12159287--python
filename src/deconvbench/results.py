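"""Result container shared by all deconvolution models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ProportionMatrix

__all__ = ["DeconvolutionResult"]


@dataclass
class DeconvolutionResult:
    """Estimated cell-type proportions plus per-sample diagnostics.

    Attributes
    ----------
    proportions : ProportionMatrix
        The estimate P-hat, columns on the simplex.
    method : str
        Label of the solver that produced the estimate.
    diagnostics : pandas.DataFrame
        One row per sample; always carries ``residual`` (fit residual norm
        per sample), solver-specific columns may be added (e.g. the chosen
        nu per sample, convergence flags).
    warnings : list of str
        Non-fatal solver warnings (clipped samples, non-convergence).
    """

    proportions: ProportionMatrix
    method: str
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    warnings: list[str] = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return self.proportions.values

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        p = self.proportions
        lines = [
            f"Deconvolution results: {self.method}",
            "=" * 46,
            f"cell types: {p.n_types}    samples: {p.n_samples}",
        ]
        if "residual" in self.diagnostics:
            res = self.diagnostics["residual"].to_numpy(dtype=float)
            lines.append(f"mean fit residual: {np.mean(res):.6g}")
        lines.append("-" * 46)
        lines.append(f"{'cell type':<20}{'mean':>8}{'sd':>9}{'min':>9}")
        for k, name in enumerate(p.type_names):
            row = p.values[k]
            lines.append(
                f"{name:<20}{row.mean():>8.4f}{row.std():>9.4f}{row.min():>9.4f}"
            )
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)
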