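"""Per-array linear normalization of log2 ratios.

Two-color arrays hybridized separately have array-specific location (and
possibly scale) biases; a per-column affine adjustment makes the log2 ratios
comparable between arrays before any fold-change filtering. ``median_center``
subtracts each column's median; ``median_center_scale`` additionally rescales
each column's median absolute deviation (MAD) to the grand median MAD so no
array dominates by spread alone. Both are invertible affine maps with positive
scale, so within-column ranks are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import ExpressionMatrix, ValidationError

METHODS = ("median_center", "median_center_scale")


@dataclass
class NormalizationReport:
    """Per-event affine parameters: output = (input - offset) / scale."""

    method: str
    offsets: pd.Series  # per event token
    scales: pd.Series   # strictly positive

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "scale": self.scales}).rename_axis("event")

    def invert(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        """Reconstruct the pre-normalization matrix."""
        data = matrix.data * self.scales + self.offsets
        return ExpressionMatrix(data)


def linear_normalize(
    matrix: ExpressionMatrix, method: str = "median_center"
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Affinely adjust each event column of log2 ratios.

    Missing values are ignored when estimating the column median/MAD and are
    carried through unchanged.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    finite_per_col = matrix.data.notna().sum(axis=0)
    if (finite_per_col < 2).any():
        bad = finite_per_col.index[finite_per_col < 2].tolist()
        raise ValidationError(f"columns with < 2 finite values: {bad[:5]}")

    offsets = matrix.data.median(axis=0, skipna=True)
    centered = matrix.data - offsets
    if method == "median_center":
        scales = pd.Series(1.0, index=matrix.data.columns)
        out = centered
    else:
        mads = centered.abs().median(axis=0, skipna=True)
        if (mads <= 0).any():
            bad = mads.index[mads <= 0].tolist()
            raise ValidationError(
                f"zero MAD (constant column) under median_center_scale: {bad[:5]}"
            )
        target = float(np.median(mads.to_numpy()))
        scales = mads / target
        out = centered / scales
    report = NormalizationReport(method=method, offsets=offsets, scales=scales)
    return ExpressionMatrix(out), report
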