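"""Detection-flag filtering, quantile normalization and log2 transform."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionBundle

__all__ = ["PreprocessReport", "filter_by_flags", "quantile_normalize", "log2_transform"]


@dataclass
class PreprocessReport:
    n_features_in: int
    n_features_pass_flags: int
    normalization_applied: bool

    def __post_init__(self) -> None:
        if self.n_features_pass_flags > self.n_features_in:
            raise ValueError("n_features_pass_flags exceeds n_features_in")

    def to_text(self) -> str:
        return (
            f"n_features_in\t{self.n_features_in}\n"
            f"n_features_pass_flags\t{self.n_features_pass_flags}\n"
            f"normalization_applied\t{str(self.normalization_applied).lower()}\n"
        )


def filter_by_flags(bundle: ExpressionBundle, min_detected: int) -> ExpressionBundle:
    """Keep features detected (flag P or M) in at least ``min_detected`` samples."""
    if min_detected < 0:
        raise ValueError("min_detected must be >= 0")
    if min_detected > len(bundle.sample_ids):
        raise ValueError(
            f"min_detected={min_detected} exceeds sample count {len(bundle.sample_ids)}"
        )
    detected = bundle.flags.isin(["P", "M"]).sum(axis=1)
    keep = detected[detected >= min_detected].index
    return bundle.subset_features(list(keep))


def quantile_normalize(bundle: ExpressionBundle) -> ExpressionBundle:
    """Force every sample column onto the mean order-statistic distribution.

    Ties within a column all receive the mean of the order-statistic means
    spanned by the tied block, so the transform is rank-preserving and
    idempotent.
    """
    vals = bundle.values.to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    n_feat, n_samp = vals.shape
    ref = np.sort(vals, axis=0).mean(axis=1)  # mean of order statistics
    out = np.empty_like(vals)
    for j in range(n_samp):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        normalized = np.empty(n_feat)
        i = 0
        while i < n_feat:
            k = i
            while k + 1 < n_feat and col[order[k + 1]] == col[order[i]]:
                k += 1
            block_value = ref[i : k + 1].mean()
            normalized[order[i : k + 1]] = block_value
            i = k + 1
        out[:, j] = normalized
    values = pd.DataFrame(out, index=bundle.values.index, columns=bundle.values.columns)
    return ExpressionBundle(values, bundle.flags.copy(), scale=bundle.scale)


def log2_transform(bundle: ExpressionBundle, offset: float = 0.0) -> ExpressionBundle:
    """value <- log2(value + offset); marks the bundle log2-scale."""
    if bundle.scale != "linear":
        raise ValueError("log2_transform requires a linear-scale bundle")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    shifted = bundle.values + offset
    if (shifted.to_numpy() <= 0).any():
        raise ValueError("log2_transform: some value + offset <= 0")
    values = np.log2(shifted)
    return ExpressionBundle(values, bundle.flags.copy(), scale="log2")
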