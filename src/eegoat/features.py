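"""The 11 statistical features per channel and feature-matrix assembly.

Per channel the feature vector is {mean, median, mode, standard deviation,
Q1, Q3, IQR, skewness β1, kurtosis β2, min, max}.  Conventions (frozen for
tests, configurable where noted):

* SD uses divisor n−1 (sample standard deviation).
* Q1/Q3 use linear interpolation of order statistics with plotting
  position (i−1)/(n−1) (the numpy default).
* Mode rounds amplitudes to the nearest integer first (benchmark files are
  integer µV; synthetic data is real-valued) and takes the smallest value
  on ties.
* Skewness = m3/m2^{3/2} and kurtosis = m4/m2² (non-excess: normal → 3)
  with biased central moments (divisor n); zero-variance input yields
  skewness = kurtosis = 0 with a degenerate flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .eeg_io import CLASS_ORDER, FEATURE_NAMES, FeatureMatrix
from .exceptions import ValidationError
from .oat_sampling import OATSample


@dataclass(frozen=True)
class FeatureVector:
    """One channel's 11 named statistics (µV except β1/β2, dimensionless)."""

    X_Mean: float
    X_Me: float
    X_Mo: float
    X_SD: float
    X_Q1: float
    X_Q3: float
    X_IQR: float
    X_beta1: float
    X_beta2: float
    X_Min: float
    X_Max: float
    degenerate: bool = False  # True when the input had zero variance

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def _mode_rounded(values: np.ndarray) -> float:
    """Most frequent value after rounding to the nearest integer; smallest wins ties."""
    rounded = np.rint(values).astype(np.int64)
    uniques, counts = np.unique(rounded, return_counts=True)
    return float(uniques[np.argmax(counts)])  # uniques sorted → first max is smallest


def extract_features(
    values,
    quantile_method: str = "linear",
    excess_kurtosis: bool = False,
    unbiased_moments: bool = False,
) -> FeatureVector:
    """Compute the 11-feature summary of one channel's sampled amplitudes."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("feature extraction needs a 1-D sequence of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite amplitude values")

    q1 = float(np.quantile(x, 0.25, method=quantile_method))
    q3 = float(np.quantile(x, 0.75, method=quantile_method))
    m2 = float(np.var(x))  # biased central moment
    degenerate = m2 == 0.0
    if degenerate:
        beta1, beta2 = 0.0, 0.0
    else:
        import warnings

        with warnings.catch_warnings():
            # near-constant data: handled below via the degenerate flag
            warnings.filterwarnings(
                "ignore", message=".*catastrophic cancellation.*", category=RuntimeWarning
            )
            beta1 = float(sps.skew(x, bias=not unbiased_moments))
            beta2 = float(
                sps.kurtosis(x, fisher=excess_kurtosis, bias=not unbiased_moments)
            )
        # numerically constant input (m2 underflow) → same degenerate path
        if not (np.isfinite(beta1) and np.isfinite(beta2)):
            beta1, beta2, degenerate = 0.0, 0.0, True
    return FeatureVector(
        X_Mean=float(np.mean(x)),
        X_Me=float(np.median(x)),
        X_Mo=_mode_rounded(x),
        X_SD=float(np.std(x, ddof=1)),
        X_Q1=q1,
        X_Q3=q3,
        X_IQR=q3 - q1,
        X_beta1=beta1,
        X_beta2=beta2,
        X_Min=float(np.min(x)),
        X_Max=float(np.max(x)),
        degenerate=degenerate,
    )


def features_per_class(sample: OATSample, class_label: str, **conventions) -> FeatureMatrix:
    """One 11-feature row per channel of a combined OAT sample."""
    if sample.n_rows == 0:
        raise ValidationError("cannot extract features from an empty sample")
    rows = [
        extract_features(sample.data[:, j], **conventions).as_array()
        for j in range(sample.n_channels)
    ]
    return FeatureMatrix.from_arrays(
        np.vstack(rows),
        labels=[class_label] * sample.n_channels,
        sets=[sample.set_id] * sample.n_channels,
    )


def assemble_full_matrix(per_class: list[FeatureMatrix]) -> FeatureMatrix:
    """Stack per-class matrices in class order healthy, seizure-free, seizure."""
    if not per_class:
        raise ValidationError("no matrices to assemble")
    for fm in per_class:
        if list(fm.df.columns) != list(per_class[0].df.columns):
            raise ValidationError("feature matrices have mismatched columns")

    def class_rank(fm: FeatureMatrix) -> int:
        label = fm.df["class"].iloc[0]
        return CLASS_ORDER.index(label) if label in CLASS_ORDER else len(CLASS_ORDER)

    ordered = sorted(per_class, key=class_rank)
    import pandas as pd

    return FeatureMatrix(pd.concat([fm.df for fm in ordered], ignore_index=True))


def plot_feature_boxplots(fm: FeatureMatrix, path) -> None:
    """Side-by-side box plots of the 11 features pooled over classes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 5))
    ax.boxplot([fm.df[name] for name in FEATURE_NAMES], tick_labels=list(FEATURE_NAMES))
    ax.set_ylabel("µV (β1/β2 dimensionless)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
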