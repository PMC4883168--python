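"""Optimum-allocation sampling (OAT) of segmented EEG recordings.

The recording of a class (N time points × C channels) is cut into k
contiguous segments.  A total sample size n is fixed from a confidence
specification,

    n0 = z² p (1 − p) / d²          (unadjusted size)
    n  = n0 / (1 + (n0 − 1) / N)    (finite-population correction)

and allocated across segments proportionally to N_i · sqrt(Σ_j S_ij²),
where S_ij² is the sample variance of channel j within segment i — the
optimum-allocation rule that sends more of the sample to high-variability
segments.  Rows are then drawn by simple random sampling without
replacement within each segment, and per-set samples are stacked into the
combined per-class sample that feeds feature extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .eeg_io import SignalSet
from .exceptions import ValidationError


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SamplingDesign:
    """Confidence specification and the derived per-class sample size."""

    z: float
    p: float
    d: float
    N: int
    n0: float = field(init=False)
    n: int = field(init=False)

    def __post_init__(self) -> None:
        n0 = base_sample_size(self.z, self.p, self.d)
        if self.N < 1:
            raise ValidationError("population size N must be >= 1")
        object.__setattr__(self, "n0", n0)
        object.__setattr__(self, "n", corrected_sample_size(n0, self.N))


@dataclass(frozen=True)
class SegmentStats:
    """Per-segment size and per-channel variances used by the allocation."""

    segment_index: int  # 1-based, as in Seg_1..Seg_k
    row_range: tuple[int, int]  # 0-based half-open [start, stop)
    per_channel_variances: np.ndarray  # S_ij² for each channel j (µV²)

    @property
    def N_i(self) -> int:
        return self.row_range[1] - self.row_range[0]

    @property
    def C(self) -> int:
        """Channel count (the allocation formula's channel index bound)."""
        return int(np.asarray(self.per_channel_variances).size)

    @property
    def weight(self) -> float:
        """Allocation weight N_i · sqrt(Σ_j S_ij²)."""
        return self.N_i * math.sqrt(float(np.sum(self.per_channel_variances)))


@dataclass(frozen=True)
class AllocationPlan:
    """Integer allocations n(i) per segment, summing exactly to n."""

    allocations: tuple[int, ...]
    n: int
    method: str = "optimum"  # or "proportional_fallback" when all weights vanish

    def __post_init__(self) -> None:
        if sum(self.allocations) != self.n:
            raise ValidationError(
                f"allocations {self.allocations} do not sum to n={self.n}"
            )
        if any(a < 0 for a in self.allocations):
            raise ValidationError("allocations must be non-negative")


@dataclass
class OATSample:
    """Selected rows per segment plus the extracted data matrix."""

    set_id: str
    selected_rows: list[np.ndarray]  # per segment, sorted unique time indices
    data: np.ndarray  # selected rows × channels
    channel_ids: list[str]

    @property
    def n_rows(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[1])


def segment_bounds(T: int, k: int) -> list[tuple[int, int]]:
    """Cut [0, T) into k contiguous segments; the last absorbs the remainder.

    The first k−1 segments have length ⌊T/k⌋ (4097 points with k=4 give
    1024/1024/1024/1025).
    """
    if k < 1 or k > T:
        raise ValidationError(f"need 1 <= k <= T, got k={k}, T={T}")
    base = T // k
    bounds = [(i * base, (i + 1) * base) for i in range(k - 1)]
    bounds.append(((k - 1) * base, T))
    return bounds


def base_sample_size(z: float, p: float, d: float) -> float:
    """Unadjusted sample size n0 = z² p (1−p) / d², unrounded."""
    if z <= 0:
        raise ValidationError("z must be positive")
    if not 0 < p < 1:
        raise ValidationError("p must lie strictly between 0 and 1")
    if d <= 0:
        raise ValidationError("d must be positive")
    return z * z * p * (1.0 - p) / (d * d)


def corrected_sample_size(n0: float, N: int) -> int:
    """Finite-population-corrected size n = round(n0 / (1 + (n0−1)/N))."""
    if n0 <= 0:
        raise ValidationError("n0 must be positive")
    if N < 1:
        raise ValidationError("N must be >= 1")
    n = _round_half_up(n0 / (1.0 + (n0 - 1.0) / N))
    return max(1, min(n, N))


def compute_segment_stats(
    ss: SignalSet, bounds: list[tuple[int, int]]
) -> list[SegmentStats]:
    """Per-segment per-channel sample variances (divisor n−1)."""
    data = ss.data
    T = data.shape[0]
    prev_stop = 0
    stats: list[SegmentStats] = []
    for i, (start, stop) in enumerate(bounds, start=1):
        if start != prev_stop or stop <= start or stop > T:
            raise ValidationError(
                f"segment {i}: range [{start}, {stop}) invalid for T={T}"
            )
        if stop - start < 2:
            raise ValidationError(
                f"segment {i}: length {stop - start} < 2, variance undefined"
            )
        variances = np.var(data[start:stop], axis=0, ddof=1)
        stats.append(
            SegmentStats(
                segment_index=i,
                row_range=(start, stop),
                per_channel_variances=variances,
            )
        )
        prev_stop = stop
    if prev_stop != T:
        raise ValidationError("segments do not cover the full recording")
    return stats


def _largest_remainder(real: np.ndarray, total: int, caps: np.ndarray) -> np.ndarray:
    """Round real allocations to integers summing to `total`, never above caps."""
    floors = np.floor(real).astype(int)
    floors = np.minimum(floors, caps)
    deficit = total - int(floors.sum())
    remainders = real - floors
    # Hand out remaining units by largest fractional part; skip capped entries.
    order = np.argsort(-remainders, kind="stable")
    out = floors.copy()
    idx = 0
    while deficit > 0 and idx < len(order):
        i = order[idx]
        if out[i] < caps[i]:
            out[i] += 1
            deficit -= 1
        idx += 1
    if deficit > 0:
        raise ValidationError("total sample size exceeds the population size")
    return out


def optimum_allocate(n: int, stats: list[SegmentStats]) -> AllocationPlan:
    """Allocate n across segments ∝ N_i·sqrt(ΣS_ij²), integer and conserving.

    Real-valued shares are rounded by the largest-remainder method so the
    integers sum to n exactly; shares are capped at each segment's size
    with the excess redistributed proportionally among uncapped segments.
    If every weight is zero the allocation falls back to proportional-to-
    size and the plan's ``method`` records it.
    """
    k = len(stats)
    if k == 0:
        raise ValidationError("need at least one segment")
    if n < k:
        raise ValidationError(f"total sample size n={n} smaller than k={k} segments")
    sizes = np.array([s.N_i for s in stats], dtype=int)
    if n > sizes.sum():
        raise ValidationError(f"n={n} exceeds total population {sizes.sum()}")
    weights = np.array([s.weight for s in stats], dtype=float)
    method = "optimum"
    if not np.any(weights > 0):
        weights = sizes.astype(float)
        method = "proportional_fallback"

    # Water-filling: proportional shares, capping at segment sizes and
    # redistributing the excess among the still-uncapped segments.
    real = np.zeros(k)
    active = weights > 0
    capped = np.zeros(k, dtype=bool)
    remaining = float(n)
    while True:
        share = np.zeros(k)
        mask = active & ~capped
        if not mask.any():
            break
        share[mask] = remaining * weights[mask] / weights[mask].sum()
        over = mask & (share > sizes + 1e-12)
        if not over.any():
            real[mask] = share[mask]
            break
        real[over] = sizes[over]
        capped |= over
        remaining -= float(sizes[over].sum())

    # If active segments saturated, spill the rest onto zero-weight ones
    # proportionally to their size (they have no variability signal).
    leftover = n - real.sum()
    while leftover > 1e-9:
        idle = ~active & ~capped
        if not idle.any():
            break
        share = leftover * sizes[idle] / sizes[idle].sum()
        tmp = np.zeros(k)
        tmp[idle] = share
        over = idle & (tmp > sizes + 1e-12)
        if not over.any():
            real[idle] = share
            break
        real[over] = sizes[over]
        capped |= over
        leftover = n - real.sum()

    allocations = _largest_remainder(real, n, sizes)
    return AllocationPlan(allocations=tuple(int(a) for a in allocations), n=n,
                          method=method)


def draw_oat_sample(
    ss: SignalSet,
    plan: AllocationPlan,
    bounds: list[tuple[int, int]],
    seed: int | np.random.Generator,
) -> OATSample:
    """Draw n(i) rows per segment by SRS without replacement, seeded.

    Selected indices are returned sorted within each segment, and the
    stacked data matrix keeps ascending time order.
    """
    if len(plan.allocations) != len(bounds):
        raise ValidationError("allocation plan and segment bounds differ in length")
    rng = np.random.default_rng(seed)
    data = ss.data
    selected: list[np.ndarray] = []
    for (start, stop), n_i in zip(bounds, plan.allocations):
        N_i = stop - start
        if n_i > N_i:
            raise ValidationError(
                f"allocation {n_i} exceeds segment size {N_i} at rows [{start},{stop})"
            )
        idx = rng.choice(np.arange(start, stop), size=n_i, replace=False)
        selected.append(np.sort(idx))
    all_rows = np.concatenate(selected) if selected else np.empty(0, dtype=int)
    return OATSample(
        set_id=ss.set_id,
        selected_rows=selected,
        data=data[all_rows],
        channel_ids=ss.channel_ids,
    )


def combine_oat_samples(samples: list[OATSample]) -> OATSample:
    """Stack per-set OAT samples channel-wise into the combined class sample.

    Row blocks follow the input order (set A's rows, then set B's, ...);
    the combined row count is the sum of the inputs'.
    """
    if not samples:
        raise ValidationError("no samples to combine")
    n_channels = {s.n_channels for s in samples if s.n_rows > 0} or {
        samples[0].n_channels
    }
    if len(n_channels) != 1:
        raise ValidationError(
            f"channel-count mismatch across samples: {sorted(n_channels)}"
        )
    non_empty = [s for s in samples if s.n_rows > 0]
    data = (
        np.vstack([s.data for s in non_empty])
        if non_empty
        else samples[0].data
    )
    return OATSample(
        set_id="+".join(s.set_id for s in samples),
        selected_rows=[rows for s in samples for rows in s.selected_rows],
        data=data,
        channel_ids=samples[0].channel_ids,
    )
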