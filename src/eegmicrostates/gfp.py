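"""Global field power and its local maxima.

GFP(t) is the spatial standard deviation of the scalp potential across
electrodes at time t: sqrt((1/C) * sum_i (v_i(t) - vbar(t))^2). Its local
maxima are the moments of highest topographic signal-to-noise; microstate
clustering operates on the topographies at those peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .io import EpochSet

__all__ = ["GFPSeries", "compute_gfp", "find_gfp_peaks", "peak_topographies"]


@dataclass
class GFPSeries:
    """Per-epoch GFP traces and (optionally) their peak sample indices.

    ``values`` has shape (n_epochs, epoch_len); ``peak_indices`` is one
    index array per epoch, empty until :func:`find_gfp_peaks` fills it.
    """

    values: np.ndarray
    srate: float
    peak_indices: list[np.ndarray] | None = None

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def all_peaks(self) -> np.ndarray:
        """Peak GFP values pooled over epochs (after peak detection)."""
        if self.peak_indices is None:
            raise DataError("peaks have not been detected yet")
        return np.concatenate(
            [self.values[e][idx] for e, idx in enumerate(self.peak_indices)]
        )


def compute_gfp(es: EpochSet) -> GFPSeries:
    """GFP per sample for every epoch.

    The definition assumes average-referenced data; non-average-referenced
    input triggers a warning and an implicit re-reference (GFP is only
    reference-invariant under the average-reference convention).
    """
    epochs = es.epochs
    if es.reference != "average":
        warnings.warn(
            "computing GFP on non-average-referenced epochs; "
            "re-referencing implicitly",
            stacklevel=2,
        )
        epochs = epochs - epochs.mean(axis=1, keepdims=True)
    # population std across the channel axis == sqrt(mean squared deviation)
    values = epochs.std(axis=1, ddof=0)
    return GFPSeries(values=values, srate=es.srate)


def find_gfp_peaks(g: GFPSeries, min_separation: int = 1) -> GFPSeries:
    """Locate strict local maxima of the GFP within each epoch.

    A peak satisfies values[t-1] < values[t] > values[t+1]; epoch edges never
    qualify. With ``min_separation`` > 1, peaks closer than that are thinned
    by keeping the larger of any violating pair (greedy, by descending GFP).
    """
    if min_separation < 1:
        raise ParameterError("min_separation must be >= 1 sample")
    peak_lists: list[np.ndarray] = []
    for trace in g.values:
        if trace.size < 3:
            raise DataError("epochs must have at least 3 samples for peak detection")
        interior = trace[1:-1]
        is_peak = (interior > trace[:-2]) & (interior > trace[2:])
        peaks = np.flatnonzero(is_peak) + 1
        if min_separation > 1 and peaks.size > 1:
            order = peaks[np.argsort(trace[peaks])[::-1]]
            kept: list[int] = []
            for p in order:
                if all(abs(p - q) >= min_separation for q in kept):
                    kept.append(int(p))
            peaks = np.array(sorted(kept), dtype=int)
        peak_lists.append(peaks)
    return GFPSeries(values=g.values, srate=g.srate, peak_indices=peak_lists)


def peak_topographies(es: EpochSet, g: GFPSeries) -> np.ndarray:
    """Stack the scalp maps at all GFP peaks into an (n_peaks, n_channels) array."""
    if g.peak_indices is None:
        raise DataError("run find_gfp_peaks first")
    maps = [es.epochs[e][:, idx].T for e, idx in enumerate(g.peak_indices)]
    return np.concatenate(maps, axis=0)
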