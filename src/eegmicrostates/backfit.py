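"""Backfitting templates to the full time course and temporal parameters.

Every sample of every epoch is assigned to the template with the highest
absolute spatial correlation (backfitting), short runs are absorbed by their
neighbors (minimum-duration smoothing), and the label sequence is summarized
per class into the three standard microstate parameters:

- Duration: mean length of that class's contiguous runs, in ms;
- Frequency: number of that class's runs per second of analyzed time;
- Coverage: fraction of analyzed samples carrying that class.

Runs never span epoch boundaries. With everything computed on the same label
sequence, coverage == frequency * duration holds exactly per subject and
class (in consistent units); note that this identity does not survive
averaging across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .clustering import MicrostateMaps, normalize_maps
from .errors import DataError, FormatError, ParameterError
from .io import EpochSet

__all__ = [
    "UNASSIGNED",
    "LabelSequence",
    "backfit",
    "smooth_labels",
    "run_length_encode",
    "parameters_from_labels",
    "compute_parameters",
    "build_cohort_table",
    "summarize_cohort",
]

#: Label value for samples below the correlation floor.
UNASSIGNED = -1


@dataclass
class LabelSequence:
    """Per-sample microstate class assignments for one subject.

    ``labels`` is (n_epochs, epoch_len) with class indices 0..K-1 or
    :data:`UNASSIGNED`. ``correlations`` keeps the full |r| to every template
    (n_epochs, epoch_len, K) so smoothing can re-assign samples;
    ``correlation_trace`` is the |r| to the assigned template.
    """

    labels: np.ndarray
    srate: float
    correlations: np.ndarray
    class_labels: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.correlations.shape[:2]:
            raise FormatError("labels and correlations shapes disagree")

    @property
    def n_classes(self) -> int:
        return self.correlations.shape[2]

    @property
    def correlation_trace(self) -> np.ndarray:
        safe = np.clip(self.labels, 0, None)
        trace = np.take_along_axis(self.correlations, safe[..., None], axis=2)[..., 0]
        return np.where(self.labels == UNASSIGNED, np.nan, trace)


def backfit(es: EpochSet, maps: MicrostateMaps, min_corr: float = 0.0) -> LabelSequence:
    """Label every sample with its best-matching template.

    Assignment maximizes |spatial correlation|; ties go to the lower class
    index. Samples whose best |r| falls below ``min_corr`` are left
    unassigned (the default 0 assigns everything).
    """
    if es.n_channels != maps.n_channels:
        raise FormatError(
            f"epochs have {es.n_channels} channels, maps {maps.n_channels}"
        )
    if not 0 <= min_corr <= 1:
        raise ParameterError("min_corr must lie in [0, 1]")
    e, c, l = es.epochs.shape
    flat = es.epochs.transpose(0, 2, 1).reshape(e * l, c)
    corr = np.abs(normalize_maps(flat) @ normalize_maps(maps.maps).T)
    labels = corr.argmax(axis=1)
    if min_corr > 0:
        labels[corr.max(axis=1) < min_corr] = UNASSIGNED
    return LabelSequence(
        labels=labels.reshape(e, l),
        srate=es.srate,
        correlations=corr.reshape(e, l, maps.k),
        class_labels=list(maps.labels),
    )


def run_length_encode(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal runs of a 1-D label vector as (values, lengths)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return np.array([], dtype=labels.dtype), np.array([], dtype=int)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return labels[starts], ends - starts


def _short_run_positions(
    values: np.ndarray, lengths: np.ndarray, min_len: int
) -> np.ndarray:
    return np.flatnonzero((lengths < min_len) & (values != UNASSIGNED))


def smooth_labels(ls: LabelSequence, min_duration_ms: float = 20.0) -> LabelSequence:
    """Absorb runs shorter than ``min_duration_ms`` into their neighbors.

    Short runs are resolved one at a time, shortest first (leftmost on ties):
    each sample of the run is re-assigned to whichever neighboring run's
    template correlates better with it at that sample (at an epoch edge only
    the inner neighbor is available), and runs are recomputed after every
    step. The shortest-first order matters: brief misassignment islands heal
    back into their parent run before that (possibly floor-length) parent is
    itself touched. The samplewise rule admits flip-flop configurations, so
    after an iteration cap any zone of consecutive short runs still standing
    is resolved contiguously: the zone is relabeled as an optimal two-segment
    split between its flanking runs' classes (the split point maximizes the
    summed |r|), preserving at most one class transition per zone. Runs never
    cross epoch boundaries; a run truncated by the epoch edge may stay short.
    """
    if min_duration_ms < 0:
        raise ParameterError("min_duration_ms must be >= 0")
    min_len = int(round(min_duration_ms * ls.srate / 1000.0))
    if min_len <= 1:
        return ls
    labels = ls.labels.copy()
    for ep in range(labels.shape[0]):
        seq = labels[ep]
        corr = ls.correlations[ep]
        max_steps = 10 * max(1, len(run_length_encode(seq)[0]))
        for _ in range(max_steps):
            values, lengths = run_length_encode(seq)
            short = _short_run_positions(values, lengths, min_len)
            if short.size == 0:
                break
            ri = short[np.argmin(lengths[short])]
            left = values[ri - 1] if ri > 0 else None
            right = values[ri + 1] if ri < len(values) - 1 else None
            if left is None and right is None:
                break  # single run in the epoch; nothing to absorb into
            starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
            s, n = starts[ri], lengths[ri]
            for t in range(s, s + n):
                if left is None:
                    seq[t] = right
                elif right is None:
                    seq[t] = left
                else:
                    cl = corr[t, left] if left != UNASSIGNED else -np.inf
                    cr = corr[t, right] if right != UNASSIGNED else -np.inf
                    seq[t] = left if cl >= cr else right
        labels[ep] = _resolve_short_zones(seq, corr, min_len)
    return replace(ls, labels=labels)


def _resolve_short_zones(
    seq: np.ndarray, corr: np.ndarray, min_len: int
) -> np.ndarray:
    """Contiguously relabel zones of leftover short runs.

    A zone is a maximal stretch of consecutive interior, assigned runs
    shorter than ``min_len``. Epoch-edge runs are exempt from the floor and
    act as flanks; unassigned runs stay put and also act as flanks. A zone is
    split [start, j) -> left flank class, [j, end) -> right flank class at
    the j maximizing the summed |r| (j may be 0 or the zone length, i.e. a
    full merge), so at most one class transition survives per zone.
    """
    seq = seq.copy()
    values, lengths = run_length_encode(seq)
    n_runs = len(values)
    if n_runs < 3:
        return seq
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    member = (lengths < min_len) & (values != UNASSIGNED)
    member[0] = member[-1] = False  # edge runs are exempt
    ri = 0
    while ri < n_runs:
        if not member[ri]:
            ri += 1
            continue
        rj = ri
        while rj + 1 < n_runs and member[rj + 1]:
            rj += 1
        s = starts[ri]
        e = starts[rj] + lengths[rj]
        left, right = values[ri - 1], values[rj + 1]
        if left == right:
            seq[s:e] = left
        elif left == UNASSIGNED and right == UNASSIGNED:
            pass  # nothing informative to absorb into
        else:
            big = np.full(e - s, -np.inf)
            r_left = corr[s:e, left] if left != UNASSIGNED else big
            r_right = corr[s:e, right] if right != UNASSIGNED else big
            # score(j) = sum r_left[:j] + sum r_right[j:], maximized over j
            gain = np.concatenate([[0.0], np.cumsum(r_left - r_right)])
            j = int(np.argmax(gain))
            seq[s : s + j] = left
            seq[s + j : e] = right
        ri = rj + 1
    return seq


def class_run_counts(
    labels: np.ndarray, n_classes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class run and sample counts of an (epochs, samples) label array.

    Runs are maximal same-label stretches within an epoch (a separator breaks
    them at epoch boundaries); unassigned samples are counted in neither.
    """
    labels = np.atleast_2d(np.asarray(labels))
    sep = np.full((labels.shape[0], 1), UNASSIGNED - 1, dtype=labels.dtype)
    values, lengths = run_length_encode(np.concatenate([labels, sep], axis=1).ravel())
    keep = values >= 0
    n_runs = np.bincount(values[keep], minlength=n_classes)
    n_samples = np.bincount(
        values[keep], weights=lengths[keep], minlength=n_classes
    ).astype(int)
    return n_runs, n_samples


def parameters_from_labels(
    labels: np.ndarray, srate: float, n_classes: int
) -> pd.DataFrame:
    """Duration/Frequency/Coverage per class from an (epochs, samples) label array.

    This is the single definition of the run-length statistics: the synthetic
    generator's ground truth and the analysis pipeline both call it, so
    "planted" and "recovered" parameters are always computed identically.

    Total analyzed time is all samples; unassigned samples count toward the
    denominator (so per-class coverages plus the unassigned fraction sum to
    one, and coverage == frequency * duration holds exactly per class).
    """
    labels = np.atleast_2d(np.asarray(labels))
    total_samples = labels.size
    total_seconds = total_samples / srate
    n_runs, n_samples = class_run_counts(labels, n_classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        duration_ms = np.where(
            n_runs > 0, n_samples / np.maximum(n_runs, 1) / srate * 1000.0, np.nan
        )
    return pd.DataFrame(
        {
            "class_index": np.arange(n_classes),
            "duration_ms": duration_ms,
            "frequency_per_s": n_runs / total_seconds,
            "coverage_fraction": n_samples / total_samples,
        }
    )


def compute_parameters(
    ls: LabelSequence,
    subject_id: str,
    group: str,
    gev: float | None = None,
) -> pd.DataFrame:
    """Per-class parameter rows for one subject (long format).

    Columns: subject_id, group, class, duration_ms, frequency_per_s,
    coverage_fraction, gev. A class that never occurs gets Duration = NaN,
    Frequency = 0, Coverage = 0.
    """
    table = parameters_from_labels(ls.labels, ls.srate, ls.n_classes)
    table.insert(0, "subject_id", subject_id)
    table.insert(1, "group", group)
    table["class"] = [ls.class_labels[i] for i in table.pop("class_index")]
    table["gev"] = gev
    cols = [
        "subject_id", "group", "class",
        "duration_ms", "frequency_per_s", "coverage_fraction", "gev",
    ]
    return table[cols]


def build_cohort_table(subject_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-subject parameter tables into one tidy cohort table."""
    if not subject_tables:
        raise ParameterError("no subjects supplied")
    table = pd.concat(subject_tables, ignore_index=True)
    if table["group"].nunique() < 1:
        raise ParameterError("cohort table has no groups")
    return table


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per group x class x parameter (wide summary table).

    Coverage is reported in percent, matching the conventional presentation.
    A group with a single subject gets SD = NaN.
    """
    work = table.copy()
    work["coverage_pct"] = work["coverage_fraction"] * 100.0
    params = ["duration_ms", "frequency_per_s", "coverage_pct"]
    grouped = work.groupby(["class", "group"])[params]
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    out = pd.concat({"mean": mean, "sd": sd}, axis=1)
    out.columns = [f"{p}_{stat}" for stat, p in out.columns]
    return out.reset_index()
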