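"""Reading EEG recordings and the preprocessing chain.

The chain mirrors standard resting-state microstate preprocessing: zero-phase
band-pass, polyphase downsampling, segmentation into fixed-length epochs,
amplitude-based artifact rejection, and average re-referencing. All amplitudes
are kept in microvolts throughout.

Recordings come either from EDF files (read through MNE) or from delimited
text matrices (rows = channels) with a one-name-per-line channel sidecar.
A cohort manifest is a delimited table with columns ``subject_id``, ``group``
and ``path``.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DataError, FormatError, ParameterError

__all__ = [
    "GROUPS",
    "Recording",
    "EpochSet",
    "read_recording",
    "load_manifest",
    "write_delimited_recording",
    "write_edf",
    "bandpass_filter",
    "downsample",
    "segment_epochs",
    "reject_amplitude_artifacts",
    "average_reference",
    "preprocess_recording",
]

#: Valid cohort group labels, in the order groups are reported.
GROUPS = ("seizure", "seizure_free", "control")


@dataclass
class Recording:
    """One subject's continuous multichannel EEG.

    Attributes
    ----------
    subject_id : str
    group : str
        One of :data:`GROUPS`.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    srate : float
        Sampling rate in Hz.
    channel_names : list of str
    """

    subject_id: str
    group: str
    data: np.ndarray
    srate: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("recording data must be a 2-D channels x samples matrix")
        if self.data.shape[0] < 2:
            raise FormatError("a recording needs at least 2 channels")
        if len(self.channel_names) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if self.srate <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.group not in GROUPS:
            raise ParameterError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not np.all(np.isfinite(self.data)):
            bad = [
                self.channel_names[i]
                for i in np.unique(np.nonzero(~np.isfinite(self.data))[0])
            ]
            raise DataError(
                f"non-finite samples in subject {self.subject_id} "
                f"on channels {bad}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Artifact-screened fixed-length segments of one recording.

    ``epochs`` is a 3-D array (n_epochs, n_channels, epoch_len_samples) in
    microvolts. ``reference`` records whether the average reference has been
    applied. ``n_rejected`` accumulates across rejection passes.
    """

    subject_id: str
    group: str
    epochs: np.ndarray
    srate: float
    epoch_seconds: float = 2.0
    n_rejected: int = 0
    reference: str = "original"

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise FormatError("epochs must be (n_epochs, n_channels, n_samples)")
        expected = int(round(self.epoch_seconds * self.srate))
        if self.epochs.shape[2] != expected:
            raise FormatError(
                f"epoch length {self.epochs.shape[2]} does not match "
                f"{self.epoch_seconds} s at {self.srate} Hz ({expected} samples)"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[2]


# ---------------------------------------------------------------------------
# reading / writing


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest (columns subject_id, group, path)."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except OSError as exc:
        raise FormatError(f"cannot read manifest {path}: {exc}") from exc
    missing = {"subject_id", "group", "path"} - set(table.columns)
    if missing:
        raise FormatError(f"manifest {path} lacks columns {sorted(missing)}")
    bad = set(table["group"]) - set(GROUPS)
    if bad:
        raise FormatError(f"manifest has unknown groups {sorted(bad)}")
    return table


def _read_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


def _read_delimited(
    path: Path, srate: float | None, sidecar: Path | None
) -> tuple[np.ndarray, float, list[str]]:
    if srate is None:
        raise ParameterError(f"delimited recording {path} needs an explicit srate")
    try:
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    except OSError as exc:
        raise FormatError(f"cannot read recording {path}: {exc}") from exc
    except ValueError:
        data = np.loadtxt(path, ndmin=2)  # whitespace-delimited fallback
    if sidecar is None:
        sidecar = path.with_suffix(path.suffix + ".channels")
    if sidecar.exists():
        names = [ln.strip() for ln in sidecar.read_text().splitlines() if ln.strip()]
        if len(names) != data.shape[0]:
            raise FormatError(
                f"{path}: {data.shape[0]} data rows but sidecar {sidecar} "
                f"lists {len(names)} channels"
            )
    else:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return data, float(srate), names


def read_recording(
    path: str | Path,
    manifest_entry: dict | pd.Series,
    srate: float | None = None,
    sidecar: str | Path | None = None,
) -> Recording:
    """Read one EEG recording (EDF or delimited matrix) into a :class:`Recording`.

    Parameters
    ----------
    path
        EDF file (``.edf``) or delimited numeric matrix (rows = channels).
    manifest_entry
        Mapping with at least ``subject_id`` and ``group``.
    srate
        Required for delimited matrices (EDF carries its own rate).
    sidecar
        Channel-name file, one name per line; defaults to
        ``<path>.channels`` for delimited input.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"recording file not found: {path}")
    if path.suffix.lower() == ".edf":
        data, rate, names = _read_edf(path)
    else:
        data, rate, names = _read_delimited(
            path, srate, Path(sidecar) if sidecar else None
        )
    return Recording(
        subject_id=str(manifest_entry["subject_id"]),
        group=str(manifest_entry["group"]),
        data=data,
        srate=rate,
        channel_names=names,
    )


def write_delimited_recording(
    path: str | Path, data: np.ndarray, channel_names: Sequence[str]
) -> None:
    """Write a channels x samples matrix as CSV plus a channel sidecar."""
    path = Path(path)
    np.savetxt(path, np.asarray(data), delimiter=",", fmt="%.6g")
    sidecar = path.with_suffix(path.suffix + ".channels")
    sidecar.write_text("\n".join(channel_names) + "\n")


def write_edf(
    path: str | Path,
    data: np.ndarray,
    srate: float,
    channel_names: Sequence[str],
    physical_unit: str = "uV",
) -> None:
    """Write a minimal EDF file (16-bit, 1-second data records).

    Amplitudes are taken in microvolts. The recording is truncated to whole
    1-second records; samples map linearly onto the full 16-bit digital range,
    so the quantization error is at most half of one digital step.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise FormatError("channel name count does not match data rows")
    if srate != int(srate) or srate <= 0:
        raise ParameterError("EDF writer supports integer sampling rates only")
    spr = int(srate)  # samples per record per channel (1 s records)
    n_rec = n_samp // spr
    if n_rec == 0:
        raise DataError("recording shorter than one 1-second EDF record")
    data = data[:, : n_rec * spr]

    pmax = float(np.abs(data).max())
    pmax = max(pmax, 1.0)
    pmin = -pmax
    dmin, dmax = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),  # patient id
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (n_ch + 1)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),  # record duration, seconds
            pad(str(n_ch), 4),
        ]
    )
    fields: list[bytes] = []
    for getter, width in [
        (lambda i: channel_names[i], 16),
        (lambda i: "EEG", 80),
        (lambda i: physical_unit, 8),
        (lambda i: f"{pmin:.6g}", 8),
        (lambda i: f"{pmax:.6g}", 8),
        (lambda i: str(dmin), 8),
        (lambda i: str(dmax), 8),
        (lambda i: "", 80),
        (lambda i: str(spr), 8),
        (lambda i: "", 32),
    ]:
        fields.append(b"".join(pad(getter(i), width) for i in range(n_ch)))
    header += b"".join(fields)

    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin) * gain + dmin).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_rec):
            chunk = digital[:, rec * spr : (rec + 1) * spr]
            fh.write(chunk.tobytes())


# ---------------------------------------------------------------------------
# preprocessing operations


def bandpass_filter(rec: Recording, low: float, high: float) -> Recording:
    """Zero-phase Butterworth band-pass, applied channel-wise.

    A 4th-order filter is applied forward and backward (``sosfiltfilt``),
    i.e. 8th order overall with no phase distortion — topographies keep
    their timing.
    """
    nyq = rec.srate / 2
    if not (0 < low < high):
        raise ParameterError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ParameterError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rec.srate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


def downsample(rec: Recording, target_srate: float) -> Recording:
    """Polyphase resampling to ``target_srate`` with built-in anti-aliasing."""
    if target_srate >= rec.srate:
        raise ParameterError(
            f"target rate {target_srate} Hz must be below {rec.srate} Hz"
        )
    ratio = Fraction(target_srate / rec.srate).limit_denominator(1000)
    out = signal.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    return replace(rec, data=out, srate=float(target_srate))


def segment_epochs(rec: Recording, epoch_seconds: float = 2.0) -> EpochSet:
    """Cut the recording into non-overlapping fixed-length epochs.

    The trailing remainder shorter than one epoch is discarded. Epoch k spans
    samples [k*L, (k+1)*L).
    """
    length = int(round(epoch_seconds * rec.srate))
    n_epochs = rec.n_samples // length
    if n_epochs == 0:
        raise DataError(
            f"subject {rec.subject_id}: recording ({rec.n_samples} samples) "
            f"shorter than one {epoch_seconds}-s epoch ({length} samples)"
        )
    trimmed = rec.data[:, : n_epochs * length]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, length).transpose(1, 0, 2)
    return EpochSet(
        subject_id=rec.subject_id,
        group=rec.group,
        epochs=epochs.copy(),
        srate=rec.srate,
        epoch_seconds=epoch_seconds,
    )


def reject_amplitude_artifacts(es: EpochSet, threshold: float = 100.0) -> EpochSet:
    """Drop epochs whose peak absolute amplitude reaches ``threshold`` uV.

    The comparison is >=: an epoch touching the threshold is rejected,
    a retained epoch is strictly below it. Order of survivors is preserved.
    """
    if threshold <= 0:
        raise ParameterError("rejection threshold must be positive")
    peak = np.abs(es.epochs).max(axis=(1, 2))
    keep = peak < threshold
    n_rej = int((~keep).sum())
    if not keep.any():
        raise DataError(
            f"subject {es.subject_id}: all {es.n_epochs} epochs exceed "
            f"{threshold} uV, nothing left to analyze"
        )
    return replace(es, epochs=es.epochs[keep], n_rejected=es.n_rejected + n_rej)


def average_reference(es: EpochSet) -> EpochSet:
    """Re-reference every time point to the mean across channels.

    GFP and topographic correlation are defined on average-referenced data;
    this is a required step before any microstate computation. Idempotent.
    """
    mean = es.epochs.mean(axis=1, keepdims=True)
    return replace(es, epochs=es.epochs - mean, reference="average")


def preprocess_recording(
    rec: Recording,
    band: tuple[float, float] = (1.0, 40.0),
    target_srate: float = 500.0,
    epoch_seconds: float = 2.0,
    reject_uv: float = 100.0,
    min_epochs: int = 30,
    epoch_filter: Callable[[EpochSet], np.ndarray] | None = None,
) -> EpochSet:
    """Full preprocessing chain for one recording.

    Band-pass -> downsample -> epoch -> (optional external keep/drop hook)
    -> amplitude rejection -> average reference. ``epoch_filter`` receives the
    segmented :class:`EpochSet` and returns a boolean keep-mask; it is the
    hook for externally supplied artifact decisions (e.g. manually marked
    interictal discharges or ICA-cleaned epoch selections).

    Falling below ``min_epochs`` retained epochs emits a warning; only zero
    retained epochs is an error.
    """
    out = bandpass_filter(rec, *band)
    if target_srate < rec.srate:
        out = downsample(out, target_srate)
    es = segment_epochs(out, epoch_seconds)
    if epoch_filter is not None:
        keep = np.asarray(epoch_filter(es), dtype=bool)
        if keep.shape != (es.n_epochs,):
            raise ParameterError("epoch_filter must return one flag per epoch")
        if not keep.any():
            raise DataError(f"subject {es.subject_id}: epoch filter kept no epochs")
        es = replace(es, epochs=es.epochs[keep], n_rejected=int((~keep).sum()))
    es = reject_amplitude_artifacts(es, reject_uv)
    if es.n_epochs < min_epochs:
        warnings.warn(
            f"subject {es.subject_id}: only {es.n_epochs} artifact-free epochs "
            f"(recommended minimum {min_epochs})",
            stacklevel=2,
        )
    return average_reference(es)
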