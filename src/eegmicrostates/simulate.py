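"""Synthetic multichannel EEG with planted microstate structure.

The generator emulates eyes-closed resting-state EEG the way microstate
analysis sees it: at every moment the scalp field is one of K fixed template
topographies, its strength waxes and wanes with a rectified alpha-band
envelope, and spatially correlated noise is superimposed. The label dynamics
follow a semi-Markov model — the next class is drawn from a transition law
with no self-transitions, and the dwell time from a per-class gamma
distribution — because empirical microstate durations (tens of ms at 500 Hz)
are far from the geometric dwell times a per-sample Markov chain would give.

Everything about the ground truth (template maps, per-sample labels, realized
Duration/Frequency/Coverage) is returned alongside the signals, and the
realized parameters are computed by the very same run-length code the
analysis pipeline uses, so parameter-recovery tests compare like with like.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .backfit import class_run_counts, parameters_from_labels
from .clustering import CANONICAL_LABELS, MicrostateMaps, canonical_templates
from .errors import ParameterError
from .io import GROUPS, Recording, write_delimited_recording, write_edf
from .montage import layout_positions

__all__ = [
    "GroupProfile",
    "GeneratorConfig",
    "GroundTruth",
    "Cohort",
    "make_templates",
    "sample_label_sequence",
    "sample_subject_labels",
    "synthesize_subject",
    "default_group_profiles",
    "null_group_profiles",
    "make_cohort",
    "sample_cohort_parameters",
]


@dataclass(frozen=True)
class GroupProfile:
    """Planted per-class dynamics for one group.

    ``mean_duration_ms`` sets the gamma dwell-time mean per class;
    ``entry_weights`` set the relative probability of switching *into* each
    class (self-transitions excluded), which controls class Frequency and,
    together with duration, Coverage.
    """

    mean_duration_ms: tuple[float, ...]
    entry_weights: tuple[float, ...]


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate the recording setup the pipeline targets: 64 channels at
    1,000 Hz, three groups of 10/12/17 subjects, 30 two-second epochs each,
    class dwell times in the 60-120 ms regime, and a signal-to-noise ratio
    (template RMS over noise RMS) of 4.
    """

    n_channels: int = 64
    srate: float = 1000.0
    k: int = 4
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"seizure": 10, "seizure_free": 12, "control": 17}
    )
    epochs_per_subject: int = 30
    epoch_seconds: float = 2.0
    mean_duration_ms: tuple[float, ...] = (75.0, 78.0, 88.0, 82.0)
    gamma_shape: float = 4.0
    entry_weights: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    snr: float = 4.0
    gfp_freq_hz: float = 10.0
    noise_spatial_scale: float = 0.35
    between_subject_cv: float = 0.15
    amplitude_uv: float = 80.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ParameterError(
                "at least 2 classes required (a 1-class chain has no valid "
                "zero-self-transition law)"
            )
        if len(self.mean_duration_ms) != self.k or len(self.entry_weights) != self.k:
            raise ParameterError("per-class settings must have length k")
        if min(self.mean_duration_ms) <= 0:
            raise ParameterError("mean durations must be positive")
        if self.snr <= 0:
            raise ParameterError("snr must be positive")
        bad = set(self.group_sizes) - set(GROUPS)
        if bad:
            raise ParameterError(f"unknown groups {sorted(bad)}")

    @property
    def epoch_len(self) -> int:
        return int(round(self.epoch_seconds * self.srate))


@dataclass
class GroundTruth:
    """Everything planted: templates, labels, and realized parameters."""

    templates: MicrostateMaps
    labels: dict[str, np.ndarray]  # subject_id -> (n_epochs, epoch_len)
    parameters: pd.DataFrame  # tidy realized Duration/Frequency/Coverage
    profiles: dict[str, GroupProfile]


@dataclass
class Cohort:
    """A generated cohort: recordings, manifest, and ground truth."""

    recordings: list[Recording]
    manifest: pd.DataFrame
    ground_truth: GroundTruth
    config: GeneratorConfig

    def write(self, out_dir: str | Path, fmt: str = "csv") -> Path:
        """Write recordings (+ sidecars), manifest and ground-truth bundle.

        ``fmt`` is "csv" (delimited matrix + channel sidecar) or "edf".
        Refuses to overwrite an existing directory.
        """
        out_dir = Path(out_dir)
        if out_dir.exists():
            raise FileExistsError(f"output directory {out_dir} already exists")
        out_dir.mkdir(parents=True)
        rows = []
        for rec in self.recordings:
            name = f"{rec.subject_id}.{ 'edf' if fmt == 'edf' else 'csv'}"
            path = out_dir / name
            if fmt == "edf":
                write_edf(path, rec.data, rec.srate, rec.channel_names)
            else:
                write_delimited_recording(path, rec.data, rec.channel_names)
            rows.append(
                {"subject_id": rec.subject_id, "group": rec.group, "path": str(path)}
            )
        pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
        bundle = {
            "srate": self.config.srate,
            "templates": self.ground_truth.templates.maps.tolist(),
            "labels": {s: l.tolist() for s, l in self.ground_truth.labels.items()},
            "parameters": self.ground_truth.parameters.to_dict(orient="records"),
        }
        (out_dir / "ground_truth.json").write_text(json.dumps(bundle))
        return out_dir


def make_templates(
    n_channels: int = 64,
    k: int = 4,
    seed: int | np.random.Generator | None = None,
    perturbation: float = 0.0,
) -> MicrostateMaps:
    """Ground-truth template maps for the generator.

    The four canonical orientation patterns (A left-right, B right-left,
    C anterior-posterior, D fronto-central) built on the idealized layout,
    optionally perturbed by seeded smooth noise of relative size
    ``perturbation`` (0 keeps the construction bit-exact for any seed).
    """
    if k > 4:
        raise ParameterError(
            "only the 4 canonical orientations are built in; supply your own "
            "maps for k > 4"
        )
    base = canonical_templates(n_channels)
    maps = base.maps[:k].copy()
    if perturbation > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(maps.shape)
        noise -= noise.mean(axis=1, keepdims=True)
        noise /= np.linalg.norm(noise, axis=1, keepdims=True)
        maps = maps + perturbation * noise
        maps -= maps.mean(axis=1, keepdims=True)
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return MicrostateMaps(
        maps=maps,
        labels=list(CANONICAL_LABELS[:k]),
        level="reference",
        channel_names=base.channel_names,
    )


def _transition_cumdists(entry_weights: np.ndarray) -> np.ndarray:
    """Row i: cumulative distribution over next classes given current class i."""
    k = len(entry_weights)
    cum = np.empty((k, k))
    for i in range(k):
        p = entry_weights.astype(float).copy()
        p[i] = 0.0
        total = p.sum()
        if total <= 0:
            raise ParameterError("entry weights leave no valid transition")
        cum[i] = np.cumsum(p / total)
    return cum


def _sample_chain(
    n_samples: int,
    mean_duration_samples: np.ndarray,
    gamma_shape: float,
    entry_weights: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One continuous semi-Markov label chain of exactly ``n_samples``."""
    k = len(entry_weights)
    if k < 2:
        raise ParameterError("semi-Markov chain needs at least 2 classes")
    cum = _transition_cumdists(np.asarray(entry_weights, dtype=float))
    mean_min = float(np.min(mean_duration_samples))
    chunks: list[np.ndarray] = []
    filled = 0
    w0 = np.asarray(entry_weights, dtype=float)
    cur = int(np.searchsorted(np.cumsum(w0 / w0.sum()), rng.random()))
    while filled < n_samples:
        # draw a batch of runs at once; loop only over batch boundaries
        n_runs = max(16, int((n_samples - filled) / mean_min * 1.3) + 4)
        classes = np.empty(n_runs, dtype=np.int64)
        u = rng.random(n_runs)
        for i in range(n_runs):
            cur = int(np.searchsorted(cum[cur], u[i]))
            classes[i] = cur
        scales = mean_duration_samples[classes] / gamma_shape
        durations = np.maximum(
            1, np.round(rng.gamma(gamma_shape, 1.0, size=n_runs) * scales)
        ).astype(np.int64)
        chunks.append(np.repeat(classes, durations))
        filled += int(durations.sum())
    return np.concatenate(chunks)[:n_samples]


def sample_label_sequence(
    epoch_len: int,
    mean_duration_ms: tuple[float, ...],
    srate: float,
    gamma_shape: float = 4.0,
    entry_weights: tuple[float, ...] | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Semi-Markov label sequence for a single epoch.

    Run lengths are gamma(shape, mean/shape) rounded to at least one sample;
    the class entered after each run is drawn proportionally to
    ``entry_weights`` excluding the current class; the final run is truncated
    at the epoch end.
    """
    rng = np.random.default_rng(rng)
    k = len(mean_duration_ms)
    weights = np.ones(k) if entry_weights is None else np.asarray(entry_weights)
    mean_samples = np.asarray(mean_duration_ms) * srate / 1000.0
    return _sample_chain(epoch_len, mean_samples, gamma_shape, weights, rng)


def sample_subject_labels(
    cfg: GeneratorConfig, profile: GroupProfile, rng: np.random.Generator
) -> np.ndarray:
    """All epochs of one subject as an (n_epochs, epoch_len) label array.

    One continuous chain is sampled and cut at epoch boundaries — the same
    truncation the real pipeline applies when segmenting continuous EEG.
    Between-subject variability multiplies each class's mean duration and
    entry weight by an independent lognormal factor with coefficient of
    variation ``cfg.between_subject_cv``.
    """
    cv = cfg.between_subject_cv
    if cv > 0:
        sigma = np.sqrt(np.log(1 + cv**2))
        dur_mult = rng.lognormal(-(sigma**2) / 2, sigma, size=cfg.k)
        w_mult = rng.lognormal(-(sigma**2) / 2, sigma, size=cfg.k)
    else:
        dur_mult = w_mult = np.ones(cfg.k)
    mean_samples = (
        np.asarray(profile.mean_duration_ms) * dur_mult * cfg.srate / 1000.0
    )
    weights = np.asarray(profile.entry_weights) * w_mult
    total = cfg.epochs_per_subject * cfg.epoch_len
    chain = _sample_chain(total, mean_samples, cfg.gamma_shape, weights, rng)
    return chain.reshape(cfg.epochs_per_subject, cfg.epoch_len)


def _spatial_smoother(xy: np.ndarray, scale: float) -> np.ndarray:
    """Row-normalized Gaussian mixing matrix over electrode distances."""
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    w = np.exp(-d2 / (2 * scale**2))
    return w / np.linalg.norm(w, axis=1, keepdims=True)


def synthesize_subject(
    cfg: GeneratorConfig,
    templates: MicrostateMaps,
    profile: GroupProfile,
    subject_id: str,
    group: str,
    rng: np.random.Generator | int | None = None,
) -> tuple[Recording, np.ndarray]:
    """Generate one subject's continuous recording plus its label ground truth.

    signal(t) = s(t) * map_label(t) + noise(t), where s(t) is an alpha-band
    (``gfp_freq_hz``) sinusoidal carrier: the GFP of the pure signal is the
    rectified alpha envelope |s(t)|, and under polarity-invariant analysis
    the carrier's sign is immaterial. (A signed carrier rather than a
    strictly positive envelope keeps the signal free of DC, so the 1 Hz
    high-pass of the preprocessing chain leaves it intact.) Noise is
    spatially smoothed white noise; both terms are average-referenced. The
    template-to-noise RMS ratio equals ``cfg.snr`` and the final recording is
    scaled so its peak amplitude is ``cfg.amplitude_uv`` (safely below the
    100 uV rejection threshold).
    """
    rng = np.random.default_rng(rng)
    labels = sample_subject_labels(cfg, profile, rng)
    flat = labels.reshape(-1)
    t = np.arange(flat.size) / cfg.srate
    # random phase: realistic, and keeps the carrier off exact grid zeros
    phase = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * cfg.gfp_freq_hz * t + phase)
    signal = (templates.maps[flat] * carrier[:, None]).T  # (C, T)

    noise = rng.standard_normal(signal.shape)
    if cfg.noise_spatial_scale > 0:
        _, xy = layout_positions(cfg.n_channels)
        noise = _spatial_smoother(xy, cfg.noise_spatial_scale) @ noise
    noise -= noise.mean(axis=0, keepdims=True)
    rms_signal = float(np.sqrt(np.mean(signal**2)))
    rms_noise = float(np.sqrt(np.mean(noise**2)))
    noise *= rms_signal / (cfg.snr * rms_noise)

    data = signal + noise
    # raised-cosine fade-in/out: zero-phase filters ring on recordings that
    # start mid-oscillation, which would push edge samples past the
    # artifact-rejection threshold
    fade = int(round(0.2 * cfg.srate))
    if fade > 1 and data.shape[1] >= 2 * fade:
        # strictly positive weights: scaling preserves each sample's topography
        w = 0.5 * (1 - np.cos(np.pi * np.arange(1, fade + 1) / (fade + 1)))
        data[:, :fade] *= w
        data[:, -fade:] *= w[::-1]
    data *= cfg.amplitude_uv / np.abs(data).max()
    rec = Recording(
        subject_id=subject_id,
        group=group,
        data=data,
        srate=cfg.srate,
        channel_names=list(templates.channel_names or
                           [f"ch{i}" for i in range(cfg.n_channels)]),
    )
    return rec, labels


def default_group_profiles(cfg: GeneratorConfig) -> dict[str, GroupProfile]:
    """Planted group effects at the magnitudes the study reports.

    Relative to controls, the seizure group switches into class A 1.8x more
    often (raising class-A Frequency and Coverage) and dwells in class C only
    0.65x as long; the seizure-free group enters class C 0.75x as often and
    dwells 0.88x as long. Under the semi-Markov stationary law these
    multipliers put the expected class coverages at ~33% (A) and ~18% (C) in
    the seizure group and ~21% (C) in the seizure-free group against ~23/27%
    in controls — the coverage separations the study observed. Classes B and
    D are left untouched, so any group difference there is sampling noise.
    """
    base_dur = np.asarray(cfg.mean_duration_ms, dtype=float)
    base_w = np.asarray(cfg.entry_weights, dtype=float)

    def profile(dur_mult: np.ndarray, w_mult: np.ndarray) -> GroupProfile:
        return GroupProfile(
            mean_duration_ms=tuple(base_dur * dur_mult),
            entry_weights=tuple(base_w * w_mult),
        )

    ident = np.ones(cfg.k)
    seiz_dur = ident.copy()
    seiz_w = ident.copy()
    sf_dur = ident.copy()
    sf_w = ident.copy()
    if cfg.k >= 3:
        seiz_dur[2] = 0.65
        sf_dur[2] = 0.88
        sf_w[2] = 0.75
    seiz_w[0] = 1.8
    return {
        "seizure": profile(seiz_dur, seiz_w),
        "seizure_free": profile(sf_dur, sf_w),
        "control": profile(ident, ident),
    }


def null_group_profiles(cfg: GeneratorConfig) -> dict[str, GroupProfile]:
    """Identical dynamics in every group (zero planted effect)."""
    p = GroupProfile(
        mean_duration_ms=tuple(cfg.mean_duration_ms),
        entry_weights=tuple(cfg.entry_weights),
    )
    return {g: p for g in cfg.group_sizes}


def _subject_ids(cfg: GeneratorConfig) -> list[tuple[str, str]]:
    ids = []
    for group in GROUPS:
        if group not in cfg.group_sizes:
            continue
        for i in range(cfg.group_sizes[group]):
            ids.append((f"{group}_{i + 1:02d}", group))
    return ids


def make_cohort(
    cfg: GeneratorConfig | None = None,
    seed: int | np.random.Generator | None = None,
    profiles: dict[str, GroupProfile] | None = None,
) -> Cohort:
    """Generate the full three-group cohort with ground truth.

    ``profiles`` defaults to :func:`default_group_profiles` (planted group
    effects); pass :func:`null_group_profiles` output for a null cohort.
    The ground-truth parameter table is computed from the planted labels by
    the same run-length code the analysis pipeline uses.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    profiles = profiles or default_group_profiles(cfg)
    templates = make_templates(cfg.n_channels, cfg.k)
    recordings: list[Recording] = []
    labels: dict[str, np.ndarray] = {}
    param_rows: list[pd.DataFrame] = []
    manifest_rows = []
    for subject_id, group in _subject_ids(cfg):
        rec, lab = synthesize_subject(
            cfg, templates, profiles[group], subject_id, group, rng
        )
        recordings.append(rec)
        labels[subject_id] = lab
        params = parameters_from_labels(lab, cfg.srate, cfg.k)
        params.insert(0, "subject_id", subject_id)
        params.insert(1, "group", group)
        params["class"] = [templates.labels[i] for i in params.pop("class_index")]
        param_rows.append(params)
        manifest_rows.append({"subject_id": subject_id, "group": group, "path": ""})
    truth = GroundTruth(
        templates=templates,
        labels=labels,
        parameters=pd.concat(param_rows, ignore_index=True),
        profiles=profiles,
    )
    return Cohort(
        recordings=recordings,
        manifest=pd.DataFrame(manifest_rows),
        ground_truth=truth,
        config=cfg,
    )


def sample_cohort_parameters(
    cfg: GeneratorConfig | None = None,
    seed: int | np.random.Generator | None = None,
    profiles: dict[str, GroupProfile] | None = None,
) -> pd.DataFrame:
    """Cohort parameter table from planted labels only (no EEG synthesis).

    The fast path for statistical calibration studies: label sequences are
    sampled per subject and summarized directly, skipping signal generation,
    preprocessing and clustering. Columns match the pipeline's tidy
    ParameterTable (gev is absent).
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    profiles = profiles or default_group_profiles(cfg)
    class_labels = list(CANONICAL_LABELS[: cfg.k])
    rows: list[dict] = []
    total = cfg.epochs_per_subject * cfg.epoch_len
    for subject_id, group in _subject_ids(cfg):
        lab = sample_subject_labels(cfg, profiles[group], rng)
        n_runs, n_samples = class_run_counts(lab, cfg.k)
        for k in range(cfg.k):
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "class": class_labels[k],
                    "duration_ms": (
                        n_samples[k] / n_runs[k] / cfg.srate * 1000.0
                        if n_runs[k] > 0
                        else np.nan
                    ),
                    "frequency_per_s": n_runs[k] / (total / cfg.srate),
                    "coverage_fraction": n_samples[k] / total,
                }
            )
    return pd.DataFrame(rows)
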