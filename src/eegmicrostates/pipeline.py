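"""End-to-end microstate analysis of a cohort of recordings.

Per subject: preprocess -> GFP peaks -> modified K-means (subject maps).
Across subjects: two-level aggregation of subject maps into one cohort-level
template set (so all groups are backfitted with identical templates), ordered
to the canonical A-D classes; per-group maps are also aggregated for
reporting. Per subject again: backfit the cohort maps to every sample,
smooth, and tabulate Duration/Frequency/Coverage plus GEV. Finally the group
comparison (MANOVA + post-hoc ANOVA) runs on the tidy parameter table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backfit import backfit, build_cohort_table, compute_parameters, smooth_labels
from .clustering import (
    MicrostateMaps,
    aggregate_group_maps,
    compute_gev,
    modified_kmeans,
    order_maps_canonical,
)
from .gfp import compute_gfp, find_gfp_peaks, peak_topographies
from .io import EpochSet, Recording, preprocess_recording
from .stats import compare_groups

__all__ = ["CohortResult", "analyze_subject_maps", "analyze_cohort"]


@dataclass
class CohortResult:
    """Everything the cohort analysis produces."""

    cohort_maps: MicrostateMaps
    group_maps: dict[str, MicrostateMaps]
    subject_maps: dict[str, MicrostateMaps]
    parameter_table: pd.DataFrame
    stats: dict[str, dict]
    subject_gev: dict[str, float]

    def group_gev(self) -> pd.Series:
        """Mean per-subject GEV by group (fractions)."""
        gev = pd.Series(self.subject_gev, name="gev")
        groups = (
            self.parameter_table.drop_duplicates("subject_id")
            .set_index("subject_id")["group"]
        )
        return gev.groupby(groups).mean()


def analyze_subject_maps(
    es: EpochSet,
    k: int = 4,
    n_restarts: int = 20,
    seed: int | np.random.Generator | None = None,
) -> tuple[MicrostateMaps, np.ndarray]:
    """Subject-level clustering: GFP peaks -> modified K-means.

    Returns the subject's template maps and the peak topographies they were
    fitted to (needed later for GEV evaluation).
    """
    g = find_gfp_peaks(compute_gfp(es))
    peaks = peak_topographies(es, g)
    maps = modified_kmeans(
        peaks, k=k, n_restarts=n_restarts, seed=seed, srate=es.srate
    )
    return maps, peaks


def analyze_cohort(
    recordings: list[Recording],
    k: int = 4,
    n_restarts: int = 20,
    seed: int | None = None,
    band: tuple[float, float] = (1.0, 40.0),
    target_srate: float = 500.0,
    epoch_seconds: float = 2.0,
    reject_uv: float = 100.0,
    min_epochs: int = 30,
    min_corr: float = 0.0,
    smooth_ms: float = 20.0,
    family_alpha: float = 0.05,
) -> CohortResult:
    """Run the full pipeline on a cohort and compare the groups.

    ``seed`` drives all clustering restarts (per-subject streams are spawned
    from it, so the result is deterministic for a fixed seed).
    """
    ss = np.random.SeedSequence(seed)
    subject_streams = ss.spawn(len(recordings) + 2)

    subject_maps: dict[str, MicrostateMaps] = {}
    epochsets: dict[str, EpochSet] = {}
    peak_sets: dict[str, np.ndarray] = {}
    for rec, stream in zip(recordings, subject_streams[:-2]):
        es = preprocess_recording(
            rec,
            band=band,
            target_srate=target_srate,
            epoch_seconds=epoch_seconds,
            reject_uv=reject_uv,
            min_epochs=min_epochs,
        )
        maps, peaks = analyze_subject_maps(
            es, k=k, n_restarts=n_restarts, seed=np.random.default_rng(stream)
        )
        epochsets[rec.subject_id] = es
        subject_maps[rec.subject_id] = maps
        peak_sets[rec.subject_id] = peaks

    cohort_maps = order_maps_canonical(
        aggregate_group_maps(
            list(subject_maps.values()),
            k=k,
            seed=np.random.default_rng(subject_streams[-2]),
            n_restarts=n_restarts,
        )
    )

    group_rng = np.random.default_rng(subject_streams[-1])
    group_maps: dict[str, MicrostateMaps] = {}
    for group in sorted({r.group for r in recordings}):
        members = [
            subject_maps[r.subject_id] for r in recordings if r.group == group
        ]
        if len(members) >= 2:
            group_maps[group] = order_maps_canonical(
                aggregate_group_maps(members, k=k, seed=group_rng,
                                     n_restarts=n_restarts)
            )

    tables = []
    subject_gev: dict[str, float] = {}
    for rec in recordings:
        es = epochsets[rec.subject_id]
        gev = compute_gev(cohort_maps, peak_sets[rec.subject_id])
        ls = smooth_labels(backfit(es, cohort_maps, min_corr=min_corr), smooth_ms)
        tables.append(compute_parameters(ls, rec.subject_id, rec.group, gev=gev))
        subject_gev[rec.subject_id] = gev

    table = build_cohort_table(tables)
    stats = (
        compare_groups(table, family_alpha=family_alpha)
        if table["group"].nunique() >= 2
        else {}
    )
    return CohortResult(
        cohort_maps=cohort_maps,
        group_maps=group_maps,
        subject_maps=subject_maps,
        parameter_table=table,
        stats=stats,
        subject_gev=subject_gev,
    )
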