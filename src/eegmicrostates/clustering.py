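"""Polarity-invariant modified K-means clustering of GFP-peak topographies.

The "modified" K-means for scalp maps differs from ordinary K-means in two
ways: sample-to-cluster assignment uses squared spatial correlation (so a map
and its polarity flip are equivalent), and the cluster prototype is the first
principal component of its member maps rather than their mean (a mean is
ill-defined when members may appear with either sign). The objective is the
global explained variance (GEV): the GFP-squared-weighted mean squared
correlation between each map and its assigned template.

Group-level maps are obtained by re-clustering the pooled subject-level
templates (two-level aggregation), and maps are put into the canonical
A/B/C/D order by exhaustive permutation matching against built-in reference
topographies (A: left-right diagonal field, B: its mirror image, C:
anterior-posterior field, D: fronto-central maximum).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, FormatError, ParameterError
from .montage import layout_positions

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_LABELS",
    "MicrostateMaps",
    "normalize_maps",
    "spatial_correlation",
    "modified_kmeans",
    "compute_gev",
    "aggregate_group_maps",
    "canonical_templates",
    "order_maps_canonical",
]

CANONICAL_LABELS = ("A", "B", "C", "D")


@dataclass
class MicrostateMaps:
    """K unit-norm, zero-mean template topographies with class labels.

    ``gev`` is the fraction of GFP-weighted variance the templates explain on
    the data they were fitted to (or evaluated on). ``level`` distinguishes
    per-subject from aggregated (group/cohort) template sets.
    """

    maps: np.ndarray  # (K, n_channels)
    labels: list[str]
    level: str = "subject"
    gev: float | None = None
    srate: float | None = None
    channel_names: list[str] | None = None
    seed: int | None = None
    gev_history: list[float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise FormatError("maps must be (K, n_channels)")
        if len(self.labels) != self.maps.shape[0]:
            raise FormatError("one label per map required")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


def normalize_maps(x: np.ndarray) -> np.ndarray:
    """Zero-mean each row across channels and scale it to unit Euclidean norm.

    Zero rows (flat topographies) stay zero instead of dividing by zero.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    return np.divide(x, norms, out=np.zeros_like(x), where=norms > 0)


def spatial_correlation(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels between rows of two map stacks."""
    return normalize_maps(np.atleast_2d(maps_a)) @ normalize_maps(
        np.atleast_2d(maps_b)
    ).T


def _gev(gfp2: np.ndarray, corr: np.ndarray, assign: np.ndarray) -> float:
    r = corr[np.arange(len(assign)), assign]
    return float(np.sum(gfp2 * r**2) / np.sum(gfp2))


def _fit_once(
    xn: np.ndarray,
    gfp2: np.ndarray,
    k: int,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
    polarity_invariant: bool,
) -> tuple[np.ndarray, float, list[float]]:
    n, c = xn.shape
    templates = xn[rng.choice(n, size=k, replace=False)].copy()
    prev_gev = -np.inf
    history: list[float] = []
    for _ in range(max_iter):
        corr = xn @ templates.T
        strength = np.abs(corr) if polarity_invariant else corr
        assign = strength.argmax(axis=1)  # ties go to the lower class index
        for j in range(k):
            members = xn[assign == j]
            if members.size == 0:
                # re-seed an emptied cluster from the worst-fit map
                worst = int(strength.max(axis=1).argmin())
                logger.info("re-seeding empty cluster %d from map %d", j, worst)
                templates[j] = xn[worst]
                assign[worst] = j
                continue
            if polarity_invariant:
                # dominant eigenvector of the member scatter matrix
                cov = members.T @ members
                _, vecs = np.linalg.eigh(cov)
                templates[j] = vecs[:, -1]
            else:
                mean = members.mean(axis=0)
                norm = np.linalg.norm(mean)
                templates[j] = mean / norm if norm > 0 else xn[rng.integers(n)]
        corr = xn @ templates.T
        strength = np.abs(corr) if polarity_invariant else corr
        assign = strength.argmax(axis=1)
        gev = _gev(gfp2, np.abs(corr) if polarity_invariant else corr, assign)
        history.append(gev)
        if gev - prev_gev < tol * max(abs(prev_gev), 1e-12) and np.isfinite(prev_gev):
            break
        prev_gev = gev
    return templates, history[-1], history


def modified_kmeans(
    peak_maps: np.ndarray,
    k: int = 4,
    n_restarts: int = 20,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | np.random.Generator | None = None,
    polarity_invariant: bool = True,
    channel_names: list[str] | None = None,
    srate: float | None = None,
) -> MicrostateMaps:
    """Cluster peak topographies into K unit-norm template maps.

    Parameters
    ----------
    peak_maps : ndarray, shape (n_maps, n_channels)
        Topographies at GFP peaks (any reference/scaling; rows are zero-meaned
        and unit-normalized internally, their original GFP enters the GEV
        weighting).
    k : int
        Number of templates (4 for the canonical microstate classes).
    n_restarts, max_iter, tol
        Random restarts (best-of by GEV), per-restart iteration cap, and
        relative-GEV convergence tolerance.
    seed
        Integer seed or Generator; fixed seed gives a deterministic result.
    polarity_invariant : bool
        If True (default) a map and its sign flip are treated as identical,
        the convention for spontaneous EEG microstates.

    Returns
    -------
    MicrostateMaps
        Labels are provisional (``M1..Mk``) until canonical ordering.
    """
    peak_maps = np.asarray(peak_maps, dtype=float)
    if peak_maps.ndim != 2:
        raise FormatError("peak_maps must be (n_maps, n_channels)")
    n = peak_maps.shape[0]
    if k > n:
        raise ParameterError(f"cannot fit {k} templates to {n} maps")
    if k < 1 or n_restarts < 1:
        raise ParameterError("k and n_restarts must be positive")
    rng = np.random.default_rng(seed)

    centered = peak_maps - peak_maps.mean(axis=1, keepdims=True)
    gfp = np.linalg.norm(centered, axis=1) / np.sqrt(peak_maps.shape[1])
    if not np.any(gfp > 0):
        raise DataError("all peak maps are flat (zero GFP)")
    xn = normalize_maps(peak_maps)
    gfp2 = gfp**2

    best: tuple[np.ndarray, float, list[float]] | None = None
    for _ in range(n_restarts):
        templates, gev, history = _fit_once(
            xn, gfp2, k, max_iter, tol, rng, polarity_invariant
        )
        if best is None or gev > best[1]:
            best = (templates, gev, history)
    assert best is not None
    templates, gev, history = best
    templates = normalize_maps(templates)
    return MicrostateMaps(
        maps=templates,
        labels=[f"M{i + 1}" for i in range(k)],
        level="subject",
        gev=gev,
        srate=srate,
        channel_names=channel_names,
        seed=seed if isinstance(seed, int) else None,
        gev_history=history,
    )


def compute_gev(
    maps: MicrostateMaps,
    peak_maps: np.ndarray,
    gfp: np.ndarray | None = None,
    polarity_invariant: bool = True,
) -> float:
    """Global explained variance of ``maps`` on a set of topographies.

    GEV = sum_t GFP_t^2 * r_t^2 / sum_t GFP_t^2, where r_t is the
    (polarity-invariant) spatial correlation between topography t and its
    best-matching template. ``gfp`` defaults to the spatial standard
    deviation of each supplied map.
    """
    peak_maps = np.atleast_2d(np.asarray(peak_maps, dtype=float))
    if peak_maps.shape[1] != maps.n_channels:
        raise FormatError("peak maps and templates have different channel counts")
    if gfp is None:
        gfp = peak_maps.std(axis=1, ddof=0)
    gfp2 = np.asarray(gfp, dtype=float) ** 2
    if np.sum(gfp2) <= 0:
        raise DataError("total GFP is zero; GEV undefined")
    corr = spatial_correlation(peak_maps, maps.maps)
    strength = np.abs(corr) if polarity_invariant else corr
    assign = strength.argmax(axis=1)
    return _gev(gfp2, strength, assign)


def aggregate_group_maps(
    subject_maps: list[MicrostateMaps],
    k: int = 4,
    seed: int | np.random.Generator | None = None,
    n_restarts: int = 20,
) -> MicrostateMaps:
    """Second-level clustering: pool subject templates and re-cluster.

    Every subject contributes exactly K template vectors regardless of how
    many epochs it had, so subjects are weighted equally.
    """
    if len(subject_maps) < 2:
        raise ParameterError("group aggregation needs at least 2 subjects")
    n_ch = subject_maps[0].n_channels
    for m in subject_maps:
        if m.n_channels != n_ch:
            raise FormatError("subject map sets differ in channel count")
    pooled = np.concatenate([m.maps for m in subject_maps], axis=0)
    out = modified_kmeans(
        pooled,
        k=k,
        n_restarts=n_restarts,
        seed=seed,
        channel_names=subject_maps[0].channel_names,
        srate=subject_maps[0].srate,
    )
    out.level = "group"
    return out


def canonical_templates(n_channels: int = 64) -> MicrostateMaps:
    """Built-in idealized reference topographies for classes A-D.

    Constructed analytically on the 2-D electrode layout:

    - A: left-right oriented field, tilted toward the front (odd in x).
    - B: its right-left mirror image.
    - C: anterior-posterior gradient.
    - D: fronto-central maximum (radial blob).

    The A/B tilt coefficient is chosen from the layout so that A and B are
    orthogonal; D is decorrelated from C down to |r| <= 0.3. All maps are
    zero-mean, unit-norm, pairwise |r| <= 0.5.
    """
    names, xy = layout_positions(n_channels)
    x, y = xy[:, 0], xy[:, 1]

    # alpha^2 = x^2-weighted mean of y^2 makes <A, B> = 0 on this layout
    alpha = float(np.sqrt(np.sum(x**2 * y**2) / np.sum(x**2)))
    a = x * (alpha + y)
    b = -x * (alpha - y)
    c = y - y.mean()
    d = np.exp(-((x**2 + (y - 0.15) ** 2) / (2 * 0.45**2)))

    def unit(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        return v / np.linalg.norm(v)

    a, b, c, d = unit(a), unit(b), unit(c), unit(d)
    # keep the D-C correlation modest without changing D's character
    r_dc = float(d @ c)
    if abs(r_dc) > 0.3:
        d = unit(d - (r_dc - np.sign(r_dc) * 0.3) * c)
    maps = np.vstack([a, b, c, d])
    return MicrostateMaps(
        maps=maps, labels=list(CANONICAL_LABELS), level="reference",
        channel_names=names,
    )


def order_maps_canonical(
    maps: MicrostateMaps, reference: MicrostateMaps | None = None
) -> MicrostateMaps:
    """Relabel and reorder maps to the canonical A-D classes.

    Solves the assignment exactly over all K! permutations, maximizing the
    total absolute spatial correlation with the reference set; each map's
    polarity is then aligned to its reference for display consistency.
    """
    if reference is None:
        reference = canonical_templates(maps.n_channels)
    if reference.k != maps.k:
        raise ParameterError(
            f"reference has {reference.k} maps, input has {maps.k}"
        )
    if reference.n_channels != maps.n_channels:
        raise FormatError("reference and input differ in channel count")
    corr = spatial_correlation(maps.maps, reference.maps)
    best_perm = None
    best_score = -np.inf
    for perm in itertools.permutations(range(maps.k)):
        score = sum(abs(corr[perm[j], j]) for j in range(maps.k))
        if score > best_score:
            best_score = score
            best_perm = perm
    assert best_perm is not None
    order = list(best_perm)
    new_maps = maps.maps[order].copy()
    for j in range(maps.k):
        if corr[order[j], j] < 0:
            new_maps[j] = -new_maps[j]
    return MicrostateMaps(
        maps=new_maps,
        labels=list(reference.labels),
        level=maps.level,
        gev=maps.gev,
        srate=maps.srate,
        channel_names=maps.channel_names,
        seed=maps.seed,
        gev_history=maps.gev_history,
    )
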