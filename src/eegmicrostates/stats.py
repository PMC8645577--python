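"""Group comparison of microstate parameters.

For each parameter (Duration, Frequency, Coverage), the four per-class values
of a subject form a multivariate response profile; groups are compared with a
one-way MANOVA on those profiles (the multivariate approach to a
group x class mixed design, which yields the familiar Wilks' Lambda, Rao's F
and multivariate eta squared). Where the MANOVA is significant, per-class
one-way ANOVAs follow, with pairwise pooled-variance t contrasts judged
against a Bonferroni-corrected alpha of family_alpha / (n_groups * n_classes).

Wilks' Lambda = det(E) / det(E + H), with E and H the within- and
between-group SSCP matrices; eta^2 = 1 - Lambda^(1/s), s = min(p, k - 1).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "ManovaResult",
    "PosthocResult",
    "bonferroni_alpha",
    "manova_wilks",
    "posthoc_anova",
    "compare_groups",
]

PARAMETER_COLUMNS = {
    "duration": "duration_ms",
    "frequency": "frequency_per_s",
    "coverage": "coverage_fraction",
}


@dataclass
class ManovaResult:
    """One-way MANOVA summary: Wilks' Lambda, Rao's F approximation, eta^2."""

    wilks_lambda: float
    f_stat: float
    df: tuple[float, float]
    p_value: float
    eta_squared: float
    n_subjects: int
    parameter: str = ""


@dataclass
class PosthocResult:
    """Per-class one-way ANOVA with pairwise pooled-variance t contrasts."""

    class_label: str
    f_stat: float
    df: tuple[int, int]
    p_value: float
    pairwise: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    alpha_bonferroni: float = 0.05
    parameter: str = ""

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha_bonferroni)


def bonferroni_alpha(
    family_alpha: float, n_groups: int, n_classes: int
) -> float:
    """Per-comparison alpha under Bonferroni control of the family rate.

    family_alpha / (n_groups * n_classes); e.g. 0.05 / (3 * 4) = 0.004167.
    """
    if family_alpha <= 0 or n_groups <= 0 or n_classes <= 0:
        raise ParameterError("all inputs to bonferroni_alpha must be positive")
    return family_alpha / (n_groups * n_classes)


def _pivot(table: pd.DataFrame, parameter: str) -> tuple[np.ndarray, np.ndarray, list]:
    """Subjects x classes response matrix plus group labels, listwise complete."""
    col = PARAMETER_COLUMNS.get(parameter, parameter)
    if col not in table.columns:
        raise ParameterError(f"unknown parameter {parameter!r}")
    wide = table.pivot_table(
        index=["subject_id", "group"], columns="class", values=col, aggfunc="first"
    )
    n_before = len(wide)
    wide = wide.dropna()
    if len(wide) < n_before:
        logger.info(
            "%d subject(s) dropped listwise (missing %s values)",
            n_before - len(wide), parameter,
        )
    y = wide.to_numpy(dtype=float)
    groups = np.array([g for (_, g) in wide.index])
    classes = list(wide.columns)
    return y, groups, classes


def manova_wilks(
    table: pd.DataFrame, parameter: str, response: str = "profile"
) -> ManovaResult:
    """One-way MANOVA across groups on the per-class profile of one parameter.

    Parameters
    ----------
    table
        Tidy cohort parameter table (one row per subject x class).
    parameter
        "duration", "frequency" or "coverage" (or a raw column name).
    response
        "profile" tests the raw per-class values; "differences" tests the
        K-1 successive class differences — the multivariate group x class
        interaction of the mixed design. Coverage profiles sum to one per
        subject, so their raw SSCP is singular by construction and only the
        "differences" response is testable for coverage.
    """
    y, groups, _ = _pivot(table, parameter)
    if response == "differences":
        y = np.diff(y, axis=1)
    elif response != "profile":
        raise ParameterError(f"unknown response mode {response!r}")
    levels = sorted(set(groups))
    k = len(levels)
    n, p = y.shape
    if k < 2:
        raise ParameterError("MANOVA needs at least 2 groups")
    if n < p + k:
        raise DataError(f"too few subjects ({n}) for {p} responses and {k} groups")

    grand = y.mean(axis=0)
    e = np.zeros((p, p))
    h = np.zeros((p, p))
    for g in levels:
        sub = y[groups == g]
        m = sub.mean(axis=0)
        d = sub - m
        e += d.T @ d
        dm = (m - grand)[:, None]
        h += len(sub) * (dm @ dm.T)

    det_e = np.linalg.det(e)
    det_t = np.linalg.det(e + h)
    if det_e <= 0 or not np.isfinite(det_e):
        raise DataError(
            "within-group SSCP matrix is singular; consider dropping a class "
            "(regularization is off by default)"
        )
    lam = det_e / det_t

    # Rao's F approximation
    q = k - 1  # hypothesis df
    v = n - k  # error df
    if p**2 + q**2 - 5 > 0:
        t = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5))
    else:
        t = 1.0
    df1 = p * q
    df2 = (v - (p - q + 1) / 2) * t - (p * q - 2) / 2
    lam_t = lam ** (1 / t)
    f = (1 - lam_t) / lam_t * df2 / df1
    p_value = float(sps.f.sf(f, df1, df2))
    s = min(p, q)
    eta2 = 1 - lam ** (1 / s)
    return ManovaResult(
        wilks_lambda=float(lam),
        f_stat=float(f),
        df=(float(df1), float(df2)),
        p_value=p_value,
        eta_squared=float(eta2),
        n_subjects=n,
        parameter=parameter,
    )


def posthoc_anova(
    table: pd.DataFrame,
    parameter: str,
    class_label: str,
    alpha_bonferroni: float = 0.004167,
    permutations: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> PosthocResult:
    """One-way fixed-effects ANOVA for one class, with pairwise contrasts.

    Pairwise contrasts use the pooled within-group error from all groups
    (LSD-style t with df = N - k), reported unadjusted and compared to
    ``alpha_bonferroni``. With ``permutations`` set, the ANOVA p-value is
    additionally computed by label permutation instead of the F distribution.
    """
    col = PARAMETER_COLUMNS.get(parameter, parameter)
    sub = table[table["class"] == class_label].dropna(subset=[col])
    levels = sorted(sub["group"].unique())
    if len(levels) < 2:
        raise ParameterError("post-hoc ANOVA needs at least 2 groups")
    samples = [sub.loc[sub["group"] == g, col].to_numpy(dtype=float) for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ParameterError("every group needs at least 2 subjects")
    n_total = sum(len(s) for s in samples)
    k = len(levels)
    df1, df2 = k - 1, n_total - k

    msw = sum(((s - s.mean()) ** 2).sum() for s in samples) / df2
    if msw == 0:
        means = [s.mean() for s in samples]
        degenerate_p = 0.0 if len(set(means)) > 1 else 1.0
        warnings.warn(
            "zero within-group variance; ANOVA degenerate "
            f"(p set to {degenerate_p})",
            stacklevel=2,
        )
        f_stat, p_value = np.inf if degenerate_p == 0 else 0.0, degenerate_p
    else:
        f_stat, p_value = sps.f_oneway(*samples)
        f_stat, p_value = float(f_stat), float(p_value)

    if permutations is not None and msw > 0:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(samples)
        sizes = [len(s) for s in samples]
        count = 0
        for _ in range(permutations):
            shuffled = rng.permutation(pooled)
            parts = np.split(shuffled, np.cumsum(sizes)[:-1])
            if sps.f_oneway(*parts)[0] >= f_stat:
                count += 1
        p_value = (count + 1) / (permutations + 1)

    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    for (i, gi), (j, gj) in itertools.combinations(enumerate(levels), 2):
        a, b = samples[i], samples[j]
        if msw > 0:
            se = np.sqrt(msw * (1 / len(a) + 1 / len(b)))
            t_stat = (a.mean() - b.mean()) / se
            p_pair = 2 * float(sps.t.sf(abs(t_stat), df2))
        else:
            t_stat = np.inf if a.mean() != b.mean() else 0.0
            p_pair = 0.0 if a.mean() != b.mean() else 1.0
        pairwise[(gi, gj)] = (float(t_stat), p_pair)

    return PosthocResult(
        class_label=class_label,
        f_stat=f_stat,
        df=(df1, df2),
        p_value=p_value,
        pairwise=pairwise,
        alpha_bonferroni=alpha_bonferroni,
        parameter=parameter,
    )


def compare_groups(
    table: pd.DataFrame,
    family_alpha: float = 0.05,
    parameters: tuple[str, ...] = ("duration", "frequency", "coverage"),
) -> dict[str, dict]:
    """Run the full statistical comparison on a cohort parameter table.

    For each parameter: MANOVA across groups on the class-profile differences
    (the group x class interaction of the mixed design — the only testable
    response for coverage, whose raw profiles are compositional), then
    per-class post-hoc ANOVAs at the Bonferroni-corrected alpha. Returns a
    nested dict ``{parameter: {"manova": ManovaResult,
    "posthoc": {class: PosthocResult}, "alpha_bonferroni": float}}``.
    """
    classes = sorted(table["class"].unique())
    n_groups = table["group"].nunique()
    alpha = bonferroni_alpha(family_alpha, n_groups, len(classes))
    results: dict[str, dict] = {}
    for parameter in parameters:
        manova = manova_wilks(table, parameter, response="differences")
        posthoc = {
            c: posthoc_anova(table, parameter, c, alpha_bonferroni=alpha)
            for c in classes
        }
        results[parameter] = {
            "manova": manova,
            "posthoc": posthoc,
            "alpha_bonferroni": alpha,
        }
    return results
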