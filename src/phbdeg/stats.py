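"""Group comparison of t50 values: one-way ANOVA, Tukey HSD, letter display.

Blends are compared on their replicate t50 values with the classical
fixed-effects one-way ANOVA, followed by Tukey's studentized-range post hoc
test on all pairs (Tukey-Kramer standard errors when group sizes differ).
Results are summarized as a compact letter display: two groups share a
letter exactly when their pairwise difference is *not* significant.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TukeyPair",
    "GroupComparison",
    "one_way_anova",
    "tukey_hsd",
    "compact_letters",
    "compare_groups",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TukeyPair:
    """One pairwise Tukey comparison."""

    group_a: str
    group_b: str
    difference: float  # mean(a) - mean(b)
    q_statistic: float
    p_value: float
    reject: bool


@dataclass
class GroupComparison:
    """Full comparison of several groups of replicate values."""

    groups: list[str]
    group_values: dict[str, np.ndarray]
    anova_F: float
    anova_p: float
    tukey_pairs: list[TukeyPair]
    letters: dict[str, str]
    alpha: float = 0.05


def _check_groups(group_values: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    clean = {g: np.asarray(v, dtype=float) for g, v in group_values.items()}
    if len(clean) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in clean.items():
        if v.ndim != 1 or v.size < 2 or not np.all(np.isfinite(v)):
            raise ValueError(f"group {g!r} needs >= 2 finite values")
    return clean


def one_way_anova(group_values: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical between/within F-test on ``(k-1, N-k)`` degrees of freedom.

    Returns ``(F, p)``.  A configuration with all group means equal gives
    F = 0, p = 1.
    """
    clean = _check_groups(group_values)
    values = list(clean.values())
    grand = np.concatenate(values)
    n_total = grand.size
    k = len(values)
    ss_between = sum(v.size * (v.mean() - grand.mean()) ** 2 for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        if ss_between == 0:
            raise ValueError("no variance at all: F undefined")
        return float("inf"), 0.0
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    return float(f_stat), float(sps.f.sf(f_stat, df_b, df_w))


def tukey_hsd(group_values: dict[str, np.ndarray], alpha: float = 0.05) -> list[TukeyPair]:
    """Tukey's honestly-significant-difference test on all group pairs.

    The q statistic for groups i, j is ``|mean_i - mean_j| / SE`` with
    ``SE = sqrt(MSW/2 * (1/n_i + 1/n_j))`` (pooled within-group mean
    square); its p-value comes from the studentized range distribution on
    ``(k, N-k)``.  For equal group sizes this is the exact Tukey test;
    unequal sizes give the Tukey-Kramer variant.
    """
    clean = _check_groups(group_values)
    names = list(clean)
    k = len(names)
    n_total = sum(v.size for v in clean.values())
    df_w = n_total - k
    msw = sum(((v - v.mean()) ** 2).sum() for v in clean.values()) / df_w
    pairs: list[TukeyPair] = []
    for a, b in itertools.combinations(names, 2):
        va, vb = clean[a], clean[b]
        diff = float(va.mean() - vb.mean())
        se = np.sqrt(msw / 2.0 * (1.0 / va.size + 1.0 / vb.size))
        if se == 0:
            q = float("inf") if diff != 0 else 0.0
        else:
            q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
        if q == 0.0:
            p = 1.0
        pairs.append(
            TukeyPair(
                group_a=a,
                group_b=b,
                difference=diff,
                q_statistic=float(q),
                p_value=p,
                reject=bool(p < alpha),
            )
        )
    return pairs


def compact_letters(
    tukey_pairs: list[TukeyPair], group_means: dict[str, float] | None = None
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Builds letter sets so that two groups share at least one letter iff
    their pair is *not* rejected.  Starting from one all-inclusive letter,
    each rejected pair splits the letters containing both groups; an
    absorption pass then removes letters whose group set is contained in
    another's, minimizing the display.  Groups are processed in order of
    decreasing mean (when means are given) so the leading letter follows
    the magnitude ranking, matching how such displays are printed on bar
    charts.
    """
    groups: list[str] = []
    for p in tukey_pairs:
        for g in (p.group_a, p.group_b):
            if g not in groups:
                groups.append(g)
    if group_means:
        groups.sort(key=lambda g: -group_means[g])

    letters: list[set[str]] = [set(groups)]
    for pair in tukey_pairs:
        if not pair.reject:
            continue
        for s in list(letters):
            if pair.group_a in s and pair.group_b in s:
                letters.remove(s)
                letters.append(s - {pair.group_a})
                letters.append(s - {pair.group_b})
        # absorb letters contained in another letter
        letters = [
            s
            for i, s in enumerate(letters)
            if s and not any(i != j and s < other for j, other in enumerate(letters))
        ]
        # deduplicate while preserving order
        seen: list[set[str]] = []
        for s in letters:
            if s not in seen:
                seen.append(s)
        letters = seen

    # order letters by the best-ranked group they contain, then label a, b, ...
    letters.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for label, s in zip(alphabet, letters):
        for g in groups:
            if g in s:
                out[g] += label
    return out


def compare_groups(
    group_values: dict[str, object], alpha: float = 0.05, drop_non_finite: bool = True
) -> GroupComparison:
    """One-way ANOVA + Tukey HSD + compact letters in one call.

    Non-finite entries (e.g. censored t50 values coded as NaN) are dropped
    with a warning when ``drop_non_finite`` is set — a censored replicate
    carries no usable location information for a mean comparison.
    """
    cleaned: dict[str, np.ndarray] = {}
    for g, v in group_values.items():
        arr = np.asarray(v, dtype=float)
        if drop_non_finite and not np.all(np.isfinite(arr)):
            n_bad = int((~np.isfinite(arr)).sum())
            logger.warning(
                "group %r: dropping %d censored/non-finite t50 value(s) before ANOVA", g, n_bad
            )
            arr = arr[np.isfinite(arr)]
        cleaned[g] = arr
    f_stat, p = one_way_anova(cleaned)
    pairs = tukey_hsd(cleaned, alpha=alpha)
    means = {g: float(v.mean()) for g, v in cleaned.items()}
    letters = compact_letters(pairs, means)
    return GroupComparison(
        groups=list(cleaned),
        group_values=cleaned,
        anova_F=f_stat,
        anova_p=p,
        tukey_pairs=pairs,
        letters=letters,
        alpha=alpha,
    )
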