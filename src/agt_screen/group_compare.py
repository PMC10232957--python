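"""Newman-Keuls (SNK) multiple-range comparison with compact letter display.

The SNK procedure sorts group means, then tests the range of every span of
``p`` adjacent ordered means against the studentized-range critical value
q(alpha, p, df_error). A span whose range is not significant is declared
homogeneous, and none of its sub-spans are tested (the standard stepwise
protection). Homogeneous spans are contiguous in the mean ordering, so the
compact letter display reduces to labelling maximal homogeneous intervals.

With unequal group sizes the pairwise standard error uses the
Tukey-Kramer form sqrt(MSe/2 * (1/n_i + 1/n_j)) on the span's endpoint
groups.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .errors import ValidationError


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float
    letters: str
    flagged: bool = False


@lru_cache(maxsize=1024)
def _q_crit(alpha: float, span: int, df: int) -> float:
    # scipy's studentized-range ppf is accurate but slow; memoize.
    return float(studentized_range.ppf(1.0 - alpha, span, df))


def _one_way_mse(groups: Sequence[np.ndarray]) -> tuple[float, int]:
    """Pooled within-group mean square and its df from a one-way layout."""
    ss = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    df = sum(len(g) - 1 for g in groups)
    return (ss / df if df > 0 else 0.0), df


def snk_letters(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> list[GroupSummary]:
    """SNK multiple-range test over groups of observations.

    Returns one :class:`GroupSummary` per group, sorted by mean descending.
    Groups sharing any letter are not significantly different at ``alpha``.
    Groups with a single observation are reported but excluded from the
    letter computation (flagged).
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0,1)")
    if not values_by_group:
        return []
    arrays = {k: np.asarray(v, float) for k, v in values_by_group.items()}
    for k, a in arrays.items():
        if a.size == 0:
            raise ValidationError(f"group {k!r} is empty")

    testable = {k: a for k, a in arrays.items() if len(a) >= 2}
    singles = [k for k, a in arrays.items() if len(a) < 2]

    order = sorted(testable, key=lambda k: -testable[k].mean())
    means = np.array([testable[k].mean() for k in order])
    ns = np.array([len(testable[k]) for k in order])
    m = len(order)

    summaries: dict[str, GroupSummary] = {}

    if m == 0:
        letters_by_group: dict[str, str] = {}
    elif m == 1:
        letters_by_group = {order[0]: "a"}
    else:
        mse, df_e = _one_way_mse([testable[k] for k in order])
        if mse == 0.0:
            # zero within-group variance: distinct means are trivially
            # distinct, ties share a letter; flagged downstream
            letters_by_group = {}
            letter_idx = -1
            last_mean = None
            for k, mu in zip(order, means):
                if last_mean is None or mu != last_mean:
                    letter_idx += 1
                    last_mean = mu
                letters_by_group[k] = string.ascii_lowercase[letter_idx]
            for k in order:
                summaries[k] = GroupSummary(
                    k, int(len(testable[k])), float(testable[k].mean()),
                    float(testable[k].std(ddof=1)), letters_by_group[k],
                    flagged=True,
                )
        if mse > 0.0:
            homogeneous = _snk_homogeneous_spans(means, ns, mse, df_e, alpha)
            letters_by_group = _letters_from_spans(order, homogeneous)

    for k in order:
        if k in summaries:
            continue
        a = testable[k]
        summaries[k] = GroupSummary(
            k, int(len(a)), float(a.mean()), float(a.std(ddof=1)),
            letters_by_group.get(k, ""),
        )
    for k in singles:
        a = arrays[k]
        summaries[k] = GroupSummary(
            k, int(len(a)), float(a.mean()), float("nan"), "", flagged=True
        )
    return sorted(summaries.values(), key=lambda s: -s.mean)


def _snk_homogeneous_spans(
    means: np.ndarray, ns: np.ndarray, mse: float, df_e: int, alpha: float
) -> list[tuple[int, int]]:
    """Maximal non-significant index spans [i, j] over the ordered means."""
    m = len(means)
    nonsig: list[tuple[int, int]] = []

    def covered(i: int, j: int) -> bool:
        return any(a <= i and j <= b for a, b in nonsig)

    for span in range(m, 1, -1):
        for i in range(0, m - span + 1):
            j = i + span - 1
            if covered(i, j):
                continue
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q_stat = (means[i] - means[j]) / se
            if q_stat <= _q_crit(alpha, span, df_e):
                nonsig.append((i, j))
    # singletons not inside any homogeneous span
    for i in range(m):
        if not covered(i, i):
            nonsig.append((i, i))
    # keep maximal spans only
    maximal = [
        (a, b) for a, b in nonsig
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in nonsig)
    ]
    return sorted(maximal)


def _letters_from_spans(
    order: Sequence[str], spans: Sequence[tuple[int, int]]
) -> dict[str, str]:
    letters: dict[str, str] = {k: "" for k in order}
    for idx, (a, b) in enumerate(spans):
        ch = string.ascii_lowercase[idx % 26]
        for i in range(a, b + 1):
            letters[order[i]] += ch
    return letters


def group_summary(
    scored: pd.DataFrame,
    by: str,
    traits: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-trait group means with SNK letters (experimental unit = genotype).

    Parameters
    ----------
    scored : pandas.DataFrame
        Genotype-mean table carrying a grouping column ``by``
        (e.g. ``tolerance_class``, ``grain_type`` or ``cluster``).
    by : str
        Grouping column name; must be present for every record.
    traits : sequence of str
        Trait columns to summarize.

    Returns a tidy frame with columns
    ``trait, group, n, mean, sd, letters, flagged``.
    """
    if by not in scored.columns:
        raise ValidationError(f"grouping column {by!r} not in table")
    if scored[by].isna().any():
        raise ValidationError(f"grouping column {by!r} has missing labels")
    rows = []
    for trait in traits:
        if trait not in scored.columns:
            raise ValidationError(f"trait {trait!r} not in table")
        groups = {
            str(g): sub[trait].to_numpy(float)
            for g, sub in scored.groupby(by, observed=True)
        }
        for s in snk_letters(groups, alpha=alpha):
            rows.append(
                {
                    "trait": trait, "group": s.group, "n": s.n,
                    "mean": s.mean, "sd": s.sd, "letters": s.letters,
                    "flagged": s.flagged,
                }
            )
    return pd.DataFrame(rows)
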