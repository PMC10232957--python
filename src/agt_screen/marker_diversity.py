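"""SSR/InDel marker diversity statistics and single-marker trait association.

Per-locus informativeness follows the polymorphic information content in
its Botstein form,

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2,

with allele frequencies p_i taken over non-missing calls (one call per
inbred genotype per locus). Expected heterozygosity 1 - sum p_i^2 is
available as an alternative. Marker-trait association is a one-way ANOVA
of the genotype-mean trait over allele classes, reporting the F-test
p-value and R^2 = 100 * SS_between / SS_total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .multivariate import DistanceMatrix
from .trial_io import MarkerDataset

PIC_METHODS = ("botstein", "expected_het")
DISTANCE_METRICS = ("nei_li", "shared_allele", "mismatch")


@dataclass(frozen=True)
class LocusStats:
    locus: str
    na: int
    frequencies: tuple[float, ...]
    maf: float          # major (most frequent) allele frequency
    pic: float
    missing_fraction: float
    monomorphic: bool


def pic_botstein(freqs: Sequence[float]) -> float:
    p = np.asarray(freqs, float)
    if p.size and not np.isclose(p.sum(), 1.0):
        raise ValidationError("allele frequencies must sum to 1")
    homo = float((p ** 2).sum())
    cross = sum(2.0 * p[i] ** 2 * p[j] ** 2 for i, j in combinations(range(len(p)), 2))
    return 1.0 - homo - cross


def expected_heterozygosity(freqs: Sequence[float]) -> float:
    p = np.asarray(freqs, float)
    return 1.0 - float((p ** 2).sum())


def allele_stats(
    markers: MarkerDataset, method: str = "botstein"
) -> list[LocusStats]:
    """Per-locus allele counts, frequencies, MAF and PIC.

    Loci with no scored call are excluded with a warning; monomorphic loci
    get PIC 0 and are flagged.
    """
    if method not in PIC_METHODS:
        raise ValidationError(f"unknown PIC method {method!r}")
    fn = pic_botstein if method == "botstein" else expected_heterozygosity
    out = []
    for locus in markers.locus_names:
        col = [str(v) for v in markers.calls[locus] if v is not None]
        if not col:
            warnings.warn(f"locus {locus} all-missing: excluded", stacklevel=2)
            continue
        counts = pd.Series(col).value_counts()
        freqs = (counts / counts.sum()).to_numpy()
        out.append(
            LocusStats(
                locus=locus,
                na=len(counts),
                frequencies=tuple(float(f) for f in freqs),
                maf=float(freqs.max()),
                pic=float(fn(freqs)) if len(counts) > 1 else 0.0,
                missing_fraction=markers.missing_fraction(locus),
                monomorphic=len(counts) == 1,
            )
        )
    return out


def stats_frame(loci: Sequence[LocusStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"locus": s.locus, "Na": s.na, "MAF": s.maf, "PIC": s.pic,
             "missing": s.missing_fraction, "monomorphic": s.monomorphic}
            for s in loci
        ]
    )


# ---------------------------------------------------------------------------
# genetic distances


def genetic_distance(markers: MarkerDataset, metric: str = "nei_li") -> DistanceMatrix:
    """Pairwise genotype dissimilarity from allele calls.

    nei_li
        ``1 - 2 * n_shared / (n_x + n_y)`` treating each (locus, allele)
        call as a band; n_x is the number of scored loci of genotype x.
    shared_allele
        One minus the fraction of co-scored loci with identical calls.
    mismatch
        Raw count of co-scored loci with differing calls (unnormalized;
        scales with the number of loci).
    """
    if metric not in DISTANCE_METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    calls = markers.calls
    genos = list(calls.index)
    A = calls.to_numpy(object)
    n = len(genos)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = A[i], A[j]
            both = np.array([a is not None and b is not None for a, b in zip(xi, xj)])
            if metric == "nei_li":
                nx = sum(a is not None for a in xi)
                ny = sum(b is not None for b in xj)
                shared = sum(
                    a == b for a, b, ok in zip(xi, xj, both) if ok
                )
                if nx + ny == 0:
                    raise ValidationError(
                        f"no scored loci for pair ({genos[i]}, {genos[j]})"
                    )
                d = 1.0 - 2.0 * shared / (nx + ny)
            else:
                if not both.any():
                    raise ValidationError(
                        f"no co-scored locus for pair ({genos[i]}, {genos[j]})"
                    )
                same = np.array(
                    [a == b for a, b, ok in zip(xi, xj, both) if ok]
                )
                if metric == "shared_allele":
                    d = 1.0 - float(same.mean())
                else:  # mismatch
                    d = float((~same).sum())
            D[i, j] = D[j, i] = d
    return DistanceMatrix(genos, D, metric)


# ---------------------------------------------------------------------------
# single-marker association


@dataclass(frozen=True)
class MarkerTraitAssociation:
    marker: str
    trait: str
    p: float
    r2: float           # percent of trait variance explained
    n_classes: int
    n: int
    significant: bool


def single_marker_analysis(
    markers: MarkerDataset,
    records: pd.DataFrame,
    traits: Sequence[str],
    alpha: float = 0.05,
    min_class_size: int = 2,
) -> pd.DataFrame:
    """One-way ANOVA of each trait over each marker's allele classes.

    Genotypes are matched between the marker matrix and the trait table by
    normalized label. Allele classes with fewer than ``min_class_size``
    genotypes are dropped; a marker is skipped (with a reason) when fewer
    than two classes remain, as is a constant trait. Raw p-values are
    reported alongside Benjamini-Hochberg adjusted values across the
    tested marker x trait grid.
    """
    common = [g for g in markers.genotypes if g in records.index]
    if len(common) < 4:
        raise ValidationError("fewer than 4 genotypes shared between inputs")
    rows = []
    for locus in markers.locus_names:
        calls = markers.calls.loc[common, locus]
        classes = {}
        for allele, sub in calls.groupby(calls):
            if allele is not None and len(sub) >= min_class_size:
                classes[allele] = list(sub.index)
        if len(classes) < 2:
            rows.append({"marker": locus, "trait": None, "skipped":
                         "fewer than 2 allele classes of usable size"})
            continue
        for trait in traits:
            if trait not in records.columns:
                raise ValidationError(f"trait {trait!r} not in trait table")
            groups = [records.loc[ids, trait].to_numpy(float)
                      for ids in classes.values()]
            pooled = np.concatenate(groups)
            ss_total = float(((pooled - pooled.mean()) ** 2).sum())
            if ss_total == 0.0:
                rows.append({"marker": locus, "trait": trait,
                             "skipped": "constant trait"})
                continue
            ss_between = float(
                sum(len(x) * (x.mean() - pooled.mean()) ** 2 for x in groups)
            )
            f, p = stats.f_oneway(*groups)
            rows.append({
                "marker": locus, "trait": trait, "p": float(p),
                "R2": 100.0 * ss_between / ss_total,
                "n_classes": len(groups), "n": len(pooled),
                "skipped": None,
            })
    df = pd.DataFrame(rows)
    tested = df["skipped"].isna() if "skipped" in df else pd.Series(dtype=bool)
    if tested.any():
        df.loc[tested, "p_bh"] = _benjamini_hochberg(df.loc[tested, "p"].to_numpy())
        df.loc[tested, "significant"] = df.loc[tested, "p"] < alpha
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * m / (rank_idx + 1))
        adj[i] = val
        prev = val
    return adj
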