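"""RCBD ANOVA and method-of-moments variance-component estimation.

The screening is a randomized complete block design (RCBD) repeated over
seasons: each of ``r`` replicates (blocks) contains every genotype once,
and the whole experiment is run in ``s`` seasons. Variance components are
estimated by equating observed mean squares to their expectations:

single season:   E[MS_g] = sigma2_e + r*sigma2_g
pooled seasons:  E[MS_g]  = sigma2_e + r*sigma2_ge + r*s*sigma2_g
                 E[MS_gs] = sigma2_e + r*sigma2_ge

so sigma2_e = MS_error, sigma2_ge = (MS_gs - MS_e)/r and
sigma2_g = (MS_g - MS_gs)/(r*s) (single season: (MS_g - MS_e)/r).
Genotype F-tests use MS_gs as the denominator in the pooled analysis and
MS_error within a season. Negative moment estimates are clamped to zero and
flagged; the raw values stay in the ANOVA table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, ValidationError
from .trial_io import Treatment, TrialDataset


@dataclass(frozen=True)
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float
    f: float | None = None
    p: float | None = None

    @property
    def stars(self) -> str:
        if self.p is None:
            return ""
        return "**" if self.p < 0.01 else ("*" if self.p < 0.05 else "ns")


@dataclass
class AnovaTable:
    rows: list[AnovaRow]

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": r.source, "df": r.df, "ss": r.ss, "ms": r.ms,
                    "F": r.f, "p": r.p, "sig": r.stars,
                }
                for r in self.rows
            ]
        )


@dataclass
class VarianceComponents:
    """Moment estimates of the genetic variance structure for one trait."""

    sigma2_g: float
    sigma2_e: float
    r: int
    s: int = 1
    sigma2_ge: float = 0.0
    truncated: dict[str, bool] = field(default_factory=dict)
    raw: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "sigma2_g": self.sigma2_g,
            "sigma2_ge": self.sigma2_ge,
            "sigma2_e": self.sigma2_e,
            "r": self.r,
            "s": self.s,
            "truncated": dict(self.truncated),
        }


def _clamp(name: str, value: float, truncate: bool,
           truncated: dict[str, bool], raw: dict[str, float]) -> float:
    raw[name] = float(value)
    if truncate and value < 0:
        truncated[name] = True
        return 0.0
    truncated[name] = False
    return float(value)


def _balanced_matrix(dataset: TrialDataset, trait: str, season: str | None,
                     treatment: str) -> pd.DataFrame:
    if trait not in dataset.traits:
        raise ValidationError(f"trait {trait} not present in dataset")
    mat = dataset.cell_matrix(trait, season=season, treatment=treatment)
    if mat.isna().any().any():
        holes = [
            f"({g}, {c})" for g in mat.index for c in mat.columns
            if pd.isna(mat.loc[g, c])
        ]
        raise DesignError(
            f"unbalanced design for trait {trait}: missing cells "
            + ", ".join(map(str, holes[:10]))
            + ("..." if len(holes) > 10 else "")
        )
    return mat


def anova_rcbd(
    dataset: TrialDataset,
    trait: str,
    season: str,
    treatment: str = Treatment.submerged.value,
    truncate: bool = True,
) -> tuple[AnovaTable, VarianceComponents]:
    """Single-season RCBD ANOVA and variance components for one trait."""
    mat = _balanced_matrix(dataset, trait, season, treatment)
    y = mat.to_numpy(float)
    g, r = y.shape
    if g < 2:
        raise DesignError("need at least 2 genotypes")
    if r < 2:
        raise DesignError("need at least 2 replicates (error MS undefined)")

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_g = float(r * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_r = float(g * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_e = ss_total - ss_g - ss_r

    df_g, df_r = g - 1, r - 1
    df_e = df_g * df_r
    ms_g, ms_r, ms_e = ss_g / df_g, ss_r / df_r, ss_e / df_e

    if ms_e > 0:
        f_g = ms_g / ms_e
        p_g = float(stats.f.sf(f_g, df_g, df_e))
        f_r = ms_r / ms_e
        p_r = float(stats.f.sf(f_r, df_r, df_e))
    else:  # degenerate: no residual variation
        f_g = p_g = f_r = p_r = None

    table = AnovaTable([
        AnovaRow("genotype", df_g, ss_g, ms_g, f_g, p_g),
        AnovaRow("replicate", df_r, ss_r, ms_r, f_r, p_r),
        AnovaRow("error", df_e, ss_e, ms_e),
    ])
    truncated: dict[str, bool] = {}
    raw: dict[str, float] = {}
    comps = VarianceComponents(
        sigma2_g=_clamp("sigma2_g", (ms_g - ms_e) / r, truncate, truncated, raw),
        sigma2_e=_clamp("sigma2_e", ms_e, truncate, truncated, raw),
        r=r, s=1, truncated=truncated, raw=raw,
    )
    return table, comps


def anova_pooled(
    dataset: TrialDataset,
    trait: str,
    treatment: str = Treatment.submerged.value,
    truncate: bool = True,
) -> tuple[AnovaTable, VarianceComponents]:
    """Pooled-over-seasons ANOVA with replicates nested within season.

    Sources: genotype, season, replicate-within-season, genotype x season,
    pooled error. Genotype is tested against the G x S mean square,
    G x S against the pooled error.
    """
    if len(dataset.seasons) < 2:
        raise DesignError("single season: use anova_rcbd instead")
    mat = _balanced_matrix(dataset, trait, None, treatment)
    g = mat.shape[0]
    seasons = sorted({c[0] for c in mat.columns})
    reps = sorted({c[1] for c in mat.columns})
    s, r = len(seasons), len(reps)
    if mat.shape[1] != s * r:
        raise DesignError("replicate structure differs between seasons")
    if g < 2 or r < 2:
        raise DesignError("need g >= 2 and r >= 2")

    # genotype x season x replicate array
    y = np.empty((g, s, r))
    for j, sj in enumerate(seasons):
        for k, rk in enumerate(reps):
            y[:, j, k] = mat[(sj, rk)].to_numpy(float)

    grand = y.mean()
    gi = y.mean(axis=(1, 2))            # genotype means
    sj = y.mean(axis=(0, 2))            # season means
    gij = y.mean(axis=2)                # genotype x season means
    rep_js = y.mean(axis=0)             # season x replicate means

    ss_total = float(((y - grand) ** 2).sum())
    ss_g = float(s * r * ((gi - grand) ** 2).sum())
    ss_s = float(g * r * ((sj - grand) ** 2).sum())
    ss_rep = float(g * ((rep_js - sj[:, None]) ** 2).sum())
    ss_gs = float(
        r * ((gij - gi[:, None] - sj[None, :] + grand) ** 2).sum()
    )
    ss_e = ss_total - ss_g - ss_s - ss_rep - ss_gs

    df_g, df_s = g - 1, s - 1
    df_rep = s * (r - 1)
    df_gs = (g - 1) * (s - 1)
    df_e = s * (g - 1) * (r - 1)

    ms_g, ms_s = ss_g / df_g, ss_s / df_s
    ms_rep, ms_gs, ms_e = ss_rep / df_rep, ss_gs / df_gs, ss_e / df_e

    def _ftest(ms_num, df_num, ms_den, df_den):
        if ms_den <= 0:
            return None, None
        f = ms_num / ms_den
        return f, float(stats.f.sf(f, df_num, df_den))

    f_g, p_g = _ftest(ms_g, df_g, ms_gs, df_gs)
    f_s, p_s = _ftest(ms_s, df_s, ms_rep, df_rep)
    f_rep, p_rep = _ftest(ms_rep, df_rep, ms_e, df_e)
    f_gs, p_gs = _ftest(ms_gs, df_gs, ms_e, df_e)

    table = AnovaTable([
        AnovaRow("genotype", df_g, ss_g, ms_g, f_g, p_g),
        AnovaRow("season", df_s, ss_s, ms_s, f_s, p_s),
        AnovaRow("replicate(season)", df_rep, ss_rep, ms_rep, f_rep, p_rep),
        AnovaRow("genotype:season", df_gs, ss_gs, ms_gs, f_gs, p_gs),
        AnovaRow("error", df_e, ss_e, ms_e),
    ])
    truncated: dict[str, bool] = {}
    raw: dict[str, float] = {}
    comps = VarianceComponents(
        sigma2_g=_clamp("sigma2_g", (ms_g - ms_gs) / (r * s), truncate, truncated, raw),
        sigma2_ge=_clamp("sigma2_ge", (ms_gs - ms_e) / r, truncate, truncated, raw),
        sigma2_e=_clamp("sigma2_e", ms_e, truncate, truncated, raw),
        r=r, s=s, truncated=truncated, raw=raw,
    )
    return table, comps
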