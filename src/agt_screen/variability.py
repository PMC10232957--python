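"""Genetic variability parameters: GCV, PCV, heritability, genetic advance.

From the variance components and the trait grand mean x̄:

    GCV  = 100 * sqrt(sigma2_g) / x̄
    PCV  = 100 * sqrt(sigma2_p) / x̄
    h2bs = 100 * sigma2_g / sigma2_p          (broad-sense heritability, %)
    GA   = k * (h2bs/100) * sigma_g           (default, 'genotypic' basis)
         = k * (h2bs/100) * sigma_p           ('phenotypic' textbook form)
    GAM  = 100 * GA / x̄
    SED  = sqrt(2 * sigma2_e / r)

with selection differential k = 2.06 (top 5% selected). The phenotypic
variance sigma2_p depends on the reporting basis:

    plot       : sigma2_g + sigma2_ge + sigma2_e
    entry_mean : sigma2_g + sigma2_ge/s + sigma2_e/(r*s)
    single_env : sigma2_g + sigma2_e

The identity h2bs = 100 * (GCV/PCV)^2 holds by construction, which makes
published GCV/PCV/mean triples sufficient to reconstruct heritability and
genetic advance.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

from .errors import ValidationError
from .varcomp import VarianceComponents

DEFAULT_K = 2.06  # 5% selection intensity

PHENOTYPIC_BASES = ("plot", "entry_mean", "single_env")
GA_BASES = ("genotypic", "phenotypic")


@dataclass(frozen=True)
class VariabilityParams:
    gcv: float
    pcv: float
    h2bs: float | None
    ga: float
    gam: float
    mean: float
    sed: float | None = None
    k: float = DEFAULT_K
    basis: str = "plot"

    def as_dict(self) -> dict:
        return {
            "GCV": self.gcv, "PCV": self.pcv, "h2bs": self.h2bs,
            "GA": self.ga, "GAM": self.gam, "SED": self.sed,
            "mean": self.mean, "k": self.k, "basis": self.basis,
        }


def phenotypic_variance(components: VarianceComponents, basis: str) -> float:
    c = components
    if basis == "plot":
        return c.sigma2_g + c.sigma2_ge + c.sigma2_e
    if basis == "entry_mean":
        return c.sigma2_g + c.sigma2_ge / c.s + c.sigma2_e / (c.r * c.s)
    if basis == "single_env":
        return c.sigma2_g + c.sigma2_e
    raise ValidationError(f"unknown phenotypic basis {basis!r}")


def variability_from_variances(
    sigma2_g: float,
    sigma2_p: float,
    mean: float,
    k: float = DEFAULT_K,
    ga_basis: str = "genotypic",
    sigma2_e: float | None = None,
    r: int | None = None,
    basis: str = "plot",
) -> VariabilityParams:
    """Compute all variability parameters from (sigma2_g, sigma2_p, mean)."""
    if mean <= 0:
        raise ValidationError("trait mean must be positive")
    if sigma2_g < 0 or sigma2_p < 0:
        raise ValidationError("variances must be non-negative")
    if sigma2_p < sigma2_g:
        raise ValidationError("phenotypic variance cannot be below genotypic")
    if ga_basis not in GA_BASES:
        raise ValidationError(f"unknown GA basis {ga_basis!r}")

    gcv = 100.0 * sqrt(sigma2_g) / mean
    pcv = 100.0 * sqrt(sigma2_p) / mean
    h2 = 100.0 * sigma2_g / sigma2_p if sigma2_p > 0 else None
    if h2 is None:
        ga = 0.0
    else:
        sel_sd = sqrt(sigma2_g) if ga_basis == "genotypic" else sqrt(sigma2_p)
        ga = k * (h2 / 100.0) * sel_sd
    gam = 100.0 * ga / mean
    sed = None
    if sigma2_e is not None and r:
        sed = sqrt(2.0 * sigma2_e / r)
    return VariabilityParams(
        gcv=gcv, pcv=pcv, h2bs=h2, ga=ga, gam=gam,
        mean=mean, sed=sed, k=k, basis=basis,
    )


def variability_parameters(
    components: VarianceComponents,
    mean: float,
    k: float = DEFAULT_K,
    basis: str | None = None,
    ga_basis: str = "genotypic",
) -> VariabilityParams:
    """Variability parameters from ANOVA variance components.

    ``basis`` defaults to ``single_env`` for one-season components and
    ``plot`` for multi-season components.
    """
    if basis is None:
        basis = "single_env" if components.s == 1 else "plot"
    sigma2_p = phenotypic_variance(components, basis)
    return variability_from_variances(
        components.sigma2_g, sigma2_p, mean, k=k, ga_basis=ga_basis,
        sigma2_e=components.sigma2_e, r=components.r, basis=basis,
    )


def components_from_cv(gcv: float, pcv: float, mean: float) -> tuple[float, float]:
    """Invert printed GCV/PCV (%) and mean to (sigma2_g, sigma2_p)."""
    if mean <= 0:
        raise ValidationError("trait mean must be positive")
    return (gcv * mean / 100.0) ** 2, (pcv * mean / 100.0) ** 2


def categorize_variability(params: VariabilityParams) -> dict[str, str]:
    """Conventional low/moderate/high labels for CVs, heritability and GAM.

    GCV/PCV and GAM: <10 low, 10-20 moderate, >20 high.
    h2bs: <30 low, 30-60 moderate, >60 high.
    """

    def cv_cat(v: float) -> str:
        return "low" if v < 10 else ("moderate" if v <= 20 else "high")

    def h2_cat(v: float | None) -> str:
        if v is None:
            return "undefined"
        return "low" if v < 30 else ("moderate" if v <= 60 else "high")

    return {
        "gcv": cv_cat(params.gcv),
        "pcv": cv_cat(params.pcv),
        "h2bs": h2_cat(params.h2bs),
        "gam": cv_cat(params.gam),
    }
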