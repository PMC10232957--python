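"""Seeded generators for trial, germination and marker datasets.

The generators emulate the screening design — a randomized complete block
experiment with ``g`` genotypes, ``r`` replicates nested in ``s`` seasons —
with known ground-truth parameters, so every analysis stage can be tested
for recovery without any external data.

Trial values follow the additive ANOVA model

    y_ijk = mu + g_i + s_j + (gs)_ij + b_k(j) + e_ijk

with independent normal effects at the stated variances. Germination adds
a binomial layer: each replicate sows ``seeds_per_rep`` pre-germinated
seeds and AGP is the emerged fraction x 100, which puts pooled AGP values
on the lattice {100 k / (seeds_per_rep * r * s)}. Marker calls are i.i.d.
categorical draws at specified allele frequencies.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trial_io import MarkerDataset, TrialDataset
from .varcomp import anova_pooled
from .variability import variability_parameters


@dataclass(frozen=True)
class TrialSimParams:
    """Ground truth for one simulated trait.

    Defaults mirror the screening design (119 genotypes, 2 seasons, 3
    replicates) with variance components of the order seen for seedling
    traits in such trials.
    """

    mu: float = 50.0
    sigma2_g: float = 100.0
    sigma2_ge: float = 30.0
    sigma2_b: float = 5.0
    sigma2_e: float = 25.0
    g: int = 119
    s: int = 2
    r: int = 3
    seed: int = 0
    trait: str = "RI"  # unconstrained sign, safe for normal draws

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_ge, self.sigma2_b, self.sigma2_e) < 0:
            raise ValidationError("variances must be non-negative")
        if min(self.g, self.s, self.r) < 1:
            raise ValidationError("g, s, r must be >= 1")


@dataclass(frozen=True)
class GerminationSimParams:
    p: tuple[float, ...]         # per-genotype emergence probability
    seeds_per_rep: int = 5
    r: int = 3
    s: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 <= q <= 1.0 for q in self.p):
            raise ValidationError("emergence probabilities must be in [0,1]")


def simulate_trial(params: TrialSimParams) -> TrialDataset:
    """Draw one balanced trial dataset from the additive ANOVA model."""
    rng = np.random.default_rng(params.seed)
    g, s, r = params.g, params.s, params.r
    eff_g = rng.normal(0.0, np.sqrt(params.sigma2_g), g)
    eff_gs = rng.normal(0.0, np.sqrt(params.sigma2_ge), (g, s))
    eff_b = rng.normal(0.0, np.sqrt(params.sigma2_b), (s, r))
    eff_season = rng.normal(0.0, 1.0, s)  # fixed-effect-scale season shift
    eps = rng.normal(0.0, np.sqrt(params.sigma2_e), (g, s, r))

    y = (
        params.mu
        + eff_g[:, None, None]
        + eff_season[None, :, None]
        + eff_gs[:, :, None]
        + eff_b[None, :, :]
        + eps
    )

    genotypes = [f"G{i + 1:03d}" for i in range(g)]
    seasons = [f"S{j + 1}" for j in range(s)]
    gi, sj, rk = np.meshgrid(range(g), range(s), range(r), indexing="ij")
    df = pd.DataFrame(
        {
            "genotype": [genotypes[i] for i in gi.ravel()],
            "season": [seasons[j] for j in sj.ravel()],
            "replicate": rk.ravel() + 1,
            "treatment": "submerged",
            "trait": params.trait,
            "value": y.ravel(),
        }
    )
    return TrialDataset(df)


def simulate_germination(params: GerminationSimParams) -> pd.DataFrame:
    """Binomial emergence counts and AGP per replicate.

    Returns a frame with columns ``genotype, season, replicate, emerged,
    AGP``; use :func:`pooled_agp` for the per-genotype pooled summary.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for i, p in enumerate(params.p):
        name = f"G{i + 1:03d}"
        for j in range(params.s):
            for k in range(params.r):
                emerged = int(rng.binomial(params.seeds_per_rep, p))
                rows.append(
                    {
                        "genotype": name,
                        "season": f"S{j + 1}",
                        "replicate": k + 1,
                        "emerged": emerged,
                        "AGP": 100.0 * emerged / params.seeds_per_rep,
                    }
                )
    return pd.DataFrame(rows)


def pooled_agp(germination: pd.DataFrame) -> pd.Series:
    """Per-genotype AGP pooled over seasons and replicates."""
    return germination.groupby("genotype")["AGP"].mean()


def simulate_markers(
    freqs: Mapping[str, Sequence[float]],
    n: int,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> MarkerDataset:
    """Draw i.i.d. allele calls per genotype per locus.

    ``freqs`` maps locus name to its allele frequency vector; alleles are
    labelled ``a1, a2, ...`` in frequency-vector order (band-size classes).
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValidationError("missing_rate must be in [0,1)")
    rng = np.random.default_rng(seed)
    genotypes = [f"G{i + 1:03d}" for i in range(n)]
    data = {}
    for locus, p in freqs.items():
        p = np.asarray(p, float)
        if not np.isclose(p.sum(), 1.0):
            raise ValidationError(f"frequencies for {locus} must sum to 1")
        labels = np.array([f"a{i + 1}" for i in range(len(p))], dtype=object)
        calls = labels[rng.choice(len(p), size=n, p=p)]
        if missing_rate > 0:
            mask = rng.random(n) < missing_rate
            calls = np.where(mask, None, calls)
        data[locus] = calls
    return MarkerDataset(pd.DataFrame(data, index=genotypes))


def demo_panel(seed: int = 0) -> TrialDataset:
    """Convenience preset: a full 119 x 2 x 3 panel for end-to-end demos.

    Seedling traits are drawn from the additive model with variance
    components loosely matching the magnitudes seen in such screenings.
    """
    base = dict(g=119, s=2, r=3)
    presets = {
        "RI": TrialSimParams(mu=3.0, sigma2_g=120.0, sigma2_ge=40.0,
                             sigma2_b=4.0, sigma2_e=15.0, seed=seed,
                             trait="RI", **base),
    }
    frames = [simulate_trial(p).observations for p in presets.values()]
    # germination layer for AGP, probabilities spread over the panel
    rng = np.random.default_rng(seed + 1)
    probs = tuple(rng.uniform(0.1, 1.0, 119))
    germ = simulate_germination(
        GerminationSimParams(p=probs, r=3, s=2, seed=seed + 2)
    )
    germ_obs = germ.rename(columns={"AGP": "value"})[
        ["genotype", "season", "replicate", "value"]
    ]
    germ_obs["treatment"] = "submerged"
    germ_obs["trait"] = "AGP"
    frames.append(germ_obs)
    return TrialDataset(pd.concat(frames, ignore_index=True))


@dataclass
class RecoveryResult:
    table: pd.DataFrame
    n_sim: int


def recovery_experiment(
    params: TrialSimParams, n_sim: int, seed: int | None = None
) -> RecoveryResult:
    """Monte-Carlo bias/RMSE for variance components and downstream values.

    Simulates ``n_sim`` independent trials at ``params``, runs the pooled
    ANOVA on each, and summarizes the estimators of (sigma2_g, sigma2_ge,
    sigma2_e) plus downstream GCV and broad-sense heritability (plot
    basis). ``covered`` records whether the mean estimate falls within two
    Monte-Carlo standard errors of the truth.
    """
    if n_sim < 2:
        raise ValidationError("n_sim must be >= 2")
    if params.s < 2:
        raise ValidationError("recovery experiment uses the pooled ANOVA (s >= 2)")
    base_seed = params.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_sim)

    sigma2_p_true = params.sigma2_g + params.sigma2_ge + params.sigma2_e
    truth = {
        "sigma2_g": params.sigma2_g,
        "sigma2_ge": params.sigma2_ge,
        "sigma2_e": params.sigma2_e,
        "GCV": 100.0 * np.sqrt(params.sigma2_g) / params.mu if params.mu > 0 else np.nan,
        "h2bs": 100.0 * params.sigma2_g / sigma2_p_true if sigma2_p_true > 0 else np.nan,
    }
    draws: dict[str, list[float]] = {k: [] for k in truth}
    for sd in seeds:
        ds = simulate_trial(
            TrialSimParams(
                mu=params.mu, sigma2_g=params.sigma2_g,
                sigma2_ge=params.sigma2_ge, sigma2_b=params.sigma2_b,
                sigma2_e=params.sigma2_e, g=params.g, s=params.s,
                r=params.r, seed=int(sd), trait=params.trait,
            )
        )
        _, comps = anova_pooled(ds, params.trait)
        draws["sigma2_g"].append(comps.sigma2_g)
        draws["sigma2_ge"].append(comps.sigma2_ge)
        draws["sigma2_e"].append(comps.sigma2_e)
        if params.mu > 0:
            vp = variability_parameters(comps, mean=params.mu, basis="plot")
            draws["GCV"].append(vp.gcv)
            draws["h2bs"].append(vp.h2bs if vp.h2bs is not None else np.nan)

    rows = []
    for name, true_val in truth.items():
        est = np.asarray(draws[name], float)
        if est.size == 0 or np.isnan(true_val):
            continue
        mean = float(est.mean())
        mc_se = float(est.std(ddof=1) / np.sqrt(len(est)))
        rows.append(
            {
                "parameter": name,
                "truth": true_val,
                "mean_estimate": mean,
                "bias": mean - true_val,
                "rmse": float(np.sqrt(((est - true_val) ** 2).mean())),
                "mc_se": mc_se,
                "covered": bool(abs(mean - true_val) <= 2.0 * mc_se)
                if mc_se > 0 else mean == true_val,
            }
        )
    return RecoveryResult(pd.DataFrame(rows).set_index("parameter"), n_sim)
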