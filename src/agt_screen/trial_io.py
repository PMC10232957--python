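"""Readers, writers and validators for trial, genotype-mean and marker tables.

Three kinds of input feed the screening analysis:

* **Trial tables** — long-format replicated observations
  (genotype x season x replicate x treatment x trait x value) from a
  randomized complete block screening run under submergence and control.
* **Genotype-mean tables** — one row per genotype with the fourteen pooled
  trait means and an optional grain-type label. The packaged reference
  panel of 119 south-Indian landraces and check varieties ships in this
  format (``data/genotype_means_table4.csv``).
* **Marker score matrices** — genotype x locus allele calls scored from
  SSR/InDel band patterns, with ``-`` marking a missing call.

Genotype labels are whitespace-normalized and matched case-insensitively
across files, because hand-curated phenotype and marker sheets rarely agree
on exact capitalization.
"""

from __future__ import annotations

import csv
import importlib.resources
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import SchemaError, ValidationError
from .traits import CANONICAL_TRAITS, NON_NEGATIVE_TRAITS, PERCENT_TRAITS, TRAIT_ORDER

TRIAL_COLUMNS = ("genotype", "season", "replicate", "treatment", "trait", "value")

GRAIN_TYPES = (
    "short-bold",
    "short-slender",
    "medium-slender",
    "long-bold",
    "long-slender",
)


class Treatment(str, Enum):
    submerged = "submerged"
    control = "control"


def normalize_label(label: str) -> str:
    """Collapse internal whitespace and strip a genotype label."""
    return " ".join(str(label).split())


def _label_key(label: str) -> str:
    return normalize_label(label).casefold()


# ---------------------------------------------------------------------------
# trial observations


@dataclass(frozen=True)
class TrialObservation:
    """One plot/cup measurement."""

    genotype: str
    season: str
    replicate: int
    treatment: Treatment
    trait: str
    value: float

    def __post_init__(self) -> None:
        if self.trait not in CANONICAL_TRAITS:
            raise ValidationError(f"unknown trait code {self.trait!r}")
        if not math.isfinite(self.value):
            raise ValidationError(
                f"non-finite value for {self.genotype}/{self.trait}"
            )
        _check_range(self.trait, self.value, context=self.genotype)
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")


def _check_range(trait: str, value: float, context: str = "") -> None:
    where = f" ({context})" if context else ""
    if trait in PERCENT_TRAITS and not 0.0 <= value <= 100.0:
        raise ValidationError(f"{trait} outside [0,100]: {value}{where}")
    if trait in NON_NEGATIVE_TRAITS and value < 0:
        raise ValidationError(f"{trait} must be non-negative: {value}{where}")


class TrialDataset:
    """Long-format replicated trial data with its inferred design.

    Parameters
    ----------
    observations : pandas.DataFrame
        Columns ``genotype, season, replicate, treatment, trait, value``.
    """

    def __init__(self, observations: pd.DataFrame):
        missing = [c for c in TRIAL_COLUMNS if c not in observations.columns]
        if missing:
            raise SchemaError(f"trial table missing column(s): {', '.join(missing)}")
        df = observations.loc[:, list(TRIAL_COLUMNS)].copy()
        df["genotype"] = df["genotype"].map(normalize_label)
        df["season"] = df["season"].astype(str)
        df["replicate"] = df["replicate"].astype(int)
        df["treatment"] = df["treatment"].map(lambda t: Treatment(str(t)).value)
        df["trait"] = df["trait"].astype(str)
        df["value"] = df["value"].astype(float)

        unknown = sorted(set(df["trait"]) - set(CANONICAL_TRAITS))
        if unknown:
            raise ValidationError(f"unknown trait code(s): {', '.join(unknown)}")
        for trait, sub in df.groupby("trait"):
            if not sub["value"].map(math.isfinite).all():
                raise ValidationError(f"non-finite values for trait {trait}")
            for g, v in zip(sub["genotype"], sub["value"]):
                _check_range(trait, v, context=g)

        self.observations = df

    # -- design ------------------------------------------------------------

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.observations["genotype"].unique())

    @property
    def seasons(self) -> list[str]:
        return sorted(self.observations["season"].unique())

    @property
    def replicates(self) -> list[int]:
        return sorted(self.observations["replicate"].unique())

    @property
    def traits(self) -> list[str]:
        present = set(self.observations["trait"])
        return [t for t in TRAIT_ORDER if t in present]

    @property
    def design(self) -> tuple[int, int, int]:
        """(g genotypes, s seasons, r replicates)."""
        return (len(self.genotypes), len(self.seasons), len(self.replicates))

    def missing_cells(
        self, trait: str, treatment: str = Treatment.submerged.value
    ) -> list[tuple[str, str, int]]:
        """Genotype x season x replicate cells absent for a trait."""
        sub = self.observations[
            (self.observations["trait"] == trait)
            & (self.observations["treatment"] == treatment)
        ]
        have = set(zip(sub["genotype"], sub["season"], sub["replicate"]))
        return [
            (g, s, r)
            for g in self.genotypes
            for s in self.seasons
            for r in self.replicates
            if (g, s, r) not in have
        ]

    def cell_matrix(
        self,
        trait: str,
        season: str | None = None,
        treatment: str = Treatment.submerged.value,
    ) -> pd.DataFrame:
        """Pivot a trait to a genotype x (season, replicate) value matrix."""
        sub = self.observations[
            (self.observations["trait"] == trait)
            & (self.observations["treatment"] == treatment)
        ]
        if season is not None:
            sub = sub[sub["season"] == season]
            return sub.pivot_table(
                index="genotype", columns="replicate", values="value",
                aggfunc="mean",
            )
        return sub.pivot_table(
            index="genotype", columns=["season", "replicate"], values="value",
            aggfunc="mean",
        )

    def __len__(self) -> int:
        return len(self.observations)

    def __eq__(self, other) -> bool:  # round-trip testing convenience
        if not isinstance(other, TrialDataset):
            return NotImplemented
        a = self.observations.sort_values(list(TRIAL_COLUMNS)).reset_index(drop=True)
        b = other.observations.sort_values(list(TRIAL_COLUMNS)).reset_index(drop=True)
        return a.equals(b)


def read_trial_table(path: str | Path, dialect: str | None = None) -> TrialDataset:
    """Read a long-format trial table (CSV/TSV, delimiter auto-detected).

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        For non-numeric values (with the line number) or range violations.
    """
    path = Path(path)
    sep = dialect if dialect is not None else _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except ValueError as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    bad = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValidationError(f"{path.name}: non-numeric value at line {line}")
    df["value"] = pd.to_numeric(df["value"])
    return TrialDataset(df)


def write_trial_table(dataset: TrialDataset, path: str | Path, sep: str = ",") -> None:
    # %.17g guarantees a lossless float64 round-trip
    dataset.observations.to_csv(path, sep=sep, index=False, float_format="%.17g")


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


# ---------------------------------------------------------------------------
# genotype means


@dataclass(frozen=True)
class GenotypeRecord:
    """Pooled per-genotype trait means plus an optional grain-type label."""

    genotype: str
    trait_means: Mapping[str, float]
    grain_type: str | None = None

    def __post_init__(self) -> None:
        if self.grain_type is not None and self.grain_type not in GRAIN_TYPES:
            raise ValidationError(
                f"{self.genotype}: unknown grain type {self.grain_type!r}"
            )

    def complete(self) -> bool:
        return all(t in self.trait_means for t in TRAIT_ORDER)


def read_genotype_means(path: str | Path) -> list[GenotypeRecord]:
    """Read a genotype-mean table (genotype + 14 traits + optional grain_type)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    if "genotype" not in df.columns:
        raise SchemaError(f"{path.name}: missing required column: genotype")
    missing = [t for t in TRAIT_ORDER if t not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing trait column(s): {', '.join(missing)}"
        )
    df["genotype"] = df["genotype"].map(normalize_label)
    keys = df["genotype"].map(_label_key)
    dup = keys[keys.duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate genotype label(s): {', '.join(dup)}")

    records = []
    for _, row in df.iterrows():
        means = {}
        for t in TRAIT_ORDER:
            v = row[t]
            if pd.isna(v):
                raise ValidationError(
                    f"missing value for genotype {row['genotype']!r}, trait {t}"
                )
            v = float(v)
            _check_range(t, v, context=row["genotype"])
            means[t] = v
        gt = None
        if "grain_type" in df.columns and not pd.isna(row.get("grain_type")):
            gt = str(row["grain_type"]).strip().lower().replace(" ", "-")
        records.append(GenotypeRecord(row["genotype"], means, gt))
    return records


def records_to_frame(records: Iterable[GenotypeRecord]) -> pd.DataFrame:
    """Genotype-indexed DataFrame of trait means (+ grain_type if present)."""
    rows = []
    for rec in records:
        row = {"genotype": rec.genotype, **{t: rec.trait_means.get(t) for t in TRAIT_ORDER}}
        row["grain_type"] = rec.grain_type
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("genotype")
    if frame["grain_type"].isna().all():
        frame = frame.drop(columns="grain_type")
    return frame


def load_reference_panel() -> pd.DataFrame:
    """Load the packaged 119-genotype reference panel of pooled trait means.

    Returns a genotype-indexed DataFrame with the fourteen trait columns and
    the published grain-type label for every landrace and check variety.
    """
    resource = importlib.resources.files("agt_screen.data").joinpath(
        "genotype_means_table4.csv"
    )
    with importlib.resources.as_file(resource) as fp:
        return records_to_frame(read_genotype_means(fp))


# ---------------------------------------------------------------------------
# marker scores


@dataclass
class MarkerDataset:
    """Genotype x locus allele-call matrix with per-locus allele inventories.

    ``calls`` holds allele identifiers (band-size classes) as strings, with
    ``None``/NaN for missing. One call per genotype per locus: the panel is
    inbred landraces scored from band presence, so heterozygotes are not
    represented.
    """

    calls: pd.DataFrame
    loci: list[dict] = field(default_factory=list)

    MISSING = "-"

    def __post_init__(self) -> None:
        self.calls = self.calls.copy()
        self.calls.index = [normalize_label(g) for g in self.calls.index]
        self.calls = self.calls.where(self.calls.notna(), None)
        self.calls = self.calls.replace({self.MISSING: None, "": None})
        if not self.loci:
            self.loci = [{"locus": c, "type": "SSR", "chromosome": None}
                         for c in self.calls.columns]

    @property
    def genotypes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def locus_names(self) -> list[str]:
        return list(self.calls.columns)

    def alleles(self, locus: str) -> list[str]:
        """Sorted allele inventory over non-missing calls."""
        col = self.calls[locus]
        return sorted({str(v) for v in col if v is not None})

    def missing_fraction(self, locus: str) -> float:
        col = self.calls[locus]
        return float(sum(v is None for v in col)) / len(col)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkerDataset):
            return NotImplemented
        return self.calls.equals(other.calls)


def read_marker_scores(path: str | Path) -> MarkerDataset:
    """Read a marker score matrix: first column genotype, remaining loci.

    Cells are allele labels; ``-`` or blank marks a missing call. A locus
    with no scored call at all is kept but flagged with a warning
    (monomorphic-undetermined).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    first = df.columns[0]
    df = df.set_index(first)
    ds = MarkerDataset(df)
    for locus in ds.locus_names:
        if ds.missing_fraction(locus) == 1.0:
            warnings.warn(
                f"locus {locus} has no scored calls (monomorphic-undetermined)",
                stacklevel=2,
            )
    return ds


def write_marker_scores(dataset: MarkerDataset, path: str | Path) -> None:
    out = dataset.calls.fillna(MarkerDataset.MISSING)
    out.index.name = "genotype"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# validation report


@dataclass
class ValidationReport:
    """Report-only summary of balance gaps, range violations and coverage."""

    passed: bool
    issues: list[str]
    trait_coverage: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "issues": list(self.issues),
            "trait_coverage": dict(self.trait_coverage),
        }


def validate_dataset(dataset: TrialDataset) -> ValidationReport:
    """Check a trial dataset for balance and per-trait coverage.

    Range violations are enforced at construction, so the report focuses on
    design balance: every genotype x season x replicate cell should be
    present for every trait/treatment combination observed.
    """
    issues: list[str] = []
    coverage: dict[str, int] = {}
    for trait in dataset.traits:
        sub = dataset.observations[dataset.observations["trait"] == trait]
        coverage[trait] = int(sub["genotype"].nunique())
        for treatment in sorted(sub["treatment"].unique()):
            for g, s, r in dataset.missing_cells(trait, treatment):
                issues.append(
                    f"missing cell: trait={trait} treatment={treatment} "
                    f"genotype={g} season={s} replicate={r}"
                )
    g, s, r = dataset.design
    if g < 2:
        issues.append("fewer than 2 genotypes: ANOVA not possible")
    if r < 2:
        issues.append("fewer than 2 replicates: error MS not estimable")
    return ValidationReport(passed=not issues, issues=issues, trait_coverage=coverage)
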