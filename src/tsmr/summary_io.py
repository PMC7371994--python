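"""GWAS summary-statistic data model and delimited-table I/O.

This module defines the two core containers used throughout the package —
:class:`SnpAssociation` (one SNP's association statistics in one GWAS) and
:class:`SummaryDataset` (an ordered, rsID-keyed collection of them) — plus
effect-size conversions from odds-ratio scale and readers/writers for
delimited summary tables with a configurable column mapping.

Packaged fixture tables (four stroke phenotypes paired with an Alzheimer's
disease outcome, and a SNP x trait p-value matrix) are exposed through
:func:`load_fixture` so the full pipeline can run without any download.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
from scipy import stats

__all__ = [
    "NUCLEOTIDES",
    "DEFAULT_SCHEMA",
    "SummaryDataError",
    "DuplicateSnpError",
    "SnpAssociation",
    "SummaryDataset",
    "beta_from_or",
    "se_from_ci",
    "read_summary_table",
    "write_summary_table",
    "load_fixture",
    "FIXTURE_PHENOTYPES",
]

NUCLEOTIDES = frozenset("ACGT")

#: Default column mapping (attribute name -> column header) for summary tables.
DEFAULT_SCHEMA: dict[str, str] = {
    "snp_id": "snp",
    "chrom": "chr",
    "nearby_gene": "gene",
    "effect_allele": "ea",
    "other_allele": "nea",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
}

REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue")

FIXTURE_PHENOTYPES = ("AS", "AIS", "LAS", "CES")

# GWAS cohort sizes attached to the packaged fixtures (stroke exposure
# meta-analysis and the AD stage-1 outcome meta-analysis).
_FIXTURE_SIZES = {
    "exposure": dict(n_total=521_612, n_cases=67_162, n_controls=454_450),
    "outcome": dict(n_total=54_162, n_cases=17_008, n_controls=37_154),
}


class SummaryDataError(ValueError):
    """Malformed summary-statistic input."""


class DuplicateSnpError(SummaryDataError):
    """Two records share one rsID within a dataset."""


def beta_from_or(or_value: float) -> float:
    """Convert an odds ratio to a log-odds effect size, ``ln(OR)``.

    Raises
    ------
    ValueError
        If ``or_value`` is not strictly positive.
    """
    if not or_value > 0:
        raise ValueError(f"odds ratio must be > 0, got {or_value!r}")
    return math.log(or_value)


def se_from_ci(ci_lower: float, ci_upper: float) -> float:
    """Standard error of a log-odds beta from a 95% CI on the OR scale.

    Computes ``(ln(ci_upper) - ln(ci_lower)) / (2 * 1.96)``.  The result
    depends only on the ratio of the bounds and is 0 for a degenerate CI.
    """
    if not ci_lower > 0:
        raise ValueError(f"CI bounds must be > 0, got lower={ci_lower!r}")
    if ci_upper < ci_lower:
        raise ValueError(f"inverted CI: ({ci_lower!r}, {ci_upper!r})")
    return (math.log(ci_upper) - math.log(ci_lower)) / (2.0 * 1.96)


def _parse_float(raw) -> float | None:
    """Parse a possibly dash-glyph-polluted numeric cell; None for NA."""
    if raw is None:
        return None
    if isinstance(raw, float):
        return None if math.isnan(raw) else raw
    text = str(raw).strip()
    if text == "" or text.upper() in {"NA", "NAN", "NONE", "."}:
        return None
    # Published tables mix ASCII hyphens with en dashes and minus signs.
    for dash in ("–", "−", "—"):
        text = text.replace(dash, "-")
    return float(text)


@dataclass
class SnpAssociation:
    """Summary statistics for one SNP in one GWAS.

    ``beta`` is the additive per-allele log-odds effect of ``effect_allele``
    relative to ``other_allele``; ``se`` its standard error; ``pvalue`` the
    two-sided association p-value.  ``eaf`` and ``nearby_gene`` are optional.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    eaf: float | None = None
    nearby_gene: str | None = None

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        if self.effect_allele not in NUCLEOTIDES:
            raise SummaryDataError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} is not one of A/C/G/T"
            )
        if self.other_allele not in NUCLEOTIDES:
            raise SummaryDataError(
                f"{self.snp_id}: other allele {self.other_allele!r} is not one of A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise SummaryDataError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise SummaryDataError(f"{self.snp_id}: se must be > 0, got {self.se!r}")
        if not 0 < self.pvalue <= 1:
            raise SummaryDataError(f"{self.snp_id}: pvalue must be in (0, 1], got {self.pvalue!r}")
        if self.eaf is not None and not 0 <= self.eaf <= 1:
            raise SummaryDataError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf!r}")
        self._check_pvalue_consistency()

    def _check_pvalue_consistency(self) -> None:
        # Warn-only: printed p-values come from meta-analysis machinery and
        # rounded betas, so only flag gross |z| disagreement (> 1 unit).
        z_implied = abs(self.beta) / self.se
        if self.pvalue < 1e-300 or z_implied > 37:
            return  # two-sided normal p underflows; nothing to compare
        z_printed = stats.norm.isf(self.pvalue / 2.0)
        if abs(z_implied - z_printed) > 1.0:
            warnings.warn(
                f"{self.snp_id}: p-value {self.pvalue:g} implies |z|≈{z_printed:.2f} "
                f"but beta/se gives {z_implied:.2f}",
                stacklevel=3,
            )


@dataclass
class SummaryDataset:
    """Ordered collection of :class:`SnpAssociation`, keyed by rsID."""

    trait_label: str
    records: dict[str, SnpAssociation] = field(default_factory=dict)
    n_total: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        for key, rec in self.records.items():
            if key != rec.snp_id:
                raise SummaryDataError(f"record keyed {key!r} has snp_id {rec.snp_id!r}")
        if (
            self.n_total is not None
            and self.n_cases is not None
            and self.n_controls is not None
            and self.n_cases + self.n_controls != self.n_total
        ):
            raise SummaryDataError(
                f"{self.trait_label}: n_cases + n_controls "
                f"({self.n_cases} + {self.n_controls}) != n_total ({self.n_total})"
            )

    def add(self, record: SnpAssociation) -> None:
        if record.snp_id in self.records:
            raise DuplicateSnpError(f"duplicate rsID {record.snp_id!r} in {self.trait_label!r}")
        self.records[record.snp_id] = record

    @property
    def snp_ids(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpAssociation]:
        return iter(self.records.values())

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.records

    def __getitem__(self, snp_id: str) -> SnpAssociation:
        return self.records[snp_id]

    def to_frame(self, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
        schema = dict(schema or DEFAULT_SCHEMA)
        rows = []
        for rec in self:
            row = {}
            for attr, col in schema.items():
                row[col] = getattr(rec, attr)
            rows.append(row)
        return pd.DataFrame(rows, columns=list(schema.values()))


def read_summary_table(
    path,
    schema: Mapping[str, str] | None = None,
    trait_label: str = "",
    delimiter: str = "\t",
    **dataset_kwargs,
) -> SummaryDataset:
    """Read a delimited summary-statistics table into a :class:`SummaryDataset`.

    ``schema`` maps :class:`SnpAssociation` attribute names to column headers
    (defaults to :data:`DEFAULT_SCHEMA`); optional attributes whose columns are
    absent are simply left unset.  Rows with unparseable required fields are
    rejected collectively, reporting their 1-based data row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = dict(schema or DEFAULT_SCHEMA)
    frame = pd.read_csv(path, sep=delimiter, dtype=str)
    for attr in REQUIRED_FIELDS:
        col = schema.get(attr)
        if col is None or col not in frame.columns:
            raise SummaryDataError(f"{path}: required column {col!r} (field {attr!r}) missing")

    dataset = SummaryDataset(trait_label=trait_label or path.stem, **dataset_kwargs)
    bad_rows: list[tuple[int, str]] = []
    for idx, row in frame.iterrows():
        kwargs = {}
        for attr, col in schema.items():
            if col not in frame.columns:
                continue
            raw = row[col]
            if attr in ("snp_id", "chrom", "effect_allele", "other_allele", "nearby_gene"):
                value = None if pd.isna(raw) else str(raw).strip()
                if value == "":
                    value = None
            else:
                try:
                    value = _parse_float(raw)
                except ValueError:
                    bad_rows.append((idx + 1, f"unparseable {col}={raw!r}"))
                    value = None
            if value is not None:
                kwargs[attr] = value
        missing = [f for f in REQUIRED_FIELDS if f not in kwargs]
        if missing:
            bad_rows.append((idx + 1, f"missing required field(s) {missing}"))
            continue
        try:
            dataset.add(SnpAssociation(**kwargs))
        except DuplicateSnpError:
            raise
        except SummaryDataError as exc:
            bad_rows.append((idx + 1, str(exc)))
    if bad_rows:
        detail = "; ".join(f"row {n}: {msg}" for n, msg in bad_rows)
        raise SummaryDataError(f"{path}: rejected {len(bad_rows)} row(s): {detail}")
    return dataset


def write_summary_table(
    dataset: SummaryDataset,
    path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> None:
    """Write a dataset back to a delimited table (inverse of the reader)."""
    frame = dataset.to_frame(schema)
    frame.to_csv(path, sep=delimiter, index=False)


def _fixture_path(filename: str) -> Path:
    return Path(str(resources.files("tsmr").joinpath("fixtures", filename)))


def load_fixture(name: str, role: str | None = None):
    """Load a packaged fixture.

    ``load_fixture(phenotype, role)`` with phenotype in ``AS/AIS/LAS/CES`` and
    role ``"exposure"`` or ``"outcome"`` returns a :class:`SummaryDataset`
    transcribed digit-for-digit from the published instrument tables.
    ``load_fixture("pleiotropy_matrix")`` returns a SNP x trait p-value
    :class:`pandas.DataFrame` (rsID index; NaN where no lookup was available).
    """
    if name == "pleiotropy_matrix":
        frame = pd.read_csv(_fixture_path("pleiotropy_matrix.tsv"), sep="\t", index_col="snp")
        return frame
    phenotype = name.upper()
    if phenotype not in FIXTURE_PHENOTYPES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_PHENOTYPES} or 'pleiotropy_matrix'")
    if role not in ("exposure", "outcome"):
        raise KeyError(f"fixture role must be 'exposure' or 'outcome', got {role!r}")
    path = _fixture_path(f"{phenotype.lower()}_{role}.tsv")
    label = phenotype if role == "exposure" else "AD"
    return read_summary_table(path, trait_label=label, **_FIXTURE_SIZES[role])
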