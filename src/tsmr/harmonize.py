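"""Instrument selection and exposure/outcome allele harmonization.

Aligns two summary datasets on shared instruments, resolves allele
orientation (including strand-complement records), applies the selection
rules of a two-sample MR analysis — genome-wide significance on the exposure
side, exclusion of outcome-associated SNPs, proxy substitution, palindromic
ambiguity handling — and records the reason for every dropped SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .summary_io import NUCLEOTIDES, SnpAssociation, SummaryDataset

__all__ = [
    "COMPLEMENT",
    "HarmonizationError",
    "NoInstrumentsError",
    "HarmonizedInstrument",
    "SelectionRules",
    "is_palindromic",
    "align_alleles",
    "select_instruments",
    "write_drop_log",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class HarmonizationError(ValueError):
    """Raised when an exposure/outcome record pair cannot be aligned."""

    def __init__(self, message: str, reason: str = "allele_mismatch") -> None:
        super().__init__(message)
        self.reason = reason


class NoInstrumentsError(ValueError):
    """Selection left no usable instrument ("no_instruments")."""


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the unordered allele pair is {A,T} or {C,G}."""
    ea, oa = str(effect_allele).upper(), str(other_allele).upper()
    if ea not in NUCLEOTIDES or oa not in NUCLEOTIDES:
        raise ValueError(f"alleles must be single nucleotides, got {effect_allele!r}/{other_allele!r}")
    return COMPLEMENT[ea] == oa


@dataclass
class HarmonizedInstrument:
    """An exposure/outcome pair for one SNP after allele alignment."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    pval_exp: float | None = None
    pval_out: float | None = None
    eaf_exp: float | None = None
    eaf_out: float | None = None
    flipped: bool = False
    palindromic: bool = False
    proxy_of: str | None = None

    def __post_init__(self) -> None:
        if not self.se_exp > 0:
            raise ValueError(f"{self.snp_id}: se_exp must be > 0")
        if not self.se_out > 0:
            raise ValueError(f"{self.snp_id}: se_out must be > 0")


@dataclass
class SelectionRules:
    """Thresholds and explicit lists governing instrument selection.

    ``explicit_exclusions`` maps rsID -> reason string; ``proxy_map`` maps an
    exposure rsID to the outcome-dataset rsID whose statistics stand in for
    it.  ``palindromic_exclusions`` lists SNPs dropped as palindromic when
    ``drop_palindromic`` is on regardless of frequency.
    """

    exposure_p_max: float = 5e-8
    outcome_p_min: float = 0.05
    drop_palindromic: bool = False
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58)
    explicit_exclusions: dict[str, str] = field(default_factory=dict)
    palindromic_exclusions: tuple[str, ...] = ()
    proxy_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.exposure_p_max < self.outcome_p_min <= 1:
            raise ValueError(
                "require 0 < exposure_p_max < outcome_p_min <= 1, got "
                f"{self.exposure_p_max!r}, {self.outcome_p_min!r}"
            )
        lo, hi = self.palindromic_eaf_window
        if not (0 <= lo <= hi <= 1):
            raise ValueError(f"palindromic_eaf_window must lie in [0, 1]: ({lo}, {hi})")
        if abs((lo + hi) / 2.0 - 0.5) > 1e-9:
            raise ValueError(f"palindromic_eaf_window must be symmetric about 0.5: ({lo}, {hi})")
        self.palindromic_exclusions = tuple(self.palindromic_exclusions)

    def to_dict(self) -> dict:
        return {
            "exposure_p_max": self.exposure_p_max,
            "outcome_p_min": self.outcome_p_min,
            "drop_palindromic": self.drop_palindromic,
            "palindromic_eaf_window": list(self.palindromic_eaf_window),
            "explicit_exclusions": dict(self.explicit_exclusions),
            "palindromic_exclusions": list(self.palindromic_exclusions),
            "proxy_map": dict(self.proxy_map),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SelectionRules":
        data = dict(data)
        if "palindromic_eaf_window" in data:
            data["palindromic_eaf_window"] = tuple(data["palindromic_eaf_window"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SelectionRules":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _complemented(record: SnpAssociation) -> SnpAssociation:
    return replace(
        record,
        effect_allele=COMPLEMENT[record.effect_allele],
        other_allele=COMPLEMENT[record.other_allele],
    )


def align_alleles(
    exposure: SnpAssociation,
    outcome: SnpAssociation,
    proxy_of: str | None = None,
) -> HarmonizedInstrument:
    """Orient an outcome record onto the exposure record's effect allele.

    Same orientation passes effects through; swapped alleles negate the
    outcome beta (and reflect its EAF); strand-complement pairs are
    complemented first, but only when the pair is non-palindromic, since a
    complemented palindromic pair is indistinguishable from a swap.
    """
    ea, oa = exposure.effect_allele, exposure.other_allele
    out = outcome
    palindromic = is_palindromic(ea, oa)
    if {out.effect_allele, out.other_allele} != {ea, oa}:
        if not palindromic and {COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele]} == {ea, oa}:
            out = _complemented(out)
        else:
            raise HarmonizationError(
                f"{exposure.snp_id}: outcome alleles {outcome.effect_allele}/"
                f"{outcome.other_allele} incompatible with exposure {ea}/{oa}",
                reason="allele_mismatch",
            )
    if (out.effect_allele, out.other_allele) == (ea, oa):
        beta_out, eaf_out, flipped = out.beta, out.eaf, False
    elif (out.effect_allele, out.other_allele) == (oa, ea):
        beta_out = -out.beta
        eaf_out = None if out.eaf is None else 1.0 - out.eaf
        flipped = True
    else:  # pragma: no cover - excluded by the set comparison above
        raise HarmonizationError(f"{exposure.snp_id}: unexpected allele state")
    return HarmonizedInstrument(
        snp_id=outcome.snp_id if proxy_of else exposure.snp_id,
        beta_exp=exposure.beta,
        se_exp=exposure.se,
        beta_out=beta_out,
        se_out=out.se,
        pval_exp=exposure.pvalue,
        pval_out=out.pvalue,
        eaf_exp=exposure.eaf,
        eaf_out=eaf_out,
        flipped=flipped,
        palindromic=palindromic,
        proxy_of=proxy_of,
    )


def _eaf_ambiguous(eaf: float | None, window: tuple[float, float]) -> bool:
    # Missing EAF cannot rule out intermediate frequency -> ambiguous.
    return eaf is None or window[0] <= eaf <= window[1]


def select_instruments(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    rules: SelectionRules | None = None,
) -> tuple[list[HarmonizedInstrument], list[tuple[str, str]]]:
    """Apply the selection pipeline and harmonize the survivors.

    Fixed stage order: exposure significance (strict ``p < exposure_p_max``),
    proxy substitution, missing-in-outcome, outcome association
    (``p < outcome_p_min``), explicit exclusions, palindromic ambiguity
    (only when ``drop_palindromic``), allele alignment.  Returns the kept
    instruments in exposure order and a ``(snp_id, reason)`` drop log.
    """
    rules = rules or SelectionRules()
    kept: list[HarmonizedInstrument] = []
    dropped: list[tuple[str, str]] = []
    for rec in exposure:
        if not rec.pvalue < rules.exposure_p_max:
            dropped.append((rec.snp_id, "exposure_not_significant"))
            continue
        out_id = rules.proxy_map.get(rec.snp_id, rec.snp_id)
        if out_id not in outcome:
            dropped.append((rec.snp_id, "missing_in_outcome"))
            continue
        out = outcome[out_id]
        if out.pvalue < rules.outcome_p_min:
            dropped.append((rec.snp_id, "outcome_associated"))
            continue
        if rec.snp_id in rules.explicit_exclusions:
            dropped.append((rec.snp_id, rules.explicit_exclusions[rec.snp_id] or "explicit_exclusion"))
            continue
        if rules.drop_palindromic and is_palindromic(rec.effect_allele, rec.other_allele):
            ambiguous = (
                rec.snp_id in rules.palindromic_exclusions
                or _eaf_ambiguous(rec.eaf, rules.palindromic_eaf_window)
                or _eaf_ambiguous(out.eaf, rules.palindromic_eaf_window)
            )
            if ambiguous:
                dropped.append((rec.snp_id, "palindromic_ambiguous"))
                continue
        try:
            inst = align_alleles(rec, out, proxy_of=rec.snp_id if out_id != rec.snp_id else None)
        except HarmonizationError as exc:
            dropped.append((rec.snp_id, exc.reason))
            continue
        kept.append(inst)
    if not kept:
        raise NoInstrumentsError("no_instruments")
    return kept, dropped


def write_drop_log(dropped: Iterable[tuple[str, str]], path) -> None:
    lines = ["snp_id\treason"]
    lines += [f"{snp}\t{reason}" for snp, reason in dropped]
    Path(path).write_text("\n".join(lines) + "\n")
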