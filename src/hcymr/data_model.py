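"""Domain types, summary-statistics I/O, harmonization and instrument selection.

Two-sample Mendelian randomization works from per-variant GWAS summary
statistics: for each candidate instrument (a SNP), an effect estimate on the
exposure from one study and an effect estimate on the outcome from another.
This module defines the containers those numbers travel in, reads them from
delimited text tables, aligns exposure and outcome effects to a shared effect
allele, and applies the standard instrument-qualification filters
(genome-wide significance, LD pruning against a caller-supplied r-squared
table, and removal of variants annotated as pleiotropic).

The package never queries reference panels or annotation servers: LD and
pleiotropy information enter as plain tables supplied by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "HarmonizedInstrument",
    "InstrumentSet",
    "SelectionConfig",
    "SummaryStatsError",
    "HarmonizationError",
    "SelectionError",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
    "f_statistic",
    "select_instruments",
    "instrument_set_to_tables",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: standard column names; a column map translates file headers onto these
STANDARD_COLUMNS = ("variant_id", "effect_allele", "beta", "se",
                    "p_value", "chromosome", "nearby_gene")
REQUIRED_COLUMNS = ("variant_id", "effect_allele", "beta", "se")


class SummaryStatsError(ValueError):
    """A summary-statistics table could not be read or failed validation."""


class HarmonizationError(ValueError):
    """Exposure and outcome associations could not be aligned."""


class SelectionError(ValueError):
    """Instrument selection received inconsistent inputs."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's effect estimate in one GWAS.

    ``beta`` is the per-allele effect of ``effect_allele``: SD units of the
    exposure for a continuous trait, log-odds for a binary outcome.
    """

    variant_id: str
    effect_allele: str
    beta: float
    se: float
    p_value: float | None = None
    chromosome: str | None = None
    nearby_gene: str | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise SummaryStatsError(
                f"{self.variant_id}: effect allele {self.effect_allele!r} "
                "is not a single nucleotide (A/C/G/T)")
        if not math.isfinite(self.beta):
            raise SummaryStatsError(f"{self.variant_id}: beta is not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise SummaryStatsError(
                f"{self.variant_id}: se must be finite and > 0, got {self.se}")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise SummaryStatsError(
                f"{self.variant_id}: p-value {self.p_value} outside (0, 1]")


def f_statistic(beta_exposure: float, se_exposure: float) -> float:
    """Instrument-strength F statistic, the squared z-score (beta/se)^2.

    F below 10 is the conventional weak-instrument warning threshold.
    """
    if se_exposure <= 0:
        raise ValueError("se_exposure must be > 0")
    return (beta_exposure / se_exposure) ** 2


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects for one variant, on a shared effect allele."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    f_statistic: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise HarmonizationError(
                f"{self.variant_id}: standard errors must be > 0")
        if math.isnan(self.f_statistic):
            object.__setattr__(
                self, "f_statistic",
                f_statistic(self.beta_exposure, self.se_exposure))


@dataclass(frozen=True)
class InstrumentSet:
    """An ordered set of harmonized instruments for one outcome cohort.

    Sample sizes are optional; they are only needed by the Steiger
    directionality test (``n_exposure`` plus case/control counts).
    """

    label: str
    instruments: tuple[HarmonizedInstrument, ...]
    n_exposure: int | None = None
    n_outcome_cases: int | None = None
    n_outcome_controls: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "instruments", tuple(self.instruments))
        if len(self.instruments) == 0:
            raise HarmonizationError(f"{self.label}: empty instrument set")
        ids = [inst.variant_id for inst in self.instruments]
        if len(set(ids)) != len(ids):
            raise HarmonizationError(f"{self.label}: duplicate variant ids")
        for n in (self.n_exposure, self.n_outcome_cases, self.n_outcome_controls):
            if n is not None and n <= 0:
                raise HarmonizationError(f"{self.label}: sample sizes must be positive")

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self) -> Iterator[HarmonizedInstrument]:
        return iter(self.instruments)

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(inst.variant_id for inst in self.instruments)

    @property
    def beta_exposure(self) -> np.ndarray:
        return np.array([inst.beta_exposure for inst in self.instruments])

    @property
    def se_exposure(self) -> np.ndarray:
        return np.array([inst.se_exposure for inst in self.instruments])

    @property
    def beta_outcome(self) -> np.ndarray:
        return np.array([inst.beta_outcome for inst in self.instruments])

    @property
    def se_outcome(self) -> np.ndarray:
        return np.array([inst.se_outcome for inst in self.instruments])

    @property
    def f_statistics(self) -> np.ndarray:
        return np.array([inst.f_statistic for inst in self.instruments])

    def without(self, variant_id: str) -> "InstrumentSet":
        """A copy excluding one variant."""
        kept = tuple(i for i in self.instruments if i.variant_id != variant_id)
        if len(kept) == len(self.instruments):
            raise KeyError(variant_id)
        return replace(self, instruments=kept)

    def subset(self, variant_ids: Iterable[str]) -> "InstrumentSet":
        wanted = set(variant_ids)
        kept = tuple(i for i in self.instruments if i.variant_id in wanted)
        return replace(self, instruments=kept)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for instrument qualification.

    Defaults follow common MR practice: genome-wide significance 5e-8 for
    the variant-exposure association, LD pruning at r^2 >= 0.05, and proxy
    substitution only at r^2 > 0.8.  ``excluded_variants`` maps variant ids
    to a free-text reason (e.g. a pleiotropy annotation from a manual
    screen) and is applied unconditionally.
    """

    gwas_p_threshold: float = 5e-8
    ld_r2_threshold: float = 0.05
    proxy_r2_threshold: float = 0.8
    excluded_variants: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("gwas_p_threshold", "ld_r2_threshold", "proxy_r2_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise SelectionError(f"{name} must lie in (0, 1), got {v}")


# ---------------------------------------------------------------------------
# I/O

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
) -> list[VariantAssociation]:
    """Read a delimited summary-statistics table into VariantAssociation records.

    ``column_map`` maps standard names (``variant_id``, ``effect_allele``,
    ``beta``, ``se``, optionally ``p_value``, ``chromosome``,
    ``nearby_gene``) onto the file's column headers.  Standard names already
    present in the file need no mapping.  Rows with missing beta or se are
    rejected with an error naming the offending row, never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise SummaryStatsError(f"summary-statistics file not found: {path}")
    sep = delimiter if delimiter is not None else _sep_for(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str})

    column_map = dict(column_map or {})
    resolved: dict[str, str] = {}
    for std in STANDARD_COLUMNS:
        col = column_map.get(std, std)
        if col in df.columns:
            resolved[std] = col
    missing = [c for c in REQUIRED_COLUMNS if c not in resolved]
    if missing:
        raise SummaryStatsError(
            f"{path}: required column(s) {missing} not found "
            f"(file has {list(df.columns)})")

    records: list[VariantAssociation] = []
    for idx, row in df.iterrows():
        vid = str(row[resolved["variant_id"]])
        beta = row[resolved["beta"]]
        se = row[resolved["se"]]
        if pd.isna(beta) or pd.isna(se):
            raise SummaryStatsError(
                f"{path}: row {idx} ({vid}): missing beta or se")
        try:
            beta = float(beta)
            se = float(se)
        except (TypeError, ValueError) as exc:
            raise SummaryStatsError(
                f"{path}: row {idx} ({vid}): non-numeric beta/se") from exc
        pval = None
        if "p_value" in resolved and not pd.isna(row[resolved["p_value"]]):
            pval = float(row[resolved["p_value"]])
        try:
            records.append(VariantAssociation(
                variant_id=vid,
                effect_allele=str(row[resolved["effect_allele"]]).upper(),
                beta=beta,
                se=se,
                p_value=pval,
                chromosome=(str(row[resolved["chromosome"]])
                            if "chromosome" in resolved
                            and not pd.isna(row[resolved["chromosome"]]) else None),
                nearby_gene=(str(row[resolved["nearby_gene"]])
                             if "nearby_gene" in resolved
                             and not pd.isna(row[resolved["nearby_gene"]]) else None),
            ))
        except SummaryStatsError as exc:
            raise SummaryStatsError(f"{path}: row {idx}: {exc}") from exc
    return records


def write_summary_stats(records: Sequence[VariantAssociation],
                        path: str | Path,
                        *, delimiter: str | None = None) -> None:
    """Write records in the same delimited layout ``read_summary_stats`` reads."""
    path = Path(path)
    sep = delimiter if delimiter is not None else _sep_for(path)
    df = pd.DataFrame({
        "variant_id": [r.variant_id for r in records],
        "chromosome": [r.chromosome for r in records],
        "nearby_gene": [r.nearby_gene for r in records],
        "effect_allele": [r.effect_allele for r in records],
        "beta": [r.beta for r in records],
        "se": [r.se for r in records],
        "p_value": [r.p_value for r in records],
    })
    df.to_csv(path, sep=sep, index=False)


def instrument_set_to_tables(iset: InstrumentSet,
                             effect_allele: str = "A",
                             ) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """Decompose a harmonized set back into exposure and outcome association lists.

    Both sides carry the same effect allele, so re-harmonizing the result is
    a no-op (harmonization is idempotent).
    """
    exposure = [VariantAssociation(i.variant_id, effect_allele,
                                   i.beta_exposure, i.se_exposure)
                for i in iset]
    outcome = [VariantAssociation(i.variant_id, effect_allele,
                                  i.beta_outcome, i.se_outcome)
               for i in iset]
    return exposure, outcome


# ---------------------------------------------------------------------------
# Harmonization

def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    *,
    label: str = "",
    n_exposure: int | None = None,
    n_outcome_cases: int | None = None,
    n_outcome_controls: int | None = None,
    assume_same_strand: bool = False,
) -> tuple[InstrumentSet, list[str]]:
    """Align exposure and outcome effects to the exposure's effect allele.

    Matching is by variant id.  If the outcome reports the same allele the
    outcome beta is kept as-is; if it reports a different, non-complementary
    allele it is taken to be the other allele and the outcome beta's sign is
    flipped.  A complementary allele is ambiguous without strand
    information — it may be the same allele read off the opposite strand or
    the other allele — so such variants are excluded by default
    (``AMBIGUOUS_STRAND``); with ``assume_same_strand=True`` the complement
    is treated as the other allele and sign-flipped.  Variants absent from
    the outcome study are dropped (``MISSING_IN_OUTCOME``).

    Returns the instrument set plus an audit log with one line per dropped
    variant.
    """
    outcome_by_id = {v.variant_id: v for v in outcome}
    if len(outcome_by_id) != len(outcome):
        raise HarmonizationError("duplicate variant ids in outcome collection")
    seen: set[str] = set()
    instruments: list[HarmonizedInstrument] = []
    audit: list[str] = []
    for exp in exposure:
        if exp.variant_id in seen:
            raise HarmonizationError(
                f"duplicate variant id in exposure collection: {exp.variant_id}")
        seen.add(exp.variant_id)
        out = outcome_by_id.get(exp.variant_id)
        if out is None:
            audit.append(f"{exp.variant_id}\tMISSING_IN_OUTCOME\t"
                         "variant absent from outcome study")
            continue
        if out.effect_allele == exp.effect_allele:
            beta_out = out.beta
        elif out.effect_allele == COMPLEMENT[exp.effect_allele]:
            if not assume_same_strand:
                audit.append(
                    f"{exp.variant_id}\tAMBIGUOUS_STRAND\t"
                    f"outcome allele {out.effect_allele} is the complement of "
                    f"{exp.effect_allele}; cannot distinguish strand flip from "
                    "allele swap without strand info")
                continue
            beta_out = -out.beta
        else:
            beta_out = -out.beta
        instruments.append(HarmonizedInstrument(
            variant_id=exp.variant_id,
            beta_exposure=exp.beta,
            se_exposure=exp.se,
            beta_outcome=beta_out,
            se_outcome=out.se,
        ))
    if not instruments:
        raise HarmonizationError(
            f"{label or 'harmonize'}: no variants shared between exposure and outcome")
    iset = InstrumentSet(
        label=label,
        instruments=tuple(instruments),
        n_exposure=n_exposure,
        n_outcome_cases=n_outcome_cases,
        n_outcome_controls=n_outcome_controls,
    )
    return iset, audit


# ---------------------------------------------------------------------------
# Instrument selection

def _ld_lookup(ld_matrix, known_ids: set[str]) -> dict[tuple[str, str], float]:
    """Normalize an LD table (long-format DataFrame or (a, b, r2) iterable)."""
    if ld_matrix is None:
        return {}
    if isinstance(ld_matrix, pd.DataFrame):
        triples = ld_matrix[["variant_a", "variant_b", "r2"]].itertuples(index=False)
    else:
        triples = ld_matrix
    lookup: dict[tuple[str, str], float] = {}
    for a, b, r2 in triples:
        for v in (a, b):
            if v not in known_ids:
                raise SelectionError(f"LD table references unknown variant {v}")
        lookup[(a, b)] = float(r2)
        lookup[(b, a)] = float(r2)
    return lookup


def select_instruments(
    candidates: Sequence[VariantAssociation],
    config: SelectionConfig | None = None,
    ld_matrix: pd.DataFrame | Iterable[tuple[str, str, float]] | None = None,
    pleiotropy_flags: Mapping[str, str] | None = None,
) -> tuple[list[VariantAssociation], list[str]]:
    """Qualify exposure-associated variants as instruments.

    Filters, in order: genome-wide significance on the exposure p-value;
    explicit exclusions from the config; pleiotropy annotations (variant id
    -> trait); greedy LD pruning that, within each correlated group
    (r^2 >= threshold), keeps the variant with the smallest exposure
    p-value (ties broken by lexicographically smaller rsID).  Every removal
    is logged with a reason code.  With no LD table and no flags, all
    significant candidates are retained.
    """
    config = config or SelectionConfig()
    pleiotropy_flags = dict(pleiotropy_flags or {})
    audit: list[str] = []

    significant: list[VariantAssociation] = []
    for cand in candidates:
        if cand.p_value is None or cand.p_value < config.gwas_p_threshold:
            significant.append(cand)
        else:
            audit.append(f"{cand.variant_id}\tNOT_SIGNIFICANT\t"
                         f"p={cand.p_value:.3g} >= {config.gwas_p_threshold:g}")

    survivors: list[VariantAssociation] = []
    for cand in significant:
        if cand.variant_id in config.excluded_variants:
            audit.append(f"{cand.variant_id}\tEXCLUDED\t"
                         f"{config.excluded_variants[cand.variant_id]}")
        elif cand.variant_id in pleiotropy_flags:
            audit.append(f"{cand.variant_id}\tPLEIOTROPY\t"
                         f"associated with {pleiotropy_flags[cand.variant_id]}")
        else:
            survivors.append(cand)

    ld = _ld_lookup(ld_matrix, {c.variant_id for c in candidates})

    # greedy pruning in order of ascending p-value; order-invariant for
    # distinct p-values, deterministic under ties via the rsID tie-break
    def sort_key(v: VariantAssociation):
        return (v.p_value if v.p_value is not None else 0.0, v.variant_id)

    kept: list[VariantAssociation] = []
    for cand in sorted(survivors, key=sort_key):
        clash = next(
            (k for k in kept
             if ld.get((cand.variant_id, k.variant_id), 0.0) >= config.ld_r2_threshold),
            None)
        if clash is None:
            kept.append(cand)
        else:
            r2 = ld[(cand.variant_id, clash.variant_id)]
            audit.append(f"{cand.variant_id}\tLD_PRUNED\t"
                         f"r2={r2:.3g} with {clash.variant_id}")
    # restore input order
    order = {c.variant_id: i for i, c in enumerate(candidates)}
    kept.sort(key=lambda v: order[v.variant_id])
    return kept, audit
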