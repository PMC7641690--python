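"""Reading, validation and allele harmonization of GWAS summary statistics.

Two-sample Mendelian randomization pairs SNP–exposure associations (here:
serum iron, ferritin, transferrin, transferrin saturation from a European
iron-status GWAS meta-analysis) with SNP–outcome associations (vascular
disease scans of UK-Biobank scale). The two sources report effects relative
to their own choice of effect allele and strand, so before any estimator can
run, the outcome betas must be re-expressed relative to the exposure's
effect alleles. This module provides the variant containers, a delimited-text
reader with row-level validation, and the harmonization step including
palindromic-SNP resolution by effect-allele frequency.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: field -> column-name presets for common summary-statistic layouts.
COLUMN_PRESETS: dict[str, dict[str, str]] = {
    # canonical schema written by this package
    "default": {
        "rsid": "rsid",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "beta": "beta",
        "se": "se",
        "eaf": "eaf",
        "n": "n",
        "pvalue": "pvalue",
    },
    # Neale-lab-style UK Biobank release headers
    "neale": {
        "rsid": "variant",
        "effect_allele": "minor_allele",
        "other_allele": "major_allele",
        "beta": "beta",
        "se": "se",
        "eaf": "minor_AF",
        "n": "n_complete_samples",
        "pvalue": "pval",
    },
}

_REQUIRED_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se")
_OPTIONAL_FIELDS = ("eaf", "n", "pvalue")


class SummaryDataError(Exception):
    """Base class for summary-data problems."""


class ConfigurationError(SummaryDataError):
    """A column mapping or policy option is invalid."""


class HarmonizationError(SummaryDataError):
    """Allele sets cannot be reconciled for a SNP."""


class MissingInstrumentError(SummaryDataError):
    """A requested instrument SNP is absent from the association table."""


class DegenerateInstrumentError(SummaryDataError):
    """An exposure beta of exactly zero makes the Wald ratio undefined."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's effect estimate in one GWAS.

    ``beta`` is the additive per-effect-allele effect (per SD or per unit of
    the biomarker on the exposure side; on the outcome scale for disease
    scans); ``se`` its standard error. ``eaf`` is the effect-allele
    frequency, used to orient palindromic variants.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    n: float | None = None
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.rsid}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.rsid}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele identical")
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: non-finite beta")
        if not (self.se > 0) or not np.isfinite(self.se):
            raise ValueError(f"{self.rsid}: non-positive SE")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.rsid}: EAF outside (0,1)")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or C/G variants, whose strand is ambiguous."""
        return self.other_allele == COMPLEMENT[self.effect_allele]


@dataclass
class InstrumentSet:
    """The instrument SNPs for one exposure biomarker.

    ``direction_flag`` records whether a higher biomarker value indicates
    higher systemic iron (true for iron, ferritin, transferrin saturation;
    false for transferrin, which rises when iron stores fall).
    """

    exposure_name: str
    direction_flag: bool
    variants: list[VariantAssociation]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("instrument may not be empty")
        rsids = [v.rsid for v in self.variants]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsids in instrument")


@dataclass
class OutcomeSet:
    """SNP–outcome associations for one disease in one stratum."""

    outcome_name: str
    stratum: str = "all"  # one of all / male / female
    n_cases: int | None = None
    n_total: int | None = None
    variants: dict[str, VariantAssociation] = field(default_factory=dict)

    @classmethod
    def from_associations(
        cls,
        outcome_name: str,
        associations: Iterable[VariantAssociation],
        stratum: str = "all",
        n_cases: int | None = None,
        n_total: int | None = None,
    ) -> "OutcomeSet":
        variants: dict[str, VariantAssociation] = {}
        for assoc in associations:
            if assoc.rsid in variants:
                raise ValueError(f"duplicate rsid {assoc.rsid} in outcome table")
            variants[assoc.rsid] = assoc
        return cls(outcome_name, stratum, n_cases, n_total, variants)


@dataclass
class HarmonizedInstrument:
    """Allele-aligned paired exposure/outcome summary statistics.

    The substrate of every estimator: for each retained SNP j, ``gamma[j]``
    (exposure beta) and ``Gamma[j]`` (outcome beta) refer to the same effect
    allele on the same strand.
    """

    rsids: list[str]
    gamma: np.ndarray
    se_gamma: np.ndarray
    Gamma: np.ndarray
    se_Gamma: np.ndarray
    orientation_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.se_gamma = np.asarray(self.se_gamma, dtype=float)
        self.Gamma = np.asarray(self.Gamma, dtype=float)
        self.se_Gamma = np.asarray(self.se_Gamma, dtype=float)
        n = len(self.rsids)
        if n < 1:
            raise ValueError("harmonized instrument is empty")
        for name in ("gamma", "se_gamma", "Gamma", "se_Gamma"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.se_gamma <= 0) or np.any(self.se_Gamma <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.rsids)


@dataclass(frozen=True)
class HarmonizationPolicy:
    """How to treat palindromic variants and strand mismatches.

    palindromic: ``keep`` (align by allele letters only), ``drop``, or
    ``eaf-resolve`` (orient by effect-allele-frequency agreement; a SNP is
    dropped only when both EAFs lie within ``eaf_threshold`` of 0.5, where
    frequency carries no strand information).
    """

    palindromic: str = "eaf-resolve"
    eaf_threshold: float = 0.08
    allow_strand_flip: bool = True

    def __post_init__(self) -> None:
        if self.palindromic not in ("keep", "drop", "eaf-resolve"):
            raise ConfigurationError(f"unknown palindromic policy {self.palindromic!r}")
        if not (0 <= self.eaf_threshold < 0.5):
            raise ConfigurationError("eaf_threshold must be in [0, 0.5)")


def _parse_float(text: str) -> float:
    value = float(text)
    return value


def read_summary_table(
    path,
    column_map: Mapping[str, str] | str | None = None,
    delimiter: str = "\t",
    rejections: list[tuple[int, str]] | None = None,
) -> list[VariantAssociation]:
    """Read a delimited summary-statistics table into variant records.

    ``column_map`` maps field names (rsid, effect_allele, other_allele, beta,
    se, and optionally eaf, n, pvalue) to column headers; a preset name
    ("default", "neale") or None (identity/default schema) is accepted.
    Rows violating the record invariants are rejected with a per-row reason
    logged at WARNING (and appended to ``rejections`` if given) rather than
    aborting the read.
    """
    if column_map is None:
        column_map = COLUMN_PRESETS["default"]
    elif isinstance(column_map, str):
        try:
            column_map = COLUMN_PRESETS[column_map]
        except KeyError:
            raise ConfigurationError(f"unknown column preset {column_map!r}") from None

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for fieldname in _REQUIRED_FIELDS:
            col = column_map.get(fieldname)
            if col is None:
                raise ConfigurationError(f"column_map lacks required field {fieldname!r}")
            if col not in header:
                raise ConfigurationError(f"mapped column {col!r} ({fieldname}) missing from {path}")

        records: list[VariantAssociation] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                kwargs: dict = {
                    "rsid": row[column_map["rsid"]].strip(),
                    "effect_allele": row[column_map["effect_allele"]].strip().upper(),
                    "other_allele": row[column_map["other_allele"]].strip().upper(),
                    "beta": _parse_float(row[column_map["beta"]]),
                    "se": _parse_float(row[column_map["se"]]),
                }
                for optional in _OPTIONAL_FIELDS:
                    col = column_map.get(optional)
                    if col and col in row and row[col] not in (None, "", "NA", "nan"):
                        kwargs[optional] = _parse_float(row[col])
                records.append(VariantAssociation(**kwargs))
            except (ValueError, KeyError) as exc:
                reason = str(exc) if str(exc) else type(exc).__name__
                if isinstance(exc, ValueError) and "could not convert" in reason:
                    reason = f"unparseable numeric: {reason}"
                logger.warning("%s line %d rejected: %s", path, lineno, reason)
                if rejections is not None:
                    rejections.append((lineno, reason))
    return records


def associations_from_frame(df) -> list[VariantAssociation]:
    """Convert a canonical-schema DataFrame (as emitted by the synthetic
    generator) into validated variant records without a file round-trip."""
    records = []
    for row in df.itertuples(index=False):
        records.append(
            VariantAssociation(
                rsid=str(row.rsid),
                effect_allele=str(row.effect_allele).upper(),
                other_allele=str(row.other_allele).upper(),
                beta=float(row.beta),
                se=float(row.se),
                eaf=float(row.eaf) if "eaf" in df.columns else None,
                n=float(row.n) if "n" in df.columns else None,
                pvalue=float(row.pvalue) if "pvalue" in df.columns else None,
            )
        )
    return records


def write_summary_table(records: Sequence[VariantAssociation], path, delimiter: str = "\t") -> None:
    """Write records in the canonical schema (round-trips with the reader)."""
    cols = _REQUIRED_FIELDS + _OPTIONAL_FIELDS
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(cols)
        for rec in records:
            writer.writerow(
                [
                    rec.rsid,
                    rec.effect_allele,
                    rec.other_allele,
                    repr(rec.beta),
                    repr(rec.se),
                    "" if rec.eaf is None else repr(rec.eaf),
                    "" if rec.n is None else repr(rec.n),
                    "" if rec.pvalue is None else repr(rec.pvalue),
                ]
            )


def build_instrument(
    exposure_name: str,
    direction_flag: bool,
    associations: Sequence[VariantAssociation],
    snp_filter: Sequence[str],
) -> InstrumentSet:
    """Select the instrument SNPs, in ``snp_filter`` order, from a table."""
    if not snp_filter:
        raise MissingInstrumentError("instrument may not be empty (empty snp_filter)")
    by_rsid: dict[str, list[VariantAssociation]] = {}
    for assoc in associations:
        by_rsid.setdefault(assoc.rsid, []).append(assoc)
    chosen: list[VariantAssociation] = []
    for rsid in snp_filter:
        hits = by_rsid.get(rsid, [])
        if not hits:
            raise MissingInstrumentError(f"instrument SNP {rsid} absent from associations")
        if len(hits) > 1:
            raise MissingInstrumentError(f"instrument SNP {rsid} occurs {len(hits)} times")
        chosen.append(hits[0])
    return InstrumentSet(exposure_name, direction_flag, chosen)


def _complement_variant(v: VariantAssociation) -> VariantAssociation:
    # strand flip relabels alleles; beta and eaf stay with the (renamed) effect allele
    return replace(
        v,
        effect_allele=COMPLEMENT[v.effect_allele],
        other_allele=COMPLEMENT[v.other_allele],
    )


def _swap_variant(v: VariantAssociation) -> VariantAssociation:
    return replace(
        v,
        effect_allele=v.other_allele,
        other_allele=v.effect_allele,
        beta=-v.beta,
        eaf=None if v.eaf is None else 1.0 - v.eaf,
    )


def harmonize(
    instrument: InstrumentSet,
    outcome: OutcomeSet,
    policy: HarmonizationPolicy | None = None,
) -> HarmonizedInstrument:
    """Align outcome betas to the instrument's effect alleles.

    For each instrument SNP found in the outcome: matching alleles pass
    through; swapped alleles flip the outcome beta and complement its EAF;
    a strand complement (A<->T, C<->G relabelling) is applied when that is
    the only way to reconcile the allele sets. Palindromic SNPs are handled
    per policy; with ``eaf-resolve`` the orientation is taken from whether
    the two EAFs fall on the same side of 0.5. Every action is recorded in
    the orientation log; SNPs absent from the outcome are dropped with a
    warning.
    """
    policy = policy or HarmonizationPolicy()
    rsids: list[str] = []
    gamma, se_gamma, Gamma, se_Gamma = [], [], [], []
    log: list[str] = []

    for x in instrument.variants:
        o = outcome.variants.get(x.rsid)
        if o is None:
            msg = f"{x.rsid}: absent from outcome {outcome.outcome_name}/{outcome.stratum}; dropped"
            logger.warning(msg)
            log.append(msg)
            continue

        actions: list[str] = []
        if x.is_palindromic:
            if policy.palindromic == "drop":
                log.append(f"{x.rsid}: palindromic; dropped by policy")
                continue
            # letter-alignment first (palindromic allele sets always match)
            if {o.effect_allele, o.other_allele} != {x.effect_allele, x.other_allele}:
                raise HarmonizationError(
                    f"{x.rsid}: outcome alleles {o.effect_allele}/{o.other_allele} "
                    f"incompatible with {x.effect_allele}/{x.other_allele}"
                )
            if o.effect_allele != x.effect_allele:
                o = _swap_variant(o)
                actions.append("swap")
            if policy.palindromic == "eaf-resolve":
                if x.eaf is None or o.eaf is None:
                    log.append(f"{x.rsid}: palindromic without both EAFs; dropped")
                    continue
                close_x = abs(x.eaf - 0.5) < policy.eaf_threshold
                close_o = abs(o.eaf - 0.5) < policy.eaf_threshold
                if close_x and close_o:
                    log.append(
                        f"{x.rsid}: palindromic, both EAFs within "
                        f"{policy.eaf_threshold} of 0.5; dropped"
                    )
                    continue
                if (x.eaf - 0.5) * (o.eaf - 0.5) < 0:
                    # frequencies disagree: outcome effect allele was the
                    # opposite-strand partner; flip orientation
                    o = _swap_variant(o)
                    actions.append("eaf_flip")
                else:
                    actions.append("eaf_ok")
            else:  # keep
                actions.append("palindromic_keep")
        else:
            x_set = {x.effect_allele, x.other_allele}
            o_set = {o.effect_allele, o.other_allele}
            if o_set == x_set:
                pass
            elif policy.allow_strand_flip and {
                COMPLEMENT[a] for a in o_set
            } == x_set:
                o = _complement_variant(o)
                actions.append("strand_flip")
            else:
                raise HarmonizationError(
                    f"{x.rsid}: outcome alleles {o.effect_allele}/{o.other_allele} "
                    f"incompatible with {x.effect_allele}/{x.other_allele}"
                )
            if o.effect_allele != x.effect_allele:
                o = _swap_variant(o)
                actions.append("swap")

        log.append(f"{x.rsid}: {'+'.join(actions) if actions else 'passthrough'}")
        rsids.append(x.rsid)
        gamma.append(x.beta)
        se_gamma.append(x.se)
        Gamma.append(o.beta)
        se_Gamma.append(o.se)

    if not rsids:
        raise HarmonizationError(
            f"no instrument SNPs could be harmonized with outcome {outcome.outcome_name}"
        )
    return HarmonizedInstrument(rsids, np.array(gamma), np.array(se_gamma),
                                np.array(Gamma), np.array(se_Gamma), log)


def orient_to_exposure_increasing(h: HarmonizedInstrument) -> HarmonizedInstrument:
    """Re-sign each SNP so every exposure beta is positive.

    Negating gamma_j and Gamma_j together leaves the Wald ratio untouched but
    gives the orientation convention Egger regression requires.
    """
    if np.any(h.gamma == 0):
        zero = [r for r, g in zip(h.rsids, h.gamma) if g == 0]
        raise DegenerateInstrumentError(f"exposure beta exactly zero for {', '.join(zero)}")
    sign = np.where(h.gamma < 0, -1.0, 1.0)
    log = list(h.orientation_log)
    for rsid, s in zip(h.rsids, sign):
        if s < 0:
            log.append(f"{rsid}: reoriented to exposure-increasing allele")
    return HarmonizedInstrument(
        list(h.rsids), h.gamma * sign, h.se_gamma.copy(), h.Gamma * sign, h.se_Gamma.copy(), log
    )


def instrument_strength(h: HarmonizedInstrument) -> np.ndarray:
    """Per-SNP F statistic, F_j = (gamma_j / se_gamma_j)^2.

    F < 10 is the conventional weak-instrument flag; weak SNPs are logged.
    """
    F = (h.gamma / h.se_gamma) ** 2
    for rsid, f in zip(h.rsids, F):
        if f < 10:
            logger.warning("%s: weak instrument (F = %.3g < 10)", rsid, f)
    return F


def weak_instrument_flags(h: HarmonizedInstrument) -> np.ndarray:
    """Boolean mask of SNPs with F below the conventional threshold of 10."""
    return instrument_strength(h) < 10
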