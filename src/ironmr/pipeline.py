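"""Exposure x outcome x stratum analysis grid with multiplicity control.

Orchestrates the full two-sample MR analysis: read each exposure's
instrument table and each outcome stratum's summary file, harmonize and
orient, compute the fixed-effect IVW estimate (primary) plus the configured
sensitivity estimators and the Egger pleiotropy intercept, classify every
cell against a Bonferroni family-wise threshold, and emit plot-ready TSV
tables plus a run-metadata file. A grid of 4 exposures and 12 outcomes
gives the family size 48 and per-test threshold 0.05/48.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .estimators import (
    EggerRegression,
    InsufficientInstrumentsError,
    IVWEstimator,
    MREstimate,
    SimpleMedianEstimator,
    WeightedMedianEstimator,
    sex_difference_test,
)
from .summary_data import (
    HarmonizationError,
    HarmonizationPolicy,
    InstrumentSet,
    OutcomeSet,
    build_instrument,
    harmonize,
    instrument_strength,
    orient_to_exposure_increasing,
    read_summary_table,
)

logger = logging.getLogger(__name__)

STRATA = ("all", "male", "female")
KNOWN_METHODS = ("ivw_fixed", "simple_median", "weighted_median", "egger_slope")

#: fixed column order of the long-format results table
LONG_COLUMNS = [
    "exposure",
    "outcome",
    "stratum",
    "method",
    "beta",
    "se",
    "or_point",
    "ci_low",
    "ci_high",
    "pvalue",
    "n_snps",
    "significance_class",
    "weak_instrument_flag",
    "egger_intercept",
    "egger_intercept_p",
    "concordant_direction",
    "direction_note",
]


@dataclass
class ExposureSpec:
    name: str
    file: str
    direction_flag: bool = True


@dataclass
class OutcomeSpec:
    name: str
    files: dict[str, str]  # stratum -> path
    n_cases: int | None = None


@dataclass
class AnalysisConfig:
    """Declarative description of one grid run."""

    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    snp_filter: list[str]
    methods: list[str] = field(
        default_factory=lambda: ["ivw_fixed", "simple_median", "weighted_median", "egger_slope"]
    )
    alpha_family: float = 0.05
    alpha_nominal: float = 0.05
    palindromic_policy: str = "eaf-resolve"
    eaf_threshold: float = 0.08
    se_mode: str = "full_delta"
    bootstrap_B: int = 5000
    seed: int = 0
    column_map: str | dict | None = None
    delimiter: str = "\t"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ValueError("need at least one exposure and one outcome")
        if not (0 < self.alpha_family < 1):
            raise ValueError("alpha_family must be in (0,1)")
        for m in self.methods:
            if m not in KNOWN_METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {KNOWN_METHODS}")

    @property
    def policy(self) -> HarmonizationPolicy:
        return HarmonizationPolicy(self.palindromic_policy, self.eaf_threshold)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["exposures"] = [ExposureSpec(**e) for e in raw["exposures"]]
        raw["outcomes"] = [OutcomeSpec(**o) for o in raw["outcomes"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class AnalysisRecord:
    """One exposure x outcome x stratum x method row of the results grid."""

    exposure: str
    outcome: str
    stratum: str
    method: str
    beta: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    significance_class: str
    weak_instrument_flag: bool
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    concordant_direction: bool | None = None
    direction_note: str = ""


@dataclass
class CellFailure:
    exposure: str
    outcome: str
    stratum: str
    reason: str


@dataclass
class SexDifference:
    exposure: str
    outcome: str
    method: str
    z: float
    pvalue: float


@dataclass
class GridResult:
    """Everything one grid run produced."""

    records: list[AnalysisRecord]
    failures: list[CellFailure]
    sex_differences: list[SexDifference]
    threshold_strict: float
    threshold_nominal: float
    config: AnalysisConfig

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def bonferroni_threshold(alpha_family: float, n_exposures: int, n_outcomes: int) -> float:
    """Family-wise per-test threshold alpha / (n_exposures * n_outcomes)."""
    if n_exposures < 1 or n_outcomes < 1:
        raise ValueError("exposure and outcome counts must be at least 1")
    return alpha_family / (n_exposures * n_outcomes)


def classify(pvalue: float, threshold_strict: float, threshold_nominal: float = 0.05) -> str:
    """Three-way significance taxonomy.

    p below the Bonferroni threshold -> "significant"; between it and the
    nominal level -> "potential"; otherwise "null".
    """
    if threshold_strict > threshold_nominal:
        raise ValueError("strict threshold must not exceed the nominal one")
    if pvalue < threshold_strict:
        return "significant"
    if pvalue < threshold_nominal:
        return "potential"
    return "null"


def sensitivity_concordance(betas) -> bool:
    """True when every method's beta shares one sign (zero matches either)."""
    betas = [b for b in betas if b != 0]
    if not betas:
        return True
    return all(b > 0 for b in betas) or all(b < 0 for b in betas)


def _cell_seed(base_seed: int, exposure: str, outcome: str, stratum: str) -> int:
    """Per-cell bootstrap seed keyed by cell identity, not iteration order."""
    tag = zlib.crc32(f"{exposure}|{outcome}|{stratum}".encode())
    return int(np.random.SeedSequence([int(base_seed), tag]).generate_state(1, np.uint32)[0])


def estimate_cell(
    instrument: InstrumentSet,
    outcome: OutcomeSet,
    methods=KNOWN_METHODS,
    policy: HarmonizationPolicy | None = None,
    se_mode: str = "full_delta",
    bootstrap_B: int = 5000,
    seed: int = 0,
) -> tuple[dict[str, MREstimate], dict]:
    """Estimate one exposure/outcome/stratum cell with all requested methods.

    Returns (method -> estimate) plus cell-level metadata: per-SNP F
    statistics, the weak-instrument flag, the Egger intercept and its p, and
    the harmonization orientation log.
    """
    h = orient_to_exposure_increasing(harmonize(instrument, outcome, policy))
    F = instrument_strength(h)
    meta: dict = {
        "F": F,
        "weak_instrument_flag": bool(np.any(F < 10)),
        "orientation_log": h.orientation_log,
        "egger_intercept": None,
        "egger_intercept_p": None,
        "n_snps": h.n_snps,
    }
    estimates: dict[str, MREstimate] = {}
    for method in methods:
        try:
            if method == "ivw_fixed":
                estimates[method] = IVWEstimator(se_mode=se_mode).fit(h).to_estimate()
            elif method == "simple_median":
                estimates[method] = (
                    SimpleMedianEstimator(B=bootstrap_B, seed=seed, se_mode=se_mode)
                    .fit(h).to_estimate()
                )
            elif method == "weighted_median":
                estimates[method] = (
                    WeightedMedianEstimator(B=bootstrap_B, seed=seed + 1, se_mode=se_mode)
                    .fit(h).to_estimate()
                )
            elif method == "egger_slope":
                reg = EggerRegression().fit(h)
                estimates[method] = reg.to_estimate()
                meta["egger_intercept"] = reg.intercept_
                meta["egger_intercept_p"] = reg.intercept_pvalue_
        except InsufficientInstrumentsError as exc:
            logger.warning("%s skipped: %s", method, exc)
    return estimates, meta


def run_grid(config: AnalysisConfig) -> GridResult:
    """Run the full grid described by ``config``.

    Harmonization failures in a cell are recorded and the grid continues;
    records are emitted for every successful cell whether or not anything is
    significant. Deterministic given the config (bootstrap seeds derive from
    the config seed and the cell identity).
    """
    threshold_strict = bonferroni_threshold(
        config.alpha_family, len(config.exposures), len(config.outcomes)
    )
    threshold_nominal = config.alpha_nominal

    instruments: dict[str, InstrumentSet] = {}
    for spec in config.exposures:
        assocs = read_summary_table(spec.file, config.column_map, config.delimiter)
        instruments[spec.name] = build_instrument(
            spec.name, spec.direction_flag, assocs, config.snp_filter
        )

    outcome_sets: dict[tuple[str, str], OutcomeSet] = {}
    for ospec in config.outcomes:
        for stratum in STRATA:
            path = ospec.files.get(stratum)
            if path is None:
                continue
            if not Path(path).exists():
                logger.warning(
                    "outcome %s stratum %s: file %s missing; stratum skipped",
                    ospec.name, stratum, path,
                )
                continue
            assocs = read_summary_table(path, config.column_map, config.delimiter)
            outcome_sets[(ospec.name, stratum)] = OutcomeSet.from_associations(
                ospec.name, assocs, stratum, n_cases=ospec.n_cases
            )

    records: list[AnalysisRecord] = []
    failures: list[CellFailure] = []
    cell_estimates: dict[tuple[str, str, str], dict[str, MREstimate]] = {}

    for espec in config.exposures:
        instrument = instruments[espec.name]
        direction_note = (
            "" if espec.direction_flag else "higher value = lower iron status"
        )
        for ospec in config.outcomes:
            for stratum in STRATA:
                oset = outcome_sets.get((ospec.name, stratum))
                if oset is None:
                    continue
                try:
                    estimates, meta = estimate_cell(
                        instrument,
                        oset,
                        methods=config.methods,
                        policy=config.policy,
                        se_mode=config.se_mode,
                        bootstrap_B=config.bootstrap_B,
                        seed=_cell_seed(config.seed, espec.name, ospec.name, stratum),
                    )
                except (HarmonizationError, ValueError) as exc:
                    failures.append(CellFailure(espec.name, ospec.name, stratum, str(exc)))
                    logger.error(
                        "cell %s x %s (%s) failed: %s", espec.name, ospec.name, stratum, exc
                    )
                    continue
                cell_estimates[(espec.name, ospec.name, stratum)] = estimates
                concordant = (
                    sensitivity_concordance([e.beta for e in estimates.values()])
                    if len(estimates) >= 2
                    else None
                )
                for method, est in estimates.items():
                    records.append(
                        AnalysisRecord(
                            exposure=espec.name,
                            outcome=ospec.name,
                            stratum=stratum,
                            method=method,
                            beta=est.beta,
                            se=est.se,
                            or_point=est.or_point,
                            ci_low=est.ci_low,
                            ci_high=est.ci_high,
                            pvalue=est.pvalue,
                            n_snps=est.n_snps,
                            significance_class=classify(
                                est.pvalue, threshold_strict, threshold_nominal
                            ),
                            weak_instrument_flag=meta["weak_instrument_flag"],
                            egger_intercept=meta["egger_intercept"],
                            egger_intercept_p=meta["egger_intercept_p"],
                            concordant_direction=concordant,
                            direction_note=direction_note,
                        )
                    )

    if not records:
        raise RuntimeError("empty grid: no cell could be analysed")

    # exploratory male-vs-female comparison, not multiplicity-corrected
    sex_diffs: list[SexDifference] = []
    for espec in config.exposures:
        for ospec in config.outcomes:
            male = cell_estimates.get((espec.name, ospec.name, "male"))
            female = cell_estimates.get((espec.name, ospec.name, "female"))
            if not male or not female:
                continue
            for method in config.methods:
                if method in male and method in female:
                    z, p = sex_difference_test(male[method], female[method])
                    sex_diffs.append(SexDifference(espec.name, ospec.name, method, z, p))

    return GridResult(records, failures, sex_diffs, threshold_strict, threshold_nominal, config)


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return repr(float(value))
    return str(value)


def write_results(result: GridResult, output_dir) -> dict[str, Path]:
    """Write the long results table, forest-plot tables and run metadata.

    All outputs are TSV/YAML text; floats are written at full double
    precision so a rerun with the same config is byte-identical.
    """
    if not result.records:
        raise ValueError("no records to write")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    long_path = output_dir / "results_long.tsv"
    with open(long_path, "w") as fh:
        fh.write("\t".join(LONG_COLUMNS) + "\n")
        for rec in result.records:
            fh.write("\t".join(_fmt(getattr(rec, c)) for c in LONG_COLUMNS) + "\n")
    paths["long"] = long_path

    # forest-plot-ready tables: primary (IVW) estimates only
    for name, strata in (("forest_overall.tsv", ("all",)), ("forest_by_sex.tsv", ("male", "female"))):
        path = output_dir / name
        cols = ["exposure", "outcome", "stratum", "or_point", "ci_low", "ci_high", "pvalue"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for rec in result.records:
                if rec.method == "ivw_fixed" and rec.stratum in strata:
                    fh.write("\t".join(_fmt(getattr(rec, c)) for c in cols) + "\n")
        paths[name] = path

    sex_path = output_dir / "sex_differences.tsv"
    with open(sex_path, "w") as fh:
        fh.write("exposure\toutcome\tmethod\tz\tpvalue\n")
        for d in result.sex_differences:
            fh.write(f"{d.exposure}\t{d.outcome}\t{d.method}\t{_fmt(d.z)}\t{_fmt(d.pvalue)}\n")
    paths["sex_differences"] = sex_path

    meta_path = output_dir / "run_metadata.yaml"
    meta = {
        "software": {"name": "ironmr", "version": __version__},
        "threshold_strict": float(result.threshold_strict),
        "threshold_nominal": float(result.threshold_nominal),
        "n_records": len(result.records),
        "n_failures": len(result.failures),
        "failures": [dataclasses.asdict(f) for f in result.failures],
        "config": result.config.to_dict(),
        "notes": [
            "threshold_strict is the Bonferroni family-wise per-test threshold "
            "(alpha_family / (n_exposures * n_outcomes)) derived from the overall grid",
            "sex_differences.tsv is exploratory and not multiplicity-corrected",
        ],
    }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    paths["metadata"] = meta_path
    return paths


def config_for_study(study, data_dir, output_dir=None, **overrides) -> AnalysisConfig:
    """Build an AnalysisConfig for a written SyntheticStudy directory."""
    data_dir = Path(data_dir)
    exposures = [
        ExposureSpec(name, str(data_dir / f"exposure_{name}.tsv"), direction)
        for name, direction in study.exposures.items()
    ]
    outcomes = [
        OutcomeSpec(
            name,
            {
                stratum: str(data_dir / f"outcome_{name}_{stratum}.tsv")
                for stratum in info["strata"]
            },
            n_cases=info.get("n_cases"),
        )
        for name, info in study.outcome_info.items()
    ]
    return AnalysisConfig(
        exposures=exposures,
        outcomes=outcomes,
        snp_filter=list(study.snp_filter),
        output_dir=None if output_dir is None else str(output_dir),
        **overrides,
    )
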