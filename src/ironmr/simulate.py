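"""Synthetic summary-level MR datasets with known ground truth.

The generator emulates, at summary level, the statistical structure of a
two-sample design: a small panel of strong instruments measured in an
exposure GWAS of ~49,000 Europeans, and outcome scans of UK-Biobank scale
(361,194 subjects; binary vascular-disease endpoints analysed with linear
models, so outcome betas are of order 1e-4..1e-2). Estimates are drawn from
the estimators' own assumed sampling model,

    gamma_hat_j ~ Normal(gamma_j, se_gamma_j^2)
    Gamma_hat_j ~ Normal(theta * gamma_j + alpha_j, se_Gamma_j^2)
    alpha_j     ~ Normal(mu_alpha, tau^2)   independent of gamma (InSIDE)

with independent exposure- and outcome-side errors (non-overlapping
cohorts). An optional allele scramble randomises effect/other orientation
and strand in the emitted tables without touching the underlying draws, so
a harmonized analysis must be invariant to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .summary_data import COMPLEMENT

__all__ = [
    "SimulationParams",
    "SyntheticStudy",
    "simulate_cell",
    "simulate_study",
    "fixture_iron_study",
    "FIXTURE_SEED",
]

#: pinned seed of the packaged fixture study
FIXTURE_SEED = 604

N_EXPOSURE_GWAS = 48972
N_OUTCOME_ALL = 361194
N_OUTCOME_MALE = 167020
N_OUTCOME_FEMALE = 194174

#: fixture instrument metadata: rsid, effect allele, other allele, EAF.
#: rs1799945 is C/G palindromic on purpose, to exercise EAF resolution.
FIXTURE_SNPS = [
    ("rs1800562", "A", "G", 0.07),
    ("rs1799945", "C", "G", 0.15),
    ("rs855791", "A", "G", 0.44),
]
#: per-SD-of-systemic-iron exposure effects for the fixture SNPs
FIXTURE_GAMMA_REF = np.array([0.33, 0.19, 0.18])

#: biomarker -> (direction_flag, scale of its betas relative to systemic iron)
DEFAULT_EXPOSURES = {
    "iron": (True, 1.0),
    "ferritin": (True, 0.8),
    "transferrin": (False, -0.9),
    "transferrin_saturation": (True, 1.1),
}

#: outcome -> (n_cases, sex-stratified summary data available)
DEFAULT_OUTCOMES = {
    "coronary_atherosclerosis": (14334, True),
    "varicose_veins_lower_extremities": (8763, True),
    "deep_vein_thrombosis": (6795, True),
    "pulmonary_embolism": (2289, True),
    "phlebitis_thrombophlebitis": (2000, True),
    "peripheral_artery_disease": (1230, True),
    "aortic_aneurysm": (589, True),
    "atherosclerosis": (566, False),
    "arterial_embolism_thrombosis": (510, False),
    "cerebral_aneurysm": (225, False),
    "varicose_veins_other_sites": (222, False),
    "aortic_dissection": (129, False),
}

#: qualitative causal pattern of the fixture study, on the systemic-iron
#: scale: a detrimental venous effect in both sexes and a male-driven
#: protective arterial effect; all other cells null. Synthetic stand-ins,
#: not estimates taken from any study.
FIXTURE_THETA = {
    ("varicose_veins_lower_extremities", "all"): 0.006,
    ("varicose_veins_lower_extremities", "male"): 0.006,
    ("varicose_veins_lower_extremities", "female"): 0.006,
    ("coronary_atherosclerosis", "all"): -0.0025,
    ("coronary_atherosclerosis", "male"): -0.008,
    ("coronary_atherosclerosis", "female"): -0.0005,
}


@dataclass
class SimulationParams:
    """Knobs of the summary-level generative model.

    theta is the true causal effect (outcome beta per exposure unit);
    pleiotropy_mean/pleiotropy_sd parameterise the direct-effect
    distribution (mean 0 with sd > 0 gives balanced pleiotropy); se_gamma
    defaults to gamma/sqrt(F) with per-SNP F drawn log-uniformly from
    f_range, mirroring the strong-instrument regime (F of tens to
    thousands) while allowing a weak-SNP toggle via f_range.
    """

    J: int = 3
    theta: float = 0.0
    gamma_true: np.ndarray | list | None = None
    se_gamma: np.ndarray | list | float | None = None
    se_Gamma: np.ndarray | list | float = 0.002
    f_range: tuple[float, float] = (50.0, 2000.0)
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_n: int | None = None
    allele_scramble: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ValueError("J must be at least 1")
        if self.pleiotropy_n is not None and not (0 <= self.pleiotropy_n <= self.J):
            raise ValueError("pleiotropy_n must be between 0 and J")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be nonnegative")
        if np.any(np.asarray(self.se_Gamma) <= 0):
            raise ValueError("se_Gamma must be positive")
        if self.se_gamma is not None and np.any(np.asarray(self.se_gamma) <= 0):
            raise ValueError("se_gamma must be positive")
        if self.gamma_true is not None and len(np.atleast_1d(self.gamma_true)) != self.J:
            raise ValueError("gamma_true length must equal J")


def _default_snp_meta(J: int, rng: np.random.Generator) -> list[tuple[str, str, str, float]]:
    meta = []
    for j in range(J):
        alleles = ("C", "G") if j % 3 == 2 else ("A", "G")  # every third SNP palindromic
        eaf = float(rng.uniform(0.1, 0.35))
        meta.append((f"rs{1000000 + j}", alleles[0], alleles[1], eaf))
    return meta


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2 * stats.norm.sf(np.abs(beta / se))


def _table(meta, beta, se, n) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rsid": [m[0] for m in meta],
            "effect_allele": [m[1] for m in meta],
            "other_allele": [m[2] for m in meta],
            "beta": beta,
            "se": se,
            "eaf": [m[3] for m in meta],
            "n": n,
            "pvalue": _pvalues(np.asarray(beta), np.asarray(se)),
        }
    )


def _scramble_table(df: pd.DataFrame, rng: np.random.Generator) -> tuple[pd.DataFrame, list[str]]:
    """Randomly swap effect/other orientation and strand, row by row.

    Pure re-representation: a swap negates the beta and complements the EAF;
    a strand flip relabels both alleles and changes no number.
    """
    df = df.copy()
    ops: list[str] = []
    for i in range(len(df)):
        applied = []
        if rng.random() < 0.5:
            ea, oa = df.at[i, "effect_allele"], df.at[i, "other_allele"]
            df.at[i, "effect_allele"], df.at[i, "other_allele"] = oa, ea
            df.at[i, "beta"] = -df.at[i, "beta"]
            df.at[i, "eaf"] = 1.0 - df.at[i, "eaf"]
            applied.append("swap")
        if rng.random() < 0.5:
            df.at[i, "effect_allele"] = COMPLEMENT[df.at[i, "effect_allele"]]
            df.at[i, "other_allele"] = COMPLEMENT[df.at[i, "other_allele"]]
            applied.append("strand")
        ops.append("+".join(applied) if applied else "none")
    return df, ops


def simulate_cell(
    params: SimulationParams,
    seed: int | None = None,
    snp_meta: list[tuple[str, str, str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate one exposure table, one outcome table and their ground truth.

    Deterministic per seed. The value-generating random stream is separate
    from the allele-scramble stream, so runs that differ only in
    ``allele_scramble`` share identical underlying estimates.
    """
    if seed is None:
        seed = params.seed
    if seed is None:
        raise ValueError("a seed is required")
    ss = np.random.SeedSequence([int(seed), 0x1A0])
    rng_values, rng_scramble = (np.random.default_rng(s) for s in ss.spawn(2))

    J = params.J
    if params.gamma_true is None:
        gamma = rng_values.uniform(0.1, 0.5, J)
    else:
        gamma = np.asarray(params.gamma_true, dtype=float)
    if params.se_gamma is None:
        log_lo, log_hi = np.log(params.f_range)
        F = np.exp(rng_values.uniform(log_lo, log_hi, J))
        se_gamma = np.abs(gamma) / np.sqrt(F)
    else:
        se_gamma = np.broadcast_to(np.asarray(params.se_gamma, dtype=float), (J,)).copy()
    se_Gamma = np.broadcast_to(np.asarray(params.se_Gamma, dtype=float), (J,)).copy()

    alpha = params.pleiotropy_mean + params.pleiotropy_sd * rng_values.standard_normal(J)
    if params.pleiotropy_n is not None:
        # invalid-instrument scenarios: only the first pleiotropy_n SNPs
        # carry a direct effect
        alpha[params.pleiotropy_n:] = 0.0
    gamma_hat = gamma + se_gamma * rng_values.standard_normal(J)
    Gamma_hat = params.theta * gamma + alpha + se_Gamma * rng_values.standard_normal(J)

    if snp_meta is None:
        snp_meta = _default_snp_meta(J, rng_values)
    exposure = _table(snp_meta, gamma_hat, se_gamma, N_EXPOSURE_GWAS)
    outcome = _table(snp_meta, Gamma_hat, se_Gamma, N_OUTCOME_ALL)
    ops = ["none"] * J
    if params.allele_scramble:
        outcome, ops = _scramble_table(outcome, rng_scramble)

    truth = {
        "seed": int(seed),
        "theta": params.theta,
        "gamma_true": gamma.tolist(),
        "alpha": alpha.tolist(),
        "se_gamma": se_gamma.tolist(),
        "se_Gamma": se_Gamma.tolist(),
        "scramble_ops": ops,
    }
    return exposure, outcome, truth


@dataclass
class SyntheticStudy:
    """A full multi-exposure, multi-outcome synthetic study.

    ``manifest`` records every generator input (seed, design, per-cell true
    effects and pleiotropy draws, scrambles applied), sufficient to
    recompute the expectation of every emitted beta and to regenerate the
    study byte-for-byte.
    """

    exposures: dict[str, bool]  # name -> direction_flag
    snp_filter: list[str]
    exposure_tables: dict[str, pd.DataFrame]
    outcome_tables: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    outcome_info: dict[str, dict] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def write(self, directory) -> Path:
        """Materialise the study as TSV files plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in self.exposure_tables.items():
            df.to_csv(directory / f"exposure_{name}.tsv", sep="\t", index=False)
        for (name, stratum), df in self.outcome_tables.items():
            df.to_csv(directory / f"outcome_{name}_{stratum}.tsv", sep="\t", index=False)
        with open(directory / "manifest.json", "w") as fh:
            # insertion order is meaningful: it is the RNG consumption order
            json.dump(self.manifest, fh, indent=1)
        return directory


def _stratum_se(se_all: float, stratum: str) -> float:
    # sampling noise scales with 1/sqrt(n) of the stratum
    if stratum == "male":
        return se_all * float(np.sqrt(N_OUTCOME_ALL / N_OUTCOME_MALE))
    if stratum == "female":
        return se_all * float(np.sqrt(N_OUTCOME_ALL / N_OUTCOME_FEMALE))
    return se_all


def _outcome_se(n_cases: int, n_total: int = N_OUTCOME_ALL, mean_het: float = 0.15) -> float:
    # linear-model SE for a binary trait: sqrt(p(1-p)) / sqrt(2 n q(1-q))
    p = n_cases / n_total
    return float(np.sqrt(p * (1 - p)) / np.sqrt(2 * n_total * mean_het * (1 - mean_het)))


def simulate_study(
    seed: int,
    theta_map: dict[tuple[str, str], float] | None = None,
    exposures: dict[str, tuple[bool, float]] | None = None,
    outcomes: dict[str, tuple[int, bool]] | None = None,
    gamma_ref: np.ndarray | None = None,
    snp_meta: list[tuple[str, str, str, float]] | None = None,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    allele_scramble: bool = False,
    f_range: tuple[float, float] = (50.0, 2000.0),
) -> SyntheticStudy:
    """Generate a study laid out like the iron–vascular-disease analysis.

    One exposure file per biomarker (betas proportional to a shared
    per-SD-of-systemic-iron effect ``gamma_ref``, negative for transferrin)
    and one outcome file per disease and stratum, with ``theta_map`` giving
    each (outcome, stratum) cell's true effect on the systemic-iron scale
    (cells absent from the map are null). The emitted files are directly
    consumable by the analysis pipeline.
    """
    exposures = exposures or DEFAULT_EXPOSURES
    outcomes = outcomes or DEFAULT_OUTCOMES
    theta_map = theta_map or {}
    snp_meta = snp_meta or FIXTURE_SNPS
    if gamma_ref is None:
        gamma_ref = FIXTURE_GAMMA_REF[: len(snp_meta)]
    gamma_ref = np.asarray(gamma_ref, dtype=float)
    J = len(snp_meta)
    if len(gamma_ref) != J:
        raise ValueError("gamma_ref length must match snp_meta")

    ss = np.random.SeedSequence([int(seed), 0x57D])
    rng_values, rng_scramble = (np.random.default_rng(s) for s in ss.spawn(2))

    log_lo, log_hi = np.log(f_range)
    F = np.exp(rng_values.uniform(log_lo, log_hi, J))

    exposure_tables: dict[str, pd.DataFrame] = {}
    exposure_truth: dict[str, dict] = {}
    for name, (direction, scale) in exposures.items():
        g = scale * gamma_ref
        se_g = np.abs(g) / np.sqrt(F)
        g_hat = g + se_g * rng_values.standard_normal(J)
        exposure_tables[name] = _table(snp_meta, g_hat, se_g, N_EXPOSURE_GWAS)
        exposure_truth[name] = {"scale": scale, "gamma": g.tolist(), "se_gamma": se_g.tolist()}

    outcome_tables: dict[tuple[str, str], pd.DataFrame] = {}
    outcome_info: dict[str, dict] = {}
    cells: dict[str, dict] = {}
    for name, (n_cases, has_strata) in outcomes.items():
        se_all = _outcome_se(n_cases)
        strata = ["all"] + (["male", "female"] if has_strata else [])
        outcome_info[name] = {"n_cases": n_cases, "strata": strata}
        for stratum in strata:
            theta = theta_map.get((name, stratum), 0.0)
            se_G = np.full(J, _stratum_se(se_all, stratum))
            alpha = pleiotropy_mean + pleiotropy_sd * rng_values.standard_normal(J)
            Gamma_hat = theta * gamma_ref + alpha + se_G * rng_values.standard_normal(J)
            n_tot = {"all": N_OUTCOME_ALL, "male": N_OUTCOME_MALE, "female": N_OUTCOME_FEMALE}[stratum]
            table = _table(snp_meta, Gamma_hat, se_G, n_tot)
            ops = ["none"] * J
            if allele_scramble:
                table, ops = _scramble_table(table, rng_scramble)
            outcome_tables[(name, stratum)] = table
            cells[f"{name}|{stratum}"] = {
                "theta": theta,
                "alpha": alpha.tolist(),
                "se_Gamma": se_G.tolist(),
                "scramble_ops": ops,
            }

    manifest = {
        "seed": int(seed),
        "snp_meta": [list(m) for m in snp_meta],
        "gamma_ref": gamma_ref.tolist(),
        "per_snp_F": F.tolist(),
        "f_range": list(f_range),
        "pleiotropy_mean": pleiotropy_mean,
        "pleiotropy_sd": pleiotropy_sd,
        "allele_scramble": allele_scramble,
        "theta_map": {f"{k[0]}|{k[1]}": v for k, v in theta_map.items()},
        "exposures": exposure_truth,
        "cells": cells,
    }
    return SyntheticStudy(
        exposures={name: direction for name, (direction, _) in exposures.items()},
        snp_filter=[m[0] for m in snp_meta],
        exposure_tables=exposure_tables,
        outcome_tables=outcome_tables,
        outcome_info=outcome_info,
        manifest=manifest,
    )


def study_from_manifest(manifest: dict) -> SyntheticStudy:
    """Regenerate a study from its manifest (same seed, same bytes)."""
    theta_map = {tuple(k.split("|")): v for k, v in manifest["theta_map"].items()}
    outcomes: dict[str, tuple[int, bool]] = {}
    for key in manifest["cells"]:
        name, stratum = key.split("|")
        n_cases, has_strata = outcomes.get(name, (DEFAULT_OUTCOMES.get(name, (1000, False))[0], False))
        outcomes[name] = (n_cases, has_strata or stratum != "all")
    exposures = {
        name: (truth["scale"] > 0, truth["scale"])
        for name, truth in manifest["exposures"].items()
    }
    return simulate_study(
        seed=manifest["seed"],
        theta_map=theta_map,
        exposures=exposures,
        outcomes=outcomes,
        gamma_ref=np.asarray(manifest["gamma_ref"]),
        snp_meta=[tuple(m) for m in manifest["snp_meta"]],
        pleiotropy_mean=manifest["pleiotropy_mean"],
        pleiotropy_sd=manifest["pleiotropy_sd"],
        allele_scramble=manifest["allele_scramble"],
        f_range=tuple(manifest["f_range"]),
    )


def fixture_iron_study(allele_scramble: bool = False) -> SyntheticStudy:
    """The packaged 3-SNP, 4-exposure, 12-outcome study with a pinned seed.

    Generated deterministically at call time (no bundled data, no network):
    strong instruments (per-SNP F well above 10), outcome betas of order
    1e-4..1e-2, a positive venous effect in both sexes and a male-driven
    protective arterial effect. All values are synthetic stand-ins.
    """
    return simulate_study(
        seed=FIXTURE_SEED,
        theta_map=dict(FIXTURE_THETA),
        allele_scramble=allele_scramble,
        f_range=(200.0, 2000.0),
    )
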