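"""Synthetic dialysis-release curves and HPLC encapsulation batches.

The release generator simulates the dialysis-membrane sink assay exactly:
between sample times the cumulative released mass follows the biexponential
law; at each sample time one aliquot (default 1 mL of a 14 mL bath) is
withdrawn — its drug mass permanently leaves the system — and replaced with
blank buffer.  The HPLC generator draws per-batch encapsulation-efficiency
truths and emits internal-standard calibration points plus each batch's
unknown peak-area ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from imequant.release import BiexpParams, DEFAULT_BIEXP_PARAMS, eval_release_model

__all__ = [
    "ReleaseTruth",
    "HplcBatchConfig",
    "HplcBatch",
    "default_release_truth",
    "gen_release",
    "gen_hplc_batches",
]


@dataclass
class ReleaseTruth:
    """Ground-truth release kinetics and assay geometry."""

    f_burst: float = DEFAULT_BIEXP_PARAMS.f_burst
    k_burst: float = DEFAULT_BIEXP_PARAMS.k_burst  # 1/day
    k_sustained: float = DEFAULT_BIEXP_PARAMS.k_sustained  # 1/day
    loaded_mass: float = 2000.0  # ug
    bath_volume: float = 14.0  # mL
    aliquot_volume: float = 1.0  # mL
    sample_times: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.25, 0.5, 1, 2, 3, 5, 7, 10, 14, 18, 21, 24], dtype=float
        )
    )  # days
    measurement_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if not 0.0 <= self.f_burst <= 1.0:
            raise ValueError("f_burst must lie in [0, 1]")
        if self.k_burst <= 0 or self.k_sustained <= 0:
            raise ValueError("rate constants must be positive")
        if self.aliquot_volume >= self.bath_volume:
            raise ValueError("aliquot volume must be smaller than the bath")
        if len(self.sample_times) and np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.sample_times < 0):
            raise ValueError("sample times must be non-negative")

    @property
    def params(self) -> BiexpParams:
        return BiexpParams(self.f_burst, self.k_burst, self.k_sustained)


def default_release_truth(seed: int = 0, **overrides) -> ReleaseTruth:
    return ReleaseTruth(seed=seed, **overrides)


@dataclass
class ReleaseSimResult:
    table: pd.DataFrame  # t_days, conc_ug_per_ml (measured), conc_true
    true_bath_conc: np.ndarray
    withdrawn_mass: np.ndarray  # ug removed at each sampling
    mass_balance_error: float  # max relative conservation violation


def gen_release(truth: ReleaseTruth) -> ReleaseSimResult:
    """Simulate the sampled dialysis sink and report aliquot concentrations.

    Conservation (withdrawn + bath + unreleased = loaded) holds to machine
    precision at every step and is reported for auditing.
    """
    rng = np.random.default_rng(truth.seed)
    released = eval_release_model(truth.params, truth.sample_times) * truth.loaded_mass
    n = len(truth.sample_times)
    conc = np.zeros(n)
    withdrawn = np.zeros(n)
    removed_total = 0.0
    err = 0.0
    for i in range(n):
        bath_mass = released[i] - removed_total
        conc[i] = bath_mass / truth.bath_volume
        withdrawn[i] = conc[i] * truth.aliquot_volume
        removed_total += withdrawn[i]
        bath_after = bath_mass - withdrawn[i]
        unreleased = truth.loaded_mass - released[i]
        balance = removed_total + bath_after + unreleased
        err = max(err, abs(balance - truth.loaded_mass) / truth.loaded_mass)
    if truth.measurement_cv > 0:
        sigma_log = np.sqrt(np.log(1 + truth.measurement_cv**2))
        noise = rng.lognormal(mean=-sigma_log**2 / 2, sigma=sigma_log, size=n)
    else:
        noise = np.ones(n)
    table = pd.DataFrame(
        {
            "t_days": truth.sample_times,
            "conc_ug_per_ml": conc * noise,
            "conc_true": conc,
        }
    )
    return ReleaseSimResult(table=table, true_bath_conc=conc, withdrawn_mass=withdrawn,
                            mass_balance_error=err)


@dataclass
class HplcBatchConfig:
    n_batches: int = 7
    total_drug_mg: float = 4.0
    true_ee_mean: float = 78.7  # %
    true_ee_sd: float = 5.5  # %
    #: analyte/internal-standard concentration ratios of the calibration standards
    standards: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.25, 0.5, 1.0, 1.5, 2.0], dtype=float)
    )
    response_slope: float = 0.85  # detector response: area ratio per conc ratio
    response_intercept: float = 0.01
    internal_standard_conc: float = 100.0  # ug/mL
    sample_volume_ml: float = 20.0  # the unencapsulated fraction is assayed in this volume
    area_noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.standards = np.asarray(self.standards, dtype=float)
        if not 0 <= self.true_ee_mean <= 100:
            raise ValueError("EE mean must lie in [0, 100]%")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")
        # Standards must bracket the largest possible unknown (EE = 0).
        max_ratio = (self.total_drug_mg * 1000 / self.sample_volume_ml
                     / self.internal_standard_conc)
        if self.standards.max() < max_ratio * 0.05:
            raise ValueError("standards grid does not span plausible unknowns")


@dataclass
class HplcBatch:
    batch_id: int
    true_ee_percent: float
    true_unencapsulated_mg: float
    standards: pd.DataFrame  # conc_ratio, area_ratio
    unknown_area_ratio: float


def gen_hplc_batches(config: HplcBatchConfig) -> list[HplcBatch]:
    """Simulate one manufacturing campaign's HPLC quantification inputs.

    Per batch: a true EE from the configured (truncated) normal, the implied
    unencapsulated drug mass in the assay volume, noiseless-linear detector
    response perturbed by multiplicative area noise.
    """
    rng = np.random.default_rng(config.seed)
    batches = []
    for b in range(config.n_batches):
        ee = float(np.clip(rng.normal(config.true_ee_mean, config.true_ee_sd), 0.0, 100.0))
        unencap_mg = config.total_drug_mg * (1 - ee / 100.0)
        unknown_conc = unencap_mg * 1000.0 / config.sample_volume_ml  # ug/mL
        unknown_ratio_true = unknown_conc / config.internal_standard_conc

        def areas(conc_ratios: np.ndarray) -> np.ndarray:
            ideal = config.response_slope * conc_ratios + config.response_intercept
            if config.area_noise_cv > 0:
                return ideal * rng.lognormal(
                    -config.area_noise_cv**2 / 2, config.area_noise_cv, size=np.shape(conc_ratios)
                )
            return ideal

        std = pd.DataFrame(
            {"conc_ratio": config.standards, "area_ratio": areas(config.standards)}
        )
        batches.append(
            HplcBatch(
                batch_id=b,
                true_ee_percent=ee,
                true_unencapsulated_mg=unencap_mg,
                standards=std,
                unknown_area_ratio=float(areas(np.array(unknown_ratio_true))),
            )
        )
    return batches
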