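"""Synthetic cytokine-panel generator.

Emulates the statistical structure the downstream analysis assumes: a
32-analyte multiplex bead-array panel measured in technical triplicate on a
2×2 design (APOE3/APOE4 genotype × vehicle/Aβ treatment) with ~10 samples per
cell, group-dependent mean shifts on a subset of informative analytes,
block-correlated analytes, occasional gross replicate outliers, Poisson bead
counts, and a noisy sparse linear map from analytes to a continuous metabolic
response (basal oxygen consumption rate semantics).

Fluorescence values are generated log-normal — bead-array intensities are
positive and right-skewed — and all group effects are applied on the log
scale, so a planted ``effect_size`` of d is a standardized mean shift of d
(in within-group SD units) between the designated groups on the log scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .panel import GENOTYPES, TREATMENTS, PanelDataset


class ConfigError(ValueError):
    """Raised when a SyntheticConfig field is invalid; names the field."""


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of the synthetic panel generator.

    ``effect_size`` is the standardized between-group mean shift (within-group
    SD units, applied on the log scale); the first half of the informative
    analytes carry the genotype contrast (APOE3 higher), the second half the
    treatment contrast (Aβ higher). ``outlier_scale`` displaces one replicate
    of an affected triplicate by that many replicate SDs. Identical config and
    seed give bit-identical output.
    """

    n_per_group: int = 10
    n_analytes: int = 32
    n_informative: int | None = None  # default: min(8, n_analytes)
    effect_size: float = 1.0
    block_size: int = 4
    block_correlation: float = 0.3
    between_sample_sd: float = 0.4
    n_replicates: int = 3
    outlier_rate: float = 0.02
    outlier_scale: float = 10.0
    replicate_cv: float = 0.05
    bead_count_mean: float = 70.0
    zero_inflation_rate: float = 0.0
    n_zero_inflated: int = 0
    response_coefficients: dict[int, float] | None = None
    response_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_per_group": self.n_per_group,
            "n_analytes": self.n_analytes,
            "block_size": self.block_size,
            "n_replicates": self.n_replicates,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if not 0 <= self.resolved_n_informative() <= self.n_analytes:
            raise ConfigError("n_informative must satisfy 0 <= n_informative <= n_analytes")
        if not 0 <= self.n_zero_inflated <= self.n_analytes:
            raise ConfigError("n_zero_inflated must satisfy 0 <= n_zero_inflated <= n_analytes")
        for name in ("outlier_rate", "zero_inflation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ConfigError("block_correlation must lie in [0, 1)")
        positive = {
            "between_sample_sd": self.between_sample_sd,
            "bead_count_mean": self.bead_count_mean,
            "outlier_scale": self.outlier_scale,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v!r}")
        for name in ("effect_size", "replicate_cv", "response_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.response_coefficients is not None:
            for j in self.response_coefficients:
                if not 0 <= int(j) < self.n_analytes:
                    raise ConfigError(
                        f"response_coefficients index {j} outside 0..{self.n_analytes - 1}"
                    )

    def resolved_n_informative(self) -> int:
        if self.n_informative is None:
            return min(8, self.n_analytes)
        return self.n_informative

    def coefficient_vector(self) -> np.ndarray:
        beta = np.zeros(self.n_analytes)
        if self.response_coefficients:
            for j, v in self.response_coefficients.items():
                beta[int(j)] = float(v)
        return beta


def _analyte_names(m: int) -> list[str]:
    return [f"CYT{j + 1:02d}" for j in range(m)]


def generate_panel(config: SyntheticConfig) -> PanelDataset:
    """Draw one replicate-level panel dataset from the generator model.

    The returned panel's ``truth`` records the latent per-sample log values,
    which analytes are informative for which contrast, and every planted
    outlier (at most one per triplicate) and structural zero.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[0])

    m, k = config.n_analytes, config.resolved_n_informative()
    n = 4 * config.n_per_group
    genos = np.repeat([g for g in GENOTYPES for _ in TREATMENTS], config.n_per_group)
    treats = np.repeat(list(TREATMENTS) * 2, config.n_per_group)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    samples = pd.DataFrame(
        {"genotype": genos, "treatment": treats}, index=pd.Index(sample_ids, name="sample_id")
    )

    base_log = rng.uniform(np.log(10.0), np.log(5000.0), size=m)
    k_geno = (k + 1) // 2
    geno_informative = list(range(k_geno))
    treat_informative = list(range(k_geno, k))

    sigma = config.between_sample_sd
    delta = config.effect_size * sigma
    shift = np.zeros((n, m))
    shift[np.ix_(genos == "APOE3", geno_informative)] += delta
    shift[np.ix_(treats == "abeta", treat_informative)] += delta

    # Block factor model: corr(z_j, z_j') = block_correlation within a block.
    rho = config.block_correlation
    n_blocks = -(-m // config.block_size)
    factors = rng.standard_normal((n, n_blocks))
    noise = rng.standard_normal((n, m))
    block_of = np.arange(m) // config.block_size
    z = np.sqrt(rho) * factors[:, block_of] + np.sqrt(1.0 - rho) * noise
    log_values = base_log + shift + sigma * z
    true_values = np.exp(log_values)

    # Technical replicates: multiplicative lognormal noise with exact CV.
    cv = config.replicate_cv
    sigma_rep = np.sqrt(np.log1p(cv * cv))
    reps = true_values[:, :, None] * np.exp(
        rng.normal(0.0, sigma_rep, size=(n, m, config.n_replicates))
    )

    # Planted gross outliers: at most one replicate per triplicate, displaced
    # additively by outlier_scale replicate SDs (sign flipped if it would go
    # negative).
    outliers: list[dict] = []
    planted = rng.random((n, m)) < config.outlier_rate
    which = rng.integers(0, config.n_replicates, size=(n, m))
    signs = rng.choice([-1.0, 1.0], size=(n, m))
    analytes = _analyte_names(m)
    sd_rep = cv * true_values
    for i, j in zip(*np.nonzero(planted)):
        r = which[i, j]
        disp = signs[i, j] * config.outlier_scale * sd_rep[i, j]
        if reps[i, j, r] + disp <= 0:
            disp = -disp
        reps[i, j, r] += disp
        outliers.append(
            {
                "sample_id": sample_ids[i],
                "analyte": analytes[j],
                "replicate": int(r),
                "displacement": float(disp),
            }
        )

    # Optional zero inflation on the trailing non-informative analytes, to
    # exercise the low-prevalence (>25% non-zero) filter downstream.
    zero_cells: list[dict] = []
    zi_analytes = list(range(m - config.n_zero_inflated, m)) if config.n_zero_inflated else []
    if zi_analytes and config.zero_inflation_rate > 0:
        zero_mask = rng.random((n, len(zi_analytes))) < config.zero_inflation_rate
        for i, jj in zip(*np.nonzero(zero_mask)):
            j = zi_analytes[jj]
            reps[i, j, :] = 0.0
            zero_cells.append({"sample_id": sample_ids[i], "analyte": analytes[j]})

    beads = rng.poisson(config.bead_count_mean, size=reps.shape).astype(float)

    truth = {
        "scale": "log",
        "log_values": log_values,
        "base_log_means": base_log,
        "genotype_informative": [analytes[j] for j in geno_informative],
        "treatment_informative": [analytes[j] for j in treat_informative],
        "log_effect": float(delta),
        "effect_size": float(config.effect_size),
        "outliers": outliers,
        "zero_cells": zero_cells,
        "config": dataclasses.asdict(config),
    }
    return PanelDataset(
        samples=samples, analytes=analytes, values=reps, bead_counts=beads, truth=truth
    )


def generate_response(panel: PanelDataset, config: SyntheticConfig) -> PanelDataset:
    """Attach a continuous response: sparse linear map of analytes plus noise.

    The response is ``beta · s_i + eps_i`` where ``s_i`` are the per-sample
    true analyte values standardized across samples (the latent log values
    for synthetic panels; log replicate means otherwise) and
    ``eps ~ N(0, response_noise_sd)``. Coefficients and the noiseless signal
    are stored in ``truth`` so construction R² is recoverable.
    """
    config.validate()
    beta = config.coefficient_vector()
    if len(beta) != panel.n_analytes:
        raise ConfigError(
            f"response_coefficients cover {len(beta)} analytes but panel has {panel.n_analytes}"
        )
    if panel.truth is not None and "log_values" in panel.truth:
        latent = np.asarray(panel.truth["log_values"], dtype=float)
    else:
        with np.errstate(divide="ignore"):
            latent = np.log(np.nanmean(panel.values, axis=2))
    sd = latent.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    s = (latent - latent.mean(axis=0)) / sd
    signal = s @ beta

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    response = signal + rng.normal(0.0, config.response_noise_sd, size=len(signal))

    samples = panel.samples.copy()
    samples["response"] = response
    truth = dict(panel.truth or {})
    truth["response_coefficients"] = beta
    truth["response_signal"] = signal
    truth["response_noise_sd"] = float(config.response_noise_sd)
    return dataclasses.replace(panel, samples=samples, truth=truth)
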