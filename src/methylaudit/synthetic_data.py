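"""Synthetic beta-matrix generator with complete truth tables.

Plants three probe classes:

* **snp** — a per-probe D-allele frequency drawn uniformly from
  ``maf_range``; per-sample genotypes drawn from Hardy-Weinberg proportions;
  betas centered on (mu_CC, mu_CD, mu_DD), by default (0.97, 0.50, 0.03) —
  the tri-modal, half-signal-loss pattern of a CpG-destroying polymorphism
  at a heavily methylated site.
* **background** — no genotype structure; a per-probe baseline mean drawn
  from a high (~0.9) / low (~0.1) / mid (~0.5) mixture.
* **trait** — one probe labeled cg05575921 whose mean depends on a per-sample
  smoking label.

Noise is clipped Normal per cell (a stand-in for array chemistry, not a
claim about it). Identical config + seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_methylation import BetaMatrix
from .phi_traits import SMOKING_PROBE_ID

PROBE_CLASS_SNP = "snp"
PROBE_CLASS_BACKGROUND = "background"
PROBE_CLASS_TRAIT = "trait"

_GENOTYPES = np.array(["CC", "CD", "DD"])

# Background baseline mixture: mostly near-fully (un)methylated sites, some
# intermediate, mirroring the overall 450K beta landscape.
_BACKGROUND_MODES = np.array([0.9, 0.1, 0.5])
_BACKGROUND_WEIGHTS = np.array([0.45, 0.45, 0.10])
_BACKGROUND_MODE_SD = 0.04


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters for :func:`simulate_dataset`."""

    n_samples: int = 111
    n_snp_probes: int = 50
    n_background_probes: int = 500
    maf_range: tuple[float, float] = (0.15, 0.5)
    genotype_means: tuple[float, float, float] = (0.97, 0.50, 0.03)
    beta_sd: float = 0.03
    missing_rate: float = 0.0
    smoking_prevalence: float = 0.5
    smoking_means: tuple[float, float] = (0.85, 0.45)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.n_snp_probes < 0:
            raise ConfigurationError("n_snp_probes must be >= 0")
        if self.n_background_probes < 0:
            raise ConfigurationError("n_background_probes must be >= 0")
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise ConfigurationError(
                f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}"
            )
        mu_cc, mu_cd, mu_dd = self.genotype_means
        if not mu_dd < mu_cd < mu_cc:
            raise ConfigurationError(
                f"genotype_means must satisfy mu_DD < mu_CD < mu_CC, "
                f"got {self.genotype_means}"
            )
        if self.beta_sd <= 0:
            raise ConfigurationError(f"beta_sd must be > 0, got {self.beta_sd}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError(
                f"missing_rate must lie in [0, 1), got {self.missing_rate}"
            )
        if not 0.0 <= self.smoking_prevalence <= 1.0:
            raise ConfigurationError(
                f"smoking_prevalence must lie in [0, 1], got {self.smoking_prevalence}"
            )


@dataclass
class TruthTables:
    """Ground truth emitted alongside a simulated beta matrix.

    ``probes``: probe_id, probe_class, true_maf (NaN for non-snp probes).
    ``genotypes``: snp probes x samples, true genotype strings.
    ``samples``: sample_id, smoker (bool).
    ``background_means``: per-background-probe baseline mean (a probe
    property, reused when re-measuring the same individuals).
    """

    probes: pd.DataFrame
    genotypes: pd.DataFrame
    samples: pd.DataFrame
    background_means: pd.Series
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(n)]


def _draw_genotypes(rng: np.random.Generator, mafs: np.ndarray, n_samples: int):
    """HWE genotype draw: rows = snp probes, columns = samples."""
    f_d = mafs[:, None]
    f_c = 1.0 - f_d
    u = rng.random((len(mafs), n_samples))
    geno = np.full((len(mafs), n_samples), 2, dtype=np.int8)  # DD
    geno[u < f_c**2 + 2 * f_c * f_d] = 1  # CD
    geno[u < f_c**2] = 0  # CC
    return geno


def _genotype_betas(
    rng: np.random.Generator, geno: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    means = np.asarray(config.genotype_means)[geno]
    return np.clip(rng.normal(means, config.beta_sd), 0.0, 1.0)


def simulate_dataset(config: SimulationConfig) -> tuple[BetaMatrix, TruthTables]:
    """Generate a beta matrix plus full truth tables from one seed."""
    rng = np.random.default_rng(config.seed)
    sample_ids = _sample_ids(config.n_samples)
    smokers = rng.random(config.n_samples) < config.smoking_prevalence

    snp_ids = [f"sim_snp_{i + 1:05d}" for i in range(config.n_snp_probes)]
    bg_ids = [f"sim_bg_{i + 1:05d}" for i in range(config.n_background_probes)]

    mafs = rng.uniform(*config.maf_range, size=config.n_snp_probes)
    geno = _draw_genotypes(rng, mafs, config.n_samples)
    snp_betas = _genotype_betas(rng, geno, config)

    modes = rng.choice(
        _BACKGROUND_MODES, size=config.n_background_probes, p=_BACKGROUND_WEIGHTS
    )
    bg_means = np.clip(
        rng.normal(modes, _BACKGROUND_MODE_SD), 0.02, 0.98
    )
    bg_betas = np.clip(
        rng.normal(
            bg_means[:, None], config.beta_sd, (config.n_background_probes, config.n_samples)
        ),
        0.0,
        1.0,
    )

    trait_means = np.where(smokers, config.smoking_means[1], config.smoking_means[0])
    trait_betas = np.clip(
        rng.normal(trait_means, config.beta_sd), 0.0, 1.0
    )[None, :]

    values = np.vstack([snp_betas, bg_betas, trait_betas])
    probe_ids = snp_ids + bg_ids + [SMOKING_PROBE_ID]
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = values.copy()
        values[mask] = np.nan

    matrix = BetaMatrix(
        pd.DataFrame(
            values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids
        )
    )
    probes = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "probe_class": (
                [PROBE_CLASS_SNP] * len(snp_ids)
                + [PROBE_CLASS_BACKGROUND] * len(bg_ids)
                + [PROBE_CLASS_TRAIT]
            ),
            "true_maf": np.concatenate(
                [mafs, np.full(len(bg_ids) + 1, np.nan)]
            ),
        }
    )
    genotypes = pd.DataFrame(
        _GENOTYPES[geno], index=pd.Index(snp_ids, name="probe_id"), columns=sample_ids
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "smoker": smokers})
    truth = TruthTables(
        probes=probes,
        genotypes=genotypes,
        samples=samples,
        background_means=pd.Series(bg_means, index=bg_ids),
        config=config,
    )
    return matrix, truth


def resample_individuals(
    truth: TruthTables,
    config: SimulationConfig | None = None,
    per_call_error: float = 0.0,
    seed: int | None = None,
) -> tuple[BetaMatrix, TruthTables]:
    """Re-measure the same individuals: same genotypes, fresh noise.

    A fraction ``per_call_error`` of (snp probe, sample) cells is flipped to
    a random other genotype before beta generation, emulating array call
    errors. ``seed`` defaults to ``config.seed + 1`` so the replicate
    differs from the original but stays deterministic.
    """
    if config is None:
        config = truth.config
    if not 0.0 <= per_call_error < 1.0:
        raise ConfigurationError(
            f"per_call_error must lie in [0, 1), got {per_call_error}"
        )
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    sample_ids = list(truth.samples["sample_id"])
    smokers = truth.samples["smoker"].to_numpy()

    geno_codes = np.zeros(truth.genotypes.shape, dtype=np.int8)
    arr = truth.genotypes.to_numpy(dtype=object)
    geno_codes[arr == "CD"] = 1
    geno_codes[arr == "DD"] = 2
    geno = geno_codes.copy()
    if per_call_error > 0 and geno.size:
        flip = rng.random(geno.shape) < per_call_error
        shift = rng.integers(1, 3, size=geno.shape)  # +1 or +2 mod 3: never identity
        geno[flip] = (geno[flip] + shift[flip]) % 3

    snp_betas = _genotype_betas(rng, geno, config)

    bg_means = truth.background_means.to_numpy()
    bg_betas = np.clip(
        rng.normal(bg_means[:, None], config.beta_sd, (len(bg_means), len(sample_ids))),
        0.0,
        1.0,
    )
    trait_means = np.where(smokers, config.smoking_means[1], config.smoking_means[0])
    trait_betas = np.clip(rng.normal(trait_means, config.beta_sd), 0.0, 1.0)[None, :]

    values = np.vstack([snp_betas, bg_betas, trait_betas])
    probe_ids = (
        list(truth.genotypes.index)
        + list(truth.background_means.index)
        + [SMOKING_PROBE_ID]
    )
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = np.nan

    matrix = BetaMatrix(
        pd.DataFrame(
            values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids
        )
    )
    new_truth = TruthTables(
        probes=truth.probes.copy(),
        genotypes=pd.DataFrame(
            _GENOTYPES[geno], index=truth.genotypes.index, columns=sample_ids
        ),
        samples=truth.samples.copy(),
        background_means=truth.background_means.copy(),
        config=config,
    )
    return matrix, new_truth


def write_truth_tables(truth: TruthTables, out_prefix: str) -> list[str]:
    """Write truth tables as TSVs next to the simulated matrix."""
    paths = []
    for name, frame in (
        ("probes", truth.probes),
        ("genotypes", truth.genotypes.reset_index()),
        ("samples", truth.samples),
    ):
        path = f"{out_prefix}_truth_{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, na_rep="NA")
        paths.append(path)
    return paths
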