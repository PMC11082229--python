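"""Seeded simulator of spike-in-style multi-view proteomics datasets.

The generator emulates a gold-standard spike-in experiment: a constant
background proteome with a fraction of proteins spiked at known ratios
between two groups. Each dataset exposes several correlated quantification
views (spectral-count-like, topN-like, LFQ-like, directLFQ-like) built from
one latent log2 abundance surface plus view-specific noise, with
intensity-dependent (MNAR) dropout calibrated to a target missing rate —
platform-typical rates are roughly 17% for label-free DDA, 3% for DIA and
0.2% for TMT.

Randomness: one master seed; each view and noise component draws from a
child generator derived by a fixed counter, so adding a view never perturbs
the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import ContrastDesign, ExpressionMatrix, GroundTruth, MISSING

__all__ = [
    "ViewConfig", "SimulationConfig", "SpikeInDataset", "simulate_spikein",
    "calibrate_dropout", "simulate_collection",
    "PLATFORM_MISSING_RATES",
]

#: Platform-typical average missing rates used as simulation defaults.
PLATFORM_MISSING_RATES = {"DDA": 0.17, "DIA": 0.03, "TMT": 0.002}


@dataclass(frozen=True)
class ViewConfig:
    """One quantification view of the simulated dataset."""

    matrix_type: str
    noise_sd: float = 0.075     # view-specific log2 noise
    count_link: bool = False    # Poisson counts instead of intensities
    missing_rate: float = 0.17  # target MNAR dropout rate


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the spike-in generator.

    Defaults describe a label-free DDA-like two-group experiment: ~2000
    background proteins of which 10% are spiked at |log2FC| = 1 with random
    sign, base log2 abundance N(25, 3), technical-replicate noise sd 0.25,
    5 replicates per group, and the platform-typical 17% MNAR missingness.
    """

    n_proteins: int = 2000
    de_fraction: float = 0.1
    log2fc_magnitude: float = 1.0
    log2fc_sd: float = 0.0          # 0 = point mass at the magnitude
    base_mean: float = 25.0
    base_sd: float = 3.0
    replicate_sd: float = 0.25
    n_replicates: int = 5
    mnar_steepness: float = 0.5     # logistic scale on the log2 axis
    setting: str = "generic"
    views: tuple[ViewConfig, ...] = (
        ViewConfig("counts", noise_sd=0.075, count_link=True, missing_rate=0.17),
        ViewConfig("top0", noise_sd=0.15, missing_rate=0.17),
        ViewConfig("top3", noise_sd=0.12, missing_rate=0.17),
        ViewConfig("LFQ", noise_sd=0.075, missing_rate=0.17),
        ViewConfig("dlfq", noise_sd=0.075, missing_rate=0.17),
    )

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction < 1:
            raise ValueError("de_fraction must lie in [0, 1)")
        if self.base_sd <= 0 or self.replicate_sd <= 0 or self.mnar_steepness <= 0:
            raise ValueError("standard deviations and steepness must be positive")
        for v in self.views:
            if not 0 <= v.missing_rate < 1:
                raise ValueError("target missing rate must lie in [0, 1)")


@dataclass
class SpikeInDataset:
    views: dict[str, ExpressionMatrix]
    truth: GroundTruth
    design: ContrastDesign
    config: SimulationConfig
    seed: int


def calibrate_dropout(
    latent: np.ndarray, target_rate: float, steepness: float
) -> float:
    """Find the logistic dropout midpoint tau giving the target missing rate.

    P(missing | x) = 1 / (1 + exp((x - tau) / s)); the expected rate over
    the supplied latent values is matched to within 1e-4 by bisection.
    Returns -inf (no dropout) for target 0.
    """
    if not 0 <= target_rate <= 0.95:
        raise ValueError("target rate must lie in [0, 0.95]")
    if target_rate == 0:
        return -math.inf
    x = np.asarray(latent, float).ravel()

    def expected(tau: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp((x - tau) / steepness))))

    lo = float(x.min()) - 60.0 * steepness
    hi = float(x.max()) + 60.0 * steepness
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        rate = expected(mid)
        if abs(rate - target_rate) < 1e-4:
            return mid
        if rate < target_rate:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"dropout calibration did not converge for target {target_rate}"
    )


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    # counter-based derivation: independent of how many streams exist
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, stream)))


def simulate_spikein(config: SimulationConfig, seed: int) -> SpikeInDataset:
    """Generate one two-group spike-in dataset with ground truth."""
    n, r = config.n_proteins, config.n_replicates
    protein_ids = [f"P{i:05d}" for i in range(n)]
    sample_ids = [f"A{k + 1}" for k in range(r)] + [f"B{k + 1}" for k in range(r)]
    group_of = {s: s[0] for s in sample_ids}
    design = ContrastDesign(group_of=group_of, contrast=("A", "B"))

    rng = _child_rng(seed, 0)
    base = rng.normal(config.base_mean, config.base_sd, size=n)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    magnitude = np.abs(
        rng.normal(config.log2fc_magnitude, config.log2fc_sd, size=n)
        if config.log2fc_sd > 0
        else np.full(n, config.log2fc_magnitude)
    )
    signs = rng.choice([-1.0, 1.0], size=n)
    true_lfc = np.where(is_de, magnitude * signs, 0.0)

    # latent log2 surface: base + spike shift in group A + replicate noise
    rep_rng = _child_rng(seed, 1)
    latent = np.tile(base[:, None], (1, 2 * r)).astype(float)
    latent[:, :r] += true_lfc[:, None]
    latent += rep_rng.normal(0.0, config.replicate_sd, size=latent.shape)

    views: dict[str, ExpressionMatrix] = {}
    for v_i, view in enumerate(config.views):
        view_rng = _child_rng(seed, 100 + v_i)
        surface = latent + view_rng.normal(0.0, view.noise_sd, size=latent.shape)
        tau = calibrate_dropout(surface, view.missing_rate, config.mnar_steepness)
        drop_p = 1.0 / (1.0 + np.exp((surface - tau) / config.mnar_steepness))
        dropped = view_rng.random(size=surface.shape) < drop_p
        if view.count_link:
            # scale so the mean simulated count is ~100
            lam = np.exp2(surface)
            lam *= 100.0 / lam.mean()
            values = view_rng.poisson(lam).astype(float)
        else:
            values = np.exp2(surface)
        values[dropped] = MISSING
        views[view.matrix_type] = ExpressionMatrix(
            protein_ids=list(protein_ids),
            sample_ids=list(sample_ids),
            values=values,
            scale="raw",
            matrix_type=view.matrix_type,
            setting=config.setting,
        )

    truth = GroundTruth(
        is_de={p: bool(is_de[i]) for i, p in enumerate(protein_ids)},
        true_log2fc={p: float(true_lfc[i]) for i, p in enumerate(protein_ids)},
    )
    return SpikeInDataset(views=views, truth=truth, design=design,
                          config=config, seed=seed)


def simulate_collection(
    n_datasets: int,
    config: SimulationConfig | None = None,
    noise_jitter: float = 0.3,
    lfc_jitter: float = 0.2,
    seed: int = 0,
) -> list[SpikeInDataset]:
    """A family of related datasets for leave-one-dataset-out validation.

    Each dataset shares the template configuration with its replicate noise
    and fold-change magnitude jittered multiplicatively, and draws from an
    independent child seed of the master seed.
    """
    if n_datasets < 3:
        raise ValueError("a collection needs >= 3 datasets")
    config = config or SimulationConfig()
    meta_rng = _child_rng(seed, 999)
    datasets = []
    for d in range(n_datasets):
        noise_factor = float(np.exp(meta_rng.normal(0.0, noise_jitter)))
        lfc_factor = float(np.exp(meta_rng.normal(0.0, lfc_jitter)))
        cfg = replace(
            config,
            replicate_sd=config.replicate_sd * noise_factor,
            log2fc_magnitude=config.log2fc_magnitude * lfc_factor,
        )
        child_seed = int(meta_rng.integers(0, 2**31 - 1))
        datasets.append(simulate_spikein(cfg, child_seed))
    return datasets
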