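"""Synthetic per-sample stress-strain records with the statistical
structure of the study's measurements.

Ground truth comes from the published best-in-class models of the eight
products (two-letter keys): tofurky (TF), plant-based sausage (PS), spam
turkey (ST), animal sausage (AS), animal hotdog (AH), plant-based hotdog
(PH), extrafirm tofu (ET) and firm tofu (FT). Each synthetic sample draws
its linear weights from a multiplicative lognormal scatter around the
preset (so weights stay non-negative), evaluates the closed-form stresses
on a dense control grid per mode, and adds i.i.d. Gaussian measurement
noise scaled to the sample's peak stress. With scatter and noise at zero
the records are exact closed-form curves.

The noiseless datasets built from the published two-term models double as
a *synthetic stand-in* for the study's processed curve table, whose
numeric values are not printed in the running text: every quantity the
pipeline derives from them reflects the published constitutive models, not
the original raw measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mechanics import ModelWeights, piola_stress_shear, piola_stress_uniaxial
from .preprocessing import (
    MODES,
    ProductDataset,
    RawTestRecord,
    process_product,
    write_records,
)

__all__ = [
    "PRODUCTS",
    "DEFAULT_LAMBDA_MAX",
    "GeneratorConfig",
    "presets",
    "generate_sample",
    "generate_dataset",
    "reference_dataset",
]

PRODUCTS = ("TF", "PS", "ST", "AS", "AH", "PH", "ET", "FT")

#: Published best-in-class two-term models (kPa weights, dimensionless exponents).
_TWO_TERM = {
    "TF": ({1: 12.27, 5: 20.94}, None),
    "PS": ({1: 6.56, 5: 9.34}, None),
    "ST": ({1: 11.33, 3: 51.77}, None),
    "AS": ({1: 3.63, 4: 11.85}, {4: 11.83}),
    "AH": ({1: 5.80, 7: 22.83}, None),
    "PH": ({1: 6.22, 3: 7.25}, None),
    "ET": ({1: 4.42}, None),
    "FT": ({1: 4.51}, None),
}

#: Published best-in-class one-term models.
_ONE_TERM = {
    "TF": ({5: 22.08}, None),
    "PS": ({5: 16.01}, None),
    "ST": ({2: 3.21}, {2: 3.92}),
    "AS": ({2: 0.42}, {2: 16.01}),
    "AH": ({2: 2.55}, {2: 2.59}),
    "PH": ({2: 2.61}, {2: 2.35}),
    "ET": ({1: 4.42}, None),
    "FT": ({1: 4.51}, None),
}

#: Hyperelastic tensile limits: tofurky and extrafirm tofu fail slightly
#: above 10% stretch, animal hotdog stretches to 35%, the rest to 15-20%.
DEFAULT_LAMBDA_MAX = {
    "TF": 1.12,
    "PS": 1.15,
    "ST": 1.15,
    "AS": 1.20,
    "AH": 1.35,
    "PH": 1.20,
    "ET": 1.12,
    "FT": 1.15,
}


def presets(kind: str = "two_term") -> dict[str, ModelWeights]:
    """Published ground-truth models per product.

    ``kind`` is ``"two_term"`` (default) or ``"one_term"``.
    """
    table = {"two_term": _TWO_TERM, "one_term": _ONE_TERM}.get(kind)
    if table is None:
        raise ValueError(f"unknown preset kind {kind!r}")
    return {pid: ModelWeights.from_terms(t, e) for pid, (t, e) in table.items()}


def preset_weights(product_id: str, kind: str = "two_term") -> ModelWeights:
    try:
        return presets(kind)[product_id]
    except KeyError:
        raise KeyError(f"unknown product id {product_id!r}; choose from {PRODUCTS}") from None


@dataclass
class GeneratorConfig:
    """Study-condition defaults: at least five samples per mode, mild
    sample-to-sample parameter scatter (10% lognormal SD on the linear
    weights) and 2% of-peak additive measurement noise."""

    product_id: str | None = None
    weights: ModelWeights | None = None
    n_samples: int = 5
    lambda_max: float | None = None
    sample_scatter: float = 0.10
    noise_sd: float = 0.02
    seed: int = 0
    n_dense: int = 101  # raw-record control points per mode

    def __post_init__(self) -> None:
        if self.weights is None:
            if self.product_id is None:
                raise ValueError("give a product_id or explicit weights")
            self.weights = preset_weights(self.product_id)
        if self.lambda_max is None:
            self.lambda_max = DEFAULT_LAMBDA_MAX.get(self.product_id or "", 1.15)
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.sample_scatter < 0 or self.noise_sd < 0:
            raise ValueError("scatter and noise must be non-negative")


def _dense_grid(mode: str, lambda_max: float, n: int) -> np.ndarray:
    if mode == "tension":
        return np.linspace(1.0, lambda_max, n)
    if mode == "compression":
        return np.linspace(1.0, 0.9, n)
    if mode == "shear":
        return np.linspace(0.0, 0.1, n)
    raise ValueError(f"unknown mode {mode!r}")


def generate_sample(
    cfg: GeneratorConfig, mode: str, rng: np.random.Generator, sample_id: str = "s0"
) -> RawTestRecord:
    """One synthetic test record.

    Per-sample linear weights are ``w * exp(scatter * z)`` with independent
    standard-normal z per term (exponents stay at the preset value); the
    closed-form stress on a dense grid gets additive Gaussian noise with SD
    ``noise_sd * max|stress|``; the reference point is forced back to zero
    stress.
    """
    base = cfg.weights
    z = rng.standard_normal(8)
    w_s = ModelWeights(w=base.w * np.exp(cfg.sample_scatter * z), wexp=base.wexp.copy())
    grid = _dense_grid(mode, cfg.lambda_max, cfg.n_dense)
    stress = (
        piola_stress_shear(w_s, grid) if mode == "shear" else piola_stress_uniaxial(w_s, grid)
    )
    if cfg.noise_sd > 0:
        stress = stress + rng.normal(0.0, cfg.noise_sd * np.max(np.abs(stress)), size=grid.size)
    stress[0] = 0.0
    return RawTestRecord(
        mode=mode,
        control=grid,
        stress=stress,
        sample_id=sample_id,
        product_id=cfg.product_id or "custom",
    )


def generate_dataset(
    cfg: GeneratorConfig, out_dir: str | Path | None = None
) -> tuple[ProductDataset, list[RawTestRecord], Path | None]:
    """Generate all samples for all three modes, run the preprocessing
    pipeline, and optionally write the raw CSV fixtures plus manifest."""
    rng = np.random.default_rng(cfg.seed)
    records = []
    for mode in MODES:
        for i in range(cfg.n_samples):
            records.append(generate_sample(cfg, mode, rng, sample_id=f"s{i}"))
    manifest = write_records(records, out_dir) if out_dir is not None else None
    ds = process_product(records, product_id=cfg.product_id or "custom", lambda_max=cfg.lambda_max)
    return ds, records, manifest


def reference_dataset(product_id: str, n_points: int = 21) -> ProductDataset:
    """Noiseless synthetic stand-in for a product's processed mean curves,
    generated from its published best-in-class two-term model (see module
    docstring). Deterministic; single exact closed-form sample per mode."""
    cfg = GeneratorConfig(product_id=product_id, n_samples=1, sample_scatter=0.0, noise_sd=0.0, seed=0)
    ds, _, _ = generate_dataset(cfg)
    return ds
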