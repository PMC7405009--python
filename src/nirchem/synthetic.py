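"""Synthetic FT-NIR spectra with the structure of a powdered-truffle study.

No spectra are deposited with the study this package models, so every
downstream stage is exercised on a generator that reproduces the *statistical*
features the analysis relies on:

* a wavenumber grid spanning 3950-11550 cm^-1;
* a baseline whose absorbance rises towards low wavenumbers;
* broad Gaussian overtone/combination bands whose amplitudes differ by
  species — in particular a protein band at 6318 cm^-1 whose class ordering
  follows reported soluble-protein contents (T. melanosporum lowest,
  T. magnatum highest);
* per-replicate multiplicative/additive scatter (particle-size effects of
  powders), inverted exactly by MSC;
* a high-variance additive offset confined to the > 9000 cm^-1 region for a
  fraction of samples (the reason that region is cut before MSC);
* iid Gaussian noise, and a small origin-specific perturbation on
  non-Italian T. magnatum samples for the origin-authentication scenario.

The generative model per replicate j of sample i is::

    x_ij(nu) = a_ij + b_ij * [ baseline(nu) + sum_k A_k m_k(class_i) G_k(nu)
                               + origin(nu) ]
               + offset_i * 1[nu > threshold] + eps(nu)

with b_ij = exp(N(0, s_b)), a_ij ~ N(0, s_a), eps iid N(0, noise_sd).
Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .spectra_io import SpectraSet, make_meta

WHITE_SPECIES = ("T. magnatum", "T. borchii")
BLACK_SPECIES = ("T. aestivum", "T. indicum", "T. melanosporum")


@dataclass
class BandSpec:
    """One Gaussian absorption band.

    ``class_multipliers`` scales ``base_amplitude`` per species label;
    unlisted labels default to 1.
    """

    centre: float
    width: float
    base_amplitude: float
    class_multipliers: dict = field(default_factory=dict)

    def amplitude(self, label: str) -> float:
        return self.base_amplitude * self.class_multipliers.get(label, 1.0)

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        return np.exp(-((wavenumbers - self.centre) ** 2) / (2 * self.width**2))


@dataclass
class SyntheticConfig:
    grid_min: float = 3950.0
    grid_max: float = 11550.0
    n_points: int = 3732
    classes: dict = field(default_factory=dict)  # label -> sample count
    replicates: int = 3
    bands: list = field(default_factory=list)
    baseline_intercept: float = 0.15
    baseline_slope: float = 0.45  # rise from grid_max down to grid_min
    scatter_slope_sd: float = 0.08  # sd of log b_ij
    scatter_offset_sd: float = 0.02  # sd of a_ij
    offset_threshold: float = 9000.0
    offset_fraction: float = 0.3  # fraction of samples with the offset
    offset_sd: float = 0.5
    noise_sd: float = 0.003
    origins: dict = field(default_factory=dict)  # label -> {origin: count}
    origin_effect: dict = field(default_factory=dict)  # origin -> BandSpec
    harvest_years: tuple = (2017, 2018, 2019, 2020)
    seed: int = 0

    def validate(self):
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.grid_min >= self.grid_max:
            raise ValueError("grid_min must be < grid_max")
        if any(c < 0 for c in self.classes.values()):
            raise ValueError("class counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def make_grid(cfg: SyntheticConfig) -> np.ndarray:
    """Equally spaced ascending axis from grid_min to grid_max inclusive."""
    cfg.validate()
    return np.linspace(cfg.grid_min, cfg.grid_max, cfg.n_points)


def default_truffle_config(seed: int = 0) -> SyntheticConfig:
    """The default study design: 75 samples, 5 species, triplicate spectra.

    Class sizes are 20 T. magnatum, 5 T. borchii, 10 T. melanosporum,
    29 T. aestivum, 11 T. indicum.  The protein band at 6318 cm^-1 carries
    multipliers proportional to soluble-protein contents 8.7 : 11 : 13 : 24
    (melanosporum : aestivum : borchii : magnatum), with T. indicum set equal
    to T. melanosporum there; the remaining bands carry smaller invented
    species contrasts so all five classes are separable.  T. magnatum is
    split 14 Italian / 6 non-Italian, and non-Italian samples carry a small
    extra band making origin authentication imperfect by design.
    """
    protein = {
        "T. melanosporum": 8.7 / 11,
        "T. aestivum": 1.0,
        "T. borchii": 13 / 11,
        "T. magnatum": 24 / 11,
        "T. indicum": 8.7 / 11,
    }
    bands = [
        # protein / amide region
        BandSpec(6667, 60, 0.30, {"T. magnatum": 1.25, "T. borchii": 1.15,
                                  "T. melanosporum": 0.90, "T. indicum": 0.97}),
        BandSpec(6318, 60, 0.15, dict(protein)),
        BandSpec(4687, 60, 0.25, {"T. magnatum": 1.15, "T. indicum": 1.15,
                                  "T. melanosporum": 0.95}),
        BandSpec(4859, 60, 0.20, {"T. borchii": 1.30, "T. aestivum": 1.05}),
        BandSpec(4600, 60, 0.20, {"T. magnatum": 1.10, "T. indicum": 0.85}),
        # carbohydrate CH2 doublet
        BandSpec(4338, 30, 0.40, {"T. melanosporum": 1.12, "T. indicum": 0.90,
                                  "T. magnatum": 0.85}),
        BandSpec(4257, 30, 0.35, {"T. melanosporum": 1.08, "T. borchii": 0.85}),
        # C-H first overtone doublet
        BandSpec(5760, 15, 0.18, {"T. aestivum": 1.10, "T. indicum": 1.20,
                                  "T. borchii": 0.90}),
        BandSpec(5742, 15, 0.15, {"T. magnatum": 0.92, "T. melanosporum": 1.05}),
    ]
    return SyntheticConfig(
        classes={
            "T. magnatum": 20,
            "T. borchii": 5,
            "T. melanosporum": 10,
            "T. aestivum": 29,
            "T. indicum": 11,
        },
        bands=bands,
        origins={
            "T. magnatum": {"Italy": 14, "Bulgaria": 2, "Croatia": 2, "Romania": 2},
            "T. aestivum": {"Romania": 15, "France": 4, "Italy": 3, "unknown": 7},
        },
        origin_effect={
            origin: BandSpec(5150, 30, 0.15)
            for origin in ("Bulgaria", "Croatia", "Romania")
        },
        seed=seed,
    )


def null_config(n_classes: int = 2, n_per_class: int = 20, seed: int = 0) -> SyntheticConfig:
    """Balanced classes with *no* class effect: every band multiplier is 1.

    Under this null any classifier's balanced accuracy should hover at
    1/n_classes; used to calibrate the evaluation machinery.
    """
    base = default_truffle_config(seed=seed)
    bands = [BandSpec(b.centre, b.width, b.base_amplitude) for b in base.bands]
    return SyntheticConfig(
        classes={f"class_{i + 1}": n_per_class for i in range(n_classes)},
        bands=bands,
        origins={},
        origin_effect={},
        seed=seed,
    )


def clean_spectrum(cfg: SyntheticConfig, label: str, origin: str = "unknown") -> np.ndarray:
    """Noise-free spectrum for one class (and origin) on the config grid."""
    nu = make_grid(cfg)
    span = cfg.grid_max - cfg.grid_min
    x = cfg.baseline_intercept + cfg.baseline_slope * (cfg.grid_max - nu) / span
    for band in cfg.bands:
        x = x + band.amplitude(label) * band.profile(nu)
    eff = cfg.origin_effect.get(origin)
    if eff is not None:
        x = x + eff.base_amplitude * eff.profile(nu)
    return x


def _assign_origins(cfg: SyntheticConfig, label: str, count: int) -> list[str]:
    plan = cfg.origins.get(label)
    if not plan:
        return ["unknown"] * count
    if sum(plan.values()) != count:
        raise ValueError(
            f"origin counts for {label} sum to {sum(plan.values())}, "
            f"but the class has {count} samples"
        )
    out = []
    for origin, n in plan.items():
        out.extend([origin] * n)
    return out


def generate(cfg: SyntheticConfig) -> tuple[SpectraSet, dict]:
    """Draw a full replicate-level SpectraSet plus ground truth.

    Returns the SpectraSet and a truth dict holding the grid, the per-class
    clean spectra and a per-replicate table of the scatter coefficients
    (a, b) and sample offsets.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    nu = make_grid(cfg)

    sample_ids, labels, origins, years = [], [], [], []
    i = 0
    for label, count in cfg.classes.items():
        class_origins = _assign_origins(cfg, label, count)
        for k in range(count):
            i += 1
            sample_ids.append(f"S{i:03d}")
            labels.append(label)
            origins.append(class_origins[k])
            years.append(cfg.harvest_years[i % len(cfg.harvest_years)])
    n_samples = len(sample_ids)

    n_offset = int(round(cfg.offset_fraction * n_samples))
    offset_samples = rng.choice(n_samples, size=n_offset, replace=False)
    offsets = np.zeros(n_samples)
    offsets[offset_samples] = np.abs(rng.normal(0.0, cfg.offset_sd, size=n_offset))
    offset_mask = (nu > cfg.offset_threshold).astype(float)

    clean_cache: dict[tuple, np.ndarray] = {}
    rows, truth_rows = [], []
    ids_rep, labels_rep, origins_rep, years_rep, reps = [], [], [], [], []
    for idx in range(n_samples):
        key = (labels[idx], origins[idx])
        if key not in clean_cache:
            clean_cache[key] = clean_spectrum(cfg, labels[idx], origins[idx])
        clean = clean_cache[key]
        for rep in range(1, cfg.replicates + 1):
            b = float(np.exp(rng.normal(0.0, cfg.scatter_slope_sd)))
            a = float(rng.normal(0.0, cfg.scatter_offset_sd))
            eps = rng.normal(0.0, cfg.noise_sd, size=nu.size) if cfg.noise_sd else 0.0
            rows.append(a + b * clean + offsets[idx] * offset_mask + eps)
            truth_rows.append(
                {
                    "sample_id": sample_ids[idx],
                    "replicate": rep,
                    "species": labels[idx],
                    "origin": origins[idx],
                    "a": a,
                    "b": b,
                    "offset": offsets[idx],
                }
            )
            ids_rep.append(sample_ids[idx])
            labels_rep.append(labels[idx])
            origins_rep.append(origins[idx])
            years_rep.append(years[idx])
            reps.append(rep)

    meta = make_meta(ids_rep, labels_rep, origins_rep, years_rep, reps)
    spectra = SpectraSet(wavenumbers=nu, absorbance=np.vstack(rows), meta=meta)
    truth = {
        "wavenumbers": nu,
        "clean_spectra": {f"{lab}|{org}": v for (lab, org), v in clean_cache.items()},
        "coefficients": pd.DataFrame(truth_rows),
        "config": asdict(cfg),
    }
    return spectra, truth
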