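"""Synthetic two-sowing-date trial generator.

Emulates the reference design — 156 wheat genotypes × 2 sowing-date
conditions (normal / terminal heat stress) × 2 years × 2 replicates — with
the linear structure the downstream ANOVA assumes:

    y_ijkl = mu_j + g_i + (g·sd)_ij + y_k + (sd·y)_jk + (g·y)_ik
             + (g·sd·y)_ijk + r_l(jk) + e_ijkl

where the stress-condition mean is mu_normal·(1 − stress_penalty) and every
random term is an independent zero-mean Gaussian with its configured
variance. Each term draws from its own seeded sub-stream, so changing one
variance (e.g. residual noise) never perturbs the realized genotype effects.

A truth sidecar records the realized per-genotype effects and the expected
YP/YS they imply, for parameter-recovery tests only; analysis code never
reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import LONG_COLUMNS, TrialDataset

_TERMS = ("G", "GxSD", "Y", "SDxY", "GxY", "GxSDxY", "rep", "block", "e")


@dataclass
class TraitSpec:
    """Mean/variance structure of one simulated trait."""
    mu_normal: float
    stress_penalty: float = 0.0
    var_G: float = 0.0
    var_GxSD: float = 0.0
    var_Y: float = 0.0
    var_SDxY: float = 0.0
    var_GxY: float = 0.0
    var_GxSDxY: float = 0.0
    var_rep: float = 0.0
    var_block: float = 0.0
    var_e: float = 0.0

    def validate(self) -> None:
        for name in self.__dataclass_fields__:
            if name.startswith("var_") and getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.stress_penalty < 1:
            raise ValueError("stress_penalty must be in [0, 1)")


@dataclass
class SyntheticConfig:
    n_genotypes: int = 156
    n_years: int = 2
    n_reps: int = 2
    yield_trait: TraitSpec = field(default_factory=lambda: TraitSpec(mu_normal=899.0))
    extra_traits: dict[str, TraitSpec] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genotypes, self.n_years, self.n_reps) < 1:
            raise ValueError("design counts must be >= 1")
        self.yield_trait.validate()
        for spec in self.extra_traits.values():
            spec.validate()


def paper_scale_config(seed: int = 0, n_genotypes: int = 156,
                       include_quality: bool = False) -> SyntheticConfig:
    """Defaults calibrated to the reference panel's grain-yield scale.

    Panel means 899 (normal) and ~674 g/m² (25% stress penalty); residual
    variance 2358 g²/m⁴ giving a ~6.2% CV at the pooled mean; genotype-level
    components sized so the between-genotype SD of condition means is
    ~115 g/m² (the printed normal/stress spreads, 129 and 100, bracket this
    — one homoscedastic component set cannot reproduce both).
    """
    gy = TraitSpec(mu_normal=899.0, stress_penalty=0.25,
                   var_G=6500.0, var_GxSD=3900.0,
                   var_Y=50.0, var_SDxY=100.0,
                   var_GxY=2100.0, var_GxSDxY=2400.0,
                   var_rep=25.0, var_e=2358.0)
    extra: dict[str, TraitSpec] = {}
    if include_quality:
        # quality traits: strong genotype signal, negligible sowing-date effect
        extra = {
            "PGP": TraitSpec(13.06, 0.01, var_G=0.17, var_GxSDxY=0.03, var_e=0.091),
            "ZSV": TraitSpec(32.47, 0.02, var_G=0.36, var_GxSDxY=0.11, var_e=0.26),
            "GH": TraitSpec(44.01, 0.025, var_G=1.6, var_GxSDxY=0.23, var_e=0.72),
        }
    return SyntheticConfig(n_genotypes=n_genotypes, yield_trait=gy,
                           extra_traits=extra, seed=seed)


def _simulate_trait(spec: TraitSpec, trait: str, n_g: int, n_y: int, n_r: int,
                    seed_seq: np.random.SeedSequence) -> tuple[pd.DataFrame, pd.DataFrame]:
    rngs = dict(zip(_TERMS, (np.random.default_rng(s) for s in seed_seq.spawn(len(_TERMS)))))

    def draw(term: str, var: float, shape) -> np.ndarray:
        if var == 0:
            return np.zeros(shape)
        return rngs[term].normal(0.0, np.sqrt(var), size=shape)

    mu = np.array([spec.mu_normal, spec.mu_normal * (1.0 - spec.stress_penalty)])
    g = draw("G", spec.var_G, n_g)                       # genotype main effects
    gsd = draw("GxSD", spec.var_GxSD, (n_g, 2))          # genotype × sowing date
    yr = draw("Y", spec.var_Y, n_y)
    sdy = draw("SDxY", spec.var_SDxY, (2, n_y))
    gy_ = draw("GxY", spec.var_GxY, (n_g, n_y))
    gsdy = draw("GxSDxY", spec.var_GxSDxY, (n_g, 2, n_y))
    rep = draw("rep", spec.var_rep, (2, n_y, n_r))       # replication within SD × year
    eps = draw("e", spec.var_e, (n_g, 2, n_y, n_r))

    cell = (mu[None, :, None, None]
            + g[:, None, None, None]
            + gsd[:, :, None, None]
            + yr[None, None, :, None]
            + sdy[None, :, :, None]
            + gy_[:, None, :, None]
            + gsdy[:, :, :, None]
            + rep[None, :, :, :]
            + eps)

    gi, ci, yi, ri = np.meshgrid(np.arange(n_g), np.arange(2), np.arange(n_y),
                                 np.arange(n_r), indexing="ij")
    long = pd.DataFrame({
        "genotype": gi.ravel() + 1,
        "condition": np.where(ci.ravel() == 0, "normal", "stress"),
        "year": yi.ravel() + 1,
        "rep": ri.ravel() + 1,
        "block": np.nan,
        "trait": trait,
        "value": cell.ravel(),
    })

    truth = pd.DataFrame({
        "genotype": np.arange(1, n_g + 1),
        "trait": trait,
        "g": g,
        "gxsd_normal": gsd[:, 0],
        "gxsd_stress": gsd[:, 1],
        "expected_YP": mu[0] + g + gsd[:, 0],
        "expected_YS": mu[1] + g + gsd[:, 1],
    })
    return long, truth


def generate_trial(cfg: SyntheticConfig) -> tuple[TrialDataset, pd.DataFrame]:
    """Simulate a fully balanced trial; reproducible for a given seed.

    Returns the dataset and a truth table (one row per genotype per trait)
    holding realized effects, expected YP/YS and — for the yield trait — the
    true tolerance label implied by the expected yields.
    """
    cfg.validate()
    frames, truths = [], []
    specs = [("GY", cfg.yield_trait)] + list(cfg.extra_traits.items())
    for idx, (trait, spec) in enumerate(specs):
        seq = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(idx,))
        long, truth = _simulate_trait(spec, trait, cfg.n_genotypes,
                                      cfg.n_years, cfg.n_reps, seq)
        frames.append(long)
        truths.append(truth)
    records = pd.concat(frames, ignore_index=True)[LONG_COLUMNS]
    truth = pd.concat(truths, ignore_index=True)

    # true tolerance labels for the yield trait, from expected (not sampled) yields
    yt = truth["trait"] == "GY"
    yp, ys = truth.loc[yt, "expected_YP"], truth.loc[yt, "expected_YS"]
    xp, xs = yp.mean(), ys.mean()
    if xp != xs and (yp > 0).all():
        hsi = (1 - ys / yp) / (1 - xs / xp)
        truth.loc[yt, "true_HSI"] = hsi
        truth.loc[yt, "true_label"] = np.select(
            [hsi <= 0.8, hsi <= 1.3], ["tolerant", "semi_tolerant"], "susceptible")
    return TrialDataset(records), truth


def scaled_down(cfg: SyntheticConfig, n_genotypes: int) -> SyntheticConfig:
    """Same variance structure on a smaller panel (for fast tests)."""
    return replace(cfg, n_genotypes=n_genotypes)
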