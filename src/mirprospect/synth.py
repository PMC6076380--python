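"""Synthetic cohort generator with the statistical structure of a matched
prospective blood-miRNA biomarker study.

Defaults emulate a cohort of 534 COPD patients (33 developing cancer during
follow-up, 501 matched controls) profiled on microarrays measuring 2549
miRNAs with replicate probes. Intensities are log-normal: each miRNA has a
latent log2 baseline drawn from a broad uniform range and a per-miRNA log2
SD, so neither the linear nor the log scale is uniformly Gaussian across
features. A configurable minority of miRNAs carries a planted case/control
mean shift of ``effect_size_d`` standard deviations on the log2 scale,
mostly down-regulated in cases (default 74% down). Covariates (age, gender,
smoking, pack-years) are drawn from one common distribution in both cohorts
— the matched design — with optional age/smoking coupling into expression to
exercise the confounder screens. Each dataset ships a "signal" category
enriched for planted markers plus random categories, giving the enrichment
stage positive and negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as io_mod
from .exceptions import ConfigurationError
from .matrix import ExpressionMatrix

__all__ = ["SynthConfig", "SynthDataset", "generate", "write_dataset"]


@dataclass
class SynthConfig:
    """Study-design parameters of one synthetic cohort."""

    n_mirnas: int = 2549
    n_cases: int = 33
    n_controls: int = 501
    frac_de: float = 0.05
    effect_size_d: float = 0.65
    frac_down: float = 0.74
    n_replicates_per_probe: int = 3
    background_level: float = 0.0
    seed: int = 1234
    history_group_probs: tuple[float, float, float, float] = (0.82, 0.05, 0.10, 0.03)
    # latent intensity model
    log2_mean_range: tuple[float, float] = (6.0, 14.0)
    log2_sd_range: tuple[float, float] = (0.8, 1.4)
    replicate_sd: float = 0.1
    # covariate model (identical in both cohorts: matched design)
    age_mean: float = 67.0
    age_sd: float = 7.8
    packyears_mean: float = 48.0
    packyears_sd: float = 37.0
    p_female: float = 0.35
    smoking_probs: tuple[float, float, float] = (0.041, 0.723, 0.236)
    # optional covariate-expression coupling (off by default)
    n_age_coupled: int = 0
    age_slope_log2: float = 0.0
    n_smoking_coupled: int = 0
    smoking_shift_d: float = 0.0
    # categories
    n_random_categories: int = 10
    category_size: int = 25
    signal_inclusion_prob: float = 0.8

    def __post_init__(self) -> None:
        for name in ("n_mirnas", "n_cases", "n_controls", "n_replicates_per_probe"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.n_cases + self.n_controls < 4:
            raise ConfigurationError("n_cases + n_controls must be at least 4")
        for name in ("frac_de", "frac_down", "signal_inclusion_prob", "p_female"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.background_level < 0:
            raise ConfigurationError("background_level must be nonnegative")
        probs = np.asarray(self.history_group_probs, float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ConfigurationError("history_group_probs must be a 4-vector summing to 1")
        if abs(sum(self.smoking_probs) - 1) > 1e-9:
            raise ConfigurationError("smoking_probs must sum to 1")


@dataclass
class SynthDataset:
    """Raw replicate-level expression, annotation, planted truth and categories."""

    expression: ExpressionMatrix
    annotation: pd.DataFrame
    truth: pd.DataFrame  # columns: mirna_id, signed_d
    categories: dict[str, list[str]]
    config: SynthConfig = field(repr=False, default=None)


def _draw_covariates(cfg: SynthConfig, rng: np.random.Generator, n: int, is_case: np.ndarray):
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 40, 90)
    packyears = np.clip(rng.normal(cfg.packyears_mean, cfg.packyears_sd, n), 0, None)
    gender = np.where(rng.random(n) < cfg.p_female, "f", "m")
    smoking = rng.choice(["never", "past", "present"], size=n, p=cfg.smoking_probs)
    p = np.asarray(cfg.history_group_probs, float)
    # group is the cross of history x outcome; sample it conditionally on cohort
    group = np.empty(n, dtype=int)
    ctrl = ~is_case
    group[ctrl] = rng.choice([1, 3], size=int(ctrl.sum()), p=[p[0], p[2]] / (p[0] + p[2]))
    group[is_case] = rng.choice([2, 4], size=int(is_case.sum()), p=[p[1], p[3]] / (p[1] + p[3]))
    return age, packyears, gender, smoking, group


def generate(config: SynthConfig) -> SynthDataset:
    """Generate one dataset; bit-identical for a fixed config (including seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_mir, n_cases, n_ctrl = cfg.n_mirnas, cfg.n_cases, cfg.n_controls
    n = n_cases + n_ctrl
    width = max(4, len(str(n_mir)))
    mirna_ids = [f"syn-miR-{i + 1:0{width}d}" for i in range(n_mir)]
    sample_ids = [f"sample_{j + 1:04d}" for j in range(n)]
    is_case = np.zeros(n, dtype=bool)
    is_case[n_ctrl:] = True

    # latent per-miRNA intensity model (log2 scale)
    mu = rng.uniform(*cfg.log2_mean_range, size=n_mir)
    sigma = rng.uniform(*cfg.log2_sd_range, size=n_mir)

    # planted effects
    n_de = int(round(cfg.frac_de * n_mir))
    de_idx = rng.choice(n_mir, size=n_de, replace=False)
    signs = np.where(rng.random(n_de) < cfg.frac_down, -1.0, 1.0)
    effect = np.zeros(n_mir)
    effect[de_idx] = signs * cfg.effect_size_d * sigma[de_idx]

    age, packyears, gender, smoking, group = _draw_covariates(cfg, rng, n, is_case)

    latent = mu[:, None] + rng.normal(0.0, 1.0, (n_mir, n)) * sigma[:, None]
    latent += effect[:, None] * is_case[None, :]

    if cfg.n_age_coupled > 0 and cfg.age_slope_log2 != 0.0:
        non_de = np.setdiff1d(np.arange(n_mir), de_idx)
        coupled = non_de[: cfg.n_age_coupled]
        latent[coupled] += cfg.age_slope_log2 * (age - age.mean())[None, :]
    if cfg.n_smoking_coupled > 0 and cfg.smoking_shift_d != 0.0:
        non_de = np.setdiff1d(np.arange(n_mir), de_idx)
        coupled = non_de[cfg.n_age_coupled : cfg.n_age_coupled + cfg.n_smoking_coupled]
        present = (smoking == "present").astype(float)
        latent[coupled] += (cfg.smoking_shift_d * sigma[coupled])[:, None] * present[None, :]

    # replicate probes: noisy copies of the latent value plus a background level
    reps = cfg.n_replicates_per_probe
    noise = rng.normal(0.0, cfg.replicate_sd, (n_mir, reps, n))
    raw = np.exp2(latent[:, None, :] + noise) + cfg.background_level
    probe_ids = [f"{mid}_probe{r + 1}" for mid in mirna_ids for r in range(reps)]
    probe_group = pd.Series(np.repeat(mirna_ids, reps), index=probe_ids, name="probe_group")
    values = pd.DataFrame(
        raw.reshape(n_mir * reps, n), index=pd.Index(probe_ids, name="miRNA"), columns=sample_ids
    )
    expression = ExpressionMatrix(values=values, state="raw", probe_group=probe_group)

    annotation = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": np.where(is_case, "case", "control"),
            "history": (group >= 3).astype(int),
            "group": group,
            "age": np.round(age, 1),
            "gender": gender,
            "smoking": smoking,
            "packyears": np.round(packyears, 1),
        }
    )

    truth = pd.DataFrame(
        {
            "mirna_id": [mirna_ids[i] for i in de_idx],
            "signed_d": signs * cfg.effect_size_d,
        }
    ).sort_values("mirna_id", kind="mergesort").reset_index(drop=True)

    categories = _build_categories(cfg, rng, mirna_ids, de_idx)
    return SynthDataset(
        expression=expression,
        annotation=annotation,
        truth=truth,
        categories=categories,
        config=cfg,
    )


def _build_categories(
    cfg: SynthConfig, rng: np.random.Generator, mirna_ids: list[str], de_idx: np.ndarray
) -> dict[str, list[str]]:
    """One planted-signal category plus random same-size categories."""
    n_mir = len(mirna_ids)
    size = min(cfg.category_size, max(2, n_mir - 1))
    categories: dict[str, list[str]] = {}
    planted = list(de_idx)
    signal: list[int] = [i for i in planted if rng.random() < cfg.signal_inclusion_prob]
    signal = signal[:size]
    pool = np.setdiff1d(np.arange(n_mir), np.asarray(signal, int))
    if len(signal) < size:
        filler = rng.choice(pool, size=size - len(signal), replace=False)
        signal = signal + list(filler)
    categories["signal_planted"] = sorted(mirna_ids[i] for i in signal)
    for c in range(cfg.n_random_categories):
        members = rng.choice(n_mir, size=size, replace=False)
        categories[f"random_{c + 1:02d}"] = sorted(mirna_ids[i] for i in members)
    return categories


def write_dataset(ds: SynthDataset, directory: str | Path) -> dict[str, Path]:
    """Write expression TSV, annotation CSV, categories GMT and truth TSV.

    Round-trips losslessly through the readers in :mod:`mirprospect.io`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "annotation": directory / "annotation.csv",
        "categories": directory / "categories.gmt",
        "truth": directory / "truth.tsv",
    }
    io_mod.write_expression(ds.expression, paths["expression"])
    io_mod.write_annotation(ds.annotation, paths["annotation"])
    io_mod.write_gmt(ds.categories, paths["categories"])
    io_mod.write_truth(ds.truth, paths["truth"])
    return paths
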