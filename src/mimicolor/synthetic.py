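"""Synthetic inputs for exercising the full pipeline without measured data.

Two generators: smooth flower-like reflectance spectra (baseline plus
Gaussian components, emulating the UV-blue profile of the study flowers)
and binomial choice datasets drawn from a known discrimination function
with per-subject coefficient variation (emulating per-bee
proportion-correct data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colorspace import DEFAULT_GRID, Spectrum
from .discrimination import DiscriminationFunction, ChoiceDataset, eval_discrimination

__all__ = ["SpectrumRecipe", "ChoiceRecipe", "make_spectrum", "make_choice_data"]


@dataclass(frozen=True)
class SpectrumRecipe:
    """Baseline + Gaussian components + optional noise, clipped to [0, 1].

    ``components`` is a sequence of (center nm, width nm, amplitude).
    """

    baseline: float = 0.05
    components: tuple[tuple[float, float, float], ...] = ()
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for center, width, _amp in self.components:
            if not (200.0 <= center <= 750.0):
                raise ValueError("component centers must lie within [300, 650] +/- 100 nm")
            if width <= 0:
                raise ValueError("component widths must be positive")

    @classmethod
    def uv_blue(cls, seed: int | None = None) -> "SpectrumRecipe":
        """A UV-blue floral profile: reflectance peaks near 350 and 440 nm."""
        return cls(
            baseline=0.05,
            components=((350.0, 25.0, 0.25), (440.0, 35.0, 0.45)),
            noise_sd=0.005,
            seed=seed,
        )


def make_spectrum(recipe: SpectrumRecipe, grid: np.ndarray | None = None) -> Spectrum:
    """Realise a recipe on the 10 nm grid (deterministic under its seed)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    vals = np.full(grid.shape, recipe.baseline, dtype=float)
    for center, width, amp in recipe.components:
        vals += amp * np.exp(-(((grid - center) / width) ** 2))
    if recipe.noise_sd > 0:
        rng = np.random.default_rng(recipe.seed)
        vals += rng.normal(0.0, recipe.noise_sd, grid.shape)
    return Spectrum(grid, np.clip(vals, 0.0, 1.0))


@dataclass(frozen=True)
class ChoiceRecipe:
    """Binomial choice data from a known psychometric curve.

    Each subject's value of ``random_param`` is perturbed by a Gaussian
    draw with SD ``subject_sd``; proportions are binomial counts over
    ``trials_per_level`` choices at each colour-distance level.
    """

    fn: DiscriminationFunction
    delta_c_levels: tuple[float, ...]
    n_subjects: int = 5
    random_param: str | None = None
    subject_sd: float = 0.0
    trials_per_level: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.delta_c_levels)) < 3:
            raise ValueError("need at least 3 distinct colour-distance levels")
        if self.n_subjects < 1 or self.trials_per_level < 1:
            raise ValueError("subjects and trials must be positive")


def _perturbed(fn: DiscriminationFunction, param: str, delta: float) -> DiscriminationFunction:
    coef = dict(fn.coefficients)
    coef[param] = coef[param] + delta
    return DiscriminationFunction(form=fn.form, coefficients=coef,
                                  clamp_floor=fn.clamp_floor)


def make_choice_data(recipe: ChoiceRecipe) -> ChoiceDataset:
    """Simulate the per-subject choice table for a recipe.

    Invalid subject-level coefficient draws (e.g. pushing Mo above K) are
    resampled with a warning, up to 100 attempts per subject.
    """
    rng = np.random.default_rng(recipe.seed)
    levels = np.asarray(recipe.delta_c_levels, dtype=float)
    rows = []
    for s in range(recipe.n_subjects):
        fn_s = recipe.fn
        if recipe.random_param is not None and recipe.subject_sd > 0:
            for attempt in range(100):
                try:
                    fn_s = _perturbed(recipe.fn, recipe.random_param,
                                      float(rng.normal(0.0, recipe.subject_sd)))
                    break
                except ValueError:
                    if attempt == 0:
                        warnings.warn(
                            "subject-level draw produced invalid coefficients; resampling",
                            stacklevel=2,
                        )
            else:  # pragma: no cover
                raise RuntimeError("could not draw valid subject coefficients in 100 attempts")
        # generate from the raw curve: fitted lower asymptotes can sit below
        # the two-alternative chance floor (observed proportions do too)
        pi = np.clip(eval_discrimination(fn_s, levels, clamp=False), 0.0, 1.0)
        n_correct = rng.binomial(recipe.trials_per_level, pi)
        for dc, k in zip(levels, n_correct):
            rows.append(
                {"subject_id": f"bee_{s + 1}", "delta_c_hu": float(dc),
                 "n_correct": int(k), "n_trials": recipe.trials_per_level}
            )
    return ChoiceDataset(pd.DataFrame(rows))
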