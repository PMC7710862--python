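"""Monte-Carlo confusion analysis for floral mimicry.

Combines the flower-colour PDFs with the bee discrimination functions to
ask: how often would a bee with a given level of experience confuse a
rewardless mimic flower with its rewarding model?  Colour loci are drawn
from each species' bivariate PDF, paired, converted to hexagon distances,
and pushed through the psychometric curves; a comparison "fails" when its
distance falls below the function's 75%-accuracy threshold (pi75).

Within a species, sampled loci are classed by the empirical quantiles of
their own density values: **typical** colours lie above the 0.9 density
quantile, **less frequent** between 0.45 and 0.55, **rare** between 0.15
and 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .color_pdf import BivariatePDF
from .discrimination import DiscriminationFunction, eval_discrimination, threshold_distance

__all__ = [
    "FREQUENCY_BANDS",
    "ClassifiedLoci",
    "MimicryReport",
    "classify_frequency",
    "class_pair_distances",
    "cross_species_distances",
    "discrimination_report",
]

#: quantile bands of sampled density values defining each frequency class
FREQUENCY_BANDS = {
    "typical": (0.90, 1.00),
    "less_frequent": (0.45, 0.55),
    "rare": (0.15, 0.25),
}


@dataclass
class ClassifiedLoci:
    """Sampled loci with their densities, class labels and the density
    bands (d ranges) of each frequency class."""

    data: pd.DataFrame = field(repr=False)  # columns x, y, density, freq_class
    density_bands: dict[str, tuple[float, float]]

    def loci(self, freq_class: str) -> np.ndarray:
        sub = self.data[self.data["freq_class"] == freq_class]
        return sub[["x", "y"]].to_numpy()


def classify_frequency(pdf: BivariatePDF, n: int = 100_000, seed=None) -> ClassifiedLoci:
    """Sample ``n`` loci, evaluate their joint density, and class each locus
    as typical / less_frequent / rare (or unclassified) by the empirical
    density quantiles at 0.15, 0.25, 0.45, 0.55 and 0.90.
    """
    if n < 10_000:
        raise ValueError("classification needs n >= 10,000 samples")
    xy = pdf.sample(n, seed=seed)
    if float(np.std(xy[:, 0])) < 1e-12 or float(np.std(xy[:, 1])) < 1e-12:
        raise ValueError("degenerate PDF: sampled loci have (near) zero variance")
    d = pdf.density(xy[:, 0], xy[:, 1])
    labels = np.full(n, "unclassified", dtype=object)
    bands: dict[str, tuple[float, float]] = {}
    for name, (qlo, qhi) in FREQUENCY_BANDS.items():
        lo = float(np.quantile(d, qlo))
        hi = float(np.quantile(d, qhi)) if qhi < 1.0 else float(np.inf)
        sel = (d > lo) & (d <= hi)
        labels[sel] = name
        bands[name] = (lo, hi)
        if not np.any(sel):  # pragma: no cover - bands contain ~10% by construction
            raise ValueError(f"frequency class {name!r} is empty")
    df = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "density": d, "freq_class": labels})
    return ClassifiedLoci(data=df, density_bands=bands)


def class_pair_distances(
    classed: ClassifiedLoci,
    pair: tuple[str, str],
    cap: int = 100_000,
    seed=None,
) -> tuple[float, dict[str, tuple[float, float]]]:
    """Mean hexagon distance between random cross-pairs of two frequency
    classes (at most ``cap`` pairs), plus the density bands of each class."""
    a = classed.loci(pair[0])
    b = classed.loci(pair[1])
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError(f"empty frequency class in pair {pair}")
    rng = np.random.default_rng(seed)
    m = min(cap, a.shape[0] * b.shape[0])
    ia = rng.integers(0, a.shape[0], size=m)
    ib = rng.integers(0, b.shape[0], size=m)
    dist = np.hypot(a[ia, 0] - b[ib, 0], a[ia, 1] - b[ib, 1])
    bands = {c: classed.density_bands[c] for c in pair}
    return float(dist.mean()), bands


def cross_species_distances(
    pdf_a: BivariatePDF,
    pdf_b: BivariatePDF,
    n_pairs: int = 100_000,
    seed=None,
) -> np.ndarray:
    """Hexagon distances between ``n_pairs`` loci drawn independently from
    two species' PDFs and paired elementwise."""
    if n_pairs < 10_000:
        raise ValueError("cross-species sampling needs n_pairs >= 10,000")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_a, seed_b = seq.spawn(2)
    xa = pdf_a.sample(n_pairs, seed=seed_a)
    xb = pdf_b.sample(n_pairs, seed=seed_b)
    return np.hypot(xa[:, 0] - xb[:, 0], xa[:, 1] - xb[:, 1])


@dataclass
class MimicryReport:
    """Per-condition summary of one flower-region pair's distance sample."""

    pair: str
    median_dc: float
    min_dc: float
    max_dc: float
    #: per condition name: (pi at median, pi min, pi max, percent below threshold)
    conditions: dict[str, tuple[float, float, float, float]]
    threshold: float = 0.75
    flags: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        row: dict[str, float | str] = {
            "pair": self.pair,
            "median_dc": self.median_dc,
            "min_dc": self.min_dc,
            "max_dc": self.max_dc,
        }
        for name, (pi_med, pi_lo, pi_hi, pct) in self.conditions.items():
            row[f"pi_{name}"] = pi_med
            row[f"pi_{name}_min"] = pi_lo
            row[f"pi_{name}_max"] = pi_hi
            row[f"pct_below_{name}"] = pct
        return pd.DataFrame([row])


def discrimination_report(
    distances: np.ndarray,
    fns: dict[str, DiscriminationFunction],
    threshold: float = 0.75,
    pair: str = "pair",
) -> MimicryReport:
    """Summarise a colour-distance sample through each discrimination
    function: accuracy at the median distance, the clamped accuracy range,
    and the percentage of comparisons falling below the function's
    ``threshold``-accuracy distance (the confusable fraction).

    A function whose upper asymptote K is below ``threshold`` can never
    reach the target accuracy; its percent-below is 100 by convention and
    the report flags it.
    """
    dist = np.asarray(distances, dtype=float)
    if dist.size == 0:
        raise ValueError("empty distance sample")
    med = float(np.median(dist))
    conditions: dict[str, tuple[float, float, float, float]] = {}
    flags: dict[str, str] = {}
    for name, fn in fns.items():
        pi = eval_discrimination(fn, dist, clamp=True)
        pi_med = float(eval_discrimination(fn, med, clamp=True))
        if fn.K <= threshold:
            pct = 100.0
            flags[name] = f"upper asymptote K={fn.K:.3f} below threshold {threshold}"
        else:
            thr_dc = threshold_distance(fn, threshold)
            pct = 100.0 * float(np.mean(dist < thr_dc))
        conditions[name] = (pi_med, float(pi.min()), float(pi.max()), pct)
    return MimicryReport(
        pair=pair,
        median_dc=med,
        min_dc=float(dist.min()),
        max_dc=float(dist.max()),
        conditions=conditions,
        threshold=threshold,
        flags=flags,
    )
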