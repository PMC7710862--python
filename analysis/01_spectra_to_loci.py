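#!/usr/bin/env python
"""Stage 1 — model flower reflectance spectra as bee colour loci.

Generates a small population of synthetic UV-blue flower spectra (the
reflectance profile class of the study flowers), converts each to a
honeybee hexagon colour locus under the default visual system (green-leaf
adaptation background, daylight illuminant), and writes the loci table.

Finding to check in the output: all flower loci fall in the blue/UV-blue
sector (x < 0.2, y > 0), and the adaptation background itself maps to the
achromatic centre (0, 0).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from mimicolor.colorspace import VisualSystem, spectrum_to_locus, write_loci_csv
from mimicolor.synthetic import SpectrumRecipe, make_spectrum

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    rng = np.random.default_rng(seed)
    vs = VisualSystem.honeybee()

    loci = {"background": spectrum_to_locus(vs.background, vs)}
    for i in range(40):
        recipe = SpectrumRecipe(
            baseline=0.05,
            components=(
                (350.0, 25.0, 0.25 + rng.normal(0.0, 0.03)),
                (440.0, 35.0, 0.45 + rng.normal(0.0, 0.05)),
            ),
            noise_sd=0.004,
            seed=int(rng.integers(2**31)),
        )
        loci[f"flower_{i + 1:02d}"] = spectrum_to_locus(make_spectrum(recipe), vs)

    OUT.mkdir(exist_ok=True)
    write_loci_csv(loci, OUT / "synthetic_loci.csv")

    df = pd.DataFrame({"x": [l.x for k, l in loci.items() if k != "background"],
                       "y": [l.y for k, l in loci.items() if k != "background"]})
    print(f"modelled {len(df)} synthetic flower spectra -> {OUT / 'synthetic_loci.csv'}")
    print(f"background locus: ({loci['background'].x:+.2e}, {loci['background'].y:+.2e})"
          "  (achromatic centre)")
    print(f"flower loci span x in [{df.x.min():.3f}, {df.x.max():.3f}], "
          f"y in [{df.y.min():.3f}, {df.y.max():.3f}]")
    in_sector = ((df.x < 0.2) & (df.y > 0)).mean()
    print(f"fraction in the blue/UV-blue sector (x < 0.2, y > 0): {in_sector:.0%}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
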