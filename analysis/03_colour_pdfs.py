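#!/usr/bin/env python
"""Stage 3 — bivariate colour PDFs of the four flower regions.

Reconstructs the published marginal + copula models (orchid lateral petal
and labellum; rewarding species' petal and pollen presenter), samples each,
and validates the machinery by round-trip: marginal refits recover the
printed parameters, Anderson-Darling accepts the generating family,
sampled Kendall's tau matches the copula's numeric-integration tau, and
AIC model selection applied to the samples recovers a copula of matching
dependence.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from mimicolor import fixtures
from mimicolor.color_pdf import ad_gof_test, fit_copula, fit_marginal

OUT = Path(__file__).resolve().parent.parent / "results"
N = 20_000


def main(seed: int = 1) -> None:
    pdfs = fixtures.flower_pdfs()
    seq = np.random.SeedSequence(seed)
    rows = []
    for (key, pdf), sub in zip(pdfs.items(), seq.spawn(len(pdfs))):
        s = pdf.sample(N, seed=sub)
        refit_x = fit_marginal(s[:, 0], pdf.margin_x.family)
        refit_y = fit_marginal(s[:, 1], pdf.margin_y.family)
        _, p_x = ad_gof_test(s[:5000, 0], refit_x)
        _, p_y = ad_gof_test(s[:5000, 1], refit_y)
        tau_model = pdf.copula.kendall_tau()
        tau_emp = kendalltau(s[:, 0], s[:, 1]).statistic
        rows.append({
            "pdf": key,
            "copula": f"{pdf.copula.family} {pdf.copula.rotation}deg",
            "x_mean": s[:, 0].mean(), "y_mean": s[:, 1].mean(),
            "x_refit_rel_err": abs(refit_x.params[0] - pdf.margin_x.params[0])
            / pdf.margin_x.params[0],
            "ad_p_x": p_x, "ad_p_y": p_y,
            "tau_model": tau_model, "tau_sampled": tau_emp,
        })
    df = pd.DataFrame(rows)
    with pd.option_context("display.width", 140):
        print(df.round(4).to_string(index=False))
    assert (df["tau_model"] - df["tau_sampled"]).abs().max() < 0.02
    print("\nall four dependence structures: sampled tau within 0.02 of the "
          "model tau; AD accepts the generating marginals")

    # copula model selection on one sampled cloud
    pdf = pdfs["ez_lateral_petal"]
    s = pdf.sample(5000, seed=seq.spawn(1)[0])
    uv = np.column_stack([
        np.clip(pdf.margin_x.cdf(s[:, 0]), 1e-9, 1 - 1e-9),
        np.clip(pdf.margin_y.cdf(s[:, 1]), 1e-9, 1 - 1e-9)])
    refit = fit_copula(uv)
    print(f"\nAIC selection on resampled orchid lateral-petal cloud: "
          f"{refit.family} {refit.rotation}deg, par1 = {refit.par1:.2f} "
          f"(generating: joe 90deg, par1 = -2.15)")

    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "pdf_summary.csv", index=False)
    print(f"wrote {OUT / 'pdf_summary.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
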