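"""Published model parameters shipped as JSON resources.

These are the fitted psychometric coefficients and flower-colour PDF
parameters of the *Eulophia zeyheriana* / *Wahlenbergia cuspidata* mimicry
study, reconstructed from the printed parameter tables (the underlying raw
spectra are not required).  PDF IDs: ``wc_petal``, ``wc_pollen``,
``ez_lateral_petal``, ``ez_labellum``.
"""

from __future__ import annotations

import json
from importlib import resources

from ..color_pdf import BivariatePDF
from ..discrimination import DiscriminationFunction

__all__ = ["discrimination_functions", "flower_pdfs", "load_all"]


def _read(name: str) -> dict:
    with resources.files(__package__).joinpath(name).open() as fh:
        return json.load(fh)


def discrimination_functions() -> dict[str, DiscriminationFunction]:
    """The successive-viewing blue/yellow (3-parameter) and absolute-
    conditioning (4-parameter) discrimination functions."""
    raw = _read("discrimination_functions.json")
    return {k: DiscriminationFunction.from_dict(d) for k, d in raw.items()}


def flower_pdfs() -> dict[str, BivariatePDF]:
    """The four bivariate colour PDFs (marginals + copulas), validated at
    load time by the model classes' own invariants."""
    raw = _read("flower_pdfs.json")
    return {k: BivariatePDF.from_dict(d) for k, d in raw.items()}


def load_all() -> dict:
    """Everything: ``{"discrimination": {...}, "pdfs": {...}}``."""
    return {"discrimination": discrimination_functions(), "pdfs": flower_pdfs()}
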