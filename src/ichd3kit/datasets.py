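"""Bundled reference data."""

from __future__ import annotations

from importlib import resources

from .agreement import ConfusionMatrix


def load_validation_confusion() -> ConfusionMatrix:
    """Cross-tabulation of the reference validation study (n = 102 attacks).

    Rows: a headache specialist's labels; columns: the algorithm's labels,
    over the categories MO, MA, TTH, NOT_CLASSIFIABLE.  86 attacks lie on the
    diagonal (agreement) and 16 off it; the unweighted Cohen's kappa is 0.742.
    """
    path = resources.files("ichd3kit.data").joinpath("validation_confusion.csv")
    with resources.as_file(path) as p:
        return ConfusionMatrix.from_csv(p)
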