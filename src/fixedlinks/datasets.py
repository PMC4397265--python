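"""Bundled study data.

The package ships the published 8 x 8 Pearson correlation matrix among
the three reasoning composites (figural, numerical, verbal) and the hit
rates in the five working-memory task conditions, observed on n = 200
participants.  Correlations are available only at two-decimal printed
precision, so quantities refit from this matrix can drift by a point or
two in the second decimal relative to the original covariance-matrix
analysis.
"""

from __future__ import annotations

from importlib import resources

from .engine import SampleMoments
from .model import REASONING_NAMES, WMC_NAMES

__all__ = ["load_study_correlations", "STUDY_N"]

#: sample size of the study the bundled correlations come from
STUDY_N = 200


def load_study_correlations(wmc_only: bool = False) -> SampleMoments:
    """The bundled 8 x 8 correlation matrix as SampleMoments (n = 200).

    With ``wmc_only`` the 5 x 5 block of the working-memory conditions
    is returned (the measurement-model analyses use only that block).
    """
    path = resources.files("fixedlinks.data") / "wmc_reasoning_correlations.csv"
    with resources.as_file(path) as p:
        moments = SampleMoments.from_csv(p, n=STUDY_N, is_correlation=True)
    assert moments.names == REASONING_NAMES + WMC_NAMES
    if wmc_only:
        return moments.subset(list(WMC_NAMES))
    return moments
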