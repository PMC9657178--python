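"""Four native differential-expression engines over a common result schema.

Each engine represents one statistical family used in consensus DE calling:

* ``nb_exact`` — exact conditional negative-binomial test (edgeR family),
* ``nb_wald`` — negative-binomial Wald test on shrunken dispersions
  (DESeq2 family),
* ``noise`` — nonparametric signal-vs-noise probability of DE
  (NOISeq family),
* ``eb`` — empirical-Bayes beta-negative-binomial posterior probability
  of DE (EBSeq family).

All engines emit one :class:`DEResult` record per gene passing the shared
expression filter, with a unified score column: ``fdr`` holds the
BH-adjusted p-value for the frequentist engines and 1 - probability-of-DE
for the other two, so a single threshold applies across methods.
"""

from ._common import DEResult, ENGINE_NAMES, assign_status, bh_adjust, expression_filter
from ._dispersion import DispersionModel, estimate_dispersion
from ._nb_exact import nb_exact_test
from ._nb_wald import nb_wald_test
from ._noise import noise_test
from ._eb import eb_test

__all__ = [
    "DEResult",
    "ENGINE_NAMES",
    "DispersionModel",
    "assign_status",
    "bh_adjust",
    "estimate_dispersion",
    "expression_filter",
    "nb_exact_test",
    "nb_wald_test",
    "noise_test",
    "eb_test",
    "run_engine",
]


def run_engine(name: str, ds, **kwargs):
    """Dispatch an engine by name (``nb_exact``, ``nb_wald``, ``noise``, ``eb``)."""
    if name == "nb_exact":
        return nb_exact_test(ds, **kwargs)
    if name == "nb_wald":
        return nb_wald_test(ds, **kwargs)
    if name == "noise":
        return noise_test(ds, **kwargs)
    if name == "eb":
        return eb_test(ds, **kwargs)
    raise ValueError(f"unknown engine {name!r}; choose from {ENGINE_NAMES}")
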