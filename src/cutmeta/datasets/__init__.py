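"""Packaged example datasets.

Two published meta-analyses ship with the package as plain CSV:

* Apgar score and neonatal mortality in low-birth-weight babies — 10 cohort
  studies reporting unadjusted log odds ratios at cut-points 3 and/or 6,
  with bootstrap within-study correlations for the five studies reporting
  both cut-points.
* Microvessel density and mortality in non-small-cell lung carcinoma — 16
  studies reporting adjusted log hazard ratios per 1-unit density change
  under the Chalkley and/or all-vessels counting methods, with patient-level
  correlations for the three dual-method studies.
"""

from importlib import resources

from ..data_model import MetaDataset, load_long_table

__all__ = ["load_apgar", "load_microvessel", "dataset_path"]


def dataset_path(name: str):
    return resources.files(__package__) / name


def load_apgar() -> MetaDataset:
    """Apgar-score meta-analysis (log odds ratios at cut-points 3 and 6)."""
    with resources.as_file(dataset_path("apgar_effects.csv")) as eff, resources.as_file(
        dataset_path("apgar_corr.csv")
    ) as corr:
        return load_long_table(eff, corr, default_scale="log_odds")


def load_microvessel() -> MetaDataset:
    """Microvessel-density meta-analysis (log hazard ratios, two methods)."""
    with resources.as_file(dataset_path("microvessel_effects.csv")) as eff, resources.as_file(
        dataset_path("microvessel_corr.csv")
    ) as corr:
        return load_long_table(eff, corr, default_scale="log_hazard")
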