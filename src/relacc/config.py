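"""Versioned defaults: every fixed assumption of the pipeline in one file.

``defaults.yaml`` records the analysis constants (wear rule, bin widths, MX
grid), the VO2-ENMO calibration model registry, the generator defaults, and
the calibration targets with their pre-registered tolerance.  Code-level
dataclass defaults mirror the generator section; a unit test keeps the two in
sync.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=1)
def defaults() -> dict:
    """The parsed ``defaults.yaml`` shipped with the package."""
    text = resources.files("relacc").joinpath("defaults.yaml").read_text("utf-8")
    return yaml.safe_load(text)


def vo2_enmo_model(name: str | None = None):
    """A named entry of the VO2-ENMO model registry (default entry if None)."""
    from .relative import Vo2EnmoModel

    d = defaults()
    if name is None:
        name = d["default_vo2_enmo_model"]
    try:
        entry = d["vo2_enmo_models"][name]
    except KeyError:
        raise KeyError(
            f"unknown VO2-ENMO model {name!r}; available: "
            f"{sorted(d['vo2_enmo_models'])}"
        ) from None
    return Vo2EnmoModel(
        slope=float(entry["slope"]),
        intercept=float(entry["intercept"]),
        source_label=entry.get("source_label", name),
    )


def calibration_targets() -> dict:
    return dict(defaults()["calibration_targets"])


def default_cohort_spec(seed: int = 0, **overrides):
    """Build the default :class:`~relacc.cohort.CohortSpec` from ``defaults.yaml``."""
    from .cohort import (
        ActivitySpec,
        BodyfatModel,
        CohortSpec,
        PlantedEffects,
        PopulationVariation,
        Vo2PeakModel,
    )

    d = defaults()

    def tup(section: dict) -> dict:
        return {
            k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
        }

    kwargs = dict(
        tup(d["cohort"]),
        activity_model=ActivitySpec(**d["activity_model"]),
        vo2peak_model=Vo2PeakModel(**d["vo2peak_model"]),
        bodyfat_model=BodyfatModel(**d["bodyfat_model"]),
        effects=PlantedEffects(**tup(d["effects"])),
        variation=PopulationVariation(**d["variation"]),
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)
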