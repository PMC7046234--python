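"""Access to the packaged published reference tables.

The JSON bundle holds published reference values for freshwater turtle
demography: the AICc columns of the four-candidate trait model comparison,
stage-elasticity tables per zone, and the zone-level demographic parameters
(observed, predicted, and the minimum values giving non-negative growth).
They serve as comparison targets for the convention-search diagnostic and
as worked-example inputs; the package never asserts exact agreement with
model-dependent cells.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

__all__ = ["load_reference_tables", "reference_zone_inputs", "reference_targets"]


@lru_cache(maxsize=1)
def load_reference_tables() -> dict:
    path = resources.files("turtleharvest.data") / "reference_tables.json"
    return json.loads(path.read_text())


def reference_zone_inputs(which: str = "predicted") -> dict:
    """Zone -> {adult_survival, age_maturity, fecundity} matrix inputs."""
    demo = load_reference_tables()["demography"]
    return {
        zone: {
            "adult_survival": demo[zone][which]["adult_survival"],
            "age_maturity": demo[zone][which]["age_maturity"],
            "fecundity": demo[zone][which]["fecundity"],
        }
        for zone in ("temperate", "tropical")
    }


def reference_targets() -> dict:
    """Zone -> {elasticity, r_min} reference cells for convention_search."""
    ref = load_reference_tables()
    return {
        zone: {
            "elasticity": ref["elasticities"]["predicted"][zone],
            "r_min": ref["demography"][zone]["r_min"],
        }
        for zone in ("temperate", "tropical")
    }
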