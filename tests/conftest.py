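"""Shared fixtures: small synthetic experiments reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from cytoscreen.configs import small_screen
from cytoscreen.fcs import EventMatrix, arcsinh_transform
from cytoscreen.pipeline import run_all
from cytoscreen.synthetic import (
    AntibodySpec,
    MarkerSpec,
    SimulationConfig,
    simulate_batch,
    simulate_sample_unit,
)


def mixture_config(separation: float = 1.9, seed: int = 0, n_events: int = 4000,
                   hi_frac: float = 0.0) -> SimulationConfig:
    """Four-subset PBMC-like mixture with configurable staining separation."""
    lo = 0.3
    hi = lo + separation
    markers = ["CD3", "CD19", "CD56", "CD4", "CD8", "CD161"]

    def subset(high: list[str], bimodal_cd161: bool = False) -> dict[str, MarkerSpec]:
        out = {}
        for m in markers:
            if m == "CD161" and bimodal_cd161:
                out[m] = MarkerSpec(mean=lo, sd=0.3, hi_mean=lo + 2.0, hi_frac=hi_frac)
            else:
                out[m] = MarkerSpec(mean=hi if m in high else lo, sd=0.3)
        return out

    return SimulationConfig(
        donors={"D1": {"CD4 T": 0.3, "CD8 T": 0.3, "B Cells": 0.2, "NK Cells": 0.2}},
        subsets={
            "CD4 T": subset(["CD3", "CD4"]),
            "CD8 T": subset(["CD3", "CD8"], bimodal_cd161=hi_frac > 0),
            "B Cells": subset(["CD19"]),
            "NK Cells": subset(["CD56"]),
        },
        antibodies={"Blank": AntibodySpec()},
        n_events=n_events,
        seed=seed,
    )


def mixture_events(separation: float = 1.9, seed: int = 0, n_events: int = 4000,
                   hi_frac: float = 0.0):
    """Arcsinh event matrix plus ground-truth sidecar for one sample unit."""
    config = mixture_config(separation, seed, n_events, hi_frac)
    raw, sidecar = simulate_sample_unit(config, "D1", "fresh", "Blank")
    return arcsinh_transform(raw), sidecar


@pytest.fixture(scope="session")
def small_run():
    """Full pipeline run on the bundled small screen (seed 1), with truth."""
    config, manifest, hierarchy, opts = small_screen(seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_all(config, manifest, hierarchy, opts, sidecars=True)
    return config, manifest, result


@pytest.fixture(scope="session")
def drift_batches():
    """(null, drifted) arcsinh batches plus B-cell masks for CD19 drift QC."""
    out = {}
    for name, drift in (("null", False), ("drift", True)):
        config, manifest, _h, _o = small_screen(seed=5, drift=drift)
        events, sidecar = simulate_batch(config, manifest, "batch_01")
        out[name] = (arcsinh_transform(events), (sidecar["subset"] == "B Cells").to_numpy())
    return out["null"], out["drift"]
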