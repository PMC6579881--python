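"""Bundled experiment configurations and config-file loading.

``small_screen`` is the package's reference synthetic experiment: a
desk-scale version of the two-tier barcoded antibody screen.  Three
donors and two treatments (fresh / formaldehyde-fixed) are encoded on
a 2-of-4 CD45 inner tier; twenty antibody wells (a blank plus 19
antibodies) are split into two batches of ten on a 2-of-5 palladium
outer tier, giving 120 sample units.  Four PBMC-like subsets (CD4 T,
CD8 T, B, NK) are separated by ~1.9 arcsinh units on their lineage
markers; CD8 T cells carry a bimodal CD161 (30% high) so that
profiling yields CD161hi / CD161lo subsets.  The screen plants one
differential antibody (elevated only in CD161hi CD8 T cells), one
fixation gain (x2.5), one global fixation loss (x0.2) and one
subset-specific loss, all recoverable by the downstream statistics.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .design import ExperimentManifest, Well, build_manifest, make_scheme
from .ekbalam import GatingHierarchy, Rule
from .pipeline import PipelineOptions
from .synthetic import AntibodySpec, DriftSpec, MarkerSpec, SimulationConfig

__all__ = ["small_screen", "default_hierarchy", "load_run_config"]

INNER_CHANNELS = ["CD45_BC1", "CD45_BC2", "CD45_BC3", "CD45_BC4"]
OUTER_CHANNELS = ["PD_BC1", "PD_BC2", "PD_BC3", "PD_BC4", "PD_BC5"]

HI = 2.2   # positive lineage level, arcsinh units
LO = 0.3   # background level
SD = 0.3


def default_hierarchy() -> GatingHierarchy:
    """Two-level PBMC hierarchy: T/B/NK, then CD4 vs CD8 T cells."""
    return GatingHierarchy(
        root="Cell",
        levels=[
            [
                Rule("Cell", "T Cells", (("CD3", "+"), ("CD19", "-"))),
                Rule("Cell", "B Cells", (("CD19", "+"), ("CD3", "-"))),
                Rule("Cell", "NK Cells", (("CD3", "-"), ("CD19", "-"), ("CD56", "+"))),
            ],
            [
                Rule("T Cells", "CD4 T", (("CD4", "+"), ("CD8", "-"))),
                Rule("T Cells", "CD8 T", (("CD8", "+"), ("CD4", "-"))),
            ],
        ],
    )


def _subset(profile: dict[str, float | MarkerSpec]) -> dict[str, MarkerSpec]:
    out = {}
    for marker in ["CD3", "CD19", "CD56", "CD4", "CD8", "CD161"]:
        spec = profile.get(marker, LO)
        out[marker] = spec if isinstance(spec, MarkerSpec) else MarkerSpec(float(spec), SD)
    return out


def small_screen(
    seed: int = 0,
    n_events: int = 400,
    n_wells: int = 20,
    drift: bool = False,
) -> tuple[SimulationConfig, ExperimentManifest, GatingHierarchy, PipelineOptions]:
    """Build the bundled small synthetic screen (see module docstring)."""
    donors = {
        "D1": {"CD4 T": 0.30, "CD8 T": 0.25, "B Cells": 0.25, "NK Cells": 0.20},
        "D2": {"CD4 T": 0.35, "CD8 T": 0.20, "B Cells": 0.25, "NK Cells": 0.20},
        "D3": {"CD4 T": 0.25, "CD8 T": 0.30, "B Cells": 0.20, "NK Cells": 0.25},
    }
    subsets = {
        "CD4 T": _subset({"CD3": HI, "CD4": HI}),
        "CD8 T": _subset(
            {"CD3": HI, "CD8": HI,
             "CD161": MarkerSpec(mean=LO, sd=SD, hi_mean=LO + 2.0, hi_frac=0.30)}
        ),
        "B Cells": _subset({"CD19": HI}),
        "NK Cells": _subset({"CD56": HI}),
    }

    wells = [Well("W01", "Blank", is_control=True)]
    antibodies: dict[str, AntibodySpec] = {"Blank": AntibodySpec(default_frac=0.0)}
    # Deterministic, varied baseline positive fractions per subset.
    base = [0.05, 0.15, 0.30, 0.50, 0.70]
    subset_names = ["CD4 T", "CD8 T", "B Cells", "NK Cells"]
    special = {
        "CD26L": AntibodySpec(frac={"CD161hi CD8 T": 0.60, "CD161lo CD8 T": 0.10,
                                    "CD4 T": 0.10, "B Cells": 0.08, "NK Cells": 0.12}),
        "FIXG": AntibodySpec(frac={s: 0.40 for s in subset_names}),
        "FIXL": AntibodySpec(frac={s: 0.50 for s in subset_names}),
        "SUBL": AntibodySpec(frac={"B Cells": 0.60, "NK Cells": 0.60}),
    }
    special_names = list(special)
    for i in range(1, n_wells):
        if i <= len(special_names):
            name = special_names[i - 1]
            spec = special[name]
        else:
            name = f"AB{i:02d}"
            frac = {
                s: base[(i + j) % len(base)] for j, s in enumerate(subset_names)
            }
            spec = AntibodySpec(frac=frac)
        wells.append(Well(f"W{i + 1:02d}", name))
        antibodies[name] = spec

    fixation = {"FIXG": 2.5, "FIXL": 0.2, "SUBL": {"NK Cells": 0.2}}
    config = SimulationConfig(
        donors=donors,
        subsets=subsets,
        antibodies=antibodies,
        fixation=fixation,
        drift=DriftSpec(marker="CD19", slope=0.0019, batches=["batch_01"]) if drift else None,
        n_events=n_events,
        seed=seed,
    )
    manifest = build_manifest(
        donors=list(donors),
        treatments=["fresh", "fixed"],
        wells=wells,
        batch_size=10,
        inner_scheme=make_scheme(INNER_CHANNELS, 2),
        outer_scheme=make_scheme(OUTER_CHANNELS, 2),
    )
    hierarchy = default_hierarchy()
    opts = PipelineOptions(
        seed=seed,
        profiling_markers=config.markers,
        diff_target="CD161hi CD8 T",
        diff_reference="CD161lo CD8 T",
    )
    return config, manifest, hierarchy, opts


# ---------------------------------------------------------------------------
# YAML run-config loading


def _marker_spec(v) -> MarkerSpec:
    if isinstance(v, dict):
        return MarkerSpec(**v)
    return MarkerSpec(mean=float(v))


def load_run_config(path: str | Path):
    """Load a YAML run config into (config, manifest, hierarchy, options).

    The schema mirrors the builtin builder; ``simulation: builtin``
    selects the bundled small screen, overridable by ``seed``,
    ``n_events`` and ``drift`` keys.
    """
    spec = yaml.safe_load(Path(path).read_text())
    seed = int(spec.get("seed", 0))
    sim = spec.get("simulation", "builtin")
    if sim == "builtin" or (isinstance(sim, dict) and sim.get("builtin")):
        kwargs = sim if isinstance(sim, dict) else {}
        kwargs = {k: v for k, v in kwargs.items() if k in ("n_events", "n_wells", "drift")}
        config, manifest, hierarchy, opts = small_screen(seed=seed, **kwargs)
    else:
        config = SimulationConfig(
            donors=sim["donors"],
            subsets={
                s: {m: _marker_spec(v) for m, v in profile.items()}
                for s, profile in sim["subsets"].items()
            },
            antibodies={
                a: AntibodySpec(**v) for a, v in sim.get("antibodies", {}).items()
            },
            fixation=sim.get("fixation", {}),
            drift=DriftSpec(**sim["drift"]) if sim.get("drift") else None,
            n_events=int(sim.get("n_events", 200)),
            seed=seed,
        )
        d = spec["design"]
        manifest = build_manifest(
            donors=list(config.donors),
            treatments=d.get("treatments", ["fresh", "fixed"]),
            wells=[Well(*w) if isinstance(w, list) else Well(w, w) for w in d["wells"]],
            batch_size=int(d.get("batch_size", 10)),
            inner_scheme=make_scheme(d.get("inner_channels", INNER_CHANNELS), 2),
            outer_scheme=make_scheme(d.get("outer_channels", OUTER_CHANNELS), 2),
            exclusions=d.get("exclusions", ()),
        )
        hierarchy = (
            GatingHierarchy.from_dict(spec["hierarchy"])
            if "hierarchy" in spec
            else default_hierarchy()
        )
        opts = PipelineOptions(seed=seed)
    for key, value in spec.get("options", {}).items():
        if not hasattr(opts, key):
            raise ValueError(f"unknown pipeline option {key!r}")
        setattr(opts, key, value)
    return config, manifest, hierarchy, opts
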