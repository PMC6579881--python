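"""Seeded synthetic barcoded mass-cytometry experiments with ground truth.

The generator emulates the screen's design end to end: multi-subset
PBMC-like mixtures with per-subset marker profiles (Gaussian
modalities on the arcsinh scale, optionally bimodal with a "hi"
fraction), two-tier combinatorial barcode channels with configurable
noise, a per-antibody screen readout channel, linear acquisition-time
background drift, and multiplicative fixation perturbations -- plus
per-event ground-truth sidecars so every pipeline stage can be scored
against what was planted.

Values are drawn on the arcsinh scale, where staining separations are
naturally specified, and mapped to raw ion counts via
``sinh(x) * cofactor`` (clipped at zero).  Random streams are keyed
by (seed, donor, well): the fresh and fixed aliquots of a well share
the same draws, and fixation enters only as a deterministic
multiplicative factor on raw readout intensities, so planted fold
changes are exact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ExperimentManifest, Well
from .fcs import DEFAULT_COFACTOR, EventMatrix, write_fcs

__all__ = [
    "MarkerSpec",
    "SimulationConfig",
    "simulate_sample_unit",
    "simulate_batch",
    "write_experiment",
]


@dataclass(frozen=True)
class MarkerSpec:
    """One marker's modality in one subset, on the arcsinh scale.

    Unimodal: mean/sd.  Bimodal: lo_mean/hi_mean with ``hi_frac`` of
    events in the high component; component membership is recorded in
    the sidecar through the profile name (e.g. ``CD161hi CD8 T``).
    """

    mean: float = 0.0
    sd: float = 0.3
    hi_mean: float | None = None
    hi_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("marker sd must be positive")
        if not 0.0 <= self.hi_frac <= 1.0:
            raise ValueError("hi_frac must lie in [0, 1]")
        if self.hi_frac > 0 and self.hi_mean is None:
            raise ValueError("bimodal marker needs hi_mean")

    @property
    def bimodal(self) -> bool:
        return self.hi_frac > 0 and self.hi_mean is not None


@dataclass
class AntibodySpec:
    """Screen readout behaviour of one antibody well.

    ``frac`` maps a subset or profile name to the fraction of its
    events positive on the readout channel; unlisted groups fall back
    to the subset entry, then to ``default_frac``.
    """

    pos_level: float = 3.0
    neg_level: float = 0.3
    sd: float = 0.25
    frac: dict[str, float] = field(default_factory=dict)
    default_frac: float = 0.0

    def frac_for(self, profile: str, subset: str) -> float:
        if profile in self.frac:
            return self.frac[profile]
        if subset in self.frac:
            return self.frac[subset]
        return self.default_frac


@dataclass
class DriftSpec:
    """Linear rise of one marker's negative-modality background over time."""

    marker: str
    slope: float  # arcsinh units per unit acquisition time
    batches: list[str] | None = None  # None = every batch


@dataclass
class SimulationConfig:
    donors: dict[str, dict[str, float]]  # donor -> subset -> frequency
    subsets: dict[str, dict[str, MarkerSpec]]  # subset -> marker -> spec
    antibodies: dict[str, AntibodySpec] = field(default_factory=dict)
    fixation: dict[str, float | dict[str, float]] = field(default_factory=dict)
    drift: DriftSpec | None = None
    barcode_positive: float = 2.5  # arcsinh level of a positive barcode channel
    barcode_negative: float = 0.3
    barcode_sd: float = 0.15
    readout_channel: str = "PE"
    fixed_treatment: str = "fixed"
    n_events: int = 200  # per sample unit
    acquisition_window: float = 1000.0  # seconds per batch
    cofactor: float = DEFAULT_COFACTOR
    seed: int = 0

    def __post_init__(self) -> None:
        for donor, freqs in self.donors.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"subset frequencies for {donor!r} sum to {total}, not 1")
            unknown = set(freqs) - set(self.subsets)
            if unknown:
                raise ValueError(f"donor {donor!r} references unknown subsets {unknown}")

    @property
    def markers(self) -> list[str]:
        seen: list[str] = []
        for profile in self.subsets.values():
            for m in profile:
                if m not in seen:
                    seen.append(m)
        return seen

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _unit_rng(config: SimulationConfig, donor: str, well_id: str) -> np.random.Generator:
    """Stream shared by the fresh and fixed aliquots of one (donor, well)."""
    donors = list(config.donors)
    key = hashlib.sha256(f"{donor}|{well_id}".encode()).digest()[:4]
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(donors.index(donor),
                                                       int.from_bytes(key, "big")))
    )


def _profile_name(subset: str, components: dict[str, bool]) -> str:
    """Profiling-style ground-truth name: bimodal component tags + subset."""
    tags = [f"{m}{'hi' if hi else 'lo'}" for m, hi in components.items()]
    return (" ".join(tags) + " " + subset) if tags else subset


def simulate_sample_unit(
    config: SimulationConfig,
    donor: str,
    treatment: str,
    well: Well | str,
    n_events: int | None = None,
    stream_seed: np.random.Generator | None = None,
) -> tuple[EventMatrix, pd.DataFrame]:
    """Draw one (donor, treatment, well) sample unit on the raw scale.

    Returns the raw EventMatrix (marker channels plus the readout
    channel) and a sidecar frame with per-event ``subset`` and
    ``profile`` ground truth.
    """
    if isinstance(well, str):
        well = Well(well_id=well, antibody=well)
    n = config.n_events if n_events is None else n_events
    rng = stream_seed or _unit_rng(config, donor, well.well_id)
    freqs = config.donors[donor]
    subset_names = sorted(freqs)
    probs = np.array([freqs[s] for s in subset_names])
    subset_idx = rng.choice(len(subset_names), size=n, p=probs)
    subsets = np.array(subset_names, dtype=object)[subset_idx]

    markers = config.markers
    X = np.zeros((n, len(markers)))
    profiles = np.empty(n, dtype=object)
    hi_draw = {}  # (subset, marker) -> per-event uniform, drawn once for determinism
    for j, marker in enumerate(markers):
        noise = rng.normal(size=n)
        u = rng.uniform(size=n)
        for s_i, subset in enumerate(subset_names):
            spec = config.subsets[subset].get(marker, MarkerSpec())
            mask = subset_idx == s_i
            if spec.bimodal:
                hi = u[mask] < spec.hi_frac
                mean = np.where(hi, spec.hi_mean, spec.mean)
                hi_draw[(subset, marker)] = (mask, hi)
            else:
                mean = spec.mean
            X[mask, j] = mean + spec.sd * noise[mask]

    # Ground-truth profile names from the bimodal component draws.
    comp_tags = [dict() for _ in range(n)]
    for (subset, marker), (mask, hi) in sorted(hi_draw.items()):
        idx = np.flatnonzero(mask)
        for pos, event in enumerate(idx):
            comp_tags[event][marker] = bool(hi[pos])
    for i in range(n):
        profiles[i] = _profile_name(subsets[i], comp_tags[i])

    # Screen readout.
    antibody = well.antibody
    spec = config.antibodies.get(antibody, AntibodySpec())
    u_pos = rng.uniform(size=n)
    readout_noise = rng.normal(size=n)
    frac = np.array([spec.frac_for(profiles[i], subsets[i]) for i in range(n)])
    positive = u_pos < frac
    readout = np.where(positive, spec.pos_level, spec.neg_level) + spec.sd * readout_noise

    values = np.column_stack([X, readout])
    raw = np.clip(np.sinh(values) * config.cofactor, 0.0, None)

    if treatment == config.fixed_treatment and antibody in config.fixation:
        factor = config.fixation[antibody]
        if isinstance(factor, dict):
            f = np.array([factor.get(s, 1.0) for s in subsets])
        else:
            f = float(factor)
        j = len(markers)  # readout column
        raw[:, j] = raw[:, j] * f

    channel_names = markers + [config.readout_channel]
    sidecar = pd.DataFrame(
        {
            "donor": donor,
            "treatment": treatment,
            "well": well.well_id,
            "antibody": antibody,
            "subset": subsets,
            "profile": profiles,
            "readout_positive": positive,
        }
    )
    return EventMatrix(raw, channel_names, scale="raw"), sidecar


def simulate_batch(
    config: SimulationConfig,
    manifest: ExperimentManifest,
    batch_id: str,
) -> tuple[EventMatrix, pd.DataFrame]:
    """Pool a batch's sample units with their two-tier barcode channels.

    Events are shuffled with a seeded stream, acquisition times are
    assigned uniformly (sorted) over the acquisition window, and the
    optional drift spec raises the target marker's negative-modality
    background linearly with time.
    """
    wells = manifest.batch(batch_id)
    inner = manifest.inner_scheme
    outer = manifest.outer_scheme
    batch_index = [bid for bid, _ in manifest.batches].index(batch_id)
    batch_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(10_000 + batch_index,))
    )

    blocks, sidecars = [], []
    bc_channels = list(inner.channels) + list(outer.channels)
    for pos, well in enumerate(wells):
        outer_code = outer.codes[pos]
        for donor in manifest.donors:
            for treatment in manifest.treatments:
                unit, sidecar = simulate_sample_unit(config, donor, treatment, well)
                inner_code = inner.codes[manifest.inner_code_id(donor, treatment)]
                n = unit.n_events
                bc = np.empty((n, len(bc_channels)))
                for j, ch in enumerate(bc_channels):
                    positive = (ch in inner_code) or (ch in outer_code)
                    level = config.barcode_positive if positive else config.barcode_negative
                    bc[:, j] = level + config.barcode_sd * batch_rng.normal(size=n)
                raw_bc = np.clip(np.sinh(bc) * config.cofactor, 0.0, None)
                blocks.append(np.column_stack([unit.values, raw_bc]))
                sidecars.append(sidecar)

    values = np.vstack(blocks)
    sidecar = pd.concat(sidecars, ignore_index=True)
    order = batch_rng.permutation(values.shape[0])
    values = values[order]
    sidecar = sidecar.iloc[order].reset_index(drop=True)
    times = np.sort(batch_rng.uniform(0.0, config.acquisition_window, size=values.shape[0]))

    channel_names = config.markers + [config.readout_channel] + bc_channels
    if config.drift is not None and (
        config.drift.batches is None or batch_id in config.drift.batches
    ):
        j = channel_names.index(config.drift.marker)
        arc = np.arcsinh(values[:, j] / config.cofactor)
        neg_mask = _negative_modality_mask(config, config.drift.marker, sidecar["subset"])
        arc[neg_mask] = arc[neg_mask] + config.drift.slope * times[neg_mask]
        values[:, j] = np.clip(np.sinh(arc) * config.cofactor, 0.0, None)

    sidecar.insert(0, "batch", batch_id)
    events = EventMatrix(values, channel_names, scale="raw", acquisition_time=times)
    return events, sidecar


def _negative_modality_mask(
    config: SimulationConfig, marker: str, subsets: pd.Series
) -> np.ndarray:
    """Events whose subset sits in the marker's negative modality."""
    means = {}
    for subset, profile in config.subsets.items():
        spec = profile.get(marker, MarkerSpec())
        means[subset] = spec.hi_mean if spec.bimodal and spec.hi_frac >= 0.5 else spec.mean
    lo, hi = min(means.values()), max(means.values())
    midpoint = 0.5 * (lo + hi)
    negative_subsets = {s for s, m in means.items() if m <= midpoint}
    return subsets.isin(negative_subsets).to_numpy()


def write_experiment(
    config: SimulationConfig,
    manifest: ExperimentManifest,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write every batch as FCS plus sidecar CSV and a provenance JSON.

    Output is byte-identical across reruns with the same config and
    seed (deterministic FCS writer, fixed CSV formatting).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for batch_id, _wells in manifest.batches:
        events, sidecar = simulate_batch(config, manifest, batch_id)
        fcs_path = out_dir / f"{batch_id}.fcs"
        write_fcs(events, fcs_path)
        csv_path = out_dir / f"{batch_id}_sidecar.csv"
        sidecar.to_csv(csv_path, index=False)
        paths[batch_id] = fcs_path
    manifest.save(out_dir / "manifest.json")
    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_batches": manifest.n_batches,
        "n_sample_units": manifest.n_sample_units,
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    return paths
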