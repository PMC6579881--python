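"""Combinatorial barcode schemes and experiment manifests.

A k-of-n barcode scheme marks each pooled sample with a unique
combination of k positive channels out of n barcoding channels.  The
screen design uses two tiers: an inner CD45-based tier encoding
(donor, treatment) pairs -- 2-of-4, six codes -- and an outer
palladium tier encoding the well's position within its batch of ten
-- 2-of-5, ten codes.  A full batch therefore resolves into
6 x 10 = 60 combined codes.  The manifest tracks donors, treatments,
antibody wells, their batching, and post-hoc well exclusions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations, product
from math import comb, ceil
from pathlib import Path
from typing import Sequence

__all__ = [
    "BarcodeScheme",
    "Well",
    "ExperimentManifest",
    "make_scheme",
    "build_manifest",
    "expected_codes_per_batch",
]


@dataclass(frozen=True)
class BarcodeScheme:
    """k-of-n combinatorial code table over an ordered channel list.

    Codes are the k-subsets of the channels enumerated in lexicographic
    order of channel index; ``code_ids`` run 0..C(n,k)-1.
    """

    channels: tuple[str, ...]
    k: int
    codes: tuple[frozenset[str], ...]

    @property
    def n_codes(self) -> int:
        return len(self.codes)

    def code_id(self, positive_channels: frozenset[str] | set[str]) -> int | None:
        """Return the code id of a channel set, or None if not a valid code."""
        target = frozenset(positive_channels)
        try:
            return self._lookup[target]
        except AttributeError:
            object.__setattr__(self, "_lookup", {c: i for i, c in enumerate(self.codes)})
            return self._lookup.get(target)
        except KeyError:
            return None

    def to_dict(self) -> dict:
        return {"channels": list(self.channels), "k": self.k}


def make_scheme(channels: Sequence[str], k: int) -> BarcodeScheme:
    """Enumerate the k-of-n scheme over ``channels``.

    4 channels choose 2 gives the 6 inner (donor x treatment) codes;
    5 choose 2 gives the 10 outer within-batch codes.
    """
    channels = tuple(channels)
    if len(set(channels)) != len(channels):
        raise ValueError("barcode channels must be unique")
    if not 1 <= k <= len(channels):
        raise ValueError(f"k={k} out of range for {len(channels)} channels")
    codes = tuple(frozenset(c) for c in combinations(channels, k))
    assert len(codes) == comb(len(channels), k)
    return BarcodeScheme(channels=channels, k=k, codes=codes)


@dataclass(frozen=True)
class Well:
    well_id: str
    antibody: str
    is_control: bool = False


@dataclass
class ExperimentManifest:
    """Bookkeeping for a two-tier barcoded screen.

    ``inner_scheme`` encodes (donor, treatment); ``outer_scheme``
    encodes a well's position within its batch.  Excluded wells stay in
    the batch structure but are flagged, mirroring post-hoc exclusion
    of failed wells.
    """

    donors: list[str]
    treatments: list[str]
    wells: list[Well]
    batch_size: int
    inner_scheme: BarcodeScheme
    outer_scheme: BarcodeScheme
    batches: list[tuple[str, list[Well]]] = field(default_factory=list)
    exclusions: set[str] = field(default_factory=set)

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    @property
    def n_sample_units(self) -> int:
        """All (donor, treatment, well) combinations, exclusions included."""
        return len(self.donors) * len(self.treatments) * len(self.wells)

    @property
    def n_retained_units(self) -> int:
        kept = sum(1 for w in self.wells if w.well_id not in self.exclusions)
        return len(self.donors) * len(self.treatments) * kept

    def inner_code_id(self, donor: str, treatment: str) -> int:
        pairs = list(product(self.donors, self.treatments))
        return pairs.index((donor, treatment))

    def batch(self, batch_id: str) -> list[Well]:
        for bid, wells in self.batches:
            if bid == batch_id:
                return wells
        raise KeyError(f"unknown batch {batch_id!r}")

    def to_dict(self) -> dict:
        return {
            "donors": self.donors,
            "treatments": self.treatments,
            "wells": [[w.well_id, w.antibody, w.is_control] for w in self.wells],
            "batch_size": self.batch_size,
            "inner_scheme": self.inner_scheme.to_dict(),
            "outer_scheme": self.outer_scheme.to_dict(),
            "batches": [[bid, [w.well_id for w in ws]] for bid, ws in self.batches],
            "exclusions": sorted(self.exclusions),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def build_manifest(
    donors: Sequence[str],
    treatments: Sequence[str],
    wells: Sequence[Well | tuple],
    batch_size: int,
    inner_scheme: BarcodeScheme,
    outer_scheme: BarcodeScheme,
    exclusions: Sequence[str] = (),
) -> ExperimentManifest:
    """Partition wells into batches and fix both code assignments.

    Wells are batched in input order into ``ceil(n_wells/batch_size)``
    batches.  Each (donor, treatment) pair takes the inner code of its
    lexicographic position; each well takes the outer code of its
    position within its batch.  The reference screen design -- 372
    wells, 3 donors, 2 treatments, batches of 10 -- yields 38 batches
    and 2,232 sample units (2,160 after excluding 12 wells).
    """
    donors = list(donors)
    treatments = list(treatments)
    wells = [w if isinstance(w, Well) else Well(*w) for w in wells]
    if len({w.well_id for w in wells}) != len(wells):
        raise ValueError("well ids must be unique")
    if len(donors) * len(treatments) > inner_scheme.n_codes:
        raise ValueError(
            f"{len(donors)}x{len(treatments)} donor/treatment pairs exceed "
            f"{inner_scheme.n_codes} inner codes"
        )
    if batch_size > outer_scheme.n_codes:
        raise ValueError(
            f"batch size {batch_size} exceeds {outer_scheme.n_codes} outer codes"
        )
    if batch_size < 1:
        raise ValueError("batch size must be positive")
    unknown = set(exclusions) - {w.well_id for w in wells}
    if unknown:
        raise ValueError(f"exclusions reference unknown wells: {sorted(unknown)}")

    n_batches = ceil(len(wells) / batch_size)
    batches = []
    for b in range(n_batches):
        chunk = wells[b * batch_size : (b + 1) * batch_size]
        batches.append((f"batch_{b + 1:02d}", chunk))
    return ExperimentManifest(
        donors=donors,
        treatments=treatments,
        wells=wells,
        batch_size=batch_size,
        inner_scheme=inner_scheme,
        outer_scheme=outer_scheme,
        batches=batches,
        exclusions=set(exclusions),
    )


def expected_codes_per_batch(
    manifest: ExperimentManifest, batch_id: str
) -> list[tuple[int, int, str, str, str]]:
    """Enumerate (inner_code_id, outer_code_id, donor, treatment, well_id).

    A full batch of the reference design yields 6 x 10 = 60 entries;
    partial final batches yield 6 x n_wells.
    """
    wells = manifest.batch(batch_id)
    entries = []
    for pos, well in enumerate(wells):
        for donor, treatment in product(manifest.donors, manifest.treatments):
            inner = manifest.inner_code_id(donor, treatment)
            entries.append((inner, pos, donor, treatment, well.well_id))
    return entries
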