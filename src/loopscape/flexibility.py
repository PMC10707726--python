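"""Normalized B-factor (z-score) profiles and region flexibility labels.

Crystals refined from different datasets have incomparable absolute
B-factors (overall protein B can differ by a factor of two between forms),
so per-residue Cα B-factors are z-scored within a normalization population
— by default the chain they belong to — before regions are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, EmptySelectionError
from .structure_io import RegionSpec, Structure

__all__ = ["BFactorProfile", "RegionFlexibility",
           "normalize_bfactors", "region_flexibility"]


@dataclass
class BFactorProfile:
    """Per-residue Cα B-factors with their within-scope z-scores."""

    residue_keys: list[tuple[str, int]]
    raw_b: np.ndarray
    z: np.ndarray
    scope: str                      # "chain" or "structure"
    gaps: list[tuple[str, int]] = field(default_factory=list)  # residues missing Cα

    def __len__(self) -> int:
        return len(self.residue_keys)

    def region_values(self, region: RegionSpec,
                      chain_id: str | None = None) -> np.ndarray:
        idx = [i for i, (cid, num) in enumerate(self.residue_keys)
               if region.contains(num) and (chain_id is None or cid == chain_id)]
        return self.z[idx]


@dataclass
class RegionFlexibility:
    region: str
    mean_z: float
    label: str                      # rigid | average | flexible
    n_residues: int


def _zscore(raw: np.ndarray) -> np.ndarray:
    sd = raw.std()
    if sd == 0:
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def normalize_bfactors(s: Structure, scope: str = "chain",
                       chain_id: str | None = None) -> BFactorProfile:
    """Z-score the Cα B-factors of a structure.

    ``scope="chain"`` normalizes each chain against itself (the default:
    chains from different crystals are then comparable); ``"structure"``
    uses one population over all selected chains.  Residues without a Cα
    are reported as gaps.
    """
    if scope not in {"chain", "structure"}:
        raise ConfigurationError(f"unknown normalization scope {scope!r}")
    chain_ids = [chain_id] if chain_id else s.protein_chain_ids()
    keys: list[tuple[str, int]] = []
    raw: list[float] = []
    gaps: list[tuple[str, int]] = []
    spans: list[tuple[int, int]] = []  # index ranges per chain
    for cid in chain_ids:
        start = len(keys)
        for r in s.residues(cid):
            ca = r.ca()
            if ca is None:
                gaps.append((cid, r.seq_num))
                continue
            keys.append((cid, r.seq_num))
            raw.append(ca.b_factor)
        spans.append((start, len(keys)))
    if not keys:
        raise EmptySelectionError(f"no Cα B-factors found in {s.id!r}")
    raw_arr = np.array(raw, dtype=float)
    if scope == "structure":
        z = _zscore(raw_arr)
    else:
        z = np.empty_like(raw_arr)
        for lo, hi in spans:
            if hi > lo:
                z[lo:hi] = _zscore(raw_arr[lo:hi])
    return BFactorProfile(keys, raw_arr, z, scope, gaps)


def region_flexibility(profile: BFactorProfile, region: RegionSpec,
                       threshold: float = 0.5,
                       chain_id: str | None = None) -> RegionFlexibility:
    """Mean z over a region with a three-way rigid/average/flexible label.

    The label threshold (default ±0.5 z units) is a reporting convention,
    not a physical constant.
    """
    vals = profile.region_values(region, chain_id)
    if len(vals) == 0:
        raise EmptySelectionError(
            f"region {region.name} ({region.start}-{region.end}) has no "
            "residues in the B-factor profile")
    mean_z = float(vals.mean())
    if mean_z > threshold:
        label = "flexible"
    elif mean_z < -threshold:
        label = "rigid"
    else:
        label = "average"
    return RegionFlexibility(region.name, mean_z, label, len(vals))
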