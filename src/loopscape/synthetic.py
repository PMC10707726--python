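"""Synthetic structure and sequence generators with planted ground truth.

The generator lays a Cα trace (plus a crude backbone and side-chain
carbons) on a loose helical curve with the canonical 3.8 Å Cα–Cα spacing,
then plants exactly the statistical features the analysis stages look for:

* one flexible loop present in two discrete conformations (a smooth swing
  of known amplitude),
* inflated B-factors inside the flexible span,
* optional per-residue outlier displacements,
* an optional known rigid-body transform generating a second chain,
* optional hydrogen bonds placed at an exact donor–acceptor distance.

Every planted quantity is recorded in :class:`GroundTruth`, so downstream
statistics can be predicted analytically.  Output is deterministic under
the spec seed (byte-identical files).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .structure_io import (AtomRecord, ONE_TO_THREE, RegionSpec, Residue,
                           Structure)

__all__ = ["SyntheticSpec", "GroundTruth", "generate_structure",
           "generate_conformer_pair", "generate_family", "DEFAULT_LOOPS"]

# Four loop spans mimicking the relative lengths of the TsaBgl loops
# (16 / 9 / 26 / 19 residues) on a 200-residue scaffold.
DEFAULT_LOOPS = (
    RegionSpec("L1", 30, 45),
    RegionSpec("L2", 70, 78),
    RegionSpec("L3", 110, 135),
    RegionSpec("L4", 160, 178),
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Loose helix with exact 3.8 Å Cα spacing: turn 50°, radius 3.5 Å.
_TURN = np.deg2rad(50.0)
_RADIUS = 3.5
_RISE = float(np.sqrt(3.8 ** 2 - (2 * _RADIUS * np.sin(_TURN / 2)) ** 2))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic structure; identical (spec, seed) pairs
    produce byte-identical output."""

    n_residues: int = 200
    loop_spans: tuple[RegionSpec, ...] = DEFAULT_LOOPS
    flexible_loop: str = "L3"
    swing_amplitude: float = 6.0          # Å, planted conformer displacement
    noise_sigma: float = 0.1              # per-axis Gaussian σ, Å
    b_background_mean: float = 20.0       # Å²
    b_background_sd: float = 5.0          # Å²
    b_flex_shift: float = 10.0            # Å² added inside the flexible span
    rigid_transform: tuple | None = None  # (rotation 3x3, translation 3)
    outliers: tuple[tuple[int, float], ...] = ()
    planted_hbonds: tuple[tuple[int, int], ...] = ()
    sequence: str | None = None
    with_sidechains: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_residues < 10:
            raise ConfigurationError("need at least 10 residues")
        if self.noise_sigma < 0 or self.swing_amplitude < 0:
            raise ConfigurationError("noise_sigma and swing_amplitude must be >= 0")
        spans = sorted(self.loop_spans, key=lambda r: r.start)
        for rg in spans:
            if rg.start < 1 or rg.end > self.n_residues:
                raise ConfigurationError(
                    f"loop {rg.name} ({rg.start}-{rg.end}) outside 1-{self.n_residues}")
        for a, b in zip(spans, spans[1:]):
            if b.start <= a.end:
                raise ConfigurationError(
                    f"loop spans {a.name} and {b.name} overlap")
        if self.flexible_loop not in {r.name for r in self.loop_spans}:
            raise ConfigurationError(
                f"flexible_loop {self.flexible_loop!r} is not a loop span name")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ConfigurationError("sequence length must equal n_residues")

    def flexible_span(self) -> RegionSpec:
        return next(r for r in self.loop_spans if r.name == self.flexible_loop)


@dataclass
class GroundTruth:
    """Everything that was planted, sufficient to predict every downstream
    statistic analytically or by direct simulation."""

    seed: int
    flexible_loop: str
    planted_displacement: np.ndarray      # per residue (index 0 = residue 1), Å
    true_transform: tuple | None = None   # (R, t) mapping chain A onto chain B
    planted_contacts: list[tuple[int, int]] = field(default_factory=list)
    sequence: str = ""
    b_flex_shift: float = 0.0
    noise_sigma: float = 0.0


def _backbone_curve(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack([_RADIUS * np.cos(_TURN * i),
                            _RADIUS * np.sin(_TURN * i),
                            _RISE * i])


def _swing_profile(spec: SyntheticSpec) -> np.ndarray:
    """Per-residue planted displacement: a smooth bump over the flexible
    span whose maximum equals exactly ``swing_amplitude``."""
    disp = np.zeros(spec.n_residues)
    if spec.swing_amplitude == 0:
        return disp
    rg = spec.flexible_span()
    idx = np.arange(rg.start - 1, rg.end)
    t = (idx - (rg.start - 1) + 1) / (len(rg) + 1)
    w = np.sin(np.pi * t)
    disp[idx] = spec.swing_amplitude * w / w.max()
    return disp


def _residue_atoms(i: int, ca: np.ndarray, curve: np.ndarray,
                   res_name: str, with_sidechains: bool) -> list[tuple[str, str, np.ndarray]]:
    n = len(curve)
    prev_i, next_i = max(i - 1, 0), min(i + 1, n - 1)
    tang = curve[next_i] - curve[prev_i]
    tang = tang / np.linalg.norm(tang)
    radial = np.array([ca[0], ca[1], 0.0])
    nr = np.linalg.norm(radial)
    radial = radial / nr if nr > 1e-9 else np.array([1.0, 0.0, 0.0])
    binorm = np.cross(tang, radial)
    bn = np.linalg.norm(binorm)
    binorm = binorm / bn if bn > 1e-9 else np.array([0.0, 0.0, 1.0])
    atoms = [("N", "N", ca - 1.46 * tang),
             ("CA", "C", ca),
             ("C", "C", ca + 1.52 * tang),
             ("O", "O", ca + 1.52 * tang + 1.23 * radial)]
    if with_sidechains and res_name != "GLY":
        atoms.append(("CB", "C", ca + 1.53 * binorm))
        # short apolar side chains for contact tests
        if res_name in {"LEU", "ILE", "PHE", "MET", "VAL", "TRP", "TYR"}:
            atoms.append(("CG", "C", ca + 2.9 * binorm))
            atoms.append(("CD1", "C", ca + 3.9 * binorm + 0.5 * tang))
    return atoms


def generate_structure(spec: SyntheticSpec) -> tuple[Structure, GroundTruth]:
    """Build one synthetic structure from a spec, with its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    seq = spec.sequence or "".join(rng.choice(list(AA20), spec.n_residues))
    curve = _backbone_curve(spec.n_residues)
    noise = (rng.normal(0.0, spec.noise_sigma, curve.shape)
             if spec.noise_sigma > 0 else np.zeros_like(curve))
    disp = _swing_profile(spec)
    # swing direction: radially outward from the helix axis
    radial = np.column_stack([curve[:, 0], curve[:, 1], np.zeros(len(curve))])
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)

    # local frames (hence all intra-residue atom offsets) come from the
    # unswung template, so a swing or outlier shifts each residue rigidly
    # and the twins stay bit-identical outside the flexible span
    frame = curve + noise
    shift = disp[:, None] * radial
    for resnum, amount in spec.outliers:
        shift[resnum - 1] += amount * radial[resnum - 1]
    ca = frame + shift

    flex = spec.flexible_span()
    base_b = rng.normal(spec.b_background_mean, spec.b_background_sd,
                        spec.n_residues)
    base_b = np.clip(base_b, 1.0, None)
    in_flex = np.array([flex.contains(i + 1) for i in range(spec.n_residues)])
    base_b[in_flex] += spec.b_flex_shift

    atom_templates = [
        [(nm, el, xyz - frame[i])
         for nm, el, xyz in _residue_atoms(i, frame[i], frame,
                                           ONE_TO_THREE.get(seq[i], "ALA"),
                                           spec.with_sidechains)]
        for i in range(spec.n_residues)
    ]

    def build_chain(cid: str, transform=None) -> list[Residue]:
        residues = []
        for i in range(spec.n_residues):
            rname = ONE_TO_THREE.get(seq[i], "ALA")
            rr = Residue(cid, i + 1, "", rname)
            for nm, el, offset in atom_templates[i]:
                xyz = ca[i] + offset
                if transform is not None:
                    R, t = transform
                    xyz = R @ xyz + t
                rr.atoms.append(AtomRecord(nm, el, np.round(xyz, 3),
                                           b_factor=round(float(base_b[i]), 2)))
            residues.append(rr)
        return residues

    s = Structure(id=f"synthetic-{spec.seed}")
    s.metadata["generator_seed"] = spec.seed
    s.chains["A"] = build_chain("A")
    if spec.rigid_transform is not None:
        R, t = spec.rigid_transform
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise ConfigurationError("rigid_transform rotation must be proper")
        s.chains["B"] = build_chain("B", transform=(R, t))

    planted = []
    for res_a, res_b in spec.planted_hbonds:
        # place residue b's carbonyl O at exactly 2.9 Å from residue a's N,
        # pointing radially outward so no other polar atom comes close
        for ch in s.chains.values():
            ra, rb = ch[res_a - 1], ch[res_b - 1]
            n_pos = ra.atom("N").coords
            rb.atom("O").coords = np.round(n_pos + 2.9 * radial[res_a - 1], 3)
        planted.append((res_a, res_b))

    truth = GroundTruth(
        seed=spec.seed,
        flexible_loop=spec.flexible_loop,
        planted_displacement=disp,
        true_transform=spec.rigid_transform,
        planted_contacts=planted,
        sequence=seq,
        b_flex_shift=spec.b_flex_shift,
        noise_sigma=spec.noise_sigma,
    )
    return s, truth


def generate_conformer_pair(spec: SyntheticSpec
                            ) -> tuple[Structure, Structure, GroundTruth]:
    """Twin structures identical outside the flexible span.

    The "folded" twin is the unswung template; the "straight" twin has the
    flexible span displaced along a smooth arc of the planted amplitude.
    B-factors are inflated inside the span on both twins.
    """
    folded_spec = dataclasses.replace(spec, swing_amplitude=0.0)
    folded, _ = generate_structure(folded_spec)
    straight, truth = generate_structure(spec)
    folded.id = f"synthetic-folded-{spec.seed}"
    straight.id = f"synthetic-straight-{spec.seed}"
    return folded, straight, truth


def generate_family(n_species: int = 6,
                    ref_length: int = 160,
                    loops: tuple[RegionSpec, ...] = (
                        RegionSpec("L1", 20, 33),
                        RegionSpec("L2", 50, 58),
                        RegionSpec("L3", 80, 105),
                        RegionSpec("L4", 125, 143),
                    ),
                    loop_offsets: dict[str, tuple[str, int]] | None = None,
                    invariant_columns: tuple[int, ...] = (),
                    mutation_rate: float = 0.1,
                    force_variation: bool = False,
                    seed: int = 0) -> tuple[dict[str, str], dict]:
    """Reference sequence plus mutated/indel-bearing homologs.

    ``loop_offsets`` maps species tag -> (loop name, offset): positive
    offsets insert random residues mid-loop, negative ones delete.
    ``invariant_columns`` (1-based reference positions) are never mutated;
    with ``force_variation`` every other position differs from the
    reference in at least one homolog, so planted invariant columns are
    exactly the fully conserved ones.  Returns (records, truth).
    """
    rng = np.random.default_rng(seed)
    loop_offsets = dict(loop_offsets or {})
    for rg in loops:
        if rg.end > ref_length:
            raise ConfigurationError(f"loop {rg.name} outside the reference")
    for tag, (loop_name, off) in loop_offsets.items():
        rg = next((r for r in loops if r.name == loop_name), None)
        if rg is None:
            raise ConfigurationError(f"unknown loop {loop_name!r}")
        if len(rg) + off <= 0:
            raise ConfigurationError(
                f"offset {off} makes loop {loop_name} non-positive")
    ref = "".join(rng.choice(list(AA20), ref_length))
    invariant = set(invariant_columns)
    records = {"REF": ref}
    expected_lengths = {"REF": {rg.name: len(rg) for rg in loops}}
    tags = [f"SP{i + 1}" for i in range(n_species - 1)]
    mutated_somewhere: set[int] = set()
    for tag in tags:
        seq = list(ref)
        for pos in range(ref_length):
            if (pos + 1) in invariant:
                continue
            if rng.random() < mutation_rate:
                choices = [c for c in AA20 if c != seq[pos]]
                seq[pos] = rng.choice(choices)
                mutated_somewhere.add(pos + 1)
        lengths = {rg.name: len(rg) for rg in loops}
        if tag in loop_offsets:
            loop_name, off = loop_offsets[tag]
            rg = next(r for r in loops if r.name == loop_name)
            mid = (rg.start + rg.end) // 2  # 1-based
            if off > 0:
                ins = "".join(rng.choice(list(AA20), off))
                seq = seq[:mid] + list(ins) + seq[mid:]
            else:
                seq = seq[:mid] + seq[mid - off:]
            lengths[loop_name] = len(rg) + off
        records[tag] = "".join(seq)
        expected_lengths[tag] = lengths
    if force_variation:
        # guarantee every non-invariant column varies in >= 1 homolog;
        # indel-bearing homologs are avoided (their positions are shifted)
        clean_tags = [t for t in tags if t not in loop_offsets]
        if not clean_tags:
            raise ConfigurationError(
                "force_variation needs at least one homolog without an indel")
        for pos in range(1, ref_length + 1):
            if pos in invariant or pos in mutated_somewhere:
                continue
            tag = clean_tags[int(rng.integers(len(clean_tags)))]
            seq = list(records[tag])
            choices = [c for c in AA20 if c != seq[pos - 1]]
            seq[pos - 1] = rng.choice(choices)
            records[tag] = "".join(seq)
            mutated_somewhere.add(pos)
    truth = {
        "seed": seed,
        "loops": {rg.name: (rg.start, rg.end) for rg in loops},
        "expected_lengths": expected_lengths,
        "invariant_columns": sorted(invariant),
    }
    return records, truth
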