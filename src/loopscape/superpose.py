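"""Rigid-body superposition and per-residue displacement profiles.

The Kabsch algorithm gives the closed-form least-squares proper rotation
between two paired point sets; :func:`refine_superposition` wraps it in the
usual iterative outlier rejection (drop pairs whose residual exceeds a
multiple of the residual standard deviation, refit, repeat).  Pairing is
strictly by author residue number — sequence alignment never happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FitError, PairingError, RefinementError
from .structure_io import RegionSpec, Residue, Structure

__all__ = [
    "Superposition", "DisplacementProfile",
    "kabsch_fit", "refine_superposition", "rmsd", "displacement_profile",
]


@dataclass
class Superposition:
    """Result of a rigid-body fit mapping P onto Q: x -> rotation @ x + translation."""

    rotation: np.ndarray          # (3, 3) proper rotation
    translation: np.ndarray       # (3,)
    rmsd: float                   # over kept pairs, Å
    kept_mask: np.ndarray         # bool per input pair
    n_cycles_run: int = 0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


@dataclass
class DisplacementProfile:
    """Per-residue Cα displacement between two conformers after core superposition."""

    residue_keys: list[tuple[str, int]]
    displacement: np.ndarray      # (n,), Å
    core_mask: np.ndarray = field(default=None)  # True where residue was in the fit
    unpaired: list[tuple[str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residue_keys)

    def at(self, seq_num: int) -> float:
        for key, d in zip(self.residue_keys, self.displacement):
            if key[1] == seq_num:
                return float(d)
        raise KeyError(f"residue {seq_num} not in profile")

    def restrict(self, region: RegionSpec) -> "DisplacementProfile":
        idx = [i for i, k in enumerate(self.residue_keys)
               if region.contains(k[1])]
        return DisplacementProfile(
            [self.residue_keys[i] for i in idx],
            self.displacement[idx],
            None if self.core_mask is None else self.core_mask[idx],
        )


def _as_points(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise PairingError(f"expected an (n, 3) coordinate array, got shape {X.shape}")
    return X


def _check_paired(P: np.ndarray, Q: np.ndarray, min_pairs: int = 1) -> None:
    if len(P) != len(Q):
        raise PairingError(f"point sets differ in size: {len(P)} vs {len(Q)}")
    if len(P) < min_pairs:
        raise FitError(f"need at least {min_pairs} pairs, got {len(P)}")


def kabsch_fit(P, Q) -> Superposition:
    """Least-squares proper-rotation superposition of P onto Q.

    Minimises the r.m.s.d. of ``R @ P + t`` against ``Q`` over all proper
    rotations R (determinant +1; reflections are excluded, so mirror-image
    point sets keep a positive residual).
    """
    P, Q = _as_points(P), _as_points(Q)
    _check_paired(P, Q, min_pairs=3)
    Pm, Qm = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - Pm, Q - Qm
    # collinear (or coincident) points leave the rotation under-determined
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise FitError("degenerate geometry: points are collinear")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = Qm - R @ Pm
    resid = np.linalg.norm(P @ R.T + t - Q, axis=1)
    return Superposition(
        rotation=R,
        translation=t,
        rmsd=float(np.sqrt(np.mean(resid ** 2))),
        kept_mask=np.ones(len(P), dtype=bool),
        n_cycles_run=0,
    )


def refine_superposition(P, Q, max_cycles: int = 5,
                         reject_sigma: float = 2.0) -> Superposition:
    """Iterative outlier-rejecting Kabsch fit.

    Each cycle fits on the kept pairs and drops pairs whose residual exceeds
    ``reject_sigma`` times the r.m.s. residual of the kept set (the standard
    deviation of the residuals, whose mean vector is zero after the fit);
    iteration stops when no pair is dropped or ``max_cycles`` fits have been
    run.  The reported r.m.s.d. covers the final kept pairs only.
    """
    P, Q = _as_points(P), _as_points(Q)
    _check_paired(P, Q, min_pairs=3)
    if max_cycles < 0:
        raise ValueError("max_cycles must be >= 0")
    if max_cycles == 0:
        return kabsch_fit(P, Q)
    kept = np.ones(len(P), dtype=bool)
    trace: list[dict] = []
    fit = None
    for cycle in range(1, max_cycles + 1):
        fit = kabsch_fit(P[kept], Q[kept])
        resid = np.linalg.norm(fit.apply(P) - Q, axis=1)
        sd = float(np.sqrt(np.mean(resid[kept] ** 2)))
        drop = kept & (resid > reject_sigma * sd) if sd > 0 else np.zeros_like(kept)
        trace.append({"cycle": cycle, "kept": int(kept.sum()),
                      "rmsd": fit.rmsd, "dropped": int(drop.sum())})
        if not drop.any():
            return Superposition(fit.rotation, fit.translation, fit.rmsd,
                                 kept.copy(), n_cycles_run=cycle)
        new_kept = kept & ~drop
        if new_kept.sum() < 3:
            raise RefinementError(
                f"refinement rejected too many pairs ({int(new_kept.sum())} left)",
                cycle_trace=trace)
        kept = new_kept
    # cycle budget exhausted: refit on the final kept set for the report
    fit = kabsch_fit(P[kept], Q[kept])
    return Superposition(fit.rotation, fit.translation, fit.rmsd,
                         kept.copy(), n_cycles_run=max_cycles)


def rmsd(P, Q, superpose: bool = False) -> float:
    """Root-mean-square deviation of paired points, optionally after a Kabsch fit."""
    P, Q = _as_points(P), _as_points(Q)
    _check_paired(P, Q, min_pairs=1)
    if superpose:
        return kabsch_fit(P, Q).rmsd
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def _ca_table(residues: list[Residue]) -> dict[tuple[int, str], np.ndarray]:
    table = {}
    for r in residues:
        ca = r.ca()
        if ca is not None:
            table[(r.seq_num, r.ins_code)] = ca.coords
    return table


def displacement_profile(
    s_a: Structure, chain_a: str,
    s_b: Structure, chain_b: str,
    core: RegionSpec | list[RegionSpec],
    core_is_exclusion: bool = False,
    max_cycles: int = 1,
    reject_sigma: float = 2.0,
) -> DisplacementProfile:
    """Per-residue Cα displacement of chain_b relative to chain_a.

    The superposition is fitted ONLY on core-region Cα atoms (or, with
    ``core_is_exclusion=True``, on everything outside the given regions —
    the usual "full chain minus loops" frame), then applied to the whole
    chain; the profile reports the Cα distance for every residue shared by
    author number.
    """
    regions = [core] if isinstance(core, RegionSpec) else list(core)
    res_a = s_a.residues(chain_a)
    res_b = s_b.residues(chain_b)
    ca_a, ca_b = _ca_table(res_a), _ca_table(res_b)
    shared = [k for k in sorted(ca_a) if k in ca_b]
    unpaired = ([(chain_a, k[0]) for k in sorted(ca_a) if k not in ca_b]
                + [(chain_b, k[0]) for k in sorted(ca_b) if k not in ca_a])
    in_region = np.array(
        [any(rg.contains(k[0]) for rg in regions) for k in shared], dtype=bool)
    core_mask = ~in_region if core_is_exclusion else in_region
    if core_mask.sum() < 3:
        raise FitError(
            f"fewer than 3 shared core residues ({int(core_mask.sum())})")
    A = np.array([ca_a[k] for k in shared])
    B = np.array([ca_b[k] for k in shared])
    if max_cycles > 1:
        fit = refine_superposition(B[core_mask], A[core_mask],
                                   max_cycles=max_cycles,
                                   reject_sigma=reject_sigma)
    else:
        fit = kabsch_fit(B[core_mask], A[core_mask])
    disp = np.linalg.norm(fit.apply(B) - A, axis=1)
    keys = [(chain_a, k[0]) for k in shared]
    return DisplacementProfile(keys, disp, core_mask, unpaired)
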