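"""Geometric hydrogen-bond and hydrophobic-contact detection.

Crystal structures at typical resolution carry no hydrogen atoms, so the
hydrogen-bond criterion is the standard distance-only fallback: a polar
donor and acceptor heavy atom (N/O, optionally S) within a cutoff.
Hydrophobic contacts are side-chain carbon pairs of apolar residues within
a cutoff, reported once per residue pair at the minimum carbon–carbon
distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .structure_io import RegionSpec, Residue, Structure

__all__ = ["Contact", "detect_hbonds", "detect_hydrophobic", "loop_contact_report"]

ResKey = tuple[str, int, str]

# Apolar residues whose side-chain carbons participate in hydrophobic packing.
APOLAR = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR", "CYS"}
# Tyr contributes ring carbons only (the hydroxyl end is polar).
TYR_RING = {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}
MAINCHAIN = {"N", "CA", "C", "O", "OXT"}
# Hydroxyl oxygens that can donate as well as accept.
DONOR_OXYGENS = {"OG", "OG1", "OH"}


@dataclass(frozen=True)
class Contact:
    """One detected interaction, stored once in canonical residue-key order."""

    kind: str                      # hbond | hydrophobic
    res_a: ResKey
    res_b: ResKey
    res_name_a: str
    res_name_b: str
    atom_a: str
    atom_b: str
    distance: float

    def involves(self, seq_num: int) -> bool:
        return self.res_a[1] == seq_num or self.res_b[1] == seq_num


def _canonical(kind, key_a, name_a, atom_a, key_b, name_b, atom_b, dist) -> Contact:
    if (key_b, atom_b) < (key_a, atom_a):
        key_a, name_a, atom_a, key_b, name_b, atom_b = \
            key_b, name_b, atom_b, key_a, name_a, atom_a
    return Contact(kind, key_a, key_b, name_a, name_b, atom_a, atom_b,
                   round(float(dist), 4))


def _polar_atoms(residues: list[Residue], include_sulfur: bool):
    """(residue, atom, coords, is_donor, is_acceptor, is_mainchain) rows."""
    rows = []
    for r in residues:
        seen = set()
        for a in r.atoms:
            if a.name in seen:          # altloc collapse: keep best copy
                continue
            best = r.atom(a.name)
            el = (best.element or best.name[:1]).upper()
            if el not in {"N", "O"} and not (include_sulfur and el == "S"):
                continue
            seen.add(a.name)
            donor = el == "N" or best.name in DONOR_OXYGENS or el == "S"
            acceptor = el in {"O", "S"} or el == "N"
            rows.append((r, best.name, best.coords, donor, acceptor,
                         best.name in MAINCHAIN))
    return rows


def detect_hbonds(s: Structure, chain_id: str | None = None,
                  d_max: float = 3.5, seq_sep_min: int = 2,
                  include_sulfur: bool = False,
                  include_het: bool = False) -> list[Contact]:
    """Distance-only hydrogen bonds: donor–acceptor N/O heavy-atom pairs ≤ d_max.

    Same-residue pairs are always excluded; mainchain–mainchain pairs within
    ``seq_sep_min`` residues on the same chain are excluded (they are
    covalently constrained), while pairs involving a side chain only need to
    be on different residues.
    """
    if d_max <= 0:
        raise ConfigurationError("d_max must be positive")
    residues = s.residues(chain_id, include_het=include_het)
    rows = _polar_atoms(residues, include_sulfur)
    if not rows:
        return []
    coords = np.array([row[2] for row in rows])
    tree = cKDTree(coords)
    out: list[Contact] = []
    for i, j in sorted(tree.query_pairs(d_max)):
        ra, na, ca_, da, aa, ma = rows[i]
        rb, nb, cb, db, ab, mb = rows[j]
        if ra.key == rb.key:
            continue
        if ra.chain_id == rb.chain_id:
            sep = abs(ra.seq_num - rb.seq_num)
            min_sep = seq_sep_min if (ma and mb) else 1
            if sep < min_sep:
                continue
        if not ((da and ab) or (db and aa)):
            continue
        dist = float(np.linalg.norm(ca_ - cb))
        out.append(_canonical("hbond", ra.key, ra.res_name, na,
                              rb.key, rb.res_name, nb, dist))
    return sorted(set(out), key=lambda c: (c.res_a, c.res_b, c.atom_a, c.atom_b))


def _sidechain_carbons(r: Residue):
    for a in r.atoms:
        el = (a.element or a.name[:1]).upper()
        if el != "C" or a.name in {"C", "CA"}:
            continue
        if r.res_name == "TYR" and a.name not in TYR_RING:
            continue
        best = r.atom(a.name)
        yield best.name, best.coords


def detect_hydrophobic(s: Structure, chain_id: str | None = None,
                       d_max: float = 4.5,
                       include_het: bool = False) -> list[Contact]:
    """Hydrophobic contacts: apolar side-chain carbon pairs within d_max.

    One contact per residue pair, at the minimum carbon–carbon distance.
    """
    if d_max <= 0:
        raise ConfigurationError("d_max must be positive")
    rows = []
    for r in s.residues(chain_id, include_het=include_het):
        if r.res_name not in APOLAR:
            continue
        for name, xyz in _sidechain_carbons(r):
            rows.append((r, name, xyz))
    if not rows:
        return []
    coords = np.array([row[2] for row in rows])
    tree = cKDTree(coords)
    best: dict[tuple[ResKey, ResKey], Contact] = {}
    for i, j in tree.query_pairs(d_max):
        ra, na, ca_ = rows[i]
        rb, nb, cb = rows[j]
        if ra.key == rb.key:
            continue
        dist = float(np.linalg.norm(ca_ - cb))
        c = _canonical("hydrophobic", ra.key, ra.res_name, na,
                       rb.key, rb.res_name, nb, dist)
        pair = (c.res_a, c.res_b)
        if pair not in best or dist < best[pair].distance:
            best[pair] = c
    return sorted(best.values(), key=lambda c: (c.res_a, c.res_b))


def loop_contact_report(s: Structure, chain_id: str,
                        loops: list[RegionSpec],
                        hbond_dmax: float = 3.5,
                        phobic_dmax: float = 4.5,
                        seq_sep_min: int = 2) -> dict[str, list[Contact]]:
    """Union of both detectors, grouped by the loop a contact touches.

    A contact is assigned to every loop containing one of its residues;
    loop spans must be pairwise disjoint.
    """
    for i, a in enumerate(loops):
        for b in loops[i + 1:]:
            if a.start <= b.end and b.start <= a.end:
                raise ConfigurationError(
                    f"loop regions {a.name} and {b.name} overlap")
    contacts = (detect_hbonds(s, chain_id, d_max=hbond_dmax,
                              seq_sep_min=seq_sep_min)
                + detect_hydrophobic(s, chain_id, d_max=phobic_dmax))
    report: dict[str, list[Contact]] = {rg.name: [] for rg in loops}
    for c in contacts:
        for rg in loops:
            if rg.contains(c.res_a[1]) or rg.contains(c.res_b[1]):
                report[rg.name].append(c)
    return report


def contact_counts(report: dict[str, list[Contact]]) -> dict[str, dict[str, int]]:
    out = {}
    for loop, cs in report.items():
        out[loop] = {
            "hbond": sum(1 for c in cs if c.kind == "hbond"),
            "hydrophobic": sum(1 for c in cs if c.kind == "hydrophobic"),
            "total": len(cs),
        }
    return out
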