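"""Hierarchical coordinate model and PDB/mmCIF input/output.

The model mirrors the crystallographic file hierarchy: a :class:`Structure`
holds ordered chains, each chain an ordered list of :class:`Residue` objects
carrying :class:`AtomRecord` atoms.  Residues are addressed everywhere by
*author numbering* — the residue numbers assigned by the depositors (e.g.
Gln300) — because that is the coordinate system in which loop regions are
defined in the literature.  Parsing and writing are backed by gemmi.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import ConfigurationError, EmptySelectionError, StructureParseError

# Standard 3-letter amino-acid codes (20 canonical + common variants).
AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL", "UNK",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "UNK": "X",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE" and k != "UNK"}


@dataclass
class AtomRecord:
    """One atom: label, element, Cartesian coordinates (Å), B-factor (Å²)."""

    name: str
    element: str
    coords: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if self.b_factor < 0:
            raise ValueError(f"atom {self.name}: negative B-factor")


@dataclass
class Residue:
    """One residue identified by (chain_id, seq_num, ins_code), author numbering."""

    chain_id: str
    seq_num: int
    ins_code: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    het: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.ins_code)

    def atom(self, name: str) -> AtomRecord | None:
        """Highest-occupancy atom with this label (altloc collapsed);
        ties broken by altloc letter order."""
        cands = [a for a in self.atoms if a.name == name]
        if not cands:
            return None
        return min(cands, key=lambda a: (-a.occupancy, a.altloc))

    def ca(self) -> AtomRecord | None:
        return self.atom("CA")


@dataclass
class Structure:
    """An entry: ordered chains of ordered residues, plus free-form metadata."""

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise ConfigurationError(
                f"structure {self.id!r} has no chain {chain_id!r} "
                f"(chains: {sorted(self.chains)})"
            ) from None

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def protein_chain_ids(self) -> list[str]:
        """Chains containing at least one non-HET polymer residue."""
        return [cid for cid, res in self.chains.items()
                if any(not r.het for r in res)]

    def n_protein_chains(self) -> int:
        return len(self.protein_chain_ids())

    def residues(self, chain_id: str | None = None,
                 include_het: bool = False) -> list[Residue]:
        chains = [self.chain(chain_id)] if chain_id else list(self.chains.values())
        return [r for ch in chains for r in ch if include_het or not r.het]

    def validate(self) -> None:
        for cid, residues in self.chains.items():
            keys = [(r.seq_num, r.ins_code) for r in residues]
            if keys != sorted(keys):
                raise ValueError(f"chain {cid}: residues not ordered by (seq_num, ins_code)")
            if len(set(keys)) != len(keys):
                raise ValueError(f"chain {cid}: duplicate residue identifiers")


@dataclass(frozen=True)
class RegionSpec:
    """A named author-numbered residue span, inclusive on both ends."""

    name: str
    start: int
    end: int
    chain: str = "*"

    def __post_init__(self):
        if self.start > self.end:
            raise ConfigurationError(
                f"region {self.name}: start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, seq_num: int) -> bool:
        return self.start <= seq_num <= self.end

    def resolve(self, s: Structure, chain_id: str | None = None,
                include_het: bool = False) -> list[Residue]:
        cid = chain_id or (self.chain if self.chain != "*" else None)
        residues = [r for r in s.residues(cid, include_het=include_het)
                    if self.contains(r.seq_num)]
        return residues


@dataclass
class Selection:
    """Ordered atom selection: one row per (residue, atom) kept."""

    residue_keys: list[tuple[str, int, str]]
    atom_names: list[str]
    coords: np.ndarray  # (n, 3)
    b_factors: np.ndarray  # (n,)
    res_names: list[str]
    missing: list[tuple[tuple[str, int, str], str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residue_keys)


def select_atoms(s: Structure, region: RegionSpec,
                 atom_names: Iterable[str] = ("CA",),
                 chain_id: str | None = None,
                 include_het: bool = False) -> Selection:
    """Select atoms by region and atom label.

    Altloc duplicates are collapsed to the highest-occupancy copy (ties by
    altloc letter).  Residues lacking a requested atom are skipped and
    reported in ``Selection.missing``.
    """
    names = list(atom_names)
    residues = region.resolve(s, chain_id, include_het=include_het)
    if not residues:
        raise EmptySelectionError(
            f"region {region.name} ({region.start}-{region.end}) selects no "
            f"residues in structure {s.id!r}"
            + (f" chain {chain_id!r}" if chain_id else ""))
    keys, labels, xyz, bs, rnames, missing = [], [], [], [], [], []
    for r in residues:
        for nm in names:
            a = r.atom(nm)
            if a is None:
                missing.append((r.key, nm))
                continue
            keys.append(r.key)
            labels.append(nm)
            xyz.append(a.coords)
            bs.append(a.b_factor)
            rnames.append(r.res_name)
    if not keys:
        raise EmptySelectionError(
            f"region {region.name} ({region.start}-{region.end}): no atom "
            f"named {names} present in any selected residue")
    return Selection(keys, labels, np.array(xyz, dtype=float),
                     np.array(bs, dtype=float), rnames, missing)


# ---------------------------------------------------------------------------
# gemmi-backed file I/O


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f not in {"pdb", "mmcif", "cif"}:
            raise ConfigurationError(f"unknown coordinate format {fmt!r}")
        return "mmcif" if f in {"mmcif", "cif"} else "pdb"
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    return "pdb"


def parse_structure(path: str | Path, fmt: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into the hierarchical model.

    Every ATOM/HETATM record becomes an :class:`AtomRecord`; altloc
    duplicates are retained at parse time (they collapse at selection time).
    Only the first model of multi-model files is used.
    """
    path = Path(path)
    kind = _detect_format(path, fmt)
    if not path.exists():
        raise StructureParseError(f"{path}: file not found")
    try:
        if kind == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    st.setup_entities()
    out = Structure(id=st.name or path.stem)
    out.metadata["space_group"] = st.spacegroup_hm or ""
    if st.raw_remarks:
        out.metadata["n_remarks"] = len(st.raw_remarks)
    if len(st) == 0:
        return out
    model = st[0]
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            het = res.het_flag == "H"
            rr = Residue(
                chain_id=chain.name,
                seq_num=res.seqid.num,
                ins_code=(res.seqid.icode or "").strip(),
                res_name=res.name,
                het=het,
            )
            for atom in res:
                rr.atoms.append(AtomRecord(
                    name=atom.name,
                    element=atom.element.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    b_factor=max(atom.b_iso, 0.0),
                    occupancy=atom.occ,
                    altloc=(atom.altloc or "").strip("\x00").strip(),
                ))
            residues.append(rr)
        # keep file order but enforce the ordering invariant
        residues.sort(key=lambda r: (r.seq_num, r.ins_code))
        out.chains[chain.name] = residues
    return out


def to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    for cid, residues in s.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = r.res_name
            gr.seqid = gemmi.SeqId(r.seq_num, r.ins_code or " ")
            gr.het_flag = "H" if r.het else "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element or a.name[:1])
                ga.pos = gemmi.Position(*a.coords)
                ga.b_iso = a.b_factor
                ga.occ = a.occupancy
                ga.altloc = a.altloc[:1] if a.altloc else "\x00"
                gr.add_atom(ga)
            chain.add_residue(gr)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path: str | Path, fmt: str = "pdb") -> Path:
    """Write the model as a PDB file (fixed-column ATOM/HETATM records)."""
    if fmt.lower() != "pdb":
        raise ConfigurationError(f"write format {fmt!r} not supported (pdb only)")
    path = Path(path)
    st = to_gemmi(s)
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise StructureParseError(f"{path}: cannot write ({exc})") from exc
    return path


def structures_equal(a: Structure, b: Structure,
                     coord_tol: float = 1e-3, b_tol: float = 1e-2) -> bool:
    """Model equality at PDB fixed-column precision
    (coordinates to 3 decimals, B-factors to 2)."""
    if list(a.chains) != list(b.chains):
        return False
    for cid in a.chains:
        ra, rb = a.chains[cid], b.chains[cid]
        if len(ra) != len(rb):
            return False
        for x, y in zip(ra, rb):
            if (x.seq_num, x.ins_code, x.res_name) != (y.seq_num, y.ins_code, y.res_name):
                return False
            if len(x.atoms) != len(y.atoms):
                return False
            for ax, ay in zip(x.atoms, y.atoms):
                if ax.name != ay.name:
                    return False
                if not np.allclose(ax.coords, ay.coords, atol=coord_tol, rtol=0):
                    return False
                if abs(ax.b_factor - ay.b_factor) > b_tol:
                    return False
    return True


def chain_sequence(s: Structure, chain_id: str) -> str:
    """One-letter sequence of the observed polymer residues of a chain."""
    return "".join(THREE_TO_ONE.get(r.res_name, "X")
                   for r in s.residues(chain_id))
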