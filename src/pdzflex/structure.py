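"""Crystal-structure reading, domain extraction and ensemble assembly.

Structures are read with gemmi (PDB and mmCIF) into a light in-memory model
that keeps, per residue, the selected C-alpha coordinate and B-factor plus
the full heavy-atom records needed by the contacts analysis.  Domains are
extracted by author residue number (1-based, inclusive ranges, e.g. the
PDZ1 domain of syntenin-1 as residues 114-193) and assembled into aligned
ensembles restricted to the residues resolved in every member.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import (
    EmptyDomainError,
    EmptyStructureError,
    InsufficientOverlapError,
    MissingChainError,
    ParseError,
)

__all__ = [
    "ResidueId",
    "AtomRecord",
    "ResidueRecord",
    "ChainRecord",
    "StructureModel",
    "DomainInstance",
    "AlignedEnsemble",
    "DOMAIN_PRESETS",
    "read_structure",
    "extract_domain",
    "build_ensemble",
    "write_ensemble_pdb",
    "write_structure_pdb",
    "instances_to_tsv",
]

#: Domain boundary presets (author residue numbers, inclusive).  The
#: crystallographic assignment puts PDZ1 at 114-193; the MD setup uses the
#: alternative start 113.  PDZ2 is 197-273 in both.
DOMAIN_PRESETS: dict[str, tuple[int, int]] = {
    "PDZ1": (114, 193),
    "PDZ1_MD": (113, 193),
    "PDZ2": (197, 273),
}


@dataclass(frozen=True)
class ResidueId:
    """Identity of one residue: (chain, author number, insertion code)."""

    chain_id: str
    number: int
    insertion_code: str = ""
    name: str = "ALA"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.name}{self.number}{self.insertion_code}"


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray  # (3,) Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0


@dataclass
class ResidueRecord:
    rid: ResidueId
    atoms: list[AtomRecord] = field(default_factory=list)
    ca: np.ndarray | None = None  # selected C-alpha coordinate
    ca_b: float | None = None  # its B-factor


@dataclass
class ChainRecord:
    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    def residue_numbers(self) -> list[int]:
        return [r.rid.number for r in self.residues]


@dataclass
class StructureModel:
    """One model of one crystal structure: ordered chains of residues."""

    structure_id: str
    chains: dict[str, ChainRecord] = field(default_factory=dict)

    def chain(self, chain_id: str) -> ChainRecord:
        if chain_id not in self.chains:
            raise MissingChainError(
                f"structure {self.structure_id!r} has no chain {chain_id!r} "
                f"(chains: {sorted(self.chains)})"
            )
        return self.chains[chain_id]

    def n_calpha(self) -> int:
        return sum(
            1 for ch in self.chains.values() for r in ch.residues if r.ca is not None
        )


@dataclass
class DomainInstance:
    """One labelled domain copy: ordered residues with C-alpha coordinates."""

    label: str
    structure_id: str
    chain_id: str
    domain_name: str
    residue_ids: list[ResidueId]
    ca_coords: np.ndarray  # (N, 3)
    b_factors: np.ndarray  # (N,)
    gaps: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        self.b_factors = np.asarray(self.b_factors, dtype=float)
        n = len(self.residue_ids)
        if self.ca_coords.shape != (n, 3) or self.b_factors.shape != (n,):
            raise ValueError("residue_ids, ca_coords and b_factors lengths differ")

    def residue_keys(self) -> list[tuple[int, str]]:
        return [(r.number, r.insertion_code) for r in self.residue_ids]

    def __len__(self) -> int:
        return len(self.residue_ids)


@dataclass
class AlignedEnsemble:
    """Domain instances restricted to the residues resolved in all members."""

    members: list[DomainInstance]
    common_keys: list[tuple[int, str]]  # (number, insertion code), ascending
    coords: np.ndarray  # (n_members, n_common, 3)
    b_factors: np.ndarray  # (n_members, n_common)

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.members]

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.array([k[0] for k in self.common_keys], dtype=int)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_residues(self) -> int:
        return len(self.common_keys)


def _select_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Pick one altloc: highest occupancy, ties by lexicographic altloc id."""
    return min(atoms, key=lambda a: (-a.occ, a.altloc if a.altloc != "\0" else ""))


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(
    path: str | Path,
    format: str = "auto",
    model_index: int = 0,
    structure_id: str | None = None,
) -> StructureModel:
    """Read a PDB/mmCIF file into a :class:`StructureModel`.

    Only one model is kept (the first by default).  For each residue the
    atoms are reduced to a single altloc per atom name (highest occupancy,
    ties broken by lexicographically smallest altloc id); residues without a
    C-alpha are kept in the all-atom records but carry ``ca=None`` and are
    excluded from C-alpha tracks.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path} contains no models")
    if model_index >= len(st):
        raise ParseError(f"{path}: model index {model_index} out of range ({len(st)} models)")
    gmodel = st[model_index]

    model = StructureModel(structure_id=structure_id or (st.name or path.stem))
    for gchain in gmodel:
        chain = ChainRecord(chain_id=gchain.name)
        for gres in gchain:
            rid = ResidueId(
                chain_id=gchain.name,
                number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                name=gres.name,
            )
            rec = ResidueRecord(rid=rid)
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in gres:
                by_name.setdefault(atom.name, []).append(atom)
            for name, group in by_name.items():
                atom = _select_altloc(group)
                alt = atom.altloc if atom.altloc not in ("\0", "") else ""
                coords = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if not np.all(np.isfinite(coords)):
                    raise ParseError(
                        f"{path}: non-finite coordinates at {rid} atom {name}"
                    )
                rec.atoms.append(
                    AtomRecord(
                        name=name,
                        element=atom.element.name,
                        coords=coords,
                        occupancy=atom.occ,
                        altloc=alt,
                        b_factor=atom.b_iso,
                    )
                )
                if name == "CA" and atom.element.name.upper() != "CA":  # exclude calcium ions
                    rec.ca = coords
                    rec.ca_b = atom.b_iso
            chain.residues.append(rec)
        model.chains[chain.chain_id] = chain
    if model.n_calpha() == 0:
        raise EmptyStructureError(f"{path}: structure contains no C-alpha atoms")
    return model


def extract_domain(
    structure: StructureModel,
    chain_id: str,
    first: int,
    last: int,
    domain_name: str,
) -> DomainInstance:
    """Extract the C-alpha-bearing residues with ``first <= number <= last``.

    Residue numbers in the range without a modelled C-alpha are listed in
    ``gaps``.  Raises if the chain is absent or the range is empty.
    """
    if first > last:
        raise ValueError(f"first ({first}) must be <= last ({last})")
    chain = structure.chain(chain_id)
    picked = [
        r
        for r in chain.residues
        if r.ca is not None and first <= r.rid.number <= last
    ]
    picked.sort(key=lambda r: (r.rid.number, r.rid.insertion_code))
    if not picked:
        raise EmptyDomainError(
            f"{structure.structure_id}:{chain_id} has no C-alpha residues in "
            f"[{first}, {last}]"
        )
    present = {r.rid.number for r in picked}
    gaps = [n for n in range(first, last + 1) if n not in present]
    return DomainInstance(
        label=f"{structure.structure_id}:{chain_id}:{domain_name}",
        structure_id=structure.structure_id,
        chain_id=chain_id,
        domain_name=domain_name,
        residue_ids=[r.rid for r in picked],
        ca_coords=np.array([r.ca for r in picked]),
        b_factors=np.array(
            [r.ca_b if r.ca_b is not None else np.nan for r in picked]
        ),
        gaps=gaps,
    )


def build_ensemble(instances: list[DomainInstance]) -> AlignedEnsemble:
    """Restrict instances to their common residues and stack coordinates.

    The common residue set is the intersection of (number, insertion code)
    keys over all members, in ascending order; at least three residues must
    survive the intersection.
    """
    if len(instances) < 2:
        raise InsufficientOverlapError("an ensemble needs at least two members")
    key_sets = [set(inst.residue_keys()) for inst in instances]
    common = set.intersection(*key_sets)
    if len(common) < 3:
        coverage = ", ".join(
            f"{inst.label}: {len(ks)} residues" for inst, ks in zip(instances, key_sets)
        )
        raise InsufficientOverlapError(
            f"members share only {len(common)} residues (need >= 3); {coverage}"
        )
    common_keys = sorted(common)
    coords = np.empty((len(instances), len(common_keys), 3))
    b = np.empty((len(instances), len(common_keys)))
    for i, inst in enumerate(instances):
        index = {k: j for j, k in enumerate(inst.residue_keys())}
        rows = [index[k] for k in common_keys]
        coords[i] = inst.ca_coords[rows]
        b[i] = inst.b_factors[rows]
    return AlignedEnsemble(
        members=list(instances), common_keys=common_keys, coords=coords, b_factors=b
    )


# ---------------------------------------------------------------------------
# writers


def _gemmi_structure(models: list[tuple[str, StructureModel]]) -> gemmi.Structure:
    st = gemmi.Structure()
    for num, (name, model) in enumerate(models, start=1):
        gmodel = gemmi.Model(num)
        for chain in model.chains.values():
            gchain = gemmi.Chain(chain.chain_id)
            for res in chain.residues:
                gres = gemmi.Residue()
                gres.name = res.rid.name
                gres.seqid = gemmi.SeqId(res.rid.number, res.rid.insertion_code or " ")
                gres.het_flag = "A"
                for atom in res.atoms:
                    gatom = gemmi.Atom()
                    gatom.name = atom.name
                    gatom.element = gemmi.Element(atom.element)
                    gatom.pos = gemmi.Position(*atom.coords)
                    gatom.occ = atom.occupancy
                    gatom.b_iso = atom.b_factor
                    if atom.altloc:
                        gatom.altloc = atom.altloc
                    gres.add_atom(gatom)
                gchain.add_residue(gres)
            gmodel.add_chain(gchain)
        st.add_model(gmodel)
    st.setup_entities()
    return st


def write_structure_pdb(model: StructureModel, path: str | Path) -> None:
    """Write one structure as a single-model PDB file."""
    _gemmi_structure([(model.structure_id, model)]).write_pdb(str(path))


def _instance_as_model(inst: DomainInstance) -> StructureModel:
    chain = ChainRecord(chain_id=inst.chain_id)
    for rid, xyz, b in zip(inst.residue_ids, inst.ca_coords, inst.b_factors):
        chain.residues.append(
            ResidueRecord(
                rid=rid,
                atoms=[
                    AtomRecord(
                        name="CA", element="C", coords=np.asarray(xyz), b_factor=float(b)
                    )
                ],
                ca=np.asarray(xyz),
                ca_b=float(b),
            )
        )
    return StructureModel(structure_id=inst.structure_id, chains={inst.chain_id: chain})


def write_ensemble_pdb(instances: list[DomainInstance], path: str | Path) -> None:
    """Write domain instances as a multi-model, C-alpha-only PDB file.

    Model k holds instance k.  Coordinates survive the round trip to PDB
    field precision (1e-3 Angstrom).
    """
    models = [(inst.label, _instance_as_model(inst)) for inst in instances]
    _gemmi_structure(models).write_pdb(str(path))


def instances_to_tsv(instances: list[DomainInstance], path: str | Path) -> None:
    """Write instances as TSV: structure_id, chain, resnum, icode, resname, x, y, z, b."""
    with open(path, "w") as fh:
        fh.write("structure_id\tchain\tresnum\ticode\tresname\tx\ty\tz\tb\n")
        for inst in instances:
            for rid, xyz, b in zip(inst.residue_ids, inst.ca_coords, inst.b_factors):
                fh.write(
                    f"{inst.structure_id}\t{rid.chain_id}\t{rid.number}\t"
                    f"{rid.insertion_code}\t{rid.name}\t"
                    f"{xyz[0]:.6f}\t{xyz[1]:.6f}\t{xyz[2]:.6f}\t{b:.6f}\n"
                )
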