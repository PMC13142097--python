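"""Interdomain contact identification and region participation.

A residue pair across two domains is a contact when any heavy-atom pair is
within the heavy-atom cutoff (default 4.5 Angstrom).  Hydrogen bonds are
approximated donor/acceptor-agnostically as N/O-N/O pairs within the polar
cutoff (default 3.5 Angstrom) — crystal models rarely carry hydrogens, so
no angular criterion is applied.  A region's contact participation is the
fraction of its residues appearing in at least one contact pair; in the
tandem PDZ analysis, interface segments with participation above 0.8 are
the ones whose flexibility is suppressed by the interdomain arrangement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import PdzflexError
from .structure import ResidueId, StructureModel

__all__ = ["DomainRange", "ContactPair", "ContactSet", "find_contacts", "region_contact_fraction", "contacts_to_tsv"]

_WATER_NAMES = {"HOH", "WAT", "DOD"}
_POLAR_ELEMENTS = {"N", "O"}


@dataclass(frozen=True)
class DomainRange:
    """A domain as (chain, first residue, last residue), inclusive."""

    chain_id: str
    first: int
    last: int

    def contains(self, rid: ResidueId) -> bool:
        return rid.chain_id == self.chain_id and self.first <= rid.number <= self.last


@dataclass
class ContactPair:
    res_a: ResidueId
    res_b: ResidueId
    min_distance: float  # closest heavy-atom distance, A
    polar: bool  # any N/O-N/O pair within the polar cutoff


@dataclass
class ContactSet:
    pairs: list[ContactPair]
    heavy_cutoff: float
    polar_cutoff: float

    def residues_in_contact(self, side: str) -> set[tuple[str, int, str]]:
        if side not in ("A", "B"):
            raise ValueError("side must be 'A' or 'B'")
        attr = "res_a" if side == "A" else "res_b"
        return {getattr(p, attr).key for p in self.pairs}

    def swapped(self) -> "ContactSet":
        return ContactSet(
            pairs=[
                ContactPair(p.res_b, p.res_a, p.min_distance, p.polar)
                for p in self.pairs
            ],
            heavy_cutoff=self.heavy_cutoff,
            polar_cutoff=self.polar_cutoff,
        )


def _domain_atoms(structure: StructureModel, domain: DomainRange):
    """Heavy atoms of non-water residues in the domain range."""
    rows = []
    chain = structure.chain(domain.chain_id)
    for res in chain.residues:
        if res.rid.name in _WATER_NAMES or not domain.contains(res.rid):
            continue
        for atom in res.atoms:
            if atom.element.upper() in ("H", "D"):
                continue
            rows.append((res.rid, atom))
    if not rows:
        raise PdzflexError(
            f"no heavy atoms in {domain.chain_id}:{domain.first}-{domain.last} "
            f"of {structure.structure_id}"
        )
    coords = np.array([a.coords for _, a in rows])
    return rows, coords


def find_contacts(
    structure: StructureModel,
    domain_a: DomainRange,
    domain_b: DomainRange,
    heavy_cutoff: float = 4.5,
    polar_cutoff: float = 3.5,
) -> ContactSet:
    """All residue-residue contacts between two domains.

    Requires all-atom records.  For each contacting residue pair the
    minimum heavy-atom distance is recorded, plus a polar flag if any
    N/O-N/O atom pair is within ``polar_cutoff``.
    """
    rows_a, coords_a = _domain_atoms(structure, domain_a)
    rows_b, coords_b = _domain_atoms(structure, domain_b)
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    by_pair: dict[tuple, ContactPair] = {}
    for ia, ib_list in enumerate(tree_a.query_ball_tree(tree_b, heavy_cutoff)):
        rid_a, atom_a = rows_a[ia]
        for ib in ib_list:
            rid_b, atom_b = rows_b[ib]
            d = float(np.linalg.norm(atom_a.coords - atom_b.coords))
            polar = (
                d <= polar_cutoff
                and atom_a.element.upper() in _POLAR_ELEMENTS
                and atom_b.element.upper() in _POLAR_ELEMENTS
            )
            key = (rid_a.key, rid_b.key)
            if key in by_pair:
                pair = by_pair[key]
                pair.min_distance = min(pair.min_distance, d)
                pair.polar = pair.polar or polar
            else:
                by_pair[key] = ContactPair(rid_a, rid_b, d, polar)
    pairs = sorted(by_pair.values(), key=lambda p: (p.res_a.key, p.res_b.key))
    return ContactSet(pairs=pairs, heavy_cutoff=heavy_cutoff, polar_cutoff=polar_cutoff)


def region_contact_fraction(
    contacts: ContactSet, region: tuple[int, int], side: str = "A"
) -> float:
    """Fraction of region residues participating in >= 1 contact pair.

    ``region`` is an inclusive residue-number span on the stated side.
    """
    first, last = region
    if first > last:
        raise ValueError("region first must be <= last")
    in_contact = {num for _, num, _ in contacts.residues_in_contact(side)}
    span = range(first, last + 1)
    hits = sum(1 for n in span if n in in_contact)
    return hits / len(span)


def contacts_to_tsv(contacts: ContactSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("chain_a\tresnum_a\tresname_a\tchain_b\tresnum_b\tresname_b\tmin_distance\tpolar\n")
        for p in contacts.pairs:
            fh.write(
                f"{p.res_a.chain_id}\t{p.res_a.number}\t{p.res_a.name}\t"
                f"{p.res_b.chain_id}\t{p.res_b.number}\t{p.res_b.name}\t"
                f"{p.min_distance:.6f}\t{int(p.polar)}\n"
            )
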