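"""Synthetic benchmark data with known ground truth.

Every input the analysis pipeline consumes can be generated here with
controlled, region-wise flexibility:

* crystal-like ensembles — ~10 two-chain structures, each chain carrying a
  PDZ1-like (114-193) and PDZ2-like (197-273) domain on a shared helical
  C-alpha scaffold.  Flexible loop regions (by default the chain-B PDZ1
  spans 119-125 and 181-184, per-coordinate sigma 1.5 A) receive iid
  Gaussian displacements; everywhere else a small scaffold jitter
  (sigma 0.05 A) applies, and each structure gets a rigid-body jitter
  (rotation <= 5 degrees, translation <= 2 A) that superposition must
  remove.  Chain asymmetry emulates differential crystal-contact restraint:
  only one chain/domain combination carries the elevated loop flexibility.
* B-factors consistent with the injected fluctuation via B = 8 pi^2 sigma^2
  (isotropic per-direction mean-square displacement sigma^2).
* stationary-fluctuation trajectories in >= 5 replicates, with optional
  restrained regions (sigma reduced by a stated factor) emulating the
  suppression of interface flexibility in a tandem-domain context.
* NOE tables whose ratios are anticorrelated with the displacement sigma:
  ratio = clip(0.85 - k * sigma + eps, 0, 1), k = 0.2 per Angstrom,
  eps ~ N(0, 0.02), intensities back-computed with I_unsat = 1.

The flexibility model is iid Gaussian displacement about a shared mean —
no correlated loop modes — which is sufficient for testing detection and
parameter recovery.  RNG streams are separated per artifact kind by
spawning a child ``SeedSequence`` for scaffold, displacements, jitter,
trajectory and NOE noise, so e.g. changing the number of trajectory frames
never perturbs the crystal set of the same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .rmsf import Trajectory
from .structure import (
    AtomRecord,
    ChainRecord,
    ResidueId,
    ResidueRecord,
    StructureModel,
)

__all__ = [
    "FlexibleRegionSpec",
    "DomainLayout",
    "SyntheticEnsembleSpec",
    "make_scaffold",
    "make_crystal_set",
    "make_trajectory",
    "make_noe_table",
    "make_interface_model",
    "sigma_to_bfactor",
    "default_sigma_map",
]

EIGHT_PI_SQ = 8.0 * np.pi**2


def sigma_to_bfactor(sigma: float | np.ndarray) -> float | np.ndarray:
    """Isotropic B-factor for a per-coordinate displacement sigma (A)."""
    return EIGHT_PI_SQ * np.asarray(sigma, dtype=float) ** 2


@dataclass(frozen=True)
class FlexibleRegionSpec:
    """A flexible span: (chain, domain, inclusive residue range, sigma in A)."""

    chain_id: str
    domain: str
    first: int
    last: int
    sigma: float


@dataclass(frozen=True)
class DomainLayout:
    name: str
    first: int
    last: int


@dataclass
class SyntheticEnsembleSpec:
    """Parameters of a synthetic crystal ensemble.

    Defaults emulate the tandem-PDZ study setup: 10 two-chain structures,
    PDZ1-like domain 114-193 and PDZ2-like domain 197-273 per chain, with
    elevated loop flexibility (sigma 1.5 A) only in chain B's PDZ1 at the
    two binding-cleft loops 119-125 and 181-184.
    """

    n_structures: int = 10
    chains: tuple[str, ...] = ("A", "B")
    domains: tuple[DomainLayout, ...] = (
        DomainLayout("PDZ1", 114, 193),
        DomainLayout("PDZ2", 197, 273),
    )
    flexible_regions: tuple[FlexibleRegionSpec, ...] = (
        FlexibleRegionSpec("B", "PDZ1", 119, 125, 1.5),
        FlexibleRegionSpec("B", "PDZ1", 181, 184, 1.5),
    )
    scaffold_sigma: float = 0.05
    max_rotation_deg: float = 5.0
    max_translation: float = 2.0
    chain_offset: float = 45.0  # x-shift between chains, A
    seed: int = 0

    def __post_init__(self) -> None:
        layouts = {d.name: d for d in self.domains}
        for reg in self.flexible_regions:
            if reg.sigma < 0:
                raise ValueError("sigma must be >= 0")
            if reg.domain not in layouts:
                raise ValueError(f"region references unknown domain {reg.domain!r}")
            dom = layouts[reg.domain]
            if not (dom.first <= reg.first <= reg.last <= dom.last):
                raise ValueError(
                    f"region {reg.first}-{reg.last} not inside domain "
                    f"{reg.domain} ({dom.first}-{dom.last})"
                )
            if reg.chain_id not in self.chains:
                raise ValueError(f"region references unknown chain {reg.chain_id!r}")

    @property
    def residue_numbers(self) -> np.ndarray:
        lo = min(d.first for d in self.domains)
        hi = max(d.last for d in self.domains)
        return np.arange(lo, hi + 1)

    def sigma_map(self, chain_id: str) -> np.ndarray:
        """Per-residue displacement sigma for one chain."""
        residues = self.residue_numbers
        sigma = np.full(residues.size, self.scaffold_sigma)
        for reg in self.flexible_regions:
            if reg.chain_id == chain_id:
                mask = (residues >= reg.first) & (residues <= reg.last)
                sigma[mask] = reg.sigma
        return sigma


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def make_scaffold(n_residues: int, seed: int) -> np.ndarray:
    """Idealised helix-like C-alpha trace, consecutive spacing 3.8 +/- 0.1 A.

    A regular helix (radius 2.28 A, rise 1.5 A, 100 degrees per residue)
    with a tiny seeded perturbation (sigma 0.01 A) so different seeds give
    different, but geometrically equivalent, scaffolds.
    """
    if n_residues < 4:
        raise ValueError("scaffold needs at least 4 residues")
    rng = np.random.default_rng(seed)
    i = np.arange(n_residues)
    theta = np.deg2rad(100.0) * i
    coords = np.column_stack(
        [2.28 * np.cos(theta), 2.28 * np.sin(theta), 1.5 * i]
    )
    return coords + rng.normal(0.0, 0.01, coords.shape)


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _model_from_chains(
    structure_id: str, chains: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
) -> StructureModel:
    model = StructureModel(structure_id=structure_id)
    for chain_id, (residues, coords, b) in chains.items():
        chain = ChainRecord(chain_id=chain_id)
        for num, xyz, bf in zip(residues, coords, b):
            rid = ResidueId(chain_id=chain_id, number=int(num), name="ALA")
            atom = AtomRecord(
                name="CA", element="C", coords=np.asarray(xyz), b_factor=float(bf)
            )
            chain.residues.append(
                ResidueRecord(rid=rid, atoms=[atom], ca=atom.coords, ca_b=atom.b_factor)
            )
        model.chains[chain_id] = chain
    return model


def make_crystal_set(
    spec: SyntheticEnsembleSpec,
) -> tuple[list[StructureModel], dict]:
    """Generate the crystal-like ensemble plus its ground-truth record.

    Each structure is the shared per-chain scaffold plus iid Gaussian
    per-coordinate displacement (region sigma inside flexible spans,
    scaffold sigma elsewhere) plus a per-structure rigid-body jitter.
    B-factors are written as 8 pi^2 sigma^2 of the generating sigma.
    """
    ss = np.random.SeedSequence(spec.seed)
    ss_scaffold, ss_disp, ss_jitter = ss.spawn(3)
    rng_disp = np.random.default_rng(ss_disp)
    rng_jitter = np.random.default_rng(ss_jitter)

    residues = spec.residue_numbers
    base = make_scaffold(residues.size, _child_seed(ss_scaffold))
    scaffolds = {
        chain: base + np.array([i * spec.chain_offset, 0.0, 0.0])
        for i, chain in enumerate(spec.chains)
    }
    sigma = {chain: spec.sigma_map(chain) for chain in spec.chains}
    bfac = {chain: sigma_to_bfactor(sigma[chain]) for chain in spec.chains}

    structures = []
    for s in range(spec.n_structures):
        rot = _random_rotation(rng_jitter, spec.max_rotation_deg)
        direction = rng_jitter.normal(size=3)
        direction /= np.linalg.norm(direction)
        trans = rng_jitter.uniform(0.0, spec.max_translation) * direction
        chains = {}
        for chain in spec.chains:
            noise = rng_disp.normal(0.0, 1.0, (residues.size, 3)) * sigma[chain][:, None]
            coords = scaffolds[chain] + noise
            center = coords.mean(axis=0)
            coords = (coords - center) @ rot.T + center + trans
            chains[chain] = (residues, coords, bfac[chain])
        structures.append(_model_from_chains(f"S{s + 1:02d}", chains))

    ground_truth = {
        "seed": spec.seed,
        "n_structures": spec.n_structures,
        "chains": list(spec.chains),
        "domains": [asdict(d) for d in spec.domains],
        "flexible_regions": [asdict(r) for r in spec.flexible_regions],
        "scaffold_sigma": spec.scaffold_sigma,
        "bfactor_rule": "B = 8*pi^2*sigma^2",
    }
    return structures, ground_truth


def default_sigma_map(
    residue_numbers: np.ndarray,
    loop_regions: list[tuple[int, int]],
    loop_sigma: float = 0.4,
    scaffold_sigma: float = 0.05,
) -> np.ndarray:
    """Per-residue sigma map: loop sigma inside the given spans, else scaffold."""
    residue_numbers = np.asarray(residue_numbers)
    sigma = np.full(residue_numbers.size, scaffold_sigma)
    for first, last in loop_regions:
        sigma[(residue_numbers >= first) & (residue_numbers <= last)] = loop_sigma
    return sigma


def make_trajectory(
    n_frames: int,
    sigma_map: np.ndarray,
    seed: int,
    residue_numbers: np.ndarray | None = None,
    restrained_regions: list[tuple[int, int]] | None = None,
    restraint_factor: float = 3.0,
    dt: float = 100.0,
    replicate_id: str = "rep",
) -> Trajectory:
    """Stationary-fluctuation trajectory: scaffold + iid Gaussian noise.

    ``restrained_regions`` have their sigma divided by ``restraint_factor``
    (default 3), emulating interface residues held by cross-domain contacts
    in a tandem construct.  Times run 0, dt, 2*dt, ... ps.
    """
    if n_frames < 2:
        raise ValueError("a trajectory needs at least 2 frames")
    sigma_map = np.asarray(sigma_map, dtype=float).copy()
    if residue_numbers is None:
        residue_numbers = np.arange(1, sigma_map.size + 1)
    residue_numbers = np.asarray(residue_numbers)
    if residue_numbers.size != sigma_map.size:
        raise ValueError("sigma_map and residue_numbers lengths differ")
    if restrained_regions:
        for first, last in restrained_regions:
            mask = (residue_numbers >= first) & (residue_numbers <= last)
            sigma_map[mask] /= restraint_factor
    ss = np.random.SeedSequence(seed)
    ss_scaffold, ss_noise = ss.spawn(2)
    scaffold = make_scaffold(sigma_map.size, _child_seed(ss_scaffold))
    rng = np.random.default_rng(ss_noise)
    frames = scaffold[None, :, :] + rng.normal(
        0.0, 1.0, (n_frames, sigma_map.size, 3)
    ) * sigma_map[None, :, None]
    return Trajectory(
        replicate_id=replicate_id,
        times=np.arange(n_frames) * dt,
        frames=frames,
        residue_numbers=residue_numbers,
    )


def make_noe_table(
    sigma_map: np.ndarray,
    seed: int,
    residue_numbers: np.ndarray | None = None,
    base_ratio: float = 0.85,
    slope: float = 0.2,
    noise_sd: float = 0.02,
) -> pd.DataFrame:
    """NOE peak table with ratios anticorrelated with displacement sigma.

    ratio = clip(base_ratio - slope * sigma + eps, 0, 1), eps ~ N(0, noise_sd);
    I_unsat = 1 and I_sat = ratio, so the ratio is recovered exactly.
    """
    sigma_map = np.asarray(sigma_map, dtype=float)
    if residue_numbers is None:
        residue_numbers = np.arange(1, sigma_map.size + 1)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, sigma_map.size) if noise_sd > 0 else 0.0
    ratio = np.clip(base_ratio - slope * sigma_map + eps, 0.0, 1.0)
    return pd.DataFrame(
        {
            "resnum": np.asarray(residue_numbers, dtype=int),
            "I_sat": ratio,
            "I_unsat": np.ones(sigma_map.size),
        }
    )


def make_interface_model(gap: float = 4.0) -> tuple[StructureModel, dict]:
    """A small all-atom interface fixture with known contact ground truth.

    Two facing five-residue strands: domain A is chain A residues 1-5 plus a
    non-interface residue 6 displaced away; domain B is chain B residues
    11-15.  Facing C-alphas are ``gap`` Angstrom apart (in contact at the
    default 4.5 A heavy cutoff); residue A3 carries a side-chain O that
    faces an N on B13 at 2.9 A, a polar (hydrogen-bond proxy) contact.
    Ground truth: region (1, 5) on side A has participation 1.0, region
    (1, 6) has 5/6.
    """
    spacing = 3.8

    def residue(chain_id, num, name, atoms):
        rid = ResidueId(chain_id=chain_id, number=num, name=name)
        recs = [
            AtomRecord(name=an, element=el, coords=np.array(xyz), b_factor=10.0)
            for an, el, xyz in atoms
        ]
        ca = next((a.coords for a in recs if a.name == "CA"), None)
        return ResidueRecord(rid=rid, atoms=recs, ca=ca, ca_b=10.0)

    chain_a = ChainRecord(chain_id="A")
    for i, num in enumerate(range(1, 6)):
        x = i * spacing
        atoms = [("CA", "C", (x, 0.0, 0.0))]
        if num == 3:
            atoms.append(("OD1", "O", (x, 1.0, 0.0)))
        chain_a.residues.append(residue("A", num, "ALA" if num != 3 else "ASP", atoms))
    # residue 6: far from the interface
    chain_a.residues.append(residue("A", 6, "ALA", [("CA", "C", (5 * spacing, -30.0, 0.0))]))

    chain_b = ChainRecord(chain_id="B")
    for i, num in enumerate(range(11, 16)):
        x = i * spacing
        atoms = [("CA", "C", (x, gap, 0.0))]
        if num == 13:
            atoms.append(("ND2", "N", (x, 1.0 + 2.9, 0.0)))
        chain_b.residues.append(residue("B", num, "ALA" if num != 13 else "ASN", atoms))

    model = StructureModel(
        structure_id="IFACE", chains={"A": chain_a, "B": chain_b}
    )
    truth = {
        "region_full_contact": [1, 5],
        "region_partial_contact": [1, 6],
        "partial_fraction": 5 / 6,
        "polar_pair": [["A", 3], ["B", 13]],
        "polar_distance": 2.9,
    }
    return model, truth


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
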