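"""Domain types and chemical utilities.

Molecules are kept as canonical SMILES plus a fixed, hydrogen-explicit atom
order that every conformation of the molecule shares.  The module provides
Bemis-Murcko scaffolds, MACCS fingerprints, ETKDG conformer generation with
optional MMFF94 refinement, a deterministic synthetic library of drug-like
toy molecules, and an analytic bonded/Lennard-Jones oracle that plays the
role of the expensive quantum-chemical labeler during simulations and tests.
"""

from __future__ import annotations

import functools
import zlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, MACCSkeys
from rdkit.Chem.Scaffolds import MurckoScaffold

from .units import ENERGY_UNIT_KCAL, to_kcal_mol

RDLogger.DisableLog("rdApp.*")

PROVENANCE_TAGS = ("generated", "ff_optimized", "md")

# Covalent radii (A) used for toy-oracle equilibrium bond lengths.
_COVALENT_RADIUS = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}

# Equilibrium-length contraction per bond order (single/aromatic/double/
# triple), so generated geometries sit near the toy potential's minimum.
_BOND_ORDER_FACTOR = {1.0: 1.0, 1.5: 0.93, 2.0: 0.87, 3.0: 0.78}

# Per-element reference energies (kcal/mol) emulating the total-energy
# scale of quantum-chemical labels (scaled down): each atom contributes a
# large negative constant, so labeled energies have molecule-level
# magnitudes far from zero — the scale on which relative-standard-deviation
# disagreement scores are well behaved — while energy differences between
# conformations are untouched.
_ATOM_REF_ENERGY = {
    "H": -300.0, "C": -1000.0, "N": -1400.0, "O": -1900.0, "F": -2500.0,
    "P": -8000.0, "S": -9900.0, "Cl": -11400.0, "Br": -25000.0,
    "I": -37000.0,
}

# Lennard-Jones switching window (A): interactions taper smoothly to zero
# at the cutoff, the standard short-range convention of classical force
# fields.  The window matches the predictors' default distance threshold so
# the oracle's physics lives entirely inside the models' receptive range.
LJ_SWITCH_ON = 3.4
LJ_CUTOFF = 4.0

# Lennard-Jones well depths (kcal/mol) and diameters (A), OPLS-like values.
_LJ_PARAMS = {
    "H": (0.020, 2.50), "C": (0.070, 3.40), "N": (0.170, 3.25),
    "O": (0.210, 3.00), "F": (0.220, 2.95), "P": (0.200, 3.70),
    "S": (0.250, 3.60), "Cl": (0.300, 3.40), "Br": (0.300, 3.60),
    "I": (0.350, 3.90),
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Molecule:
    """Chemical identity with a fixed hydrogen-explicit atom order.

    ``atoms`` lists ``(element symbol, atomic number, atomic mass in amu)``
    in the order shared by every conformation's coordinate rows.  ``bonds``
    holds the covalent connectivity as index pairs into that order.
    """

    id: str
    smiles: str
    atoms: tuple[tuple[str, int, float], ...]
    bonds: tuple[tuple[int, int], ...]
    bond_orders: tuple[float, ...] | None = None  # 1, 1.5, 2, 3; None = single

    @classmethod
    def from_smiles(cls, smiles: str, mol_id: str | None = None) -> "Molecule":
        rd = Chem.MolFromSmiles(smiles)
        if rd is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        canonical = Chem.MolToSmiles(rd)
        # Re-parse the canonical form so the atom order is a deterministic
        # function of chemical identity alone, then make hydrogens explicit.
        rdh = Chem.AddHs(Chem.MolFromSmiles(canonical))
        atoms = tuple(
            (a.GetSymbol(), a.GetAtomicNum(), a.GetMass()) for a in rdh.GetAtoms()
        )
        bonds = tuple(
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rdh.GetBonds()
        )
        orders = tuple(b.GetBondTypeAsDouble() for b in rdh.GetBonds())
        return cls(id=mol_id if mol_id is not None else canonical,
                   smiles=canonical, atoms=atoms, bonds=bonds,
                   bond_orders=orders)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_heavy_atoms(self) -> int:
        return sum(1 for s, _, _ in self.atoms if s != "H")

    def masses(self) -> np.ndarray:
        return np.array([m for _, _, m in self.atoms], dtype=float)

    def symbols(self) -> list[str]:
        return [s for s, _, _ in self.atoms]

    def to_rdkit(self, with_h: bool = True) -> Chem.Mol:
        """RDKit molecule in this molecule's canonical atom order."""
        rd = Chem.MolFromSmiles(self.smiles)
        return Chem.AddHs(rd) if with_h else rd


@dataclass(frozen=True)
class Conformation:
    """One 3-D coordinate set of a molecule, optionally energy-labeled."""

    molecule: Molecule
    conf_id: str
    coords: np.ndarray  # N x 3, Angstrom
    provenance: str = "generated"
    energy: float | None = None
    energy_unit: str = ENERGY_UNIT_KCAL

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.shape != (self.molecule.n_atoms, 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match atom count "
                f"{self.molecule.n_atoms} of molecule {self.molecule.id}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates in {self.key}")
        if self.provenance not in PROVENANCE_TAGS:
            raise ValueError(f"unknown provenance tag: {self.provenance!r}")
        if self.energy is not None and not np.isfinite(self.energy):
            raise ValueError(f"non-finite energy in {self.key}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.molecule.id, self.conf_id)

    @property
    def energy_kcal(self) -> float:
        if self.energy is None:
            raise ValueError(f"conformation {self.key} has no energy label")
        return to_kcal_mol(self.energy, self.energy_unit)

    def with_energy(self, energy_kcal: float) -> "Conformation":
        return Conformation(self.molecule, self.conf_id, self.coords,
                            self.provenance, float(energy_kcal), ENERGY_UNIT_KCAL)


@dataclass(frozen=True)
class Scaffold:
    """Bemis-Murcko framework; empty SMILES for acyclic molecules."""

    smiles: str

    @property
    def is_empty(self) -> bool:
        return self.smiles == ""


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint (MACCS keys by default)."""

    bits: tuple[int, ...]  # indices of set bits, sorted
    length: int

    def popcount(self) -> int:
        return len(self.bits)

    def as_array(self) -> np.ndarray:
        arr = np.zeros(self.length, dtype=np.float64)
        if self.bits:
            arr[list(self.bits)] = 1.0
        return arr


class LabeledDataset:
    """Collection of energy-labeled conformations with per-molecule lookup."""

    def __init__(self, entries: list[Conformation] | None = None):
        self.entries: list[Conformation] = []
        self.index: dict[str, list[int]] = {}
        self._keys: set[tuple[str, str]] = set()
        for conf in entries or []:
            self.add(conf)

    def add(self, conf: Conformation) -> None:
        if conf.energy is None:
            raise ValueError(f"conformation {conf.key} is unlabeled")
        if conf.key in self._keys:
            raise ValueError(f"duplicate (molecule, conformer) pair {conf.key}")
        self._keys.add(conf.key)
        self.index.setdefault(conf.molecule.id, []).append(len(self.entries))
        self.entries.append(conf)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i: int) -> Conformation:
        return self.entries[i]

    def molecules(self) -> list[Molecule]:
        """Unique molecules in first-appearance order."""
        seen, out = set(), []
        for conf in self.entries:
            if conf.molecule.id not in seen:
                seen.add(conf.molecule.id)
                out.append(conf.molecule)
        return out

    def for_molecule(self, mol_id: str) -> list[Conformation]:
        return [self.entries[i] for i in self.index.get(mol_id, [])]

    def energies_kcal(self) -> np.ndarray:
        return np.array([c.energy_kcal for c in self.entries])

    def subset(self, positions) -> "LabeledDataset":
        return LabeledDataset([self.entries[i] for i in positions])

    def union(self, other: "LabeledDataset") -> "LabeledDataset":
        return LabeledDataset(self.entries + other.entries)


@dataclass
class ToyOracleParams:
    """Parameters of the analytic bonded + Lennard-Jones labeling oracle.

    Bond terms are harmonic springs ``k (d - d0)^2``; nonbonded pairs
    (separated by more than two bonds) interact through 12-6 Lennard-Jones.
    Gaussian noise of width ``noise_std`` is applied to reported energies
    only — forces stay exactly analytic so consistency checks remain exact.
    """

    bond_idx: np.ndarray      # B x 2 int
    bond_k: np.ndarray        # kcal/mol/A^2
    bond_d0: np.ndarray       # A
    pair_idx: np.ndarray      # P x 2 int
    pair_eps: np.ndarray      # kcal/mol
    pair_sigma: np.ndarray    # A
    noise_std: float = 0.0
    seed: int = 0
    energy_offset: float = 0.0  # sum of atomic reference energies

    @classmethod
    def for_molecule(cls, mol: Molecule, k: float = 300.0,
                     noise_std: float = 0.0, seed: int = 0,
                     total_energy_scale: bool = False) -> "ToyOracleParams":
        symbols = mol.symbols()
        bonds = np.array(mol.bonds, dtype=int).reshape(-1, 2)
        orders = (mol.bond_orders if mol.bond_orders is not None
                  else (1.0,) * len(bonds))
        d0 = np.array([(_COVALENT_RADIUS[symbols[i]] + _COVALENT_RADIUS[symbols[j]])
                       * _BOND_ORDER_FACTOR.get(order, 1.0)
                       for (i, j), order in zip(bonds, orders)])
        ks = np.full(len(bonds), float(k))
        # Exclude 1-2 and 1-3 neighbours from the nonbonded list.
        n = mol.n_atoms
        adj: list[set[int]] = [set() for _ in range(n)]
        for i, j in bonds:
            adj[i].add(j)
            adj[j].add(i)
        excluded = {tuple(sorted(b)) for b in bonds.tolist()}
        for j in range(n):
            for i in adj[j]:
                for kk in adj[j]:
                    if i < kk:
                        excluded.add((i, kk))
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if (i, j) not in excluded]
        pair_idx = np.array(pairs, dtype=int).reshape(-1, 2)
        eps = np.array([np.sqrt(_LJ_PARAMS[symbols[i]][0] * _LJ_PARAMS[symbols[j]][0])
                        for i, j in pair_idx])
        sigma = np.array([(_LJ_PARAMS[symbols[i]][1] + _LJ_PARAMS[symbols[j]][1]) / 2
                          for i, j in pair_idx])
        offset = (sum(_ATOM_REF_ENERGY.get(s, -1000.0) for s in symbols)
                  if total_energy_scale else 0.0)
        return cls(bond_idx=bonds, bond_k=ks, bond_d0=d0, pair_idx=pair_idx,
                   pair_eps=eps, pair_sigma=sigma,
                   noise_std=float(noise_std), seed=int(seed),
                   energy_offset=float(offset))


# ---------------------------------------------------------------------------
# Parsing and basic chemistry
# ---------------------------------------------------------------------------

def parse_molecules(source: str, fmt: str = "smiles") -> list[Molecule]:
    """Parse molecules from SMILES text (one per line, optional name) or SDF text.

    Raises ``ValueError`` naming the offending line/record on parse failure
    and on empty input.
    """
    if fmt == "smiles":
        mols = []
        n_records = 0
        for lineno, raw in enumerate(source.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            n_records += 1
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else None
            try:
                mol = Molecule.from_smiles(
                    smiles, mol_id=name if name else f"mol-{n_records - 1}")
            except ValueError:
                raise ValueError(
                    f"unparseable SMILES record {n_records} (line {lineno}): "
                    f"{smiles!r}") from None
            mols.append(mol)
        if not mols:
            raise ValueError("empty molecule source")
        return mols
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier()
        supplier.SetData(source, removeHs=True)
        mols = []
        for rec, rd in enumerate(supplier, start=1):
            if rd is None:
                raise ValueError(f"unparseable SDF record {rec}")
            name = rd.GetProp("_Name") if rd.HasProp("_Name") else ""
            mols.append(Molecule.from_smiles(
                Chem.MolToSmiles(rd), mol_id=name or f"mol-{rec - 1}"))
        if not mols:
            raise ValueError("empty molecule source")
        return mols
    raise ValueError(f"unknown format: {fmt!r}")


def bemis_murcko(mol: Molecule) -> Scaffold:
    """Bemis-Murcko framework: ring systems plus linkers, side chains removed."""
    rd = Chem.MolFromSmiles(mol.smiles)
    core = MurckoScaffold.GetScaffoldForMol(rd)
    return Scaffold(smiles=Chem.MolToSmiles(core) if core.GetNumAtoms() else "")


def scaffold_of_scaffold(scaf: Scaffold) -> Scaffold:
    """Re-apply the framework extraction to a scaffold (idempotence check)."""
    if scaf.is_empty:
        return scaf
    return bemis_murcko(Molecule.from_smiles(scaf.smiles))


@functools.lru_cache(maxsize=100000)
def _maccs_of_smiles(smiles: str) -> Fingerprint:
    if smiles == "":
        return Fingerprint(bits=(), length=167)
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise ValueError(f"unparseable SMILES for fingerprint: {smiles!r}")
    fp = MACCSkeys.GenMACCSKeys(rd)
    return Fingerprint(bits=tuple(sorted(fp.GetOnBits())), length=fp.GetNumBits())


def maccs(mol: Molecule | Scaffold | str) -> Fingerprint:
    """MACCS-keys fingerprint (167 bit positions, 166 informative).

    Depends only on chemical identity, never on coordinates (cached per
    SMILES).  An empty scaffold yields the all-zero fingerprint.
    """
    smiles = mol.smiles if isinstance(mol, (Molecule, Scaffold)) else mol
    return _maccs_of_smiles(smiles)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a & b| / |a | b|; two empty fingerprints give 0."""
    if a.length != b.length:
        raise ValueError(f"fingerprint length mismatch: {a.length} != {b.length}")
    sa, sb = set(a.bits), set(b.bits)
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union


# ---------------------------------------------------------------------------
# Conformer generation
# ---------------------------------------------------------------------------

def generate_conformations(mol: Molecule, n: int, seed: int,
                           optimize: bool = False) -> list[Conformation]:
    """Generate ``n`` ETKDGv3 conformers, optionally MMFF94-refined.

    Per-conformer embedding seeds are ``seed + index`` so any prefix of the
    output is reproducible on its own.  Conformers that fail to embed are
    skipped; zero successes raise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rdh = mol.to_rdkit(with_h=True)
    out: list[Conformation] = []
    provenance = "ff_optimized" if optimize else "generated"
    for i in range(n):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + i
        rdw = Chem.Mol(rdh)
        cid = AllChem.EmbedMolecule(rdw, params)
        if cid < 0:
            continue
        if optimize:
            try:
                AllChem.MMFFOptimizeMolecule(rdw, confId=cid)
            except Exception:
                pass
        coords = np.array(rdw.GetConformer(cid).GetPositions(), dtype=float)
        out.append(Conformation(mol, conf_id=f"c{i}", coords=coords,
                                provenance=provenance))
    if not out:
        raise ValueError(f"all embeddings failed for molecule {mol.id}")
    return out


# ---------------------------------------------------------------------------
# Synthetic library
# ---------------------------------------------------------------------------

# Ring cores with one substitution slot.  Ring-closure digits are chosen per
# role so fragments nest without digit clashes: slot-bearing primary cores
# use 1, secondary (terminal) cores use 2.
_CORES_PRIMARY = [
    "c1ccc({})cc1",          # benzene
    "c1ccc({})nc1",          # pyridine
    "c1cnc({})cn1",          # pyrimidine
    "c1cc({})ncn1",          # pyrimidine isomer
    "c1cc({})nnc1",          # pyridazine
    "c1cc({})cs1",           # thiophene
    "c1cc({})co1",           # furan
    "c1cc({})cn1C",          # N-methylpyrrole
    "c1cc({})on1",           # isoxazole
    "c1cc({})sn1",           # isothiazole
    "c1nc({})sc1",           # thiazole
    "c1nc({})oc1",           # oxazole
    "c1cn({})cn1",           # N-linked imidazole
    "c1cn({})nc1",           # N-linked pyrazole
    "c1nn({})cn1",           # N-linked triazole
    "C1CCC({})CC1",          # cyclohexane
    "C1CCC({})C1",           # cyclopentane
    "C1CC({})C1",            # cyclobutane
    "C1CC1{}",               # cyclopropane
    "C1CCN({})CC1",          # piperidine (N-linked)
    "C1CCN({})C1",           # pyrrolidine (N-linked)
    "C1CN({})C1",            # azetidine (N-linked)
    "C1COCCN1{}",            # morpholine (N-linked)
    "C1CN(C)CCN1{}",         # N-methylpiperazine (N-linked)
    "C1CS(=O)(=O)CCN1{}",    # thiomorpholine dioxide (N-linked)
    "C1CCS(=O)(=O)C1{}",     # sulfolane-like (C-linked via concat)
    "C1COC1{}",              # oxetane
    "C1CCOC1{}",             # tetrahydrofuran
    "c1ccc2c(c1)CCC2{}",     # indane
    "c1cc3c(cc1{})OCO3",     # benzodioxole (digit 3: slot precedes closure)
    "c1ccc2[nH]ccc2c1{}",    # indole (C-linked via concat)
    "c1ccc2ncccc2c1{}",      # quinoline
    "c1ccc2scnc2c1{}",       # benzothiazole
    "C1CC2CCC1CC2{}",        # bicyclo[2.2.2]octane
]
_CORES_SECONDARY = [
    "c2ccccc2", "c2ccncc2", "c2cscc2", "c2ccco2", "c2cnccn2",
    "c2ccc(F)cc2", "c2ccc(Cl)cc2", "c2ccc(C)cc2", "c2cnn(C)c2",
    "c2nccs2", "c2ncco2", "c2ccnnc2", "c2cc(C)on2",
    "C2CCCCC2", "C2CCNCC2", "C2COCCO2", "C2CC2", "C2CCC2",
    "C2CCOC2", "C2CCNC2", "C2CCS(=O)(=O)C2", "C2CC3CCC2CC3",
]
_LINKERS = ["", "C", "CC", "O", "OC", "NC", "C(=O)", "C(=O)N", "CN(C)",
            "S", "CO", "CCN", "C(=O)O", "S(=O)(=O)", "OCC", "N(C)C(=O)",
            "C(C)", "CCC"]
_SUBSTITUENTS = ["C", "CC", "OC", "F", "Cl", "C#N", "C(F)(F)F", "N(C)C",
                 "CO", "OCC", "C(C)C", "CCO", "C(=O)OC", "C(=O)N(C)C",
                 "S(=O)(=O)C", "CC#N", "OC(F)F", "N"]


def synthetic_library(n: int, seed: int) -> list[Molecule]:
    """Deterministic library of ``n`` distinct drug-like toy molecules.

    Molecules are assembled from a fixed fragment grammar: a substituted
    ring core optionally joined through a linker to a second ring.  The
    grammar guarantees broad Bemis-Murcko scaffold diversity while keeping
    molecules small enough for fast conformer embedding.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(int(seed))
    seen: set[str] = set()
    mols: list[Molecule] = []
    attempts = 0
    while len(mols) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("fragment grammar exhausted before reaching n")
        core = _CORES_PRIMARY[rng.integers(len(_CORES_PRIMARY))]
        if rng.random() < 0.75:  # two-ring molecule
            linker = _LINKERS[rng.integers(len(_LINKERS))]
            tail = _CORES_SECONDARY[rng.integers(len(_CORES_SECONDARY))]
            inner = linker + tail
        else:  # single ring with a substituent
            inner = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
        smiles = core.format(inner)
        rd = Chem.MolFromSmiles(smiles)
        if rd is None:  # grammar produced an invalid combination
            continue
        canonical = Chem.MolToSmiles(rd)
        if canonical in seen:
            continue
        seen.add(canonical)
        mols.append(Molecule.from_smiles(canonical, mol_id=f"lib-{len(mols):05d}"))
    return mols


# ---------------------------------------------------------------------------
# Toy labeling oracle
# ---------------------------------------------------------------------------

def toy_oracle_energy_forces(coords: np.ndarray, params: ToyOracleParams
                             ) -> tuple[float, np.ndarray]:
    """Noise-free energy (kcal/mol) and analytic forces (kcal/mol/A)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    energy = params.energy_offset
    forces = np.zeros_like(coords)

    def _accumulate(idx, de_dd, dvec, d):
        # dE/dr_i = dE/dd * (r_i - r_j)/d ; force is the negative gradient.
        unit = dvec / d[:, None]
        grad = de_dd[:, None] * unit
        np.add.at(forces, idx[:, 0], -grad)
        np.add.at(forces, idx[:, 1], grad)

    if len(params.bond_idx):
        dvec = coords[params.bond_idx[:, 0]] - coords[params.bond_idx[:, 1]]
        d = np.linalg.norm(dvec, axis=1)
        if np.any(d < 0.1):
            raise ValueError("overlapping atoms (bond distance < 0.1 A)")
        stretch = d - params.bond_d0
        energy += float(np.sum(params.bond_k * stretch**2))
        _accumulate(params.bond_idx, 2.0 * params.bond_k * stretch, dvec, d)

    if len(params.pair_idx):
        dvec = coords[params.pair_idx[:, 0]] - coords[params.pair_idx[:, 1]]
        d = np.linalg.norm(dvec, axis=1)
        if np.any(d < 0.1):
            raise ValueError("overlapping atoms (nonbonded distance < 0.1 A)")
        within = d < LJ_CUTOFF
        if np.any(within):
            dw = d[within]
            sr6 = (params.pair_sigma[within] / dw) ** 6
            eps = params.pair_eps[within]
            lj = 4.0 * eps * (sr6**2 - sr6)
            dlj = 4.0 * eps * (-12.0 * sr6**2 + 6.0 * sr6) / dw
            # quintic smoothstep switch: 1 below the window, 0 at cutoff
            t = np.clip((dw - LJ_SWITCH_ON) / (LJ_CUTOFF - LJ_SWITCH_ON),
                        0.0, 1.0)
            sw = 1.0 - (10.0 * t**3 - 15.0 * t**4 + 6.0 * t**5)
            dsw = -(30.0 * t**2 - 60.0 * t**3 + 30.0 * t**4)                 / (LJ_CUTOFF - LJ_SWITCH_ON)
            energy += float(np.sum(lj * sw))
            de_dd = np.zeros_like(d)
            de_dd[within] = dlj * sw + lj * dsw
            _accumulate(params.pair_idx, de_dd, dvec, d)

    assert forces.shape == (n, 3)
    return energy, forces


def toy_oracle(conf: Conformation, params: ToyOracleParams
               ) -> tuple[float, np.ndarray]:
    """Label a conformation: (energy kcal/mol, forces N x 3 kcal/mol/A).

    Label noise, when enabled, is drawn deterministically from the oracle
    seed and the conformation's identity, and never touches the forces.
    """
    energy, forces = toy_oracle_energy_forces(conf.coords, params)
    if params.noise_std > 0:
        tag = f"{conf.molecule.id}/{conf.conf_id}".encode()
        sub = (int(params.seed) * 2654435761 + zlib.crc32(tag)) % (2**31)
        rng = np.random.default_rng(sub)
        energy += float(rng.normal(0.0, params.noise_std))
    return energy, forces


def label_conformations(confs: list[Conformation], k: float = 300.0,
                        noise_std: float = 0.0, seed: int = 0,
                        total_energy_scale: bool = True) -> LabeledDataset:
    """Label conformations with the toy oracle, parameters cached per molecule.

    By default labels sit on the total-energy-like scale (atomic reference
    offsets included), the scale quantum-chemical pipelines deliver and the
    one on which relative disagreement scores are meaningful.
    """
    cache: dict[str, ToyOracleParams] = {}
    out = LabeledDataset()
    for conf in confs:
        mol = conf.molecule
        if mol.smiles not in cache:
            cache[mol.smiles] = ToyOracleParams.for_molecule(
                mol, k=k, noise_std=noise_std, seed=seed,
                total_energy_scale=total_energy_scale)
        energy, _ = toy_oracle(conf, cache[mol.smiles])
        out.add(conf.with_energy(energy))
    return out
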