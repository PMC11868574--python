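"""Reading and writing labeled conformation datasets.

Formats:

* SDF (V2000): one record per conformation, energy in the ``SDDF_ENERGY``
  property with ``SDDF_ENERGY_UNIT`` in {kcal/mol, hartree}.  MOL-block
  coordinates carry 4 decimals; a ``SDDF_COORDS_PRECISE`` property stores
  the coordinates at full precision so dataset round-trips are lossless.
* CSV manifest: columns molecule_id, conf_id, provenance, energy_kcal_mol,
  sdf_path — an index over one or more SDF files.
* XYZ: single-conformation export.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from rdkit import Chem

from .molkit import Conformation, LabeledDataset, Molecule
from .units import ENERGY_UNIT_HARTREE, ENERGY_UNIT_KCAL, to_kcal_mol

_ENERGY_TAG = "SDDF_ENERGY"
_UNIT_TAG = "SDDF_ENERGY_UNIT"
_MOLID_TAG = "SDDF_MOL_ID"
_CONFID_TAG = "SDDF_CONF_ID"
_PROV_TAG = "SDDF_PROVENANCE"
_PRECISE_TAG = "SDDF_COORDS_PRECISE"

_UNIT_ALIASES = {
    "kcal/mol": ENERGY_UNIT_KCAL,
    "kcal·mol-1": ENERGY_UNIT_KCAL,
    "hartree": ENERGY_UNIT_HARTREE,
    "au": ENERGY_UNIT_HARTREE,
}


def _conf_to_rdkit(conf: Conformation) -> Chem.Mol:
    rd = conf.molecule.to_rdkit(with_h=True)
    rdconf = Chem.Conformer(rd.GetNumAtoms())
    for i, (x, y, z) in enumerate(conf.coords):
        rdconf.SetAtomPosition(i, (float(x), float(y), float(z)))
    rd.RemoveAllConformers()
    rd.AddConformer(rdconf, assignId=True)
    rd.SetProp("_Name", f"{conf.molecule.id}/{conf.conf_id}")
    return rd


def write_sdf(dataset: LabeledDataset | list[Conformation], path: str) -> None:
    """Write conformations (labeled or not) to an SDF file."""
    writer = Chem.SDWriter(str(path))
    try:
        for conf in dataset:
            rd = _conf_to_rdkit(conf)
            rd.SetProp(_MOLID_TAG, conf.molecule.id)
            rd.SetProp(_CONFID_TAG, conf.conf_id)
            rd.SetProp(_PROV_TAG, conf.provenance)
            if conf.energy is not None:
                rd.SetProp(_ENERGY_TAG, f"{conf.energy:.17g}")
                rd.SetProp(_UNIT_TAG, conf.energy_unit)
            rd.SetProp(_PRECISE_TAG,
                       " ".join(f"{v:.9f}" for v in conf.coords.ravel()))
            writer.write(rd)
    finally:
        writer.close()


def _atom_order_mapping(rd_read: Chem.Mol, mol: Molecule) -> list[int]:
    """Map canonical atom positions to file atom positions."""
    file_symbols = [a.GetSymbol() for a in rd_read.GetAtoms()]
    if file_symbols == mol.symbols():
        file_bonds = {tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx())))
                      for b in rd_read.GetBonds()}
        if file_bonds == {tuple(sorted(b)) for b in mol.bonds}:
            return list(range(mol.n_atoms))
    match = rd_read.GetSubstructMatch(mol.to_rdkit(with_h=True))
    if len(match) != mol.n_atoms:
        raise ValueError(
            f"cannot map SDF atom order for molecule {mol.id}")
    return list(match)


def read_sdf(path: str, require_energy: bool = True
             ) -> LabeledDataset | list[Conformation]:
    """Read an SDF file written by :func:`write_sdf` or a plain labeled SDF.

    Energies tagged in hartree are converted to kcal/mol on read.  With
    ``require_energy`` every record must carry the energy tag; offending
    records are reported together in one error.
    """
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    confs: list[Conformation] = []
    missing: list[int] = []
    for rec, rd in enumerate(supplier, start=1):
        if rd is None:
            raise ValueError(f"unparseable SDF record {rec} in {path}")
        rd_noh = Chem.RemoveHs(Chem.Mol(rd))
        smiles = Chem.MolToSmiles(rd_noh)
        mol_id = rd.GetProp(_MOLID_TAG) if rd.HasProp(_MOLID_TAG) else None
        mol = Molecule.from_smiles(smiles, mol_id=mol_id)
        mapping = _atom_order_mapping(rd, mol)
        if rd.HasProp(_PRECISE_TAG):
            flat = np.array(rd.GetProp(_PRECISE_TAG).split(), dtype=float)
            file_coords = flat.reshape(-1, 3)
        else:
            file_coords = np.array(rd.GetConformer().GetPositions(), dtype=float)
        coords = file_coords[mapping]
        conf_id = rd.GetProp(_CONFID_TAG) if rd.HasProp(_CONFID_TAG) else f"c{rec - 1}"
        prov = rd.GetProp(_PROV_TAG) if rd.HasProp(_PROV_TAG) else "generated"
        energy = None
        if rd.HasProp(_ENERGY_TAG):
            raw = float(rd.GetProp(_ENERGY_TAG))
            unit_raw = rd.GetProp(_UNIT_TAG) if rd.HasProp(_UNIT_TAG) else "kcal/mol"
            unit = _UNIT_ALIASES.get(unit_raw.strip().lower())
            if unit is None:
                raise ValueError(f"record {rec}: unknown {_UNIT_TAG} {unit_raw!r}")
            energy = to_kcal_mol(raw, unit)
        elif require_energy:
            missing.append(rec)
            continue
        confs.append(Conformation(mol, conf_id=conf_id, coords=coords,
                                  provenance=prov, energy=energy))
    if missing:
        raise ValueError(
            f"records missing {_ENERGY_TAG} tag in {path}: {missing}")
    if require_energy:
        return LabeledDataset(confs)
    return confs


def write_csv_manifest(dataset: LabeledDataset, csv_path: str,
                       sdf_path: str | None = None) -> None:
    """Write the dataset SDF plus a CSV manifest indexing it."""
    if sdf_path is None:
        sdf_path = os.path.splitext(str(csv_path))[0] + ".sdf"
    write_sdf(dataset, sdf_path)
    rows = [{"molecule_id": c.molecule.id, "conf_id": c.conf_id,
             "provenance": c.provenance, "energy_kcal_mol": c.energy_kcal,
             "sdf_path": os.path.basename(sdf_path)} for c in dataset]
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def read_csv_manifest(csv_path: str) -> LabeledDataset:
    df = pd.read_csv(csv_path)
    base = os.path.dirname(os.path.abspath(str(csv_path)))
    datasets = {p: read_sdf(os.path.join(base, p)) for p in df["sdf_path"].unique()}
    by_key = {c.key: c for p in datasets for c in datasets[p]}
    confs = []
    for _, row in df.iterrows():
        key = (str(row["molecule_id"]), str(row["conf_id"]))
        conf = by_key[key]
        confs.append(conf.with_energy(float(row["energy_kcal_mol"])))
    return LabeledDataset(confs)


def read_dataset(path: str) -> LabeledDataset:
    """Dispatch on extension (.sdf or .csv manifest)."""
    p = str(path)
    if p.endswith(".csv"):
        return read_csv_manifest(p)
    return read_sdf(p)


def write_dataset(dataset: LabeledDataset, path: str) -> None:
    p = str(path)
    if p.endswith(".csv"):
        write_csv_manifest(dataset, p)
    else:
        write_sdf(dataset, p)


def write_xyz(conf: Conformation, path: str, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{conf.molecule.n_atoms}\n{comment}\n")
        for sym, (x, y, z) in zip(conf.molecule.symbols(), conf.coords):
            fh.write(f"{sym} {x:.6f} {y:.6f} {z:.6f}\n")
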