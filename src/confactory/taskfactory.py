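"""Desk-scale volunteer-computing task protocol.

Tasks wrap a single conformation as a V2000 MOL block plus a property
specifier; results come back as JSON property dictionaries.  Distribution
runs over a file-based message broker: one file per message in
``pending/``, ``claimed/``, ``done/``, ``failed/`` or ``quarantine/``
subdirectories of a spool directory.  Claiming renames a file from
pending to claimed — atomic within one filesystem — so no two workers can
receive the same message; FIFO order comes from zero-padded sequence
prefixes in filenames.  A fraction of tasks can be duplicated for
redundant-result verification under a relative tolerance.
"""

from __future__ import annotations

import json
import math
import os
import tempfile
import time
import traceback
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .molkit import Conformation, Molecule

_STATES = ("pending", "claimed", "done", "failed", "quarantine")
_SEQ_DIGITS = 20


@dataclass(frozen=True)
class Task:
    """One unit of work: a conformation MOL block plus a property specifier."""

    task_type: str
    identifier: str
    content: str                      # V2000 MOL block
    verifies: str | None = None      # identifier of the task this duplicates


@dataclass(frozen=True)
class TaskResult:
    """Answer to a task: property name -> numeric value."""

    task_type: str
    identifier: str
    results: dict

    def __post_init__(self):
        for name, value in self.results.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite result {name}={value} "
                                 f"for task {self.identifier}")

    def to_json(self) -> str:
        return json.dumps({"task_type": self.task_type,
                           "identifier": self.identifier,
                           "results": self.results})


@dataclass
class ProjectConfig:
    """Labeling-project parameters."""

    task_type: str = "conformational_energy"
    min_examples_per_task: int = 1
    max_examples_per_task: int = 1
    verification_threshold: float = 1e-3   # relative tolerance
    duplication_fraction: float = 0.0      # fraction of tasks re-issued

    def __post_init__(self):
        if self.min_examples_per_task > self.max_examples_per_task:
            raise ValueError("min_examples_per_task > max_examples_per_task")
        if self.verification_threshold <= 0:
            raise ValueError("verification_threshold must be positive")
        if not 0.0 <= self.duplication_fraction <= 1.0:
            raise ValueError("duplication_fraction must be in [0, 1]")


def estimate_volume(conf: Conformation) -> int:
    """Task volume estimate: the conformation's total atom count."""
    return conf.molecule.n_atoms


def conformation_to_molblock(conf: Conformation) -> str:
    rd = conf.molecule.to_rdkit(with_h=True)
    rdconf = Chem.Conformer(rd.GetNumAtoms())
    for i, (x, y, z) in enumerate(conf.coords):
        rdconf.SetAtomPosition(i, (float(x), float(y), float(z)))
    rd.RemoveAllConformers()
    rd.AddConformer(rdconf, assignId=True)
    rd.SetProp("_Name", f"{conf.molecule.id}/{conf.conf_id}")
    return Chem.MolToMolBlock(rd)


def molblock_to_conformation(block: str, provenance: str = "generated"
                             ) -> Conformation:
    """Parse a task MOL block back to a conformation (4-decimal precision)."""
    rd = Chem.MolFromMolBlock(block, removeHs=False, sanitize=True)
    if rd is None:
        raise ValueError("unparseable MOL block")
    name = rd.GetProp("_Name") if rd.HasProp("_Name") else "task/c0"
    mol_id, _, conf_id = name.partition("/")
    smiles = Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(rd)))
    mol = Molecule.from_smiles(smiles, mol_id=mol_id or None)
    coords = np.array(rd.GetConformer().GetPositions(), dtype=float)
    symbols = [a.GetSymbol() for a in rd.GetAtoms()]
    if symbols != mol.symbols():
        match = rd.GetSubstructMatch(mol.to_rdkit(with_h=True))
        if len(match) != mol.n_atoms:
            raise ValueError(f"cannot map MOL block atom order for {mol_id}")
        coords = coords[list(match)]
    return Conformation(mol, conf_id=conf_id or "c0", coords=coords,
                        provenance=provenance)


def make_tasks(confs, project: ProjectConfig) -> list[Task]:
    """One task per conformation plus verification duplicates.

    ``ceil(duplication_fraction * n)`` tasks are re-issued under fresh
    identifiers, marked with the identifier they verify.
    """
    confs = list(confs)
    if not confs:
        raise ValueError("no conformations to make tasks from")
    tasks = []
    for conf in confs:
        ident = f"{conf.molecule.id}/{conf.conf_id}"
        try:
            block = conformation_to_molblock(conf)
        except Exception as exc:
            raise ValueError(f"cannot serialize conformation {ident}: {exc}")
        tasks.append(Task(task_type=project.task_type, identifier=ident,
                          content=block))
    n_dup = math.ceil(project.duplication_fraction * len(confs))
    for i in range(n_dup):
        src = tasks[i]
        tasks.append(Task(task_type=src.task_type,
                          identifier=f"{src.identifier}#dup{i}",
                          content=src.content, verifies=src.identifier))
    return tasks


def verify_result(primary: TaskResult, duplicate: TaskResult,
                  cfg: ProjectConfig) -> tuple[bool, str]:
    """Accept iff every shared property agrees within the relative threshold.

    Values below 1e-8 in magnitude are compared by absolute difference.
    Mismatched property sets or task types are rejected with a reason.
    """
    if primary.task_type != duplicate.task_type:
        return False, (f"task_type mismatch: {primary.task_type!r} vs "
                       f"{duplicate.task_type!r}")
    keys_a, keys_b = set(primary.results), set(duplicate.results)
    if keys_a != keys_b:
        return False, f"property-set mismatch: {sorted(keys_a ^ keys_b)}"
    for name in sorted(keys_a):
        a, b = primary.results[name], duplicate.results[name]
        scale = max(abs(a), abs(b))
        diff = abs(a - b)
        rel = diff if scale < 1e-8 else diff / scale
        if rel > cfg.verification_threshold:
            return False, (f"property {name!r} differs: {a} vs {b} "
                           f"(relative difference {rel:.3g})")
    return True, "accept"


# ---------------------------------------------------------------------------
# File-based message broker
# ---------------------------------------------------------------------------

class Broker:
    """Spool-directory message broker with atomic claim semantics."""

    def __init__(self, spool_dir: str, claim_timeout_s: float = 1800.0):
        self.spool = str(spool_dir)
        self.claim_timeout_s = claim_timeout_s
        for state in _STATES:
            os.makedirs(os.path.join(self.spool, state), exist_ok=True)
        self._seq = 0

    def _dir(self, state: str) -> str:
        return os.path.join(self.spool, state)

    def _listing(self, state: str) -> list[str]:
        return sorted(f for f in os.listdir(self._dir(state))
                      if not f.startswith("."))

    def counts(self) -> dict:
        return {state: len(self._listing(state)) for state in _STATES}

    # -- enqueue ------------------------------------------------------------

    def enqueue(self, task: Task) -> str:
        """Append one message; returns the message filename (the receipt)."""
        self._seq += 1
        seq = time.time_ns() * 1000 + self._seq % 1000
        safe_ident = task.identifier.replace("/", "_").replace("#", "_")
        fname = f"{seq:0{_SEQ_DIGITS}d}-{safe_ident}.json"
        payload = {"task_type": task.task_type, "identifier": task.identifier,
                   "content": task.content, "verifies": task.verifies}
        fd, tmp = tempfile.mkstemp(dir=self.spool, prefix=".enqueue-")
        with os.fdopen(fd, "w") as fh:
            json.dump(payload, fh)
        os.rename(tmp, os.path.join(self._dir("pending"), fname))
        return fname

    # -- claim --------------------------------------------------------------

    def claim(self) -> tuple[str, Task] | None:
        """Atomically claim the oldest pending message.

        Returns ``(receipt, task)``, or ``None`` when the queue is empty
        (an explicit empty signal, not an error).  Corrupt messages are
        quarantined and skipped.
        """
        while True:
            pending = self._listing("pending")
            if not pending:
                return None
            progressed = False
            for fname in pending:
                src = os.path.join(self._dir("pending"), fname)
                dst = os.path.join(self._dir("claimed"), fname)
                try:
                    os.rename(src, dst)
                except (FileNotFoundError, OSError):
                    continue  # someone else claimed it first
                progressed = True
                try:
                    with open(dst) as fh:
                        payload = json.load(fh)
                    task = Task(task_type=payload["task_type"],
                                identifier=payload["identifier"],
                                content=payload["content"],
                                verifies=payload.get("verifies"))
                except Exception as exc:
                    warnings.warn(f"quarantining corrupt message {fname}: {exc}")
                    os.rename(dst, os.path.join(self._dir("quarantine"), fname))
                    break  # rescan pending
                os.utime(dst)
                return fname, task
            if not progressed:
                return None

    # -- complete / fail ----------------------------------------------------

    def _finish(self, receipt: str, state: str, extra: dict) -> None:
        src = os.path.join(self._dir("claimed"), receipt)
        with open(src) as fh:
            payload = json.load(fh)
        payload.update(extra)
        fd, tmp = tempfile.mkstemp(dir=self.spool, prefix=".finish-")
        with os.fdopen(fd, "w") as fh:
            json.dump(payload, fh)
        os.rename(tmp, os.path.join(self._dir(state), receipt))
        os.unlink(src)

    def complete(self, receipt: str, result: TaskResult) -> None:
        self._finish(receipt, "done", {"results": result.results})

    def fail(self, receipt: str, error: str) -> None:
        self._finish(receipt, "failed", {"error": error})

    # -- maintenance ---------------------------------------------------------

    def requeue_stale(self) -> int:
        """Return claims older than the timeout to pending."""
        now = time.time()
        n = 0
        for fname in self._listing("claimed"):
            path = os.path.join(self._dir("claimed"), fname)
            try:
                age = now - os.path.getmtime(path)
            except FileNotFoundError:
                continue
            if age > self.claim_timeout_s:
                os.rename(path, os.path.join(self._dir("pending"), fname))
                n += 1
        return n

    def results(self) -> list[dict]:
        out = []
        for fname in self._listing("done"):
            with open(os.path.join(self._dir("done"), fname)) as fh:
                out.append(json.load(fh))
        return out


def broker_enqueue(spool_dir: str, task: Task) -> str:
    return Broker(spool_dir).enqueue(task)


def broker_claim(spool_dir: str):
    return Broker(spool_dir).claim()


def broker_complete(spool_dir: str, receipt: str, result: TaskResult) -> None:
    Broker(spool_dir).complete(receipt, result)


def worker_loop(spool_dir: str, calculator, max_tasks: int | None = None,
                worker_id: str = "worker") -> dict:
    """Claim-compute-complete loop over the spool.

    ``calculator`` maps a MOL block string to a property dictionary.  A
    calculator exception marks that task failed (with a traceback
    reference) and the loop continues; it never poisons the queue.
    """
    broker = Broker(spool_dir)
    done = failed = 0
    while max_tasks is None or done + failed < max_tasks:
        claimed = broker.claim()
        if claimed is None:
            break
        receipt, task = claimed
        try:
            results = calculator(task.content)
            broker.complete(receipt, TaskResult(
                task_type=task.task_type, identifier=task.identifier,
                results=dict(results)))
            done += 1
        except Exception:
            broker.fail(receipt, traceback.format_exc(limit=5))
            failed += 1
    return {"worker_id": worker_id, "done": done, "failed": failed,
            **broker.counts()}
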