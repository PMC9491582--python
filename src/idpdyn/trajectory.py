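"""Trajectory and tabular I/O, the shared data model, and atom selection.

Conventions used throughout the package: coordinates in Å, time in ps,
relaxation rates in s^-1, residues numbered 1..N contiguously.  File
reading and writing is delegated to MDAnalysis; the in-memory model is a
plain in-core container so analysis code never touches file handles.
Solvent and ion residues are dropped at read time — every analysis stage
concerns the protein (or bead chain) only.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "Topology",
    "Trajectory",
    "ExperimentalRates",
    "read_trajectory",
    "write_trajectory",
    "select_atoms",
    "read_relaxation_table",
]

#: residue names discarded at read time (water, counter ions)
SOLVENT_RESNAMES = {
    "HOH", "WAT", "SOL", "TIP3", "TIP4", "TIP5", "SPC",
    "NA", "NA+", "SOD", "CL", "CL-", "CLA", "K", "K+", "POT", "MG", "CA2",
}

#: atom names considered backbone, plus their bonded hydrogens
BACKBONE_ATOM_NAMES = {
    "N", "CA", "C", "O", "OXT", "OT1", "OT2",
    "H", "HN", "H1", "H2", "H3", "HA", "HA2", "HA3",
}


@dataclass
class Topology:
    """Residue/atom bookkeeping for one molecule.

    ``atom_residue_index`` maps each atom to a 0-based position in the
    residue arrays; residue ids themselves are 1-based and contiguous.
    """

    residue_ids: np.ndarray
    residue_names: list[str]
    atom_names: list[str]
    elements: list[str]
    atom_residue_index: np.ndarray

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.atom_residue_index = np.asarray(self.atom_residue_index, dtype=int)
        n_res = len(self.residue_ids)
        if n_res < 2:
            raise ValidationError(f"need at least 2 residues, got {n_res}")
        if not np.array_equal(self.residue_ids, np.arange(1, n_res + 1)):
            raise ValidationError("residue ids must be contiguous and 1-based")
        if len(self.residue_names) != n_res:
            raise ValidationError("residue_names length mismatch")
        n_atoms = len(self.atom_names)
        if len(self.elements) != n_atoms or len(self.atom_residue_index) != n_atoms:
            raise ValidationError("per-atom arrays must have equal length")
        if n_atoms and (self.atom_residue_index.min() < 0
                        or self.atom_residue_index.max() >= n_res):
            raise ValidationError("atom_residue_index out of range")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atoms_of_residue(self, residue_id: int) -> np.ndarray:
        """Atom indices belonging to a 1-based residue id."""
        return np.flatnonzero(self.atom_residue_index == residue_id - 1)


@dataclass
class Trajectory:
    """In-core coordinate time series with fixed frame spacing.

    coordinates: (n_frames, n_atoms, 3) in Å; frame_interval in ps.
    """

    topology: Topology
    coordinates: np.ndarray
    frame_interval: float
    label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValidationError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise FormatError(
                f"atom-count mismatch: topology has {self.topology.n_atoms} atoms, "
                f"frames have {self.coordinates.shape[1]}"
            )
        if self.coordinates.shape[0] < 2:
            raise ValidationError(f"need at least 2 frames, got {self.coordinates.shape[0]}")
        if not (self.frame_interval > 0):
            raise ValidationError("frame_interval must be > 0 ps")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def total_time(self) -> float:
        """Total trajectory length T in ps (n_frames * frame_interval)."""
        return self.n_frames * self.frame_interval


@dataclass
class ExperimentalRates:
    """Per-residue experimental R1/R2 rates in s^-1; NaN marks missing."""

    residue_ids: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    r1_err: np.ndarray | None = None
    r2_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.r1 = np.asarray(self.r1, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        if len(set(self.residue_ids.tolist())) != len(self.residue_ids):
            raise ValidationError("residue ids must be unique")
        for name, arr in (("R1", self.r1), ("R2", self.r2)):
            if arr.shape != self.residue_ids.shape:
                raise ValidationError(f"{name} length mismatch")
            bad = np.flatnonzero(~np.isnan(arr) & (arr <= 0))
            if bad.size:
                raise ValidationError(
                    f"non-positive {name} at row {bad[0] + 1} "
                    f"(residue {self.residue_ids[bad[0]]}): {arr[bad[0]]}"
                )


def _clean_universe(u, topology_path):
    """Protein-only AtomGroup with solvent/ions removed."""
    ag = u.atoms
    resnames = getattr(ag, "resnames", None)
    if resnames is not None:
        keep = ~np.isin(np.char.upper(resnames.astype(str)), sorted(SOLVENT_RESNAMES))
        ag = ag[keep]
    if len(ag) == 0:
        raise FormatError(f"no non-solvent atoms found in {topology_path}")
    return ag


def _elements_from(ag) -> list[str]:
    try:
        return [str(e).capitalize() for e in ag.elements]
    except Exception:
        # fall back to the leading letter of the atom name (PDB convention)
        out = []
        for name in ag.names:
            stripped = name.lstrip("0123456789")
            out.append(stripped[:1].upper() if stripped else "X")
        return out


def read_trajectory(
    topology_path: str | Path,
    coords_path: str | Path | None = None,
    frame_interval: float | None = None,
    label: str = "",
) -> Trajectory:
    """Read a topology (PDB/GRO) plus coordinate series (DCD/XTC) into memory.

    Coordinates are returned in Å regardless of the on-disk unit (MDAnalysis
    converts XTC's nm).  ``frame_interval`` (ps) overrides any time metadata
    in the coordinate file and is required when the file carries none.
    """
    import MDAnalysis as mda

    topology_path = str(topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if coords_path is None:
                u = mda.Universe(topology_path)
            else:
                u = mda.Universe(topology_path, str(coords_path))
        except (OSError, EOFError) as exc:
            raise FormatError(f"unreadable trajectory input: {exc}") from exc
        except ValueError as exc:
            # MDAnalysis raises ValueError on topology/coordinate atom mismatch
            raise FormatError(str(exc)) from exc
        ag = _clean_universe(u, topology_path)
        n_frames = len(u.trajectory)
        coords = np.empty((n_frames, len(ag), 3), dtype=float)
        try:
            for i, _ts in enumerate(u.trajectory):
                coords[i] = ag.positions
        except (OSError, EOFError) as exc:
            raise FormatError(f"truncated coordinate file at frame {i}: {exc}") from exc
        dt = None
        if frame_interval is not None:
            dt = float(frame_interval)
        else:
            raw_dt = getattr(u.trajectory, "dt", None)
            if raw_dt and raw_dt > 0 and n_frames > 1:
                t0 = u.trajectory[0].time
                t1 = u.trajectory[1].time
                dt = float(t1 - t0) if t1 > t0 else float(raw_dt)
        if dt is None or dt <= 0:
            raise ValidationError(
                "coordinate file carries no usable time metadata; pass frame_interval (ps)"
            )
        residues = ag.residues
        resnames = [str(r) for r in residues.resnames]
        # renumber contiguously from 1, preserving file order
        res_index = {rix: k for k, rix in enumerate(residues.resindices)}
        atom_residue_index = np.array([res_index[a.resindex] for a in ag], dtype=int)
        topo = Topology(
            residue_ids=np.arange(1, len(residues) + 1),
            residue_names=resnames,
            atom_names=[str(n) for n in ag.names],
            elements=_elements_from(ag),
            atom_residue_index=atom_residue_index,
        )
    return Trajectory(topo, coords, dt, label=label or Path(topology_path).stem)


def write_trajectory(
    traj: Trajectory,
    topology_path: str | Path,
    coords_path: str | Path | None = None,
) -> None:
    """Write a Trajectory as PDB (topology + first frame) plus DCD/XTC frames.

    Round trip through :func:`read_trajectory` reproduces coordinates within
    format precision: DCD and PDB are float32 (~1e-3 Å at protein scale),
    XTC is lossy at 1e-3 nm = 1e-2 Å.
    """
    import MDAnalysis as mda

    topo = traj.topology
    n_atoms = topo.n_atoms
    u = mda.Universe.empty(
        n_atoms,
        n_residues=topo.n_residues,
        atom_resindex=topo.atom_residue_index,
        residue_segindex=np.zeros(topo.n_residues, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", topo.atom_names)
    u.add_TopologyAttr("elements", topo.elements)
    u.add_TopologyAttr("resnames", topo.residue_names)
    u.add_TopologyAttr("resids", topo.residue_ids)
    u.atoms.positions = traj.coordinates[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if coords_path is None and str(topology_path).lower().endswith(".pdb"):
                # self-contained multi-model PDB so the pair invariant
                # (n_frames >= 2) survives a topology-only round trip
                with mda.Writer(str(topology_path), multiframe=True,
                                n_atoms=n_atoms) as w:
                    for frame in traj.coordinates:
                        u.atoms.positions = frame
                        w.write(u.atoms)
                u.atoms.positions = traj.coordinates[0]
            else:
                u.atoms.write(str(topology_path))
            if coords_path is not None:
                from MDAnalysis.coordinates.memory import MemoryReader

                u.load_new(traj.coordinates.astype(np.float32), format=MemoryReader,
                           dt=traj.frame_interval)
                with mda.Writer(str(coords_path), n_atoms=n_atoms) as w:
                    for _ts in u.trajectory:
                        w.write(u.atoms)
        except OSError as exc:
            raise FormatError(f"cannot write trajectory output: {exc}") from exc


def select_atoms(source: Trajectory | Topology, mode: str = "all") -> np.ndarray:
    """Deterministic atom-index sets for the documented selection modes.

    ``sidechain`` is the complement of the backbone within the molecule;
    glycine contributes no sidechain atoms beyond its HA2/HA3 hydrogens,
    which count as backbone, so its sidechain set is empty.
    """
    topo = source.topology if isinstance(source, Trajectory) else source
    names = np.array([n.upper() for n in topo.atom_names])
    elements = np.array([e.upper() for e in topo.elements])
    if mode == "all":
        return np.arange(topo.n_atoms)
    if mode == "heavy":
        return np.flatnonzero(elements != "H")
    if mode == "CA":
        return np.flatnonzero(names == "CA")
    if mode == "backbone":
        return np.flatnonzero(np.isin(names, sorted(BACKBONE_ATOM_NAMES)))
    if mode == "sidechain":
        return np.flatnonzero(~np.isin(names, sorted(BACKBONE_ATOM_NAMES)))
    raise ValidationError(
        f"unknown selection mode {mode!r}; choose from all, heavy, backbone, sidechain, CA"
    )


def read_relaxation_table(path: str | Path) -> ExperimentalRates:
    """Parse a delimited text table of per-residue R1/R2 rates (s^-1).

    The header must name a residue column and R1/R2 columns (case
    insensitive; 'res', 'residue', 'resid' all accepted).  Blank cells are
    treated as missing, not zero.  Optional uncertainty columns are matched
    by names like 'R1_err'/'R2_err'.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [str(c).strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}

    def find(*cands):
        for cand in cands:
            if cand in lower:
                return lower[cand]
        return None

    res_col = find("residue", "resid", "res", "residue_id", "resnum")
    r1_col = find("r1")
    r2_col = find("r2")
    if res_col is None or (r1_col is None and r2_col is None):
        raise FormatError(
            f"table header must name residue and R1/R2 columns; found {list(df.columns)}"
        )

    def numeric(col, what):
        if col is None:
            return np.full(len(df), np.nan)
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(vals <= 0)
        if bad.size:
            raise ValidationError(
                f"non-positive {what} at row {bad[0] + 2} of {path}: {vals[bad[0]]}"
            )
        return vals

    r1 = numeric(r1_col, "R1")
    r2 = numeric(r2_col, "R2")
    r1e_col = find("r1_err", "r1err", "dr1", "r1_sd")
    r2e_col = find("r2_err", "r2err", "dr2", "r2_sd")
    r1e = pd.to_numeric(df[r1e_col], errors="coerce").to_numpy() if r1e_col else None
    r2e = pd.to_numeric(df[r2e_col], errors="coerce").to_numpy() if r2e_col else None
    return ExperimentalRates(
        residue_ids=df[res_col].to_numpy(dtype=int),
        r1=r1, r2=r2, r1_err=r1e, r2_err=r2e,
    )
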