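"""Data model and file I/O for peak series, relaxation tables and coordinates.

Every downstream analysis consumes only the types defined here:
:class:`ResidueID`, :class:`PeakSeries`, :class:`RelaxationRecord`,
:class:`VolumePair`, :class:`StructureModel` and :class:`Trajectory`.

File formats
------------
* peak-series TSV: a header line ``# axis: <name> <v1> <v2> ...`` followed by
  one row per residue (``PHE8<TAB>y1<TAB>y2 ...``);
* Sparky-style ``.list``: same header, rows keyed by one-letter assignments
  such as ``F8N-H``;
* coordinates: standard PDB ``ATOM``/``MODEL`` records (parsed with
  Biopython); multi-model files double as trajectories.

All writers emit a provenance header (tool version and an input hash when
one is supplied). Coordinates are Angstrom throughout the package.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from . import __version__

logger = logging.getLogger(__name__)

# default relative errors applied when a table carries none
DEFAULT_RELAXATION_ERROR_FRACTION = 0.02
DEFAULT_VOLUME_ERROR_FRACTION = 0.05


class FormatError(ValueError):
    """Raised for malformed input files."""


class DuplicateRecordError(FormatError):
    """Raised when the same residue appears twice in one table."""


class EmptyStructureError(FormatError):
    """Raised when a coordinate file contains no ATOM records."""


AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
STANDARD_CODES = frozenset(AA_3TO1) | {"UNK"}


@dataclass(frozen=True, order=True)
class ResidueID:
    """A 1-based residue position with its three-letter code.

    ``atom_label`` identifies the reporter group (backbone amide by
    default); it participates in equality so side-chain probes can coexist
    with backbone data for the same position.
    """

    seq_number: int
    residue_code: str = "UNK"
    atom_label: str = "N-H"

    def __post_init__(self) -> None:
        if self.seq_number < 1:
            raise ValueError(f"seq_number must be >= 1, got {self.seq_number}")
        if self.residue_code not in STANDARD_CODES:
            raise ValueError(f"unknown residue code {self.residue_code!r}")

    @property
    def label(self) -> str:
        """Table label, e.g. ``PHE8``."""
        return f"{self.residue_code}{self.seq_number}"

    @property
    def one_letter(self) -> str:
        return AA_3TO1.get(self.residue_code, "X")

    @classmethod
    def from_label(cls, label: str, atom_label: str = "N-H") -> "ResidueID":
        """Parse ``PHE8`` (three-letter) or ``F8`` (one-letter) labels."""
        label = label.strip()
        alpha = ""
        i = 0
        while i < len(label) and label[i].isalpha():
            alpha += label[i]
            i += 1
        num = label[i:]
        if not num.isdigit():
            raise FormatError(f"cannot parse residue label {label!r}")
        alpha = alpha.upper()
        if len(alpha) == 3 and alpha in STANDARD_CODES:
            code = alpha
        elif len(alpha) == 1 and alpha in AA_1TO3:
            code = AA_1TO3[alpha]
        else:
            raise FormatError(f"cannot parse residue label {label!r}")
        return cls(int(num), code, atom_label)

    @classmethod
    def from_sparky(cls, assignment: str) -> "ResidueID":
        """Parse a Sparky-style assignment such as ``F8N-H``."""
        assignment = assignment.strip()
        if len(assignment) < 2 or assignment[0].upper() not in AA_1TO3:
            raise FormatError(f"cannot parse assignment {assignment!r}")
        i = 1
        while i < len(assignment) and assignment[i].isdigit():
            i += 1
        if i == 1:
            raise FormatError(f"cannot parse assignment {assignment!r}")
        atom = assignment[i:] or "N-H"
        return cls(int(assignment[1:i]), AA_1TO3[assignment[0].upper()], atom)


AXIS_NAMES = ("time_hr", "urea_M", "delay_ms")


@dataclass
class PeakSeries:
    """One residue's peak intensity/volume against a swept variable."""

    residue: ResidueID
    axis_name: str
    axis_values: np.ndarray
    values: np.ndarray
    errors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.axis_values = np.asarray(self.axis_values, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis_name not in AXIS_NAMES:
            raise ValueError(
                f"axis_name must be one of {AXIS_NAMES}, got {self.axis_name!r}"
            )
        if self.axis_values.ndim != 1 or len(self.axis_values) != len(self.values):
            raise ValueError("axis_values and values must be 1-D and equal length")
        if np.any(self.axis_values < 0):
            raise ValueError("axis values must be non-negative")
        if np.any(np.diff(self.axis_values) <= 0):
            raise ValueError("axis values must be strictly increasing")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if len(self.errors) != len(self.values):
                raise ValueError("errors must match values in length")
            if np.any(self.errors < 0):
                raise ValueError("errors must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RelaxationRecord:
    """Per-residue 15N relaxation observables at a single field."""

    residue: ResidueID
    R1: float
    R2: float
    NOE: float
    R1_err: Optional[float] = None
    R2_err: Optional[float] = None
    NOE_err: Optional[float] = None
    eta_xy: Optional[float] = None
    eta_xy_err: Optional[float] = None
    eta_zz: Optional[float] = None
    eta_zz_err: Optional[float] = None
    field_MHz: float = 500.13
    temperature_K: float = 300.0

    def __post_init__(self) -> None:
        if self.R1 <= 0 or self.R2 <= 0:
            raise ValueError(f"{self.residue.label}: R1 and R2 must be positive")
        if self.field_MHz <= 0:
            raise ValueError("field_MHz must be positive")
        if self.R2 < self.R1:
            warnings.warn(
                f"{self.residue.label}: R2 < R1 is unphysical for ns tumbling",
                stacklevel=2,
            )

    def with_default_errors(
        self, fraction: float = DEFAULT_RELAXATION_ERROR_FRACTION
    ) -> "RelaxationRecord":
        """Return a copy with missing errors set to ``fraction``·|value|."""
        updates = {}
        for name in ("R1", "R2", "NOE", "eta_xy", "eta_zz"):
            val = getattr(self, name)
            err = getattr(self, f"{name}_err")
            if val is not None and err is None:
                updates[f"{name}_err"] = fraction * abs(val) if val != 0 else fraction
        return replace(self, **updates) if updates else self


@dataclass
class VolumePair:
    """Diamagnetic/paramagnetic peak-volume pair for one residue."""

    residue: ResidueID
    V_dia: float
    V_para: float

    def __post_init__(self) -> None:
        if self.V_dia <= 0:
            raise ValueError(f"{self.residue.label}: V_dia must be positive")
        if self.V_para < 0:
            raise ValueError(f"{self.residue.label}: V_para must be non-negative")


@dataclass(frozen=True)
class Atom:
    name: str
    residue: ResidueID
    element: str
    xyz: tuple  # Angstrom


@dataclass
class StructureModel:
    """A set of atoms with Angstrom coordinates (first model of a PDB)."""

    atoms: list
    n_models: int = 1

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError("structure has no atoms")
        coords = np.array([a.xyz for a in self.atoms], dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def indices_where(self, predicate) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if predicate(a)], dtype=int
        )

    def residues(self) -> list:
        seen, out = set(), []
        for a in self.atoms:
            key = (a.residue.seq_number, a.residue.residue_code)
            if key not in seen:
                seen.add(key)
                out.append(ResidueID(*key))
        return out


@dataclass
class Trajectory:
    """Multi-frame coordinates sharing one topology. Frames in Angstrom."""

    topology: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval_ps: float = 0.2
    box: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology.atoms):
            raise ValueError("frames inconsistent with topology atom count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# peak-series I/O
# ---------------------------------------------------------------------------

def _parse_axis_header(lines: list) -> tuple:
    for line in lines:
        if line.startswith("#") and "axis:" in line:
            parts = line.split("axis:", 1)[1].split()
            if len(parts) < 2:
                raise FormatError("axis header must name the axis and its values")
            name, vals = parts[0], parts[1:]
            try:
                return name, np.array([float(v) for v in vals])
            except ValueError as exc:
                raise FormatError(f"non-numeric axis value in header: {exc}") from exc
    raise FormatError("missing '# axis: <name> <v1> <v2> ...' header")


def read_peak_series(path, dialect: str = "tsv") -> list:
    """Read a peak-series table; one :class:`PeakSeries` per residue row.

    Rows containing non-numeric cells are dropped with a logged warning.
    """
    if dialect not in ("tsv", "sparky_list"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = Path(path).read_text().splitlines()
    axis_name, axis_values = _parse_axis_header(lines)
    out, seen = [], set()
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        label, cells = fields[0], fields[1:]
        if len(cells) != len(axis_values):
            logger.warning("row %s: expected %d values, got %d — dropped",
                           label, len(axis_values), len(cells))
            continue
        try:
            values = np.array([float(c) for c in cells])
        except ValueError:
            logger.warning("row %s: non-numeric cell — dropped", label)
            continue
        if dialect == "sparky_list":
            residue = ResidueID.from_sparky(label)
        else:
            residue = ResidueID.from_label(label)
        key = (residue.seq_number, residue.residue_code, residue.atom_label)
        if key in seen:
            raise DuplicateRecordError(f"duplicate residue {residue.label}")
        seen.add(key)
        out.append(PeakSeries(residue, axis_name, axis_values.copy(), values))
    return out


def provenance_header(input_hash: Optional[str] = None) -> str:
    head = f"# ribodyn v{__version__}"
    if input_hash:
        head += f" input-sha1:{input_hash}"
    return head


def hash_bytes(data: bytes) -> str:
    return hashlib.sha1(data).hexdigest()[:12]


def write_peak_series(path, series: Sequence[PeakSeries],
                      dialect: str = "tsv",
                      input_hash: Optional[str] = None) -> None:
    """Write peak series in a format :func:`read_peak_series` round-trips."""
    if not series:
        raise ValueError("no series to write")
    axis = series[0].axis_values
    name = series[0].axis_name
    for s in series:
        if s.axis_name != name or not np.array_equal(s.axis_values, axis):
            raise ValueError("all series must share one axis to be written together")
    lines = [provenance_header(input_hash),
             "# axis: " + name + " " + " ".join(repr(float(v)) for v in axis)]
    for s in series:
        if dialect == "sparky_list":
            label = f"{s.residue.one_letter}{s.residue.seq_number}{s.residue.atom_label}"
        else:
            label = s.residue.label
        lines.append(label + "\t" + "\t".join(repr(float(v)) for v in s.values))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# relaxation-table I/O
# ---------------------------------------------------------------------------

_RELAX_COLUMNS = ["residue", "R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err",
                  "eta_xy", "eta_xy_err", "eta_zz", "eta_zz_err"]


def read_relaxation_table(path, field_MHz: Optional[float] = None,
                          temperature_K: float = 300.0) -> list:
    """Read a TSV relaxation table.

    The field may be given in a ``# field_MHz: <value>`` header or via the
    ``field_MHz`` argument (the argument wins). Optional eta columns may be
    absent or written as ``nan``.
    """
    lines = Path(path).read_text().splitlines()
    header_cols = None
    records = []
    seen = set()
    for line in lines:
        if line.startswith("#"):
            if "field_MHz:" in line and field_MHz is None:
                field_MHz = float(line.split("field_MHz:", 1)[1].split()[0])
            if "temperature_K:" in line:
                temperature_K = float(line.split("temperature_K:", 1)[1].split()[0])
            continue
        if not line.strip():
            continue
        cells = line.split()
        if header_cols is None and cells[0] == "residue":
            header_cols = cells
            continue
        cols = header_cols or _RELAX_COLUMNS[: len(cells)]
        row = dict(zip(cols, cells))
        try:
            residue = ResidueID.from_label(row["residue"])
            kwargs = {}
            for name in ("R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err",
                         "eta_xy", "eta_xy_err", "eta_zz", "eta_zz_err"):
                if name in row and row[name].lower() != "nan":
                    kwargs[name] = float(row[name])
        except (KeyError, ValueError):
            logger.warning("relaxation row %r dropped (non-numeric cell)", cells[0])
            continue
        if residue in seen:
            raise DuplicateRecordError(f"duplicate residue {residue.label}")
        seen.add(residue)
        if field_MHz is None:
            raise FormatError("spectrometer field not given in header or argument")
        records.append(RelaxationRecord(residue=residue, field_MHz=field_MHz,
                                        temperature_K=temperature_K, **kwargs))
    return records


def write_relaxation_table(path, records: Sequence[RelaxationRecord],
                           input_hash: Optional[str] = None) -> None:
    if not records:
        raise ValueError("no records to write")
    recs = [r.with_default_errors() for r in records]
    lines = [provenance_header(input_hash),
             f"# field_MHz: {recs[0].field_MHz}",
             f"# temperature_K: {recs[0].temperature_K}",
             "\t".join(_RELAX_COLUMNS)]
    for r in recs:
        cells = [r.residue.label]
        for name in _RELAX_COLUMNS[1:]:
            v = getattr(r, name)
            cells.append("nan" if v is None else repr(float(v)))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_volume_table(path) -> dict:
    """Read a two-column ``residue<TAB>volume`` table into a dict."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split()
        if cells[0] == "residue":
            continue
        residue = ResidueID.from_label(cells[0])
        if residue in out:
            raise DuplicateRecordError(f"duplicate residue {residue.label}")
        try:
            out[residue] = float(cells[1])
        except ValueError:
            logger.warning("volume row %r dropped (non-numeric cell)", cells[0])
    return out


def write_volume_table(path, volumes: dict, input_hash: Optional[str] = None) -> None:
    lines = [provenance_header(input_hash), "residue\tvolume"]
    for residue in sorted(volumes, key=lambda r: r.seq_number):
        lines.append(f"{residue.label}\t{float(volumes[residue])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def read_structure(path, model: int = 0) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel` (first model by default).

    Residue numbering is preserved as written (1-based in all shipped
    examples); insertion codes are rejected.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    models = list(structure)
    if not models:
        raise EmptyStructureError(f"{path}: no ATOM records")
    atoms = _model_atoms(models[model])
    if not atoms:
        raise EmptyStructureError(f"{path}: no ATOM records")
    return StructureModel(atoms=atoms, n_models=len(models))


def _model_atoms(model) -> list:
    atoms = []
    for chain in model:
        for res in chain:
            hetflag, seq, icode = res.id
            if icode.strip():
                raise FormatError(
                    f"insertion code {icode!r} at residue {seq} not supported"
                )
            if seq < 1:
                raise FormatError(f"residue number {seq} < 1 not supported")
            code = res.get_resname().strip().upper()
            rid = ResidueID(seq, code if code in STANDARD_CODES else "UNK")
            for atom in res:
                element = (atom.element or atom.get_name()[0]).strip().upper()
                atoms.append(Atom(atom.get_name(), rid, element,
                                  tuple(float(x) for x in atom.coord)))
    return atoms


def read_trajectory(path, frame_interval_ps: float = 0.2) -> Trajectory:
    """Read a multi-model PDB as a trajectory (model 1 is the topology)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("t", str(path))
    models = list(structure)
    if not models:
        raise EmptyStructureError(f"{path}: no ATOM records")
    topo = StructureModel(atoms=_model_atoms(models[0]), n_models=len(models))
    frames = []
    for m in models:
        coords = np.array([a.coord for a in m.get_atoms()], dtype=float)
        if coords.shape[0] != len(topo.atoms):
            raise FormatError("trajectory model atom counts differ")
        frames.append(coords)
    return Trajectory(topology=topo, frames=np.array(frames),
                      frame_interval_ps=frame_interval_ps)


_PDB_LINE = ("{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} "
             "{chain:1s}{resseq:>4d}{icode:1s}   "
             "{x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}          "
             "{element:>2s}")


def write_structure(path, structure: StructureModel,
                    bfactors: Optional[np.ndarray] = None,
                    remarks: Iterable[str] = ()) -> None:
    """Write a single-model PDB, optionally substituting B-factors."""
    lines = [f"REMARK   ribodyn v{__version__}"]
    lines += [f"REMARK   {r}" for r in remarks]
    for i, atom in enumerate(structure.atoms):
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        b = 0.0 if bfactors is None else float(bfactors[i])
        x, y, z = atom.xyz
        lines.append(_PDB_LINE.format(
            record="ATOM", serial=i + 1, name=name, altloc=" ",
            resname=atom.residue.residue_code, chain="A",
            resseq=atom.residue.seq_number, icode=" ",
            x=x, y=y, z=z, occ=1.0, b=b, element=atom.element[:2]))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(path, traj: Trajectory) -> None:
    """Write a trajectory as a multi-model PDB readable by :func:`read_trajectory`."""
    lines = [f"REMARK   ribodyn v{__version__}",
             f"REMARK   frame_interval_ps {traj.frame_interval_ps}"]
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:>4d}")
        for i, atom in enumerate(traj.topology.atoms):
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            x, y, z = traj.frames[f, i]
            lines.append(_PDB_LINE.format(
                record="ATOM", serial=i + 1, name=name, altloc=" ",
                resname=atom.residue.residue_code, chain="A",
                resseq=atom.residue.seq_number, icode=" ",
                x=x, y=y, z=z, occ=1.0, b=0.0, element=atom.element[:2]))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
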