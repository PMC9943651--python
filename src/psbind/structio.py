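"""Structure, map and titration-table input/output.

All other modules consume the types defined here.  Units are fixed at the
package boundary: coordinates and grid geometry in Å, concentrations in μM,
B-factors in Å², anisotropy dimensionless.

PDB and mmCIF parsing is delegated to gemmi (wwPDB v3.3 columns for PDB,
``atom_site`` category for mmCIF); HETATM records are treated identically to
ATOM.  CCP4/MRC maps are read and written through gemmi honouring the header
axis-order fields, so maps with non-XYZ fast axes are re-sorted on load.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TITRATION_COLUMNS = [
    "oligo",
    "condition",
    "replicate",
    "probe_conc_uM",
    "protein_conc_uM",
    "anisotropy",
]

CALLS_COLUMNS = [
    "linkage_id",
    "chain",
    "res5",
    "res3",
    "call",
    "peak_Rp_sigma",
    "peak_Sp_sigma",
    "b_factor",
    "reliable",
]


class FormatError(ValueError):
    """Raised when an input stream does not parse under its declared format."""


class SchemaError(ValueError):
    """Raised when a tabular input is missing a required column."""


@dataclass
class AtomRecord:
    """One ATOM/HETATM record.

    ``position`` is in Å, ``b_factor`` in Å², ``occupancy`` a fraction in
    [0, 1].  ``altloc`` and ``insertion_code`` are single characters, blank
    meaning absent.
    """

    serial: int
    name: str
    altloc: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    element: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor {self.b_factor}")
        if not self.element:
            raise ValueError("element symbol must be non-empty")

    @property
    def key(self) -> tuple:
        return (
            self.chain_id,
            self.residue_number,
            self.insertion_code,
            self.name,
            self.altloc,
        )


@dataclass
class StructureModel:
    """Flat, ordered collection of atoms from one coordinate file."""

    atoms: list[AtomRecord] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom identifier {dup}")

    def __len__(self) -> int:
        return len(self.atoms)

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self, chain_id: str) -> dict[tuple[int, str], list[AtomRecord]]:
        """Atoms grouped by (residue_number, insertion_code), file order."""
        groups: dict[tuple[int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                groups.setdefault((a.residue_number, a.insertion_code), []).append(a)
        return groups


@dataclass
class DensityGrid:
    """Axis-aligned 3-D scalar map.

    ``values`` is indexed [ix, iy, iz]; voxel (i, j, k) sits at
    ``origin + spacing * (i, j, k)``.  ``sigma`` is the map standard
    deviation used for σ-normalisation of peak heights; by default it is
    recomputed from the voxels, but a caller may supply the parent
    experiment's value (e.g. from a CCP4 header).
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    sigma: float | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be positive")
        if self.sigma is None:
            self.sigma = float(np.std(self.values))

    @property
    def dimensions(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def usable(self) -> bool:
        """False for degenerate (constant-valued, σ=0) maps."""
        return self.sigma > 0

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.origin
        hi = self.origin + self.spacing * (np.array(self.values.shape) - 1)
        return lo, hi

    def contains(self, position: np.ndarray) -> bool:
        lo, hi = self.bounds()
        p = np.asarray(position, dtype=float)
        return bool(np.all(p >= lo - 1e-9) and np.all(p <= hi + 1e-9))

    def interpolate(self, position: np.ndarray) -> float:
        """Trilinear interpolation at a Cartesian position (Å)."""
        p = np.asarray(position, dtype=float)
        if not self.contains(p):
            raise ValueError(f"position {p} outside grid bounds {self.bounds()}")
        frac = (p - self.origin) / self.spacing
        i0 = np.floor(frac).astype(int)
        i0 = np.minimum(i0, np.array(self.values.shape) - 2)
        i0 = np.maximum(i0, 0)
        t = frac - i0
        v = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (t[0] if dx else 1 - t[0])
                        * (t[1] if dy else 1 - t[1])
                        * (t[2] if dz else 1 - t[2])
                    )
                    v += w * self.values[i0[0] + dx, i0[1] + dy, i0[2] + dz]
        return float(v)


@dataclass
class TitrationSeries:
    """One replicate of an anisotropy titration.

    Concentrations in μM (probe = labelled oligonucleotide, i.e. RNA_total in
    the binding equations; protein = Prot_total).
    """

    probe_conc: float
    protein_conc: np.ndarray
    anisotropy: np.ndarray
    condition: str = ""
    replicate_id: int = 0
    oligo: str = ""

    def __post_init__(self) -> None:
        self.protein_conc = np.asarray(self.protein_conc, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.protein_conc.shape != self.anisotropy.shape:
            raise ValueError("protein_conc and anisotropy must have equal length")
        if self.probe_conc <= 0:
            raise ValueError("probe_conc must be positive")
        if np.any(self.protein_conc < 0):
            raise ValueError("protein concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.protein_conc)


# ---------------------------------------------------------------------------
# structures


def _infer_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def read_structure(path: str, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Missing occupancy defaults to 1.0 and missing B-factor to 0.0 (gemmi
    already applies these defaults).  Every ATOM/HETATM becomes exactly one
    AtomRecord; altlocs are preserved, never collapsed.
    """
    fmt = fmt or _infer_format(path)
    if fmt not in ("pdb", "mmcif"):
        raise ValueError(f"unknown structure format {fmt!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"failed to parse {path} as {fmt}: {exc}") from exc
    atoms: list[AtomRecord] = []
    serial = 0
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    serial += 1
                    atoms.append(
                        AtomRecord(
                            serial=atom.serial or serial,
                            name=atom.name,
                            altloc=atom.altloc if atom.altloc != "\x00" else "",
                            residue_name=res.name,
                            chain_id=chain.name,
                            residue_number=res.seqid.num,
                            insertion_code=(res.seqid.icode or "").strip(),
                            position=[atom.pos.x, atom.pos.y, atom.pos.z],
                            occupancy=float(atom.occ),
                            b_factor=float(atom.b_iso),
                            element=atom.element.name,
                        )
                    )
        break  # first model only
    return StructureModel(atoms=atoms, source_id=os.path.basename(str(path)))


def write_structure(model: StructureModel, path: str) -> None:
    """Write a StructureModel as a PDB file (one model, one chain per id)."""
    st = gemmi.Structure()
    st.name = model.source_id or "psbind"
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for rec in model.atoms:
        if rec.chain_id not in chains:
            chains[rec.chain_id] = gemmi.Chain(rec.chain_id)
        chain = chains[rec.chain_id]
        res = None
        if len(chain) > 0:
            last = chain[len(chain) - 1]
            if last.seqid.num == rec.residue_number and last.name == rec.residue_name:
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = rec.residue_name
            res.seqid = gemmi.SeqId(rec.residue_number, rec.insertion_code or " ")
            res.het_flag = "A"
            chain.add_residue(res)
            res = chain[len(chain) - 1]
        atom = gemmi.Atom()
        atom.name = rec.name
        atom.altloc = rec.altloc or "\x00"
        atom.pos = gemmi.Position(*rec.position)
        atom.occ = rec.occupancy
        atom.b_iso = rec.b_factor
        atom.element = gemmi.Element(rec.element)
        atom.serial = rec.serial
        res.add_atom(atom)
    for chain in chains.values():
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# maps

_RMS_WORD = 55  # CCP4 header word holding the map RMS deviation


def read_map(path: str) -> DensityGrid:
    """Read a CCP4/MRC map into a DensityGrid.

    Axis order is taken from the header MAPC/MAPR/MAPS fields (gemmi's
    ``setup`` re-sorts to X-fast), so maps written with any permutation load
    identically.  σ is taken from the header RMS word when positive,
    otherwise recomputed over the voxels.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"failed to read CCP4/MRC map {path}: {exc}") from exc
    m.setup(float("nan"))
    grid = m.grid
    values = np.array(grid, dtype=float)
    spacing = np.array(grid.spacing, dtype=float)
    origin = np.array(
        [m.header_float(50), m.header_float(51), m.header_float(52)], dtype=float
    )
    header_rms = float(m.header_float(_RMS_WORD))
    sigma = header_rms if header_rms > 0 else float(np.std(values))
    dg = DensityGrid(origin=origin, spacing=spacing, values=values, sigma=sigma)
    if not dg.usable:
        logger.warning("map %s has zero variance (constant values); flagged unusable", path)
    return dg


def write_map(grid: DensityGrid, path: str) -> None:
    """Write a DensityGrid as a CCP4 map (orthogonal P1 cell)."""
    nx, ny, nz = grid.dimensions
    g = gemmi.FloatGrid(nx, ny, nz)
    cell = gemmi.UnitCell(
        nx * grid.spacing[0], ny * grid.spacing[1], nz * grid.spacing[2], 90, 90, 90
    )
    g.set_unit_cell(cell)
    np.asarray(g)[:] = grid.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    m.set_header_float(50, float(grid.origin[0]))
    m.set_header_float(51, float(grid.origin[1]))
    m.set_header_float(52, float(grid.origin[2]))
    m.set_header_float(_RMS_WORD, float(grid.sigma))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# tables


def read_titrations(path: str) -> list[TitrationSeries]:
    """Read the titration CSV into one TitrationSeries per
    (oligo, condition, replicate) group.

    Required columns: oligo, condition, replicate, probe_conc_uM,
    protein_conc_uM, anisotropy.  Extra columns are ignored with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in TITRATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"titration CSV missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in TITRATION_COLUMNS]
    if extra:
        logger.warning("ignoring extra titration columns: %s", ", ".join(extra))
    if (df["protein_conc_uM"] < 0).any():
        raise ValueError("negative protein concentration in titration table")
    out = []
    for (oligo, condition, rep), sub in df.groupby(
        ["oligo", "condition", "replicate"], sort=False
    ):
        probe = float(sub["probe_conc_uM"].iloc[0])
        out.append(
            TitrationSeries(
                probe_conc=probe,
                protein_conc=sub["protein_conc_uM"].to_numpy(),
                anisotropy=sub["anisotropy"].to_numpy(),
                condition=str(condition),
                replicate_id=int(rep),
                oligo=str(oligo),
            )
        )
    return out


def write_titrations(series: list[TitrationSeries], path: str) -> None:
    rows = []
    for s in series:
        for p, a in zip(s.protein_conc, s.anisotropy):
            rows.append(
                {
                    "oligo": s.oligo,
                    "condition": s.condition,
                    "replicate": s.replicate_id,
                    "probe_conc_uM": s.probe_conc,
                    "protein_conc_uM": p,
                    "anisotropy": a,
                }
            )
    pd.DataFrame(rows, columns=TITRATION_COLUMNS).to_csv(path, index=False)


def write_calls(calls, path: str) -> None:
    """Write stereo calls to CSV (or JSON if the path ends in .json)."""
    rows = [
        {
            "linkage_id": c.linkage_id,
            "chain": c.chain,
            "res5": c.res5,
            "res3": c.res3,
            "call": c.call,
            "peak_Rp_sigma": c.peak_rp_sigma,
            "peak_Sp_sigma": c.peak_sp_sigma,
            "b_factor": c.b_factor,
            "reliable": c.reliable,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=CALLS_COLUMNS)
    if str(path).endswith(".json"):
        df.to_json(path, orient="records", indent=1)
    else:
        df.to_csv(path, index=False)
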