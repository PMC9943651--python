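"""Protein-oligonucleotide contact analysis and Cα superposition.

Contacts use the Bondi van der Waals radii; a pair is in contact when its
distance is at most r_vdw(a) + r_vdw(b) + tolerance.  Contacts between two
polar-capable atoms (N, O, or an S acceptor) within the polar cutoff are
classified ``polar``; otherwise a pair involving at least one carbon or
sulfur is ``vdw_hydrophobic``; anything else is ``other``.

Superposition is the Kabsch closed-form least-squares rotation (SVD with
determinant correction) followed by iterative rejection of pairs deviating
more than ``reject_sigma`` times the current RMSD, emulating the refinement
cycles of common structure-alignment tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import AtomRecord, StructureModel

# Bondi vdW radii (Å)
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "SE": 1.90,
    "I": 1.98,
}

POLAR_ELEMENTS = {"N", "O", "S"}
DEFAULT_VDW_TOLERANCE = 0.5  # Å
DEFAULT_POLAR_CUTOFF = 3.5  # Å

WATER_NAMES = {"HOH", "WAT", "DOD"}

AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}


@dataclass
class Contact:
    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float
    kind: str  # vdw_hydrophobic | polar | other

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")

    @property
    def pair_label(self) -> str:
        a, b = self.atom_a, self.atom_b
        return (
            f"{a.element}:{a.name}({a.residue_name}{a.residue_number})"
            f"...{b.element}:{b.name}({b.residue_name}{b.residue_number})"
        )


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    rejected: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation determinant must be +1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# selections


def is_water(atom: AtomRecord) -> bool:
    return atom.residue_name in WATER_NAMES


def is_protein(atom: AtomRecord) -> bool:
    return atom.residue_name in AA3


def is_nucleic(atom: AtomRecord) -> bool:
    return atom.residue_name.strip() in {
        "A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU", "I", "DI",
    }


def select_atoms(model: StructureModel, selection) -> list[AtomRecord]:
    """Resolve a selection into atoms.

    ``selection`` may be a predicate, a list of AtomRecord, or a selection
    string composed of clauses joined by " and ": ``chain A,B``,
    ``protein``, ``nucleic``, ``water``, ``element S``, ``name OP1,OP2``.
    """
    if callable(selection):
        return [a for a in model.atoms if selection(a)]
    if isinstance(selection, (list, tuple)) and (
        not selection or isinstance(selection[0], AtomRecord)
    ):
        return list(selection)
    preds = []
    for clause in str(selection).split(" and "):
        clause = clause.strip()
        if not clause:
            continue
        parts = clause.split()
        kw = parts[0].lower()
        if kw == "chain":
            ids = set("".join(parts[1:]).split(","))
            preds.append(lambda a, ids=ids: a.chain_id in ids)
        elif kw == "protein":
            preds.append(is_protein)
        elif kw == "nucleic":
            preds.append(is_nucleic)
        elif kw == "water":
            preds.append(is_water)
        elif kw == "element":
            els = {e.upper() for e in "".join(parts[1:]).split(",")}
            preds.append(lambda a, els=els: a.element.upper() in els)
        elif kw == "name":
            nms = set("".join(parts[1:]).split(","))
            preds.append(lambda a, nms=nms: a.name in nms)
        else:
            raise ValueError(f"unknown selection keyword {kw!r}")
    return [a for a in model.atoms if all(p(a) for p in preds)]


def _dominant_altloc(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep, per (chain, residue, name), the highest-occupancy conformer."""
    best: dict[tuple, AtomRecord] = {}
    for a in atoms:
        k = (a.chain_id, a.residue_number, a.insertion_code, a.name)
        if k not in best or a.occupancy > best[k].occupancy:
            best[k] = a
    return list(best.values())


# ---------------------------------------------------------------------------
# contacts


def vdw_radius(atom: AtomRecord) -> float:
    el = atom.element.upper()
    if el not in VDW_RADII:
        raise ValueError(f"no van der Waals radius for element {el!r} (atom {atom.name})")
    return VDW_RADII[el]


def find_contacts(
    model: StructureModel,
    sel_a,
    sel_b,
    vdw_tolerance: float = DEFAULT_VDW_TOLERANCE,
    polar_cutoff: float = DEFAULT_POLAR_CUTOFF,
    all_altlocs: bool = False,
) -> list[Contact]:
    """All inter-selection atom pairs within vdW contact distance.

    By default only the highest-occupancy conformer of each altloc group is
    considered.  The result is symmetric in the two selections.
    """
    atoms_a = select_atoms(model, sel_a)
    atoms_b = select_atoms(model, sel_b)
    if not atoms_a or not atoms_b:
        raise ValueError("both selections must be non-empty")
    keys_a = {a.key for a in atoms_a}
    if any(b.key in keys_a for b in atoms_b):
        raise ValueError("selections must be disjoint")
    if not all_altlocs:
        atoms_a = _dominant_altloc(atoms_a)
        atoms_b = _dominant_altloc(atoms_b)
    xyz_a = np.array([a.position for a in atoms_a])
    xyz_b = np.array([b.position for b in atoms_b])
    max_r = max(max(vdw_radius(a) for a in atoms_a), max(vdw_radius(b) for b in atoms_b))
    cutoff = 2 * max_r + vdw_tolerance
    tree = cKDTree(xyz_b)
    contacts: list[Contact] = []
    for i, a in enumerate(atoms_a):
        for j in tree.query_ball_point(xyz_a[i], cutoff):
            b = atoms_b[j]
            d = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
            if d <= 0 or d > vdw_radius(a) + vdw_radius(b) + vdw_tolerance:
                continue
            ea, eb = a.element.upper(), b.element.upper()
            if ea in POLAR_ELEMENTS and eb in POLAR_ELEMENTS and d <= polar_cutoff:
                kind = "polar"
            elif "C" in (ea, eb) or "S" in (ea, eb):
                kind = "vdw_hydrophobic"
            else:
                kind = "other"
            contacts.append(Contact(atom_a=a, atom_b=b, distance=d, kind=kind))
    return contacts


def summarize_pocket(contacts: list[Contact]) -> list[dict]:
    """Residues of the second selection ranked by hydrophobic contacts to
    sulfur atoms of the first; each entry reports residue, count, min distance."""
    stats: dict[tuple, dict] = {}
    for c in contacts:
        if c.kind != "vdw_hydrophobic":
            continue
        if c.atom_a.element.upper() == "S":
            s_atom, partner = c.atom_a, c.atom_b
        elif c.atom_b.element.upper() == "S":
            s_atom, partner = c.atom_b, c.atom_a
        else:
            continue
        key = (partner.chain_id, partner.residue_number, partner.residue_name)
        entry = stats.setdefault(
            key,
            {
                "chain": partner.chain_id,
                "residue_number": partner.residue_number,
                "residue_name": partner.residue_name,
                "n_contacts": 0,
                "min_distance": np.inf,
            },
        )
        entry["n_contacts"] += 1
        entry["min_distance"] = min(entry["min_distance"], c.distance)
    report = sorted(stats.values(), key=lambda e: (-e["n_contacts"], e["min_distance"]))
    for e in report:
        e["min_distance"] = float(e["min_distance"])
    return report


def find_water_bridges(
    model: StructureModel, sel_a, sel_b, polar_cutoff: float = DEFAULT_POLAR_CUTOFF
) -> list[tuple[AtomRecord, AtomRecord, AtomRecord]]:
    """Water-mediated contacts: a water oxygen within the polar cutoff of a
    polar atom in each selection.  Returns (atom_a, water, atom_b) triples."""
    waters = [a for a in model.atoms if is_water(a) and a.element.upper() == "O"]
    atoms_a = [a for a in select_atoms(model, sel_a) if a.element.upper() in POLAR_ELEMENTS]
    atoms_b = [b for b in select_atoms(model, sel_b) if b.element.upper() in POLAR_ELEMENTS]
    bridges = []
    for w in waters:
        near_a = [a for a in atoms_a if np.linalg.norm(a.position - w.position) <= polar_cutoff]
        near_b = [b for b in atoms_b if np.linalg.norm(b.position - w.position) <= polar_cutoff]
        for a in near_a:
            for b in near_b:
                bridges.append((a, w, b))
    return bridges


# ---------------------------------------------------------------------------
# superposition


def _calpha_sequence(model: StructureModel, chain_id: str):
    """One-letter sequence and matching Cα records for a protein chain."""
    seq, atoms = [], []
    for (_num, _icode), res_atoms in model.residues(chain_id).items():
        resname = res_atoms[0].residue_name
        if resname not in AA3:
            continue
        ca = next((a for a in res_atoms if a.name == "CA"), None)
        if ca is None:
            continue
        seq.append(AA3[resname])
        atoms.append(ca)
    return "".join(seq), atoms


def match_calpha(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_a: str,
    chain_b: str,
    min_pairs: int = 30,
):
    """Pair Cα atoms of two protein chains by global sequence alignment.

    Identity scoring with affine gaps; only aligned positions with identical
    residues are paired.  Returns (coords_a, coords_b) as (n, 3) arrays.
    """
    from Bio import Align

    seq_a, ca_a = _calpha_sequence(model_a, chain_a)
    seq_b, ca_b = _calpha_sequence(model_b, chain_b)
    if not seq_a or not seq_b:
        raise ValueError("selected chains contain no protein Cα atoms")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    ia_list, ib_list = [], []
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for off in range(a_end - a_start):
            ia, ib = a_start + off, b_start + off
            if seq_a[ia] == seq_b[ib]:
                ia_list.append(ia)
                ib_list.append(ib)
    if len(ia_list) < min_pairs:
        raise ValueError(
            f"only {len(ia_list)} matched Cα pairs; insufficient overlap (<{min_pairs})"
        )
    coords_a = np.array([ca_a[i].position for i in ia_list])
    coords_b = np.array([ca_b[i].position for i in ib_list])
    return coords_a, coords_b


def kabsch(coords_ref: np.ndarray, coords_mob: np.ndarray):
    """Least-squares rotation/translation mapping mobile onto reference.

    Returns (rotation, translation, rmsd); the rotation is reflection-
    corrected so its determinant is +1.
    """
    ref = np.asarray(coords_ref, dtype=float)
    mob = np.asarray(coords_mob, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("need matching (n, 3) coordinate arrays")
    if ref.shape[0] < 3:
        raise ValueError("need at least 3 pairs")
    cen_ref = ref.mean(axis=0)
    cen_mob = mob.mean(axis=0)
    x = mob - cen_mob
    y = ref - cen_ref
    # degenerate (collinear) sets leave the rotation about the line free
    _, sing, _ = np.linalg.svd(x)
    if sing[1] < 1e-8 * max(sing[0], 1.0):
        raise ValueError("coordinate set is collinear; superposition degenerate")
    h = x.T @ y
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cen_ref - rot @ cen_mob
    moved = x @ rot.T + cen_ref
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def superpose(
    coords_ref: np.ndarray,
    coords_mob: np.ndarray,
    reject_sigma: float = 2.0,
    max_cycles: int = 5,
) -> SuperpositionResult:
    """Kabsch superposition with iterative outlier-pair rejection.

    After each fit, pairs deviating more than ``reject_sigma`` × RMSD are
    dropped and the fit repeated, up to ``max_cycles`` or until no pair is
    rejected.  Indices of rejected pairs (into the input arrays) are
    reported.
    """
    ref = np.asarray(coords_ref, dtype=float)
    mob = np.asarray(coords_mob, dtype=float)
    active = np.arange(ref.shape[0])
    rot, trans, rmsd = kabsch(ref, mob)
    for _ in range(max_cycles):
        if rmsd < 1e-8:  # already an essentially exact fit
            break
        moved = mob[active] @ rot.T + trans
        dev = np.sqrt(np.sum((moved - ref[active]) ** 2, axis=1))
        keep = dev <= reject_sigma * rmsd
        if keep.all() or keep.sum() < 3:
            break
        active = active[keep]
        rot, trans, rmsd = kabsch(ref[active], mob[active])
    rejected = sorted(set(range(ref.shape[0])) - set(active.tolist()))
    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        rmsd=rmsd,
        n_atoms=len(active),
        rejected=rejected,
    )


def superpose_chains(
    model_ref: StructureModel,
    model_mob: StructureModel,
    chain_ref: str,
    chain_mob: str,
    reject_sigma: float = 2.0,
    max_cycles: int = 5,
) -> SuperpositionResult:
    """Convenience: match Cα pairs by sequence, then superpose."""
    ref, mob = match_calpha(model_ref, model_mob, chain_ref, chain_mob)
    return superpose(ref, mob, reject_sigma=reject_sigma, max_cycles=max_cycles)
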