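"""Synthetic fixtures: PS-DNA strands with programmed stereochemistry,
matching anomalous difference maps, and titration tables.

The strand builder places phosphate groups on an idealized B-form helix
(rise 3.4 Å, twist 36°, backbone radius 9.4 Å).  Only the phosphate-group
geometry is metrically correct — bases and sugars are not built, since every
downstream computation (linkage extraction, chirality, map peaks) consumes
the phosphate group only.  Atom-name conventions: OP1/OP2 mark the two
non-bridging candidate sites (P-O 1.48 Å); sulfur occupancy is carried by
"SP" atoms (P-S 1.95 Å, along the same tetrahedral direction), one per
programmed conformer — a single full-occupancy SP for Rp or Sp, two
half-occupancy altloc conformers for mixed, mirroring how unresolved PS
stereoisomers are refined as dual 0.5-occupancy alternatives.

The map renderer emits values directly on the σ scale of the parent
experiment (grid ``sigma`` is 1 by construction): a Gaussian blob of the
stated σ-height at every sulfur position, weighted by occupancy, plus
Gaussian voxel noise of the stated σ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .binding import BindingParams, default_protein_grid, simulate_titration
from .stereo import assign_chirality, extract_linkages
from .structio import (
    AtomRecord,
    DensityGrid,
    StructureModel,
    write_titrations,
)

HELIX_RISE = 3.4  # Å per nucleotide
HELIX_TWIST = np.deg2rad(36.0)
HELIX_RADIUS = 9.4  # Å, backbone phosphorus radius
P_O_BRIDGE = 1.60  # Å, P-O5'/O3' ester bonds
P_O_NONBRIDGE = 1.48  # Å
P_S_BOND = 1.95  # Å
DEFAULT_BLOB_HEIGHT = 10.0  # σ; a full-occupancy sulfur in a well-measured map
DEFAULT_BLOB_WIDTH = 0.9  # Å, Gaussian σ of a sulfur peak
MAP_SPACING = 0.5  # Å
MAP_PADDING = 4.0  # Å

# unit tetrahedral directions in the local phosphate frame
_TET = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


@dataclass
class FixtureSpec:
    """Recipe for one synthetic PS strand + map fixture."""

    n_nucleotides: int
    stereo_pattern: list[str]
    b_profile: list[float] | None = None
    pocket_linkage: int | None = None
    map_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_link = self.n_nucleotides - 1
        if len(self.stereo_pattern) != n_link:
            raise ValueError(
                f"stereo_pattern length {len(self.stereo_pattern)} != n-1 = {n_link}"
            )
        for s in self.stereo_pattern:
            if s not in ("Rp", "Sp", "mixed"):
                raise ValueError(f"invalid stereo label {s!r}")
        if self.b_profile is None:
            self.b_profile = [30.0] * n_link
        if len(self.b_profile) != n_link:
            raise ValueError("b_profile length must equal n_nucleotides - 1")


def _helix_frame(i: int):
    """Phosphorus position and local orthonormal frame for linkage i (0-based)."""
    ang = i * HELIX_TWIST
    p = np.array(
        [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), i * HELIX_RISE]
    )
    radial = np.array([np.cos(ang), np.sin(ang), 0.0])
    axial = np.array([0.0, 0.0, 1.0])
    tangent = np.cross(axial, radial)
    frame = np.stack([radial, tangent, axial], axis=1)  # columns
    return p, frame


def build_ps_strand(spec: FixtureSpec, chain_id: str = "A") -> StructureModel:
    """Build the phosphate backbone of a PS strand with programmed
    stereochemistry; optionally add a two-side-chain protein pocket."""
    atoms: list[AtomRecord] = []
    serial = 0
    n = spec.n_nucleotides

    def add(name, resnum, pos, element, occ=1.0, b=20.0, altloc="", resname="DT",
            chain=chain_id):
        nonlocal serial
        serial += 1
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                altloc=altloc,
                residue_name=resname,
                chain_id=chain,
                residue_number=resnum,
                insertion_code="",
                position=pos,
                occupancy=occ,
                b_factor=b,
                element=element,
            )
        )

    # per-residue atom buffers so file order is residue-by-residue
    res_atoms: dict[int, list] = {i: [] for i in range(1, n + 1)}
    sulfur_positions: list[tuple[int, np.ndarray, float]] = []
    for j in range(1, n):  # linkage j joins residue j and j+1
        b_iso = float(spec.b_profile[j - 1])
        p_pos, frame = _helix_frame(j)
        o5 = p_pos + P_O_BRIDGE * frame @ _TET[0]
        o3 = p_pos + P_O_BRIDGE * frame @ _TET[1]
        site = [p_pos + P_O_NONBRIDGE * frame @ _TET[2 + k] for k in range(2)]
        s_at = [p_pos + P_S_BOND * frame @ _TET[2 + k] for k in range(2)]
        # which site index gives Rp is a pure geometry question
        rp_idx = _rp_site(p_pos, o5, o3, site)
        label = spec.stereo_pattern[j - 1]
        res_atoms[j].append(("O3'", o3, "O", 1.0, b_iso, ""))
        res_atoms[j + 1].append(("P", p_pos, "P", 1.0, b_iso, ""))
        res_atoms[j + 1].append(("O5'", o5, "O", 1.0, b_iso, ""))
        res_atoms[j + 1].append(("OP1", site[0], "O", 1.0, b_iso, ""))
        res_atoms[j + 1].append(("OP2", site[1], "O", 1.0, b_iso, ""))
        if label == "mixed":
            res_atoms[j + 1].append(("SP", s_at[rp_idx], "S", 0.5, b_iso, "A"))
            res_atoms[j + 1].append(("SP", s_at[1 - rp_idx], "S", 0.5, b_iso, "B"))
            sulfur_positions.append((j, s_at[rp_idx], 0.5))
            sulfur_positions.append((j, s_at[1 - rp_idx], 0.5))
        else:
            idx = rp_idx if label == "Rp" else 1 - rp_idx
            res_atoms[j + 1].append(("SP", s_at[idx], "S", 1.0, b_iso, ""))
            sulfur_positions.append((j, s_at[idx], 1.0))
    for resnum in range(1, n + 1):
        for name, pos, el, occ, b, alt in res_atoms[resnum]:
            add(name, resnum, pos, el, occ=occ, b=b, altloc=alt)

    if spec.pocket_linkage is not None:
        _add_pocket(add, spec, sulfur_positions)

    return StructureModel(atoms=atoms, source_id=f"ps_strand_n{n}_seed{spec.seed}")


def _rp_site(p_pos, o5, o3, sites) -> int:
    """Index of the non-bridging site where a sulfur would be Rp (standalone
    geometry, same triple-product convention as stereo.assign_chirality)."""
    from .stereo import _NEGATIVE_VOLUME_IS_R

    a, b, c, d = sites[0], o3, o5, sites[1]
    vol = float(np.dot(a - d, np.cross(b - d, c - d)))
    is_r_at_0 = (vol < 0) if _NEGATIVE_VOLUME_IS_R else (vol > 0)
    return 0 if is_r_at_0 else 1


def _add_pocket(add, spec: FixtureSpec, sulfur_positions) -> None:
    """Two side-chain fragments (Arg, Lys) whose aliphatic carbons sit at van
    der Waals distance from the first sulfur of the chosen linkage."""
    target = next(
        (pos for j, pos, _occ in sulfur_positions if j == spec.pocket_linkage), None
    )
    if target is None:
        raise ValueError(f"pocket_linkage {spec.pocket_linkage} has no sulfur")
    away = np.array([np.cos(0.3), np.sin(0.3), 0.2])
    away /= np.linalg.norm(away)
    perp = np.cross(away, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    # S...C contact at 3.8 Å (inside Bondi S+C+0.5 = 4.0 Å)
    cz = target + 3.8 * away
    ce = target + 3.8 * (0.8 * away + 0.6 * perp)
    add("CZ", 205, cz, "C", b=25.0, resname="ARG", chain="P")
    add("NH1", 205, cz + np.array([1.0, 0.6, 0.4]), "N", b=25.0, resname="ARG", chain="P")
    add("CE", 206, ce, "C", b=25.0, resname="LYS", chain="P")
    add("NZ", 206, ce + np.array([-0.5, 1.1, 0.6]), "N", b=25.0, resname="LYS", chain="P")


def render_anomalous_map(
    model: StructureModel,
    blob_sigma_height: float = DEFAULT_BLOB_HEIGHT,
    blob_width: float = DEFAULT_BLOB_WIDTH,
    noise: float = 0.0,
    seed: int = 0,
    spacing: float = MAP_SPACING,
    padding: float = MAP_PADDING,
) -> DensityGrid:
    """Synthetic anomalous difference map for a model's sulfur atoms.

    A Gaussian blob of peak height ``blob_sigma_height`` (σ units) is placed
    at every sulfur, weighted by its occupancy, plus Gaussian voxel noise of
    SD ``noise`` σ.  Values are on the σ scale by construction, so the
    grid's ``sigma`` is 1.
    """
    sulfurs = [a for a in model.atoms if a.element.upper() == "S"]
    if not sulfurs:
        import warnings

        warnings.warn("model contains no sulfur atoms; map will be empty", stacklevel=2)
    coords = np.array([a.position for a in model.atoms])
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    dims = np.ceil((hi - lo) / spacing).astype(int) + 1
    rng = np.random.default_rng(seed)
    values = (
        rng.normal(0.0, noise, size=tuple(dims)) if noise > 0 else np.zeros(tuple(dims))
    )
    axes = [lo[k] + spacing * np.arange(dims[k]) for k in range(3)]
    cut = 4.0 * blob_width
    for atom in sulfurs:
        c = atom.position
        sl = []
        for k in range(3):
            i0 = max(int(np.floor((c[k] - cut - lo[k]) / spacing)), 0)
            i1 = min(int(np.ceil((c[k] + cut - lo[k]) / spacing)) + 1, dims[k])
            sl.append((i0, i1))
        gx = axes[0][sl[0][0] : sl[0][1]]
        gy = axes[1][sl[1][0] : sl[1][1]]
        gz = axes[2][sl[2][0] : sl[2][1]]
        dx2 = (gx - c[0])[:, None, None] ** 2
        dy2 = (gy - c[1])[None, :, None] ** 2
        dz2 = (gz - c[2])[None, None, :] ** 2
        blob = (
            blob_sigma_height
            * atom.occupancy
            * np.exp(-(dx2 + dy2 + dz2) / (2.0 * blob_width**2))
        )
        values[sl[0][0] : sl[0][1], sl[1][0] : sl[1][1], sl[2][0] : sl[2][1]] += blob
    return DensityGrid(origin=lo, spacing=np.full(3, spacing), values=values, sigma=1.0)


def random_fixture_spec(rng: np.random.Generator, n_nucleotides: int | None = None,
                        map_noise_sigma: float = 0.0) -> FixtureSpec:
    """Random strand spec (uniform Rp/Sp/mixed pattern, B around 30 Å²)."""
    if n_nucleotides is None:
        n_nucleotides = int(rng.integers(6, 16))
    pattern = list(rng.choice(["Rp", "Sp", "mixed"], size=n_nucleotides - 1))
    b_profile = list(rng.uniform(20.0, 45.0, size=n_nucleotides - 1))
    return FixtureSpec(
        n_nucleotides=n_nucleotides,
        stereo_pattern=[str(s) for s in pattern],
        b_profile=b_profile,
        map_noise_sigma=map_noise_sigma,
        seed=int(rng.integers(2**31)),
    )


def make_binding_fixture(
    params_by_key: dict[tuple[str, str], BindingParams],
    csv_path: str,
    truth_path: str | None = None,
    probe_conc: float = 0.05,
    protein_grid=None,
    n_replicates: int = 3,
    noise_sd: float = 0.003,
    seed: int = 0,
) -> None:
    """Write a titration CSV (structio schema) for several (oligo, condition)
    systems plus a sidecar JSON with the generating ground truth.

    The default design mirrors the standard assay: 50 nM probe, triplicate,
    protein 0.1-120 μM.
    """
    if protein_grid is None:
        protein_grid = default_protein_grid()
    all_series = []
    truth = {}
    for i, ((oligo, condition), params) in enumerate(sorted(params_by_key.items())):
        all_series.extend(
            simulate_titration(
                params,
                probe_conc=probe_conc,
                protein_grid=protein_grid,
                n_replicates=n_replicates,
                noise_sd=noise_sd,
                seed=seed + 1000 * i,
                condition=condition,
                oligo=oligo,
            )
        )
        truth[f"{oligo}|{condition}"] = {
            "k_d_uM": params.k_d,
            "a0": params.a0,
            "da": params.da,
            "ns": params.ns,
            "noise_sd": noise_sd,
            "probe_conc_uM": probe_conc,
        }
    write_titrations(all_series, csv_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)


def verify_strand(model: StructureModel, spec: FixtureSpec) -> bool:
    """Sanity check: chirality of every programmed single-conformer sulfur
    matches the spec pattern (used by tests and make-fixtures)."""
    linkages = extract_linkages(model, chains=["A"])
    if len(linkages) != spec.n_nucleotides - 1:
        return False
    sulfurs = {
        (a.residue_number, a.altloc): a
        for a in model.atoms
        if a.element.upper() == "S"
    }
    for lk in linkages:
        want = spec.stereo_pattern[lk.linkage_id - 1]
        if want == "mixed":
            continue
        s = sulfurs.get((lk.linkage_id + 1, ""))
        if s is None:
            return False
        d0 = np.linalg.norm(s.position - lk.p_pos - (lk.nonbridge[0].position - lk.p_pos) * (
            P_S_BOND / P_O_NONBRIDGE))
        site = 0 if d0 < 0.1 else 1
        if assign_chirality(lk, site) != want:
            return False
    return True
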