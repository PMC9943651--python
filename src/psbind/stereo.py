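"""Rp/Sp stereochemistry of phosphorothioate (PS) linkages.

A PS linkage replaces one non-bridging phosphate oxygen with sulfur, making
the phosphorus a stereocenter.  Given a coordinate model, the two candidate
non-bridging sites of each internucleotide phosphate are identified, the
configuration a sulfur would have at each site is computed from the signed
tetrahedral volume under the CIP priority order S > O3' > O5' > O(non-
bridging), and sulfur-sensitive anomalous difference map peaks at the two
sites decide the call:

* neither peak reaches the contour threshold        -> indeterminate
* one peak >= threshold and >= margin x the other   -> Rp or Sp
* both peaks >= threshold within the margin         -> mixed (the dual
  0.5-occupancy-conformer situation)

Linkages whose phosphate-group mean B-factor exceeds ``b_max`` (default
60 Å²) are considered too disordered for a reliable call and forced to
indeterminate with ``reliable=False``.  Linkages are numbered 5'->3'
starting at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structio import DensityGrid, StructureModel

# Sign convention of the tetrahedral triple product, calibrated once against
# an independent CIP implementation on constructed ideal centers and frozen:
# with substituent positions ordered by descending priority (a, b, c, d),
# (a-d)·((b-d)×(c-d)) < 0 is R and > 0 is S.
_NEGATIVE_VOLUME_IS_R = True

MIN_TETRA_VOLUME = 0.1  # Å³; below this the center is considered degenerate
P_O_BOND_RANGE = (1.4, 2.2)  # Å, accepted P-O / P-S bridge distances
DEFAULT_THRESHOLD_SIGMA = 3.5  # map contour level used for a positive peak
DEFAULT_B_MAX = 60.0  # Å²; disorder cutoff for a reliable call
DEFAULT_RATIO_MARGIN = 1.5  # "clearly indicated" vs "evenly distributed"
DEFAULT_PEAK_RADIUS = 1.0  # Å search radius around a candidate site

O3_NAMES = {"O3'", "O3*"}
O5_NAMES = {"O5'", "O5*"}
NONBRIDGE_NAMES = {"OP1", "OP2", "O1P", "O2P"}


def stereoisomer_count(n_nucleotides: int) -> int:
    """Number of discrete Rp/Sp stereoisomers of an n-mer PS strand, 2^(n-1)."""
    if n_nucleotides < 1:
        raise ValueError("need at least one nucleotide")
    return 2 ** (n_nucleotides - 1)


@dataclass
class NonbridgeSite:
    """One candidate non-bridging position (an OP1/OP2 site)."""

    position: np.ndarray
    name: str
    altloc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class PSLinkage:
    """One internucleotide phosphorothioate, numbered from the 5' end."""

    linkage_id: int
    chain: str
    res5: str
    res3: str
    p_pos: np.ndarray
    o5_pos: np.ndarray
    o3_pos: np.ndarray
    nonbridge: list[NonbridgeSite] = field(default_factory=list)
    mean_b: float = 0.0

    def __post_init__(self) -> None:
        self.p_pos = np.asarray(self.p_pos, dtype=float)
        self.o5_pos = np.asarray(self.o5_pos, dtype=float)
        self.o3_pos = np.asarray(self.o3_pos, dtype=float)
        if len(self.nonbridge) != 2:
            raise ValueError("a PS linkage needs exactly two non-bridging sites")
        for apex, nm in ((self.o5_pos, "O5'"), (self.o3_pos, "O3'")):
            d = float(np.linalg.norm(apex - self.p_pos))
            if not P_O_BOND_RANGE[0] <= d <= P_O_BOND_RANGE[1]:
                raise ValueError(f"P-{nm} distance {d:.2f} Å outside {P_O_BOND_RANGE}")
        if abs(self.tetra_volume()) < MIN_TETRA_VOLUME:
            raise ValueError("substituents are near-coplanar; geometry degenerate")

    def tetra_volume(self) -> float:
        """Signed volume spanned by the four substituents (Å³)."""
        a = self.nonbridge[0].position
        b = self.o3_pos
        c = self.o5_pos
        d = self.nonbridge[1].position
        return float(np.dot(a - d, np.cross(b - d, c - d))) / 6.0


@dataclass
class StereoCall:
    """Per-linkage stereochemistry call with its map evidence."""

    linkage_id: int
    call: str  # Rp | Sp | mixed | indeterminate
    peak_rp_sigma: float
    peak_sp_sigma: float
    reliable: bool
    rationale: str = ""
    chain: str = ""
    res5: str = ""
    res3: str = ""
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        if self.call not in ("Rp", "Sp", "mixed", "indeterminate"):
            raise ValueError(f"invalid call {self.call!r}")
        if not self.reliable and self.call != "indeterminate":
            raise ValueError("an unreliable linkage must be called indeterminate")


# ---------------------------------------------------------------------------
# linkage extraction


def extract_linkages(model: StructureModel, chains=None) -> list[PSLinkage]:
    """One PSLinkage per internucleotide phosphate, numbered 5'->3' from 1.

    Residues are taken in file order per chain; the linkage between residues
    i and i+1 uses O3' of residue i and P/O5'/OP1/OP2 of residue i+1.
    Linkages with a missing backbone atom are skipped with a warning.
    Dual-altloc non-bridging atoms are grouped into two candidate positions
    (sites closer than 0.6 Å merge).
    """
    if chains is None:
        chains = model.chains()
    linkages: list[PSLinkage] = []
    for chain_id in chains:
        residues = model.residues(chain_id)
        keys = list(residues.keys())
        lid = 0
        for prev_key, key in zip(keys[:-1], keys[1:]):
            lid += 1
            prev_atoms = residues[prev_key]
            atoms = residues[key]
            o3 = _first(prev_atoms, O3_NAMES)
            p = _first(atoms, {"P"})
            o5 = _first(atoms, O5_NAMES)
            nb_atoms = [a for a in atoms if a.name in NONBRIDGE_NAMES]
            missing = [
                nm
                for nm, atom in (("O3'", o3), ("P", p), ("O5'", o5))
                if atom is None
            ]
            if missing or len(nb_atoms) < 2:
                warnings.warn(
                    f"chain {chain_id} linkage {lid}: missing backbone atom(s) "
                    f"{missing or 'OP1/OP2'}; skipped",
                    stacklevel=2,
                )
                continue
            sites = _group_sites(nb_atoms)
            if len(sites) != 2:
                warnings.warn(
                    f"chain {chain_id} linkage {lid}: could not resolve two "
                    f"non-bridging sites ({len(sites)} found); skipped",
                    stacklevel=2,
                )
                continue
            group_b = [p.b_factor] + [s.b_factor for s in sites]
            res5_name = f"{prev_atoms[0].residue_name}{prev_key[0]}"
            res3_name = f"{atoms[0].residue_name}{key[0]}"
            try:
                linkages.append(
                    PSLinkage(
                        linkage_id=lid,
                        chain=chain_id,
                        res5=res5_name,
                        res3=res3_name,
                        p_pos=p.position,
                        o5_pos=o5.position,
                        o3_pos=o3.position,
                        nonbridge=sites,
                        mean_b=float(np.mean(group_b)),
                    )
                )
            except ValueError as exc:
                warnings.warn(
                    f"chain {chain_id} linkage {lid}: bad geometry ({exc}); skipped",
                    stacklevel=2,
                )
    return linkages


def _first(atoms, names):
    for a in atoms:
        if a.name in names:
            return a
    return None


def _group_sites(nb_atoms, merge_dist: float = 0.6) -> list[NonbridgeSite]:
    """Cluster non-bridging atom records into distinct spatial sites."""
    sites: list[NonbridgeSite] = []
    for a in nb_atoms:
        for s in sites:
            if np.linalg.norm(a.position - s.position) < merge_dist:
                break
        else:
            sites.append(
                NonbridgeSite(
                    position=a.position,
                    name=a.name,
                    altloc=a.altloc,
                    occupancy=a.occupancy,
                    b_factor=a.b_factor,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# chirality


def assign_chirality(linkage: PSLinkage, sulfur_site: int) -> str:
    """Configuration ("Rp" or "Sp") if the sulfur occupies the given
    non-bridging site (0 or 1).

    Priorities at phosphorus: S > O3' > O5' > O(non-bridging); the label
    follows the sign of the triple product (a-d)·((b-d)×(c-d)) over the
    priority-ordered substituent positions (see module constant).
    """
    if sulfur_site not in (0, 1):
        raise ValueError("sulfur_site must be 0 or 1")
    s_pos = linkage.nonbridge[sulfur_site].position
    o_pos = linkage.nonbridge[1 - sulfur_site].position
    a, b, c, d = s_pos, linkage.o3_pos, linkage.o5_pos, o_pos
    vol = float(np.dot(a - d, np.cross(b - d, c - d)))
    if abs(vol) / 6.0 < MIN_TETRA_VOLUME:
        raise ValueError("near-degenerate geometry; chirality indeterminate")
    negative = vol < 0
    is_r = negative if _NEGATIVE_VOLUME_IS_R else not negative
    return "Rp" if is_r else "Sp"


def rp_site_index(linkage: PSLinkage) -> int:
    """Index (0/1) of the non-bridging site where a sulfur would be Rp."""
    return 0 if assign_chirality(linkage, 0) == "Rp" else 1


# ---------------------------------------------------------------------------
# map peaks


def peak_height(grid: DensityGrid, position, radius: float = DEFAULT_PEAK_RADIUS) -> float:
    """Peak height in σ units near a position.

    Maximum of the trilinearly interpolated value at the query position and
    the values at grid nodes within ``radius``, divided by the grid σ.
    """
    pos = np.asarray(position, dtype=float)
    if not grid.contains(pos):
        raise ValueError(f"position {pos} outside map bounds")
    if not grid.usable:
        raise ValueError("map has zero variance; σ-normalisation undefined")
    best = grid.interpolate(pos)
    lo_idx = np.ceil((pos - radius - grid.origin) / grid.spacing).astype(int)
    hi_idx = np.floor((pos + radius - grid.origin) / grid.spacing).astype(int)
    lo_idx = np.maximum(lo_idx, 0)
    hi_idx = np.minimum(hi_idx, np.array(grid.values.shape) - 1)
    if np.all(hi_idx >= lo_idx):
        ix = np.arange(lo_idx[0], hi_idx[0] + 1)
        iy = np.arange(lo_idx[1], hi_idx[1] + 1)
        iz = np.arange(lo_idx[2], hi_idx[2] + 1)
        gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
        pts = grid.origin + grid.spacing * np.stack([gx, gy, gz], axis=-1)
        within = np.sum((pts - pos) ** 2, axis=-1) <= radius**2
        if np.any(within):
            best = max(best, float(np.max(grid.values[gx, gy, gz][within])))
    return best / grid.sigma


# ---------------------------------------------------------------------------
# classification


def classify_linkage(
    grid: DensityGrid,
    linkage: PSLinkage,
    threshold_sigma: float = DEFAULT_THRESHOLD_SIGMA,
    b_max: float = DEFAULT_B_MAX,
    ratio_margin: float = DEFAULT_RATIO_MARGIN,
    peak_radius: float = DEFAULT_PEAK_RADIUS,
) -> StereoCall:
    """Four-way stereo call for one linkage from anomalous map evidence."""
    common = dict(
        linkage_id=linkage.linkage_id,
        chain=linkage.chain,
        res5=linkage.res5,
        res3=linkage.res3,
        b_factor=linkage.mean_b,
    )
    if linkage.mean_b > b_max:
        return StereoCall(
            call="indeterminate",
            peak_rp_sigma=float("nan"),
            peak_sp_sigma=float("nan"),
            reliable=False,
            rationale=f"mean B {linkage.mean_b:.1f} Å² exceeds cutoff {b_max:.0f} Å²",
            **common,
        )
    rp_idx = rp_site_index(linkage)
    sites = {
        "Rp": linkage.nonbridge[rp_idx].position,
        "Sp": linkage.nonbridge[1 - rp_idx].position,
    }
    for label, pos in sites.items():
        if not grid.contains(pos):
            raise ValueError(
                f"linkage {linkage.linkage_id}: {label} candidate site outside map; "
                "model and map frames do not match"
            )
    peak_rp = peak_height(grid, sites["Rp"], peak_radius)
    peak_sp = peak_height(grid, sites["Sp"], peak_radius)
    if peak_rp < threshold_sigma and peak_sp < threshold_sigma:
        call, why = "indeterminate", "no anomalous density at either site"
    elif peak_rp >= threshold_sigma and peak_rp >= ratio_margin * peak_sp:
        call, why = "Rp", "density clearly indicates the Rp site"
    elif peak_sp >= threshold_sigma and peak_sp >= ratio_margin * peak_rp:
        call, why = "Sp", "density clearly indicates the Sp site"
    else:
        call, why = "mixed", (
            "density evenly distributed at both sites "
            "(dual 0.5-occupancy conformers)"
        )
    return StereoCall(
        call=call,
        peak_rp_sigma=float(peak_rp),
        peak_sp_sigma=float(peak_sp),
        reliable=True,
        rationale=why,
        **common,
    )


def call_strand(
    grid: DensityGrid,
    model: StructureModel,
    chains=None,
    threshold_sigma: float = DEFAULT_THRESHOLD_SIGMA,
    b_max: float = DEFAULT_B_MAX,
    ratio_margin: float = DEFAULT_RATIO_MARGIN,
    peak_radius: float = DEFAULT_PEAK_RADIUS,
) -> list[StereoCall]:
    """Stereo calls for every linkage of the selected chains, 5'->3' order."""
    calls = []
    for linkage in extract_linkages(model, chains):
        calls.append(
            classify_linkage(
                grid,
                linkage,
                threshold_sigma=threshold_sigma,
                b_max=b_max,
                ratio_margin=ratio_margin,
                peak_radius=peak_radius,
            )
        )
    return calls


def summarize_calls(calls: list[StereoCall]) -> dict[str, int]:
    """Counts by label over a collection of calls."""
    out = {"Rp": 0, "Sp": 0, "mixed": 0, "indeterminate": 0}
    for c in calls:
        out[c.call] += 1
    return out
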