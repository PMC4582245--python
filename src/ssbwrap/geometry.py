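"""Geometry of the SSB-ssDNA complex and structure-derived constraints.

The wrapped complex contributes to the tether extension through the
separation ``x_SSB`` of the ssDNA entry and exit points on the protein,
projected onto the force axis by rotational Boltzmann averaging (the
Langevin orientation factor).  A co-crystal structure of the wrapped
ssDNA path constrains which ``(N_w, x_SSB)`` pairs are geometrically
possible, at three stringency levels:

1. protein size only (``0 <= x_SSB <= 6.5 nm``),
2. end-to-end distances between all nucleotide pairs ``N_w`` apart on the
   wrapping path,
3. distances between groups of nucleotides anchored at the Trp-54/His-55/
   Arg-56 "hotspot" cluster of each monomer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

PROTEIN_SIZE_NM = 6.5
DEFAULT_CONTACT_CUTOFF_NM = 0.6  # midpoint of the 5-7 A phosphate-residue range


def orientation_factor(z):
    """Langevin function ``L(z) = coth(z) - 1/z`` (rotational alignment).

    Evaluated by series below ``z = 1e-4`` for numerical stability.
    Maps [0, inf) onto [0, 1), monotone increasing; ``L(z) ~ z/3`` for
    small ``z`` (isotropic limit), ``L -> 1`` for full alignment.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0):
        raise ValueError("z must be non-negative")
    safe = np.where(z_arr < 1e-4, 1.0, z_arr)
    exact = 1.0 / np.tanh(safe) - 1.0 / safe
    series = z_arr / 3.0 - z_arr**3 / 45.0
    out = np.where(z_arr < 1e-4, series, exact)
    return out.item() if np.ndim(z) == 0 else out


def effective_size(x_ssb, force, thermal_energy: float = 4.09):
    """Orientation-averaged projection ``x_SSB L(F x_SSB / kBT)`` (nm)."""
    x = np.asarray(x_ssb, dtype=float)
    f = np.asarray(force, dtype=float)
    if np.any(x < 0) or np.any(f < 0):
        raise ValueError("x_ssb and force must be non-negative")
    out = x * orientation_factor(f * x / thermal_energy)
    return out.item() if np.ndim(x_ssb) == 0 and np.ndim(force) == 0 else out


def effective_size_integral(x_ssb: float, force, thermal_energy: float = 4.09):
    """Closed form ``int_0^F x L(F' x / kBT) dF' = kBT ln(sinh z / z)`` (pN nm)."""
    f = np.asarray(force, dtype=float)
    z = f * x_ssb / thermal_energy
    small = z < 1e-4
    large = z > 20.0
    mid = np.where(small | large, 1.0, z)
    val_mid = np.log(np.sinh(mid) / mid)
    val_small = z**2 / 6.0 - z**4 / 180.0
    with np.errstate(divide="ignore"):
        val_large = z - np.log(2.0 * np.maximum(z, 1.0))
    out = thermal_energy * np.where(small, val_small, np.where(large, val_large, val_mid))
    return out.item() if np.ndim(force) == 0 else out


@dataclass
class StructureModel:
    """Wrapped-ssDNA path geometry with hotspot anchor annotations.

    Attributes
    ----------
    positions_nm
        ``(N, 3)`` coordinates of one reference atom per nucleotide,
        ordered 5'->3' along a single continuous wrapping path, in nm.
    hotspot_groups
        Per-monomer lists of nucleotide indices within contact distance of
        the hotspot residue cluster (6-7 nt each on the crystal structure).
    hotspot_contact_sets
        Possibly larger contact sets used for contour enumeration; on a
        nearly closed wrapping path one hotspot can contact nucleotides
        from both the entry and exit segments.  Defaults to the groups.
    metadata
        Provenance: source file, chain join order, reference atom, cutoff.
    """

    positions_nm: np.ndarray
    hotspot_groups: list[list[int]] = field(default_factory=list)
    hotspot_contact_sets: list[list[int]] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        if self.positions_nm.ndim != 2 or self.positions_nm.shape[1] != 3:
            raise ValueError("positions_nm must be (N, 3)")
        if self.hotspot_contact_sets is None:
            self.hotspot_contact_sets = [list(g) for g in self.hotspot_groups]

    def __len__(self) -> int:
        return len(self.positions_nm)


def end_to_end_bounds(structure: StructureModel, n_wrapped: int) -> tuple[float, float]:
    """Min/max distance between nucleotide pairs separated by ``n_wrapped`` nt.

    A wrap of ``n_wrapped`` nucleotides occupies path indices ``i .. j``
    with ``|i - j| = n_wrapped - 1``; the entry/exit separation ``x_SSB``
    of any such wrap is bracketed by the extremes over all index pairs.
    ``n_wrapped = 1`` gives ``(0, 0)``.  The upper bound is capped at the
    protein size (6.5 nm).
    """
    n = len(structure)
    if not 1 <= n_wrapped <= n:
        raise ValueError(f"n_wrapped must lie in [1, {n}]")
    if n_wrapped == 1:
        return 0.0, 0.0
    sep = n_wrapped - 1
    d = np.linalg.norm(structure.positions_nm[sep:] - structure.positions_nm[:-sep], axis=1)
    return float(d.min()), float(min(d.max(), PROTEIN_SIZE_NM))


def _hull_band(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper/lower convex envelopes of scattered ``(N_w, x)`` points.

    Returns integer ``N_w`` values spanned and the piecewise-linear lower
    and upper hull evaluated there (the "smooth contour spanning the
    range" of the point set).
    """

    def half_hull(pts):
        hull: list[np.ndarray] = []
        for p in pts:
            while len(hull) >= 2:
                o, a = hull[-2], hull[-1]
                cross = (a[0] - o[0]) * (p[1] - o[1]) - (a[1] - o[1]) * (p[0] - o[0])
                if cross <= 0:
                    hull.pop()
                else:
                    break
            hull.append(p)
        return np.array(hull)

    pts = points[np.lexsort((points[:, 1], points[:, 0]))]
    # per-N_w extremes first, so vertical runs cannot mask the envelope
    xs = np.unique(pts[:, 0])
    mins = np.array([[x, pts[pts[:, 0] == x, 1].min()] for x in xs])
    maxs = np.array([[x, pts[pts[:, 0] == x, 1].max()] for x in xs])
    lower_pts = half_hull(mins)
    upper_pts = half_hull(maxs[::-1])[::-1]
    nws = np.arange(int(np.ceil(pts[0, 0])), int(np.floor(pts[-1, 0])) + 1)
    lo = np.interp(nws, lower_pts[:, 0], lower_pts[:, 1])
    hi = np.interp(nws, upper_pts[:, 0], upper_pts[:, 1])
    return nws, lo, hi


def hotspot_contours(structure: StructureModel, min_separation: int = 8):
    """Contour bands in ``(N_w, x_SSB)`` space from inter-hotspot distances.

    Every pair of nucleotides drawn from (distinct or wrap-around) hotspot
    contact sets and separated by at least ``min_separation`` along the
    path contributes a point ``(|i - j| + 1, distance)``.  Points are
    clustered into contiguous ``N_w`` bands (gaps > 2 nt split regions)
    and each band is smoothed into its convex envelope.

    Returns a list of ``(nw_values, x_min, x_max)`` arrays, one per region,
    ordered by increasing ``N_w``.
    """
    sets = structure.hotspot_contact_sets
    if not sets or all(len(s) == 0 for s in sets):
        raise ValueError("structure has no hotspot contact sets")
    pos = structure.positions_nm
    pts = []
    for gi in range(len(sets)):
        for gj in range(gi, len(sets)):
            for a in sets[gi]:
                for b in sets[gj]:
                    if b - a < min_separation:
                        continue
                    pts.append((b - a + 1, float(np.linalg.norm(pos[a] - pos[b]))))
    if not pts:
        raise ValueError("no inter-hotspot nucleotide pairs found")
    pts = np.array(sorted(set(pts)), dtype=float)
    # split into contiguous-N_w clusters
    nw_sorted = np.unique(pts[:, 0])
    breaks = np.where(np.diff(nw_sorted) > 2)[0]
    edges = np.concatenate([[nw_sorted[0]], nw_sorted[breaks + 1], [nw_sorted[-1] + 1]])
    regions = []
    for lo_edge, hi_edge in zip(edges[:-1], edges[1:]):
        mask = (pts[:, 0] >= lo_edge) & (pts[:, 0] < hi_edge)
        cluster = pts[mask]
        if len(cluster) < 2:
            continue
        nws, lo, hi = _hull_band(cluster)
        regions.append((nws, np.clip(lo, 0, PROTEIN_SIZE_NM), np.clip(hi, 0, PROTEIN_SIZE_NM)))
    return regions


@dataclass
class ConstraintEnvelope:
    """Per-``N_w`` bounds on ``x_SSB`` at the three stringency levels.

    Level 1 is the protein-size box, level 2 the end-to-end scan of the
    wrapping path, level 3 the hotspot contour bands.  Nesting
    (level 3 inside level 2 inside level 1) is enforced by clipping.
    """

    n_ss: int
    level2: dict[int, tuple[float, float]]
    level3: dict[int, tuple[float, float]]
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_structure(cls, structure: StructureModel, n_ss: int | None = None,
                       min_separation: int = 8) -> "ConstraintEnvelope":
        n = len(structure)
        n_ss = n_ss if n_ss is not None else n
        level2 = {}
        for nw in range(1, n + 1):
            lo, hi = end_to_end_bounds(structure, nw)
            level2[nw] = (max(0.0, lo), min(hi, PROTEIN_SIZE_NM))
        level3 = {}
        try:
            regions = hotspot_contours(structure, min_separation=min_separation)
        except ValueError:
            regions = []
        for nws, los, his in regions:
            for nw, lo, hi in zip(nws.astype(int), los, his):
                if nw in level2:
                    lo = max(lo, level2[nw][0])
                    hi = min(hi, level2[nw][1])
                if hi < lo:
                    continue
                if nw in level3:  # overlapping regions: take the union
                    lo = min(lo, level3[nw][0])
                    hi = max(hi, level3[nw][1])
                level3[nw] = (lo, hi)
        return cls(n_ss=n_ss, level2=level2, level3=level3,
                   metadata=dict(structure.metadata))

    def bounds(self, n_wrapped: int, level: int) -> tuple[float, float] | None:
        """``(x_min, x_max)`` at the given level, or None if infeasible."""
        if level == 1:
            return (0.0, PROTEIN_SIZE_NM) if 0 <= n_wrapped <= self.n_ss else None
        table = self.level2 if level == 2 else self.level3
        if level not in (2, 3):
            raise ValueError("level must be 1, 2 or 3")
        return table.get(int(n_wrapped))

    def to_frame(self):
        """Tabular form (n_w, x_min_nm, x_max_nm, level)."""
        import pandas as pd

        rows = []
        for nw in range(0, self.n_ss + 1):
            rows.append((nw, 0.0, PROTEIN_SIZE_NM, 1))
        for level, table in ((2, self.level2), (3, self.level3)):
            for nw in sorted(table):
                lo, hi = table[nw]
                rows.append((nw, lo, hi, level))
        return pd.DataFrame(rows, columns=["n_w", "x_min_nm", "x_max_nm", "level"])


# ---------------------------------------------------------------------------
# PDB input/output

_NUCLEOTIDE_RESNAMES = {"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "T", "U"}
DEFAULT_HOTSPOT_RESIDS = (54, 55, 56)


def load_structure(path, nucleotide_chains: list[str] | None = None,
                   reference_atom: str = "P",
                   hotspot_resids: tuple[int, ...] = DEFAULT_HOTSPOT_RESIDS,
                   contact_cutoff_nm: float = DEFAULT_CONTACT_CUTOFF_NM) -> StructureModel:
    """Build a :class:`StructureModel` from a PDB file.

    One reference atom per nucleotide is taken (phosphate P, falling back
    to C1' when absent, e.g. at a 5' terminus).  Multiple ssDNA chains are
    joined into one continuous 5'->3' path in ``nucleotide_chains`` order
    (file order when omitted); the junction choice is recorded in the
    metadata.  Hotspot groups are nucleotides whose reference atom lies
    within ``contact_cutoff_nm`` of any atom of residues 54-56 of each
    protein chain.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PDBParser(QUIET=True).get_structure("s", str(path))[0]

    nuc_coords: list[np.ndarray] = []
    chain_order: list[str] = []
    hotspot_atoms: dict[str, list[np.ndarray]] = {}
    chains = {c.id: c for c in model}
    ids = nucleotide_chains if nucleotide_chains else list(chains)
    for cid in ids:
        chain = chains[cid]
        coords = []
        for res in chain:
            if res.get_resname().strip() in _NUCLEOTIDE_RESNAMES:
                atom = None
                for name in (reference_atom, "C1'"):
                    if name in res:
                        atom = res[name]
                        break
                if atom is not None:
                    coords.append(atom.get_coord() / 10.0)  # A -> nm
            elif res.id[1] in hotspot_resids:
                hotspot_atoms.setdefault(cid, []).extend(
                    a.get_coord() / 10.0 for a in res)
        if coords:
            nuc_coords.extend(coords)
            chain_order.append(cid)
    if not nuc_coords:
        raise ValueError(f"no nucleotide path found in {path}")
    positions = np.asarray(nuc_coords)

    groups = []
    for cid in sorted(hotspot_atoms):
        hs = np.asarray(hotspot_atoms[cid])
        dists = np.linalg.norm(positions[:, None, :] - hs[None, :, :], axis=2).min(axis=1)
        members = np.where(dists <= contact_cutoff_nm)[0].tolist()
        if members:
            groups.append(members)
    groups.sort(key=lambda g: min(g))

    return StructureModel(
        positions_nm=positions,
        hotspot_groups=groups,
        metadata={
            "source": str(path),
            "nucleotide_chain_order": chain_order,
            "reference_atom": reference_atom,
            "contact_cutoff_nm": contact_cutoff_nm,
        },
    )


def write_structure_pdb(structure: StructureModel, path,
                        anchor_positions_nm: np.ndarray | None = None) -> None:
    """Write a minimal PDB representation of a wrapping path.

    Nucleotides become DT residues (P atoms) on chain A; optional hotspot
    anchors become GLY-54 CA atoms on chains W, X, Y, Z so the hotspot
    detection in :func:`load_structure` can be exercised round-trip.
    """
    lines = []
    serial = 1
    for i, p in enumerate(structure.positions_nm, start=1):
        x, y, z = p * 10.0
        lines.append(
            f"ATOM  {serial:>5d}  P   DT  A{i:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           P"
        )
        serial += 1
    if anchor_positions_nm is not None:
        for k, p in enumerate(np.asarray(anchor_positions_nm)):
            x, y, z = p * 10.0
            cid = "WXYZ"[k % 4]
            lines.append(
                f"ATOM  {serial:>5d}  CA  GLY {cid}  54    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
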