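"""Structure-based spin-label distance prediction.

A nitroxide label attached at an engineered cysteine samples a cloud of
unpaired-electron positions set by its flexible tether. This module
approximates that ensemble with an accessible-volume model: electron
positions are sampled at a fixed tether length from CB inside a cone about
the CA→CB axis, positions clashing with the protein are discarded, and the
survivors (uniform weights) define the label cloud. Distance distributions
between two clouds are weighted pairwise-distance histograms smoothed with
a Gaussian. Coordinates are Å internally; distances are reported in nm.

The cone is sampled in a local frame built from the residue's own N, CA
and CB atoms, so clouds — and therefore predicted distributions — are
exactly invariant under rigid-body motion of the structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.distance import cdist

from .distributions import DistanceDistribution, DistanceGrid

__all__ = [
    "StructureModel",
    "LabelSite",
    "LabelCloud",
    "read_structure",
    "build_label_cloud",
    "predict_distribution",
    "write_pdb",
]

_ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}


@dataclass
class StructureModel:
    """Atomic structure with one or more coordinate sets (models/frames).

    `atoms` holds per-atom metadata (chain, resid, resname, name, element);
    `coords` is (n_models, n_atoms, 3) in Å.
    """

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords and atoms have mismatched atom counts")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def masses(self) -> np.ndarray:
        return np.array(
            [_ELEMENT_MASSES.get(e, 12.011) for e in self.atoms["element"]]
        )

    def atom_index(self, chain: str, resid: int, name: str) -> int:
        mask = (
            (self.atoms["chain"] == chain)
            & (self.atoms["resid"] == resid)
            & (self.atoms["name"] == name)
        )
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size != 1:
            raise KeyError(
                f"atom {name} of {chain}:{resid} "
                f"{'missing' if idx.size == 0 else 'ambiguous'}"
            )
        return int(idx[0])

    def residue_mask(self, chain: str, resid: int) -> np.ndarray:
        return (
            (self.atoms["chain"] == chain) & (self.atoms["resid"] == resid)
        ).to_numpy()

    def select(self, chain: str | None = None, resids=None) -> np.ndarray:
        mask = np.ones(len(self.atoms), dtype=bool)
        if chain is not None:
            mask &= (self.atoms["chain"] == chain).to_numpy()
        if resids is not None:
            mask &= self.atoms["resid"].isin(list(resids)).to_numpy()
        return np.flatnonzero(mask)


@dataclass
class LabelSite:
    """Labelling site resolved to its N/CA/CB attachment frame (Å)."""

    chain: str
    resid: int
    n_xyz: np.ndarray
    ca_xyz: np.ndarray
    cb_xyz: np.ndarray

    def __post_init__(self) -> None:
        for a, b in (
            (self.n_xyz, self.ca_xyz),
            (self.ca_xyz, self.cb_xyz),
            (self.n_xyz, self.cb_xyz),
        ):
            if np.allclose(a, b):
                raise ValueError("frame atoms must be mutually distinct")
        d = float(np.linalg.norm(self.cb_xyz - self.ca_xyz))
        if not (1.2 <= d <= 1.8):
            raise ValueError(f"CA-CB distance {d:.2f} Å outside [1.2, 1.8]")

    @classmethod
    def from_structure(
        cls, structure: StructureModel, chain: str, resid: int, model: int = 0
    ) -> "LabelSite":
        resmask = structure.residue_mask(chain, resid)
        if not resmask.any():
            raise KeyError(f"residue {chain}:{resid} not in structure")
        resname = structure.atoms.loc[resmask, "resname"].iloc[0]
        if resname == "GLY":
            raise ValueError(f"cannot label glycine at {chain}:{resid} (no CB)")
        xyz = {}
        for name in ("N", "CA", "CB"):
            try:
                xyz[name] = structure.coords[model, structure.atom_index(chain, resid, name)]
            except KeyError as exc:
                raise ValueError(
                    f"site {chain}:{resid} lacks frame atom {name}"
                ) from exc
        return cls(chain, resid, xyz["N"], xyz["CA"], xyz["CB"])


@dataclass
class LabelCloud:
    """Candidate unpaired-electron positions (Å) with normalized weights."""

    positions: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] < 1:
            raise ValueError("cloud must contain at least one position")
        if self.weights is None:
            self.weights = np.full(len(self.positions), 1.0 / len(self.positions))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0):
                raise ValueError("weights must be nonnegative")
            total = self.weights.sum()
            if total <= 0:
                raise ValueError("weights must not all vanish")
            self.weights = self.weights / total

    @property
    def centroid(self) -> np.ndarray:
        return self.weights @ self.positions


def read_structure(path) -> StructureModel:
    """Read a (possibly multi-model) PDB file.

    Author residue numbering is preserved; for disordered atoms the
    highest-occupancy altloc is kept (Biopython's default selection).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no models in {path}")
    rows = []
    coords_first = []
    index = {}
    for atom in models[0].get_atoms():
        residue = atom.get_parent()
        chain = residue.get_parent().id
        het, resid, _ = residue.id
        rows.append(
            {
                "chain": chain,
                "resid": int(resid),
                "resname": residue.get_resname().strip(),
                "name": atom.get_name(),
                "element": (atom.element or "C").strip().upper() or "C",
            }
        )
        index[(chain, int(resid), atom.get_name())] = len(coords_first)
        coords_first.append(atom.get_coord())
    atoms = pd.DataFrame(rows)
    n_atoms = len(atoms)
    coords = np.empty((len(models), n_atoms, 3))
    coords[0] = np.asarray(coords_first)
    for m, model in enumerate(models[1:], start=1):
        coords[m] = np.nan
        for atom in model.get_atoms():
            residue = atom.get_parent()
            chain = residue.get_parent().id
            _, resid, _ = residue.id
            key = (chain, int(resid), atom.get_name())
            if key in index:
                coords[m, index[key]] = atom.get_coord()
        if np.isnan(coords[m]).any():
            raise ValueError(
                f"model {m + 1} in {path} is missing atoms present in model 1"
            )
    return StructureModel(atoms=atoms, coords=coords)


def _cone_directions(
    site: LabelSite, cone_half_angle_deg: float, n_samples: int, rng
) -> np.ndarray:
    """Directions uniform over the spherical cap about the CA→CB axis,
    expressed in a frame built from the residue's own atoms (rigid-body
    covariant)."""
    e1 = site.cb_xyz - site.ca_xyz
    e1 = e1 / np.linalg.norm(e1)
    v = site.n_xyz - site.ca_xyz
    e2 = v - (v @ e1) * e1
    norm = np.linalg.norm(e2)
    if norm < 1e-8:
        raise ValueError("N, CA, CB are collinear; cannot build a label frame")
    e2 = e2 / norm
    e3 = np.cross(e1, e2)
    cos_min = np.cos(np.deg2rad(cone_half_angle_deg))
    cos_theta = rng.uniform(cos_min, 1.0, n_samples)
    sin_theta = np.sqrt(1.0 - cos_theta**2)
    phi = rng.uniform(0.0, 2.0 * np.pi, n_samples)
    return (
        cos_theta[:, None] * e1
        + (sin_theta * np.cos(phi))[:, None] * e2
        + (sin_theta * np.sin(phi))[:, None] * e3
    )


def build_label_cloud(
    structure: StructureModel,
    site: LabelSite | tuple[str, int],
    tether_length: float = 7.0,
    cone_half_angle: float = 90.0,
    n_samples: int = 2000,
    clash_cutoff: float = 2.5,
    seed: int = 0,
    model: int | None = None,
) -> LabelCloud:
    """Accessible-volume label cloud at one site.

    Candidate positions sit at `tether_length` Å from CB within the cone of
    `cone_half_angle` degrees about the CA→CB axis; candidates within
    `clash_cutoff` Å of any heavy atom outside the site's own residue are
    rejected. For multi-model structures (model=None) the per-model clouds
    are pooled with equal model weights.
    """
    if not (0 < cone_half_angle <= 180):
        raise ValueError("cone half-angle must be in (0, 180] degrees")
    if tether_length <= 0 or clash_cutoff < 0 or n_samples < 1:
        raise ValueError("invalid label-model parameters")
    models = range(structure.n_models) if model is None else [model]
    heavy = (structure.atoms["element"] != "H").to_numpy()
    all_pos, all_w = [], []
    for m in models:
        if isinstance(site, LabelSite):
            s = site
        else:
            s = LabelSite.from_structure(structure, site[0], site[1], model=m)
        rng = np.random.default_rng(seed + 7919 * m)
        dirs = _cone_directions(s, cone_half_angle, n_samples, rng)
        candidates = s.cb_xyz + tether_length * dirs
        exclude = structure.residue_mask(s.chain, s.resid)
        env_idx = np.flatnonzero(heavy & ~exclude)
        if env_idx.size:
            d = cdist(candidates, structure.coords[m, env_idx])
            keep = d.min(axis=1) >= clash_cutoff
        else:
            keep = np.ones(len(candidates), dtype=bool)
        if keep.any():
            pos = candidates[keep]
            all_pos.append(pos)
            all_w.append(np.full(len(pos), 1.0 / (len(pos) * len(list(models)))))
    if not all_pos:
        raise ValueError(
            f"all label candidates clash at {site}: site appears buried"
        )
    return LabelCloud(np.vstack(all_pos), np.concatenate(all_w))


def predict_distribution(
    cloud1: LabelCloud,
    cloud2: LabelCloud,
    grid: DistanceGrid | None = None,
    smoothing_sigma: float = 0.05,
) -> DistanceDistribution:
    """Inter-cloud distance distribution on `grid` (nm).

    Weighted pairwise distances are deposited by linear binning (which
    preserves the distribution mean) and smoothed with a Gaussian of
    `smoothing_sigma` nm.
    """
    grid = grid or DistanceGrid()
    d_nm = 0.1 * cdist(cloud1.positions, cloud2.positions).ravel()
    w = np.outer(cloud1.weights, cloud2.weights).ravel()
    r = grid.values
    if d_nm.min() < grid.r_min or d_nm.max() > grid.r_max:
        raise ValueError(
            f"grid [{grid.r_min}, {grid.r_max}] nm does not cover observed "
            f"distances [{d_nm.min():.3f}, {d_nm.max():.3f}] nm"
        )
    # linear binning onto grid nodes
    x = (d_nm - grid.r_min) / grid.step
    i0 = np.clip(np.floor(x).astype(int), 0, r.size - 2)
    frac = x - i0
    hist = np.zeros(r.size)
    np.add.at(hist, i0, w * (1.0 - frac))
    np.add.at(hist, i0 + 1, w * frac)
    if smoothing_sigma > 0:
        hist = gaussian_filter1d(
            hist, sigma=smoothing_sigma / grid.step, mode="constant"
        )
    z = np.trapezoid(hist, r)
    if z <= 0:
        raise ValueError("empty distance histogram")
    return DistanceDistribution(grid, hist / z)


# --------------------------------------------------------------- PDB output


def write_pdb(structure: StructureModel, path) -> None:
    """Write a StructureModel as a (multi-model) PDB text file."""
    lines = []
    multi = structure.n_models > 1
    for m in range(structure.n_models):
        if multi:
            lines.append(f"MODEL     {m + 1:4d}")
        serial = 1
        for i, row in structure.atoms.iterrows():
            x, y, z = structure.coords[m, i]
            name = row["name"]
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {pad_name}{'':1s}{row['resname']:>3s} "
                f"{row['chain']}{row['resid']:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {row['element']:>2s}"
            )
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
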