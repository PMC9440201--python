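"""Alternating-access conformational metrics for two-domain transporters.

Implements the orientation collective variables α and β that quantify the
intracellular and extracellular openings of an MFS-fold transporter: each
domain (N and C) is split into intracellular and extracellular halves; α is
the angle at the center of mass of the extracellular half of the whole
protein between the centers of mass of the two intracellular half-domains,
and β is the mirror-image extracellular angle. Also provides salt-bridge
monitoring along multi-model trajectories (minimum side-chain N–O distance,
moving average, formed fraction) and the harmonic distance-restraint energy
used for DEER-guided refinement bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import StructureModel

__all__ = [
    "DomainSplit",
    "OrientationCV",
    "SaltBridgePair",
    "Restraint",
    "RestraintSet",
    "split_domains",
    "compute_alpha_beta",
    "salt_bridge_series",
    "restraint_energy",
]

_DONOR_ATOMS = {"ARG": ["NE", "NH1", "NH2"], "LYS": ["NZ"]}
_ACCEPTOR_ATOMS = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}
_VALID_DONOR = {"NE", "NH1", "NH2", "NZ"}
_VALID_ACCEPTOR = {"OD1", "OD2", "OE1", "OE2"}


@dataclass
class DomainSplit:
    """Residue ids of the intra/extracellular halves of the N and C domains."""

    n_intra: list[int]
    n_extra: list[int]
    c_intra: list[int]
    c_extra: list[int]
    chain: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_intra", "n_extra", "c_intra", "c_extra"):
            if not getattr(self, name):
                raise ValueError(f"half {name} is empty")
        if set(self.n_intra) & set(self.n_extra) or set(self.c_intra) & set(
            self.c_extra
        ):
            raise ValueError("halves within a domain must be disjoint")


@dataclass(frozen=True)
class OrientationCV:
    """Intracellular (alpha) and extracellular (beta) opening angles, deg."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for v in (self.alpha, self.beta):
            if not (0.0 < v <= 180.0):
                raise ValueError(f"angle {v} outside (0, 180] degrees")


@dataclass
class SaltBridgePair:
    """Arg/Lys donor vs Asp/Glu acceptor side-chain contact."""

    donor: tuple[str, int]  # (chain, resid)
    acceptor: tuple[str, int]
    donor_atoms: list[str] | None = None
    acceptor_atoms: list[str] | None = None
    formed_cutoff: float = 4.0  # Å, conventional salt-bridge criterion

    def __post_init__(self) -> None:
        if self.formed_cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.donor_atoms is not None and not set(self.donor_atoms) <= _VALID_DONOR:
            raise ValueError(f"donor atoms must be within {sorted(_VALID_DONOR)}")
        if (
            self.acceptor_atoms is not None
            and not set(self.acceptor_atoms) <= _VALID_ACCEPTOR
        ):
            raise ValueError(
                f"acceptor atoms must be within {sorted(_VALID_ACCEPTOR)}"
            )


@dataclass
class Restraint:
    site1: str
    site2: str
    target_nm: float
    k: float = 10.0  # kcal/mol/Å², the reMD refinement default

    def __post_init__(self) -> None:
        if self.target_nm <= 0:
            raise ValueError("target distance must be positive")
        if self.k < 0:
            raise ValueError("force constant must be nonnegative")


@dataclass
class RestraintSet:
    restraints: list[Restraint] = field(default_factory=list)

    def __iter__(self):
        return iter(self.restraints)

    def __len__(self):
        return len(self.restraints)


# ------------------------------------------------------------ domain splits


def split_domains(
    structure: StructureModel,
    n_range: tuple[int, int],
    c_range: tuple[int, int],
    mode: str = "by-sequence",
    chain: str | None = None,
    membrane_normal_up: bool = True,
) -> DomainSplit:
    """Split the N- and C-domain residue ranges into equal halves.

    by-sequence: ordered residues split at the midpoint; with an odd count
    the extra residue goes to the first (intracellular) half.
    by-z: split at the median CA z within the domain; the lower-z half is
    intracellular when `membrane_normal_up` (periplasm toward +z).
    """
    if (
        n_range[0] <= c_range[1]
        and c_range[0] <= n_range[1]
    ):
        raise ValueError("N- and C-domain ranges must not overlap")
    halves = {}
    for prefix, (lo, hi) in (("n", n_range), ("c", c_range)):
        sel = structure.atoms
        mask = (sel["resid"] >= lo) & (sel["resid"] <= hi)
        if chain is not None:
            mask &= sel["chain"] == chain
        resids = sorted(sel.loc[mask, "resid"].unique())
        if not resids:
            raise ValueError(f"domain range {lo}-{hi} not present in structure")
        if mode == "by-sequence":
            cut = (len(resids) + 1) // 2  # odd count: extra residue first half
            first, second = resids[:cut], resids[cut:]
        elif mode == "by-z":
            z = {}
            for rid in resids:
                row = sel.index[
                    mask.to_numpy()
                    & (sel["resid"] == rid).to_numpy()
                    & (sel["name"] == "CA").to_numpy()
                ]
                if len(row) == 0:
                    raise ValueError(f"residue {rid} lacks a CA atom")
                z[rid] = structure.coords[0, row[0], 2]
            median = float(np.median(list(z.values())))
            first = [rid for rid in resids if z[rid] < median]
            second = [rid for rid in resids if z[rid] >= median]
            if not membrane_normal_up:
                first, second = second, first
        else:
            raise ValueError(f"unknown split mode {mode!r}")
        if not first or not second:
            raise ValueError(f"empty half in domain {prefix} ({lo}-{hi})")
        halves[f"{prefix}_intra"] = first
        halves[f"{prefix}_extra"] = second
    return DomainSplit(chain=chain, **halves)


# -------------------------------------------------------------- orientation


def _center_of_mass(
    structure: StructureModel,
    resids,
    chain: str | None,
    model: int,
    mass_weighted: bool,
    ca_only: bool,
) -> np.ndarray:
    idx = structure.select(chain=chain, resids=resids)
    if ca_only:
        names = structure.atoms["name"].to_numpy()
        idx = idx[names[idx] == "CA"]
    if idx.size == 0:
        raise ValueError("no atoms selected for center of mass")
    xyz = structure.coords[model, idx]
    if mass_weighted:
        m = structure.masses[idx]
        return (m[:, None] * xyz).sum(axis=0) / m.sum()
    return xyz.mean(axis=0)


def _angle_deg(p1: np.ndarray, vertex: np.ndarray, p3: np.ndarray) -> float:
    v1 = p1 - vertex
    v2 = p3 - vertex
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValueError("degenerate (zero-length) vector in angle computation")
    c = np.clip((v1 @ v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def compute_alpha_beta(
    structure: StructureModel,
    split: DomainSplit,
    mass_weighted: bool = True,
    ca_only: bool = False,
    model: int = 0,
) -> OrientationCV:
    """α: angle at COM(extracellular protein half) between COM(N intra half)
    and COM(C intra half); β: the extracellular mirror image."""
    com = lambda resids: _center_of_mass(  # noqa: E731
        structure, resids, split.chain, model, mass_weighted, ca_only
    )
    alpha = _angle_deg(
        com(split.n_intra), com(split.n_extra + split.c_extra), com(split.c_intra)
    )
    beta = _angle_deg(
        com(split.n_extra), com(split.n_intra + split.c_intra), com(split.c_extra)
    )
    return OrientationCV(alpha=alpha, beta=beta)


# -------------------------------------------------------------- salt bridge


def salt_bridge_series(
    trajectory: StructureModel,
    pair: SaltBridgePair,
    window: int = 1,
) -> pd.DataFrame:
    """Per-frame minimum donor-N to acceptor-O distance with moving average.

    Returns a DataFrame with columns frame, distance (Å), moving_avg,
    formed; frames with missing side-chain atoms get NaN and are excluded
    from the moving average and the formed fraction (reported in
    `df.attrs`), alongside `df.attrs["formed_fraction"]`.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    don_chain, don_resid = pair.donor
    acc_chain, acc_resid = pair.acceptor
    atoms = trajectory.atoms
    don_res = atoms.loc[trajectory.residue_mask(don_chain, don_resid)]
    acc_res = atoms.loc[trajectory.residue_mask(acc_chain, acc_resid)]
    if don_res.empty or acc_res.empty:
        raise ValueError("donor or acceptor residue not found in trajectory")
    don_names = pair.donor_atoms or _DONOR_ATOMS.get(
        don_res["resname"].iloc[0], sorted(_VALID_DONOR)
    )
    acc_names = pair.acceptor_atoms or _ACCEPTOR_ATOMS.get(
        acc_res["resname"].iloc[0], sorted(_VALID_ACCEPTOR)
    )
    don_idx = don_res.index[don_res["name"].isin(don_names)].to_numpy()
    acc_idx = acc_res.index[acc_res["name"].isin(acc_names)].to_numpy()
    n_frames = trajectory.n_models
    dist = np.full(n_frames, np.nan)
    errors = []
    for f in range(n_frames):
        if don_idx.size == 0 or acc_idx.size == 0:
            errors.append((f, "missing side-chain atoms"))
            continue
        d = np.linalg.norm(
            trajectory.coords[f, don_idx][:, None, :]
            - trajectory.coords[f, acc_idx][None, :, :],
            axis=-1,
        )
        dist[f] = d.min()
    s = pd.Series(dist)
    moving = s.rolling(window, center=True, min_periods=1).mean()
    valid = ~np.isnan(dist)
    formed = np.where(valid, dist < pair.formed_cutoff, False)
    df = pd.DataFrame(
        {
            "frame": np.arange(n_frames),
            "distance": dist,
            "moving_avg": moving.to_numpy(),
            "formed": formed,
        }
    )
    df.attrs["formed_fraction"] = (
        float(formed[valid].mean()) if valid.any() else float("nan")
    )
    df.attrs["errors"] = errors
    return df


# ---------------------------------------------------------- restraint energy


def restraint_energy(
    distances_nm,
    restraints: RestraintSet,
    half_factor: bool = True,
) -> tuple[float, np.ndarray]:
    """Harmonic DEER-restraint energy E = Σ ½ k (d - d_target)², kcal/mol.

    `distances_nm` is a sequence aligned with `restraints` (nm); force
    constants are kcal/mol/Å² so displacements are converted to Å. Set
    `half_factor=False` for the k(Δd)² convention.
    """
    d = np.asarray(distances_nm, dtype=float)
    if d.shape != (len(restraints),):
        raise ValueError(
            f"{d.size} distances vs {len(restraints)} restraints: misaligned"
        )
    factor = 0.5 if half_factor else 1.0
    terms = np.array(
        [
            factor * res.k * ((di - res.target_nm) * 10.0) ** 2
            for di, res in zip(d, restraints)
        ]
    )
    return float(terms.sum()), terms
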