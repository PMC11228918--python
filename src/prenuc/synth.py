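"""Synthetic inputs with known ground truth for every pipeline stage.

Three families of generators:

* growth series — integrate the two candidate growth laws
  (dN/dt = a·r for diffusion-limited, dN/dt = b·r² for
  interface-transfer-limited attachment) exactly and sample noisy
  solvodynamic diameters, so the regime diagnostic can be scored
  against a known mechanism;
* DLS correlograms — second-cumulant decays with additive noise, so the
  sizing chain can be scored against a known diameter;
* planted molecular configurations — periodic boxes in which the
  single-linkage partition at the stated cutoff is the planted cluster
  plan by construction, with optional scripted cluster coalescence,
  plus telegraph-process H-bond event matrices with a known breaking
  rate.

Every generator is deterministic under its seed and embeds its ground
truth in the returned object; recovery tests read the truth from there
and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .dls import Correlogram, InstrumentSpec, gamma_from_diameter
from .growth import SALICYLAMIDE, MolecularConstants, SizeSeries, SolutionSpec
from .md.geometry import min_image_distance, wrap_coords
from .md.hbond import HBondEvents
from .md.trajectory import Frame, Topology

__all__ = [
    "GrowthSimSpec",
    "SyntheticSizeSeries",
    "gen_growth_series",
    "growth_closed_form_radius",
    "SyntheticCorrelogram",
    "gen_correlogram",
    "solute_template",
    "PlantedConfigSpec",
    "PlantedSystem",
    "gen_planted_config",
    "TelegraphSpec",
    "gen_bond_telegraph",
]

# ---------------------------------------------------------------------------
# growth series
# ---------------------------------------------------------------------------

#: Default sampling schedule (h): one sizing measurement every 3 h over
#: 72 h, the cadence of the emulated light-scattering time series.
DEFAULT_TIMES_H = tuple(float(t) for t in range(3, 73, 3))


@dataclass(frozen=True)
class GrowthSimSpec:
    """Ground-truth description of one synthetic growth experiment.

    regime : ``diffusion`` (dN/dt = a·r) or ``interface_transfer``
        (dN/dt = b·r²).
    rate : a in molecules/(h·nm) or b in molecules/(h·nm²).  Defaults
        reproduce growth from D = 400 nm to ~2800 nm over 72 h, the
        range spanned by measured cluster sizes.
    initial_diameter_nm : starting solvodynamic diameter.
    noise_sigma : multiplicative Gaussian noise on sampled diameters,
        as a fraction of D (0.02 emulates instrument repeatability).
    """

    regime: str
    rate: float | None = None
    initial_diameter_nm: float = 400.0
    times_h: tuple = DEFAULT_TIMES_H
    noise_sigma: float = 0.02
    seed: int = 0
    constants: MolecularConstants = SALICYLAMIDE

    def __post_init__(self) -> None:
        if self.regime not in ("diffusion", "interface_transfer"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.rate is not None and self.rate <= 0:
            raise ValueError("rate constant must be positive")
        if self.initial_diameter_nm <= 0:
            raise ValueError("initial diameter must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")

    @property
    def rate_value(self) -> float:
        if self.rate is not None:
            return self.rate
        return 1.0e6 if self.regime == "diffusion" else 1.2e3


@dataclass
class SyntheticSizeSeries:
    """A noisy size series plus the exact trajectory that generated it."""

    series: SizeSeries
    truth: dict


def growth_closed_form_radius(spec: GrowthSimSpec, t_h) -> np.ndarray:
    """Analytic r(t) for the two growth laws (noise-free).

    With N = (4π/3)·r³/ϑ:
      diffusion (dN/dt = a·r):      r² = r₀² + a·ϑ·t/(2π)
      interface (dN/dt = b·r²):     r  = r₀ + b·ϑ·t/(4π)
    """
    t = np.asarray(t_h, dtype=float)
    r0 = spec.initial_diameter_nm / 2.0
    v = spec.constants.molecular_volume_nm3
    k = spec.rate_value
    if spec.regime == "diffusion":
        return np.sqrt(r0**2 + k * v * t / (2.0 * np.pi))
    return r0 + k * v * t / (4.0 * np.pi)


def gen_growth_series(
    spec: GrowthSimSpec, solution: SolutionSpec | None = None
) -> SyntheticSizeSeries:
    """Integrate the growth law and sample a noisy diameter series.

    The ODE in cluster occupancy N is integrated adaptively (relative
    tolerance 1e-8); both laws also admit closed forms, which the test
    suite uses as an independent oracle on the integrator.
    """
    v = spec.constants.molecular_volume_nm3
    k = spec.rate_value
    n0 = (np.pi / 6.0) * spec.initial_diameter_nm**3 / v

    def radius_of(n: float) -> float:
        return 0.5 * (6.0 * v * n / np.pi) ** (1.0 / 3.0)

    def rhs(_t, y):
        r = radius_of(y[0])
        return [k * r if spec.regime == "diffusion" else k * r * r]

    times = np.asarray(spec.times_h, dtype=float)
    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1])),
        [n0],
        t_eval=times,
        rtol=1e-8,
        atol=max(1e-6 * n0, 1.0),
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"growth ODE integration failed: {sol.message}")
    n_clean = sol.y[0]
    d_clean = (6.0 * v * n_clean / np.pi) ** (1.0 / 3.0)

    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sigma, size=d_clean.shape) if spec.noise_sigma else 0.0
    d_noisy = np.maximum(d_clean * (1.0 + noise), 1e-6)

    if solution is None:
        solution = SolutionSpec(solvent="synthetic", x_mol_l=1.0, x_star_mol_l=1.0)
    series = SizeSeries(solution=solution, times_h=times, diameters_nm=d_noisy)
    truth = {
        "regime": spec.regime,
        "rate": k,
        "initial_diameter_nm": spec.initial_diameter_nm,
        "clean_diameters_nm": d_clean,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }
    return SyntheticSizeSeries(series=series, truth=truth)


# ---------------------------------------------------------------------------
# DLS correlograms
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCorrelogram:
    correlogram: Correlogram
    truth: dict


def gen_correlogram(
    true_diameter_nm: float,
    instrument: InstrumentSpec = InstrumentSpec(),
    pdi: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    beta: float = 0.8,
    n_lags: int = 120,
) -> SyntheticCorrelogram:
    """Truncated second-cumulant correlogram for a known diameter.

    g2−1 = β·exp(−2Γτ + µ₂τ²) with Γ the Stokes–Einstein decay rate of
    the given diameter under the instrument and µ₂ = PDI·Γ²; additive
    Gaussian noise of standard deviation ``noise_sigma``.  Lags span
    roughly 2.5 decay times, log-spaced, keeping the quadratic term in
    its valid (decaying) range.
    """
    if true_diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    if not 0 <= pdi < 0.4:
        raise ValueError("pdi must be in [0, 0.4) for a truncated cumulant form")
    gamma = gamma_from_diameter(true_diameter_nm, instrument)
    mu2 = pdi * gamma**2
    tau = np.geomspace(0.005 / gamma, 2.5 / gamma, n_lags)
    g = beta * np.exp(-2.0 * gamma * tau + mu2 * tau**2)
    if noise_sigma:
        rng = np.random.default_rng(seed)
        g = g + rng.normal(0.0, noise_sigma, size=g.shape)
    corr = Correlogram(lags_us=tau, g2_minus_1=g, instrument=instrument)
    truth = {
        "diameter_nm": true_diameter_nm,
        "gamma_per_us": gamma,
        "pdi": pdi,
        "beta": beta,
        "noise_sigma": noise_sigma,
        "seed": seed,
    }
    return SyntheticCorrelogram(correlogram=corr, truth=truth)


# ---------------------------------------------------------------------------
# planted molecular configurations
# ---------------------------------------------------------------------------


def solute_template() -> dict:
    """Rigid 12-atom planar solute template (nm).

    A benzene ring (atoms 0–5), an amide carbon (6) bearing a carbonyl
    oxygen acceptor (7) and an N–H donor pair (8, 9), and a hydroxyl
    O–H donor/acceptor pair (10, 11).  Exercises ring-plane fitting and
    donor/acceptor bookkeeping; makes no force-field fidelity claim.
    """
    ring_r = 0.139
    coords = np.array(
        [
            [ring_r * math.cos(math.radians(60 * k)), ring_r * math.sin(math.radians(60 * k)), 0.0]
            for k in range(6)
        ]
        + [
            [0.289, 0.000, 0.0],   # amide C
            [0.350, 0.105, 0.0],   # carbonyl O (acceptor)
            [0.350, -0.105, 0.0],  # amide N (donor)
            [0.448, -0.125, 0.0],  # amide H
            [0.105, 0.245, 0.0],   # hydroxyl O (donor + acceptor)
            [0.125, 0.342, 0.0],   # hydroxyl H
        ]
    )
    elements = np.array(
        ["C", "C", "C", "C", "C", "C", "C", "O", "N", "H", "O", "H"], dtype=object
    )
    masses = np.array(
        [12.011] * 7 + [15.999, 14.007, 1.008, 15.999, 1.008]
    )
    charges = np.array(
        [0.15, 0.20, 0.0, 0.0, 0.0, 0.0, 0.55, -0.55, -0.60, 0.40, -0.60, 0.45]
    )
    eps = np.array([0.40] * 7 + [0.65, 0.70, 0.06, 0.65, 0.06])
    sigma = np.array([0.33] * 7 + [0.30, 0.32, 0.10, 0.30, 0.10])
    ring_pos = np.array([0, 1, 2, 3, 4, 5, -1, -1, -1, -1, -1, -1])
    is_donor = np.zeros(12, dtype=bool)
    is_donor[[8, 10]] = True
    is_acceptor = np.zeros(12, dtype=bool)
    is_acceptor[[7, 10]] = True
    donor_of_h = {9: 8, 11: 10}
    return {
        "coords": coords,
        "elements": elements,
        "masses": masses,
        "charges": charges,
        "eps": eps,
        "sigma": sigma,
        "ring_pos": ring_pos,
        "is_donor": is_donor,
        "is_acceptor": is_acceptor,
        "donor_of_h": donor_of_h,
    }


@dataclass(frozen=True)
class PlantedConfigSpec:
    """Plan for a planted-cluster periodic configuration.

    cluster_sizes : solute molecules per cluster; molecules within a
        cluster are chained so consecutive heavy-atom nearest distances
        equal ``nearest_gap_nm`` (below the cutoff), and clusters are
        kept farther than ``cutoff_nm + inter_margin_nm`` apart, so the
        single-linkage partition at the cutoff is the plan itself.
    n_solvent : single-site solvent dummies placed uniformly without
        overlap (chemistry-free; H-bond studies use solute topologies).
    first_cluster_center_nm : optional anchor for cluster 0; placing it
        near a box face exercises periodic wrapping.
    merge_schedule : optional list of (frame, target, mover) cluster
        indices; from that frame on, the mover's molecules are fused
        onto the target's chain, dropping the cluster count by one.
    """

    box_nm: tuple = (12.0, 12.0, 12.0)
    cluster_sizes: tuple = (5, 3, 1)
    n_solvent: int = 0
    cutoff_nm: float = 0.35
    nearest_gap_nm: float = 0.30
    inter_margin_nm: float = 0.30
    seed: int = 0
    n_frames: int = 1
    frame_interval_ps: float = 20.0
    first_cluster_center_nm: tuple | None = None
    merge_schedule: tuple = ()

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be >= 1")
        if self.nearest_gap_nm >= self.cutoff_nm:
            raise ValueError("nearest_gap must be below the cutoff for chaining to link")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


@dataclass
class PlantedSystem:
    topology: Topology
    frames: list
    truth: dict


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _chain_coords(template: dict, size: int, gap: float) -> np.ndarray:
    """Coordinates of a ``size``-molecule chain along x, one template per link."""
    heavy = template["elements"] != "H"
    xs = template["coords"][heavy][:, 0]
    step = (xs.max() - xs.min()) + gap
    blocks = [template["coords"] + np.array([j * step, 0.0, 0.0]) for j in range(size)]
    return np.vstack(blocks)


def _cluster_atom_coords(template, size, gap, rotation, center):
    chain = _chain_coords(template, size, gap)
    centroid = chain.mean(axis=0)
    return (chain - centroid) @ rotation.T + center


def gen_planted_config(spec: PlantedConfigSpec) -> PlantedSystem:
    """Build a configuration whose cluster partition is known exactly.

    Raises on infeasible packing (box too small for the requested plan
    and margins) rather than silently overlapping clusters.
    """
    rng = np.random.default_rng(spec.seed)
    template = solute_template()
    box = np.asarray(spec.box_nm, dtype=float)
    sizes = list(spec.cluster_sizes)
    n_clusters = len(sizes)

    rotations = [_rotation_matrix(rng) for _ in sizes]
    radii = []
    for s, rot in zip(sizes, rotations):
        chain = _chain_coords(template, s, spec.nearest_gap_nm)
        centroid = chain.mean(axis=0)
        radii.append(float(np.linalg.norm(chain - centroid, axis=1).max()))

    # worst-case radius if every scheduled merge lands on this cluster
    total_chain = _chain_coords(template, sum(sizes), spec.nearest_gap_nm)
    worst_radius = float(
        np.linalg.norm(total_chain - total_chain.mean(axis=0), axis=1).max()
    )
    sep_pad = spec.cutoff_nm + spec.inter_margin_nm

    centers: list[np.ndarray] = []
    for c in range(n_clusters):
        if c == 0 and spec.first_cluster_center_nm is not None:
            centers.append(np.asarray(spec.first_cluster_center_nm, dtype=float))
            continue
        placed = False
        need_r = worst_radius if spec.merge_schedule else radii[c]
        for _ in range(2000):
            cand = rng.uniform(0.0, box)
            ok = all(
                min_image_distance(cand, centers[k], box)
                > need_r + (worst_radius if spec.merge_schedule else radii[k]) + sep_pad
                for k in range(len(centers))
            )
            if ok:
                centers.append(cand)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"infeasible packing: cannot place cluster {c} "
                f"(box {box.tolist()}, plan {sizes})"
            )

    # --- topology -----------------------------------------------------
    n_solute = sum(sizes)
    tpl_n = len(template["elements"])
    elements, masses, charges, eps, sig = [], [], [], [], []
    mol_id, mol_type, ring_pos = [], [], []
    is_donor, is_acceptor, donor_id = [], [], []
    for m in range(n_solute):
        base = m * tpl_n
        elements.extend(template["elements"])
        masses.extend(template["masses"])
        charges.extend(template["charges"])
        eps.extend(template["eps"])
        sig.extend(template["sigma"])
        mol_id.extend([m] * tpl_n)
        mol_type.extend(["solute"] * tpl_n)
        ring_pos.extend(template["ring_pos"])
        is_donor.extend(template["is_donor"])
        is_acceptor.extend(template["is_acceptor"])
        donor_id.extend(
            [template["donor_of_h"].get(k, -1) + base if k in template["donor_of_h"] else -1
             for k in range(tpl_n)]
        )
    for s_idx in range(spec.n_solvent):
        m = n_solute + s_idx
        elements.append("X")
        masses.append(32.0)
        charges.append(0.0)
        eps.append(0.50)
        sig.append(0.31)
        mol_id.append(m)
        mol_type.append("solvent")
        ring_pos.append(-1)
        is_donor.append(False)
        is_acceptor.append(False)
        donor_id.append(-1)

    topology = Topology(
        element=np.array(elements, dtype=object),
        mass_amu=np.array(masses),
        charge_e=np.array(charges),
        lj_epsilon_kj_mol=np.array(eps),
        lj_sigma_nm=np.array(sig),
        molecule_id=np.array(mol_id),
        molecule_type=np.array(mol_type, dtype=object),
        is_donor=np.array(is_donor, dtype=bool),
        is_acceptor=np.array(is_acceptor, dtype=bool),
        donor_id=np.array(donor_id),
        ring_pos=np.array(ring_pos),
    )

    # cluster membership in molecule ids (plan order)
    memberships: list[list[int]] = []
    m0 = 0
    for s in sizes:
        memberships.append(list(range(m0, m0 + s)))
        m0 += s

    def build_solute_coords(groups: list[dict]) -> np.ndarray:
        coords = np.empty((n_solute * tpl_n, 3))
        for g in groups:
            atoms = _cluster_atom_coords(
                template, len(g["mols"]), spec.nearest_gap_nm, g["rotation"], g["center"]
            )
            for j, mol in enumerate(g["mols"]):
                coords[mol * tpl_n : (mol + 1) * tpl_n] = atoms[j * tpl_n : (j + 1) * tpl_n]
        return wrap_coords(coords, box)

    groups = [
        {"mols": list(mem), "rotation": rot, "center": ctr}
        for mem, rot, ctr in zip(memberships, rotations, centers)
    ]

    # solvent positions (static across frames)
    solute_coords0 = build_solute_coords(groups)
    solvent_coords = np.empty((spec.n_solvent, 3))
    occupied = solute_coords0
    for s_idx in range(spec.n_solvent):
        for _ in range(5000):
            cand = rng.uniform(0.0, box)
            d = min_image_distance(cand, occupied, box)
            if np.min(d) > 0.20:
                solvent_coords[s_idx] = cand
                occupied = np.vstack([occupied, cand])
                break
        else:
            raise ValueError("infeasible packing: cannot place solvent without overlap")

    schedule = {int(f): (int(a), int(b)) for f, a, b in spec.merge_schedule}
    frames: list[Frame] = []
    counts_per_frame: list[int] = []
    live = {i: g for i, g in enumerate(groups)}
    for fidx in range(spec.n_frames):
        if fidx in schedule:
            tgt, mov = schedule[fidx]
            if tgt not in live or mov not in live:
                raise ValueError(f"merge schedule references a merged-away cluster at frame {fidx}")
            live[tgt]["mols"] = live[tgt]["mols"] + live[mov]["mols"]
            del live[mov]
        solute_coords = build_solute_coords(list(live.values()))
        coords = (
            np.vstack([solute_coords, solvent_coords])
            if spec.n_solvent
            else solute_coords
        )
        frames.append(
            Frame(time_ps=fidx * spec.frame_interval_ps, box_nm=box.copy(), coords_nm=coords)
        )
        counts_per_frame.append(len(live))

    truth = {
        "cluster_sizes": tuple(sizes),
        "memberships": memberships,
        "cutoff_nm": spec.cutoff_nm,
        "counts_per_frame": counts_per_frame,
        "seed": spec.seed,
    }
    return PlantedSystem(topology=topology, frames=frames, truth=truth)


# ---------------------------------------------------------------------------
# telegraph-process H-bond events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TelegraphSpec:
    """Two-state Markov bond dynamics sampled on a uniform frame grid.

    Each of ``n_bonds`` independent bonds starts present; per frame
    interval it breaks with probability 1−exp(−k·Δt) and (if broken)
    reforms with probability 1−exp(−k_reform·Δt).  With k_reform = 0
    the continuous survival is exactly exp(−k·t) at the sampled times.
    """

    n_bonds: int = 500
    n_frames: int = 100
    frame_interval_ps: float = 20.0
    breaking_rate_per_ps: float = 0.01
    reforming_rate_per_ps: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bonds < 1 or self.n_frames < 2:
            raise ValueError("need at least 1 bond and 2 frames")
        if self.breaking_rate_per_ps < 0 or self.reforming_rate_per_ps < 0:
            raise ValueError("rates must be non-negative")


def gen_bond_telegraph(spec: TelegraphSpec) -> HBondEvents:
    rng = np.random.default_rng(spec.seed)
    dt = spec.frame_interval_ps
    p_break = 1.0 - math.exp(-spec.breaking_rate_per_ps * dt)
    p_reform = 1.0 - math.exp(-spec.reforming_rate_per_ps * dt)
    present = np.empty((spec.n_bonds, spec.n_frames), dtype=bool)
    present[:, 0] = True
    for j in range(1, spec.n_frames):
        u = rng.random(spec.n_bonds)
        stay = present[:, j - 1] & (u >= p_break)
        reform = ~present[:, j - 1] & (u < p_reform)
        present[:, j] = stay | reform
    times = np.arange(spec.n_frames) * dt
    pairs = [(b, -1, -1) for b in range(spec.n_bonds)]
    return HBondEvents(pairs=pairs, present=present, times_ps=times)
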