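"""Geometric hydrogen-bond detection and lifetime curves.

A hydrogen bond exists in a frame when the donor–acceptor minimum-image
distance is within the cutoff (3.5 Å default) and the angle at the
donor between the donor→hydrogen and donor→acceptor vectors is within
the angular cutoff (30° default).  Both cutoffs are inclusive, which
makes the criteria reproducible bit-for-bit.

Lifetimes come in two standard flavors, both provided because neither
is canonically "the" H-bond lifetime:

* continuous survival — probability that a bond present at t₀ stays
  present in every sampled frame through t₀+t;
* intermittent autocorrelation — ⟨h(t₀)h(t₀+t)⟩/⟨h⟩, which forgives
  transient breaks.

Both start at 1 and the continuous curve can never exceed the
intermittent one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import min_image_displacement
from .trajectory import Topology

__all__ = ["HBondCriteria", "HBondEvents", "hbond_events", "hbond_lifetime"]


@dataclass(frozen=True)
class HBondCriteria:
    da_cutoff_nm: float = 0.35
    hda_angle_max_deg: float = 30.0
    mode: str = "continuous"

    def __post_init__(self) -> None:
        if self.da_cutoff_nm <= 0:
            raise ValueError("donor-acceptor cutoff must be positive")
        if not 0.0 < self.hda_angle_max_deg <= 90.0:
            raise ValueError("H-donor-acceptor angle cutoff must be in (0, 90] degrees")
        if self.mode not in ("continuous", "intermittent"):
            raise ValueError(f"unknown lifetime mode {self.mode!r}")


@dataclass
class HBondEvents:
    """Presence matrix of candidate donor→acceptor bonds over frames.

    ``pairs`` lists (donor atom, hydrogen atom, acceptor atom) triples;
    ``present`` is boolean with shape (n_pairs, n_frames);
    ``times_ps`` the frame times.
    """

    pairs: list[tuple[int, int, int]]
    present: np.ndarray
    times_ps: np.ndarray


def hbond_events(
    frames,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
    intermolecular_only: bool = True,
) -> HBondEvents:
    """Evaluate the geometric criteria for every donor/acceptor pair and frame."""
    donors = topology.donor_pairs()
    acceptors = topology.acceptor_atoms()
    if not donors or acceptors.size == 0:
        raise ValueError("topology must flag at least one donor hydrogen and one acceptor")

    triples = []
    for d, h in donors:
        for a in acceptors:
            if a == d or a == h:
                continue
            if intermolecular_only and topology.molecule_id[a] == topology.molecule_id[d]:
                continue
            triples.append((d, h, int(a)))
    if not triples:
        raise ValueError("no candidate donor-acceptor pairs (all intramolecular?)")

    d_idx = np.array([t[0] for t in triples])
    h_idx = np.array([t[1] for t in triples])
    a_idx = np.array([t[2] for t in triples])
    cos_max = np.cos(np.radians(criteria.hda_angle_max_deg))

    present = np.zeros((len(triples), len(frames)), dtype=bool)
    times = np.empty(len(frames))
    for j, f in enumerate(frames):
        times[j] = f.time_ps
        xyz = f.coords_nm
        v_da = min_image_displacement(xyz[d_idx], xyz[a_idx], f.box_nm)
        v_dh = min_image_displacement(xyz[d_idx], xyz[h_idx], f.box_nm)
        r_da = np.linalg.norm(v_da, axis=1)
        with np.errstate(invalid="ignore"):
            cos_theta = np.einsum("ij,ij->i", v_da, v_dh) / (
                r_da * np.linalg.norm(v_dh, axis=1)
            )
        present[:, j] = (r_da <= criteria.da_cutoff_nm) & (cos_theta >= cos_max)
    return HBondEvents(pairs=triples, present=present, times_ps=times)


def hbond_lifetime(events: HBondEvents, mode: str = "continuous"):
    """Lifetime curve P(t) from a presence matrix.

    Continuous mode: survival probability that a bond present at an
    origin frame remains present at every frame up to lag t, averaged
    over all bonds and origins.  Intermittent mode: presence
    autocorrelation ⟨h(0)h(t)⟩/⟨h⟩.  Returned on the lag grid of mean
    inter-frame spacings (non-uniform spacing enters via the actual
    frame times).

    Returns ``(lag_times_ps, p)``; flags an empty result (all-zero
    presence) by returning ``p`` of NaNs.
    """
    if mode not in ("continuous", "intermittent"):
        raise ValueError(f"unknown lifetime mode {mode!r}")
    h = events.present
    n_pairs, n_frames = h.shape
    if n_frames < 2:
        raise ValueError("need at least 2 frames for a lifetime curve")
    lags = np.arange(n_frames)
    # lag k reported at the mean time separation over valid origins
    t = events.times_ps
    lag_times = np.array([np.mean(t[k:] - t[: n_frames - k]) for k in lags])

    if not h.any():
        return lag_times, np.full(n_frames, np.nan)

    p = np.empty(n_frames)
    if mode == "intermittent":
        for k in lags:
            num = np.sum(h[:, : n_frames - k] & h[:, k:])
            den = np.sum(h[:, : n_frames - k])
            p[k] = num / den if den else np.nan
    else:
        # surv[:, j] holds "present at every frame j..j+k"; it shrinks
        # by one column per lag increment
        surv = h.copy()
        for k in lags:
            width = n_frames - k
            den = int(h[:, :width].sum())
            num = int(surv.sum())
            p[k] = num / den if den else np.nan
            if width > 1:
                surv = surv[:, : width - 1] & h[:, k + 1 :]
    return lag_times, p
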