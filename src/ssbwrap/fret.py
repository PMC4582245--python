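"""FRET observables and reptation-diffusion estimation.

An acceptor at the 5' ss-dsDNA junction and a donor on the protein report
the SSB position on the ssDNA through the Forster relation; for poly(dT)
one Forster radius of ~6 nm corresponds to ~18 nt.  The lifetime of the
high-FRET (junction-proximal) state approximates the first-passage time
for the protein to diffuse one Forster radius away from the junction,
giving the 1D estimator ``D = L^2 / (2 tau)``.

Combining the wrapping state (35 vs 56 nt) with the FRET level (high vs
low) yields four joint states i-iv used to discriminate sliding
(reptation) from rolling diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: joint state -> (wrapped nt, high FRET?)
JOINT_STATES = {
    "i": (35, False),
    "ii": (35, True),
    "iii": (56, True),
    "iv": (56, False),
}

#: FRET level threshold separating the reported E ~ 0.5 and E ~ 0 levels.
FRET_LEVEL_THRESHOLD = 0.25


@dataclass(frozen=True)
class FretModel:
    """Forster relation on the ssDNA lattice (separations in nt)."""

    forster_radius_nt: float = 18.0
    forster_radius_nm: float = 6.0

    def efficiency(self, separation):
        """``E = 1 / (1 + (r/R0)^6)``; 0.5 at one Forster radius."""
        r = np.asarray(separation, dtype=float)
        if np.any(r < 0):
            raise ValueError("separation must be non-negative")
        out = 1.0 / (1.0 + (r / self.forster_radius_nt) ** 6)
        return out.item() if np.ndim(separation) == 0 else out


def fret_efficiency(separation, model: FretModel | None = None):
    """FRET efficiency at a donor-acceptor separation (nt)."""
    return (model or FretModel()).efficiency(separation)


def efficiency_from_counts(donor, acceptor, background: float = 0.0):
    """Per-bin proximity ratio ``E = A / (A + D)`` after background subtraction."""
    d = np.maximum(np.asarray(donor, dtype=float) - background, 0.0)
    a = np.maximum(np.asarray(acceptor, dtype=float) - background, 0.0)
    total = d + a
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(total > 0, a / np.maximum(total, 1e-300), np.nan)
    return e


def junction_departure_dwells(times, separation_nt, r0_nt: float = 18.0) -> np.ndarray:
    """High-FRET lifetimes: junction contact until departure by one R0.

    A dwell starts when the separation reaches 0 (protein at the
    junction) and ends when it first reaches ``r0_nt``; this is the
    first-passage time the 1D estimator assumes.  A final censored dwell
    is discarded.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(separation_nt, dtype=float)
    dwells = []
    start = None
    for ti, si in zip(t, s):
        if start is None:
            if si <= 0:
                start = ti
        elif si >= r0_nt:
            dwells.append(ti - start)
            start = None
    return np.asarray(dwells)


def estimate_diffusion(high_fret_lifetimes, length_scale_nt: float = 18.0,
                       n_boot: int = 1000, seed: int = 0) -> dict:
    """1D diffusion constant from mean high-FRET lifetime.

    ``D = L^2 / (2 <tau>)`` (mean-first-passage convention over one
    Forster radius ``L``), with a bootstrap percentile confidence
    interval.  Requires at least 3 lifetimes.
    """
    tau = np.asarray(high_fret_lifetimes, dtype=float)
    if len(tau) == 0:
        raise ValueError("empty lifetime list")
    if len(tau) < 3:
        raise ValueError("need at least 3 lifetimes for a diffusion estimate")
    d_hat = length_scale_nt**2 / (2.0 * tau.mean())
    rng = np.random.default_rng(seed)
    boots = length_scale_nt**2 / (
        2.0 * rng.choice(tau, size=(n_boot, len(tau))).mean(axis=1))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"D_nt2_per_s": float(d_hat), "ci95": (float(lo), float(hi)),
            "n_dwells": len(tau), "mean_lifetime_s": float(tau.mean())}


def classify_joint_transitions(joint_sequence) -> dict:
    """Count sliding, rolling and mode-change events in a joint-state path.

    * sliding: FRET level flips at fixed wrapping state (i<->ii, iii<->iv);
    * mode change: wrapping state flips (ii<->iii, i<->iv, and the
      correlated i<->iii / ii<->iv cases);
    * rolling: the signature triples i->iii->ii or ii->iii->i (wrap one
      ssDNA end, release the other).

    Counts are determined by the (wrap, FRET) semantics of the labels, not
    the labels themselves.
    """
    seq = list(joint_sequence)
    for s in seq:
        if s not in JOINT_STATES:
            raise ValueError(f"unknown joint state {s!r}")
    sliding = rolling = mode_change = 0
    for a, b in zip(seq[:-1], seq[1:]):
        if a == b:
            continue
        wrap_a, fret_a = JOINT_STATES[a]
        wrap_b, fret_b = JOINT_STATES[b]
        if wrap_a != wrap_b:
            mode_change += 1
        elif fret_a != fret_b:
            sliding += 1
    for a, b, c in zip(seq[:-2], seq[1:-1], seq[2:]):
        if (a, b, c) in (("i", "iii", "ii"), ("ii", "iii", "i")):
            rolling += 1
    return {"sliding_count": sliding, "rolling_count": rolling,
            "mode_change_count": mode_change}
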