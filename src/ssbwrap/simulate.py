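"""Synthetic-data generation for every stage of the wrapping pipeline.

The instrument traces behind this analysis are not redistributable, so
the generators here emulate their statistical structure: piecewise-
constant extension traces from nearest-neighbour hopping among the five
wrapping states with force-dependent Bell-Evans rates (exact Gillespie
sampling), Gaussian measurement noise at the native 66 kHz acquisition
rate, quasi-static force ramps at ~65 nm/s with 0.3 pN/nm traps,
donor/acceptor photon counts from 1D reptation diffusion, and stepwise
RecA displacement staircases.  Every simulator returns its ground truth
alongside the observable trace; seeded runs are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ssbwrap.fret import FretModel
from ssbwrap.geometry import StructureModel
from ssbwrap.landscape import EnergyLandscape, transition_rate
from ssbwrap.polymer import (
    CalibrationWarning,
    PolymerParams,
    TetherComposition,
    dsdna_extension_per_bp,
)
from ssbwrap.reca import five_state_expected_dx
from ssbwrap.traces import Trace


@dataclass
class SimulationConfig:
    """Instrument and model parameters for a synthetic run.

    ``seed`` is mandatory: every stochastic generator draws from
    ``numpy.random.default_rng(seed)`` and nothing else.
    """

    seed: int
    landscape: EnergyLandscape = field(default_factory=EnergyLandscape.reference)
    protocol: str = "constant"  # "constant" | "ramp"
    force: float = 5.0  # pN (constant-force protocol)
    ramp_speed_nm_s: float = 65.0
    trap_stiffness_pn_nm: float = 0.3  # per trap; two traps act in series
    f_start: float = 0.25  # pN
    f_max: float = 25.0  # pN
    noise_sd_nm: float = 25.0  # at the native rate (~1 nm at 10 Hz)
    native_rate_hz: float = 66000.0
    duration_s: float = 60.0
    initial_state: int | None = None  # default: unbound (0) at constant force
    comp: TetherComposition = field(default_factory=TetherComposition)
    # FRET / reptation
    diffusion_nt2_s: float = 27.0
    lattice_nt: int = 35  # unwrapped nucleotides available for reptation
    reptation_start_nt: int = 0  # initial separation from the junction
    fret: FretModel = field(default_factory=FretModel)
    photon_rate_hz: float = 300.0
    fret_bin_hz: float = 10.0
    # RecA displacement rates (1/s); the underlying kinetics are not
    # modelled mechanistically, only configurable per-step rates
    reca_rates: dict = field(default_factory=lambda: {
        "i_ii": 0.5, "ii_i": 0.5, "nucleation": 0.1, "iii_iv": 0.25, "iv_v": 0.3})

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for every stochastic run")
        if any(v < 0 for v in self.reca_rates.values()):
            raise ValueError("rates must be non-negative")


def _rate_matrix_at_force(landscape: EnergyLandscape, force: float) -> dict:
    states = sorted(landscape.energies)
    rates: dict[tuple[int, int], float] = {}
    for a, b in zip(states[:-1], states[1:]):
        if (a, b) in landscape.barriers:
            rates[(a, b)] = transition_rate(a, b, force, landscape)
            rates[(b, a)] = transition_rate(b, a, force, landscape)
    return rates


def gillespie_states(landscape: EnergyLandscape, force: float, duration: float,
                     rng: np.random.Generator, initial_state: int = 0,
                     max_events: int = 2_000_000):
    """Exact CTMC path over the nearest-neighbour pathway at constant force.

    Returns ``(event_times, states)`` with ``event_times[0] = 0`` and
    ``states[k]`` occupied on ``[event_times[k], event_times[k+1])``.
    """
    rates = _rate_matrix_at_force(landscape, force)
    states_order = sorted(landscape.energies)
    t, s = 0.0, initial_state
    times, path = [0.0], [s]
    if all(r == 0 for r in rates.values()) and len(states_order) > 1:
        warnings.warn("all transition rates are zero; static trace", UserWarning)
        return np.array(times), np.array(path)
    for _ in range(max_events):
        outs = [(k, r) for k, r in rates.items() if k[0] == s and r > 0]
        if not outs:
            break
        total = sum(r for _k, r in outs)
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        u = rng.random() * total
        acc = 0.0
        for (_frm, nxt), r in outs:
            acc += r
            if u <= acc:
                s = nxt
                break
        times.append(t)
        path.append(s)
    return np.array(times), np.array(path)


def sample_state_occupancy(landscape: EnergyLandscape, force: float, n: int,
                           rng: np.random.Generator) -> dict[int, int]:
    """Multinomial state-occupancy sample from the tilted Boltzmann weights."""
    states = sorted(landscape.energies)
    p = np.array([landscape.occupancies(force)[s] for s in states])
    counts = rng.multinomial(n, p)
    return {s: int(c) for s, c in zip(states, counts)}


def simulate_constant_force_trace(cfg: SimulationConfig):
    """Constant-force extension trace with additive Gaussian noise.

    Returns ``(trace, truth)``; the trace carries compaction-positive
    ``dx`` sampled at the native rate, the truth dict carries the exact
    hop times and state path.
    """
    if cfg.protocol != "constant":
        raise ValueError("config protocol must be 'constant'")
    rng = np.random.default_rng(cfg.seed)
    init = cfg.initial_state if cfg.initial_state is not None else 0
    ev_t, ev_s = gillespie_states(cfg.landscape, cfg.force, cfg.duration_s, rng,
                                  initial_state=init)
    n = int(round(cfg.duration_s * cfg.native_rate_hz))
    t = np.arange(n) / cfg.native_rate_hz
    state_at = ev_s[np.searchsorted(ev_t, t, side="right") - 1]
    levels = {s: float(cfg.landscape.dx_state(s, cfg.force))
              for s in cfg.landscape.energies}
    dx = np.array([levels[s] for s in state_at])
    if cfg.noise_sd_nm > 0:
        dx = dx + rng.normal(0.0, cfg.noise_sd_nm, size=n)
    trace = Trace(time=t, dx=dx, force=cfg.force,
                  meta={"seed": cfg.seed, "protocol": "constant"})
    truth = {"event_times": ev_t, "states": ev_s, "levels": levels}
    return trace, truth


# ---------------------------------------------------------------------------
# force ramp

def _separation_tables(cfg: SimulationConfig):
    """Per-state trap-separation vs force tables for quasi-static inversion."""
    k_eff = cfg.trap_stiffness_pn_nm / 2.0  # two traps in series
    f = np.arange(0.05, cfg.f_max + 0.26, 0.01)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CalibrationWarning)
        xi_ds = np.asarray(dsdna_extension_per_bp(f, cfg.landscape.params))
        xi_ss = cfg.landscape.params.ssdna.extension_per_nt(f)
    bare = xi_ds * cfg.comp.n_ds + xi_ss * cfg.comp.n_ss
    tables = {}
    for s in cfg.landscape.energies:
        ext = bare - np.asarray(cfg.landscape.dx_state(s, f))
        tables[s] = ext + f / k_eff
    return f, tables, bare


def simulate_force_ramp(cfg: SimulationConfig, record_rate_hz: float = 500.0):
    """Quasi-static force-ramp FEC with state hopping and rupture force.

    Trap separation grows at ``ramp_speed_nm_s``; at each instant the
    force balances tether elasticity against the series trap stiffness.
    Kinetics are time-inhomogeneous (thinning of a majorizing rate); the
    unbound state is absorbing because ramps run in protein-free buffer.
    Returns ``{"fec": DataFrame, "rupture_force": float | nan, "truth"}``.
    """
    if cfg.protocol != "ramp":
        raise ValueError("config protocol must be 'ramp'")
    rng = np.random.default_rng(cfg.seed)
    f_grid, sep_tables, _bare = _separation_tables(cfg)
    state = cfg.initial_state if cfg.initial_state is not None else 65

    def force_of(sep: float, s: int) -> float:
        return float(np.interp(sep, sep_tables[s], f_grid))

    sep0 = float(np.interp(cfg.f_start, f_grid, sep_tables[state]))
    sep_max = float(sep_tables[state].max())
    t_end = (min(sep_max, float(np.interp(cfg.f_max, f_grid, sep_tables[0])))
             - sep0) / cfg.ramp_speed_nm_s

    def total_rate(s: int, f: float) -> float:
        return sum(r for (a, _b), r in _rate_matrix_at_force(cfg.landscape, f).items()
                   if a == s)

    events = [(0.0, state)]
    rupture = np.nan
    t, window = 0.0, 0.02
    while t < t_end and state != 0:
        f_now = force_of(sep0 + cfg.ramp_speed_nm_s * t, state)
        f_next = force_of(sep0 + cfg.ramp_speed_nm_s * min(t + window, t_end), state)
        lam = 2.0 * max(total_rate(state, f_now), total_rate(state, f_next), 1e-12)
        tau = rng.exponential(1.0 / lam)
        if tau > window or t + tau > t_end:
            t += window
            continue
        t += tau
        f_here = force_of(sep0 + cfg.ramp_speed_nm_s * t, state)
        rates = {k: r for k, r in _rate_matrix_at_force(cfg.landscape, f_here).items()
                 if k[0] == state}
        tot = sum(rates.values())
        if rng.random() < tot / lam:  # accept thinning proposal
            u, acc = rng.random() * tot, 0.0
            for (_a, b), r in rates.items():
                acc += r
                if u <= acc:
                    state = b
                    break
            events.append((t, state))
            if state == 0:
                rupture = f_here
    # sampled FEC
    n = max(2, int(t_end * record_rate_hz))
    ts = np.linspace(0.0, t_end, n)
    ev_t = np.array([e[0] for e in events])
    ev_s = np.array([e[1] for e in events])
    st = ev_s[np.searchsorted(ev_t, ts, side="right") - 1]
    forces = np.array([force_of(sep0 + cfg.ramp_speed_nm_s * ti, si)
                       for ti, si in zip(ts, st)])
    ext = np.array([float(np.interp(fi, f_grid, sep_tables[si])) - fi / (cfg.trap_stiffness_pn_nm / 2)
                    for fi, si in zip(forces, st)])
    if cfg.noise_sd_nm > 0:
        ext = ext + rng.normal(0.0, cfg.noise_sd_nm
                               / np.sqrt(max(cfg.native_rate_hz / record_rate_hz, 1.0)),
                               size=n)
    fec = pd.DataFrame({"time_s": ts, "force_pN": forces, "extension_nm": ext,
                        "state": st})
    return {"fec": fec, "rupture_force": float(rupture),
            "truth": {"event_times": ev_t, "states": ev_s}}


# ---------------------------------------------------------------------------
# reptation / FRET

def simulate_reptation_fret(cfg: SimulationConfig):
    """Reflected 1D random walk of the SSB on its unwrapped ssDNA.

    The protein position (donor-acceptor separation in nt from the 5'
    junction) hops +-1 nt at rate ``D`` per direction (so the MSD slope
    is ``2 D``); reflecting boundaries at 0 and ``lattice_nt - 1``.
    Returns a photon-count :class:`~ssbwrap.traces.Trace` (Poisson donor/
    acceptor at ``fret_bin_hz``) plus the exact position path.
    """
    if cfg.lattice_nt < 2:
        raise ValueError("reptation lattice needs at least 2 sites")
    rng = np.random.default_rng(cfg.seed)
    d = cfg.diffusion_nt2_s
    t, pos = 0.0, int(cfg.reptation_start_nt)
    if not 0 <= pos < cfg.lattice_nt:
        raise ValueError("reptation_start_nt outside the lattice")
    times, positions = [0.0], [pos]
    if d > 0:
        while t < cfg.duration_s:
            left_ok = pos > 0
            right_ok = pos < cfg.lattice_nt - 1
            total = d * (left_ok + right_ok)
            t += rng.exponential(1.0 / total)
            if t >= cfg.duration_s:
                break
            if left_ok and right_ok:
                pos += 1 if rng.random() < 0.5 else -1
            else:
                pos += 1 if right_ok else -1
            times.append(t)
            positions.append(pos)
    times = np.array(times)
    positions = np.array(positions)
    n_bins = max(1, int(cfg.duration_s * cfg.fret_bin_hz))
    bin_t = (np.arange(n_bins) + 0.5) / cfg.fret_bin_hz
    pos_at = positions[np.searchsorted(times, bin_t, side="right") - 1]
    eff = cfg.fret.efficiency(pos_at.astype(float))
    per_bin = cfg.photon_rate_hz / cfg.fret_bin_hz
    acceptor = rng.poisson(per_bin * eff)
    donor = rng.poisson(per_bin * (1.0 - eff))
    trace = Trace(time=bin_t, dx=np.zeros(n_bins), force=cfg.force,
                  donor=donor, acceptor=acceptor,
                  meta={"seed": cfg.seed, "protocol": "fret"})
    return trace, {"times": times, "positions": positions}


# ---------------------------------------------------------------------------
# RecA displacement

def simulate_reca_displacement(cfg: SimulationConfig):
    """Stepwise RecA displacement staircase through states ii->iii->iv->v.

    Before nucleation the SSB hops between the 56-nt (i) and 35-nt (ii)
    modes; RecA nucleates only from ii (needs >14 nt of exposed ssDNA),
    then the filament strips the SSB with exponential per-step dwell
    times.  A zero nucleation rate gives a pure hopping trace.
    """
    rng = np.random.default_rng(cfg.seed)
    model = five_state_expected_dx(cfg.force, cfg.landscape.params,
                                   cfg.landscape.x_ssb, cfg.comp)
    r = cfg.reca_rates
    t, state = 0.0, "ii"
    seq_t, seq_s = [0.0], ["ii"]
    while t < cfg.duration_s and state != "v":
        if state in ("i", "ii"):
            outs = ({"ii": r["i_ii"]} if state == "i"
                    else {"i": r["ii_i"], "iii": r["nucleation"]})
        elif state == "iii":
            outs = {"iv": r["iii_iv"]}
        else:  # iv
            outs = {"v": r["iv_v"]}
        total = sum(outs.values())
        if total == 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= cfg.duration_s:
            break
        u, acc = rng.random() * total, 0.0
        for nxt, rate in outs.items():
            acc += rate
            if u <= acc:
                state = nxt
                break
        seq_t.append(t)
        seq_s.append(state)
    n = int(round(cfg.duration_s * cfg.native_rate_hz))
    ts = np.arange(n) / cfg.native_rate_hz
    idx = np.searchsorted(np.array(seq_t), ts, side="right") - 1
    dx = np.array([model.dx[seq_s[i]] for i in idx])
    if cfg.noise_sd_nm > 0:
        dx = dx + rng.normal(0.0, cfg.noise_sd_nm, size=n)
    trace = Trace(time=ts, dx=dx, force=cfg.force,
                  meta={"seed": cfg.seed, "protocol": "reca"})
    return trace, {"event_times": np.array(seq_t), "states": seq_s,
                   "levels": model.dx}


# ---------------------------------------------------------------------------
# synthetic wrapping-path fixture

_FIXTURE_STEP_NM = 0.56  # per-nucleotide arc step along the wrapped path
_FIXTURE_DIAMETER_NM = 6.5
_FIXTURE_CLOSURE_NT = 65  # the 65-nt wrap exits where it entered


def _seam_points(amplitude: float, t: np.ndarray) -> np.ndarray:
    """Baseball-seam curve on the unit sphere (two equatorial oscillations)."""
    theta = np.pi / 2 + amplitude * np.sin(2 * t)
    return np.column_stack([np.sin(theta) * np.cos(t),
                            np.sin(theta) * np.sin(t),
                            np.cos(theta)])


def fixture_wrapping_path(n_nt: int = 70) -> StructureModel:
    """Deterministic stand-in for the crystallographic ssDNA wrapping path.

    SYNTHETIC geometry, not derived from any deposited structure: a
    baseball-seam curve on a 6.5 nm-diameter sphere, resampled at uniform
    0.56 nm arc steps, closing after 65 nucleotides so that a 65-nt wrap
    exits next to its entry point (< 2 nm end-to-end) while a 35-nt wrap
    spans the sphere (~5.5 nm), mimicking the topology of the real
    tetramer.  Four hotspot anchors sit a quarter-wrap apart; their
    7-nucleotide contact groups reproduce the banded level-3 constraint
    geometry, with the wrap-around tail contacting the first hotspot.
    """
    if not 2 <= n_nt <= 70:
        raise ValueError("n_nt must lie in [2, 70]")
    radius = _FIXTURE_DIAMETER_NM / 2.0
    closure_len = _FIXTURE_CLOSURE_NT * _FIXTURE_STEP_NM
    t_dense = np.linspace(0.0, 2 * np.pi, 20001)

    def seam_length(b: float) -> float:
        pts = _seam_points(b, t_dense) * radius
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    amp = brentq(lambda b: seam_length(b) - closure_len, 0.05, 1.55, xtol=1e-10)
    pts = _seam_points(amp, t_dense) * radius
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    total = arc[-1]

    def at_arc(s: float) -> np.ndarray:
        s = s % total
        i = int(np.searchsorted(arc, s, side="right") - 1)
        i = min(i, len(arc) - 2)
        w = (s - arc[i]) / (arc[i + 1] - arc[i])
        return pts[i] * (1 - w) + pts[i + 1] * w

    positions = np.array([at_arc(i * _FIXTURE_STEP_NM) for i in range(n_nt)])

    anchor_nts = [3.0, 3.0 + 16.25, 3.0 + 32.5, 3.0 + 48.75]
    anchors = []
    for a in anchor_nts:
        p = at_arc(a * _FIXTURE_STEP_NM)
        anchors.append(p * (1.0 + 0.2 / radius))  # nudged off-path, residue-like
    anchors = np.array(anchors)

    groups, contact_sets = [], []
    base = min(n_nt, _FIXTURE_CLOSURE_NT)
    for p in anchors:
        d = np.linalg.norm(positions - p, axis=1)
        members = sorted(np.argsort(d[:base])[:7].tolist())
        groups.append(members)
        contacts = sorted(np.where(d <= 1.95)[0].tolist())
        contact_sets.append(contacts if contacts else members)
    return StructureModel(
        positions_nm=positions,
        hotspot_groups=groups,
        hotspot_contact_sets=contact_sets,
        metadata={
            "source": "synthetic baseball-seam fixture",
            "seam_amplitude_rad": amp,
            "arc_step_nm": _FIXTURE_STEP_NM,
            "closure_nt": _FIXTURE_CLOSURE_NT,
            "anchor_nts": anchor_nts,
        },
    )
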