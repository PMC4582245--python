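"""RecA filament formation and stepwise SSB displacement.

A RecA filament extends ssDNA to 1.5x the dsDNA per-bp extension.  When
RecA invades the 70-nt site occupied by an SSB it strips the protein
through discrete intermediates; five states are distinguished by their
expected extension change relative to the bare tether at fixed force:

    i    SSB wrapping 56 nt, no RecA
    ii   SSB wrapping 35 nt, no RecA
    iii  SSB wrapping 35 nt, remaining 35 nt RecA-coated
    iv   SSB wrapping 17 nt, remaining 53 nt RecA-coated
    v    no SSB, fully RecA-coated (about +10 nm at 5 pN)

In this module extension changes are signed relative to the bare tether
with *positive = longer* (the display convention for RecA traces), the
opposite of the compaction-positive convention used for wrapping alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ssbwrap.geometry import effective_size
from ssbwrap.landscape import DEFAULT_X_SSB
from ssbwrap.polymer import (
    PolymerParams,
    TetherComposition,
    bare_extension,
    dsdna_extension_per_bp,
    ssdna_extension_per_nt,
)

RECA_STATES = ("i", "ii", "iii", "iv", "v")

#: (wrapped nt, RecA on the unwrapped remainder?) per displacement state
STATE_DEFS = {
    "i": (56, False),
    "ii": (35, False),
    "iii": (35, True),
    "iv": (17, True),
    "v": (0, True),
}


def reca_full_extension(force, comp: TetherComposition,
                        params: PolymerParams | None = None):
    """Extension (nm) of the tether with RecA covering all ssDNA.

    RecA-coated ssDNA extends 1.5x per-nucleotide relative to dsDNA per
    base pair: ``xi_ds N_ds + 1.5 xi_ds N_ss``.
    """
    params = params or PolymerParams()
    xi_ds = dsdna_extension_per_bp(force, params)
    return xi_ds * comp.n_ds + 1.5 * xi_ds * comp.n_ss


def reca_extension_change_vs_bare(force, n_ss: int = 70,
                                  params: PolymerParams | None = None):
    """Extension gained on full RecA coating, ``(1.5 xi_ds - xi_ss) N_ss`` (nm)."""
    params = params or PolymerParams()
    return (1.5 * dsdna_extension_per_bp(force, params)
            - ssdna_extension_per_nt(force, params)) * n_ss


def ssb_reca_extension(force, comp: TetherComposition, x_ssb: float,
                       params: PolymerParams | None = None):
    """Extension (nm) with ``comp.n_wrapped`` nt on SSB, the rest RecA-coated.

    Reduces to :func:`reca_full_extension` at ``n_wrapped = 0`` and loses
    the RecA term entirely at full wrap.
    """
    params = params or PolymerParams()
    xi_ds = dsdna_extension_per_bp(force, params)
    return (xi_ds * comp.n_ds + 1.5 * xi_ds * (comp.n_ss - comp.n_wrapped)
            + effective_size(x_ssb, force, params.thermal_energy))


@dataclass
class RecAStateModel:
    """Predicted extension changes (vs bare, nm) of the five intermediates."""

    force: float
    dx: dict[str, float]
    definitions: dict[str, tuple[int, bool]] = field(default_factory=lambda: dict(STATE_DEFS))

    def __post_init__(self) -> None:
        order = [self.dx[s] for s in RECA_STATES]
        if not all(a < b for a, b in zip(order[:-1], order[1:])):
            raise ValueError("state extension ordering i < ii < iii < iv < v violated")

    def nearest(self, dx_obs: float, ambiguity_nm: float = 0.0) -> list[str]:
        """State(s) whose predicted level is nearest ``dx_obs``.

        Returns more than one candidate when a second prediction lies
        within ``ambiguity_nm`` of the best match.
        """
        dists = {s: abs(self.dx[s] - dx_obs) for s in RECA_STATES}
        best = min(dists.values())
        return [s for s in RECA_STATES if dists[s] <= best + ambiguity_nm]


def five_state_expected_dx(force: float, params: PolymerParams | None = None,
                           x_ssb: dict[int, float] | None = None,
                           comp: TetherComposition | None = None) -> RecAStateModel:
    """Expected extension change of each SSB/RecA intermediate at ``force``."""
    params = params or PolymerParams()
    x_ssb = dict(x_ssb or DEFAULT_X_SSB)
    comp = comp or TetherComposition()
    bare = bare_extension(force, comp, params)
    dx = {}
    for s, (nw, reca) in STATE_DEFS.items():
        c = TetherComposition(n_ds=comp.n_ds, n_ss=comp.n_ss, n_wrapped=nw)
        if reca:
            if nw == 0:
                ext = reca_full_extension(force, c, params)
            else:
                ext = ssb_reca_extension(force, c, x_ssb[nw], params)
        else:
            xi_ss = ssdna_extension_per_nt(force, params)
            xeff = effective_size(x_ssb[nw], force, params.thermal_energy)
            ext = (dsdna_extension_per_bp(force, params) * c.n_ds
                   + xi_ss * (c.n_ss - nw) + xeff)
        dx[s] = float(ext - bare)
    return RecAStateModel(force=force, dx=dx)


def assign_reca_states(seg, model: RecAStateModel, ambiguity_nm: float = 0.5):
    """Label segmented-displacement plateaus with the nearest i-v state.

    Returns the input :class:`~ssbwrap.traces.SegmentedTrace` with labels
    replaced and a pathway summary; level ambiguities (two predictions
    within ``ambiguity_nm``) report all candidates joined by ``|``.
    """
    from ssbwrap.traces import Segment, SegmentedTrace

    labelled = []
    for s in seg.segments:
        cands = model.nearest(s.mean_dx, ambiguity_nm=ambiguity_nm)
        labelled.append(Segment(start=s.start, end=s.end,
                                label="|".join(cands), mean_dx=s.mean_dx))
    merged: list = []
    for s in labelled:
        if merged and merged[-1].label == s.label:
            w1, w2 = merged[-1].duration, s.duration
            merged[-1].mean_dx = (merged[-1].mean_dx * w1 + s.mean_dx * w2) / (w1 + w2)
            merged[-1].end = s.end
        else:
            merged.append(s)
    transitions = [(a.label, b.label, b.start) for a, b in zip(merged[:-1], merged[1:])]
    pathway = " -> ".join(s.label for s in merged)
    return SegmentedTrace(segments=merged, transitions=transitions,
                          force=seg.force, flags={**seg.flags, "pathway": pathway})
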