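"""Protocell-level events: movement, division, fusion, breakage.

A protocell grows by absorbing amphiphiles and divides once its membrane
holds more than twice the assembly threshold (``2 * L_AM`` tails), with
probability ``P_CD * (1 - 2*L_AM/b)``: the bigger the cell, the more
physically unstable.  Division assorts every membrane amphiphile and every
interior molecule or strand independently to either offspring (fair coin);
the offspring claims a protocell-free neighbor room, displacing the free
molecules there.  Adjacent protocells fuse with ``P_CF``; a protocell
breaks with ``P_CB``, disassembling its membrane into free amphiphiles.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as K
from .world import World

__all__ = [
    "division_prob",
    "divide",
    "fuse",
    "break_protocell",
    "move_protocell",
]


def division_prob(b: int, p) -> float:
    """Per-step division probability for a membrane of ``b`` tails.

    ``max(0, P_CD * (1 - 2*L_AM/b))``: zero at or below twice the assembly
    threshold, approaching ``P_CD`` for very large membranes.
    """
    if b < 1:
        raise ValueError("membrane tail count must be >= 1")
    return float(K.division_prob(float(b), p.P_CD, float(p.L_AM)))


def _free_neighbors(w: World, room: int, exclude: int = -1) -> list[int]:
    return [int(q) for q in w.nbr[room]
            if int(q) != exclude and not w.occ[q]]


def _push_contents(w: World, room: int, targets: list[int],
                   rng: np.random.Generator) -> None:
    """Distribute the free molecules and strands of ``room`` over targets."""
    nt = len(targets)
    for sp in range(K.NSP):
        n = int(w.pool[room, sp])
        if n == 0:
            continue
        split = rng.multinomial(n, [1.0 / nt] * nt)
        w.pool[room, sp] = 0
        for t, k in zip(targets, split):
            w.pool[t, sp] += int(k)
    st = w.strands
    top = int(st.meta[1])
    for s in np.flatnonzero(st.alive[:top] & (st.room[:top] == room)):
        st.room[s] = targets[rng.integers(nt)]


def divide(w: World, room: int, rng: np.random.Generator) -> int | None:
    """Divide the protocell in ``room``; returns the offspring's room.

    Requires a protocell-free neighbor (else returns None: division is
    suppressed).  Membrane amphiphiles and interior contents assort
    independently with probability 1/2 each; the displaced free molecules
    of the claimed room are pushed to its own unoccupied neighbors (or
    engulfed by the offspring if it is walled in).  Totals are conserved.
    """
    if not w.occ[room]:
        raise ValueError(f"room {room} holds no protocell")
    free = _free_neighbors(w, room)
    if not free:
        return None
    q = free[int(rng.integers(len(free)))]
    push_to = _free_neighbors(w, q, exclude=room)
    if push_to:
        _push_contents(w, q, push_to, rng)
    # else: the target room's free contents become offspring interior
    cf = int(rng.binomial(int(w.mem_fa[room]), 0.5))
    cp = int(rng.binomial(int(w.mem_pl[room]), 0.5))
    w.mem_fa[q] = cf
    w.mem_pl[q] = cp
    w.mem_fa[room] -= cf
    w.mem_pl[room] -= cp
    for sp in range(K.NSP):
        k = int(rng.binomial(int(w.pool[room, sp]), 0.5))
        w.pool[room, sp] -= k
        w.pool[q, sp] += k
    st = w.strands
    top = int(st.meta[1])
    for s in np.flatnonzero(st.alive[:top] & (st.room[:top] == room)):
        if rng.random() < 0.5:
            st.room[s] = q
    w.occ[q] = True
    if w.mem_fa[q] + w.mem_pl[q] == 0:
        w.occ[q] = False
    if w.mem_fa[room] + w.mem_pl[room] == 0:
        w.occ[room] = False
    return int(q)


def fuse(w: World, r1: int, r2: int) -> int:
    """Merge two adjacent protocells into the initiator's room ``r1``."""
    if not (w.occ[r1] and w.occ[r2]):
        raise ValueError("both rooms must hold protocells")
    if r2 not in [int(q) for q in w.nbr[r1]]:
        raise ValueError(f"rooms {r1} and {r2} are not adjacent")
    w.mem_fa[r1] += w.mem_fa[r2]
    w.mem_pl[r1] += w.mem_pl[r2]
    w.mem_fa[r2] = 0
    w.mem_pl[r2] = 0
    w.pool[r1] += w.pool[r2]
    w.pool[r2] = 0
    st = w.strands
    top = int(st.meta[1])
    sel = st.alive[:top] & (st.room[:top] == r2)
    st.room[:top][sel] = r1
    w.occ[r2] = False
    return int(r1)


def break_protocell(w: World, room: int) -> None:
    """Disassemble the membrane; everything becomes free molecules in place.

    Interior RNA is then exposed to the F_DO-scaled outside degradation
    rates from the next event on.
    """
    if not w.occ[room]:
        raise ValueError(f"room {room} holds no protocell")
    w.pool[room, K.FA] += w.mem_fa[room]
    w.pool[room, K.PL] += w.mem_pl[room]
    w.mem_fa[room] = 0
    w.mem_pl[room] = 0
    w.occ[room] = False


def move_protocell(w: World, room: int, direction: int,
                   rng: np.random.Generator) -> int | None:
    """Move the protocell one room in ``direction`` (0 up, 1 down, 2 left,
    3 right, toroidal); returns the new room or None if the target is
    occupied.  Free molecules of the target room are pushed to its other
    unoccupied neighbors (or swap into the vacated room if there are none).
    """
    if not w.occ[room]:
        raise ValueError(f"room {room} holds no protocell")
    q = int(w.nbr[room, direction])
    if w.occ[q]:
        return None
    interior = w.pool[room].copy()
    w.pool[room] = 0
    st = w.strands
    top = int(st.meta[1])
    cell_strands = np.flatnonzero(st.alive[:top] & (st.room[:top] == room))
    w.occ[room] = False
    push_to = _free_neighbors(w, q, exclude=room) or [room]
    _push_contents(w, q, push_to, rng)
    w.mem_fa[q] = w.mem_fa[room]
    w.mem_pl[q] = w.mem_pl[room]
    w.mem_fa[room] = 0
    w.mem_pl[room] = 0
    w.pool[q] += interior
    st.room[cell_strands] = q
    w.occ[q] = True
    return q
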