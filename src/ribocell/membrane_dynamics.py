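"""Membrane assembly, amphiphile exchange, permeation, phospholipid turnover.

A membrane self-assembles in a room once its amphiphile tail count reaches
``L_AM`` (one tail per fatty acid, two per phospholipid) and every
amphiphile is incorporated.  Amphiphiles join readily (``P_FJM``/``P_PJM``)
but leave against two stabilizing effects: the osmotic term
``y = 1 + i/(b/2)^(3/2)`` (interior RNA swells the cell) and the
phospholipid term ``z = 1 + F_PL * RPM`` (the anti-desorption effect).
Small molecules permeate with species-specific base rates throttled inward
by cell volume (``s = b/L_AM``), Donnan's equilibrium
(``u = 1 + F_DE * i/(b/2)^(3/2)``) and phospholipid content
(``v = 1 + F_PP * RPM``; the weak ``F_PPW`` variant for the smallest
molecules; TR relief ``v'' = 1 + F_PP * RPM/(1 + t * F_TR)`` for
nucleotide precursors, both directions).  Glycerophosphates made inside
react with two membrane fatty acids in situ to one phospholipid (``P_PF``);
phospholipids decay back to two fatty acids and one glycerophosphate
(``P_PDM`` on the membrane, ``P_PD`` elsewhere).
"""

from __future__ import annotations

import numpy as np

from . import _kernels as K
from .parameters import default_species
from .world import Membrane, Protocell, World, rpm

__all__ = [
    "membrane_formation_prob",
    "form_membrane",
    "amphiphile_leave_prob",
    "permeation_prob",
    "try_cross_membrane",
    "phospholipid_synthesis",
    "phospholipid_decay",
]

_PERM_SPECIES = {"Nt": K.NTA, "Np": K.NP_, "Npp": K.NPP, "Gp": K.GP}


def membrane_formation_prob(a: int, p) -> float:
    """Probability that ``a`` amphiphile tails assemble into a membrane.

    Zero below the ``L_AM`` threshold, else ``1 - (1 - P_MF)**x`` with
    ``x = a - L_AM + 1``: the more amphiphiles, the likelier the vesicle.
    """
    if a < 0:
        raise ValueError("tail count must be >= 0")
    return float(K.membrane_formation_prob(float(a), p.P_MF, float(p.L_AM)))


def form_membrane(w: World, room: int) -> Protocell:
    """Assemble all FA/PL of ``room`` into a membrane; contents go interior."""
    if w.occ[room]:
        raise ValueError(f"room {room} already holds a protocell")
    w.mem_fa[room] = w.pool[room, K.FA]
    w.mem_pl[room] = w.pool[room, K.PL]
    w.pool[room, K.FA] = 0
    w.pool[room, K.PL] = 0
    w.occ[room] = True
    return w.protocell(room)


def _leave_env(c: Protocell) -> tuple[int, int, float]:
    mem = c.membrane
    if mem.b <= 0:
        raise ValueError("empty membrane")
    return c.i, mem.b, rpm(mem)


def amphiphile_leave_prob(kind: str, c: Protocell, p) -> float:
    """Per-molecule probability that a membrane FA or PL desorbs this step.

    ``base / (y * z)`` with base ``P_FLM`` (FA) or ``P_PLM`` (PL): both the
    osmotic swelling from interior RNA and the phospholipid content of the
    membrane suppress desorption.
    """
    if kind not in ("FA", "PL"):
        raise ValueError(f"kind must be 'FA' or 'PL', got {kind!r}")
    ions, b, r = _leave_env(c)
    base = p.P_FLM if kind == "FA" else p.P_PLM
    return float(K.amphiphile_leave_prob(base, float(ions), float(b),
                                         p.F_PL, r))


def permeation_prob(species: str, direction: str, c: Protocell, p,
                    species_defs=None) -> float:
    """Membrane crossing probability for Nt, Np, Npp or Gp.

    Inward crossing scales with cell volume and is throttled by Donnan's
    equilibrium and phospholipid content; outward crossing only by the
    latter.  The TR transport effect relieves the phospholipid throttle for
    nucleotide precursors in both directions.
    """
    if species not in _PERM_SPECIES:
        raise ValueError(f"species must be one of {sorted(_PERM_SPECIES)}")
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")
    defs = species_defs if species_defs is not None else default_species()
    tr_domain = next((s.domain for s in defs if s.function == "transport_enhancer"),
                     None)
    t = c.t(tr_domain) if tr_domain else 0
    mem = c.membrane
    if mem.b <= 0:
        raise ValueError("empty membrane")
    return float(K.permeation_prob(p.as_vector(), _PERM_SPECIES[species],
                                   direction == "in", float(mem.fa),
                                   float(mem.pl), float(c.i), float(t)))


def try_cross_membrane(kind: str, direction: str, c: Protocell, p,
                       rng: np.random.Generator,
                       species_defs=None) -> str:
    """Resolve one crossing attempt: 'joined', 'permeated' or 'bounced'.

    Fatty acids and phospholipids join the membrane (``P_FJM``/``P_PJM``);
    Nt/Np/Npp/Gp permeate with :func:`permeation_prob`; glycerophosphates
    only react from the interior side (handled by phospholipid synthesis)
    and RNA strands never cross.
    """
    if kind == "RNA":
        return "bounced"
    if kind == "FA":
        return "joined" if rng.random() < p.P_FJM else "bounced"
    if kind == "PL":
        return "joined" if rng.random() < p.P_PJM else "bounced"
    if kind == "G":
        return "bounced"
    prob = permeation_prob(kind, direction, c, p, species_defs)
    return "permeated" if rng.random() < prob else "bounced"


def phospholipid_synthesis(w: World, room: int,
                           rng: np.random.Generator) -> int:
    """Interior G + 2 membrane FA -> membrane PL, each G with ``P_PF``.

    Limited by the membrane's fatty-acid stock (two per phospholipid).
    Returns the number of phospholipids formed.
    """
    if not w.occ[room]:
        raise ValueError(f"room {room} holds no protocell")
    k = int(rng.binomial(int(w.pool[room, K.G]), w.params.P_PF))
    k = min(k, int(w.mem_fa[room]) // 2)
    w.pool[room, K.G] -= k
    w.mem_fa[room] -= 2 * k
    w.mem_pl[room] += k
    return k


def phospholipid_decay(w: World, room: int, rng: np.random.Generator,
                       location: str = "membrane") -> int:
    """PL -> 2 FA + 1 G at ``P_PDM`` (membrane) or ``P_PD`` (free pool).

    Membrane decay keeps the fatty acids in the membrane and drops the
    glycerophosphate into the interior.  Returns the number decayed.
    """
    if location == "membrane":
        if not w.occ[room]:
            raise ValueError(f"room {room} holds no protocell")
        k = int(rng.binomial(int(w.mem_pl[room]), w.params.P_PDM))
        w.mem_pl[room] -= k
        w.mem_fa[room] += 2 * k
        w.pool[room, K.G] += k
    elif location == "free":
        k = int(rng.binomial(int(w.pool[room, K.PL]), w.params.P_PD))
        w.pool[room, K.PL] -= k
        w.pool[room, K.FA] += 2 * k
        w.pool[room, K.G] += k
    else:
        raise ValueError("location must be 'membrane' or 'free'")
    return k
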