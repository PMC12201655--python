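"""Formation and decay of the small-molecule building blocks.

The synthesis ladder runs Npp -> Np -> Nt for nucleotides and Gp -> G for
glycerophosphates.  Each step has a slow non-enzymatic rate and a fast
ribozyme-catalyzed rate (NPR, NR and GR respectively); the catalyzed rate
applies whenever at least one free strand bearing that function shares the
compartment.  Decay runs the other way (Nt -> Np, Np -> Npp, G -> Gp) but
is a distinct, likewise irreversible reaction: the precursors consumed by
synthesis are activated species, the decay products are not.  Nucleotide
decay is ``F_DO``-fold faster outside protocells.
"""

from __future__ import annotations

from typing import Iterable

from . import _kernels as K
from .parameters import SpeciesDef
from .world import World

__all__ = ["reaction_rates", "apply_reactions"]

_FUNC_BY_NAME = {
    "GR": "glycerophosphate_synthetase",
    "NR": "nucleotide_synthetase",
    "NPR": "nucleotide_precursor_synthetase",
}


def _present_functions(species_present: Iterable) -> set[str]:
    out = set()
    for s in species_present:
        if isinstance(s, SpeciesDef):
            out.add(s.function)
        elif s in _FUNC_BY_NAME:
            out.add(_FUNC_BY_NAME[s])
        else:
            out.add(str(s))
    return out


def reaction_rates(species_present: Iterable, outside: bool, p) -> dict[str, float]:
    """Per-molecule conversion probabilities for one compartment.

    ``species_present`` lists the catalytically active species in the
    compartment (SpeciesDef objects or names GR/NR/NPR); ``outside`` is True
    for a naked room, where nucleotide decay is scaled by ``F_DO``.
    """
    funcs = _present_functions(species_present)
    fdo = p.F_DO if outside else 1.0
    return {
        "Npp->Np": p.P_NPFR if "nucleotide_precursor_synthetase" in funcs else p.P_NPF,
        "Np->Nt": p.P_NFR if "nucleotide_synthetase" in funcs else p.P_NF,
        "Gp->G": p.P_GFR if "glycerophosphate_synthetase" in funcs else p.P_GF,
        "Nt->Np": min(1.0, p.P_ND * fdo),
        "Np->Npp": p.P_NPD,
        "G->Gp": p.P_GD,
    }


def apply_reactions(w: World, seed: int | None = None) -> None:
    """One reaction pass over every compartment of the world, in place.

    Conversions are drawn as one binomial per reaction per compartment
    (exactly equivalent to independent per-molecule Bernoulli trials); newly
    formed nucleotides take base A/C/G/U uniformly; all counts are computed
    from start-of-pass values, so nothing reacts twice in one call.
    """
    if seed is not None:
        K.seed_kernel_rng(int(seed) & 0x7FFFFFFF)
    w.scan()
    K.phase_react(w._par_vec, w.pool, w.occ, w._act)
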