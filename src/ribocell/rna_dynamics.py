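"""RNA-level events: ligation, template-directed synthesis, decay, movement.

RNA in the model is a chain over {A, C, G, U} that can act as a template:
substrates (free nucleotides, or fully complementary oligomers) are
attracted one site at a time next to the growing aligned block (``P_AT``,
with per-residue mispairing ``P_FP``), neighbouring aligned residues are
ligated (``P_TL``), and the whole aligned complement can separate from the
template with probability ``P_SP ** sqrt(n)`` for ``n`` base pairs.  Chains
degrade by internal bond breakage (``P_BB``, with paired sites breaking
both strands at the rarer ``P_BB ** 1.5``) and by chain-end residue decay
(``P_NDE``); both are accelerated by ``F_DO`` outside protocells.

The per-event probability functions are exact closed forms; the stochastic
operations act on a :class:`~ribocell.world.World` in place and are the same
compiled kernels the engine uses.
"""

from __future__ import annotations

import numpy as _np

from . import _kernels as K
from .world import World

__all__ = [
    "rna_move_prob",
    "bond_break_prob",
    "separation_prob",
    "random_ligation_step",
    "attract_substrate",
    "template_ligate",
    "separate_duplex",
    "degrade_rna",
    "complement",
    "reverse_complement",
]

_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


def complement(base: str) -> str:
    """Watson-Crick complement of one base (A-U, G-C; no wobble)."""
    return _COMP[base]


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def rna_move_prob(m: int, p) -> float:
    """Per-step movement probability of an RNA of mass ``m`` residues.

    ``P_MV / sqrt(m)``, the Zimm scaling of polymer diffusivity, clamped
    to 1.  ``m`` counts every residue of the complex.
    """
    if m < 1:
        raise ValueError(f"RNA mass must be >= 1, got {m}")
    return float(K.rna_move_prob(float(m), p.P_MV))


def bond_break_prob(double_stranded: bool, outside: bool, p) -> float:
    """Per-bond backbone breaking probability.

    Single-stranded sites break with ``P_BB`` (times ``F_DO`` outside
    protocells); at a double-stranded site the two parallel bonds sever
    simultaneously with the 3/2 power of that rate.
    """
    return float(K.bond_break_prob(double_stranded, outside, p.P_BB, p.F_DO))


def separation_prob(n: int, p) -> float:
    """Probability that a duplex of ``n`` base pairs separates this step.

    ``P_SP ** sqrt(n)``: a single pair falls off with ``P_SP``; longer
    hybrids separate ever more rarely (partial self-folding of the single
    strands motivates the square root rather than ``n`` itself).
    """
    if n < 1:
        raise ValueError(f"need >= 1 base pair, got {n}")
    return float(K.separation_prob(float(n), p.P_SP))


def _seed_if(seed):
    if seed is not None:
        K.seed_kernel_rng(int(seed) & 0x7FFFFFFF)


def random_ligation_step(w: World, seed: int | None = None) -> None:
    """One random-ligation pass over every compartment of ``w``.

    Each unordered pair drawn from a compartment's free nucleotides and bare
    single strands joins end-to-end with probability ``P_RL`` (concatenation
    order random); a molecule ligates at most once per step.
    """
    _seed_if(seed)
    st = w.strands
    K._build_lists(st.meta[1], st.alive, st.room, st.head, st.nxt)
    K._random_ligation(w._par_vec, w.pool, st.meta[1], st.alive, st.room,
                       st.length, st.seq, st.dstart, st.dlen, st.dseq,
                       st.dbond, st.flags, st.meta, st.free_stack,
                       w.domains, int(w.params.L_CDR), st.head, st.nxt)


def attract_substrate(w: World, slot: int, seed: int | None = None) -> bool:
    """One substrate-attraction attempt for the template in ``slot``.

    Fires with probability ``P_AT``.  The substrate is aligned at the next
    unpaired position adjacent to the aligned block (either end; a uniform
    position on a bare template): with probability ``P_FP`` a random
    non-complementary nucleotide, otherwise the complementary nucleotide or
    a fully complementary bare oligomer from the same compartment, chosen
    in proportion to their counts.  Returns True if a substrate was aligned.
    """
    _seed_if(seed)
    st = w.strands
    if not st.alive[slot]:
        raise ValueError(f"slot {slot} is not a live strand")
    if st.dlen[slot] >= st.length[slot]:
        return False
    if st.length[slot] < w.params.L_TMIN:
        return False  # too short to hold a substrate as a template
    K._build_lists(st.meta[1], st.alive, st.room, st.head, st.nxt)
    if _kernel_uniform() >= w.params.P_AT:
        return False
    buf = _np.empty(4096, _np.int64)
    got = K._attract_one(w._par_vec, w.pool, slot, st.alive, st.room,
                         st.length, st.seq, st.dstart, st.dlen, st.dseq,
                         st.dbond, st.meta, st.free_stack, st.head, st.nxt,
                         buf)
    return bool(got)


def template_ligate(w: World, slot: int, seed: int | None = None) -> int:
    """Close unligated junctions of ``slot``'s aligned block, each with P_TL.

    Returns the number of junctions ligated.
    """
    _seed_if(seed)
    st = w.strands
    n = 0
    p_tl = w.params.P_TL
    if st.dlen[slot] >= 2:
        a = int(st.dstart[slot])
        for j in range(a, a + int(st.dlen[slot]) - 1):
            if st.dbond[slot, j] == 0 and _kernel_uniform() < p_tl:
                st.dbond[slot, j] = 1
                n += 1
    return n


def separate_duplex(w: World, slot: int, seed: int | None = None,
                    force: bool = False) -> bool:
    """Attempt duplex separation for ``slot``; returns True if material left.

    Aligned material is organized in maximal ligated runs; the runs at the
    two edges of the block may each separate with ``P_SP ** sqrt(run
    length)`` (a fully ligated block is a single run — the full
    complementary chain).  Released runs of length >= 2 become free strands
    (read antiparallel, 5'->3'); single residues return to the nucleotide
    pool.  With ``force=True`` everything is released unconditionally.
    """
    _seed_if(seed)
    st = w.strands
    n = int(st.dlen[slot])
    if n < 1:
        return False
    if force:
        K._release_duplex(w.pool, slot, st.room, st.length, st.seq, st.dstart,
                          st.dlen, st.dseq, st.dbond, st.alive, st.meta,
                          st.free_stack, st.flags, w.domains,
                          int(w.params.L_CDR))
        return True
    K._separate_ends(w._par_vec, w.pool, slot, st.room, st.length, st.seq,
                     st.dstart, st.dlen, st.dseq, st.dbond, st.alive, st.meta,
                     st.free_stack, st.flags, w.domains, int(w.params.L_CDR))
    return int(st.dlen[slot]) < n


def degrade_rna(w: World, slot: int, seed: int | None = None) -> None:
    """One degradation pass (bond breaking then end decay) for ``slot``.

    Internal bonds break per :func:`bond_break_prob` (paired sites sever
    both strands); if the strand survives in place, each single-stranded
    terminal residue decays to one nucleotide precursor with probability
    ``P_NDE`` (times ``F_DO`` outside); length-1 bare products rejoin the
    free nucleotide pool.
    """
    _seed_if(seed)
    st = w.strands
    K._break_strand(w._par_vec, w.pool, slot, w.occ, st.alive, st.room,
                    st.length, st.seq, st.dstart, st.dlen, st.dseq, st.dbond,
                    st.flags, st.meta, st.free_stack, w.domains,
                    int(w.params.L_CDR))
    if st.alive[slot]:
        K._end_decay_one(w._par_vec, w.pool, w.occ, slot, st.alive, st.room,
                         st.length, st.seq, st.dstart, st.dlen, st.dseq,
                         st.dbond, st.flags, st.meta, st.free_stack,
                         w.domains, int(w.params.L_CDR))
    _cleanup_len1(w)


def _kernel_uniform() -> float:
    return float(K._uniform())


def _cleanup_len1(w: World) -> None:
    """Bare length-1 remnants are free nucleotides, not strands."""
    st = w.strands
    top = int(st.meta[1])
    for s in range(top):
        if st.alive[s] and st.length[s] == 1 and st.dlen[s] == 0:
            r = int(st.room[s])
            w.pool[r, K.NTA + int(st.seq[s, 0])] += 1
            st.alive[s] = False
            st.free_stack[st.meta[0]] = s
            st.meta[0] += 1
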