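"""Simulation state: the toroidal grid, molecule pools, strands, protocells.

The world is an ``N x N`` grid of rooms with toroidal adjacency.  A room
holds counts of small molecules (nucleotide-precursor's precursors ``Npp``,
nucleotide precursors ``Np``, nucleotides ``Nt`` per base, glycerophosphate
precursors ``Gp``, glycerophosphates ``G``, fatty acids ``FA`` and
phospholipids ``PL``), a list of RNA strands, and optionally a protocell.
A protocell occupies its whole room: its membrane is a (fatty acid,
phospholipid) pair of counts and the room's pools/strands are its interior.

For performance the state is stored as flat numpy arrays (one row per room,
structure-of-arrays for strands) shared with the numba step kernels; the
classes here provide the user-facing views (:class:`RNAStrand`,
:class:`Protocell`, ...) on top of those arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .parameters import ParameterSet, SpeciesDef, default_species, validate_params

__all__ = [
    "World",
    "StrandStore",
    "RNAStrand",
    "Membrane",
    "Protocell",
    "init_world",
    "total_equivalents",
    "rpm",
    "classify_protocell",
    "BASES",
    "encode_seq",
    "decode_seq",
]

BASES = "ACGU"
_B2I = {b: i for i, b in enumerate(BASES)}

#: pool column order (matches the kernels)
POOL_SPECIES = ("Npp", "Np", "NtA", "NtC", "NtG", "NtU", "Gp", "G", "FA", "PL")

FUNC_CODE = {
    "none": K.FUNC_NONE,
    "glycerophosphate_synthetase": K.FUNC_GR,
    "nucleotide_synthetase": K.FUNC_NR,
    "nucleotide_precursor_synthetase": K.FUNC_NPR,
    "transport_enhancer": K.FUNC_TR,
}


def encode_seq(s: str) -> np.ndarray:
    """Base string -> uint8 codes (A=0, C=1, G=2, U=3)."""
    try:
        return np.array([_B2I[c] for c in s], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence {s!r}") from None


def decode_seq(codes: np.ndarray) -> str:
    return "".join(BASES[int(c)] for c in codes)


@dataclass(frozen=True)
class RNAStrand:
    """Read-only view of one strand: sequence (5'->3'), room, duplex state."""

    sequence: str
    room: int
    inside_protocell: bool
    paired: int = 0           # aligned substrate residues (0 for a bare strand)
    pair_start: int = -1      # template offset of the aligned block

    @property
    def mass(self) -> int:
        """Residue count of the whole complex (template + aligned)."""
        return len(self.sequence) + self.paired


@dataclass(frozen=True)
class Membrane:
    fa: int
    pl: int

    @property
    def b(self) -> int:
        """Amphiphile quantity in tails: one per FA, two per PL."""
        return self.fa + 2 * self.pl


@dataclass(frozen=True)
class Protocell:
    room: int
    membrane: Membrane
    interior_counts: dict
    strands: tuple = ()

    @property
    def i(self) -> int:
        """Impermeable-ion quantity: residues of interior RNA complexes."""
        return sum(s.mass for s in self.strands if s.mass >= 2)

    def t(self, tr_domain: str) -> int:
        """Number of free interior strands carrying the TR domain."""
        return sum(1 for s in self.strands
                   if s.paired == 0 and tr_domain in s.sequence)


class StrandStore:
    """Structure-of-arrays slab of RNA strands with a free-slot stack."""

    def __init__(self, capacity: int, lmax: int = 48):
        self.lmax = int(lmax)
        cap = int(capacity)
        self.alive = np.zeros(cap, bool)
        self.room = np.zeros(cap, np.int64)
        self.length = np.zeros(cap, np.int64)
        self.seq = np.zeros((cap, lmax), np.uint8)
        self.dstart = np.full(cap, -1, np.int64)
        self.dlen = np.zeros(cap, np.int64)
        self.dseq = np.zeros((cap, lmax), np.uint8)
        self.dbond = np.zeros((cap, lmax), np.uint8)
        self.flags = np.zeros(cap, np.uint8)
        # meta[0] = number of free slots, meta[1] = high-water mark
        self.meta = np.array([cap, 0], np.int64)
        self.free_stack = np.arange(cap - 1, -1, -1, dtype=np.int64)
        # per-room linked lists (kernel scratch)
        self.head = None
        self.nxt = np.full(cap, -1, np.int64)

    @property
    def capacity(self) -> int:
        return self.alive.shape[0]

    @property
    def n_alive(self) -> int:
        return int(self.alive[: self.meta[1]].sum())

    def grow(self, extra: int) -> None:
        old = self.capacity
        for name in ("alive", "room", "length", "dstart", "dlen", "flags", "nxt"):
            arr = getattr(self, name)
            pad = np.zeros(extra, arr.dtype) if name != "dstart" else np.full(extra, -1, arr.dtype)
            setattr(self, name, np.concatenate([arr, pad]))
        for name in ("seq", "dseq", "dbond"):
            arr = getattr(self, name)
            setattr(self, name, np.vstack([arr, np.zeros((extra, self.lmax), arr.dtype)]))
        # free_stack always spans the full capacity; [0, meta[0]) are free
        nfree = int(self.meta[0])
        new_stack = np.zeros(old + extra, np.int64)
        new_stack[:nfree] = self.free_stack[:nfree]
        new_stack[nfree:nfree + extra] = np.arange(old + extra - 1, old - 1, -1)
        self.free_stack = new_stack
        self.meta[0] = nfree + extra

    def add(self, sequence: str, room: int, domains: np.ndarray, dom_len: int) -> int:
        """Insert a bare strand; returns its slot id."""
        codes = encode_seq(sequence)
        if codes.shape[0] > self.lmax:
            raise ValueError(f"sequence longer than the store width ({self.lmax})")
        if codes.shape[0] < 1:
            raise ValueError("empty sequence")
        if self.meta[0] == 0:
            self.grow(max(1024, self.capacity // 2))
        slot = int(self.free_stack[self.meta[0] - 1])
        self.meta[0] -= 1
        self.meta[1] = max(self.meta[1], slot + 1)
        self.alive[slot] = True
        self.room[slot] = room
        self.length[slot] = codes.shape[0]
        self.seq[slot, : codes.shape[0]] = codes
        self.dstart[slot] = -1
        self.dlen[slot] = 0
        self.flags[slot] = K.compute_flags(self.seq[slot], codes.shape[0],
                                           domains, dom_len)
        return slot

    def view(self, slot: int, inside: bool) -> RNAStrand:
        L = int(self.length[slot])
        return RNAStrand(
            sequence=decode_seq(self.seq[slot, :L]),
            room=int(self.room[slot]),
            inside_protocell=inside,
            paired=int(self.dlen[slot]),
            pair_start=int(self.dstart[slot]) if self.dlen[slot] else -1,
        )


class World:
    """Full simulation state on an N x N toroidal grid."""

    def __init__(self, p: ParameterSet, species: list[SpeciesDef] | None = None,
                 seed: int = 0):
        rep = validate_params(p)
        if not rep.ok:
            raise ValueError("invalid parameters: " + "; ".join(rep.errors))
        self.params = p
        self.species = list(species) if species is not None else default_species(p)
        if len(self.species) > 8:
            raise ValueError("at most 8 species are supported")
        self.N = int(p.N)
        self.R = self.N * self.N
        self.step_count = 0
        self.seed = int(seed)
        ss = np.random.SeedSequence(self.seed)
        s_py, s_nb = ss.spawn(2)
        self.rng = np.random.Generator(np.random.PCG64(s_py))
        self._kernel_seed = int(s_nb.generate_state(1, np.uint32)[0])
        self._kernel_seeded = False

        self.pool = np.zeros((self.R, K.NSP), np.int64)
        self.occ = np.zeros(self.R, bool)
        self.mem_fa = np.zeros(self.R, np.int64)
        self.mem_pl = np.zeros(self.R, np.int64)
        self.nbr = self._build_neighbors()
        cap = max(4096, int(p.T_NPPB))
        self.strands = StrandStore(cap)
        self.strands.head = np.full(self.R, -1, np.int64)
        # species tables for the kernels
        self.domains = np.zeros((len(self.species), int(p.L_CDR)), np.uint8)
        for k, sp in enumerate(self.species):
            self.domains[k] = encode_seq(sp.domain)
        self.func_codes = np.array([FUNC_CODE[sp.function] for sp in self.species],
                                   np.int8)
        # scratch arrays reused across steps
        self._i_arr = np.zeros(self.R, np.int64)
        self._t_arr = np.zeros(self.R, np.int64)
        self._act = np.zeros(self.R, np.uint8)
        self._par_vec = p.as_vector()
        self._mv_p = float(p.P_MV)
        self._mv_probs, self._mv_alias = K._build_alias_family(self._mv_p,
                                                               K._NMAX_ALIAS)

    # -- construction helpers -------------------------------------------------

    def _build_neighbors(self) -> np.ndarray:
        N = self.N
        idx = np.arange(self.R).reshape(N, N)
        nbr = np.empty((self.R, 4), np.int64)
        nbr[:, 0] = np.roll(idx, 1, axis=0).ravel()   # up
        nbr[:, 1] = np.roll(idx, -1, axis=0).ravel()  # down
        nbr[:, 2] = np.roll(idx, 1, axis=1).ravel()   # left
        nbr[:, 3] = np.roll(idx, -1, axis=1).ravel()  # right
        return nbr

    def refresh_params(self) -> None:
        """Re-read ``self.params`` into the kernel vector (after a change)."""
        if int(self.params.N) != self.N:
            raise ValueError("grid size N cannot change mid-run")
        self._par_vec = self.params.as_vector()
        if float(self.params.P_MV) != self._mv_p:
            self._mv_p = float(self.params.P_MV)
            self._mv_probs, self._mv_alias = K._build_alias_family(
                self._mv_p, K._NMAX_ALIAS)

    # -- derived state --------------------------------------------------------

    def coords(self, room: int) -> tuple[int, int]:
        return divmod(int(room), self.N)

    def room_index(self, row: int, col: int) -> int:
        return (row % self.N) * self.N + (col % self.N)

    def scan(self) -> None:
        """Refresh per-room ion counts, TR counts and active-function bits."""
        K.scan_strands(self.strands.meta[1], self.strands.alive,
                       self.strands.room, self.strands.length,
                       self.strands.dlen, self.strands.flags,
                       self.func_codes, self._i_arr, self._t_arr, self._act)

    def strands_in_room(self, room: int) -> list[RNAStrand]:
        st = self.strands
        top = int(st.meta[1])
        sel = np.flatnonzero(st.alive[:top] & (st.room[:top] == room))
        inside = bool(self.occ[room])
        return [st.view(int(s), inside) for s in sel]

    def protocell(self, room: int) -> Protocell:
        if not self.occ[room]:
            raise ValueError(f"room {room} holds no protocell")
        counts = {name: int(self.pool[room, i]) for i, name in enumerate(POOL_SPECIES)}
        return Protocell(
            room=int(room),
            membrane=Membrane(int(self.mem_fa[room]), int(self.mem_pl[room])),
            interior_counts=counts,
            strands=tuple(self.strands_in_room(room)),
        )

    def protocell_rooms(self) -> np.ndarray:
        return np.flatnonzero(self.occ)

    def add_strand(self, sequence: str, room: int) -> int:
        return self.strands.add(sequence, room, self.domains,
                                int(self.params.L_CDR))

    def room_flags(self) -> np.ndarray:
        """Per-room OR of the species bitmask over resident strands."""
        st = self.strands
        top = int(st.meta[1])
        out = np.zeros(self.R, np.uint8)
        sel = np.flatnonzero(st.alive[:top] & (st.flags[:top] != 0))
        np.bitwise_or.at(out, st.room[sel], st.flags[sel])
        return out


def init_world(p: ParameterSet, seed: int,
               species: list[SpeciesDef] | None = None) -> World:
    """Create a world with the initial materials scattered uniformly.

    ``T_NPPB`` nucleotide-precursor's precursors, ``T_FB`` fatty acids and
    ``T_GPB`` glycerophosphate precursors are each distributed independently
    and uniformly at random over the N*N rooms.  No protocells, no RNA.
    """
    w = World(p, species, seed)
    probs = np.full(w.R, 1.0 / w.R)
    w.pool[:, K.NPP] = w.rng.multinomial(int(p.T_NPPB), probs)
    w.pool[:, K.FA] = w.rng.multinomial(int(p.T_FB), probs)
    w.pool[:, K.GP] = w.rng.multinomial(int(p.T_GPB), probs)
    return w


def total_equivalents(w: World) -> tuple[int, int, int]:
    """(nucleotide, fatty-acid, glycerophosphate) material equivalents.

    * nucleotide equivalents: Npp + Np + Nt + every RNA residue (template and
      aligned substrates, free or intracellular);
    * fatty-acid equivalents: free + membrane FA, plus two per phospholipid
      (a phospholipid carries two tails);
    * glycerophosphate equivalents: Gp + G + one per phospholipid.

    These are the conserved totals of the closed system.
    """
    pool = w.pool
    st = w.strands
    top = int(st.meta[1])
    live = st.alive[:top]
    residues = int((st.length[:top][live] + st.dlen[:top][live]).sum())
    nuc = int(pool[:, [K.NPP, K.NP_, K.NTA, K.NTC, K.NTG, K.NTU]].sum()) + residues
    pl_total = int(pool[:, K.PL].sum() + w.mem_pl.sum())
    fa = int(pool[:, K.FA].sum() + w.mem_fa.sum()) + 2 * pl_total
    g = int(pool[:, [K.GP, K.G]].sum()) + pl_total
    return nuc, fa, g


def rpm(mem: Membrane) -> float:
    """Ratio of phospholipids in the membrane: 2*pl / (2*pl + fa).

    Counts tails: a phospholipid contributes two, a fatty acid one.
    """
    if mem.fa + mem.pl <= 0:
        raise ValueError("rpm undefined for an empty membrane")
    return 2.0 * mem.pl / (2.0 * mem.pl + mem.fa)


def classify_protocell(cell: Protocell, species: list[SpeciesDef]) -> set[str]:
    """Names of species whose characteristic domain occurs in the interior.

    A species is present iff some interior strand contains its domain as a
    contiguous substring; one strand may carry several domains.
    """
    out = set()
    for s in cell.strands:
        for sp in species:
            if sp.domain in s.sequence:
                out.add(sp.name)
    return out
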