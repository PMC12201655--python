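"""RNA events: probability formulas, ligation, template-directed synthesis."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribocell import _kernels as K
from ribocell.parameters import load_params
from ribocell.rna_dynamics import (attract_substrate, bond_break_prob,
                                   degrade_rna, random_ligation_step,
                                   reverse_complement, rna_move_prob,
                                   separation_prob, separate_duplex,
                                   template_ligate)
from ribocell.world import decode_seq, total_equivalents

from conftest import make_world, quiet_overrides


# --- closed-form probabilities ----------------------------------------------

@pytest.mark.parametrize("m,expected", [(1, 0.9), (4, 0.45), (81, 0.1)])
def test_rna_move_prob_zimm_scaling(m, expected, params):
    assert rna_move_prob(m, params) == pytest.approx(expected)


def test_rna_move_prob_rejects_zero_mass(params):
    with pytest.raises(ValueError):
        rna_move_prob(0, params)


@pytest.mark.parametrize("double,outside,expected", [
    (False, False, 1e-5),
    (False, True, 1e-4),
    (True, False, 1e-5 ** 1.5),
    (True, True, 1e-6),
])
def test_bond_break_prob(double, outside, expected, params):
    assert bond_break_prob(double, outside, params) == pytest.approx(expected)


def test_separation_prob_values_and_monotonicity(params):
    assert separation_prob(1, params) == pytest.approx(0.5)
    assert separation_prob(4, params) == pytest.approx(0.25)
    for n in range(1, 30):
        assert separation_prob(n + 1, params) < separation_prob(n, params)


@settings(derandomize=True, max_examples=50)
@given(m=st.integers(1, 10_000), n=st.integers(1, 10_000),
       p_mv=st.floats(0, 1), p_sp=st.floats(0, 1))
def test_probability_outputs_stay_in_unit_interval(m, n, p_mv, p_sp):
    p, _ = load_params({"P_MV": p_mv, "P_SP": p_sp})
    assert 0.0 <= rna_move_prob(m, p) <= 1.0
    assert 0.0 <= separation_prob(n, p) <= 1.0
    assert 0.0 <= bond_break_prob(True, True, p) <= 1.0


# --- random ligation ---------------------------------------------------------

def test_forced_ligation_of_two_nucleotides():
    w = make_world(**quiet_overrides(P_RL=1.0))
    w.pool[0, K.NTA] = 1
    w.pool[0, K.NTU] = 1
    random_ligation_step(w, seed=5)
    assert w.pool[0, K.NTA] == 0 and w.pool[0, K.NTU] == 0
    assert w.strands.n_alive == 1
    st_ = w.strands
    seq = decode_seq(st_.seq[0, :2])
    assert sorted(seq) == ["A", "U"]


def test_zero_rate_leaves_pool_untouched():
    w = make_world(**quiet_overrides(P_RL=0.0))
    w.pool[0, K.NTA] = 50
    random_ligation_step(w)
    assert w.pool[0, K.NTA] == 50 and w.strands.n_alive == 0


def _oracle_ligation_mean(k, p_rl, trials, rng):
    """Brute-force pairing process: every unordered pair fires with p_rl,
    realized in random order, at most one ligation per molecule."""
    pairs = list(itertools.combinations(range(k), 2))
    total = 0
    for _ in range(trials):
        fired = [pr for pr in pairs if rng.random() < p_rl]
        rng.shuffle(fired)
        used = set()
        for a, b in fired:
            if a not in used and b not in used:
                used.update((a, b))
                total += 1
    return total / trials


def test_ligation_count_matches_pair_enumeration_oracle(rng):
    k, p_rl, trials = 6, 0.05, 4000
    expected = _oracle_ligation_mean(k, p_rl, 20000, rng)
    got = 0
    for t in range(trials):
        w = make_world(**quiet_overrides(P_RL=p_rl), seed=t)
        w.pool[0, K.NTA] = k
        random_ligation_step(w, seed=t)
        got += k - int(w.pool[0, K.NTA]) - w.strands.n_alive
        # each ligation consumes 2 monomers into 1 strand
    got /= trials
    assert got == pytest.approx(expected, rel=0.15, abs=0.01)


# --- substrate attraction ----------------------------------------------------

def test_forced_complement_attraction():
    w = make_world(**quiet_overrides(P_AT=1.0))
    slot = w.add_strand("AAAAAAA", 0)
    w.pool[0, K.NTU] = 5
    assert attract_substrate(w, slot, seed=3)
    st_ = w.strands
    assert st_.dlen[slot] == 1
    assert st_.dseq[slot, st_.dstart[slot]] == 3  # U
    assert w.pool[0, K.NTU] == 4


def test_forced_false_pairing_never_complements():
    w = make_world(**quiet_overrides(P_AT=1.0, P_FP=1.0))
    slot = w.add_strand("AAAAAAA", 0)
    w.pool[0, K.NTA] = 3
    w.pool[0, K.NTC] = 3
    w.pool[0, K.NTG] = 3
    w.pool[0, K.NTU] = 3
    for trial in range(20):
        st_ = w.strands
        st_.dlen[slot] = 0
        st_.dstart[slot] = -1
        w.pool[0, K.NTA:K.NTU + 1] = 3
        assert attract_substrate(w, slot, seed=trial)
        assert st_.dseq[slot, st_.dstart[slot]] != 3  # never Watson-Crick U


def test_empty_pool_is_noop():
    w = make_world(**quiet_overrides(P_AT=1.0))
    slot = w.add_strand("AAAAAAA", 0)
    assert not attract_substrate(w, slot, seed=3)
    assert w.strands.dlen[slot] == 0


def test_short_chains_do_not_act_as_templates():
    w = make_world(**quiet_overrides(P_AT=1.0, P_RL=1.0))
    w.pool[0, K.NTA] = 1
    w.pool[0, K.NTU] = 1
    random_ligation_step(w, seed=1)
    slot = int(np.flatnonzero(w.strands.alive)[0])
    w.pool[0, K.NTA:K.NTU + 1] = 10
    assert not attract_substrate(w, slot, seed=2)


# --- template ligation & separation -----------------------------------------

def _aligned_template(w, seq, aligned, bonds=None):
    """Install a template with a manually aligned block for testing."""
    slot = w.add_strand(seq, 0)
    st_ = w.strands
    st_.dstart[slot] = 0
    st_.dlen[slot] = len(aligned)
    for i, b in enumerate(aligned):
        st_.dseq[slot, i] = "ACGU".index(b)
    if bonds:
        for j, v in enumerate(bonds):
            st_.dbond[slot, j] = v
    return slot


def test_forced_template_ligation_merges_adjacent_monomers():
    w = make_world(**quiet_overrides(P_TL=1.0))
    slot = _aligned_template(w, "AAAAAAA", "UU")
    assert template_ligate(w, slot, seed=1) == 1
    assert w.strands.dbond[slot, 0] == 1


def test_zero_template_ligation_changes_nothing():
    w = make_world(**quiet_overrides(P_TL=0.0))
    slot = _aligned_template(w, "AAAAAAA", "UU")
    assert template_ligate(w, slot, seed=1) == 0
    assert w.strands.dbond[slot, 0] == 0


def test_full_duplex_separation_releases_reverse_complement():
    w = make_world(**quiet_overrides())
    tmpl = "UUGAGCG"
    comp = reverse_complement(tmpl)
    # aligned bases at template positions are the per-position complements
    aligned = "".join({"A": "U", "U": "A", "C": "G", "G": "C"}[b] for b in tmpl)
    slot = _aligned_template(w, tmpl, aligned, bonds=[1] * 6)
    assert separate_duplex(w, slot, force=True)
    st_ = w.strands
    assert st_.dlen[slot] == 0
    released = [s for s in np.flatnonzero(st_.alive) if s != slot]
    assert len(released) == 1
    assert decode_seq(st_.seq[released[0], :7]) == comp


def test_zero_separation_probability_never_releases():
    w = make_world(**quiet_overrides(P_SP=0.0))
    slot = _aligned_template(w, "AAAAAAA", "UUUUUUU", bonds=[1] * 6)
    for s in range(50):
        assert not separate_duplex(w, slot, seed=s)


def test_ligated_partial_copy_stays_until_complete():
    # a ligated three-residue run is anchored; only the full chain leaves
    w = make_world(**quiet_overrides(P_SP=0.99))
    slot = _aligned_template(w, "AAAAAAA", "UUU", bonds=[1, 1])
    for s in range(50):
        separate_duplex(w, slot, seed=s)
    assert w.strands.dlen[slot] == 3


def test_lone_monomer_substrate_falls_off_at_p_sp():
    w = make_world(**quiet_overrides(P_SP=1.0))
    slot = _aligned_template(w, "AAAAAAA", "U")
    assert separate_duplex(w, slot, seed=1)
    assert w.strands.dlen[slot] == 0
    assert w.pool[0, K.NTU] == 1


# --- degradation -------------------------------------------------------------

def test_forced_bond_breaking_shatters_to_monomers():
    w = make_world(**quiet_overrides(P_BB=1.0))
    slot = w.add_strand("ACG", 0)
    n0 = total_equivalents(w)[0]
    degrade_rna(w, slot, seed=1)
    assert w.strands.n_alive == 0
    assert w.pool[0, K.NTA] == 1
    assert w.pool[0, K.NTC] == 1
    assert w.pool[0, K.NTG] == 1
    assert total_equivalents(w)[0] == n0


def test_end_decay_conserves_nucleotide_equivalents():
    w = make_world(**quiet_overrides(P_NDE=1.0))
    slot = w.add_strand("ACGUACG", 0)
    n0 = total_equivalents(w)[0]
    degrade_rna(w, slot, seed=1)
    st_ = w.strands
    assert st_.length[slot] == 5  # both single-stranded ends decayed
    assert decode_seq(st_.seq[slot, :5]) == "CGUAC"
    assert w.pool[0, K.NP_] == 2
    assert total_equivalents(w)[0] == n0


def _fragment_multiset_oracle(L, p, trials, rng):
    """Independent-bond-Bernoulli enumeration: distribution over sorted
    fragment-length tuples for a strand of length L."""
    from collections import Counter
    out = Counter()
    for _ in range(trials):
        cuts = rng.random(L - 1) < p
        frags, start = [], 0
        for j, c in enumerate(cuts):
            if c:
                frags.append(j + 1 - start)
                start = j + 1
        frags.append(L - start)
        out[tuple(sorted(frags))] += 1
    return out


def test_fragment_distribution_matches_bernoulli_oracle(rng):
    from collections import Counter
    L, p_bb, trials = 8, 0.3, 3000
    oracle = _fragment_multiset_oracle(L, p_bb, 60000, rng)
    got = Counter()
    for t in range(trials):
        # F_DO = 1: the strand sits in a naked room and the oracle models
        # the bare per-bond rate
        w = make_world(**quiet_overrides(P_BB=p_bb, F_DO=1.0), seed=t)
        slot = w.add_strand("ACGUACGU", 0)
        degrade_rna(w, slot, seed=t)
        st_ = w.strands
        frags = [int(st_.length[s]) for s in np.flatnonzero(st_.alive)]
        frags += [1] * int(w.pool[0, K.NTA:K.NTU + 1].sum())
        got[tuple(sorted(frags))] += 1
    # compare the most probable outcomes by frequency
    for key, n_oracle in oracle.most_common(6):
        p_exp = n_oracle / 60000
        p_got = got.get(key, 0) / trials
        assert p_got == pytest.approx(p_exp, abs=4 * np.sqrt(p_exp / trials) + 0.005)


# --- replication fidelity ----------------------------------------------------

def test_copy_of_copy_restores_original_sequence():
    """With no false pairing and ample monomers, the released complement is
    the exact reverse complement, and a second round restores the original."""
    from ribocell.engine_scenarios import step
    tmpl = "UUGAGCG"
    w = make_world(**quiet_overrides(
        P_AT=0.9, P_TL=0.2, P_SP=0.5, P_MV=0.0), N=2, seed=9)
    w.add_strand(tmpl, 0)
    w.pool[0, K.NTA:K.NTU + 1] = 200
    seqs = set()
    for _ in range(2000):
        step(w)
        st_ = w.strands
        for s in np.flatnonzero(st_.alive[:int(st_.meta[1])]):
            if st_.dlen[s] == 0:
                seqs.add(decode_seq(st_.seq[s, :int(st_.length[s])]))
    assert reverse_complement(tmpl) in seqs
    assert {s for s in seqs if len(s) == 7} <= {tmpl, reverse_complement(tmpl)}


def test_mismatch_frequency_tracks_false_pairing_rate():
    """Monte Carlo: with P_FP = 0.02 about 2% of incorporated residues
    mispair (uniform over the three wrong bases)."""
    w = make_world(**quiet_overrides(P_AT=1.0, P_FP=0.02), N=2, seed=4)
    slot = w.add_strand("AAAAAAA", 0)
    st_ = w.strands
    wrong = total = 0
    for t in range(4000):
        st_.dlen[slot] = 0
        st_.dstart[slot] = -1
        w.pool[0, K.NTA:K.NTU + 1] = 50
        if attract_substrate(w, slot, seed=None):
            total += 1
            if st_.dseq[slot, st_.dstart[slot]] != 3:
                wrong += 1
    assert total > 3500
    assert wrong / total == pytest.approx(0.02, abs=0.008)
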