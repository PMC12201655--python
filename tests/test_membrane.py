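"""Membrane assembly, amphiphile exchange, permeation, phospholipid turnover."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribocell import _kernels as K
from ribocell.membrane_dynamics import (amphiphile_leave_prob, form_membrane,
                                        membrane_formation_prob,
                                        permeation_prob, phospholipid_decay,
                                        phospholipid_synthesis,
                                        try_cross_membrane)
from ribocell.parameters import load_params
from ribocell.world import rpm, total_equivalents

from conftest import make_world, quiet_overrides


def test_membrane_formation_prob_values(params):
    assert membrane_formation_prob(200, params) == pytest.approx(0.1)
    assert membrane_formation_prob(199, params) == 0.0
    assert membrane_formation_prob(202, params) == pytest.approx(1 - 0.9 ** 3)
    assert membrane_formation_prob(0, params) == 0.0


def test_form_membrane_takes_all_amphiphiles():
    w = make_world()
    w.pool[4, K.FA] = 100
    w.pool[4, K.PL] = 60  # 220 tails: above threshold
    w.pool[4, K.NPP] = 7
    cell = form_membrane(w, 4)
    assert (cell.membrane.fa, cell.membrane.pl) == (100, 60)
    assert cell.membrane.b == 220
    assert w.pool[4, K.FA] == 0 and w.pool[4, K.PL] == 0
    assert cell.interior_counts["Npp"] == 7
    with pytest.raises(ValueError):
        form_membrane(w, 4)


def _cell(w, room=0, fa=300, pl=0, strands=()):
    w.occ[room] = True
    w.mem_fa[room] = fa
    w.mem_pl[room] = pl
    for s in strands:
        w.add_strand(s, room)
    return w.protocell(room)


def test_amphiphile_leave_prob_default_limits(params):
    w = make_world()
    cell = _cell(w)
    # no interior RNA, no phospholipids: the bare Table rates
    assert amphiphile_leave_prob("FA", cell, params) == pytest.approx(0.002)
    assert amphiphile_leave_prob("PL", cell, params) == pytest.approx(1e-4)


def test_amphiphile_leave_prob_phospholipid_suppression(params):
    w = make_world()
    cell = _cell(w, fa=320, pl=40)  # RPM = 80/400 = 0.2, z = 1 + 5*0.2 = 2
    assert rpm(cell.membrane) == pytest.approx(0.2)
    assert amphiphile_leave_prob("FA", cell, params) == pytest.approx(0.001)


def test_amphiphile_leave_prob_osmotic_suppression(params):
    w = make_world()
    free = amphiphile_leave_prob("FA", _cell(w), params)
    w2 = make_world()
    swollen = amphiphile_leave_prob(
        "FA", _cell(w2, strands=["ACGUACG"] * 30), params)
    assert swollen < free


@settings(derandomize=True, max_examples=40)
@given(ions=st.integers(0, 5000), pl=st.integers(0, 200),
       f_pl=st.floats(0, 50))
def test_leave_prob_monotone_and_bounded(ions, pl, f_pl):
    fa = 400 - 2 * pl
    b = fa + 2 * pl
    r = 2.0 * pl / b
    val = K.amphiphile_leave_prob(0.002, float(ions), float(b), f_pl, r)
    assert 0.0 <= val <= 0.002
    assert K.amphiphile_leave_prob(0.002, float(ions + 1), float(b), f_pl, r) <= val


def test_permeation_prob_printed_examples(params):
    w = make_world()
    cell = _cell(w, fa=200, pl=0)  # b = 200 = L_AM: s = 1, u = 1, v = 1
    assert permeation_prob("Nt", "out", cell, params) == pytest.approx(5e-5)
    assert permeation_prob("Nt", "in", cell, params) == pytest.approx(5e-5)


def test_permeation_transport_ribozyme_relief(params):
    w = make_world()
    # RPM = 0.5, one free TR strand inside
    cell = _cell(w, fa=200, pl=100, strands=["CUGCUAG"])
    v_tr = 1 + 20 * 0.5 / (1 + 1 * 100)
    assert v_tr == pytest.approx(1.0990, abs=1e-4)
    got = permeation_prob("Np", "out", cell, params)
    assert got == pytest.approx(0.05 / v_tr)
    # without TR the divisor is 1 + F_PP * RPM = 11
    w2 = make_world()
    cell2 = _cell(w2, fa=200, pl=100)
    assert permeation_prob("Np", "out", cell2, params) == pytest.approx(0.05 / 11)


def test_permeation_monotone_in_rpm_and_clamped(params):
    w = make_world()
    vals = []
    for pl in (0, 20, 50, 90):
        w2 = make_world()
        cell = _cell(w2, fa=400 - 2 * pl, pl=pl)
        for spn in ("Nt", "Np", "Npp", "Gp"):
            p_ = permeation_prob(spn, "in", cell, params)
            assert 0.0 <= p_ <= 1.0
        vals.append(permeation_prob("Npp", "in", cell, params))
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_try_cross_membrane_outcomes(params, rng):
    w = make_world()
    cell = _cell(w)
    assert try_cross_membrane("RNA", "in", cell, params, rng) == "bounced"
    assert try_cross_membrane("G", "in", cell, params, rng) == "bounced"
    joins = sum(try_cross_membrane("FA", "in", cell, params, rng) == "joined"
                for _ in range(2000))
    assert joins == pytest.approx(1800, abs=80)  # P_FJM = 0.9
    cell_s1 = _cell(make_world(), fa=200)  # b = L_AM: no volume boost
    crossings = sum(
        try_cross_membrane("Gp", "in", cell_s1, params, rng) == "permeated"
        for _ in range(2000))
    assert crossings == pytest.approx(1800, abs=80)  # P_GPP = 0.9 at RPM 0


def test_phospholipid_synthesis_forced(rng):
    w = make_world(**quiet_overrides(P_PF=1.0))
    _cell(w, fa=2, pl=0)
    w.pool[0, K.G] = 1
    before = total_equivalents(w)
    assert phospholipid_synthesis(w, 0, rng) == 1
    assert w.mem_fa[0] == 0 and w.mem_pl[0] == 1 and w.pool[0, K.G] == 0
    assert total_equivalents(w) == before


def test_phospholipid_synthesis_stoichiometry_guard(rng):
    w = make_world(**quiet_overrides(P_PF=1.0))
    _cell(w, fa=1, pl=0)
    w.pool[0, K.G] = 5
    assert phospholipid_synthesis(w, 0, rng) == 0
    assert w.mem_fa[0] == 1 and w.pool[0, K.G] == 5


def test_phospholipid_decay_membrane_and_free(rng):
    w = make_world(**quiet_overrides(P_PDM=1.0))
    _cell(w, fa=10, pl=4)
    before = total_equivalents(w)
    r0 = rpm(w.protocell(0).membrane)
    assert phospholipid_decay(w, 0, rng, "membrane") == 4
    assert w.mem_fa[0] == 18 and w.mem_pl[0] == 0
    assert w.pool[0, K.G] == 4  # heads drop into the interior
    assert total_equivalents(w) == before
    assert rpm(w.protocell(0).membrane) < r0

    w2 = make_world(**quiet_overrides(P_PD=1.0))
    w2.pool[3, K.PL] = 5
    before = total_equivalents(w2)
    assert phospholipid_decay(w2, 3, rng, "free") == 5
    assert w2.pool[3, K.FA] == 10 and w2.pool[3, K.G] == 5
    assert total_equivalents(w2) == before


def test_fa_and_pl_leave_equally_when_effects_off():
    """With F_PL = 0 and P_FLM = P_PLM the two species desorb at the same
    rate: the precondition of the spread-collapse experiment."""
    p, _ = load_params({"F_PL": 0.0, "P_FLM": 1e-4})
    w = make_world()
    cell = _cell(w, fa=200, pl=100)
    assert amphiphile_leave_prob("FA", cell, p) == \
        amphiphile_leave_prob("PL", cell, p)
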