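"""Synthetic SILAC generator: closed-form kinetics vs ODE, noise, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from mitopulse.digest import DigestSpec
from mitopulse.proteins import ProteinRecord
from mitopulse.simulate import (
    NO_NOISE,
    NoiseModel,
    PulseDesign,
    TurnoverParams,
    channel_amounts_chase,
    channel_amounts_psilac,
    default_psilac_scenario,
    generate_evidence,
)

PSILAC = PulseDesign(design_kind="psilac", pre_h=8, drug_h=16)
CHASE = PulseDesign(design_kind="pulse_chase", pulse_h=4, chase_h=4)


# ---------------------------------------------------------------------------
# ODE quadrature oracles: integrate dX/dt = s(t) - kd(t) X per cohort
# ---------------------------------------------------------------------------

def _integrate(rhs_windows, y0):
    """Integrate piecewise; the rate switch between windows is discontinuous."""
    y = y0
    t = 0.0
    for rhs, duration in rhs_windows:
        sol = solve_ivp(rhs, (t, t + duration), y, rtol=1e-11, atol=1e-14)
        assert sol.status == 0
        y = sol.y[:, -1]
        t += duration
    return y


def ode_psilac(p, d, drug_on):
    f = p.f if drug_on else 1.0
    kd2 = p.g * p.kd if drug_on else p.kd
    windows = [
        (lambda t, y: [-p.kd * y[0], p.s - p.kd * y[1]], d.pre_h),
        (lambda t, y: [-kd2 * y[0], p.s * f - kd2 * y[1]], d.drug_h),
    ]
    return _integrate(windows, [p.s / p.kd, 0.0])


def ode_chase(p, d, drug_on):
    f = p.f if drug_on else 1.0
    kd2 = p.g * p.kd if drug_on else p.kd
    windows = [
        (lambda t, y: [-p.kd * y[0], 0.0, p.s - p.kd * y[2]], d.pulse_h),
        # chase: pre-existing pool stays at baseline kd, new cohorts at kd2
        (lambda t, y: [-p.kd * y[0], p.s * f - kd2 * y[1], -kd2 * y[2]], d.chase_h),
    ]
    return _integrate(windows, [p.s / p.kd, 0.0, 0.0])


PARAM_GRID = [
    TurnoverParams(s=s, kd=kd, f=f, g=g)
    for s in (10.0, 500.0)
    for kd in (0.005, 0.05, 0.3)
    for f in (0.0, 0.2, 1.0)
    for g in (1.0, 3.0)
]


@pytest.mark.parametrize("drug_on", [True, False])
def test_psilac_closed_form_matches_ode(drug_on):
    for p in PARAM_GRID:
        expected = ode_psilac(p, PSILAC, drug_on)
        got = channel_amounts_psilac(p, PSILAC, drug_on)
        np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-9)


@pytest.mark.parametrize("drug_on", [True, False])
def test_chase_closed_form_matches_ode(drug_on):
    for p in PARAM_GRID:
        expected = ode_chase(p, CHASE, drug_on)
        got = channel_amounts_chase(p, CHASE, drug_on)
        np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-9)


# ---------------------------------------------------------------------------
# closed-form limits
# ---------------------------------------------------------------------------

def test_no_synthesis_no_prelabel_gives_zero_new():
    design = PulseDesign(design_kind="psilac", pre_h=0, drug_h=16)
    p = TurnoverParams(s=100, kd=0.05, f=0.0, g=1.0)
    _, new = channel_amounts_psilac(p, design, drug_on=True)
    assert new == pytest.approx(0.0, abs=1e-12)


def test_neutral_drug_equals_vehicle():
    p = TurnoverParams(s=100, kd=0.05, f=1.0, g=1.0)
    assert channel_amounts_psilac(p, PSILAC, True) == channel_amounts_psilac(p, PSILAC, False)
    assert channel_amounts_chase(p, CHASE, True) == channel_amounts_chase(p, CHASE, False)


def test_linear_accumulation_limit():
    """kd -> 0: the new cohort accumulates linearly, s*(t1 + f*t2)."""
    p = TurnoverParams(s=100.0, kd=1e-6, f=0.3, g=1.0)
    _, new = channel_amounts_psilac(p, PSILAC, drug_on=True)
    expected = p.s * (PSILAC.pre_h + p.f * PSILAC.drug_h)
    assert new == pytest.approx(expected, rel=1e-3)


def test_unchanged_degradation_means_equal_heavy():
    p = TurnoverParams(s=50, kd=0.1, f=0.2, g=1.0)
    h_drug = channel_amounts_chase(p, CHASE, True)[2]
    h_veh = channel_amounts_chase(p, CHASE, False)[2]
    assert h_drug == pytest.approx(h_veh, rel=1e-12)


def test_full_synthesis_block_empties_medium_channel():
    p = TurnoverParams(s=50, kd=0.1, f=0.0, g=2.0)
    assert channel_amounts_chase(p, CHASE, True)[1] == 0.0


def test_mg132_restores_baseline_degradation():
    p = TurnoverParams(s=50, kd=0.1, f=0.2, g=3.0)
    h_blocked = channel_amounts_chase(p, CHASE, True, proteasome_blocked=True)[2]
    h_vehicle = channel_amounts_chase(p, CHASE, False)[2]
    assert h_blocked == pytest.approx(h_vehicle, rel=1e-12)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        TurnoverParams(s=1, kd=0.0)
    with pytest.raises(ValueError):
        TurnoverParams(s=1, kd=0.1, g=0.5)
    with pytest.raises(ValueError):
        channel_amounts_psilac(TurnoverParams(s=1, kd=0.1), CHASE, True)


# ---------------------------------------------------------------------------
# evidence generation
# ---------------------------------------------------------------------------

def _tiny_scenario():
    proteins = [
        ProteinRecord(id=f"P{i}", sequence="MKAAAAARCCDDEEKFFGGHHKLLMMNNK" * 3)
        for i in range(3)
    ]
    params = {
        "P0": TurnoverParams(s=100, kd=0.02, f=0.1),
        "P1": TurnoverParams(s=50, kd=0.05),
        "P2": TurnoverParams(s=500, kd=0.01, f=0.5),
    }
    spec = DigestSpec(proteases=frozenset({"trypsin"}))
    return proteins, params, spec


def test_noiseless_peptide_ratios_are_exact():
    proteins, params, spec = _tiny_scenario()
    ev = generate_evidence(proteins, params, PSILAC, NO_NOISE, spec)
    for pid, p in params.items():
        _, new_cap = channel_amounts_psilac(p, PSILAC, True)
        _, new_ctl = channel_amounts_psilac(p, PSILAC, False)
        rows_r1 = ev[(ev.protein_id == pid) & (ev.replicate_id == "r1")]
        # replicate 1 unswapped: H carries the drug condition
        assert (rows_r1.intensity_H / rows_r1.intensity_M == new_cap / new_ctl).all()
        rows_r2 = ev[(ev.protein_id == pid) & (ev.replicate_id == "r2")]
        assert (rows_r2.intensity_M / rows_r2.intensity_H == new_cap / new_ctl).all()


def test_same_seed_reproducible_different_seed_not():
    proteins, params, spec = _tiny_scenario()
    noise_a = NoiseModel(seed=11)
    ev1 = generate_evidence(proteins, params, PSILAC, noise_a, spec)
    ev2 = generate_evidence(proteins, params, PSILAC, noise_a, spec)
    pd.testing.assert_frame_equal(ev1, ev2)
    ev3 = generate_evidence(proteins, params, PSILAC, NoiseModel(seed=12), spec)
    assert not ev1.equals(ev3)


def test_dropout_probability_monotone_decreasing():
    noise = NoiseModel()
    intensities = np.logspace(1, 9, 50)
    p = noise.dropout_probability(intensities)
    assert np.all(np.diff(p) <= 0)
    assert p[0] > 0.99 and p[-1] < 1e-4


def test_protein_without_observable_peptides_is_skipped(caplog):
    proteins = [ProteinRecord(id="SHORT", sequence="MK"),
                ProteinRecord(id="OK", sequence="MKAAAAAACCDDEEK")]
    params = {pid: TurnoverParams(s=10, kd=0.05) for pid in ("SHORT", "OK")}
    spec = DigestSpec(proteases=frozenset({"trypsin"}))
    ev = generate_evidence(proteins, params, PSILAC, NO_NOISE, spec)
    assert set(ev.protein_id) == {"OK"}


def test_simulated_ratio_distribution_centers_on_closed_form(rng):
    """With channel noise only, per-protein median log2 H/M is unbiased."""
    scenario = default_psilac_scenario(5, n_proteins=120, n_mt=0, n_orphans=0)
    ev = scenario.generate()
    truth = {pid: p for pid, p in scenario.params.items()}
    r1 = ev[ev.replicate_id == "r1"]
    errors = []
    for pid, group in r1.groupby("protein_id"):
        ok = (group.intensity_H > 0) & (group.intensity_M > 0)
        if ok.sum() < 3:
            continue
        observed = np.median(np.log2(group.intensity_H[ok] / group.intensity_M[ok]))
        p = truth[pid]
        expected = np.log2(
            channel_amounts_psilac(p, scenario.design, True)[1]
            / channel_amounts_psilac(p, scenario.design, False)[1]
        )
        errors.append(observed - expected)
    errors = np.asarray(errors)
    se = errors.std(ddof=1) / np.sqrt(errors.size)
    assert abs(errors.mean()) < 3 * se + 0.02


def test_chase_condition_runs_have_fixed_channel_roles():
    proteins, params, spec = _tiny_scenario()
    design = PulseDesign(design_kind="pulse_chase", n_replicates=1,
                         conditions=("CAP", "DMSO"), swapped_replicates=frozenset())
    ev = generate_evidence(proteins, params, design, NO_NOISE, spec)
    assert set(ev.condition) == {"CAP", "DMSO"}
    for pid, p in params.items():
        light, medium, heavy = channel_amounts_chase(p, design, True)
        row = ev[(ev.protein_id == pid) & (ev.condition == "CAP")].iloc[0]
        factor = row.intensity_L / light
        assert row.intensity_M == pytest.approx(medium * factor)
        assert row.intensity_H == pytest.approx(heavy * factor)
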