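"""Equilibrium solver: oracles, conservation laws, and regime structure."""

import numpy as np
import pandas as pd
import pytest

from hgstrat.speciation import (
    Component, SpeciesDef, SpeciationTableau, SpeciationInput,
    default_tableau, thiol_from_doc, solve_equilibrium, diss_sulfide_fraction,
    regime_scan, speciate_profile, representative_input,
)


# ---------------------------------------------------------------------------
# thiol sites from DOC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("doc, expected", [
    (0.0, 0.0),
    (12.011, 1.5e-6),        # 0.15 % of 1 mmol C/L
    (4.0, 0.0015 * 4 / 12.011 * 1e-3),
])
def test_thiol_from_doc(doc, expected):
    assert thiol_from_doc(doc) == pytest.approx(expected, rel=1e-12)


def test_thiol_from_doc_rejects_negative():
    with pytest.raises(ValueError):
        thiol_from_doc(-1.0)


# ---------------------------------------------------------------------------
# toy tableaus with independent oracles
# ---------------------------------------------------------------------------

def _toy(components, species):
    return SpeciationTableau(tuple(components), tuple(species), "toy")


def test_solver_matches_quadratic_closed_form():
    """1 component M with a dimer M2: T = m + 2*K*m^2 has a closed form."""
    K, T = 1e4, 1e-3
    tab = _toy(
        [Component("M", "total", T)],
        [SpeciesDef("M2", (2,), np.log10(K))],
    )
    res = solve_equilibrium(tab)
    m_exact = (-1 + np.sqrt(1 + 8 * K * T)) / (4 * K)
    assert res.converged
    assert res.free_conc["M"] == pytest.approx(m_exact, rel=1e-9)
    assert res.species_conc["M2"] == pytest.approx(K * m_exact**2, rel=1e-9)


def test_solver_matches_two_component_closed_form():
    """M + L <-> ML: the complex concentration solves a quadratic exactly."""
    K, Tm, Tl = 10**6.5, 2e-6, 5e-7
    tab = _toy(
        [Component("M", "total", Tm), Component("L", "total", Tl)],
        [SpeciesDef("ML", (1, 1), np.log10(K))],
    )
    # K*(Tm-x)*(Tl-x) = x  ->  K x^2 - (K(Tm+Tl)+1) x + K Tm Tl = 0
    a, b, c = K, -(K * (Tm + Tl) + 1), K * Tm * Tl
    x = (-b - np.sqrt(b * b - 4 * a * c)) / (2 * a)
    res = solve_equilibrium(tab)
    assert res.converged
    assert res.species_conc["ML"] == pytest.approx(x, rel=1e-9)
    assert res.free_conc["M"] == pytest.approx(Tm - x, rel=1e-9)


def test_solver_matches_grid_refinement_oracle():
    """3 components, two competing ligands; oracle = bracket refinement on m.

    For fixed free m the ligand balances are explicit, so the metal residual
    is monotone in m and the root can be found by interval refinement
    without any Newton machinery.
    """
    K1, K2 = 10**5.0, 10**7.2
    Tm, T1, T2 = 1e-6, 3e-6, 8e-7
    tab = _toy(
        [Component("M", "total", Tm), Component("L1", "total", T1),
         Component("L2", "total", T2)],
        [SpeciesDef("ML1", (1, 1, 0), np.log10(K1)),
         SpeciesDef("ML2", (1, 0, 1), np.log10(K2))],
    )

    def metal_residual(m):
        l1 = T1 / (1 + K1 * m)
        l2 = T2 / (1 + K2 * m)
        return m + K1 * m * l1 + K2 * m * l2 - Tm

    lo, hi = 1e-30, Tm
    for _ in range(200):  # bisection to machine precision
        mid = np.sqrt(lo * hi)
        if metal_residual(mid) > 0:
            hi = mid
        else:
            lo = mid
    m_oracle = np.sqrt(lo * hi)

    res = solve_equilibrium(tab)
    assert res.converged
    assert res.free_conc["M"] == pytest.approx(m_oracle, rel=1e-6)


# ---------------------------------------------------------------------------
# conservation and structural invariants on the shipped tableau
# ---------------------------------------------------------------------------

def test_shipped_tableau_shape(tableau):
    assert len(tableau.components) == 7
    assert len(tableau.species) == 24
    assert sum(s.phase == "solid" for s in tableau.species) == 1


def _mass_balance_errors(tableau, res, inp):
    """Recompute each total-mode balance from the reported concentrations."""
    totals = {"Hg2": inp.hg2_total, "MeHg": inp.mehg_total,
              "HS": inp.h2s_total, "RS": thiol_from_doc(inp.doc)}
    errs = {}
    for comp, T in totals.items():
        if T == 0:
            continue
        j = tableau.component_index(comp)
        acc = res.free_conc[comp]
        for sp in tableau.species:
            if sp.stoichiometry[j] == 0:
                continue
            amount = res.solid_amount if sp.phase == "solid" else res.species_conc[sp.name]
            acc += sp.stoichiometry[j] * amount
        errs[comp] = abs(acc - T) / T
    return errs


def test_mass_balance_on_random_inputs(tableau, rng):
    for _ in range(60):
        inp = SpeciationInput(
            hg2_total=10 ** rng.uniform(-13, -10),
            mehg_total=10 ** rng.uniform(-13, -11),
            h2s_total=float(rng.choice([0.0, 1.0])) * 10 ** rng.uniform(-9, -4),
            doc=rng.uniform(0.5, 10.0),
        )
        res = solve_equilibrium(tableau, inp)
        assert res.converged
        for comp, err in _mass_balance_errors(tableau, res, inp).items():
            assert err < 1e-8, f"{comp} balance off by {err}"
        assert sum(res.hg_fractions.values()) == pytest.approx(1.0, abs=1e-8)
        assert all(v >= 0 for v in res.species_conc.values())


def test_no_sulfide_means_no_sulfide_species(tableau):
    res = solve_equilibrium(tableau, SpeciationInput(2.4e-12, 1e-12, 0.0, 4.0))
    assert res.converged
    assert res.diss_sulfide_fraction == 0.0
    # Hg lives on thiol and chloride/hydroxide pools only
    assert res.hg_fractions.get("Hg(SR)2", 0) > 0.9
    assert res.species_conc["Hg(SH)2"] == 0.0


def test_all_zero_hg_is_valid(tableau):
    res = solve_equilibrium(tableau, SpeciationInput(0.0, 0.0, 1e-5, 4.0))
    assert res.converged
    assert res.hg_fractions == {}
    assert res.diss_sulfide_fraction == 0.0
    assert res.species_conc["Hg(SH)2"] == 0.0


def test_sulfide_species_distribution_invariant_to_h2s(tableau):
    """Above the solid's stability window the three dissolved Hg-sulfide
    species keep a fixed pH-governed share of their pool."""
    shares = []
    for h2s in (1e-6, 1e-5, 1e-4):
        res = solve_equilibrium(tableau, representative_input(h2s))
        assert res.converged
        pool = {k: res.hg_fractions[k] for k in ("HgS2H-", "Hg(SH)2", "HgS2-2")}
        tot = sum(pool.values())
        shares.append({k: 100 * v / tot for k, v in pool.items()})
    for a in shares[1:]:
        for k in a:
            assert abs(a[k] - shares[0][k]) < 0.1  # percentage points


def test_diss_sulfide_fraction_monotone_in_h2s(tableau):
    h2s = np.logspace(-10, -4, 25)
    fracs = []
    for h in h2s:
        res = solve_equilibrium(tableau, representative_input(float(h)))
        assert res.converged
        fracs.append(res.diss_sulfide_fraction)
    assert np.all(np.diff(fracs) >= -1e-10)


def test_solid_phase_complementarity(tableau):
    """Either the solid is present at saturation (SI ~ 0) or absent and
    undersaturated (SI <= 0)."""
    for h2s in (0.0, 1e-9, 3e-8, 1e-7, 1e-5):
        res = solve_equilibrium(tableau, representative_input(h2s))
        assert res.converged
        if res.solid_amount > 0:
            assert abs(res.saturation_index) < 1e-8
        else:
            assert res.saturation_index <= 1e-9


def test_diss_sulfide_fraction_accessor(tableau):
    res = solve_equilibrium(tableau, representative_input(1e-5))
    val = diss_sulfide_fraction(res)
    manual = sum(res.hg_fractions[k] for k in ("HgS2H-", "Hg(SH)2", "HgS2-2"))
    assert val == pytest.approx(manual, rel=1e-12)
    res.converged = False
    with pytest.raises(ValueError):
        diss_sulfide_fraction(res)


# ---------------------------------------------------------------------------
# regime scan
# ---------------------------------------------------------------------------

def test_regime_scan_zero_sulfide_grid_single_regime(tableau):
    scan = regime_scan(tableau, representative_input(),
                       [0.0, 1e-12, 2e-12, 5e-12])
    assert set(scan.dominant) == {"thiol-bound"}
    assert scan.crossovers == []


def test_regime_scan_ordering_and_crossovers(tableau):
    grid = np.logspace(-10, -4.5, 60)
    scan = regime_scan(tableau, representative_input(), grid)
    assert scan.excluded == []
    # thiol -> solid -> dissolved sulfide with increasing H2S
    seen = list(dict.fromkeys(scan.dominant))
    assert seen == ["thiol-bound", "HgS(s)", "dissolved-sulfide"]
    (lo_from, lo_to, lo), (hi_from, hi_to, hi) = scan.crossovers
    assert (lo_from, lo_to) == ("thiol-bound", "HgS(s)")
    assert (hi_from, hi_to) == ("HgS(s)", "dissolved-sulfide")
    assert 0.003e-6 / 2 < lo < 0.003e-6 * 2
    assert 0.25e-6 / 2 < hi < 0.25e-6 * 2


def test_regime_scan_validates_grid(tableau):
    with pytest.raises(ValueError):
        regime_scan(tableau, representative_input(), [1e-9, 1e-8])
    with pytest.raises(ValueError):
        regime_scan(tableau, representative_input(), [1e-8, 1e-9, 1e-7])


# ---------------------------------------------------------------------------
# profile driver
# ---------------------------------------------------------------------------

def test_speciate_profile_single_row_equals_direct(tableau):
    profile = pd.DataFrame([{
        "depth_m": 100.0, "hgt_fM": 2000.0, "mehg_fM": 1000.0,
        "h2s_uM": 10.0, "doc_mgL": 4.0,
    }])
    table = speciate_profile(tableau, profile)
    direct = solve_equilibrium(tableau, SpeciationInput.from_observations(
        2000e-15, 1000e-15, 10e-6, 4.0))
    assert len(table) == 1
    assert bool(table.loc[0, "valid"]) and bool(table.loc[0, "converged"])
    assert table.loc[0, "diss_sulfide_fraction"] == pytest.approx(
        direct.diss_sulfide_fraction, rel=1e-10)


def test_speciate_profile_flags_inverted_hg(tableau):
    profile = pd.DataFrame([
        {"depth_m": 10.0, "hgt_fM": 500.0, "mehg_fM": 800.0,
         "h2s_uM": 0.0, "doc_mgL": 4.0},
        {"depth_m": 20.0, "hgt_fM": 800.0, "mehg_fM": 100.0,
         "h2s_uM": 0.0, "doc_mgL": 4.0},
    ])
    table = speciate_profile(tableau, profile)
    assert not bool(table.loc[0, "valid"])
    assert "HgT" in table.loc[0, "error"]
    assert bool(table.loc[1, "valid"])


def test_speciate_profile_empty(tableau):
    table = speciate_profile(tableau, pd.DataFrame(
        columns=["depth_m", "hgt_fM", "mehg_fM", "h2s_uM", "doc_mgL"]))
    assert table.empty


def test_speciate_profile_monotone_below_chemocline(tableau, by15_dataset):
    """Dissolved-sulfide availability rises monotonically with depth below
    the chemocline of an extended-redoxcline synthetic column."""
    prof = by15_dataset.profile
    table = speciate_profile(tableau, prof)
    below = table[prof["depth_m"] >= 80.0]
    vals = below["diss_sulfide_fraction"].to_numpy()
    assert np.all(np.diff(vals) >= -1e-9)
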