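"""Screened-Coulomb deprotonation potentials and constant-pH titration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antiport import titration as ti
from antiport import toy_system as ts


def _structure_with_probe(distance, probe_charge=-1.0, protonated_ext=True):
    """Minimal toy: one protonated carboxylate site plus a probe charge at
    ``distance`` Angstrom from the titratable proton, along z."""
    geom = ts.GeometryParams(glu_ext_protonated=protonated_ext,
                             glu_int_protonated=False, glu_o_separation=40.0)
    snap = ts.build_snapshot((0.0, 0.0), geom)
    # drop the distant intracellular glutamate and the chlorides: keep the
    # extracellular site and insert a single probe
    keep = np.array([rn == "GLU" and rid == 2
                     for rn, rid in zip(snap.resnames, snap.resids)])
    s = ts.Structure(
        ids=snap.ids[keep], elements=[e for e, k in zip(snap.elements, keep) if k],
        names=[n for n, k in zip(snap.names, keep) if k],
        resnames=[r for r, k in zip(snap.resnames, keep) if k],
        resids=snap.resids[keep], charges=snap.charges[keep],
        radii=snap.radii[keep], xyz=snap.xyz[keep],
        site_tags={"glu_ext_carboxylate": snap.site_tags["glu_ext_carboxylate"],
                   "titratable_proton": snap.site_tags["titratable_proton"]},
        protonated={"glu_ext_carboxylate": True},
        site_charge_states={"glu_ext_carboxylate":
                            snap.site_charge_states["glu_ext_carboxylate"]},
    )
    h_pos = s.xyz[s.index_of(s.site_tags["titratable_proton"][0])]
    probe_id = int(s.ids.max()) + 1
    s.ids = np.concatenate([s.ids, [probe_id]])
    s.elements.append("CL")
    s.names.append("CLA")
    s.resnames.append("CLA")
    s.resids = np.concatenate([s.resids, [9]])
    s.charges = np.concatenate([s.charges, [probe_charge]])
    s.radii = np.concatenate([s.radii, [1.81]])
    s.xyz = np.vstack([s.xyz, h_pos + np.array([0.0, 0.0, -distance])])
    return s


def brute_force_ddg(structure, site, params):
    """Independent all-pairs closed-form oracle (plain Python loops)."""
    states = structure.site_charge_states[site]
    site_ids = set(states["protonated"]) | set(states["deprotonated"])
    kappa = params.kappa
    total = 0.0
    for aid in sorted(site_ids):
        dq = states["deprotonated"].get(aid, 0.0) - states["protonated"].get(aid, 0.0)
        if aid not in set(structure.ids.tolist()):
            continue
        pi = structure.xyz[structure.index_of(aid)]
        for j, bid in enumerate(structure.ids.tolist()):
            if bid in site_ids:
                continue
            r = math.dist(pi, structure.xyz[j])
            total += 332.06 * dq * structure.charges[j] * math.exp(-kappa * r) / (params.dielectric * r)
    return total


class TestDeprotonationPotential:
    def test_no_environment_gives_zero(self):
        geom = ts.GeometryParams(glu_int_protonated=False)
        snap = ts.build_snapshot((0.0, 0.0), geom)
        keep = np.array([rid == 2 for rid in snap.resids])
        s = _structure_with_probe(5.0)
        # remove the probe again -> model-compound limit
        s.ids = s.ids[:-1]
        s.elements.pop()
        s.names.pop()
        s.resnames.pop()
        s.resids = s.resids[:-1]
        s.charges = s.charges[:-1]
        s.radii = s.radii[:-1]
        s.xyz = s.xyz[:-1]
        assert ti.deprotonation_potential(s, "glu_ext_carboxylate") == 0.0

    def test_single_anion_hand_computed(self):
        """One -1 e probe at 5 A from the proton, eps = 10, kappa = 0:
        matches the two-state Coulomb difference and penalizes
        deprotonation (positive sign)."""
        params = ti.ElectrostaticParams(dielectric=10.0, ionic_strength=0.0)
        s = _structure_with_probe(5.0)
        ddg = ti.deprotonation_potential(s, "glu_ext_carboxylate", params)
        expect = brute_force_ddg(s, "glu_ext_carboxylate", params)
        assert ddg == pytest.approx(expect, rel=1e-12)
        assert ddg > 0.0

    def test_matches_oracle_on_random_structures(self):
        """All-pairs closed-form agreement to 1e-10 relative on random toy
        boxes (screened, eps and I at defaults)."""
        params = ti.ElectrostaticParams()
        for seed in range(20):
            s = ts.random_water_box(n_waters=8, box=14.0, seed=seed)
            for site in ("glu_ext_carboxylate", "glu_int_carboxylate"):
                ddg = ti.deprotonation_potential(s, site, params)
                expect = brute_force_ddg(s, site, params)
                assert ddg == pytest.approx(expect, rel=1e-10, abs=1e-12)

    def test_overlapping_environment_rejected(self):
        s = _structure_with_probe(0.3)
        with pytest.raises(ValueError, match="overlap"):
            ti.deprotonation_potential(s, "glu_ext_carboxylate")

    def test_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation
        params = ti.ElectrostaticParams()
        s = _structure_with_probe(5.0)
        ref = ti.effective_pka(s, "glu_ext_carboxylate", params)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.2]).as_matrix()
        s.xyz = s.xyz @ rot.T + np.array([3.0, -7.0, 11.0])
        moved = ti.effective_pka(s, "glu_ext_carboxylate", params)
        assert moved == pytest.approx(ref, rel=1e-10)


class TestEffectivePka:
    def test_zero_shift_returns_reference(self):
        params = ti.ElectrostaticParams(pka_ref=4.25)
        s = _structure_with_probe(5.0, probe_charge=0.0)
        assert ti.effective_pka(s, "glu_ext_carboxylate", params) \
            == pytest.approx(4.25)

    def test_ln10_kt_shift_is_one_unit(self):
        params = ti.ElectrostaticParams(pka_ref=4.25)
        ddg = math.log(10.0) * params.kt_kcal
        assert params.pka_ref + ddg / (math.log(10.0) * params.kt_kcal) \
            == pytest.approx(5.25)

    def test_approaching_anion_raises_pka(self):
        """pKa strictly increases as a -1 e anion approaches the protonated
        site from 8 to 3 A."""
        params = ti.ElectrostaticParams()
        pkas = [ti.effective_pka(_structure_with_probe(d), "glu_ext_carboxylate", params)
                for d in np.linspace(8.0, 3.0, 11)]
        assert all(b > a for a, b in zip(pkas, pkas[1:]))

    def test_added_negative_charge_raises_ddg(self):
        """Monotone superposition: inserting any extra negative charge
        increases the deprotonation cost."""
        params = ti.ElectrostaticParams()
        rng = np.random.default_rng(5)
        base = _structure_with_probe(6.0)
        ref = ti.deprotonation_potential(base, "glu_ext_carboxylate", params)
        for _ in range(5):
            s = _structure_with_probe(6.0)
            pos = rng.uniform(-10, 10, 3)
            s.ids = np.concatenate([s.ids, [int(s.ids.max()) + 1]])
            s.elements.append("CL")
            s.names.append("CLA")
            s.resnames.append("CLA")
            s.resids = np.concatenate([s.resids, [20]])
            s.charges = np.concatenate([s.charges, [-0.5]])
            s.radii = np.concatenate([s.radii, [1.81]])
            s.xyz = np.vstack([s.xyz, s.xyz[0] + pos])
            try:
                val = ti.deprotonation_potential(s, "glu_ext_carboxylate", params)
            except ValueError:
                continue  # random position clashed with the site
            assert val > ref - 1e-12


class TestTitration:
    def test_fraction_half_at_planted_pka(self):
        pka = 5.0
        curve = ti.titration_curve(lambda ph: math.log(10.0) * (pka - ph),
                                   np.linspace(3.0, 7.0, 9), n_steps=20_000, seed=1)
        i = int(np.argmin(np.abs(curve.ph_values - pka)))
        assert curve.ph_values[i] == pka
        frac = curve.deprotonated_fraction[i]
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_planted_pka_recovered(self):
        """Planted pKa 4.8, eight pH windows spanning +-2 units, 1e5 steps:
        the Henderson-Hasselbalch fit lands within 0.1."""
        pka = 4.8
        curve = ti.titration_curve(lambda ph: math.log(10.0) * (pka - ph),
                                   np.linspace(2.8, 6.8, 8), n_steps=100_000, seed=2)
        assert curve.fitted_pka == pytest.approx(4.8, abs=0.1)
        assert curve.hill_coefficient == pytest.approx(1.0, abs=0.1)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            ti.titration_curve(lambda ph: 0.0, [4.0, 5.0, 6.0], n_steps=1000, seed=0)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            ti.titration_curve(lambda ph: 0.0, np.linspace(3, 7, 8), n_steps=10, seed=0)


class TestFitHH:
    def test_exact_data_recovered(self):
        ph = np.linspace(2.0, 7.0, 12)
        f = 1.0 / (1.0 + 10.0 ** (4.25 - ph))
        pka, n = ti.fit_hh(ph, f)
        assert pka == pytest.approx(4.25, abs=1e-8)
        assert n == pytest.approx(1.0, abs=1e-8)

    def test_hill_coefficient_recovered(self):
        ph = np.linspace(2.0, 7.0, 12)
        f = 1.0 / (1.0 + 10.0 ** (0.8 * (4.5 - ph)))
        pka, n = ti.fit_hh(ph, f)
        assert pka == pytest.approx(4.5, abs=1e-8)
        assert n == pytest.approx(0.8, abs=1e-8)

    def test_noisy_data_within_tenth(self):
        """Monte-Carlo over many seeds: sigma = 0.02 noise keeps the fitted
        pKa within 0.1 of truth."""
        ph = np.linspace(2.5, 6.5, 8)
        clean = 1.0 / (1.0 + 10.0 ** (4.4 - ph))
        errs = []
        for seed in range(100):
            noisy = np.clip(clean + np.random.default_rng(seed).normal(0, 0.02, ph.size),
                            0.0, 1.0)
            pka, _ = ti.fit_hh(ph, noisy)
            errs.append(abs(pka - 4.4))
        assert max(errs) < 0.1

    def test_degenerate_data_flagged(self):
        ph = np.linspace(2, 7, 8)
        with pytest.raises(ValueError, match="degenerate"):
            ti.fit_hh(ph, np.zeros(8))
        with pytest.raises(ValueError, match="degenerate"):
            ti.fit_hh(ph, np.ones(8))

    @settings(deadline=None, max_examples=30)
    @given(st.floats(3.0, 6.0), st.floats(0.5, 1.5))
    def test_roundtrip_property(self, pka, n):
        ph = np.linspace(1.0, 8.0, 15)
        f = 1.0 / (1.0 + 10.0 ** (n * (pka - ph)))
        got_pka, got_n = ti.fit_hh(ph, f)
        assert got_pka == pytest.approx(pka, abs=1e-6)
        assert got_n == pytest.approx(n, abs=1e-6)


def test_debye_kappa_physiological_value():
    """kappa for 0.15 M in water (eps 78.5, 298 K) is ~0.127 1/A
    (Debye length ~7.9 A), the textbook value."""
    kappa = ti.debye_kappa(0.15, 78.5, 298.0)
    assert kappa == pytest.approx(0.127, abs=0.005)
    assert ti.debye_kappa(0.0, 10.0) == 0.0
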