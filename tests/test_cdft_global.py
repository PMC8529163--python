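import math

import pytest
from hypothesis import given, settings, strategies as st

from cdftprof.cdft_global import (GlobalDescriptors, HardnessError, IonizationData,
                                  descriptors_to_ia, electrophilicity_class,
                                  global_descriptors, hardness_ranking, kid_check,
                                  vertical_ia_delta_scf, vertical_ia_koopmans)
from cdftprof.chem_io import SpeciesRecord, SpeciesTriplet
from cdftprof.synthetic import PAPER_LIGAND_IA, gen_species

# strategy: valid (I, A) pairs with a non-degenerate gap
ia_pairs = st.tuples(
    st.floats(min_value=0.5, max_value=15.0),
    st.floats(min_value=-2.0, max_value=12.0),
).filter(lambda p: p[0] - p[1] > 1e-3)


def _neutral(eps_homo, eps_lumo, e_total=None, lig="L"):
    return SpeciesRecord(lig, 0, 1, eps_homo=eps_homo, eps_lumo=eps_lumo, e_total=e_total)


def _triplet(eps_homo, eps_lumo, e_n=-120.0, e_cat=None, e_an=None, lig="L"):
    # KID-consistent totals: E(N-1) = E(N) + I = E(N) - eps_homo,
    # E(N+1) = E(N) - A = E(N) + eps_lumo
    e_cat = e_n - eps_homo if e_cat is None else e_cat
    e_an = e_n + eps_lumo if e_an is None else e_an
    return SpeciesTriplet(
        neutral=_neutral(eps_homo, eps_lumo, e_total=e_n, lig=lig),
        cation=SpeciesRecord(lig, 1, 2, e_total=e_cat),
        anion=SpeciesRecord(lig, -1, 2, e_total=e_an),
    )


class TestVerticalIA:
    def test_koopmans_negates_frontier_energies(self):
        ia = vertical_ia_koopmans(_neutral(-6.0241, -1.7554))
        assert ia.I == pytest.approx(6.0241)
        assert ia.A == pytest.approx(1.7554)
        assert ia.method == "koopmans"

    def test_koopmans_trivial_gap(self):
        ia = vertical_ia_koopmans(_neutral(-1.0, 0.0))
        assert (ia.I, ia.A) == (1.0, 0.0)

    def test_degenerate_frontier_energies_rejected_at_record_level(self):
        with pytest.raises(ValueError):
            _neutral(-5.0, -5.0)

    def test_delta_scf_direct_differences(self):
        t = _triplet(-6.0, -1.0, e_n=-100.0, e_cat=-93.5, e_an=-101.2)
        ia = vertical_ia_delta_scf(t)
        assert ia.I == pytest.approx(6.5)
        assert ia.A == pytest.approx(1.2)
        assert ia.method == "delta_scf"

    def test_delta_scf_missing_total_names_species(self):
        t = _triplet(-6.0, -1.0)
        broken = SpeciesTriplet(
            neutral=t.neutral,
            cation=SpeciesRecord("L", 1, 2, e_total=None),
            anion=t.anion)
        with pytest.raises(ValueError, match="cation"):
            vertical_ia_delta_scf(broken)

    def test_delta_scf_degenerate_ordering_rejected(self):
        # E(N-1) below E(N) makes I negative, below any A >= 0
        t = _triplet(-6.0, -1.0, e_n=-100.0, e_cat=-100.5, e_an=-101.2)
        with pytest.raises(HardnessError):
            vertical_ia_delta_scf(t)

    def test_koopmans_equals_delta_scf_on_consistent_triplet(self):
        for lig, (I, A) in PAPER_LIGAND_IA.items():
            t = _triplet(-I, -A, lig=lig)
            k = vertical_ia_koopmans(t.neutral)
            d = vertical_ia_delta_scf(t)
            assert d.I == pytest.approx(k.I, abs=1e-12)
            assert d.A == pytest.approx(k.A, abs=1e-12)


class TestGlobalDescriptors:
    @pytest.mark.parametrize("lig, expected", [
        ("Rutine", dict(chi=4.1346, eta=4.1184, omega=2.0754, S=0.2428,
                        omega_minus=6.4756, omega_plus=2.3410, net=8.8166)),
        ("Chloramphenicol Monoglucoronide",
         dict(chi=5.2081, eta=4.2387, omega=3.1996,
              omega_minus=9.2682, omega_plus=4.0601, net=13.3283)),
        ("Carbenicillin", dict(chi=3.8718, eta=5.6238, omega=1.3328, S=0.1778,
                               omega_minus=4.9530, omega_plus=1.0812, net=6.0341)),
    ])
    def test_published_panel_reproduced_from_implied_ia(self, lig, expected):
        I, A = PAPER_LIGAND_IA[lig]
        gd = global_descriptors(IonizationData(I=I, A=A, method="koopmans"))
        for key, val in expected.items():
            attr = {"net": "net_electrophilicity"}.get(key, key)
            assert getattr(gd, attr) == pytest.approx(val, abs=0.005), (lig, key)

    def test_exact_fractions(self):
        gd = global_descriptors(IonizationData(I=2.0, A=0.0, method="koopmans"))
        assert gd.chi == 1.0
        assert gd.eta == 2.0
        assert gd.omega == 0.25
        assert gd.S == 0.5
        assert gd.omega_minus == pytest.approx(1.125)
        assert gd.omega_plus == pytest.approx(0.125)
        assert gd.net_electrophilicity == pytest.approx(1.25)
        assert gd.omega_minus - gd.omega_plus == pytest.approx(gd.chi)

    def test_degenerate_gap_raises(self):
        with pytest.raises(HardnessError):
            IonizationData(I=1.0, A=1.0, method="koopmans")

    @settings(max_examples=200, deadline=None)
    @given(ia_pairs)
    def test_algebraic_identities(self, pair):
        I, A = pair
        gd = global_descriptors(IonizationData(I=I, A=A, method="koopmans"))
        assert gd.omega == pytest.approx(gd.chi**2 / (2 * gd.eta), rel=1e-10)
        assert gd.S * gd.eta == pytest.approx(1.0, rel=1e-10)
        assert gd.net_electrophilicity == pytest.approx(
            gd.omega_minus + gd.omega_plus, rel=1e-10)
        assert gd.omega_minus - gd.omega_plus == pytest.approx(gd.chi, rel=1e-9, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(ia_pairs)
    def test_round_trip_to_ionization_data(self, pair):
        I, A = pair
        gd = global_descriptors(IonizationData(I=I, A=A, method="koopmans"))
        back = descriptors_to_ia(gd)
        assert back.I == pytest.approx(I, rel=1e-12, abs=1e-12)
        assert back.A == pytest.approx(A, rel=1e-12, abs=1e-12)


class TestElectrophilicityClass:
    @pytest.mark.parametrize("omega, expected", [
        (2.0754, "strong"),    # published strong electrophile
        (1.3328, "moderate"),  # the one published moderate case
        (0.5, "marginal"),
        (1.5, "moderate"),     # boundary falls to the weaker class
        (0.8, "marginal"),
        (1.5000001, "strong"),
    ])
    def test_classes(self, omega, expected):
        assert electrophilicity_class(omega) == expected

    def test_negative_omega_rejected(self):
        with pytest.raises(ValueError):
            electrophilicity_class(-0.1)

    def test_published_panel_has_one_moderate(self, descriptor_reference):
        classes = {row.ligand_id: electrophilicity_class(row.omega)
                   for row in descriptor_reference.itertuples()}
        moderates = [lig for lig, c in classes.items() if c == "moderate"]
        assert moderates == ["Carbenicillin"]
        assert all(c == "strong" for lig, c in classes.items() if lig != "Carbenicillin")


class TestKidCheck:
    def test_consistent_triplet_has_zero_deviations(self):
        rep = kid_check(_triplet(-6.0241, -1.7554))
        assert rep.j_i == pytest.approx(0.0, abs=1e-12)
        assert rep.j_a == pytest.approx(0.0, abs=1e-12)
        assert rep.j_hl == pytest.approx(0.0, abs=1e-12)
        assert rep.passes

    def test_cation_shift_shows_up_in_j_i_only(self):
        t = _triplet(-6.0, -1.0)
        shifted = SpeciesTriplet(
            neutral=t.neutral,
            cation=SpeciesRecord("L", 1, 2, e_total=t.cation.e_total + 0.1),
            anion=t.anion)
        rep = kid_check(shifted)
        assert rep.j_i == pytest.approx(0.1, abs=1e-12)
        assert rep.j_a == pytest.approx(0.0, abs=1e-12)
        assert rep.j_hl == pytest.approx(0.1, abs=1e-12)
        assert not rep.passes

    @settings(max_examples=100, deadline=None)
    @given(st.floats(-0.5, 0.5), st.floats(-0.5, 0.5))
    def test_j_hl_is_quadrature_of_components(self, di, da):
        """Independent recomputation: j_hl must equal sqrt(j_i^2 + j_a^2)."""
        t = _triplet(-6.0, -1.0)
        perturbed = SpeciesTriplet(
            neutral=t.neutral,
            cation=SpeciesRecord("L", 1, 2, e_total=t.cation.e_total + di),
            anion=SpeciesRecord("L", -1, 2, e_total=t.anion.e_total + da))
        rep = kid_check(perturbed)
        assert rep.j_i == pytest.approx(abs(di), abs=1e-12)
        assert rep.j_a == pytest.approx(abs(da), abs=1e-12)
        assert rep.j_hl == pytest.approx(math.sqrt(di * di + da * da), abs=1e-12)
        assert rep.j_hl >= max(rep.j_i, rep.j_a) - 1e-15

    def test_generated_triplets_pass_at_tight_tolerance(self):
        for t in gen_species(seed=7):
            assert kid_check(t, tol_ev=1e-9).passes


class TestHardnessRanking:
    def test_published_panel_ranks_carbenicillin_least_reactive(self, descriptor_reference):
        panel = [
            global_descriptors(
                IonizationData(I=r.chi + r.eta / 2, A=r.chi - r.eta / 2, method="koopmans"),
                ligand_id=r.ligand_id)
            for r in descriptor_reference.itertuples()
        ]
        ranked = hardness_ranking(panel)
        assert ranked[0].ligand_id == "Carbenicillin"
        assert ranked[0].eta == pytest.approx(5.6238, abs=0.005)

    def test_single_ligand(self):
        gd = global_descriptors(IonizationData(I=5, A=1, method="koopmans"), ligand_id="X")
        assert hardness_ranking([gd]) == [gd]

    def test_equal_hardness_breaks_ties_alphabetically(self):
        a = global_descriptors(IonizationData(I=5, A=1, method="koopmans"), ligand_id="B")
        b = global_descriptors(IonizationData(I=6, A=2, method="koopmans"), ligand_id="A")
        assert [g.ligand_id for g in hardness_ranking([a, b])] == ["A", "B"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            hardness_ranking([])
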