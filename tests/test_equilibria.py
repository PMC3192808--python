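"""Equilibrium-constant algebra: conversions, avidity, mode enumeration."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multibind import (
    AffinityModel,
    dg_from_kd,
    enumerate_1to1,
    k_gs,
    k_gsg,
    kd_eff_bivalent,
    kd_from_dg,
)

from conftest import MOTIFS


class TestFreeEnergyConversion:
    @pytest.mark.parametrize(
        "dg,kd_uM",
        [(-7.1, 6.2), (-7.5, 3.2), (-5.1, 182), (-4.3, 702), (-6.0, 40), (-4.9, 255), (-4.5, 501), (-5.2, 153)],
    )
    def test_published_pairs_to_two_significant_figures(self, dg, kd_uM):
        computed = kd_from_dg(dg, 298.0) * 1e6
        assert computed == pytest.approx(kd_uM, rel=0.05)

    def test_zero_free_energy_is_molar_standard_state(self):
        assert kd_from_dg(0.0) == 1.0

    @given(st.floats(min_value=-15, max_value=5))
    @settings(deadline=None)
    def test_round_trip(self, dg):
        assert dg_from_kd(kd_from_dg(dg)) == pytest.approx(dg, abs=1e-12)


class TestBivalentKd:
    @pytest.mark.parametrize(
        "kd_n,kd_c,ceff,expected",
        [
            (117.0, 125.0, 1.6, 9.14),   # N-domain on P3, C-domain on P1
            (56.0, 125.0, 2.1, 3.33),    # N-domain on P2, C-domain on P1
            (117.0, 1396.0, 2.1, 77.78), # N-domain on P3, C-domain on P2
        ],
    )
    def test_published_cells(self, kd_n, kd_c, ceff, expected):
        assert kd_eff_bivalent(kd_n, kd_c, ceff) == pytest.approx(expected, rel=1e-2)

    def test_no_avidity_without_proximity(self):
        assert kd_eff_bivalent(100.0, 100.0, 1e-9) > 1e9

    def test_symmetric_in_binding_order(self):
        # A single product: swapping which domain binds first cannot matter.
        assert kd_eff_bivalent(50.0, 200.0, 1.5) == kd_eff_bivalent(200.0, 50.0, 1.5)


def uniform_model(motifs, kd=100.0, ceff=1.0):
    return AffinityModel(
        kd_N_uM={m: kd for m in motifs},
        kd_C_uM={m: kd for m in motifs},
        ceff_mM={(a, b): ceff for a in motifs for b in motifs if a != b},
        substitutions={},
    )


class TestEnumerate1to1:
    def test_five_motifs_thirty_modes(self, model):
        assert len(enumerate_1to1(model, MOTIFS)) == 30

    def test_single_motif_two_modes(self):
        modes = enumerate_1to1(uniform_model(["a"]), ["a"])
        assert len(modes) == 2
        assert {m.domain for m in modes} == {"N", "C"}

    @pytest.mark.parametrize("m", [1, 2, 3, 4, 5, 6])
    def test_count_matches_exhaustive_assignment_oracle(self, m):
        """Independent oracle: enumerate occupancy maps domain -> motif-or-free
        with at least one domain occupied and distinct motifs."""
        motifs = [f"x{i}" for i in range(m)]
        modes = enumerate_1to1(uniform_model(motifs), motifs)
        oracle = 0
        for n_occ in [None] + motifs:
            for c_occ in [None] + motifs:
                if n_occ is None and c_occ is None:
                    continue
                if n_occ is not None and n_occ == c_occ:
                    continue
                oracle += 1
        assert len(modes) == oracle == m * (m - 1) + 2 * m

    def test_duplicate_labels_rejected(self, model):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_1to1(model, ["P1", "P1"])

    def test_missing_affinity_is_keyed_error(self):
        m = uniform_model(["a"])
        with pytest.raises(KeyError, match="b"):
            enumerate_1to1(m, ["a", "b"])


class TestKGS:
    def test_published_composition(self, model):
        """~10% of 1:1 complexes are singly bound on the full five-motif model."""
        s = k_gs(model, MOTIFS)
        assert s.fraction_singly == pytest.approx(0.105, abs=0.01)
        assert s.fraction_doubly == pytest.approx(0.895, abs=0.01)
        assert s.fraction_singly + s.fraction_doubly == pytest.approx(1.0, abs=1e-12)

    def test_overall_dissociation_constant(self, model):
        assert k_gs(model, MOTIFS).Kd_GS_uM == pytest.approx(1.26, rel=0.02)

    def test_n_terminal_fragment_subset(self, model):
        """The three-motif N-terminal fragment binds ~1.8 uM."""
        s = k_gs(model, ["P1", "P2", "P3"])
        assert s.Kd_GS_uM == pytest.approx(1.83, rel=0.02)

    def test_substitution_feeds_missing_motif(self, model):
        # RP carries no measured affinity; it borrows P3's.
        assert model.kd_N("RP") == model.kd_N("P3")
        assert model.kd_C("RP") == model.kd_C("P3")

    def test_removing_a_motif_never_increases_k_gs(self, model):
        full = k_gs(model, MOTIFS).K_GS
        for drop in MOTIFS:
            subset = [m for m in MOTIFS if m != drop]
            assert k_gs(model, subset).K_GS <= full

    def test_improving_an_affinity_increases_k_gs(self, model):
        base = k_gs(model, MOTIFS).K_GS
        better = AffinityModel(
            kd_N_uM={**model.kd_N_uM, "P1": model.kd_N_uM["P1"] / 2},
            kd_C_uM=dict(model.kd_C_uM),
            ceff_mM=dict(model.ceff_mM),
            substitutions=dict(model.substitutions),
        )
        assert k_gs(better, MOTIFS).K_GS > base


def brute_force_pair_weights(model, motifs, convention):
    """Independent oracle: ordered mode pairs with explicit double-count
    correction (every ordered pair weighted half, since the two adaptors
    are identical), with the mixed-pair convention applied on top."""
    modes = enumerate_1to1(model, motifs)
    weights = {"dd": 0.0, "ds": 0.0, "ss": 0.0}
    for a, b in itertools.product(modes, repeat=2):
        if a is b or (a.motifs_used & b.motifs_used):
            continue
        w = 0.5 * a.association * b.association
        if a.kind == b.kind:
            key = "dd" if a.kind == "doubly" else "ss"
        else:
            key = "ds"
            if convention == "paper":
                w *= 0.5
        weights[key] += w
    return weights


class TestKGSG:
    def test_published_composition_paper_convention(self, model):
        s = k_gsg(model, MOTIFS, convention="paper")
        dd, ds, ss = s.gsg_fractions
        assert dd == pytest.approx(0.68, abs=0.015)
        assert ds == pytest.approx(0.27, abs=0.015)
        assert ss == pytest.approx(0.05, abs=0.015)

    def test_strict_convention_differs(self, model):
        s = k_gsg(model, MOTIFS, convention="strict")
        dd, ds, ss = s.gsg_fractions
        assert dd == pytest.approx(0.52, abs=0.02)
        assert ds == pytest.approx(0.44, abs=0.02)
        assert ss == pytest.approx(0.04, abs=0.02)

    def test_fractions_sum_to_one(self, model):
        for conv in ("paper", "strict"):
            assert sum(k_gsg(model, MOTIFS, convention=conv).gsg_fractions) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_two_motifs_only_both_singly(self):
        m = uniform_model(["a", "b"])
        s = k_gsg(m, ["a", "b"])
        assert s.gsg_fractions[0] == 0.0
        assert s.gsg_fractions[1] == 0.0
        assert s.gsg_fractions[2] == 1.0

    @pytest.mark.parametrize("conv", ["paper", "strict"])
    @pytest.mark.parametrize("m", [2, 3, 4, 5, 6])
    def test_weights_match_ordered_enumeration_oracle(self, conv, m, model):
        motifs = MOTIFS[: min(m, 5)] if m <= 5 else MOTIFS + ["X6"]
        mdl = model
        if m > 5:
            mdl = AffinityModel(
                kd_N_uM={**model.kd_N_uM, "X6": 200.0},
                kd_C_uM={**model.kd_C_uM, "X6": 400.0},
                ceff_mM={
                    **model.ceff_mM,
                    **{(a, "X6"): 1.0 for a in MOTIFS},
                    **{("X6", a): 1.0 for a in MOTIFS},
                },
                substitutions=dict(model.substitutions),
            )
        s = k_gsg(mdl, motifs, convention=conv)
        oracle = brute_force_pair_weights(mdl, motifs, conv)
        total = sum(oracle.values())
        assert s.gsg_fractions[0] == pytest.approx(oracle["dd"] / total, rel=1e-12)
        assert s.gsg_fractions[1] == pytest.approx(oracle["ds"] / total, rel=1e-12)
        assert s.K_GSG == pytest.approx(total / s.K_GS, rel=1e-12)

    def test_symmetric_model_fractions_depend_only_on_count(self):
        """With all single-site Kds equal and all C_eff equal, the 2:1
        composition is invariant to relabelling the motifs."""
        for m in (3, 4, 5):
            motifs = [f"m{i}" for i in range(m)]
            a = k_gsg(uniform_model(motifs), motifs).gsg_fractions
            shuffled = list(reversed(motifs))
            b = k_gsg(uniform_model(shuffled), shuffled).gsg_fractions
            assert a == pytest.approx(b, rel=1e-12)

    def test_needs_two_motifs(self, model):
        with pytest.raises(ValueError):
            k_gsg(model, ["P1"])
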