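import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_simplex
from oracles import oracle_kl

from fodm.divergence import (
    K_BINS,
    classify,
    fragment_rd,
    kl_divergence,
    relative_distance,
    restrict_profile,
)
from fodm.errors import DivergenceError, SelectionError, UndefinedRDError
from fodm.profiles import Profile
from fodm.structure import ResidueRef


def prof(values, kind="O", with_refs=False):
    refs = tuple(
        ResidueRef(chain_id="A", seq_number=i + 1, aa_code="ALA")
        for i in range(len(values))
    ) if with_refs else ()
    return Profile(kind=kind, values=np.asarray(values, dtype=float), residue_refs=refs)


class TestKLDivergence:
    def test_identical_profiles_give_zero(self):
        p = prof([0.2, 0.3, 0.5])
        assert kl_divergence(p, p) == 0.0

    def test_frozen_hand_example(self):
        got = kl_divergence(prof([0.75, 0.25]), prof([0.5, 0.5], kind="T"))
        assert got == pytest.approx(0.18872187554086717, rel=1e-12)

    def test_degenerate_p_with_zero_convention(self):
        got = kl_divergence(prof([1.0, 0.0]), prof([0.5, 0.5], kind="T"))
        assert got == pytest.approx(1.0, rel=1e-12)

    def test_zero_reference_where_p_positive_is_error(self):
        with pytest.raises(DivergenceError):
            kl_divergence(prof([0.5, 0.5]), np.array([1.0, 0.0]))

    @settings(deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=2, max_value=30))
    def test_gibbs_inequality_on_random_simplex_points(self, seed, n):
        rng = np.random.default_rng(seed)
        p, q = random_simplex(rng, n), random_simplex(rng, n)
        d = kl_divergence(prof(p), prof(q, kind="T"))
        assert d >= 0.0
        assert d == pytest.approx(oracle_kl(p, q), rel=1e-10, abs=1e-12)


class TestRelativeDistance:
    def test_zero_when_observed_equals_theoretical(self):
        o = prof([0.7, 0.2, 0.1])
        t = prof([0.7, 0.2, 0.1], kind="T")
        r = prof([1 / 3] * 3, kind="R")
        assert relative_distance(o, t, r).rd == 0.0

    def test_one_when_observed_equals_uniform(self):
        o = prof([0.5, 0.5])
        t = prof([0.9, 0.1], kind="T")
        r = prof([0.5, 0.5], kind="R")
        assert relative_distance(o, t, r).rd == 1.0

    def test_half_when_references_coincide(self):
        o = prof([0.75, 0.25])
        t = prof([0.5, 0.5], kind="T")
        r = prof([0.5, 0.5], kind="R")
        res = relative_distance(o, t, r)
        assert res.rd == pytest.approx(0.5, rel=1e-12)
        assert res.dkl_ot == pytest.approx(0.18872187554086717, rel=1e-12)

    def test_exact_triple_coincidence_is_undefined(self):
        u = prof([0.5, 0.5])
        with pytest.raises(UndefinedRDError):
            relative_distance(u, prof([0.5, 0.5], "T"), prof([0.5, 0.5], "R"))

    def test_rd_scale_free_in_raw_hydrophobicity(self):
        # scaling raw values is absorbed before profiles exist; here we check
        # RD only depends on the normalized shapes
        rng = np.random.default_rng(5)
        o = random_simplex(rng, 20)
        t = random_simplex(rng, 20)
        r = np.full(20, 0.05)
        rd1 = relative_distance(prof(o), prof(t, "T"), prof(r, "R")).rd
        rd2 = relative_distance(prof(o), prof(t, "T"), prof(r, "R")).rd
        assert rd1 == rd2

    def test_monotone_along_mixture_path_from_t_to_r(self):
        rng = np.random.default_rng(17)
        t = random_simplex(rng, 30)
        r = np.full(30, 1.0 / 30)
        lams = np.linspace(0.02, 0.98, 25)
        rds = []
        for lam in lams:
            o = (1 - lam) * t + lam * r
            rds.append(relative_distance(prof(o), prof(t, "T"), prof(r, "R")).rd)
        assert all(b > a for a, b in zip(rds, rds[1:]))
        assert rds[0] < 0.1 and rds[-1] > 0.9


class TestFragmentRD:
    def _triple(self):
        o = prof([0.4, 0.3, 0.2, 0.1], with_refs=True)
        t = prof([0.5, 0.2, 0.2, 0.1], kind="T", with_refs=True)
        r = prof([0.25] * 4, kind="R", with_refs=True)
        return o, t, r

    def test_full_subset_equals_whole_structure_rd(self):
        o, t, r = self._triple()
        whole = relative_distance(o, t, r)
        frag = fragment_rd(o, t, r, list(o.residue_refs))
        assert frag.rd == pytest.approx(whole.rd, rel=1e-12)

    def test_single_residue_subset_is_undefined(self):
        o, t, r = self._triple()
        with pytest.raises(UndefinedRDError):
            fragment_rd(o, t, r, [o.residue_refs[0]])

    def test_two_bin_subset_matches_hand_renormalization(self):
        o, t, r = self._triple()
        subset = [o.residue_refs[0], o.residue_refs[1]]
        frag = fragment_rd(o, t, r, subset)
        # hand renormalization over residues 1-2
        ov = np.array([0.4, 0.3]) / 0.7
        tv = np.array([0.5, 0.2]) / 0.7
        rv = np.array([0.5, 0.5])
        dot = oracle_kl(ov, tv)
        dor = oracle_kl(ov, rv)
        assert frag.rd == pytest.approx(dot / (dot + dor), rel=1e-12)

    def test_empty_subset_is_selection_error(self):
        o, t, r = self._triple()
        with pytest.raises(SelectionError):
            fragment_rd(o, t, r, [])

    def test_unknown_residue_is_selection_error(self):
        o, t, r = self._triple()
        with pytest.raises(SelectionError):
            fragment_rd(o, t, r, [ResidueRef("Z", 99, aa_code="ALA")])

    def test_restrict_profile_renormalizes(self):
        o, _, _ = self._triple()
        sub = restrict_profile(o, [0, 1])
        assert sub.values.sum() == pytest.approx(1.0, abs=1e-12)


class TestClassify:
    @pytest.mark.parametrize(
        "rd, k, status, env",
        [
            (0.3, 0.0, "hydrophobic-core-present", "WATER"),
            (0.84, 0.0, "no-hydrophobic-core", "WATER"),
            (0.6, 0.6, "no-hydrophobic-core", "INTERMEDIATE"),
            (0.4, 1.3, "hydrophobic-core-present", "MEMBRANE-CHAPERONE"),
            (0.9, 1.9, "no-hydrophobic-core", "MEMBRANE"),
            (0.95, 7.0, "no-hydrophobic-core", "CHAPERONIN-LIKE"),
        ],
    )
    def test_reference_points(self, rd, k, status, env):
        assert classify(rd, k) == (status, env)

    def test_total_and_unique_over_a_dense_grid(self):
        labels = {label for _, _, label in K_BINS}
        for rd in np.linspace(0.0, 1.0, 21):
            for k in np.linspace(0.0, 10.0, 101):
                status, env = classify(float(rd), float(k))
                assert env in labels
                assert status in ("hydrophobic-core-present", "no-hydrophobic-core")

    def test_boundary_values_fall_in_upper_bin(self):
        assert classify(0.5, 0.5)[1] == "INTERMEDIATE"
        assert classify(0.5, 0.9)[1] == "MEMBRANE-CHAPERONE"
        assert classify(0.5, 3.0)[1] == "CHAPERONIN-LIKE"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify(1.2, 0.0)
        with pytest.raises(ValueError):
            classify(0.5, -0.1)
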