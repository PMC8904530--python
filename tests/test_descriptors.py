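import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
import pvpstack as pv
from pvpstack.descriptors import DESCRIPTOR_DIMS
from pvpstack.seqio import STANDARD_AA, ProteinRecord

seq_strategy = st.text(alphabet=STANDARD_AA, min_size=6, max_size=50)


def _profile_for(seq, seed=0):
    return pv.generate_synthetic_pssm(ProteinRecord("x", seq), seed=seed)


class TestDimensions:
    @pytest.mark.parametrize("descriptor,dim", sorted(DESCRIPTOR_DIMS.items()))
    def test_declared_dimension(self, descriptor, dim, rng):
        seq = oracles.random_sequence(rng, 20, 40)
        rec = ProteinRecord("r", seq)
        feats = pv.encode_all(
            [rec], {"r": _profile_for(seq)}, [descriptor]
        )[descriptor]
        assert feats.shape == (1, dim)

    def test_paac_apaac_dims_scale_with_lambda(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        assert len(pv.encode_paac(seq, lam=3).values) == 23
        assert len(pv.encode_apaac(seq, lam=3).values) == 26


class TestCompositionExamples:
    def test_aac_homopolymer(self):
        v = pv.encode_aac("AAAA")
        assert v.values[0] == 1.0 and v.values[1:].sum() == 0.0

    def test_aac_uniform_four(self):
        v = pv.encode_aac("ACDE")
        expected = {aa: 0.25 for aa in "ACDE"}
        for name, val in zip(v.names, v.values):
            assert val == pytest.approx(expected.get(name, 0.0))

    def test_dpc_single_and_double(self):
        v = pv.encode_dpc("AC")
        assert dict(zip(v.names, v.values))["AC"] == 1.0
        v = pv.encode_dpc("ACA")
        d = dict(zip(v.names, v.values))
        assert d["AC"] == d["CA"] == 0.5

    def test_dde_closed_form_for_AA(self):
        # Dc(AA)=1, Tm=(4/61)^2, Tv=Tm(1-Tm)/(L-1) with L=2
        v = dict(zip(pv.encode_dde("AA").names, pv.encode_dde("AA").values))
        tm = (4 / 61) ** 2
        tv = tm * (1 - tm) / 1
        assert v["AA"] == pytest.approx((1 - tm) / math.sqrt(tv))
        # absent dipeptide: Dc = 0
        tm_ac = (4 / 61) * (2 / 61)
        tv_ac = tm_ac * (1 - tm_ac) / 1
        assert v["AC"] == pytest.approx(-tm_ac / math.sqrt(tv_ac))

    def test_dde_dc_matches_dpc(self, rng):
        seq = oracles.random_sequence(rng, 10, 30)
        # reconstruct Dc from the DDE closed form and compare to DPC
        dde = pv.encode_dde(seq).values
        dpcv = pv.encode_dpc(seq).values
        for idx, (a, b) in enumerate(
            (x + y for x in STANDARD_AA for y in STANDARD_AA)
        ):
            tm = (oracles.CODONS[a] / 61) * (oracles.CODONS[b] / 61)
            tv = tm * (1 - tm) / (len(seq) - 1)
            assert dde[idx] * math.sqrt(tv) + tm == pytest.approx(dpcv[idx])

    def test_length_preconditions(self):
        with pytest.raises(ValueError):
            pv.encode_dpc("A")
        with pytest.raises(ValueError):
            pv.encode_paac("A", lam=1)
        with pytest.raises(ValueError):
            pv.encode_eaac("ACD", window=5)


class TestCtd:
    def test_homopolymer_composition_and_transitions(self):
        c = pv.encode_ctdc("AAAAA")
        t = pv.encode_ctdt("AAAAA")
        # for every property, one group carries fraction 1 and no transitions
        comp = c.values.reshape(13, 3)
        assert np.all(comp.sum(axis=1) == pytest.approx(1.0))
        assert np.all(np.sort(comp, axis=1)[:, -1] == 1.0)
        assert np.all(t.values == 0.0)

    def test_distribution_positions_AAAA(self):
        # A's group occurrences at 1,2,3,4 (n=4): ceil(q*n)-th occurrence for
        # q in {1st,25,50,75,100}% -> indices 1,1,2,3,4 -> 25,25,50,75,100
        d = dict(zip(pv.encode_ctdd("AAAA").names, pv.encode_ctdd("AAAA").values))
        for prop, groups in pv.descriptors.CTD_GROUPS.items():
            g = next(i for i, members in enumerate(groups) if "A" in members)
            vals = [d[f"{prop}.G{g + 1}.{q}"] for q in ("first", "p25", "p50", "p75", "p100")]
            assert vals == [25.0, 25.0, 50.0, 75.0, 100.0]

    def test_empty_group_contributes_zeros(self):
        d = pv.encode_ctdd("KKKK")  # charge group 2/3 absent
        charge_g3 = [v for n, v in zip(d.names, d.values) if n.startswith("charge.G3")]
        assert charge_g3 == [0.0] * 5

    @given(seq=seq_strategy)
    @settings(max_examples=25, deadline=None)
    def test_ranges(self, seq):
        assert np.all(pv.encode_ctdt(seq).values <= 1.0)
        assert np.all(pv.encode_ctdt(seq).values >= 0.0)
        dd = pv.encode_ctdd(seq).values
        assert np.all((dd >= 0.0) & (dd <= 100.0))


class TestPseudoComposition:
    def test_paac_homopolymer_zero_correlation(self):
        v = pv.encode_paac("AAAAA", lam=1)
        assert v.values[0] == pytest.approx(1.0)
        assert v.values[20] == pytest.approx(0.0)

    @given(seq=seq_strategy)
    @settings(max_examples=25, deadline=None)
    def test_paac_apaac_sum_to_one(self, seq):
        assert pv.encode_paac(seq).values.sum() == pytest.approx(1.0)
        assert pv.encode_apaac(seq).values.sum() == pytest.approx(1.0)

    def test_eaac_homopolymer(self):
        v = pv.encode_eaac("AAAAAA", window=5)
        assert v.values[0] == pytest.approx(1.0)

    def test_aai_homopolymer_equals_normalized_index(self):
        v = pv.encode_aai("AAAA")
        expected = oracles.aai("A")
        np.testing.assert_allclose(v.values, expected)

    def test_aai_missing_residue_errors(self):
        with pytest.raises(ValueError, match="missing"):
            pv.encode_aai("ACD", {"bad": {"A": 1.0}})


class TestPssmDescriptors:
    def test_zero_profile_values(self):
        prof = pv.PssmProfile("z", np.zeros((4, 20)), "ACDM")
        assert np.all(pv.encode_pssm_aac(prof).values == 0.5)
        dp = pv.encode_pssm_dp(prof).values
        assert np.all(dp == pytest.approx(0.25))

    def test_com_zero_rows_for_absent_residues(self):
        prof = pv.PssmProfile("a", np.zeros((3, 20)), "AAA")
        block = pv.encode_pssm_com(prof).values.reshape(20, 20)
        assert np.all(block[0] == 0.5)  # A row
        assert np.all(block[1:] == 0.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_values_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        seq = oracles.random_sequence(rng, 5, 25)
        prof = _profile_for(seq, seed)
        for enc in (pv.encode_pssm_aac, pv.encode_pssm_com, pv.encode_pssm_dp):
            vals = enc(prof).values
            assert np.all((vals >= 0.0) & (vals <= 1.0))


class TestBruteForceEquivalence:
    """Every encoder agrees with an independent explicit-loop implementation."""

    cases = [
        ("AAC", pv.encode_aac, oracles.aac, False),
        ("DPC", pv.encode_dpc, oracles.dpc, False),
        ("DDE", pv.encode_dde, oracles.dde, False),
        ("CTDC", pv.encode_ctdc, oracles.ctdc, False),
        ("CTDT", pv.encode_ctdt, oracles.ctdt, False),
        ("CTDD", pv.encode_ctdd, oracles.ctdd, False),
        ("PAAC", pv.encode_paac, oracles.paac, False),
        ("APAAC", pv.encode_apaac, oracles.apaac, False),
        ("EAAC", pv.encode_eaac, oracles.eaac, False),
        ("AAI", pv.encode_aai, oracles.aai, False),
        ("PSSM_AAC", pv.encode_pssm_aac, oracles.pssm_aac, True),
        ("PSSM_COM", pv.encode_pssm_com, None, True),
        ("PSSM_DP", pv.encode_pssm_dp, oracles.pssm_dp, True),
    ]

    @pytest.mark.parametrize("name,enc,oracle,needs_profile", cases,
                             ids=[c[0] for c in cases])
    def test_matches_oracle_on_random_sequences(self, name, enc, oracle, needs_profile):
        rng = np.random.default_rng(42)
        for trial in range(20):
            seq = oracles.random_sequence(rng, 6, 30)
            if needs_profile:
                prof = _profile_for(seq, seed=trial)
                got = enc(prof).values
                if name == "PSSM_COM":
                    expected = oracles.pssm_com(prof.scores, prof.residues)
                else:
                    expected = oracle(prof.scores)
            else:
                got = enc(seq).values
                expected = oracle(seq)
            np.testing.assert_allclose(got, expected, atol=1e-12, err_msg=name)


class TestEncodeAll:
    def test_shapes_and_alignment(self, small_dataset):
        records, profiles = small_dataset
        feats = pv.encode_all(records[:10], profiles, pv.ALL_DESCRIPTORS)
        assert len(feats) == 13
        for desc, frame in feats.items():
            assert frame.shape == (10, DESCRIPTOR_DIMS[desc])
            assert list(frame.index) == [r.id for r in records[:10]]

    def test_missing_profile_errors_with_record_name(self):
        rec = ProteinRecord("lonely", "MKVLACDEFG")
        with pytest.raises(ValueError, match="lonely"):
            pv.encode_all([rec], {}, ["PSSM_AAC"])

    def test_sequence_descriptors_need_no_profiles(self):
        rec = ProteinRecord("r", "MKVLACDEFG")
        feats = pv.encode_all([rec], None, ["AAC", "DPC"])
        assert set(feats) == {"AAC", "DPC"}

    def test_deterministic(self):
        rec = ProteinRecord("r", "MKVLACDEFGHIKNPQ")
        a = pv.encode_all([rec], None, ["PAAC", "CTDD"])
        b = pv.encode_all([rec], None, ["PAAC", "CTDD"])
        for d in a:
            np.testing.assert_array_equal(a[d].to_numpy(), b[d].to_numpy())
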