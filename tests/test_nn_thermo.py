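"""Nearest-neighbor summation: worked example, class mapping, invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrmtm import (
    DINUCLEOTIDE_CLASS,
    NNParameterSet,
    ParameterError,
    SequenceRecord,
    duplex_thermo,
    load_parameter_set,
    reverse_complement,
    stack_lookup,
    thermo_table,
)

dna = st.text(alphabet="ACGT", min_size=2, max_size=300)

#: Independent oracle: all 16 dinucleotides tabulated explicitly, no class mapping.
FULL_STACK_TABLE = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}


def oracle_thermo(seq: str, symmetry: bool) -> tuple[float, float]:
    """Brute-force duplex totals from the 16-entry table (independent path)."""
    dh = sum(FULL_STACK_TABLE[seq[i:i + 2]][0] for i in range(len(seq) - 1))
    ds = sum(FULL_STACK_TABLE[seq[i:i + 2]][1] for i in range(len(seq) - 1))
    for base in (seq[0], seq[-1]):
        init = (0.1, -2.8) if base in "GC" else (2.3, 4.1)
        dh += init[0]
        ds += init[1]
    if symmetry:
        ds += -1.4
    return dh, ds


class TestParameterSet:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("GT/CA", (-8.4, -22.4)),
            ("GG/CC", (-8.0, -19.9)),
            ("CG/GC", (-10.6, -27.2)),
        ],
    )
    def test_default_stack_values(self, name, expected):
        assert NNParameterSet.default().stacks[name] == expected

    def test_default_special_terms(self):
        p = NNParameterSet.default()
        assert p.init_terminal_GC == (0.1, -2.8)
        assert p.init_terminal_AT == (2.3, 4.1)
        assert p.symmetry_correction == (0.0, -1.4)

    def test_all_stack_parameters_negative(self):
        for dh, ds in NNParameterSet.default().stacks.values():
            assert dh < 0 and ds < 0

    def test_packaged_file_equals_builtin(self):
        from hrmtm.fixtures import load_default_parameters

        loaded = load_default_parameters()
        default = NNParameterSet.default()
        assert dict(loaded.stacks) == dict(default.stacks)
        assert loaded.init_terminal_GC == default.init_terminal_GC

    def test_missing_entry_named(self, tmp_path):
        path = tmp_path / "params.tsv"
        lines = ["name\tdH_kcal_per_mol\tdS_cal_per_K_mol"]
        full = load_parameter_set(None)
        for k, (dh, ds) in full.stacks.items():
            if k != "CG/GC":
                lines.append(f"{k}\t{dh}\t{ds}")
        lines += ["init_terminal_GC\t0.1\t-2.8", "init_terminal_AT\t2.3\t4.1",
                  "symmetry_correction\t0\t-1.4"]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParameterError, match="CG/GC"):
            load_parameter_set(path)

    def test_malformed_file(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("not\ta\tparameter\ttable\n")
        with pytest.raises(ParameterError):
            load_parameter_set(path)


class TestStackLookup:
    @pytest.mark.parametrize(
        "dinuc, expected",
        [
            ("TG", (-8.5, -22.7)),  # maps to CA/GT
            ("GC", (-9.8, -24.4)),
            ("TT", (-7.9, -22.2)),  # maps to AA/TT
            ("CC", (-8.0, -19.9)),  # maps to GG/CC
        ],
    )
    def test_canonical_mapping(self, dinuc, expected):
        assert stack_lookup(dinuc) == expected

    def test_every_dinucleotide_revcomp_equivalent(self):
        for a, b in itertools.product("ACGT", repeat=2):
            d = a + b
            assert stack_lookup(d) == stack_lookup(reverse_complement(d))
            assert DINUCLEOTIDE_CLASS[d] == DINUCLEOTIDE_CLASS[reverse_complement(d)]

    def test_all_sixteen_covered_by_ten_classes(self):
        assert len(DINUCLEOTIDE_CLASS) == 16
        assert len(set(DINUCLEOTIDE_CLASS.values())) == 10

    def test_invalid_dinucleotide(self):
        with pytest.raises(ParameterError):
            stack_lookup("NX")


class TestDuplexThermo:
    def test_worked_example_with_symmetry(self):
        """GTGCAT/ATGCAC summation with the symmetry term included."""
        t = duplex_thermo("GTGCAT", symmetry_policy="always")
        assert t.dH_total == pytest.approx(-40.0)
        assert t.dS_total == pytest.approx(-112.7)
        assert t.symmetry_applied

    def test_worked_example_auto_policy_drops_symmetry(self):
        """GTGCAT is not self-complementary, so auto omits the -1.4 entropy term."""
        t = duplex_thermo("GTGCAT")
        assert t.dH_total == pytest.approx(-40.0)
        assert t.dS_total == pytest.approx(-111.3)
        assert not t.symmetry_applied

    def test_self_complementary_dimer(self):
        t = duplex_thermo("AT")
        assert t.dH_total == pytest.approx(-2.6)  # -7.2 + 2.3 + 2.3
        assert t.dS_total == pytest.approx(-13.6)  # -20.4 + 4.1 + 4.1 - 1.4
        assert t.symmetry_applied

    def test_never_policy(self):
        t = duplex_thermo("AT", symmetry_policy="never")
        assert t.dS_total == pytest.approx(-12.2)
        assert not t.symmetry_applied

    def test_result_carries_composition(self):
        t = duplex_thermo(SequenceRecord(id="x", sequence="GTGCAT"))
        assert (t.n, t.length, t.sequence_id) == (5, 6, "x")
        assert t.gc_percent == pytest.approx(50.0)

    @pytest.mark.parametrize("policy", ["auto", "always", "never"])
    @given(s=dna)
    @settings(max_examples=100, deadline=None)
    def test_revcomp_invariance(self, s, policy):
        a = duplex_thermo(s, symmetry_policy=policy)
        b = duplex_thermo(reverse_complement(s), symmetry_policy=policy)
        assert a.dH_total == pytest.approx(b.dH_total, abs=1e-12)
        assert a.dS_total == pytest.approx(b.dS_total, abs=1e-12)

    def test_negativity_exhaustive_dimers(self):
        for a, b in itertools.product("ACGT", repeat=2):
            for policy in ("auto", "always", "never"):
                t = duplex_thermo(a + b, symmetry_policy=policy)
                assert t.dH_total < 0, (a + b, policy)
                assert t.dS_total < 0, (a + b, policy)

    def test_negativity_random_sequences(self):
        rng = np.random.default_rng(20260926)
        for _ in range(1000):
            length = int(rng.integers(2, 301))
            seq = "".join(rng.choice(list("ACGT"), size=length))
            t = duplex_thermo(seq)
            assert t.dH_total < 0 and t.dS_total < 0

    def test_oracle_equivalence_on_random_sequences(self):
        """Class-mapped implementation vs explicit 16-entry table, exact."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            length = int(rng.integers(2, 301))
            seq = "".join(rng.choice(list("ACGT"), size=length))
            for policy, flag in (("always", True), ("never", False)):
                t = duplex_thermo(seq, symmetry_policy=policy)
                odh, ods = oracle_thermo(seq, symmetry=flag)
                assert t.dH_total == pytest.approx(odh, abs=1e-9)
                assert t.dS_total == pytest.approx(ods, abs=1e-9)

    @given(s1=dna, s2=dna)
    @settings(max_examples=100, deadline=None)
    def test_additivity_under_concatenation(self, s1, s2):
        """dH(s1+s2) = dH(s1) + dH(s2) + joint stack - the two joined-end inits."""
        params = NNParameterSet.default()
        t1 = duplex_thermo(s1, symmetry_policy="never")
        t2 = duplex_thermo(s2, symmetry_policy="never")
        tcat = duplex_thermo(s1 + s2, symmetry_policy="never")
        joint_dh, joint_ds = stack_lookup(s1[-1] + s2[0], params)
        init1 = params.init_terminal_GC if s1[-1] in "GC" else params.init_terminal_AT
        init2 = params.init_terminal_GC if s2[0] in "GC" else params.init_terminal_AT
        assert tcat.dH_total == pytest.approx(
            t1.dH_total + t2.dH_total + joint_dh - init1[0] - init2[0], abs=1e-9
        )
        assert tcat.dS_total == pytest.approx(
            t1.dS_total + t2.dS_total + joint_ds - init1[1] - init2[1], abs=1e-9
        )

    def test_thermo_table_shape(self, dataset):
        frame = thermo_table(list(dataset.records.values()))
        assert len(frame) == 28
        assert not frame.symmetry_applied.any()  # no amplicon is self-complementary
        assert (frame.dH_total < 0).all() and (frame.dS_total < 0).all()
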