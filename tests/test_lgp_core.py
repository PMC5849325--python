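import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lgpnet.evolution import EvolutionConfig
from lgpnet.lgp_core import (
    ARITHMETIC_OPERATORS,
    Instruction,
    Operand,
    Program,
    apply_operator,
    effective_features,
    effective_instructions,
    effective_subprogram,
    execute,
    execute_matrix,
    program_from_json,
    program_to_json,
    random_program,
    render_program,
    sigmoid,
    trace_execution,
)

from .conftest import C, F, R, chain_program, identity_program

RAND_CONFIG = EvolutionConfig(population_size=10, n_parents=10, n_generations=1,
                              tournament_size=2, max_program_length=30,
                              n_calc_registers=10)


@pytest.mark.parametrize("op,a,b,expected", [
    ("+", 2, 3, 5),
    ("-", 2, 3, -1),
    ("*", 2, 3, 6),
    ("/", 6, 2, 3),
    ("/", 5, 0, 1),            # protected division
    ("/", 5, 1e-12, 1),
    ("^", 2, 3, 8),
    ("^", -2, 3, 8),           # power uses |base|
    ("^", 10, 100, 1e6),       # magnitude clamp
    ("^", 0, -1, 1),           # domain error -> neutral element
])
def test_protected_operators(op, a, b, expected):
    assert apply_operator(op, a, b) == pytest.approx(expected)


@given(st.sampled_from(ARITHMETIC_OPERATORS),
       st.floats(-1e8, 1e8), st.floats(-1e8, 1e8))
@settings(max_examples=200, derandomize=True)
def test_operator_totality(op, a, b):
    """Protected semantics: finite operands always give a finite result."""
    assert np.isfinite(apply_operator(op, a, b))


def test_sigmoid_values():
    assert sigmoid(0.0) == 0.5
    assert sigmoid(1.0039) == pytest.approx(1 / (1 + math.exp(-1.0039)), abs=1e-12)
    assert sigmoid(1000.0) == pytest.approx(1.0)
    assert sigmoid(-1000.0) == pytest.approx(0.0)
    x = np.linspace(-5, 5, 101)
    assert np.all(np.diff(sigmoid(x)) > 0)


class TestWorkedExample:
    """The published 8-instruction trace on m[1-3] = {0.2, 0.01, 0.085}."""

    def test_r0_after_second_instruction(self, worked_example_program,
                                         worked_example_input):
        trace = trace_execution(worked_example_program, worked_example_input)
        assert trace[1]["r0"] == pytest.approx(0.51, abs=1e-12)

    def test_final_output_and_class(self, worked_example_program,
                                    worked_example_input):
        res = execute(worked_example_program, worked_example_input)
        assert round(res.final_output, 4) == 1.0039
        assert res.predicted_class == 1
        assert res.score > 0.5

    def test_false_branch_skips_guarded_chain(self, worked_example_program,
                                              worked_example_input):
        # I4 (r0 > 4) is false, so I5 and the instruction it guards (I6)
        # must not execute; r5 keeps its initial value 1.
        trace = trace_execution(worked_example_program, worked_example_input)
        assert trace[4]["executed"] is False
        assert trace[5]["executed"] is False
        assert 5 not in trace[-1]["registers"]

    def test_all_instructions_effective(self, worked_example_program):
        assert effective_instructions(worked_example_program).all()
        assert effective_features(worked_example_program) == {0, 1, 2}


def test_unassigned_output_register_defaults_to_one():
    prog = Program((Instruction("assign", "+", F(0), C(1), dest=3),),
                   n_features=1, n_calc_registers=4)
    res = execute(prog, [5.0])
    assert res.final_output == 1.0
    assert res.score == pytest.approx(0.7311, abs=1e-4)
    assert res.predicted_class == 1


def test_zero_output_is_classified_case():
    prog = Program((Instruction("assign", "-", F(0), F(0), dest=0),),
                   n_features=1, n_calc_registers=1)
    res = execute(prog, [3.7])
    assert res.final_output == 0.0
    assert res.score == 0.5
    assert res.predicted_class == 1  # boundary: score >= 0.5


def test_intron_detection_simple():
    # r[5] never reaches r[0]: instruction 1 is an intron
    prog = Program((
        Instruction("assign", "+", F(0), F(1), dest=5),
        Instruction("assign", "*", R(4), C(2), dest=0),
    ), n_features=2, n_calc_registers=6)
    mask = effective_instructions(prog)
    assert list(mask) == [False, True]
    assert effective_features(prog) == set()


def test_program_without_feature_operands_has_no_effective_features():
    prog = Program((Instruction("assign", "+", R(1), C(2), dest=0),),
                   n_features=4, n_calc_registers=2)
    assert effective_features(prog) == set()


def test_dangling_trailing_branch_is_noop_and_ineffective():
    prog = Program((
        Instruction("assign", "+", F(0), C(1), dest=0),
        Instruction("branch", "<", F(0), C(5)),
    ), n_features=1, n_calc_registers=1)
    assert list(effective_instructions(prog)) == [True, False]
    assert execute(prog, [2.0]).final_output == 3.0


def test_branch_skip_law():
    """Prefixing an instruction with a branch that is false on a given
    input equals deleting that instruction on that input."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        prog = random_program(RAND_CONFIG, 5, rng)
        x = rng.normal(size=5)
        pos = int(rng.integers(len(prog)))
        target = prog.instructions[pos]
        if target.kind == "branch":
            continue
        # f0 < f0 is false on every input
        false_branch = Instruction("branch", "<", F(0), F(0))
        guarded = Program(prog.instructions[:pos] + (false_branch,)
                          + prog.instructions[pos:], 5, prog.n_calc_registers)
        deleted = Program(prog.instructions[:pos] + prog.instructions[pos + 1:],
                          5, prog.n_calc_registers)
        assert execute(guarded, x).final_output == execute(deleted, x).final_output


def test_intron_removal_preserves_semantics_sampled():
    rng = np.random.default_rng(3)
    for _ in range(30):
        prog = random_program(RAND_CONFIG, 6, rng)
        X = rng.normal(size=(20, 6)) * 3
        full = execute_matrix(prog, X)
        sub = execute_matrix(effective_subprogram(prog), X)
        np.testing.assert_array_equal(full, sub)


def test_scalar_and_vectorized_interpreters_agree():
    rng = np.random.default_rng(11)
    for _ in range(30):
        prog = random_program(RAND_CONFIG, 4, rng)
        x = rng.normal(size=4) * 2
        trace = trace_execution(prog, x)
        final_scalar = trace[-1]["r0"] if trace else 1.0
        assert execute(prog, x).final_output == final_scalar


def test_random_program_invariant_sweep():
    rng = np.random.default_rng(0)
    constants = set(RAND_CONFIG.constant_set)
    for _ in range(2000):
        prog = random_program(RAND_CONFIG, 7, rng)
        assert 1 <= len(prog) <= RAND_CONFIG.max_program_length
        for ins in prog.instructions:
            if ins.kind == "assign":
                assert 0 <= ins.dest < RAND_CONFIG.n_calc_registers
                assert ins.op in ARITHMETIC_OPERATORS
            else:
                assert ins.op in ("<", ">")
            for opd in (ins.lhs, ins.rhs):
                if opd.kind == "const":
                    assert opd.value in constants
                elif opd.kind == "feat":
                    assert 0 <= opd.index < 7


def test_random_program_deterministic_under_seed():
    p1 = random_program(RAND_CONFIG, 5, np.random.default_rng(123))
    p2 = random_program(RAND_CONFIG, 5, np.random.default_rng(123))
    assert program_to_json(p1) == program_to_json(p2)


def test_json_roundtrip_exact(worked_example_program):
    rng = np.random.default_rng(5)
    for prog in [worked_example_program] + [random_program(RAND_CONFIG, 5, rng)
                                            for _ in range(10)]:
        back = program_from_json(program_to_json(prog))
        assert back == prog


def test_render_pseudocode(worked_example_program):
    text = render_program(worked_example_program, ["m1", "m2", "m3"])
    lines = text.splitlines()
    assert lines[0] == "if m1 > m3"
    assert lines[1].startswith("  r[0] = m2 + 0.5")
    assert len(lines) == 8


def test_program_validation_rejects_bad_indices():
    with pytest.raises(ValueError):
        Program((Instruction("assign", "+", F(5), C(1), dest=0),),
                n_features=3, n_calc_registers=2)
    with pytest.raises(ValueError):
        Program((Instruction("assign", "+", F(0), C(1), dest=9),),
                n_features=3, n_calc_registers=2)


def test_conditionally_guarded_write_keeps_prior_definition_effective():
    # r0 is written unconditionally (I1) then maybe overwritten under a
    # branch (I2-I3); the conservative rule must keep I1 effective.
    prog = Program((
        Instruction("assign", "+", F(0), C(1), dest=0),   # I1
        Instruction("branch", ">", F(1), C(2)),           # I2
        Instruction("assign", "*", F(1), C(3), dest=0),   # I3
    ), n_features=2, n_calc_registers=1)
    assert effective_instructions(prog).all()
    # branch false: I1's value survives
    assert execute(prog, [4.0, 0.0]).final_output == 5.0
    # branch true: I3 overwrites
    assert execute(prog, [4.0, 3.0]).final_output == 9.0
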