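import numpy as np
import pandas as pd
import pytest

from lgpnet.evolution import EvolutionConfig
from lgpnet.lgp_core import Instruction, Operand, Program
from lgpnet.synthetic_data import Dataset


def F(i):
    return Operand("feat", i)


def R(i):
    return Operand("calc", i)


def C(v):
    return Operand("const", float(v))


@pytest.fixture
def worked_example_program():
    """The published 8-instruction example: three feature registers
    (metabolites m1-m3), calculation registers r[0], r[4], r[5]."""
    return Program((
        Instruction("branch", ">", F(0), F(2)),            # I1: if m1 > m3
        Instruction("assign", "+", F(1), C(0.5), dest=0),  # I2:   r0 = m2 + 0.5
        Instruction("assign", "/", F(1), R(0), dest=4),    # I3: r4 = m2 / r0
        Instruction("branch", ">", R(0), C(4)),            # I4: if r0 > 4
        Instruction("branch", "<", F(2), C(10)),           # I5:   if m3 < 10
        Instruction("assign", "-", F(2), R(4), dest=5),    # I6:     r5 = m3 - r4
        Instruction("assign", "*", R(4), F(0), dest=4),    # I7: r4 = r4 * m1
        Instruction("assign", "+", R(5), R(4), dest=0),    # I8: r0 = r5 + r4
    ), n_features=3, n_calc_registers=6)


@pytest.fixture
def worked_example_input():
    return [0.2, 0.01, 0.085]


@pytest.fixture
def small_config():
    """Reduced-effort evolutionary settings for fast tests."""
    return EvolutionConfig(population_size=20, n_parents=20, n_generations=5,
                           tournament_size=4, max_program_length=10,
                           n_calc_registers=6)


def identity_program(feature_idx, n_features, n_calc=6):
    """Program whose output is just one feature value: r0 = f * 1."""
    return Program((Instruction("assign", "*", F(feature_idx), C(1), dest=0),),
                   n_features=n_features, n_calc_registers=n_calc)


def chain_program(feature_indices, n_features, n_calc=6):
    """Program whose effective features are exactly *feature_indices*:
    r0 = f_a * 1; r0 = r0 + f_b; r0 = r0 + f_c; ..."""
    idx = list(feature_indices)
    ins = [Instruction("assign", "*", F(idx[0]), C(1), dest=0)]
    for i in idx[1:]:
        ins.append(Instruction("assign", "+", R(0), F(i), dest=0))
    return Program(tuple(ins), n_features=n_features, n_calc_registers=n_calc)


@pytest.fixture
def toy_dataset():
    """Linearly separable one-signal dataset: label = (first feature > 0)."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 3))
    y = (X[:, 0] > 0).astype(int)
    idx = pd.Index([f"S{i:03d}" for i in range(len(y))], name="sample_id")
    return Dataset(pd.DataFrame(X, index=idx, columns=["A", "B", "C"]),
                   pd.Series(y, index=idx, name="label"))
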