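"""Register-machine program representation and execution semantics.

A classifier is an imperative program over a register file: read-only
feature registers (one per input metabolite), writable calculation
registers initialized to 1.0, and literal constants.  Instructions are
either assignments ``r[d] = lhs OP rhs`` or conditional branches
``if lhs CMP rhs`` that guard the single following instruction — a chain
of consecutive branches guards the one instruction after the chain, and
every condition in the chain must hold for it to execute.

The final value of the designated output register ``r[0]`` is passed
through a logistic sigmoid; samples scoring at least 0.5 are predicted
as class one (case).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ARITHMETIC_OPERATORS",
    "COMPARATORS",
    "Operand",
    "Instruction",
    "Program",
    "ExecutionResult",
    "apply_operator",
    "sigmoid",
    "execute",
    "execute_matrix",
    "trace_execution",
    "effective_instructions",
    "effective_subprogram",
    "effective_features",
    "random_program",
    "random_instruction",
    "program_to_json",
    "program_from_json",
    "render_program",
]

ARITHMETIC_OPERATORS = ("+", "-", "*", "/", "^")
COMPARATORS = ("<", ">")

#: denominators below this magnitude trigger protected division
DIV_EPS = 1e-9
#: magnitude cap for the protected power operator
POW_CAP = 1e6


@dataclass(frozen=True, slots=True)
class Operand:
    """A source of a value: a feature register, a calculation register,
    or a literal constant."""

    kind: str  # "feat" | "calc" | "const"
    value: float  # register index (int) or constant value

    def __post_init__(self) -> None:
        if self.kind not in ("feat", "calc", "const"):
            raise ValueError(f"unknown operand kind {self.kind!r}")

    @property
    def index(self) -> int:
        return int(self.value)


@dataclass(frozen=True, slots=True)
class Instruction:
    """One line of a program.

    ``kind == "assign"``: ``r[dest] = lhs op rhs`` where *op* is an
    arithmetic operator and *dest* indexes a calculation register.
    ``kind == "branch"``: ``if lhs op rhs`` where *op* is a comparator;
    *dest* is unused (kept -1).
    """

    kind: str  # "assign" | "branch"
    op: str
    lhs: Operand
    rhs: Operand
    dest: int = -1

    def __post_init__(self) -> None:
        if self.kind == "assign":
            if self.op not in ARITHMETIC_OPERATORS:
                raise ValueError(f"bad assignment operator {self.op!r}")
            if self.dest < 0:
                raise ValueError("assignment destination must be a calculation register")
        elif self.kind == "branch":
            if self.op not in COMPARATORS:
                raise ValueError(f"bad comparator {self.op!r}")
        else:
            raise ValueError(f"unknown instruction kind {self.kind!r}")

    def operands(self) -> tuple[Operand, Operand]:
        return (self.lhs, self.rhs)


@dataclass(frozen=True)
class Program:
    """An ordered instruction sequence plus its register-file shape.

    ``r[0]`` (calculation register 0) is the output register.  All
    calculation registers start at 1.0 on every execution.
    """

    instructions: tuple[Instruction, ...]
    n_features: int
    n_calc_registers: int = 150

    def __post_init__(self) -> None:
        object.__setattr__(self, "instructions", tuple(self.instructions))
        for i, ins in enumerate(self.instructions):
            if ins.kind == "assign" and not (0 <= ins.dest < self.n_calc_registers):
                raise ValueError(f"instruction {i}: destination {ins.dest} out of range")
            for opd in ins.operands():
                if opd.kind == "feat" and not (0 <= opd.index < self.n_features):
                    raise ValueError(f"instruction {i}: feature index {opd.index} out of range")
                if opd.kind == "calc" and not (0 <= opd.index < self.n_calc_registers):
                    raise ValueError(f"instruction {i}: register index {opd.index} out of range")

    def __len__(self) -> int:
        return len(self.instructions)


@dataclass(frozen=True, slots=True)
class ExecutionResult:
    final_output: float
    score: float
    predicted_class: int


def sigmoid(x):
    """Standard logistic function 1/(1+e^(-x)), stable for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def apply_operator(op: str, a, b):
    """Apply a protected arithmetic operator elementwise.

    Protection keeps execution total on arbitrary inputs: division by a
    (near-)zero denominator yields 1, and power is computed as |a|**b
    with its magnitude capped at 1e6 and undefined/overflowing cases
    yielding 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if op == "+":
        return a + b
    if op == "-":
        return a - b
    if op == "*":
        return a * b
    if op == "/":
        unsafe = np.abs(b) < DIV_EPS
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.divide(a, np.where(unsafe, 1.0, b))
        return np.where(unsafe, 1.0, out)
    if op == "^":
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            out = np.abs(a) ** b
        out = np.where(np.isfinite(out), out, 1.0)
        return np.minimum(out, POW_CAP)
    raise ValueError(f"unknown operator {op!r}")


def _resolve(opd: Operand, X: np.ndarray, calc: dict[int, np.ndarray], ones: np.ndarray):
    if opd.kind == "feat":
        return X[:, opd.index]
    if opd.kind == "calc":
        return calc.get(opd.index, ones)
    return opd.value


def execute_matrix(program: Program, X: np.ndarray) -> np.ndarray:
    """Run *program* on every row of sample matrix *X* at once.

    Returns the final value of r[0] per sample.  Branch semantics are
    tracked with a per-sample skip mask: a branch whose condition fails
    (or which is itself skipped) marks the following instruction as
    skipped, which propagates through chains of consecutive branches.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != program.n_features:
        raise ValueError(f"expected {program.n_features} features, got {X.shape[1]}")
    n = X.shape[0]
    ones = np.ones(n)
    calc: dict[int, np.ndarray] = {}
    skip = np.zeros(n, dtype=bool)
    for ins in program.instructions:
        a = _resolve(ins.lhs, X, calc, ones)
        b = _resolve(ins.rhs, X, calc, ones)
        if ins.kind == "branch":
            cond = (a < b) if ins.op == "<" else (a > b)
            skip = skip | ~cond
        else:
            new = np.asarray(apply_operator(ins.op, a, b), dtype=float)
            if new.ndim == 0:  # const OP const
                new = np.full(n, float(new))
            if skip.any():
                calc[ins.dest] = np.where(skip, calc.get(ins.dest, ones), new)
            else:
                calc[ins.dest] = new
            skip = np.zeros(n, dtype=bool)
    return np.array(calc.get(0, ones), dtype=float, copy=True)


def execute(program: Program, features: Sequence[float]) -> ExecutionResult:
    """Run *program* on one sample and classify it.

    predicted_class is 1 iff the sigmoid score is >= 0.5, i.e. iff the
    final r[0] is >= 0.
    """
    out = float(execute_matrix(program, np.asarray(features, dtype=float)[None, :])[0])
    score = sigmoid(out)
    return ExecutionResult(final_output=out, score=score, predicted_class=int(score >= 0.5))


def trace_execution(program: Program, features: Sequence[float]) -> list[dict]:
    """Scalar interpreter returning a per-instruction trace.

    Each record holds the instruction index, whether it executed, and a
    snapshot of all touched calculation registers after the step.  Used
    for inspecting small programs; the vectorized path is authoritative
    for fitness evaluation and the two must agree (tested).
    """
    x = np.asarray(features, dtype=float)
    calc: dict[int, float] = {}

    def val(opd: Operand) -> float:
        if opd.kind == "feat":
            return float(x[opd.index])
        if opd.kind == "calc":
            return calc.get(opd.index, 1.0)
        return float(opd.value)

    trace = []
    skip = False
    for i, ins in enumerate(program.instructions):
        executed = not skip
        if ins.kind == "branch":
            if executed:
                a, b = val(ins.lhs), val(ins.rhs)
                cond = (a < b) if ins.op == "<" else (a > b)
                skip = not cond
            # a skipped branch leaves skip=True for its guarded instruction
        else:
            if executed:
                calc[ins.dest] = float(apply_operator(ins.op, val(ins.lhs), val(ins.rhs)))
            skip = False
        trace.append({"index": i, "executed": executed, "registers": dict(calc),
                      "r0": calc.get(0, 1.0)})
    return trace


# ---------------------------------------------------------------------------
# effective-code (intron) analysis


def _chain_target(instructions: Sequence[Instruction], i: int) -> int:
    """Index of the instruction guarded by the branch at *i* (the first
    non-branch after the run of consecutive branches), or len() if the
    chain dangles off the end of the program."""
    j = i + 1
    while j < len(instructions) and instructions[j].kind == "branch":
        j += 1
    return j

def effective_instructions(program: Program) -> np.ndarray:
    """Boolean mask of structurally effective instructions.

    Backward scan from the output register: an assignment is effective
    iff its destination is currently needed; a branch is effective iff
    the instruction its chain guards is effective.  An assignment that
    sits under a branch may not run, so its destination stays needed
    (conservative rule) — this makes the marked subset reproduce the
    full program's final r[0] exactly on every input.
    """
    ins = program.instructions
    n = len(ins)
    eff = np.zeros(n, dtype=bool)
    needed: set[int] = {0}
    for i in range(n - 1, -1, -1):
        it = ins[i]
        if it.kind == "assign":
            if it.dest in needed:
                eff[i] = True
                guarded = i > 0 and ins[i - 1].kind == "branch"
                if not guarded:
                    needed.discard(it.dest)
                for opd in it.operands():
                    if opd.kind == "calc":
                        needed.add(opd.index)
        else:
            j = _chain_target(ins, i)
            if j < n and eff[j]:
                eff[i] = True
                for opd in it.operands():
                    if opd.kind == "calc":
                        needed.add(opd.index)
    # feature operands of effective instructions do not touch `needed`
    return eff


def effective_subprogram(program: Program) -> Program:
    """The program restricted to its effective instructions."""
    mask = effective_instructions(program)
    kept = tuple(ins for ins, m in zip(program.instructions, mask) if m)
    return Program(kept, program.n_features, program.n_calc_registers)


def effective_features(program: Program) -> set[int]:
    """Feature indices referenced by at least one effective instruction
    (branch operands included)."""
    mask = effective_instructions(program)
    feats: set[int] = set()
    for ins, m in zip(program.instructions, mask):
        if m:
            for opd in ins.operands():
                if opd.kind == "feat":
                    feats.add(opd.index)
    return feats


# ---------------------------------------------------------------------------
# random generation


def random_operand(config, n_features: int, rng: np.random.Generator) -> Operand:
    p_feat, p_calc, p_const = config.operand_probs
    u = rng.random()
    if u < p_feat:
        return Operand("feat", int(rng.integers(n_features)))
    if u < p_feat + p_calc:
        return Operand("calc", int(rng.integers(config.n_calc_registers)))
    return Operand("const", float(rng.choice(config.constant_set)))


def random_instruction(config, n_features: int, rng: np.random.Generator) -> Instruction:
    lhs = random_operand(config, n_features, rng)
    rhs = random_operand(config, n_features, rng)
    if rng.random() < config.p_branch:
        return Instruction("branch", str(rng.choice(COMPARATORS)), lhs, rhs)
    dest = int(rng.integers(config.n_calc_registers))
    return Instruction("assign", str(rng.choice(ARITHMETIC_OPERATORS)), lhs, rhs, dest)


def random_program(config, n_features: int, rng: np.random.Generator) -> Program:
    """Uniform-length random program respecting all structural invariants."""
    length = int(rng.integers(1, config.max_program_length + 1))
    ins = tuple(random_instruction(config, n_features, rng) for _ in range(length))
    return Program(ins, n_features, config.n_calc_registers)


# ---------------------------------------------------------------------------
# serialization / rendering


def _operand_to_json(opd: Operand) -> dict:
    return {"type": opd.kind, "value": opd.value}


def _operand_from_json(d: dict) -> Operand:
    return Operand(d["type"], d["value"])


def program_to_json(program: Program) -> dict:
    return {
        "n_features": program.n_features,
        "n_calc_registers": program.n_calc_registers,
        "instructions": [
            {
                "kind": ins.kind,
                "op": ins.op,
                "dest": ins.dest,
                "lhs": _operand_to_json(ins.lhs),
                "rhs": _operand_to_json(ins.rhs),
            }
            for ins in program.instructions
        ],
    }


def program_from_json(d: dict) -> Program:
    ins = tuple(
        Instruction(r["kind"], r["op"], _operand_from_json(r["lhs"]),
                    _operand_from_json(r["rhs"]), r.get("dest", -1))
        for r in d["instructions"]
    )
    return Program(ins, d["n_features"], d.get("n_calc_registers", 150))


def render_program(program: Program, feature_names: Sequence[str] | None = None) -> str:
    """Pseudocode rendering: one instruction per line, branch-guarded
    instructions indented under their chain."""

    def name(opd: Operand) -> str:
        if opd.kind == "feat":
            return feature_names[opd.index] if feature_names else f"f[{opd.index}]"
        if opd.kind == "calc":
            return f"r[{opd.index}]"
        return f"{opd.value:g}"

    lines = []
    depth = 0
    for ins in program.instructions:
        pad = "  " * depth
        if ins.kind == "branch":
            lines.append(f"{pad}if {name(ins.lhs)} {ins.op} {name(ins.rhs)}")
            depth += 1
        else:
            lines.append(f"{pad}r[{ins.dest}] = {name(ins.lhs)} {ins.op} {name(ins.rhs)}")
            depth = 0
    return "\n".join(lines)
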