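"""Constraint mini-language: parse hypothesis strings into linear systems.

A hypothesis restricts the regression coefficients through equality and
strict-inequality constraints,

    H_t:  R_E @ beta = r_E   and   R_I @ beta > r_I.

The accepted syntax is a chain of comparisons between terms, e.g.
``"b1 > b2 > b3 > 0"`` or ``"beliefW > (stigma, feminist) = 0"``.  A term
is a coefficient name, a numeric literal, a parenthesised group of names,
or a difference of two such items (``"b1 - b2 > 0.2"``).  Comparisons bind
*adjacent* terms only, so ``"a = b = c > 0"`` yields the equality rows
a - b = 0 and b - c = 0 plus the single inequality row c > 0.  ``"<"`` is
normalised to ``">"`` by mirroring.  Several hypotheses are separated by
semicolons at a higher level (see :mod:`reghyp.report`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "ConstraintSystem",
    "HypothesisError",
    "parse_hypotheses",
    "exploratory_hypotheses",
    "check_feasibility",
    "render_system",
]

_FEAS_TOL = 1e-9


class HypothesisError(ValueError):
    """Raised for malformed, unknown-name, or infeasible hypotheses."""


@dataclass
class ConstraintSystem:
    """One hypothesis as augmented equality/inequality systems.

    ``R_E`` rows are linearly independent (redundant rows are dropped at
    parse time); ``R_I`` rows are kept verbatim even when redundant —
    rank handling downstream decides between the analytic and Monte
    Carlo probability paths.
    """

    R_E: np.ndarray
    r_E: np.ndarray
    R_I: np.ndarray
    r_I: np.ndarray
    label: str = ""
    source: str = ""
    coef_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.R_E = np.atleast_2d(np.asarray(self.R_E, dtype=float))
        self.R_I = np.atleast_2d(np.asarray(self.R_I, dtype=float))
        k = max(self.R_E.shape[1], self.R_I.shape[1])
        if self.R_E.size == 0:
            self.R_E = np.empty((0, k))
        if self.R_I.size == 0:
            self.R_I = np.empty((0, k))
        self.r_E = np.asarray(self.r_E, dtype=float).reshape(self.R_E.shape[0])
        self.r_I = np.asarray(self.r_I, dtype=float).reshape(self.R_I.shape[0])
        if self.R_E.shape[1] != self.R_I.shape[1]:
            raise HypothesisError("R_E and R_I disagree on the number of coefficients")
        if self.q_E + self.q_I < 1:
            raise HypothesisError("hypothesis contains no constraints")

    @property
    def k(self) -> int:
        return self.R_E.shape[1]

    @property
    def q_E(self) -> int:
        return self.R_E.shape[0]

    @property
    def q_I(self) -> int:
        return self.R_I.shape[0]


# --- tokenizer -------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<name>@N\d+@)|(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+)"
    r"|(?P<op>[<>=(),&\-]))"
)


def _tokenize(text: str, coef_names: list[str]) -> list[tuple[str, object]]:
    """Tokenize after replacing coefficient names with sentinels.

    Names are substituted longest-first so that names containing special
    characters — e.g. ``(Intercept)`` — survive tokenization intact.
    """
    for i, name in sorted(
        enumerate(coef_names), key=lambda t: len(t[1]), reverse=True
    ):
        text = text.replace(name, f"@N{i}@")
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise HypothesisError(
                f"cannot read hypothesis at {text[pos:].strip()!r}; "
                f"valid coefficient names are {coef_names}"
            )
        pos = m.end()
        if m.group("name"):
            tokens.append(("name", int(m.group("name")[2:-1])))
        elif m.group("num"):
            tokens.append(("num", float(m.group("num"))))
        else:
            tokens.append(("op", m.group("op")))
    return tokens


# --- parser ----------------------------------------------------------------

class _Term:
    """A list of (coefficient-vector, constant) affine atoms.

    Groups carry several atoms; plain names and numbers carry one.
    """

    def __init__(self, atoms):
        self.atoms = atoms  # list of (vec, const)


class _Parser:
    def __init__(self, tokens, k):
        self.tokens = tokens
        self.k = k
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def _atom(self):
        kind, val = self.take()
        sign = 1.0
        if kind == "op" and val == "-":  # unary minus
            kind, val = self.take()
            sign = -1.0
        if kind == "name":
            vec = np.zeros(self.k)
            vec[val] = sign
            return [(vec, 0.0)]
        if kind == "num":
            return [(np.zeros(self.k), sign * val)]
        if kind == "op" and val == "(":
            atoms = []
            while True:
                atoms.extend(self._atom())
                kind, val = self.take()
                if kind == "op" and val == ",":
                    continue
                if kind == "op" and val == ")":
                    break
                raise HypothesisError("malformed group: expected ',' or ')'")
            return atoms
        raise HypothesisError("expected a coefficient name, number, or group")

    def term(self) -> _Term:
        atoms = self._atom()
        # optional single subtraction: "b1 - b2" as one linear term
        if self.peek() == ("op", "-"):
            self.take()
            rights = self._atom()
            if len(atoms) != 1 or len(rights) != 1:
                raise HypothesisError("subtraction of groups is not supported")
            (v1, c1), (v2, c2) = atoms[0], rights[0]
            atoms = [(v1 - v2, c1 - c2)]
        return _Term(atoms)

    def comparison_chain(self):
        terms = [self.term()]
        ops = []
        while self.peek()[0] == "op" and self.peek()[1] in "<>=":
            ops.append(self.take()[1])
            terms.append(self.term())
        if not ops:
            raise HypothesisError("hypothesis contains no comparator (<, >, =)")
        return terms, ops

    def chains(self):
        """Chains joined by '&' — all constraints belong to one hypothesis."""
        out = [self.comparison_chain()]
        while self.peek() == ("op", "&"):
            self.take()
            out.append(self.comparison_chain())
        if self.pos < len(self.tokens):
            raise HypothesisError("trailing input after hypothesis")
        return out


def _independent_equalities(rows, rhs):
    """Drop linearly dependent equality rows, checking consistency."""
    kept_R, kept_r = [], []
    for vec, c in zip(rows, rhs):
        if not np.any(np.abs(vec) > 1e-12):
            if abs(c) > 1e-12:
                raise HypothesisError(f"contradictory constant equality 0 = {c:g}")
            continue
        if kept_R:
            A = np.array(kept_R)
            sol, res, *_ = np.linalg.lstsq(A.T, vec, rcond=None)
            if np.allclose(A.T @ sol, vec, atol=1e-10):
                # dependent row: consistent iff implied rhs matches
                if not np.isclose(sol @ np.array(kept_r), c, atol=1e-10):
                    raise HypothesisError(
                        "equality constraints are mutually inconsistent"
                    )
                continue
        kept_R.append(vec)
        kept_r.append(c)
    return kept_R, kept_r


def _parse_single(text: str, coef_names: list[str], label: str) -> ConstraintSystem:
    k = len(coef_names)
    chains = _Parser(_tokenize(text, coef_names), k).chains()
    eq_rows, eq_rhs, in_rows, in_rhs = [], [], [], []
    for terms, ops in chains:
        for left, op, right in zip(terms[:-1], ops, terms[1:]):
            if op == "<":
                left, right = right, left
                op = ">"
            for va, ca in left.atoms:
                for vb, cb in right.atoms:
                    vec, c = va - vb, cb - ca
                    if op == "=":
                        eq_rows.append(vec)
                        eq_rhs.append(c)
                    else:
                        if not np.any(np.abs(vec) > 1e-12):
                            if c < -1e-12:
                                continue  # e.g. 1 > 0: vacuously true
                            raise HypothesisError(
                                f"constant comparison 0 > {c:g} can never hold"
                            )
                        in_rows.append(vec)
                        in_rhs.append(c)
    eq_rows, eq_rhs = _independent_equalities(eq_rows, eq_rhs)
    sys = ConstraintSystem(
        R_E=np.array(eq_rows).reshape(len(eq_rows), k),
        r_E=np.array(eq_rhs),
        R_I=np.array(in_rows).reshape(len(in_rows), k),
        r_I=np.array(in_rhs),
        label=label,
        source=re.sub(r"\s+", "", text),
        coef_names=list(coef_names),
    )
    feasible, _ = check_feasibility(sys)
    if not feasible:
        raise HypothesisError(f"hypothesis {text!r} has an empty interior (infeasible)")
    return sys


def parse_hypotheses(spec: str, coef_names: list[str]) -> list[ConstraintSystem]:
    """Parse a semicolon-separated hypothesis specification.

    Whitespace is ignored.  Each hypothesis becomes one
    :class:`ConstraintSystem`; labels are ``H1``, ``H2``, ...
    """
    if not spec or not spec.strip():
        raise HypothesisError("empty hypothesis specification")
    pieces = [p for p in spec.split(";") if p.strip()]
    if not pieces:
        raise HypothesisError("empty hypothesis specification")
    return [
        _parse_single(piece, coef_names, label=f"H{i + 1}")
        for i, piece in enumerate(pieces)
    ]


def exploratory_hypotheses(
    coef_name: str, coef_names: list[str]
) -> list[ConstraintSystem]:
    """The exhaustive triple {beta < 0, beta = 0, beta > 0} for one coefficient.

    The three regions partition the real line, so no complement is added
    in exploratory mode.
    """
    if coef_name not in coef_names:
        raise HypothesisError(
            f"unknown coefficient {coef_name!r}; valid names are {coef_names}"
        )
    systems = parse_hypotheses(
        f"{coef_name} < 0; {coef_name} = 0; {coef_name} > 0", coef_names
    )
    for sys, tag in zip(systems, ("< 0", "= 0", "> 0")):
        sys.label = f"{coef_name} {tag}"
    return systems


def check_feasibility(sys: ConstraintSystem) -> tuple[bool, np.ndarray | None]:
    """Does a point satisfy all equalities and all inequalities *strictly*?

    Solved as a linear program maximising the minimal inequality slack
    subject to the equalities; feasible iff the optimum slack is positive.
    Returns ``(True, witness)`` or ``(False, None)``.
    """
    k = sys.k
    if sys.q_E:
        # consistency of the equality system alone
        sol, *_ = np.linalg.lstsq(sys.R_E, sys.r_E, rcond=None)
        if not np.allclose(sys.R_E @ sol, sys.r_E, atol=1e-8):
            return False, None
        if sys.q_I == 0:
            return True, sol
    if sys.q_I == 0:
        return True, np.zeros(k)
    # variables (beta, t): maximise t  s.t.  R_I beta - t >= r_I, R_E beta = r_E
    c = np.zeros(k + 1)
    c[-1] = -1.0
    A_ub = np.column_stack([-sys.R_I, np.ones(sys.q_I)])
    b_ub = -sys.r_I
    A_eq = (
        np.column_stack([sys.R_E, np.zeros(sys.q_E)]) if sys.q_E else None
    )
    b_eq = sys.r_E if sys.q_E else None
    bounds = [(None, None)] * k + [(None, 1.0)]
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
    )
    if res.status != 0 or res.x is None:
        return False, None
    slack = res.x[-1]
    if slack <= _FEAS_TOL:
        return False, None
    return True, res.x[:-1]


def _render_row(vec: np.ndarray, rhs: float, op: str, names: list[str]) -> str:
    pos = [names[j] for j in np.flatnonzero(vec > 1e-12)]
    neg = [names[j] for j in np.flatnonzero(vec < -1e-12)]
    if len(pos) > 1 or len(neg) > 1 or not np.all(
        np.isin(np.round(vec[np.abs(vec) > 1e-12], 12), [-1.0, 1.0])
    ):
        raise HypothesisError("row is not renderable as a name difference")
    left = pos[0] if pos else "0"
    if neg:
        left = f"{left} - {neg[0]}"
    return f"{left} {op} {rhs:g}"


def render_system(sys: ConstraintSystem) -> str:
    """Canonical text for a parsed system (one comparison per row).

    Re-parsing the rendered text reproduces the same matrices for systems
    whose rows are differences of unit vectors — i.e. everything the
    parser itself can produce from names, groups and constants.
    """
    names = sys.coef_names or [f"b{i + 1}" for i in range(sys.k)]
    parts = [
        _render_row(vec, rhs, "=", names) for vec, rhs in zip(sys.R_E, sys.r_E)
    ] + [
        _render_row(vec, rhs, ">", names) for vec, rhs in zip(sys.R_I, sys.r_I)
    ]
    return " & ".join(parts)
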