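"""User-facing test orchestration and output formatting.

:func:`run_test` wires the full pipeline — parse hypotheses, route each to
its Bayes factor, add the complement when the specified order regions do
not exhaust coefficient space, and convert Bayes factors into posterior
hypothesis probabilities.  :func:`format_output` renders a result as a
plain-text report (three-decimal rounding) or as JSON with full-precision
values; the two agree field by field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .core import (
    BFTerms,
    TestResult,
    bf_complement,
    bf_matrix,
    compute_bf,
    posterior_probabilities,
)
from .hypotheses import (
    ConstraintSystem,
    HypothesisError,
    check_feasibility,
    exploratory_hypotheses,
    parse_hypotheses,
)
from .model import LinearModelFit, fit_linear_model
from .mvt import DEFAULT_MCREP, ProbEstimate

__all__ = ["TestRequest", "ExploratoryResult", "run_test", "format_output",
           "result_from_json"]


@dataclass
class TestRequest:
    """Everything needed to run one hypothesis test."""

    table: pd.DataFrame | None = None
    formula: str | None = None
    fit: LinearModelFit | None = None
    hyp: str = ""
    prior_probs: Union[str, "np.ndarray", list] = "equal"
    mcrep: int = DEFAULT_MCREP
    seed: int | None = None
    standardize: bool = False
    output_format: str = "text"

    def resolve_fit(self) -> LinearModelFit:
        if self.fit is not None:
            return self.fit
        if self.table is None or self.formula is None:
            raise ValueError("provide either a fitted model or table + formula")
        return fit_linear_model(self.table, self.formula, self.standardize)


@dataclass
class ExploratoryResult:
    """Zero/positive/negative test of every coefficient, including the intercept."""

    coef_names: list[str]
    per_coefficient: dict[str, TestResult] = field(default_factory=dict)
    seed: int | None = None
    mcrep: int = DEFAULT_MCREP


def _spawn_seeds(seed: int | None, count: int) -> list[int | None]:
    if seed is None:
        return [None] * count
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(count)
    ]


def _assert_disjoint_order_regions(systems: list[ConstraintSystem]) -> None:
    """Overlapping order hypotheses make the complement ill-defined.

    Pairwise disjointness of the open polyhedra is decided exactly by a
    linear program: the regions intersect iff the merged inequality
    system has an interior point.
    """
    order_only = [s for s in systems if s.q_E == 0 and s.q_I > 0]
    for i in range(len(order_only)):
        for j in range(i + 1, len(order_only)):
            a, b = order_only[i], order_only[j]
            merged = ConstraintSystem(
                R_E=np.empty((0, a.k)),
                r_E=np.empty(0),
                R_I=np.vstack([a.R_I, b.R_I]),
                r_I=np.concatenate([a.r_I, b.r_I]),
                label="overlap-check",
                coef_names=a.coef_names,
            )
            feasible, _ = check_feasibility(merged)
            if feasible:
                raise HypothesisError(
                    f"order hypotheses {a.label} ({a.source!r}) and {b.label} "
                    f"({b.source!r}) overlap; reformulate them as disjoint "
                    "regions (union estimation is not supported)"
                )


def _resolve_priors(prior_probs, count: int, complement_added: bool) -> np.ndarray:
    if isinstance(prior_probs, str):
        if prior_probs != "equal":
            raise ValueError("prior_probs must be 'equal' or a vector")
        return np.full(count, 1.0 / count)
    priors = np.asarray(prior_probs, dtype=float)
    if priors.size != count:
        hint = (
            " (the automatically added complement hypothesis also needs a prior)"
            if complement_added
            else ""
        )
        raise ValueError(
            f"{priors.size} prior probabilities for {count} hypotheses{hint}"
        )
    return priors / priors.sum()


def _confirmatory(fit: LinearModelFit, req: TestRequest) -> TestResult:
    systems = parse_hypotheses(req.hyp, fit.coef_names)
    _assert_disjoint_order_regions(systems)
    seeds = _spawn_seeds(req.seed, len(systems))
    terms: list[BFTerms] = []
    for sys, s in zip(systems, seeds):
        try:
            terms.append(compute_bf(fit, sys, mcrep=req.mcrep, seed=s))
        except Exception as exc:
            raise type(exc)(f"hypothesis {sys.label} ({sys.source!r}): {exc}") from exc
    order_terms = [
        t for t, s in zip(terms, systems) if s.q_E == 0 and s.q_I > 0
    ]
    complement = bf_complement(order_terms)
    complement_added = complement is not None
    if complement_added:
        complement.source = f"Not H1-H{len(systems)}"
        terms = [*terms, complement]
    priors = _resolve_priors(req.prior_probs, len(terms), complement_added)
    bfs = np.array([t.B for t in terms])
    return TestResult(
        hypotheses=terms,
        posterior_probs=posterior_probabilities(bfs, priors),
        prior_probs=priors,
        bf_matrix=bf_matrix(bfs),
        complement_added=complement_added,
        seed=req.seed,
        mcrep=req.mcrep,
    )


def _exploratory(fit: LinearModelFit, req: TestRequest) -> ExploratoryResult:
    out = ExploratoryResult(coef_names=list(fit.coef_names), seed=req.seed,
                            mcrep=req.mcrep)
    seeds = _spawn_seeds(req.seed, len(fit.coef_names))
    for name, s in zip(fit.coef_names, seeds):
        systems = exploratory_hypotheses(name, fit.coef_names)
        sub_seeds = _spawn_seeds(s, len(systems))
        terms = [
            compute_bf(fit, sys, mcrep=req.mcrep, seed=ss)
            for sys, ss in zip(systems, sub_seeds)
        ]
        bfs = np.array([t.B for t in terms])
        priors = np.full(3, 1 / 3)
        out.per_coefficient[name] = TestResult(
            hypotheses=terms,
            posterior_probs=posterior_probabilities(bfs, priors),
            prior_probs=priors,
            bf_matrix=bf_matrix(bfs),
            complement_added=False,  # the triple is exhaustive
            seed=s,
            mcrep=req.mcrep,
        )
    return out


def run_test(req: TestRequest) -> TestResult | ExploratoryResult:
    """Run a confirmatory test, or an exploratory sweep over all coefficients."""
    if not req.hyp or not req.hyp.strip():
        raise HypothesisError("empty hypothesis specification")
    fit = req.resolve_fit()
    if req.hyp.strip().lower() == "exploratory":
        return _exploratory(fit, req)
    return _confirmatory(fit, req)


# --- formatting ------------------------------------------------------------

def _r3(x: float) -> float:
    """Round half-even to three decimals (display convention)."""
    return float(np.round(x, 3))


def _fmt(x: float | None, width: int = 8) -> str:
    return f"{'NA' if x is None else format(_r3(x), '.3f'):>{width}}"


def _prob_dict(p: ProbEstimate | None):
    if p is None:
        return None
    return {
        "value": p.value,
        "std_error": p.std_error,
        "method": p.method,
        "draws_used": p.draws_used,
    }


def _terms_dict(t: BFTerms):
    return {
        "label": t.label,
        "source": t.source,
        "fE": t.fE,
        "cE": t.cE,
        "fI": _prob_dict(t.fI),
        "cI": _prob_dict(t.cI),
        "B": t.B,
        "ci90": list(t.ci90) if t.ci90 is not None else None,
    }


def _computation_rows(result: TestResult):
    rows = []
    for t, pp in zip(result.hypotheses, result.posterior_probs):
        rows.append(
            {
                "label": t.label,
                "c(E)": t.cE,
                "c(I|E)": t.cI.value if t.cI is not None else None,
                "c": t.c,
                "f(E)": t.fE,
                "f(I|E)": t.fI.value if t.fI is not None else None,
                "f": t.f,
                "B(t,u)": t.B,
                "PP(t)": float(pp),
            }
        )
    return rows


def _result_dict(result: TestResult):
    return {
        "hypotheses": [_terms_dict(t) for t in result.hypotheses],
        "bf_matrix": result.bf_matrix.tolist(),
        "posterior_probs": result.posterior_probs.tolist(),
        "prior_probs": result.prior_probs.tolist(),
        "computation_table": _computation_rows(result),
        "intervals": [
            list(t.ci90) if t.ci90 is not None else None
            for t in result.hypotheses
        ],
        "complement_added": result.complement_added,
        "seed": result.seed,
        "mcrep": result.mcrep,
    }


def _text_confirmatory(result: TestResult) -> str:
    labels = result.labels
    lines = ["Hypotheses:", ""]
    for t in result.hypotheses:
        lines.append(f'  {t.label}: "{t.source}"')
    lines += ["", "Posterior probability of each hypothesis (rounded):", ""]
    for label, pp in zip(labels, result.posterior_probs):
        lines.append(f"  {label}: {_r3(float(pp)):.3f}")
    lines += ["", "BF_matrix:"]
    w = max(9, max(len(f"{_r3(float(v)):.3f}") for v in result.bf_matrix.ravel()) + 2)
    lines.append("      " + "".join(f"{lab:>{w}}" for lab in labels))
    for lab, row in zip(labels, result.bf_matrix):
        lines.append(f"{lab:<6}" + "".join(f"{_r3(float(v)):>{w}.3f}" for v in row))
    lines += ["", "BF_computation:"]
    cols = ["c(E)", "c(I|E)", "c", "f(E)", "f(I|E)", "f", "B(t,u)", "PP(t)"]
    rows = _computation_rows(result)
    w = max(
        9,
        max(
            len(f"{_r3(v):.3f}")
            for row in rows for v in row.values() if isinstance(v, float)
        )
        + 2,
    )
    lines.append("      " + "".join(f"{c:>{w}}" for c in cols))
    for row in rows:
        lines.append(f"{row['label']:<6}" + "".join(_fmt(row[c], w) for c in cols))
    if any(t.ci90 is not None for t in result.hypotheses):
        lines += ["", "BFu_CI:"]
        lines.append("      " + "".join(f"{c:>10}" for c in
                                        ["B(t,u)", "lb.(5%)", "ub.(95%)"]))
        for t in result.hypotheses:
            lb, ub = (t.ci90 if t.ci90 is not None else (None, None))
            lines.append(
                f"{t.label:<6}" + _fmt(t.B, 10) + _fmt(lb, 10) + _fmt(ub, 10)
            )
    return "\n".join(lines) + "\n"


def _text_exploratory(result: ExploratoryResult) -> str:
    lines = [
        "Hypotheses:",
        "",
        '  H1: "X < 0"',
        '  H2: "X = 0"',
        '  H3: "X > 0"',
        "",
        "Posterior probabilities for each variable (rounded),",
        "assuming equal prior probabilities:",
        "",
    ]
    width = max(len(n) for n in result.coef_names) + 2
    lines.append(" " * width + "".join(f"{h:>9}" for h in ("X < 0", "X = 0", "X > 0")))
    for name in result.coef_names:
        probs = result.per_coefficient[name].posterior_probs
        lines.append(
            f"{name:<{width}}" + "".join(f"{_r3(float(p)):>9.3f}" for p in probs)
        )
    return "\n".join(lines) + "\n"


def format_output(result: TestResult | ExploratoryResult, style: str = "text") -> str:
    """Render a result: ``"text"`` (three-decimal report) or ``"json"``."""
    if style == "text":
        if isinstance(result, ExploratoryResult):
            return _text_exploratory(result)
        return _text_confirmatory(result)
    if style == "json":
        if isinstance(result, ExploratoryResult):
            payload = {
                "exploratory": True,
                "coef_names": result.coef_names,
                "results": {
                    name: _result_dict(res)
                    for name, res in result.per_coefficient.items()
                },
                "seed": result.seed,
                "mcrep": result.mcrep,
            }
        else:
            payload = _result_dict(result)
        return json.dumps(payload, indent=2, allow_nan=True)
    raise ValueError(f"unknown output style {style!r}")


def _prob_from_dict(d) -> ProbEstimate | None:
    if d is None:
        return None
    return ProbEstimate(
        value=d["value"], std_error=d["std_error"], method=d["method"],
        draws_used=d["draws_used"],
    )


def _result_from_dict(d) -> TestResult:
    terms = []
    for td in d["hypotheses"]:
        terms.append(
            BFTerms(
                label=td["label"],
                source=td["source"],
                fE=td["fE"],
                cE=td["cE"],
                fI=_prob_from_dict(td["fI"]),
                cI=_prob_from_dict(td["cI"]),
                B=td["B"],
                ci90=tuple(td["ci90"]) if td["ci90"] is not None else None,
            )
        )
    return TestResult(
        hypotheses=terms,
        posterior_probs=np.array(d["posterior_probs"]),
        prior_probs=np.array(d["prior_probs"]),
        bf_matrix=np.array(d["bf_matrix"]),
        complement_added=d["complement_added"],
        seed=d["seed"],
        mcrep=d["mcrep"],
    )


def result_from_json(text: str) -> TestResult | ExploratoryResult:
    """Rebuild a result object from its JSON rendering (lossless)."""
    d = json.loads(text)
    if d.get("exploratory"):
        out = ExploratoryResult(
            coef_names=d["coef_names"], seed=d["seed"], mcrep=d["mcrep"]
        )
        out.per_coefficient = {
            name: _result_from_dict(rd) for name, rd in d["results"].items()
        }
        return out
    return _result_from_dict(d)
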