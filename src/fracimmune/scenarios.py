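"""Config-driven scenarios and the tabular stability/simulation report.

A scenario is a flat YAML mapping whose keys are named after the model
symbols (beta_P, Lambda, c, a, mu, nu, delta, alpha1, alpha2) plus the
initial state (P0, T0) and grid (t_end, h).  Three fixtures ship with the
package — the parameter columns driving the three canonical outcomes:

* ``scenario1`` — immune collapse: E1 (pathogen at carrying capacity) LAS.
* ``scenario2`` — sustained oscillation: E2 exists but fails the sector
  condition; the system orbits a limit cycle.
* ``scenario3`` — chronic coexistence: E2 is LAS and attracts.

All three start from (P0, T0) = (0.3, 0.01).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Union

import pandas as pd
import yaml

from .model import ModelParams, State, equilibria, viability_check
from .orders import RationalOrder
from .solver import qualitative_outcome, simulate
from .stability import StabilityReport, classify, classify_equal_order

__all__ = [
    "ScenarioConfig",
    "ScenarioValidationError",
    "BUILTIN_SCENARIOS",
    "load_scenario",
    "save_scenario",
    "report",
    "Report",
]

BUILTIN_SCENARIOS = ("scenario1", "scenario2", "scenario3")

_RATE_KEYS = ("beta_P", "Lambda", "c", "a", "mu", "nu", "delta")
_ALL_KEYS = _RATE_KEYS + ("alpha1", "alpha2", "P0", "T0", "t_end", "h", "name")


class ScenarioValidationError(ValueError):
    """Raised with one message line per offending config field."""

    def __init__(self, problems: List[str]):
        self.problems = problems
        super().__init__(
            "invalid scenario configuration:\n  " + "\n  ".join(problems)
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters plus initial state and integration grid for one run."""

    name: str
    params: ModelParams
    y0: State
    t_end: float
    h: float

    def to_dict(self) -> Dict[str, object]:
        p = self.params
        return {
            "name": self.name,
            **{key: getattr(p, key) for key in _RATE_KEYS},
            "alpha1": str(p.alpha1),
            "alpha2": str(p.alpha2),
            "P0": self.y0.P,
            "T0": self.y0.T,
            "t_end": self.t_end,
            "h": self.h,
        }


def _validate(raw: Dict[str, object], origin: str) -> ScenarioConfig:
    problems: List[str] = []
    unknown = sorted(set(raw) - set(_ALL_KEYS))
    for key in unknown:
        problems.append(f"unknown key: {key}")
    missing = sorted(set(_ALL_KEYS) - {"name"} - set(raw))
    for key in missing:
        problems.append(f"missing key: {key}")

    def num(key):
        val = raw.get(key)
        if isinstance(val, (int, float)) and math.isfinite(val):
            return float(val)
        if val is not None:
            problems.append(f"{key}: not a finite number ({val!r})")
        return None

    rates = {key: num(key) for key in _RATE_KEYS}
    for key, val in rates.items():
        if val is not None and val <= 0:
            problems.append(f"{key}: must be strictly positive, got {val:g}")

    orders = {}
    for key in ("alpha1", "alpha2"):
        val = raw.get(key)
        if val is None:
            continue
        try:
            orders[key] = RationalOrder.from_value(
                val if not isinstance(val, str) else val
            )
        except (ValueError, TypeError, ZeroDivisionError) as exc:
            problems.append(f"{key}: {exc}")

    y0_vals = {}
    for key in ("P0", "T0"):
        val = num(key)
        if val is not None and val < 0:
            problems.append(f"{key}: initial population must be nonnegative")
        y0_vals[key] = val
    grid = {}
    for key in ("t_end", "h"):
        val = num(key)
        if val is not None and val <= 0:
            problems.append(f"{key}: must be strictly positive")
        grid[key] = val

    if problems:
        raise ScenarioValidationError(problems)

    params = ModelParams(**rates, **orders)
    return ScenarioConfig(
        name=str(raw.get("name", origin)),
        params=params,
        y0=State(y0_vals["P0"], y0_vals["T0"]),
        t_end=grid["t_end"],
        h=grid["h"],
    )


def load_scenario(source: Union[str, os.PathLike]) -> ScenarioConfig:
    """Load a scenario from a builtin name or a YAML config file path."""
    name = str(source)
    if name in BUILTIN_SCENARIOS:
        text = (
            resources.files("fracimmune.data").joinpath(f"{name}.yaml")
            .read_text()
        )
        raw = yaml.safe_load(text)
        return _validate(raw, origin=name)
    with open(source) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ScenarioValidationError(
            [f"config file {source} does not contain a mapping"]
        )
    return _validate(raw, origin=str(source))


def save_scenario(config: ScenarioConfig, path) -> None:
    """Write a scenario as YAML; re-reading reproduces it exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


@dataclass
class Report:
    """Stability/simulation summary of one scenario, tabulated row-wise."""

    scenario: ScenarioConfig
    rows: List[Dict[str, object]]
    reports: Dict[str, StabilityReport]
    outcome: Optional[str] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["expression", "term", "value"])

    def to_text(self) -> str:
        width = max(len(str(r["expression"])) for r in self.rows)
        lines = [f"Scenario: {self.scenario.name}"]
        for r in self.rows:
            lines.append(f"{r['expression']:<{width}}  {r['value']}")
        return "\n".join(lines)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


def _fmt_angle(a: float) -> str:
    return f"{a:.4f}"


def report(
    config: ScenarioConfig,
    include_simulation: bool = False,
    window: float = 50.0,
) -> Report:
    """Full analysis of one scenario, in the order of the summary table.

    Every value is recomputed from the configuration: equilibria and
    their existence conditions, A1/A2, the common-denominator multiple m,
    the E2 characteristic polynomial with its roots and root angles, the
    stability verdicts, and (optionally) the simulated qualitative
    outcome.
    """
    p = config.params
    eqs = equilibria(p)
    e0, e1, e2 = eqs
    rep_e1 = classify(p, e1)
    rep_e2 = classify(p, e2)
    reports = {"E0": classify(p, e0), "E1": rep_e1, "E2": rep_e2}

    rows: List[Dict[str, object]] = []

    def add(expression, term, value):
        rows.append({"expression": expression, "term": term, "value": value})

    viable, margin = viability_check(p)
    add("Immune viability mu/nu > delta", "mu/nu - delta",
        f"{margin:.4f} ({'satisfied' if viable else 'violated'})")
    add("Equilibrium point E1", "E1(Lambda, 0)",
        f"E1({p.Lambda:g}, 0)")
    add("Stability condition of E1", "delta/(mu - nu*delta) > Lambda",
        f"{rep_e1.details.get('condition', '')} "
        f"(E1 is {rep_e1.verdict})")
    e2_desc = (
        f"E2({e2.P:.2f}, {e2.T:.2f})"
        if math.isfinite(e2.P)
        else "E2 undefined"
    )
    if not e2.exists_biologically:
        e2_desc += " (biologically meaningless)"
    add("Equilibrium point E2", "E2(P*, T*)", e2_desc)

    if rep_e2.char_poly is not None:
        poly = rep_e2.char_poly
        add("Parameter A1", "1 - P*/Lambda", f"{poly.A1:.4f}")
        add("Parameter A2", "a*P*/(a*P* + 1)", f"{poly.A2:.5f}")
        add("Least common multiple of order denominators", "m", str(poly.m))
        add("Characteristic equation of eigenvalues for E2",
            "det(diag(L^(m a1), L^(m a2)) - J) = 0", poly.format())
        root_strs = [f"{r.real:.4f}{r.imag:+.4f}i" if r.imag else
                     f"{r.real:.4f}" for r in rep_e2.roots]
        add("Eigenvalues for E2", "roots", "; ".join(root_strs))
        add("Angle of eigenvalues for E2", "theta = arg(lambda) [deg]",
            "; ".join(_fmt_angle(a) for a in rep_e2.args_deg))
        add("Stability condition of E2", "|theta_i| > 90/m deg",
            f"min |theta| = {rep_e2.min_abs_arg_deg:.4f} deg vs "
            f"{rep_e2.threshold_deg:.4f} deg (E2 is {rep_e2.verdict})")
    else:
        add("Stability of E2", "", rep_e2.verdict)

    if p.alpha1 == p.alpha2 and e2.exists_biologically:
        eq_rep = classify_equal_order(p)
        reports["E2_equal_order"] = eq_rep
        add("Equal-order trace term", "A1*(A2+1) - 1",
            f"{eq_rep.details['trace_term']:.4f}")
        add("Equal-order Routh-Hurwitz branch", "a1, a2 > 0",
            str(eq_rep.details["routh_hurwitz_LAS"]))
        add("Equal-order half-angle criterion", "arccos(...) > pi*alpha",
            str(eq_rep.details["half_angle_LAS"]))
        add("Equal-order verdict", "|arg z| > alpha*pi/2",
            eq_rep.verdict)

    add("Initial conditions", "(P0, T0)", f"({config.y0.P:g}, {config.y0.T:g})")

    outcome_str = None
    if include_simulation:
        traj = simulate(p, config.y0, config.t_end, config.h)
        outcome = qualitative_outcome(traj, eqs, window=window)
        outcome_str = str(outcome)
        add("Simulated outcome", f"t_end = {config.t_end:g}, h = {config.h:g}",
            outcome_str)

    return Report(scenario=config, rows=rows, reports=reports,
                  outcome=outcome_str)
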